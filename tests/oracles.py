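"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: the local-alignment
oracle is a plain Gotoh dynamic program over an explicitly indexed matrix,
and the motif oracle enumerates every cysteine six-subset with itertools.
"""

from __future__ import annotations

import itertools

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def sw_score_oracle(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Smith-Waterman score with blast-style affine gaps (k-gap = open + k*ext)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - gap_open - gap_extend)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - gap_open - gap_extend)
            s = _B62[a[i - 1]][b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def _overlap(p, q) -> bool:
    return p[0] <= q[-1] and q[0] <= p[-1]


def motif_oracle(protein: str, windows) -> list[tuple[int, ...]]:
    """All valid six-Cys placements by exhaustive enumeration, then the same
    published selection rule: resolve the overlap cluster containing the
    leftmost placement first, preferring smaller span, then leftmost."""
    cys = [i for i, c in enumerate(protein) if c == "C"]
    valid = []
    for combo in itertools.combinations(cys, 6):
        gaps = [combo[k + 1] - combo[k] - 1 for k in range(5)]
        if all(lo <= g <= hi for g, (lo, hi) in zip(gaps, windows)):
            valid.append(combo)
    chosen = []
    remaining = sorted(valid)
    while remaining:
        cluster = {remaining[0]}
        changed = True
        while changed:
            changed = False
            for p in remaining:
                if p not in cluster and any(_overlap(p, q) for q in cluster):
                    cluster.add(p)
                    changed = True
        pick = min(cluster, key=lambda p: (p[-1] - p[0], p[0], p))
        chosen.append(pick)
        remaining = [p for p in remaining if not _overlap(p, pick)]
    return sorted(chosen)


def residue_sum_mass_oracle(seq: str) -> float:
    """Monoisotopic residue-mass sum from an explicit table (independent of
    the package's constants module)."""
    table = {
        "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
        "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
        "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
        "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
        "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
    }
    return sum(table[c] for c in seq)
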