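"""Anchoring precursors onto the consensus coordinate system.

Each candidate is aligned against the reference-bundle alignment treated as a
profile: columns are scored by position-specific residue frequencies (BLOSUM62
averaged over the observed column composition, which also gives a sensible
fallback for residues the bundle never shows), and the six cyclotide-domain
cysteine columns award a large bonus to cysteines so the cystine-knot frame
pins the alignment.  Gap costs are linear and occupancy-scaled: skipping a
column that is mostly gaps in the bundle is nearly free, which is what lets
Moebius-lineage candidates fall through the [-56,-54] and [-50,-38] deletion
windows while bracelet candidates fill them.

The consensus space holds a single cyclotide domain.  Precursors with
repeated NTR+CD units are split at the domain tail (the fixed number of
columns after Cys VI inside the CD block) and every extra repeat is anchored
independently against the NTR..CD sub-profile, reusing the same coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from . import consensus as cns
from .mining import MotifHit, PrecursorCandidate
from .seqio import ReferenceBundle

__all__ = [
    "AnchoredPrecursor",
    "DomainAnnotation",
    "LoopDecomposition",
    "UnanchorableError",
    "anchor_to_profile",
    "segment_domains",
    "decompose_loops",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWYX"
CYS_BONUS = 25.0


class UnanchorableError(ValueError):
    """The CD cysteines cannot be placed on the curated cysteine columns."""


@dataclass
class SegmentAnchor:
    """Alignment of one residue range to (a sub-range of) the profile.

    ``assignment[k]`` describes residue ``res_start + k``: ("match", pos)
    for a consensus position, ("ins", pos) for an insertion after position
    pos (pos None for insertions before the first aligned column).
    """

    res_start: int
    res_end: int
    assignment: list[tuple[str, int | None]]

    def pos_to_index(self) -> dict[int, int]:
        return {
            pos: self.res_start + k
            for k, (kind, pos) in enumerate(self.assignment)
            if kind == "match"
        }


@dataclass
class AnchoredPrecursor:
    precursor_id: str
    protein: str
    segments: list[SegmentAnchor]  # one per NTR+CD repeat; [0] includes ER/NTPP
    gap_positions: set[int]  # consensus positions with no residue (segment 0)
    aligned_span: tuple[int, int]  # first/last matched position of segment 0
    flags: tuple[str, ...] = ()
    motif_hits: tuple[MotifHit, ...] = ()

    @property
    def partial(self) -> bool:
        return "partial" in self.flags

    @property
    def repeat_count(self) -> int:
        return len(self.segments)

    def residue_at(self, pos: int, repeat: int = 0) -> str | None:
        idx = self.segments[repeat].pos_to_index().get(pos)
        return self.protein[idx] if idx is not None else None

    def index_of(self, pos: int, repeat: int = 0) -> int | None:
        return self.segments[repeat].pos_to_index().get(pos)


@dataclass(frozen=True)
class DomainAnnotation:
    er_span: tuple[int, int] | None
    ntpp_span: tuple[int, int] | None
    ntr_spans: tuple[tuple[int, int], ...]
    cd_spans: tuple[tuple[int, int], ...]
    ctr_span: tuple[int, int] | None
    flags: tuple[str, ...] = ()

    @property
    def repeat_count(self) -> int:
        return len(self.cd_spans)


@dataclass(frozen=True)
class LoopDecomposition:
    cys_idx: tuple[int, ...]  # residue indices of Cys I..VI (may be short)
    loops: tuple[str, ...]  # six inter-cysteine segments, loop 6 joined
    nd_site: int | None
    abnormality_flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# profile construction and alignment


class _Profile:
    """Position-specific scores from (optionally sequence-weighted) column
    frequencies.  Row weights let a candidate's nearest curated relatives
    dominate the register, the usual cure for multi-subfamily profiles whose
    averaged columns are ambiguous around indel boundaries."""

    def __init__(self, bundle: ReferenceBundle, weights: Sequence[float] | None = None):
        rows = bundle.alignment_rows
        ncol = len(bundle.column_map)
        aa_index = {a: i for i, a in enumerate(AA_ORDER)}
        if weights is None:
            weights = [1.0] * len(rows)
        wsum = float(sum(weights))
        counts = np.zeros((len(AA_ORDER), ncol))
        for row, w in zip(rows, weights):
            for j, ch in enumerate(row):
                if ch != "-":
                    counts[aa_index.get(ch, aa_index["X"]), j] += w
        occ = counts.sum(axis=0) / wsum
        freq = counts / np.maximum(counts.sum(axis=0), 1)
        blosum = substitution_matrices.load("BLOSUM62")
        B = np.zeros((len(AA_ORDER), len(AA_ORDER)))
        for i, a in enumerate(AA_ORDER):
            for j, b in enumerate(AA_ORDER):
                B[i, j] = blosum[a][b]
        # S[a, col] = expected BLOSUM62 score of residue a against the column
        self.S = B @ freq
        cys_cols = set(bundle.cys_columns())
        for col in cys_cols:
            self.S[aa_index["C"], col] += CYS_BONUS
        self.occupancy = occ
        self.positions = bundle.column_map
        self.aa_index = aa_index
        self.cys_cols = cys_cols


def _align_to_profile(
    protein: str,
    prof: _Profile,
    col_lo: int,
    col_hi: int,
    gap_open: float,
    gap_extend: float,
) -> list[tuple[str, int | None]]:
    """Semi-global alignment of ``protein`` to profile columns [col_lo, col_hi).

    Linear, occupancy-scaled gap costs; free end gaps on both the candidate
    and the profile.  Returns one (kind, consensus position) entry per
    residue.
    """
    cols = list(range(col_lo, col_hi))
    m, n = len(protein), len(cols)
    res_idx = [prof.aa_index.get(a, prof.aa_index["X"]) for a in protein]
    ins_cost = gap_open
    del_cost = [max(gap_extend * 0.3, gap_open * prof.occupancy[c]) for c in cols]
    NEG = -1e9
    H = np.zeros((m + 1, n + 1))
    # free leading gaps on both sides
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 up(ins), 3 left(del)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = prof.S[res_idx[i - 1], cols[j - 1]]
            diag = H[i - 1, j - 1] + s
            up = H[i - 1, j] - ins_cost
            left = H[i, j - 1] - del_cost[j - 1]
            best = max(diag, up, left)
            H[i, j] = best
            ptr[i, j] = 1 if best == diag else (2 if best == up else 3)
    # best end point on the last row or last column
    end_i, end_j, best = m, n, NEG
    for j in range(n + 1):
        if H[m, j] > best:
            best, end_i, end_j = H[m, j], m, j
    for i in range(m + 1):
        if H[i, n] > best:
            best, end_i, end_j = H[i, n], i, n
    assignment: list[tuple[str, int | None]] = [("ins", None)] * m
    i, j = end_i, end_j
    # trailing unaligned residues are insertions after the last matched column
    trail_pos = prof.positions[cols[end_j - 1]] if end_j > 0 else None
    for k in range(end_i, m):
        assignment[k] = ("ins", trail_pos)
    last_pos: int | None = None
    ops: list[tuple[int, str, int]] = []
    while i > 0 and j > 0 and not (H[i, j] == 0 and ptr[i, j] == 0 and i == 0):
        p = ptr[i, j]
        if p == 1:
            ops.append((i - 1, "match", cols[j - 1]))
            i, j = i - 1, j - 1
        elif p == 2:
            ops.append((i - 1, "ins", cols[j - 1]))
            i -= 1
        elif p == 3:
            j -= 1
        else:
            break
        if i == 0 or j == 0:
            break
    for k in range(i):  # leading unaligned residues
        assignment[k] = ("ins", None)
    prev_pos: int | None = None
    for ri, kind, col in sorted(ops):
        if kind == "match":
            prev_pos = prof.positions[col]
            assignment[ri] = ("match", prev_pos)
        else:
            # insertion recorded against the previous matched position
            assignment[ri] = ("ins", prev_pos)
    _ = last_pos
    return assignment


def _split_repeats(candidate_protein: str, hits: Sequence[MotifHit]) -> list[tuple[int, int]]:
    """Residue ranges of the NTR+CD repeat units, cut after the CD tail."""
    tail = cns.CD_RANGE[1] - cns.CYS_POSITIONS[-1]  # columns after Cys VI in the CD
    bounds: list[tuple[int, int]] = []
    start = 0
    for k, hit in enumerate(hits):
        if k == len(hits) - 1:
            end = len(candidate_protein)
        else:
            end = min(hit.cys_positions[-1] + tail + 1, hits[k + 1].cys_positions[0])
        bounds.append((start, end))
        start = end
    if not bounds:
        bounds = [(0, len(candidate_protein))]
    return bounds


def anchor_to_profile(
    candidate: PrecursorCandidate,
    bundle: ReferenceBundle,
    gap_open: float = 7.0,
    gap_extend: float = 1.0,
) -> AnchoredPrecursor:
    """Map a mined candidate onto consensus coordinates.

    The first repeat (with everything upstream of it) is aligned to the full
    profile; each further NTR+CD unit is aligned to the NTR..CTR sub-profile.
    After alignment the six motif cysteines of every CD must sit on the six
    curated cysteine columns; otherwise the candidate is unanchorable.
    Candidates rescued without a motif hit are anchored without that check
    and keep their abnormality flags.
    """
    from .mining import similarity_score

    # weight rows by prodomain similarity (softmax in score units) so the
    # candidate's own subfamily pins the indel register; the shared ER/NTR/CD
    # would otherwise wash the weights out
    scores = []
    for rid, pseq in bundle.prodomain_sequences():
        s, _ = similarity_score(candidate.protein, [(rid, pseq)])
        scores.append(s)
    smax = max(scores) or 1.0
    temp = 8.0
    weights = [float(np.exp((s - smax) / temp)) for s in scores]
    prof = _Profile(bundle, weights)
    protein = candidate.protein
    hits = sorted(candidate.motif_hits, key=lambda h: h.cys_positions[0])
    bounds = _split_repeats(protein, hits)
    ncol = len(bundle.column_map)
    ntr_col = bundle.column_of_position(cns.NTR_RANGE[0])
    segments: list[SegmentAnchor] = []
    for k, (lo, hi) in enumerate(bounds):
        col_lo = 0 if k == 0 else ntr_col
        seg_prot = protein[lo:hi]
        assignment = _align_to_profile(seg_prot, prof, col_lo, ncol, gap_open, gap_extend)
        segments.append(SegmentAnchor(res_start=lo, res_end=hi, assignment=assignment))
    # cysteine placement check per repeat
    cys_pos = set(cns.CYS_POSITIONS)
    for hit, seg in zip(hits, segments):
        placed = {
            pos
            for k, (kind, pos) in enumerate(seg.assignment)
            if kind == "match" and (seg.res_start + k) in hit.cys_positions
        }
        if placed != cys_pos:
            raise UnanchorableError(
                f"{candidate.orf.transcript_id}: CD cysteines land on consensus "
                f"{sorted(p for p in placed if p is not None)} instead of {sorted(cys_pos)}"
            )
    seg0 = segments[0]
    matched = [pos for kind, pos in seg0.assignment if kind == "match"]
    if not matched:
        raise UnanchorableError(f"{candidate.orf.transcript_id}: nothing aligned")
    span = (min(matched), max(matched))
    covered = set(matched)
    seg0_hi = span[1] if len(segments) == 1 else cns.CD_RANGE[1]
    gap_positions = {
        pos for pos in range(cns.FIRST_POSITION, seg0_hi + 1) if pos not in covered
    }
    flags = list(candidate.flags)
    if span[0] > cns.NTPP_RANGE[0]:
        flags.append("partial")
    return AnchoredPrecursor(
        precursor_id=candidate.orf.transcript_id,
        protein=protein,
        segments=segments,
        gap_positions=gap_positions,
        aligned_span=span,
        flags=tuple(dict.fromkeys(flags)),
        motif_hits=tuple(hits),
    )


# ---------------------------------------------------------------------------
# segmentation and loop decomposition

_DOMAIN_OF_POS = None


def _domain_of(pos: int, repeat: int, is_last: bool) -> str:
    if repeat == 0 and pos <= cns.ER_RANGE[1]:
        return "er"
    if repeat == 0 and pos <= cns.NTPP_RANGE[1]:
        return "ntpp"
    if pos <= cns.NTR_RANGE[1]:
        return f"ntr{repeat}"
    if pos <= cns.CD_RANGE[1]:
        return f"cd{repeat}"
    return "ctr"


def segment_domains(anchored: AnchoredPrecursor) -> DomainAnnotation:
    """Partition the protein into ER/NTPP/NTR(s)/CD(s)/CTR residue spans.

    Every residue is assigned to exactly one domain: matched residues by
    their consensus position, insertions by the domain of the preceding
    matched residue (leading unmatched residues join the first domain).
    """
    n = len(anchored.protein)
    labels: list[str | None] = [None] * n
    for r, seg in enumerate(anchored.segments):
        is_last = r == len(anchored.segments) - 1
        current = None
        for k, (kind, pos) in enumerate(seg.assignment):
            idx = seg.res_start + k
            if kind == "match":
                current = _domain_of(pos, r, is_last)
            labels[idx] = current
        # leading insertions inherit the first real label of the segment
        first = next((l for l in labels[seg.res_start : seg.res_end] if l), None)
        for idx in range(seg.res_start, seg.res_end):
            if labels[idx] is None:
                labels[idx] = first
            else:
                break
    order: list[str] = []
    spans: dict[str, tuple[int, int]] = {}
    for idx, lab in enumerate(labels):
        lab = lab or "er"
        if lab not in spans:
            spans[lab] = (idx, idx + 1)
            order.append(lab)
        else:
            s, e = spans[lab]
            if idx != e:
                raise ValueError(f"domain {lab} is not contiguous")
            spans[lab] = (s, idx + 1)
    reps = len(anchored.segments)
    ntr_spans = tuple(spans[f"ntr{r}"] for r in range(reps) if f"ntr{r}" in spans)
    cd_spans = tuple(spans[f"cd{r}"] for r in range(reps) if f"cd{r}" in spans)
    if len(cd_spans) > 1:
        for (s1, e1), (s2, e2) in zip(cd_spans, cd_spans[1:]):
            if e1 > s2:
                raise ValueError("overlapping cyclotide domains")
    return DomainAnnotation(
        er_span=spans.get("er"),
        ntpp_span=spans.get("ntpp"),
        ntr_spans=ntr_spans,
        cd_spans=cd_spans,
        ctr_span=spans.get("ctr"),
        flags=anchored.flags,
    )


def decompose_loops(anchored: AnchoredPrecursor, cd_index: int = 0) -> LoopDecomposition:
    """Split one cyclotide domain into its six inter-cysteine loops.

    Loop 6 joins the residues after Cys VI (up to the domain end) with those
    from the domain start up to Cys I, mirroring the cyclic backbone.  The
    N/D cyclization site is the residue on the consensus loop-6 N/D column
    when it is N or D, otherwise the last N/D in loop 6; domains with a
    number of cysteines other than six are decomposed over the aligned
    cysteine columns only and flagged, never rejected.
    """
    if not 0 <= cd_index < len(anchored.segments):
        raise IndexError(f"cd_index {cd_index} out of range")
    seg = anchored.segments[cd_index]
    p2i = seg.pos_to_index()
    domains = segment_domains(anchored)
    cd_span = domains.cd_spans[cd_index] if cd_index < len(domains.cd_spans) else None
    if cd_span is None:
        raise ValueError("no cyclotide domain span for this repeat")
    cys_idx = tuple(p2i[p] for p in cns.CYS_POSITIONS if p in p2i)
    flags: list[str] = []
    cd_seq = anchored.protein[cd_span[0] : cd_span[1]]
    if cd_seq.count("C") != 6 or len(cys_idx) != 6:
        flags.append("uneven_cysteines")
    loops: list[str] = []
    for a, b in zip(cys_idx, cys_idx[1:]):
        loops.append(anchored.protein[a + 1 : b])
    while len(loops) < 5:
        loops.append("")
    if cys_idx:
        tail = anchored.protein[cys_idx[-1] + 1 : cd_span[1]]
        head = anchored.protein[cd_span[0] : cys_idx[0]]
    else:
        tail, head = "", cd_seq
    loop6 = tail + head
    loops.append(loop6)
    nd_site: int | None = None
    nd_idx = p2i.get(cns.ND_POSITION)
    if nd_idx is not None and anchored.protein[nd_idx] in "ND":
        nd_site = nd_idx
    else:
        for idx in range(cd_span[1] - 1, (cys_idx[-1] if cys_idx else cd_span[0]), -1):
            if anchored.protein[idx] in "ND":
                nd_site = idx
                break
    if nd_site is None:
        flags.append("missing_ND")
    # loop-length sanity against the scan windows (loops 1..5)
    from .mining import DEFAULT_LOOP_WINDOWS

    for (lo, hi), loop in zip(DEFAULT_LOOP_WINDOWS, loops[:5]):
        if not lo <= len(loop) <= hi:
            flags.append("aberrant_loop_length")
            break
    return LoopDecomposition(
        cys_idx=cys_idx, loops=tuple(loops), nd_site=nd_site,
        abnormality_flags=tuple(dict.fromkeys(flags)),
    )
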