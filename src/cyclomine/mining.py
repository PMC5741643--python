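"""Mining cyclotide-precursor ORFs from assembled transcripts.

The search stage combines a cysteine-spacing motif scan (six cysteines whose
five internal loops fall inside configurable length windows, the hallmark of
the cystine-knot domain) with Smith-Waterman local-alignment similarity
against known mature cyclotides and curated precursor prodomains.  ORFs are
maximal stop-to-stop stretches in all six reading frames, so 5'-truncated
assemblies still surface partial precursors.  Precursors with five or seven
cysteines have no valid six-cysteine placement; they are rescued by the
similarity filter alone and flagged abnormal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .seqio import ReferenceBundle, SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "OrfCandidate",
    "MotifHit",
    "PrecursorCandidate",
    "MiningParams",
    "six_frame_orfs",
    "scan_cd_motif",
    "similarity_score",
    "mine_precursors",
    "DEFAULT_LOOP_WINDOWS",
]

# inclusive loop-length windows for loops 1..5; loop 6 spans the domain
# boundary and is unconstrained at scan time
DEFAULT_LOOP_WINDOWS: tuple[tuple[int, int], ...] = ((2, 7), (3, 6), (2, 8), (1, 2), (3, 6))


@dataclass(frozen=True)
class OrfCandidate:
    transcript_id: str
    frame: int  # +1..+3, -1..-3
    nt_span: tuple[int, int]  # 0-based half-open on the forward strand
    protein: str

    def __post_init__(self) -> None:
        if "*" in self.protein:
            raise ValueError("ORF protein must not contain a stop symbol")
        if self.nt_span[1] - self.nt_span[0] != 3 * len(self.protein):
            raise ValueError("nt_span length must be 3x protein length")


@dataclass(frozen=True)
class MotifHit:
    cys_positions: tuple[int, int, int, int, int, int]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.cys_positions, self.cys_positions[1:])):
            raise ValueError("cysteine positions must be strictly increasing")

    @property
    def loop_lengths(self) -> tuple[int, ...]:
        c = self.cys_positions
        return tuple(c[k + 1] - c[k] - 1 for k in range(5))

    @property
    def span(self) -> tuple[int, int]:
        """Half-open residue interval covering Cys I..VI."""
        return (self.cys_positions[0], self.cys_positions[-1] + 1)


@dataclass
class PrecursorCandidate:
    orf: OrfCandidate
    motif_hits: tuple[MotifHit, ...]
    similarity: float
    best_ref: str
    prodomain_similarity: float = 0.0
    passed_filters: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()
    provenance: tuple[str, ...] = ()  # transcript ids carrying this protein

    @property
    def protein(self) -> str:
        return self.orf.protein


@dataclass(frozen=True)
class MiningParams:
    min_orf_len: int = 40
    min_transcript_len: int = 200
    loop_windows: tuple[tuple[int, int], ...] = DEFAULT_LOOP_WINDOWS
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    # calibrated: smallest integer exceeding the best shuffled-decoy score
    # (composition-preserving shuffles of the bundled references scored
    # against that same reference set; 10,000 mature / 5,000 prodomain)
    min_similarity: float = 67.0
    min_prodomain_similarity: float = 65.0
    rescue_min_cys: int = 4


def six_frame_orfs(
    transcript: SequenceRecord,
    min_orf_len: int = 40,
    min_transcript_len: int = 200,
) -> list[OrfCandidate]:
    """Maximal stop-to-stop ORFs in all six frames, standard codon table.

    Transcripts shorter than ``min_transcript_len`` nucleotides yield
    nothing.  N-containing codons translate to X.  ORFs are not anchored at
    ATG: truncated assemblies retain partial precursors.
    """
    if transcript.alphabet != "nucleotide":
        raise ValueError(f"{transcript.id}: six_frame_orfs needs a nucleotide record")
    if min_orf_len < 1:
        raise ValueError("min_orf_len must be >= 1")
    seq = transcript.residues
    n = len(seq)
    if n < min_transcript_len:
        return []
    out: list[OrfCandidate] = []
    for strand in (+1, -1):
        work = seq if strand > 0 else str(Seq(seq).reverse_complement())
        for off in range(3):
            frame = strand * (off + 1)
            usable = (len(work) - off) // 3 * 3
            if usable < 3:
                continue
            protein = str(Seq(work[off : off + usable]).translate())
            start = 0
            for chunk in protein.split("*"):
                if len(chunk) >= min_orf_len:
                    aa_start = start
                    w0 = off + 3 * aa_start  # on `work` strand
                    w1 = w0 + 3 * len(chunk)
                    if strand > 0:
                        span = (w0, w1)
                    else:
                        span = (n - w1, n - w0)
                    out.append(
                        OrfCandidate(
                            transcript_id=transcript.id, frame=frame,
                            nt_span=span, protein=chunk,
                        )
                    )
                start += len(chunk) + 1  # past the stop
    return out


def _valid_placements(
    protein: str, loop_windows: Sequence[tuple[int, int]]
) -> list[tuple[int, ...]]:
    """All strictly increasing six-Cys placements whose loops fit the windows."""
    for lo, hi in loop_windows:
        if lo > hi:
            raise ValueError(f"malformed loop window ({lo}, {hi})")
    cys = [i for i, aa in enumerate(protein) if aa == "C"]
    placements: list[tuple[int, ...]] = []

    def extend(chain: list[int], depth: int) -> None:
        if depth == 6:
            placements.append(tuple(chain))
            return
        lo, hi = loop_windows[depth - 1]
        last = chain[-1]
        for c in cys:
            gap = c - last - 1
            if c <= last:
                continue
            if gap > hi:
                break
            if gap >= lo:
                extend(chain + [c], depth + 1)

    for c0 in cys:
        extend([c0], 1)
    return placements


def _overlaps(a: tuple[int, ...], b: tuple[int, ...]) -> bool:
    return a[0] <= b[-1] and b[0] <= a[-1]


def select_placements(placements: list[tuple[int, ...]]) -> list[tuple[int, ...]]:
    """Greedy leftmost-first selection of non-overlapping placements.

    The overlap cluster containing the leftmost-starting remaining placement
    is resolved first; within it the smallest total span wins, ties broken by
    leftmost start then lexicographic cysteine tuple.
    """
    remaining = sorted(placements)
    chosen: list[tuple[int, ...]] = []
    while remaining:
        seedp = remaining[0]
        cluster = {seedp}
        grew = True
        while grew:
            grew = False
            for p in remaining:
                if p not in cluster and any(_overlaps(p, q) for q in cluster):
                    cluster.add(p)
                    grew = True
        pick = min(cluster, key=lambda p: (p[-1] - p[0], p[0], p))
        chosen.append(pick)
        remaining = [p for p in remaining if not _overlaps(p, pick)]
    return sorted(chosen)


def scan_cd_motif(
    protein: str, loop_windows: Sequence[tuple[int, int]] = DEFAULT_LOOP_WINDOWS
) -> list[MotifHit]:
    """Non-overlapping cystine-knot cysteine sextets in scan order."""
    if len(protein) < 6:
        return []
    return [MotifHit(p) for p in select_placements(_valid_placements(protein, loop_windows))]


def _aligner(matrix: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = substitution_matrices.load(matrix)
    # blast convention: a gap of length k costs open + k*extend
    aln.open_gap_score = -(gap_open + gap_extend)
    aln.extend_gap_score = -gap_extend
    return aln


def similarity_score(
    candidate_protein: str,
    refs: Iterable[tuple[str, str]],
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> tuple[float, str]:
    """Best Smith-Waterman score of the candidate over (id, sequence) refs.

    Ties break on lexicographic reference id.  Local alignment scores are
    never negative; a candidate with nothing alignable scores 0.
    """
    if not candidate_protein:
        raise ValueError("empty candidate sequence")
    refs = sorted(refs, key=lambda r: r[0])
    if not refs:
        raise ValueError("reference set is empty")
    aln = _aligner(matrix, gap_open, gap_extend)
    best_score, best_id = 0.0, refs[0][0]
    for rid, rseq in refs:
        score = float(aln.score(candidate_protein, rseq))
        if score > best_score:
            best_score, best_id = score, rid
    return best_score, best_id


def _mature_refs(bundle: ReferenceBundle) -> list[tuple[str, str]]:
    return [(str(r.id), str(r.sequence)) for r in bundle.mature_refs.itertuples()]


def mine_precursors(
    transcripts: Iterable[SequenceRecord],
    bundle: ReferenceBundle,
    params: MiningParams = MiningParams(),
) -> list[PrecursorCandidate]:
    """six_frame_orfs -> scan_cd_motif -> similarity filters, deduplicated.

    A candidate passes if it has at least one motif hit and its mature-
    reference similarity or prodomain similarity clears the corresponding
    threshold; ORFs without a valid six-cysteine placement but with at least
    ``rescue_min_cys`` cysteines are rescued by the same similarity filters
    and flagged ``abnormal_cysteines``.  Exact-duplicate proteins are
    collapsed, keeping every transcript id as provenance.
    """
    mature_refs = _mature_refs(bundle)
    prodomain_refs = bundle.prodomain_sequences()
    by_protein: dict[str, PrecursorCandidate] = {}
    for rec in transcripts:
        for orf in six_frame_orfs(rec, params.min_orf_len, params.min_transcript_len):
            hits = scan_cd_motif(orf.protein, params.loop_windows)
            flags: list[str] = []
            if not hits:
                if orf.protein.count("C") < params.rescue_min_cys:
                    continue
                flags.append("abnormal_cysteines")
            sim, best = similarity_score(
                orf.protein, mature_refs, params.matrix, params.gap_open, params.gap_extend
            )
            pro_sim, _ = similarity_score(
                orf.protein, prodomain_refs, params.matrix, params.gap_open, params.gap_extend
            )
            fired: list[str] = []
            if hits:
                fired.append("motif")
            if sim >= params.min_similarity:
                fired.append("mature_similarity")
            if pro_sim >= params.min_prodomain_similarity:
                fired.append("prodomain_similarity")
            if not ({"mature_similarity", "prodomain_similarity"} & set(fired)):
                logger.debug("drop %s frame %+d: similarity %.1f below threshold",
                             orf.transcript_id, orf.frame, sim)
                continue
            prev = by_protein.get(orf.protein)
            if prev is not None:
                prev.provenance = tuple(dict.fromkeys(prev.provenance + (rec.id,)))
                continue
            by_protein[orf.protein] = PrecursorCandidate(
                orf=orf, motif_hits=tuple(hits), similarity=sim, best_ref=best,
                prodomain_similarity=pro_sim, passed_filters=tuple(fired),
                flags=tuple(flags), provenance=(rec.id,),
            )
    return list(by_protein.values())
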