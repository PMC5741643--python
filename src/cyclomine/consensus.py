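"""The consensus coordinate system shared by the reference bundle, the
anchoring profile and the synthetic generator.

Positions are integers with 0 at the N-terminal cleavage site of the (first)
cyclotide domain; prodomain positions are negative.  Quoted intervals like
[-56, -38] are inclusive on both ends.  The layout used by the shipped
synthetic bundle:

    ER    [-76, -57]   endoplasmic-reticulum signal (excluded from analysis)
    NTPP  [-56, -20]   N-terminal propeptide; indel signature region [-56,-38]
    NTR   [-19,  -1]   N-terminal repeat; series dipeptide at [-9, -8]
    CD    [  0,  30]   cyclotide domain; six Cys at fixed columns, N/D at 30
    CTR   [ 31,  38]   C-terminal tail (absent in linear precursors)
"""

from __future__ import annotations

ER_RANGE = (-76, -57)
NTPP_RANGE = (-56, -20)
NTR_RANGE = (-19, -1)
CD_RANGE = (0, 30)
CTR_RANGE = (31, 38)

FIRST_POSITION = ER_RANGE[0]
LAST_POSITION = CTR_RANGE[1]
N_COLUMNS = LAST_POSITION - FIRST_POSITION + 1  # 115

# consensus positions of the six conserved cysteines and the loop-6 N/D site
CYS_POSITIONS = (4, 8, 13, 20, 22, 27)
ND_POSITION = 30

# prodomain signature windows (classification)
MOEBIUS_DELETION_WINDOWS = ((-56, -54), (-50, -38))
INSERTION_REGION = (-50, -38)
HYBRID_MARK_WINDOW = (-32, -31)
LINEAR_BRACELET_INSERTIONS = ((-49,), (-48,), (-39,))
NTR_DIPEPTIDE_POSITIONS = (-9, -8)

# residue classes of the signature rules (one-letter sets)
MOEBIUS_CYCLIC_D1 = set("YFH")
MOEBIUS_CYCLIC_D2 = set("SAY")
BRACELET_CYCLIC_D1 = set("HNSTGKP")
BRACELET_CYCLIC_D2 = set("LNSFA")
BRACELET_LINEAR_D1 = set("QEPK")
BRACELET_LINEAR_D2 = set("DN")
LB_MARK_M49 = set("PAL")
LB_MARK_M48 = set("NA")
LB_MARK_M39 = set("DE")


def positions(rng: tuple[int, int]) -> range:
    """Inclusive consensus-position interval as a python range."""
    return range(rng[0], rng[1] + 1)


def column_of(pos: int) -> int:
    """Alignment column index of a consensus position in the shipped layout."""
    if not FIRST_POSITION <= pos <= LAST_POSITION:
        raise ValueError(f"consensus position {pos} outside [{FIRST_POSITION}, {LAST_POSITION}]")
    return pos - FIRST_POSITION


def position_of(col: int) -> int:
    if not 0 <= col < N_COLUMNS:
        raise ValueError(f"column {col} outside layout")
    return col + FIRST_POSITION


DEFAULT_COLUMN_MAP = tuple(range(FIRST_POSITION, LAST_POSITION + 1))
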