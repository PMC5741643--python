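"""Monoisotopic mass arithmetic for mature cyclotide candidates.

Cyclotides are head-to-tail cyclic peptides, so the backbone carries no free
termini: the monoisotopic mass of a cyclic peptide is the plain sum of residue
masses (no water of condensation), minus two hydrogens per disulfide bond.
Linear cyclotide-like peptides keep the terminal water.  Reduction and
carbamidomethylation (iodoacetamide) of a cystine adds one hydrogen plus one
carbamidomethyl group per cysteine, so a six-cysteine cyclotide shifts by
6 x (57.021464 + 1.007825) = 348.18 Da - the diagnostic used to confirm three
disulfide bonds in an extract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from pyteomics import mass as _ptmass

__all__ = [
    "MassConstants",
    "MatureCandidate",
    "MassIndeterminateError",
    "monoisotopic_mass",
    "alkylation_delta",
    "mz_for_charge",
    "enumerate_matures",
    "CONSTANTS",
]

# values to six decimals; comparisons are always done on unrounded numbers
PROTON = 1.007276
WATER = 18.010565
HYDROGEN = 1.007825
CARBAMIDOMETHYL = 57.021464


def _residue_table() -> dict[str, float]:
    """Monoisotopic residue (not free amino acid) masses for the 20 letters."""
    return {aa: _ptmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}


@dataclass(frozen=True)
class MassConstants:
    residue_monoisotopic: dict[str, float] = field(default_factory=_residue_table)
    proton: float = PROTON
    water: float = WATER
    hydrogen: float = HYDROGEN
    carbamidomethyl: float = CARBAMIDOMETHYL

    def __post_init__(self) -> None:
        if set(self.residue_monoisotopic) != set("ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError("residue mass table must cover exactly the 20 amino acids")
        if any(v <= 0 for v in self.residue_monoisotopic.values()):
            raise ValueError("residue masses must be positive")


CONSTANTS = MassConstants()


class MassIndeterminateError(ValueError):
    """Raised when a sequence contains a letter with no defined mass (e.g. X)."""


@dataclass(frozen=True)
class MatureCandidate:
    """A putative mature peptide excised from an annotated precursor.

    ``start_offset`` is the N-terminal trim/extension relative to consensus
    position 0 (the canonical cyclotide-domain cleavage site); negative
    offsets reach into the NTR.  Cyclic candidates end at the loop-6 N/D
    cyclization residue inclusive; linear candidates run to the end of the
    cyclotide domain.
    """

    precursor_id: str
    cd_index: int
    start_offset: int
    residues: str
    topology: str  # "cyclic" | "linear"
    n_cys: int
    n_disulfide: int
    calc_mass: float

    def __post_init__(self) -> None:
        if not -3 <= self.start_offset <= 2:
            raise ValueError("start_offset must lie in [-3, 2]")
        if self.topology not in ("cyclic", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")


def monoisotopic_mass(
    residues: str,
    topology: str = "cyclic",
    n_disulfide: int = 0,
    constants: MassConstants = CONSTANTS,
) -> float:
    """Monoisotopic mass in Da of a peptide with the given backbone topology.

    cyclic: sum of residue masses - 2H per disulfide (no terminal water).
    linear: sum of residue masses + water - 2H per disulfide.
    """
    if not residues:
        raise ValueError("empty sequence")
    if topology not in ("cyclic", "linear"):
        raise ValueError(f"unknown topology {topology!r}")
    table = constants.residue_monoisotopic
    total = 0.0
    for i, aa in enumerate(residues):
        try:
            total += table[aa]
        except KeyError:
            raise MassIndeterminateError(
                f"residue {aa!r} at position {i} has no defined monoisotopic mass"
            ) from None
    if topology == "linear":
        total += constants.water
    return total - n_disulfide * 2 * constants.hydrogen


def alkylation_delta(n_cys: int, constants: MassConstants = CONSTANTS) -> float:
    """Mass shift from reduction + carbamidomethylation of ``n_cys`` cysteines.

    Reduction adds one hydrogen per cysteine, alkylation one carbamidomethyl.
    """
    if n_cys < 0:
        raise ValueError("n_cys must be non-negative")
    return n_cys * (constants.carbamidomethyl + constants.hydrogen)


def mz_for_charge(M: float, z: int, constants: MassConstants = CONSTANTS) -> float:
    """m/z of the [M+zH]^z+ ion."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (M + z * constants.proton) / z


START_OFFSETS = range(-3, 3)  # inclusive [-3, 2] per the processing-site bracket


def enumerate_matures(
    precursor_id: str,
    cd_index: int,
    protein: str,
    pos0_index: int,
    cd_end_index: int,
    nd_site: int | None,
    constants: MassConstants = CONSTANTS,
) -> list[MatureCandidate]:
    """Enumerate the six N-terminal start variants of one cyclotide domain.

    Parameters are residue indices into ``protein``: ``pos0_index`` is the
    residue at consensus position 0, ``cd_end_index`` the last residue of the
    domain (inclusive), ``nd_site`` the loop-6 N/D residue or None.  When the
    N/D cyclization residue is present the peptide is cyclic and ends at that
    residue; otherwise it is linear and runs to the domain end.  Candidates
    containing letters without a defined mass (X) are silently excluded, as
    are non-positive-length ones.
    """
    out: list[MatureCandidate] = []
    if nd_site is not None:
        topology, end = "cyclic", nd_site
    else:
        topology, end = "linear", cd_end_index
    for off in START_OFFSETS:
        start = pos0_index + off
        if start < 0 or start > end:
            continue
        residues = protein[start : end + 1]
        if not residues:
            continue
        n_cys = residues.count("C")
        n_ss = n_cys // 2  # odd counts leave one free thiol
        try:
            m = monoisotopic_mass(residues, topology, n_ss, constants)
        except MassIndeterminateError:
            continue
        out.append(
            MatureCandidate(
                precursor_id=precursor_id,
                cd_index=cd_index,
                start_offset=off,
                residues=residues,
                topology=topology,
                n_cys=n_cys,
                n_disulfide=n_ss,
                calc_mass=m,
            )
        )
    return out


def candidate_table_rows(cands: Iterable[MatureCandidate]) -> list[dict]:
    """Flatten candidates to the output-table schema used by the CLI."""
    rows = []
    for c in cands:
        rows.append(
            {
                "precursor_id": c.precursor_id,
                "cd_index": c.cd_index,
                "start_offset": c.start_offset,
                "topology": c.topology,
                "sequence": c.residues,
                "n_cys": c.n_cys,
                "calc_mass": c.calc_mass,
                "calc_mass_alkylated": c.calc_mass + alkylation_delta(c.n_cys),
                "mz2": mz_for_charge(c.calc_mass, 2),
                "mz3": mz_for_charge(c.calc_mass, 3),
            }
        )
    return rows
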