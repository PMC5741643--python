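"""Prodomain sequence-signature classification.

Lineage (Moebius vs bracelet) is read from the NTPP indel region [-56,-38]:
Moebius-lineage precursors carry definite deletions at [-56,-54] and
[-50,-38], bracelet precursors fill the region (cyclic bracelets with minor
gaps; linear bracelets carry a deletion flanked by the diagnostic insertions
(P/A/L)(-49)-(N/A)(-48) and (D/E)(-39), which count as bracelet evidence).
Structural subfamily comes from the NTR dipeptide at [-9,-8] plus the hybrid
insertion mark at [-32,-31].  Precursors sharing the NTR dipeptide form a
molecular series; within a series, precursors with the same [-56,-38]
occupancy pattern and sufficiently similar NTPP residues form a molecular
species.  Naming is tripartite: organism code + rank + species key, with a
"prc-" prefix for previously unnamed precursors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import consensus as cns
from .anchoring import AnchoredPrecursor, LoopDecomposition

__all__ = [
    "SignatureProfile",
    "Classification",
    "NameAssignment",
    "ClassifyParams",
    "extract_signature",
    "assign_lineage",
    "assign_subfamily",
    "group_species_series",
    "assign_names",
    "classify_precursor",
]


@dataclass(frozen=True)
class ClassifyParams:
    deletion_gap_fraction: float = 0.80  # window this gapped => deletion
    insertion_occupancy_fraction: float = 0.50  # region this occupied => insertion
    species_identity_threshold: float = 0.80


@dataclass(frozen=True)
class SignatureProfile:
    """Signature marks read off an anchored precursor; '?' = not covered."""

    ntpp_occupancy: tuple[str, ...]  # over [-56,-38]: '+', '-', or '?'
    linear_bracelet_marks: tuple[str, str, str]  # residues at -49, -48, -39
    hybrid_mark: tuple[str, str]  # occupancy at [-32,-31]
    ntr_dipeptide: str  # residues at [-9,-8]
    ntpp_residues: tuple[str, ...] = ()  # over [-56,-20], '-' gap, '?' unknown


@dataclass
class Classification:
    lineage: str = "unclassified"  # moebius | bracelet | unclassified
    subfamily: str = "unassigned"
    abnormality_flags: tuple[str, ...] = ()
    series_key: str | None = None
    species_key: str | None = None
    rationale: tuple[str, ...] = ()


@dataclass(frozen=True)
class NameAssignment:
    organism_code: str
    rank: int
    entity: str  # cyclotide | precursor
    full_name: str


def _mark(anchored: AnchoredPrecursor, pos: int) -> str:
    """'?' outside coverage, '-' for a gap, else the residue letter."""
    lo, hi = anchored.aligned_span
    if pos < lo or pos > hi:
        return "?"
    res = anchored.residue_at(pos)
    return res if res is not None else "-"


def extract_signature(anchored: AnchoredPrecursor) -> SignatureProfile:
    """Read the prodomain signature directly off the anchored coordinates.

    Positions outside the aligned span yield '?' - a partial sequence never
    produces a guessed mark.
    """
    occ = tuple(
        "?" if (m := _mark(anchored, p)) == "?" else ("-" if m == "-" else "+")
        for p in cns.positions((-56, -38))
    )
    marks = tuple(_mark(anchored, p) for p in (-49, -48, -39))
    hyb = tuple(
        "?" if (m := _mark(anchored, p)) == "?" else ("-" if m == "-" else "+")
        for p in cns.positions(cns.HYBRID_MARK_WINDOW)
    )
    dipep = "".join(
        m if m not in ("-",) else "?" for m in (_mark(anchored, p) for p in cns.NTR_DIPEPTIDE_POSITIONS)
    )
    residues = tuple(_mark(anchored, p) for p in cns.positions(cns.NTPP_RANGE))
    return SignatureProfile(
        ntpp_occupancy=occ,
        linear_bracelet_marks=marks,  # type: ignore[arg-type]
        hybrid_mark=hyb,  # type: ignore[arg-type]
        ntr_dipeptide=dipep,
        ntpp_residues=residues,
    )


def _window_slice(occ: Sequence[str], window: tuple[int, int]) -> list[str]:
    # occupancy vector is indexed over [-56,-38]
    lo = window[0] - (-56)
    hi = window[1] - (-56)
    return list(occ[lo : hi + 1])


def _fraction(marks: list[str], what: str) -> float | None:
    known = [m for m in marks if m != "?"]
    if not known:
        return None
    return sum(m == what for m in known) / len(known)


def assign_lineage(
    sig: SignatureProfile, params: ClassifyParams = ClassifyParams()
) -> tuple[str, tuple[str, ...]]:
    """Moebius/bracelet/unclassified from the NTPP indel signature."""
    rationale: list[str] = []
    big = _window_slice(sig.ntpp_occupancy, (-50, -38))
    small = _window_slice(sig.ntpp_occupancy, (-56, -54))
    gap_big = _fraction(big, "-")
    gap_small = _fraction(small, "-")
    occ_big = _fraction(big, "+")
    if gap_big is None:
        return "unclassified", ("partial: NTPP indel region not covered",)
    windows_gapped = gap_big >= params.deletion_gap_fraction and (
        gap_small is None or gap_small >= params.deletion_gap_fraction
    )
    if windows_gapped:
        rationale.append(
            f"deletion windows [-56,-54] and [-50,-38] gapped "
            f"({gap_small if gap_small is not None else 'n/a'}, {gap_big:.2f})"
        )
        return "moebius", tuple(rationale)
    if occ_big is not None and occ_big >= params.insertion_occupancy_fraction:
        rationale.append(f"insertion region [-50,-38] occupied ({occ_big:.2f})")
        return "bracelet", tuple(rationale)
    m49, m48, m39 = sig.linear_bracelet_marks
    if m49 in cns.LB_MARK_M49 and m48 in cns.LB_MARK_M48 and m39 in cns.LB_MARK_M39:
        rationale.append(
            f"linear-bracelet flanking insertions present ({m49}{m48}.. {m39})"
        )
        return "bracelet", tuple(rationale)
    return "unclassified", ("no lineage-defining NTPP features",)


def assign_subfamily(
    lineage: str,
    sig: SignatureProfile,
    loops: LoopDecomposition | None = None,
) -> tuple[str, tuple[str, ...]]:
    """Structural subfamily from the NTR dipeptide and hybrid mark."""
    flags = tuple(loops.abnormality_flags) if loops is not None else ()
    d = sig.ntr_dipeptide
    if len(d) != 2 or "?" in d:
        return "unassigned", flags
    d1, d2 = d[0], d[1]
    if lineage == "moebius":
        if d == "YY":
            return "linear_moebius", flags
        if d1 in cns.MOEBIUS_CYCLIC_D1 and d2 in cns.MOEBIUS_CYCLIC_D2:
            if all(m == "+" for m in sig.hybrid_mark):
                return "hybrid", flags
            return "archetypal_moebius", flags
        return "unassigned", flags
    if lineage == "bracelet":
        m49, m48, m39 = sig.linear_bracelet_marks
        lb_marks = m49 in cns.LB_MARK_M49 and m48 in cns.LB_MARK_M48 and m39 in cns.LB_MARK_M39
        if d1 in cns.BRACELET_LINEAR_D1 and d2 in cns.BRACELET_LINEAR_D2 and lb_marks:
            return "linear_bracelet", flags
        if d1 in cns.BRACELET_CYCLIC_D1 and d2 in cns.BRACELET_CYCLIC_D2:
            return "cyclic_bracelet", flags
        return "unassigned", flags
    return "unassigned", flags


def classify_precursor(
    anchored: AnchoredPrecursor,
    loops: LoopDecomposition | None = None,
    params: ClassifyParams = ClassifyParams(),
) -> tuple[SignatureProfile, Classification]:
    """Convenience wrapper: signature -> lineage -> subfamily (no species)."""
    sig = extract_signature(anchored)
    lineage, rationale = assign_lineage(sig, params)
    subfamily, flags = assign_subfamily(lineage, sig, loops)
    if anchored.partial:
        flags = tuple(dict.fromkeys(flags + ("partial",)))
    cls = Classification(
        lineage=lineage, subfamily=subfamily, abnormality_flags=flags,
        rationale=rationale,
    )
    return sig, cls


def _ntpp_identity(a: SignatureProfile, b: SignatureProfile) -> float | None:
    num = den = 0
    for ca, cb in zip(a.ntpp_residues, b.ntpp_residues):
        if ca in "?-" or cb in "?-":
            continue
        den += 1
        num += ca == cb
    return num / den if den else None


def _ntpp_complete(sig: SignatureProfile) -> bool:
    return "?" not in sig.ntpp_occupancy


def group_species_series(
    classified: Sequence[tuple[SignatureProfile, Classification]],
    params: ClassifyParams = ClassifyParams(),
) -> list[tuple[SignatureProfile, Classification]]:
    """Fill series and species keys across a set of classified precursors.

    The series key is the NTR dipeptide.  Within a series, molecular species
    are connected components under "identical [-56,-38] occupancy pattern and
    NTPP residue identity >= threshold"; species are numbered in first-seen
    input order (YY1, YY2, ...).  Precursors whose NTPP is not fully covered
    receive a series only.
    """
    for sig, cls in classified:
        if cls.lineage in ("moebius", "bracelet") and "?" not in sig.ntr_dipeptide and len(sig.ntr_dipeptide) == 2:
            cls.series_key = sig.ntr_dipeptide
    # union-find per (lineage, series) over complete-NTPP members
    parents: dict[int, int] = {}

    def find(i: int) -> int:
        while parents[i] != i:
            parents[i] = parents[parents[i]]
            i = parents[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parents[max(ri, rj)] = min(ri, rj)

    eligible = [
        i
        for i, (sig, cls) in enumerate(classified)
        if cls.series_key is not None and _ntpp_complete(sig) and "partial" not in cls.abnormality_flags
    ]
    for i in eligible:
        parents[i] = i
    by_group: dict[tuple[str, str], list[int]] = {}
    for i in eligible:
        sig, cls = classified[i]
        by_group.setdefault((cls.lineage, cls.series_key), []).append(i)
    for (_, _), members in by_group.items():
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                i, j = members[ai], members[bi]
                si, sj = classified[i][0], classified[j][0]
                if si.ntpp_occupancy != sj.ntpp_occupancy:
                    continue
                ident = _ntpp_identity(si, sj)
                if ident is not None and ident >= params.species_identity_threshold:
                    union(i, j)
    counters: dict[str, int] = {}
    root_species: dict[int, str] = {}
    for i in eligible:  # input order fixes numbering
        sig, cls = classified[i]
        root = find(i)
        if root not in root_species:
            series = cls.series_key
            counters[series] = counters.get(series, 0) + 1
            root_species[root] = f"{series}{counters[series]}"
        cls.species_key = root_species[root]
    return list(classified)


# organism codes from the published naming examples; fallback is the genus
# initial plus the first four letters of the species epithet
ORGANISM_CODES: dict[str, str] = {
    "Viola albida var. takahashii": "valta",
    "Viola mandshurica": "viman",
    "Viola orientalis": "vorie",
    "Viola verecunda": "viver",
    "Viola acuminata": "vacum",
}


def organism_code(organism: str, table: Mapping[str, str] | None = None) -> str:
    table = ORGANISM_CODES if table is None else table
    if organism in table:
        return table[organism]
    parts = organism.split()
    if len(parts) < 2:
        raise ValueError(f"cannot derive organism code from {organism!r}")
    return (parts[0][0] + parts[1][:4]).lower()


def assign_names(
    classified: Sequence[tuple[str, str, Classification]],
    entity: str = "cyclotide",
    existing_names: Mapping[str, str] | None = None,
    code_table: Mapping[str, str] | None = None,
) -> list[NameAssignment]:
    """Tripartite names for (record id, organism, classification) triples.

    Rank is a per-(organism, species) counter in input order.  Previously
    published names are reused verbatim; otherwise precursor names carry the
    "prc-" prefix.
    """
    existing_names = existing_names or {}
    out: list[NameAssignment] = []
    counters: dict[tuple[str, str], int] = {}
    seen_codes: dict[str, str] = {}
    for rec_id, organism, cls in classified:
        code = organism_code(organism, code_table)
        if code in seen_codes and seen_codes[code] != organism:
            raise ValueError(
                f"organism code collision: {code!r} for {organism!r} and {seen_codes[code]!r}"
            )
        seen_codes[code] = organism
        if rec_id in existing_names:
            name = existing_names[rec_id]
            if entity == "precursor" and not name.startswith("prc"):
                name = f"prc-{name}"
            out.append(NameAssignment(code, 0, entity, name))
            continue
        species = cls.species_key or (cls.series_key or "U0")
        key = (code, species)
        counters[key] = counters.get(key, 0) + 1
        rank = counters[key]
        base = f"{code}{rank}-{species}"
        if entity == "precursor":
            base = f"prc-{base}"
        out.append(NameAssignment(code, rank, entity, base))
    return out
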