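"""Synthetic cyclotide transcriptomes, FPKM tables and LC-MS peak lists with
ground truth.

The template library encodes the consensus structure of the molecular-species
classification: 46 species in 13 molecular series (14 species over 5 series in
the Moebius lineage, 32 over 8 series in the bracelet lineage), each defined
by its prodomain indel signature (NTPP occupancy over [-56,-38] plus the NTR
dipeptide at [-9,-8]) and a cyclotide-domain consensus.  The Moebius-lineage
cyclotide domain is modelled on kalata B1 and the bracelet domain on
cycloviolacin O2 - the two published archetypes - with species-specific
substitutions at a few loop positions; everything else in the library is
synthetic.  Moebius precursors carry 1-3 NTR+CD repeats, bracelet precursors
always one.

A single seed drives everything; independent substreams are derived from it
deterministically, so identical seeds give byte-identical artifacts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from . import consensus as cns
from . import masscalc
from .seqio import SequenceRecord

__all__ = [
    "SpeciesTemplate",
    "PrecursorTruth",
    "SimTruth",
    "build_template_library",
    "sample_precursor",
    "build_transcriptome",
    "simulate_peaklist",
    "default_bundle",
]

# ---------------------------------------------------------------------------
# template library

ER_SEQ = "MKMSSTALLLAFLAMLLIVS"  # synthetic signal-peptide-like, 20 aa, no Cys
NTR_BASE = "KLSSGQTAFA??LPALSTA"  # 19 aa; ?? = series dipeptide at [-9,-8]
CTR_SEQ = "SLAANGLA"  # 8 aa tail, cyclic precursors only

# cyclotide-domain consensus rows over positions 0..30 ('-' = consensus gap);
# Cys at positions 4, 8, 13, 20, 22, 27 and the loop-6 N/D site at 30
CD_MOEBIUS_CYCLIC = "GLPVCGETCVGGTCNTPG--CTCSWPVCTRN"  # kalata B1
CD_MOEBIUS_LINEAR = "GLPVCGETCVGGTCNTPG--CTCSWPVCTR-"
CD_BRACELET_CYCLIC = "GIP-CGESCVWIPCISSAIGCSCKSKVCYRN"  # cycloviolacin O2
CD_BRACELET_LINEAR = "GIP-CGESCVWIPCISSAIGCSCKSKVCYR-"

_BARCODE_PALETTE = "ADEFGHIKLNQRSTVW"  # no Cys, 16 letters

# species-fixed cyclotide-domain substitution sites and their letter wheels
_CD_VARIANT_SITES_MOEBIUS = ((6, "EDQNK"), (9, "VILTS"), (16, "TSAV"))
_CD_VARIANT_SITES_BRACELET = ((6, "EDQNK"), (15, "STAGN"), (26, "VILTA"))

# per-instance sampled positions (segment, index) -> pool; mass-conservative
_NTR_POOLS = {2: "SG", 16: "TS"}
_CD_POOLS_MOEBIUS = {11: "GA"}
_CD_POOLS_BRACELET = {24: "ST"}


@dataclass(frozen=True)
class SpeciesTemplate:
    """Generative template for one molecular species.

    ``ntpp`` covers consensus [-56,-20] (37 chars), ``ntr`` [-19,-1],
    ``cd`` [0,30] and ``ctr`` [31,38]; '-' marks a consensus deletion.
    ``cd_pools``/``ntr_pools`` map string indices to residue pools sampled
    per instantiation (and per repeat), everything else is fixed.
    """

    name: str
    lineage: str  # moebius | bracelet
    subfamily: str  # archetypal_moebius | hybrid | linear_moebius | cyclic_bracelet | linear_bracelet
    series: str  # NTR dipeptide
    ntpp: str
    ntr: str
    cd: str
    ctr: str
    nd_present: bool
    repeat_choices: tuple[int, ...] = (1,)
    ntr_pools: dict[int, str] = field(default_factory=dict)
    cd_pools: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert len(self.ntpp) == 37 and len(self.ntr) == 19 and len(self.cd) == 31
        assert "?" not in self.ntr

    def canonical_mature(self) -> tuple[str, str]:
        """(sequence, topology) of the offset-0 mature peptide, pools untouched."""
        if self.nd_present:
            return self.cd.replace("-", ""), "cyclic"
        return self.cd[: cns.ND_POSITION].replace("-", ""), "linear"


def _barcode_letters(species_index: int, n: int) -> list[str]:
    pal = _BARCODE_PALETTE
    return [pal[(species_index + 3 * k) % len(pal)] for k in range(n)]


def _moebius_ntpp(subfamily: str, species_index: int) -> str:
    tail = list("ALSSSNGLGGT")  # [-30,-20]
    for k, j in enumerate((1, 3, 5, 7, 9)):
        tail[j] = _barcode_letters(species_index, 5)[k]
    mark = "--" if subfamily == "archetypal_moebius" else ("DT" if subfamily == "hybrid" else "ST")
    return "---" + "NTL" + "-" * 13 + "AVLKE" + mark + "".join(tail)


def _bracelet_cyclic_ntpp(species_index: int) -> str:
    head = list("SETLKDPLISHVTGEEALF")  # [-56,-38]
    tail = list("TPDVAQILSPAMEEGALS")  # [-37,-20]
    bars = _barcode_letters(species_index, 8)
    for k, j in enumerate((4, 8, 12)):
        head[j] = bars[k]
    for k, j in enumerate((1, 5, 9, 13, 17)):
        tail[j] = bars[3 + k]
    return "".join(head) + "".join(tail)


def _bracelet_linear_ntpp(species_index: int) -> str:
    head = list("SETLKD")  # [-56,-51]
    tail = list("TPDVAQILSPAMEEGALS")
    bars = _barcode_letters(species_index, 8)
    head[1], head[3] = bars[0], bars[1]
    for k, j in enumerate((1, 5, 9, 13, 17)):
        tail[j] = bars[2 + k]
    mid = "-" + "PN" + "-" * 8 + "D" + bars[7]
    return "".join(head) + mid + "".join(tail)


def _cd_variant(base: str, sites, species_index: int) -> str:
    cd = list(base)
    for k, (pos, wheel) in enumerate(sites):
        cd[pos] = wheel[(species_index + k) % len(wheel)]
    return "".join(cd)


# (series dipeptide, species count, structural kind)
MOEBIUS_SERIES = (("YS", 7, "cyclic"), ("YA", 2, "cyclic"), ("FA", 2, "cyclic"),
                  ("HA", 1, "cyclic"), ("YY", 2, "linear"))
BRACELET_SERIES = (("HS", 6, "cyclic"), ("NS", 5, "cyclic"), ("NL", 4, "cyclic"),
                   ("GA", 4, "cyclic"), ("GL", 3, "cyclic"), ("PS", 4, "cyclic"),
                   ("PN", 3, "linear"), ("QD", 3, "linear"))


def build_template_library() -> list[SpeciesTemplate]:
    """The 46 shipped molecular-species templates (deterministic)."""
    lib: list[SpeciesTemplate] = []
    for series, count, kind in MOEBIUS_SERIES:
        for i in range(count):
            name = f"{series}{i + 1}"
            if kind == "linear":
                sub = "linear_moebius"
                cd = _cd_variant(CD_MOEBIUS_LINEAR, _CD_VARIANT_SITES_MOEBIUS, i)
                nd, ctr, reps = False, "-" * 8, (1,)
            else:
                sub = "archetypal_moebius" if i % 2 == 0 else "hybrid"
                cd = _cd_variant(CD_MOEBIUS_CYCLIC, _CD_VARIANT_SITES_MOEBIUS, i)
                nd, ctr, reps = True, CTR_SEQ, (1, 2, 3)
            lib.append(
                SpeciesTemplate(
                    name=name, lineage="moebius", subfamily=sub, series=series,
                    ntpp=_moebius_ntpp(sub, i), ntr=NTR_BASE.replace("??", series),
                    cd=cd, ctr=ctr, nd_present=nd, repeat_choices=reps,
                    ntr_pools=dict(_NTR_POOLS), cd_pools=dict(_CD_POOLS_MOEBIUS),
                )
            )
    for series, count, kind in BRACELET_SERIES:
        for i in range(count):
            name = f"{series}{i + 1}"
            if kind == "linear":
                sub = "linear_bracelet"
                cd = _cd_variant(CD_BRACELET_LINEAR, _CD_VARIANT_SITES_BRACELET, i)
                nd, ctr = False, "-" * 8
                ntpp = _bracelet_linear_ntpp(i)
            else:
                sub = "cyclic_bracelet"
                cd = _cd_variant(CD_BRACELET_CYCLIC, _CD_VARIANT_SITES_BRACELET, i)
                nd, ctr = True, CTR_SEQ
                ntpp = _bracelet_cyclic_ntpp(i)
            lib.append(
                SpeciesTemplate(
                    name=name, lineage="bracelet", subfamily=sub, series=series,
                    ntpp=ntpp, ntr=NTR_BASE.replace("??", series),
                    cd=cd, ctr=ctr, nd_present=nd, repeat_choices=(1,),
                    ntr_pools=dict(_NTR_POOLS), cd_pools=dict(_CD_POOLS_BRACELET),
                )
            )
    assert len(lib) == 46
    return lib


# ---------------------------------------------------------------------------
# sampling

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _codons_by_aa() -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for codon, aa in sorted(_STANDARD_TABLE.forward_table.items()):
        out.setdefault(aa, []).append(codon)
    return out


CODONS = _codons_by_aa()
STOP_CODONS = tuple(sorted(_STANDARD_TABLE.stop_codons))


@dataclass
class CdTruth:
    cd_index: int
    ntr_span: tuple[int, int]  # residue indices, half-open
    cd_span: tuple[int, int]
    pos0_index: int
    nd_index: int | None
    mature: str
    topology: str
    mass: float


@dataclass
class PrecursorTruth:
    transcript_id: str
    organism: str
    section: str
    species: str
    series: str
    lineage: str
    subfamily: str
    protein: str
    n_repeats: int
    er_span: tuple[int, int]
    ntpp_span: tuple[int, int]
    ctr_span: tuple[int, int] | None
    cds: list[CdTruth]
    strand: str = "+"
    fpkm: float = 0.0
    tier: str = "low"
    expressed_peptide: bool = True


def _instantiate_segment(seq: str, pools: dict[int, str], rng: np.random.Generator) -> str:
    chars = list(seq)
    for j, pool in sorted(pools.items()):
        if chars[j] != "-":
            chars[j] = pool[rng.integers(len(pool))]
    return "".join(chars)


def sample_precursor(
    template: SpeciesTemplate, rng_seed: int | np.random.Generator
) -> tuple[PrecursorTruth, str]:
    """Instantiate a template into (truth record, CDS nucleotide sequence).

    Residues at pool positions are drawn per repeat; the protein is
    back-translated with uniformly sampled synonymous codons and the CDS is
    flanked by stop codons.  The returned truth carries exact domain
    boundaries and mature masses (computed with the mass module).
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    n_rep = int(template.repeat_choices[rng.integers(len(template.repeat_choices))])
    ntpp = template.ntpp.replace("-", "")
    parts = [ER_SEQ, ntpp]
    er_span = (0, len(ER_SEQ))
    ntpp_span = (len(ER_SEQ), len(ER_SEQ) + len(ntpp))
    cursor = ntpp_span[1]
    cds_truth: list[CdTruth] = []
    for r in range(n_rep):
        ntr = _instantiate_segment(template.ntr, template.ntr_pools, rng)
        cd_gapped = _instantiate_segment(template.cd, template.cd_pools, rng)
        cd = cd_gapped.replace("-", "")
        ntr_span = (cursor, cursor + len(ntr))
        cd_span = (ntr_span[1], ntr_span[1] + len(cd))
        pos0_index = cd_span[0]
        if template.nd_present:
            nd_index = cd_span[1] - 1  # N/D is the last CD residue (position 30)
            mature = cd
            topology = "cyclic"
        else:
            nd_index = None
            mature = cd
            topology = "linear"
        mass = masscalc.monoisotopic_mass(mature, topology, mature.count("C") // 2)
        cds_truth.append(
            CdTruth(r, ntr_span, cd_span, pos0_index, nd_index, mature, topology, mass)
        )
        parts.extend([ntr, cd])
        cursor = cd_span[1]
    ctr = template.ctr.replace("-", "")
    ctr_span = (cursor, cursor + len(ctr)) if ctr else None
    parts.append(ctr)
    protein = "".join(parts)
    codon_choices = [CODONS[aa] for aa in protein]
    cds = "".join(ch[rng.integers(len(ch))] for ch in codon_choices)
    cds = STOP_CODONS[rng.integers(len(STOP_CODONS))] + cds + STOP_CODONS[rng.integers(len(STOP_CODONS))]
    truth = PrecursorTruth(
        transcript_id="", organism="", section="", species=template.name,
        series=template.series, lineage=template.lineage, subfamily=template.subfamily,
        protein=protein, n_repeats=n_rep, er_span=er_span, ntpp_span=ntpp_span,
        ctr_span=ctr_span, cds=cds_truth,
    )
    return truth, cds


# ---------------------------------------------------------------------------
# transcriptome + FPKM

DEFAULT_ORGANISMS = (
    ("Viola albida var. takahashii", "Plagiostigma"),
    ("Viola mandshurica", "Plagiostigma"),
    ("Viola verecunda", "Plagiostigma"),
    ("Viola acuminata", "Viola"),
    ("Viola orientalis", "Chamaemelanium"),
    ("Viola tricolor", "Melanium"),
)

_NT = "ACGT"


def _random_nt(n: int, rng: np.random.Generator) -> str:
    return "".join(_NT[i] for i in rng.integers(0, 4, size=n))


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


@dataclass
class SimTruth:
    """Ground-truth ledger for a simulated transcriptome."""

    precursors: list[PrecursorTruth]
    n_decoys: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.precursors:
            for cd in p.cds:
                rows.append(
                    {
                        "transcript_id": p.transcript_id,
                        "organism": p.organism,
                        "section": p.section,
                        "species": p.species,
                        "series": p.series,
                        "lineage": p.lineage,
                        "subfamily": p.subfamily,
                        "n_repeats": p.n_repeats,
                        "cd_index": cd.cd_index,
                        "mature": cd.mature,
                        "topology": cd.topology,
                        "mass": cd.mass,
                        "fpkm": p.fpkm,
                        "tier": p.tier,
                        "expressed_peptide": p.expressed_peptide,
                        "protein": p.protein,
                    }
                )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def _substream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def build_transcriptome(
    templates: Sequence[SpeciesTemplate] | None = None,
    n_per_species: int = 2,
    n_decoys: int = 50,
    utr_len: tuple[int, int] = (30, 120),
    fpkm_mu: float = 5.0,
    fpkm_sigma: float = 1.2,
    organisms: Sequence[tuple[str, str]] = DEFAULT_ORGANISMS,
    rng_seed: int = 0,
) -> tuple[list[SequenceRecord], pd.DataFrame, SimTruth]:
    """Simulate a transcriptome: precursor transcripts, decoys and FPKM.

    Each precursor CDS is embedded in a transcript with random UTRs and a
    random strand; decoys are length-matched random-codon transcripts; FPKM
    is i.i.d. log-normal.  Organisms (and hence sections) are assigned
    round-robin over instances of each species, so with n_per_species >= the
    organism count every species is planted in every section.
    """
    if templates is None:
        templates = build_template_library()
    rng = _substream(rng_seed, 1)
    fpkm_rng = _substream(rng_seed, 2)
    decoy_rng = _substream(rng_seed, 3)
    records: list[SequenceRecord] = []
    fpkm_rows = []
    precursors: list[PrecursorTruth] = []
    cds_lengths: list[int] = []
    counter = itertools.count(1)
    for tmpl in templates:
        for j in range(n_per_species):
            truth, cds = sample_precursor(tmpl, rng)
            org, section = organisms[j % len(organisms)]
            tid = f"TRINITY_SYN{next(counter):05d}_{tmpl.name}"
            u5 = _random_nt(int(rng.integers(utr_len[0], utr_len[1] + 1)), rng)
            u3 = _random_nt(int(rng.integers(utr_len[0], utr_len[1] + 1)), rng)
            transcript = u5 + cds + u3
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                transcript = _revcomp(transcript)
            truth.transcript_id = tid
            truth.organism = org
            truth.section = section
            truth.strand = strand
            truth.fpkm = float(np.round(fpkm_rng.lognormal(fpkm_mu, fpkm_sigma), 3))
            if truth.fpkm > 500:
                truth.tier = "high"
            elif truth.fpkm > 150:
                truth.tier = "medium"
            else:
                truth.tier = "low"
            precursors.append(truth)
            cds_lengths.append(len(cds))
            records.append(
                SequenceRecord(id=tid, description=f"synthetic precursor {tmpl.name}",
                               alphabet="nucleotide", residues=transcript)
            )
            fpkm_rows.append({"transcript_id": tid, "fpkm": truth.fpkm})
    for d in range(n_decoys):
        n_codons = max(40, int(decoy_rng.choice(cds_lengths)) // 3) if cds_lengths else 150
        aa_pool = "ACDEFGHIKLMNPQRSTVWY"
        prot = "".join(aa_pool[i] for i in decoy_rng.integers(0, 20, size=n_codons))
        cds = "".join(CODONS[aa][decoy_rng.integers(len(CODONS[aa]))] for aa in prot)
        tid = f"TRINITY_DECOY{d + 1:05d}"
        u5 = _random_nt(int(decoy_rng.integers(utr_len[0], utr_len[1] + 1)), decoy_rng)
        u3 = _random_nt(int(decoy_rng.integers(utr_len[0], utr_len[1] + 1)), decoy_rng)
        records.append(
            SequenceRecord(id=tid, description="decoy", alphabet="nucleotide",
                           residues=u5 + cds + u3)
        )
        fpkm_rows.append(
            {"transcript_id": tid, "fpkm": float(np.round(decoy_rng.lognormal(fpkm_mu, fpkm_sigma), 3))}
        )
    fpkm = pd.DataFrame(fpkm_rows)
    return records, fpkm, SimTruth(precursors=precursors, n_decoys=n_decoys, seed=rng_seed)


# ---------------------------------------------------------------------------
# LC-MS peak simulation

ISOTOPE_SPACING = 1.00336  # Da, averaged 13C-12C spacing read from spectra

TIER_INTENSITY = {"low": 100.0, "medium": 500.0, "high": 1500.0}


def simulate_peaklist(
    truth: SimTruth,
    jitter_sd: float = 0.0,
    n_isotope_peaks: int = 5,
    tier_intensity: dict[str, float] | None = None,
    n_noise_peaks: int = 0,
    alkylated: bool = False,
    mz_window: tuple[float, float] = (1000.0, 2000.0),
    rt_range: tuple[float, float] = (5.0, 45.0),
    decay: float = 0.8,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Simulate a centroided peak table for the expressed mature peptides.

    For every expressed mature peptide one 2+ and one 3+ isotope envelope is
    emitted at mz = (M + z*proton)/z with spacing 1.00336/z and geometrically
    decaying intensities scaled by the abundance tier.  ``jitter_sd`` is a
    per-envelope neutral-mass calibration error (Normal, Da); the envelope
    geometry itself stays exact so spacing-based charge reading still works.
    With ``alkylated`` the neutral mass is shifted by the
    reduction+carbamidomethylation delta of the peptide's cysteine count.
    Peaks outside the acquisition m/z window are not recorded.
    """
    tier_intensity = dict(TIER_INTENSITY if tier_intensity is None else tier_intensity)
    rng = _substream(truth.seed if rng_seed == 0 else rng_seed, 7 if not alkylated else 8)
    rows = []
    for p in truth.precursors:
        if not p.expressed_peptide:
            continue
        for cd in p.cds:
            M = cd.mass
            if alkylated:
                M = M + masscalc.alkylation_delta(cd.mature.count("C"))
            rt = float(rng.uniform(*rt_range))
            # normalize the geometric profile so the summed envelope
            # intensity equals the tier base: the abundance bins then
            # recover the planted tier exactly
            norm = sum(decay**k for k in range(n_isotope_peaks))
            base = tier_intensity[p.tier] / norm
            for z in (3, 2):
                eps = float(rng.normal(0.0, jitter_sd)) if jitter_sd > 0 else 0.0
                mono = masscalc.mz_for_charge(M + eps, z)
                for k in range(n_isotope_peaks):
                    mz = mono + k * ISOTOPE_SPACING / z
                    if not mz_window[0] <= mz <= mz_window[1]:
                        continue
                    rows.append(
                        {"rt_min": rt, "mz": mz, "intensity": base * decay**k}
                    )
    for _ in range(n_noise_peaks):
        rows.append(
            {
                "rt_min": float(rng.uniform(*rt_range)),
                "mz": float(rng.uniform(*mz_window)),
                "intensity": float(rng.lognormal(3.5, 0.5)),
            }
        )
    df = pd.DataFrame(rows, columns=["rt_min", "mz", "intensity"])
    df = df.sort_values(["rt_min", "mz"], kind="mergesort").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# default reference bundle (synthetic stand-in for a curated alignment)

_BUNDLE_REPRESENTATIVES = ("YS1", "YS2", "YY1", "HS1", "NS1", "PN1")

KNOWN_MATURES = (
    ("kalata_B1", "GLPVCGETCVGGTCNTPGCTCSWPVCTRN", "archetypal_moebius"),
    ("cycloviolacin_O2", "GIPCGESCVWIPCISSAIGCSCKSKVCYRN", "archetypal_bracelet"),
)


def default_bundle():
    """Build the shipped synthetic ReferenceBundle in memory.

    One representative row per lineage/subfamily combination, laid out in the
    shared 115-column space; mature references are the two published archetype
    sequences plus the canonical matures of the representative templates
    (synthetic).
    """
    from .seqio import ReferenceBundle  # local import to avoid cycle

    lib = {t.name: t for t in build_template_library()}
    ids, rows = [], []
    mature_rows = [
        {"id": mid, "sequence": seq, "label": label} for mid, seq, label in KNOWN_MATURES
    ]
    for name in _BUNDLE_REPRESENTATIVES:
        t = lib[name]
        row = ER_SEQ + t.ntpp + t.ntr + t.cd + (t.ctr if t.ctr != "-" * 8 else "-" * 8)
        assert len(row) == cns.N_COLUMNS
        ids.append(f"ref_{t.subfamily}_{name}_synthetic")
        rows.append(row)
        seq, topo = t.canonical_mature()
        label = {"archetypal_moebius": "archetypal_moebius", "hybrid": "hybrid",
                 "linear_moebius": "linear", "cyclic_bracelet": "archetypal_bracelet",
                 "linear_bracelet": "linear"}[t.subfamily]
        mature_rows.append({"id": f"syn_{name}", "sequence": seq, "label": label})
    return ReferenceBundle(
        alignment_ids=tuple(ids),
        alignment_rows=tuple(rows),
        column_map=cns.DEFAULT_COLUMN_MAP,
        mature_refs=pd.DataFrame(mature_rows),
        metadata={"synthetic": True},
    )
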