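"""Cross-referencing transcript abundance with peptide-level detection.

Transcript expression arrives as FPKM values computed upstream (RSEM/Trinity
style); the only operation applied here is the >150 cutoff that separates
well-expressed precursors from weakly expressed ones.  The cross-level table
joins classification, FPKM tier and LC-MS match status per precursor, and the
section-sharing summary reports how molecular species distribute over the
taxonomic sections of the genus, both by species count and by precursor
count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "fpkm_tier",
    "cross_level_table",
    "section_sharing",
    "FPKM_CUTOFF",
]

FPKM_CUTOFF = 150.0


def fpkm_tier(fpkm: float, cutoff: float = FPKM_CUTOFF) -> str:
    """'above' iff fpkm is strictly greater than the cutoff."""
    if fpkm < 0:
        raise ValueError("FPKM must be non-negative")
    return "above" if fpkm > cutoff else "below"


def cross_level_table(
    classifications: pd.DataFrame,
    expression: pd.DataFrame,
    matches: pd.DataFrame,
    cutoff: float = FPKM_CUTOFF,
) -> pd.DataFrame:
    """Per-precursor join of classification, FPKM tier and peptide detection.

    ``classifications`` needs precursor_id, lineage, subfamily, series,
    species (and optionally organism); ``expression`` precursor_id and fpkm;
    ``matches`` the match_predicted output.  Peptide detection requires a
    best (minimal-|delta|) match, not merely any within-tolerance pair.
    Precursors without an FPKM row keep tier 'unknown' and are flagged, never
    dropped.
    """
    df = classifications.copy()
    fpkm_map = dict(zip(expression["precursor_id"], expression["fpkm"]))
    best = matches[matches["best"]] if len(matches) else matches
    detected = set(best["precursor_id"]) if len(best) else set()
    rows = []
    for rec in df.itertuples():
        fpkm = fpkm_map.get(rec.precursor_id)
        tier = fpkm_tier(fpkm, cutoff) if fpkm is not None else "unknown"
        rows.append(
            {
                "precursor_id": rec.precursor_id,
                "lineage": rec.lineage,
                "subfamily": rec.subfamily,
                "series": getattr(rec, "series", None),
                "species": getattr(rec, "species", None),
                "organism": getattr(rec, "organism", None),
                "fpkm": fpkm,
                "fpkm_tier": tier,
                "peptide_detected": rec.precursor_id in detected,
                "flags": "missing_fpkm" if fpkm is None else "",
            }
        )
    out = pd.DataFrame(rows)
    out["both_levels"] = (out["fpkm_tier"] == "above") & out["peptide_detected"]
    return out


def section_sharing(
    species_assignments: pd.DataFrame,
    taxa: Mapping[str, str] | pd.DataFrame,
) -> pd.DataFrame:
    """Distribution of molecular species over taxonomic sections.

    ``species_assignments`` needs columns species and organism (one row per
    precursor); ``taxa`` maps organism -> section.  Returns one row per
    exclusive k-sections bucket with percentages computed both by molecular
    species count and by precursor-sequence count; the percentages over the
    exclusive buckets sum to 100 (up to rounding).
    """
    if isinstance(taxa, pd.DataFrame):
        taxa = dict(zip(taxa["organism"], taxa["section"]))
    df = species_assignments.dropna(subset=["species"]).copy()
    df["section"] = df["organism"].map(lambda o: taxa.get(o, "unknown"))
    by_species = df.groupby("species")["section"].agg(lambda s: frozenset(s))
    n_species = len(by_species)
    n_prec = len(df)
    counts = by_species.map(len)
    prec_counts = df.join(counts.rename("k"), on="species")
    rows = []
    for k in sorted(counts.unique()):
        sp = (counts == k).sum()
        pc = (prec_counts["k"] == k).sum()
        rows.append(
            {
                "n_sections": int(k),
                "n_species": int(sp),
                "n_precursors": int(pc),
                "pct_species": 100.0 * sp / n_species if n_species else 0.0,
                "pct_precursors": 100.0 * pc / n_prec if n_prec else 0.0,
            }
        )
    return pd.DataFrame(rows)
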