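"""End-to-end orchestration: simulate -> mine -> anchor -> classify ->
masses -> match -> expression summaries, with a manifest and a plain-text
report.  Every stage writes deterministic TSV/JSON, so identical seeds and
inputs reproduce byte-identical outputs."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import consensus as cns
from . import masscalc, synthetic
from .anchoring import (
    AnchoredPrecursor,
    UnanchorableError,
    anchor_to_profile,
    decompose_loops,
    segment_domains,
)
from .classify import assign_names, classify_precursor, group_species_series
from .config import PipelineConfig, config_hash
from .expression import cross_level_table, section_sharing
from .mining import mine_precursors
from .msmatch import confirm_alkylation, deconvolute, detect_envelopes, match_predicted
from .seqio import (
    ReferenceBundle,
    load_reference_bundle,
    read_fasta,
    read_peak_table,
    write_fasta,
)

logger = logging.getLogger(__name__)

__all__ = ["run_all", "simulate_to_dir", "classify_candidates"]

FLOAT_FMT = "%.6f"


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def simulate_to_dir(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic dataset (transcripts, fpkm, peaks, truth) to a dir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sc = config.synthetic
    records, fpkm, truth = synthetic.build_transcriptome(
        n_per_species=sc.n_per_species,
        n_decoys=sc.n_decoys,
        utr_len=sc.utr_len,
        fpkm_mu=sc.fpkm_mu,
        fpkm_sigma=sc.fpkm_sigma,
        rng_seed=config.seed,
    )
    paths = {
        "transcripts": outdir / "transcripts.fasta",
        "fpkm": outdir / "fpkm.tsv",
        "peaks": outdir / "peaks.tsv",
        "truth": outdir / "truth.tsv",
        "organisms": outdir / "organisms.tsv",
    }
    write_fasta(records, paths["transcripts"])
    fpkm.to_csv(paths["fpkm"], sep="\t", index=False, float_format=FLOAT_FMT)
    peaks = synthetic.simulate_peaklist(
        truth, jitter_sd=sc.jitter_sd, n_isotope_peaks=sc.n_isotope_peaks,
        n_noise_peaks=sc.n_noise_peaks,
    )
    peaks.to_csv(paths["peaks"], sep="\t", index=False, float_format=FLOAT_FMT)
    if sc.make_alkylated:
        paths["peaks_alk"] = outdir / "peaks_alk.tsv"
        alk = synthetic.simulate_peaklist(
            truth, jitter_sd=sc.jitter_sd, n_isotope_peaks=sc.n_isotope_peaks,
            n_noise_peaks=sc.n_noise_peaks, alkylated=True,
        )
        alk.to_csv(paths["peaks_alk"], sep="\t", index=False, float_format=FLOAT_FMT)
    truth.write_tsv(paths["truth"])
    pd.DataFrame(
        [
            {"transcript_id": p.transcript_id, "organism": p.organism, "section": p.section}
            for p in truth.precursors
        ]
    ).to_csv(paths["organisms"], sep="\t", index=False)
    return paths


def classify_candidates(candidates, bundle: ReferenceBundle, config: PipelineConfig):
    """Anchor, segment and classify mined candidates.

    Returns (rows, anchored, matures): classification rows per candidate,
    the anchored precursors, and the enumerated mature candidates.
    Unanchorable candidates are recorded with a flag and excluded from
    downstream mass prediction.
    """
    rows = []
    anchored_ok: list[tuple[str, AnchoredPrecursor]] = []
    matures: list[masscalc.MatureCandidate] = []
    pairs = []
    for k, cand in enumerate(candidates):
        pid = f"prc{k + 1:04d}"
        try:
            anc = anchor_to_profile(
                cand, bundle, config.anchoring_gap_open, config.anchoring_gap_extend
            )
        except UnanchorableError as exc:
            logger.warning("unanchorable candidate %s: %s", pid, exc)
            rows.append(
                {
                    "precursor_id": pid, "transcript_id": cand.orf.transcript_id,
                    "lineage": "unclassified", "subfamily": "unassigned",
                    "series": None, "species": None,
                    "flags": "unanchorable", "rationale": str(exc),
                    "protein": cand.protein,
                    "provenance": ";".join(cand.provenance),
                }
            )
            pairs.append(None)
            continue
        loops = decompose_loops(anc, 0)
        sig, cls = classify_precursor(anc, loops, config.classify)
        pairs.append((sig, cls))
        anchored_ok.append((pid, anc))
        rows.append(
            {
                "precursor_id": pid, "transcript_id": cand.orf.transcript_id,
                "lineage": cls.lineage, "subfamily": cls.subfamily,
                "series": None, "species": None,
                "flags": ";".join(cls.abnormality_flags),
                "rationale": " | ".join(cls.rationale),
                "protein": cand.protein,
                "provenance": ";".join(cand.provenance),
            }
        )
    group_species_series([p for p in pairs if p is not None], config.classify)
    for row, pair in zip(rows, pairs):
        if pair is not None:
            row["series"] = pair[1].series_key
            row["species"] = pair[1].species_key
    by_pid = dict(anchored_ok)
    for pid, anc in anchored_ok:
        domains = segment_domains(anc)
        for i, cd_span in enumerate(domains.cd_spans):
            loops = decompose_loops(anc, i)
            pos0 = anc.index_of(0, i)
            if pos0 is None:
                continue
            matures.extend(
                masscalc.enumerate_matures(
                    pid, i, anc.protein, pos0, cd_span[1] - 1, loops.nd_site
                )
            )
    return rows, by_pid, matures


def run_all(
    config: PipelineConfig,
    outdir: str | Path,
    transcripts: str | Path | None = None,
    fpkm: str | Path | None = None,
    peaks: str | Path | None = None,
    peaks_alk: str | Path | None = None,
    organisms: str | Path | None = None,
    taxa: dict[str, str] | None = None,
    bundle_path: str | Path | None = None,
    simulate: bool = False,
) -> Path:
    """Run the full pipeline and write all outputs under ``outdir``.

    With ``simulate`` the synthetic generator first produces the inputs
    (any explicitly given paths win).  Stages that lack inputs are skipped
    and noted in the report; a stage failure aborts with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, Path] = {}
    if simulate:
        sim = simulate_to_dir(config, outdir / "simulated")
        transcripts = transcripts or sim["transcripts"]
        fpkm = fpkm or sim["fpkm"]
        peaks = peaks or sim["peaks"]
        peaks_alk = peaks_alk or sim.get("peaks_alk")
        organisms = organisms or sim["organisms"]
    if transcripts is None:
        raise ValueError("run_all: no transcripts input")
    bundle = load_reference_bundle(bundle_path)
    recs = read_fasta(transcripts, alphabet="nucleotide")
    inputs["transcripts"] = Path(transcripts)

    candidates = mine_precursors(recs, bundle, config.mining)
    cand_rows = []
    for c in sorted(candidates, key=lambda c: (c.orf.transcript_id, c.orf.nt_span)):
        cand_rows.append(
            {
                "transcript_id": c.orf.transcript_id, "frame": c.orf.frame,
                "nt_start": c.orf.nt_span[0], "nt_end": c.orf.nt_span[1],
                "protein": c.protein, "n_motif_hits": len(c.motif_hits),
                "similarity": c.similarity, "best_ref": c.best_ref,
                "flags": ";".join(c.flags),
            }
        )
    pd.DataFrame(cand_rows).to_csv(
        outdir / "candidates.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )

    candidates = sorted(candidates, key=lambda c: (c.orf.transcript_id, c.orf.nt_span))
    cls_rows, anchored, matures = classify_candidates(candidates, bundle, config)
    org_map: dict[str, str] = {}
    if organisms is not None:
        odf = pd.read_csv(organisms, sep="\t")
        org_map = dict(zip(odf["transcript_id"], odf["organism"]))
        if taxa is None and "section" in odf.columns:
            org_rows = odf.drop_duplicates("organism")
            taxa = dict(zip(org_rows["organism"], org_rows["section"]))
    for row in cls_rows:
        row["organism"] = org_map.get(row["transcript_id"], "unknown")
    cls_df = pd.DataFrame(cls_rows)
    cls_df.to_csv(outdir / "classification.tsv", sep="\t", index=False)

    # domain annotation + anchored gapped FASTA
    dom_rows = []
    with open(outdir / "anchored.fasta", "w") as fh:
        for pid, anc in anchored.items():
            d = segment_domains(anc)
            for name, span in (
                ("ER", d.er_span), ("NTPP", d.ntpp_span), ("CTR", d.ctr_span),
            ):
                if span:
                    dom_rows.append({"precursor_id": pid, "domain": name,
                                     "start": span[0], "end": span[1]})
            for i, (ntr, cd) in enumerate(zip(d.ntr_spans, d.cd_spans)):
                dom_rows.append({"precursor_id": pid, "domain": f"NTR{i + 1}",
                                 "start": ntr[0], "end": ntr[1]})
                dom_rows.append({"precursor_id": pid, "domain": f"CD{i + 1}",
                                 "start": cd[0], "end": cd[1]})
            row = ["-"] * cns.N_COLUMNS
            p2i = anc.segments[0].pos_to_index()
            for pos, idx in p2i.items():
                row[cns.column_of(pos)] = anc.protein[idx]
            fh.write(f">{pid}\n{''.join(row)}\n")
    pd.DataFrame(dom_rows).to_csv(outdir / "domains.tsv", sep="\t", index=False)

    pd.DataFrame(masscalc.candidate_table_rows(matures)).to_csv(
        outdir / "matures.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )

    matches = pd.DataFrame()
    ms_note = "no peak list supplied; MS stages skipped (transcriptome-only run)"
    if peaks is not None:
        pt = read_peak_table(peaks)
        obs = deconvolute(detect_envelopes(pt, config.match), config.match)
        alk_obs = None
        if peaks_alk is not None:
            alk_pt = read_peak_table(peaks_alk)
            alk_obs = deconvolute(
                detect_envelopes(alk_pt, config.match), config.match,
                apply_neutral_window=False,
            )
        obs = confirm_alkylation(obs, alk_obs, config.match)
        matches = match_predicted(matures, obs, config.match)
        matches.to_csv(outdir / "matches.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        ms_note = f"{len(obs)} neutral observations, {int(matches['best'].sum()) if len(matches) else 0} best matches"
        inputs["peaks"] = Path(peaks)

    cross = pd.DataFrame()
    if fpkm is not None:
        fdf = pd.read_csv(fpkm, sep="\t")
        fdf = fdf.rename(columns={"transcript_id": "precursor_id"})
        tid_to_pid = dict(zip(cls_df["transcript_id"], cls_df["precursor_id"]))
        fdf["precursor_id"] = fdf["precursor_id"].map(lambda t: tid_to_pid.get(t, t))
        cross = cross_level_table(cls_df, fdf, matches, config.fpkm_cutoff)
        cross.to_csv(outdir / "cross_level.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        inputs["fpkm"] = Path(fpkm)

    sharing = pd.DataFrame()
    if taxa and len(cls_df):
        sharing = section_sharing(cls_df.dropna(subset=["species"]), taxa)
        sharing.to_csv(outdir / "sharing.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    names = assign_names(
        [
            (row["precursor_id"], row["organism"], _cls_stub(row))
            for row in cls_rows
            if row["species"] is not None and row["organism"] != "unknown"
        ],
        entity="precursor",
    )
    with open(outdir / "names.tsv", "w") as fh:
        fh.write("precursor_id\tname\n")
        for row, nm in zip(
            [r for r in cls_rows if r["species"] is not None and r["organism"] != "unknown"],
            names,
        ):
            fh.write(f"{row['precursor_id']}\t{nm.full_name}\n")

    summary = {
        "n_candidates": len(cls_rows),
        "n_unanchorable": int((cls_df["flags"] == "unanchorable").sum()),
        "lineages": cls_df["lineage"].value_counts().sort_index().to_dict(),
        "subfamilies": cls_df["subfamily"].value_counts().sort_index().to_dict(),
        "n_series": int(cls_df["series"].dropna().nunique()),
        "n_species": int(cls_df["species"].dropna().nunique()),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    manifest = {
        "config_hash": config_hash(config),
        "config": asdict(config),
        "inputs": {k: _checksum(v) for k, v in inputs.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    demo = masscalc.monoisotopic_mass("GIPCGESCVWIPCISSAIGCSCKSKVCYRN", "cyclic", 3)
    with open(outdir / "report.txt", "w") as fh:
        fh.write("cyclomine run report\n====================\n\n")
        fh.write(f"candidates: {summary['n_candidates']}\n")
        fh.write(f"lineage tally: {summary['lineages']}\n")
        fh.write(f"subfamily tally: {summary['subfamilies']}\n")
        fh.write(f"molecular series: {summary['n_series']}, species: {summary['n_species']}\n")
        fh.write(f"MS: {ms_note}\n\n")
        fh.write("worked mass example (cycloviolacin O2, cyclic, 3 disulfides):\n")
        fh.write(f"  M = {demo:.1f} Da, alkylated {demo + masscalc.alkylation_delta(6):.1f} Da, ")
        fh.write(f"[M+2H]2+ = {masscalc.mz_for_charge(demo, 2):.1f}, ")
        fh.write(f"[M+3H]3+ = {masscalc.mz_for_charge(demo, 3):.1f}\n")
    return outdir


def _cls_stub(row):
    from .classify import Classification

    return Classification(
        lineage=row["lineage"], subfamily=row["subfamily"],
        series_key=row["series"], species_key=row["species"],
    )
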