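"""Readers and writers for the plain-text formats the pipeline touches.

FASTA in/out goes through Biopython; delimited tables through pandas.  The
reference bundle is a small directory of text files: a gapped protein
alignment of curated precursors sharing one column space, a column map that
assigns each alignment column an integer consensus position (0 = the
N-terminal cleavage site of the cyclotide domain, negative upstream), and a
table of known mature cyclotides with structural labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceRecord",
    "ReferenceBundle",
    "read_fasta",
    "write_fasta",
    "read_peak_table",
    "load_reference_bundle",
    "default_bundle_path",
]

NUCLEOTIDE_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}
PEAK_COLUMNS = ("rt_min", "mz", "intensity")


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    description: str
    alphabet: str  # "nucleotide" | "protein"
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        allowed = NUCLEOTIDE_ALPHABET if self.alphabet == "nucleotide" else PROTEIN_ALPHABET
        if self.alphabet not in ("nucleotide", "protein"):
            raise ValueError(f"record {self.id!r}: unknown alphabet {self.alphabet!r}")
        for pos, ch in enumerate(self.residues):
            if ch not in allowed:
                raise ValueError(
                    f"record {self.id!r}: illegal {self.alphabet} residue {ch!r} at position {pos}"
                )


def _infer_alphabet(seq: str) -> str:
    letters = set(seq)
    if letters <= NUCLEOTIDE_ALPHABET:
        return "nucleotide"
    return "protein"


def read_fasta(path: str | Path, alphabet: str = "auto") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, order preserved.

    ``alphabet`` is one of nucleotide/protein/auto; auto infers per record
    from residue composition (ACGTN-only reads as nucleotide).  Lowercase is
    normalized to uppercase.  Duplicate ids and illegal letters are errors.
    """
    if alphabet not in ("nucleotide", "protein", "auto"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        ab = _infer_alphabet(seq) if alphabet == "auto" else alphabet
        records.append(
            SequenceRecord(id=rec.id, description=rec.description, alphabet=ab, residues=seq)
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description or "")
        for r in records
    ]
    _BioSeqIO.write(bio, str(path), "fasta")


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_peak_table(
    path: str | Path,
    rt_col: str = "rt_min",
    mz_col: str = "mz",
    intensity_col: str = "intensity",
) -> pd.DataFrame:
    """Load a centroided peak list into a (rt_min, mz, intensity) frame.

    Comma and tab delimiters are auto-detected from the header.  Rows with
    non-positive intensity are dropped (count logged).  The result is sorted
    by (rt_min, mz); duplicate (rt_min, mz) pairs are an error upstream
    export would have to explain, so they are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    delim = _sniff_delimiter(header)
    df = pd.read_csv(path, sep=delim)
    for col in (rt_col, mz_col, intensity_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df = df.rename(columns={rt_col: "rt_min", mz_col: "mz", intensity_col: "intensity"})
    df = df[["rt_min", "mz", "intensity"]]
    for col in PEAK_COLUMNS:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {line}")
        df[col] = converted
    if (df["rt_min"] < 0).any() or (df["mz"] <= 0).any():
        raise ValueError(f"{path}: rt_min must be >= 0 and mz > 0")
    n_before = len(df)
    df = df[df["intensity"] > 0]
    dropped = n_before - len(df)
    if dropped:
        logger.info("read_peak_table: dropped %d rows with intensity <= 0", dropped)
    df = df.sort_values(["rt_min", "mz"], kind="mergesort").reset_index(drop=True)
    if df.duplicated(subset=["rt_min", "mz"]).any():
        raise ValueError(f"{path}: duplicate (rt_min, mz) pairs after loading")
    return df


@dataclass(frozen=True)
class ReferenceBundle:
    """Curated precursors in one alignment column space plus mature references.

    ``column_map[i]`` is the consensus position of alignment column i
    (strictly increasing, exactly one column maps to 0).  ``mature_refs`` has
    columns id, sequence, label with label in {archetypal_moebius,
    archetypal_bracelet, hybrid, linear}.
    """

    alignment_ids: tuple[str, ...]
    alignment_rows: tuple[str, ...]  # gapped, '-' only
    column_map: tuple[int, ...]
    mature_refs: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ncol = len(self.column_map)
        if not self.alignment_rows:
            raise ValueError("reference bundle: empty alignment")
        for rid, row in zip(self.alignment_ids, self.alignment_rows):
            if len(row) != ncol:
                raise ValueError(f"reference bundle: row {rid!r} length != column map length")
            if "." in row:
                raise ValueError(f"reference bundle: row {rid!r} uses '.' gaps; only '-' accepted")
        if len(set(self.column_map)) != ncol:
            raise ValueError("reference bundle: column map is not injective")
        if any(b <= a for a, b in zip(self.column_map, self.column_map[1:])):
            raise ValueError("reference bundle: column map is not strictly increasing")
        if self.column_map.count(0) != 1:
            raise ValueError("reference bundle: no unique column at consensus position 0")
        if not self.cys_columns():
            raise ValueError("reference bundle: no shared cysteine columns in the CD")
        if len(self.cys_columns()) != 6:
            raise ValueError(
                "reference bundle: curated CDs must share exactly six cysteine columns, "
                f"found {len(self.cys_columns())}"
            )
        need = {"id", "sequence", "label"}
        if not need <= set(self.mature_refs.columns):
            raise ValueError("reference bundle: mature_refs must have id, sequence, label")

    def column_of_position(self, pos: int) -> int:
        try:
            return self.column_map.index(pos)
        except ValueError:
            raise KeyError(f"no alignment column at consensus position {pos}") from None

    def position_of_column(self, col: int) -> int:
        return self.column_map[col]

    def cys_columns(self) -> tuple[int, ...]:
        """Alignment columns at consensus positions >= 0 where every row has C."""
        cols = []
        start = next(i for i, p in enumerate(self.column_map) if p >= 0)
        for i in range(start, len(self.column_map)):
            chars = {row[i] for row in self.alignment_rows}
            if chars == {"C"}:
                cols.append(i)
        return tuple(cols)

    def ungapped(self, idx: int) -> str:
        return self.alignment_rows[idx].replace("-", "")

    def prodomain_sequences(self) -> list[tuple[str, str]]:
        """Ungapped ER..NTR (consensus position < 0) portion of each row."""
        col0 = self.column_of_position(0)
        out = []
        for rid, row in zip(self.alignment_ids, self.alignment_rows):
            out.append((rid, row[:col0].replace("-", "")))
        return out


def default_bundle_path() -> Path:
    """Directory of the synthetic reference bundle shipped with the package."""
    return Path(__file__).parent / "data"


def load_reference_bundle(path: str | Path | None = None) -> ReferenceBundle:
    """Load a reference bundle directory; invariants verified, never repaired.

    Expects alignment.fasta (gapped protein FASTA), column_map.tsv
    (column, consensus_position) and mature_refs.tsv (id, sequence, label).
    """
    path = Path(path) if path is not None else default_bundle_path()
    aln_path = path / "alignment.fasta"
    map_path = path / "column_map.tsv"
    ref_path = path / "mature_refs.tsv"
    for p in (aln_path, map_path, ref_path):
        if not p.exists():
            raise FileNotFoundError(f"reference bundle file missing: {p}")
    ids, rows = [], []
    for rec in _BioSeqIO.parse(str(aln_path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    cmap_df = pd.read_csv(map_path, sep="\t")
    cmap_df = cmap_df.sort_values("column")
    if list(cmap_df["column"]) != list(range(len(cmap_df))):
        raise ValueError("column_map.tsv: column indices must be 0..n-1")
    column_map = tuple(int(p) for p in cmap_df["consensus_position"])
    mature = pd.read_csv(ref_path, sep="\t")
    return ReferenceBundle(
        alignment_ids=tuple(ids),
        alignment_rows=tuple(rows),
        column_map=column_map,
        mature_refs=mature,
        metadata={"path": str(path)},
    )


def write_reference_bundle(bundle: ReferenceBundle, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    recs = [
        SequenceRecord(id=i, description="", alphabet="protein", residues=r.replace("-", ""))
        for i, r in zip(bundle.alignment_ids, bundle.alignment_rows)
    ]
    # write the gapped rows directly (SequenceRecord forbids gaps by contract)
    with open(path / "alignment.fasta", "w") as fh:
        for rid, row in zip(bundle.alignment_ids, bundle.alignment_rows):
            fh.write(f">{rid}\n{row}\n")
    pd.DataFrame(
        {"column": range(len(bundle.column_map)), "consensus_position": bundle.column_map}
    ).to_csv(path / "column_map.tsv", sep="\t", index=False)
    bundle.mature_refs.to_csv(path / "mature_refs.tsv", sep="\t", index=False)
    _ = recs  # validation side effect only
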