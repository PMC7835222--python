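"""Readers and writers for the file formats the pipeline consumes and emits.

Every parser validates strictly and fails with a message naming the offending
record, column, or row; nothing is silently dropped. All tabular outputs are
TSV with a ``#``-prefixed header of parameters so runs are self-describing.

Conventions
-----------
* FASTA headers: the token before the first whitespace is the record id, the
  remainder is the organism name.
* ``species_key`` is derived from the organism name by lower-casing and
  joining its first two whitespace tokens with ``_`` (so strain suffixes such
  as "Escherichia coli K-12" and "Escherichia coli O157" collapse to the same
  key), overridable via an explicit metadata TSV.
* The only gap character is ``-``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ALPHABET)
GAP = "-"

# Residue letters accepted in lenient mode but excluded from frequency counts.
AMBIGUITY_CODES = frozenset("BJOUXZ")


class FormatError(ValueError):
    """Raised on any malformed input file."""


def derive_species_key(organism: str) -> str:
    tokens = organism.split()
    return "_".join(t.lower() for t in tokens[:2])


@dataclass
class SequenceRecord:
    """A single ungapped protein sequence with organism metadata."""

    id: str
    organism: str
    sequence: str
    species_key: str = ""

    def __post_init__(self) -> None:
        if not self.species_key:
            self.species_key = derive_species_key(self.organism)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MultipleAlignment:
    """An ordered set of equal-length gapped sequences.

    Columns where every sequence carries a gap are permitted but flagged in
    ``degenerate_columns`` (0-based); downstream scoring assigns them zero.
    """

    ids: list[str]
    sequences: list[str]
    degenerate_columns: list[int] = field(default_factory=list)

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.sequences[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None


@dataclass
class DifferentialExpressionTable:
    """Gene-level log2 fold changes with a significance call per gene."""

    frame: pd.DataFrame  # columns: gene, log2fc, significant[, padj]
    condition_label: str

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class TargetList:
    """Literature targets with their documented direction of regulation."""

    frame: pd.DataFrame  # columns: gene, expected_direction in {up, down}

    def genes(self, direction: str | None = None) -> list[str]:
        f = self.frame
        if direction is not None:
            f = f[f["expected_direction"] == direction]
        return list(f["gene"])


@dataclass
class TimeCourse:
    """One replicate's product-vs-time series.

    ``reading_kind`` is either ``"concentration"`` (µM) or ``"absorbance"``
    (AU at 340 nm); absorbance series must be calibrated against an NADH
    standard curve before rate fitting.
    """

    replicate: str
    condition: str
    times: np.ndarray  # minutes, strictly increasing
    readings: np.ndarray
    reading_kind: str = "concentration"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.readings = np.asarray(self.readings, dtype=float)
        if self.reading_kind not in ("concentration", "absorbance"):
            raise FormatError(f"unknown reading_kind {self.reading_kind!r}")
        if len(self.times) < 3:
            raise FormatError(
                f"replicate {self.replicate!r}: need >= 3 points, got {len(self.times)}"
            )
        if not np.all(np.diff(self.times) > 0):
            raise FormatError(f"replicate {self.replicate!r}: times not strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.readings))):
            raise FormatError(f"replicate {self.replicate!r}: non-finite values")


def _validate_residues(seq: str, rec_id: str, lenient: bool, allow_gaps: bool) -> None:
    allowed = AA_SET | ({GAP} if allow_gaps else set())
    if lenient:
        allowed = allowed | AMBIGUITY_CODES
    for pos, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise FormatError(
                f"record {rec_id!r}: illegal residue {ch!r} at position {pos}"
            )


def read_fasta(path: str | Path, lenient: bool = False) -> list[SequenceRecord]:
    """Read ungapped protein sequences from a FASTA file.

    In strict mode (default) any character outside the 20 standard amino-acid
    letters aborts with the offending position; ``lenient=True`` additionally
    accepts ambiguity codes (excluded from frequency counts downstream).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split(None, 1)
        rec_id = parts[0]
        organism = parts[1].strip() if len(parts) > 1 else ""
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"record {rec_id!r}: empty sequence")
        if rec_id in seen:
            raise FormatError(f"duplicate sequence id {rec_id!r}")
        seen.add(rec_id)
        _validate_residues(seq, rec_id, lenient, allow_gaps=False)
        records.append(SequenceRecord(id=rec_id, organism=organism, sequence=seq))
    if not records:
        raise FormatError(f"{path}: no sequences")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.organism}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_alignment(aln: MultipleAlignment, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec_id, seq in zip(aln.ids, aln.sequences):
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignment(path: str | Path, lenient: bool = False) -> MultipleAlignment:
    """Read a gapped FASTA alignment and validate it as a MultipleAlignment."""
    path = Path(path)
    ids: list[str] = []
    seqs: list[str] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rec_id = rec.description.split(None, 1)[0]
        seq = str(rec.seq).upper()
        if rec_id in seen:
            raise FormatError(f"duplicate sequence id {rec_id!r}")
        seen.add(rec_id)
        _validate_residues(seq, rec_id, lenient, allow_gaps=True)
        ids.append(rec_id)
        seqs.append(seq)
    if not seqs:
        raise FormatError(f"{path}: no sequences")
    if len(seqs) < 2:
        raise FormatError(f"{path}: alignment needs >= 2 sequences, got {len(seqs)}")
    ncol = len(seqs[0])
    ragged = [i for i, s in zip(ids, seqs) if len(s) != ncol]
    if ragged:
        raise FormatError(f"{path}: ragged sequence lengths for ids {ragged}")
    if ncol < 1:
        raise FormatError(f"{path}: zero-length alignment")
    degenerate = [
        c for c in range(ncol) if all(s[c] == GAP for s in seqs)
    ]
    return MultipleAlignment(ids=ids, sequences=seqs, degenerate_columns=degenerate)


def alignment_from_records(records: Sequence[SequenceRecord]) -> MultipleAlignment:
    """Build a trivial columnwise alignment from equal-length ungapped records."""
    lengths = {len(r.sequence) for r in records}
    if len(lengths) != 1:
        raise FormatError(f"records have unequal lengths {sorted(lengths)}")
    return MultipleAlignment(ids=[r.id for r in records], sequences=[r.sequence for r in records])


def read_metadata_keys(path: str | Path) -> dict[str, str]:
    """Read an id -> species_key override table (TSV columns: id, species_key)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("id", "species_key"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return dict(zip(df["id"], df["species_key"]))


def read_de_table(
    path: str | Path,
    condition_label: str,
    padj_threshold: float = 0.05,
) -> DifferentialExpressionTable:
    """Read a TSV of (gene, log2fc, padj | significant).

    A ``padj`` column is converted into the boolean ``significant`` at
    ``padj_threshold`` (the raw values are kept alongside).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene" not in df.columns or "log2fc" not in df.columns:
        missing = {"gene", "log2fc"} - set(df.columns)
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    if "padj" not in df.columns and "significant" not in df.columns:
        raise FormatError(f"{path}: need a 'padj' or 'significant' column")
    df = df.copy()
    df["gene"] = df["gene"].astype(str)
    dupes = df["gene"][df["gene"].duplicated()].unique()
    if len(dupes):
        raise FormatError(f"{path}: duplicate gene symbol(s) {list(dupes)}")
    log2fc = pd.to_numeric(df["log2fc"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(log2fc.to_numpy(dtype=float)))
    if len(bad):
        raise FormatError(
            f"{path}: non-finite log2fc at data row(s) {[int(i) + 1 for i in bad]}"
        )
    df["log2fc"] = log2fc.astype(float)
    if "padj" in df.columns:
        padj = pd.to_numeric(df["padj"], errors="coerce").astype(float)
        if ((padj < 0) | (padj > 1)).any() or padj.isna().any():
            raise FormatError(f"{path}: padj values must lie in [0, 1]")
        df["padj"] = padj
        df["significant"] = padj <= padj_threshold
    else:
        df["significant"] = df["significant"].astype(bool)
    return DifferentialExpressionTable(frame=df.reset_index(drop=True), condition_label=condition_label)


def read_target_list(path: str | Path) -> TargetList:
    """Read a TSV of (gene, expected_direction) with direction in {up, down}."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("gene", "expected_direction"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    dupes = df["gene"][df["gene"].duplicated()].unique()
    if len(dupes):
        raise FormatError(f"{path}: duplicate gene symbol(s) {list(dupes)}")
    bad = sorted(set(df["expected_direction"]) - {"up", "down"})
    if bad:
        raise FormatError(f"{path}: invalid direction value(s) {bad}; allowed: up, down")
    return TargetList(frame=df.reset_index(drop=True))


def read_timecourse(path: str | Path, reading_kind: str = "concentration") -> list[TimeCourse]:
    """Read a CSV of (replicate, condition, time_min, reading) into TimeCourses.

    Rows are grouped by (condition, replicate); each group must be a valid
    series (>= 3 points, strictly increasing times, finite readings).
    """
    df = pd.read_csv(path, comment="#")
    for col in ("replicate", "condition", "time_min", "reading"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df[["time_min", "reading"]].apply(lambda s: ~np.isfinite(pd.to_numeric(s, errors="coerce"))).any().any():
        raise FormatError(f"{path}: non-finite time or reading values")
    out: list[TimeCourse] = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        out.append(
            TimeCourse(
                replicate=str(rep),
                condition=str(cond),
                times=grp["time_min"].to_numpy(dtype=float),
                readings=grp["reading"].to_numpy(dtype=float),
                reading_kind=reading_kind,
            )
        )
    if not out:
        raise FormatError(f"{path}: no time courses")
    return out


def write_timecourses(courses: Iterable[TimeCourse], path: str | Path) -> None:
    rows = []
    for tc in courses:
        for t, y in zip(tc.times, tc.readings):
            rows.append((tc.replicate, tc.condition, t, y))
    pd.DataFrame(rows, columns=["replicate", "condition", "time_min", "reading"]).to_csv(
        path, index=False
    )


def header_block(params: dict) -> str:
    """Format a parameter dict as '#'-prefixed TSV header lines."""
    lines = []
    for key, val in params.items():
        if isinstance(val, float) and math.isfinite(val):
            val = repr(val)
        lines.append(f"# {key}={val}")
    return "\n".join(lines) + "\n"


def write_tsv_with_header(df: pd.DataFrame, path: str | Path, params: dict) -> None:
    with open(path, "w") as fh:
        fh.write(header_block(params))
        df.to_csv(fh, sep="\t", index=False)
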