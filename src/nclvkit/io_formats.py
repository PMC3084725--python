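"""Readers and writers for the external formats the pipeline touches.

Every other module consumes and produces only the in-memory domain types
defined here (:class:`HitRecord`, :class:`GeneFeature`, :class:`Genome`) or
plain :class:`pandas.DataFrame` objects (family tables, phyletic and distance
matrices).  All genomic coordinates are 1-based and inclusive (the GenBank
convention); conversion from 0-based dialects happens once, at this boundary.

Supported formats
-----------------
* 12-column tabular similarity-search results ("outfmt 6" dialect; extra
  trailing columns ignored, ``#`` comment lines skipped),
* gene coordinate tables as GFF3 (``gene``/``CDS`` rows) or 4-column TSV
  ``gene_id, start, end, strand``,
* 2- or 3-column family-membership TSV (``protein_id, family_id[, evalue]``),
* labelled TSV matrices (binary phyletic matrices bit-exactly, distances to
  12 significant digits),
* protein / nucleotide FASTA via Biopython.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised for malformed input files; the message names the offending line."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HitRecord:
    """One row of a pairwise similarity search (BLAST tabular dialect)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue!r}")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"percent identity {self.pct_identity!r} outside [0, 100]")
        if self.aln_length < 1:
            raise ValueError(f"alignment length {self.aln_length!r} < 1")


@dataclass(frozen=True)
class GeneFeature:
    """A gene interval on a linear sequenced fragment (1-based inclusive)."""

    gene_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    rank: int
    product: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")

    @property
    def midpoint(self) -> int:
        """Integer midpoint ``floor((start + end) / 2)``."""
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Genome:
    """An ordered, validated set of gene features on one linear fragment."""

    genome_id: str
    length: int
    features: tuple[GeneFeature, ...]

    def __post_init__(self) -> None:
        starts = [f.start for f in self.features]
        if starts != sorted(starts):
            raise ValueError("features must be sorted by start")
        ranks = [f.rank for f in self.features]
        if len(set(ranks)) != len(ranks):
            raise ValueError("feature ranks must be unique")
        for f in self.features:
            if f.end > self.length:
                raise ValueError(
                    f"gene {f.gene_id!r} ends at {f.end}, beyond genome length {self.length}"
                )

    @classmethod
    def from_features(
        cls, genome_id: str, length: int, features: Iterable[GeneFeature]
    ) -> "Genome":
        """Sort by start and (re)assign 0-based ranks in genome order."""
        ordered = sorted(features, key=lambda f: (f.start, f.end, f.gene_id))
        ranked = tuple(
            GeneFeature(f.gene_id, genome_id, f.start, f.end, f.strand, i, f.product)
            for i, f in enumerate(ordered)
        )
        return cls(genome_id, length, ranked)

    def gene_ids(self) -> list[str]:
        return [f.gene_id for f in self.features]

    def feature_by_id(self) -> dict[str, GeneFeature]:
        return {f.gene_id: f for f in self.features}

    def rank_of(self) -> dict[str, int]:
        return {f.gene_id: f.rank for f in self.features}

    def __len__(self) -> int:
        return len(self.features)


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

_HIT_COLUMNS = 12


def read_hits(path: str | os.PathLike) -> list[HitRecord]:
    """Parse a 12-column tabular hit file into :class:`HitRecord` rows.

    Lines starting with ``#`` and blank lines are skipped; columns beyond the
    twelfth are ignored.  Malformed lines raise :class:`FormatError` naming
    the 1-based line number.
    """
    records: list[HitRecord] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < _HIT_COLUMNS:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= {_HIT_COLUMNS} tab-separated "
                    f"fields, found {len(fields)}"
                )
            try:
                records.append(
                    HitRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_hits(hits: Iterable[HitRecord], path: str | os.PathLike) -> None:
    """Write hits back out in the same 12-column tabular dialect."""
    with open(path, "wt", encoding="utf-8") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        str(h.aln_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------


def _split_table_line(line: str) -> list[str]:
    # the TSV dialect also tolerates comma separation
    return line.split("\t") if "\t" in line else line.split(",")


def read_genome(
    path: str | os.PathLike,
    fmt: str = "tsv",
    genome_id: str | None = None,
    length: int | None = None,
) -> Genome:
    """Read gene coordinates from a 4-column TSV or a GFF3 file.

    TSV dialect: ``gene_id, start, end, strand`` (tab- or comma-separated, an
    optional header row is detected).  GFF3: only ``gene`` and ``CDS`` rows
    are used; the fragment length comes from a ``##sequence-region`` directive
    when present.  If ``length`` is not supplied and not declared, the maximum
    feature end is used.
    """
    if fmt == "tsv":
        return _read_genome_tsv(path, genome_id=genome_id, length=length)
    if fmt == "gff3":
        return _read_genome_gff3(path, genome_id=genome_id, length=length)
    raise ValueError(f"unknown genome format {fmt!r} (expected 'tsv' or 'gff3')")


def _read_genome_tsv(
    path: str | os.PathLike, genome_id: str | None, length: int | None
) -> Genome:
    gid = genome_id or Path(path).stem
    feats: list[GeneFeature] = []
    seen_data = False
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_table_line(line)
            if len(fields) < 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 columns")
            if not seen_data and not fields[1].strip().lstrip("-").isdigit():
                continue  # header row
            seen_data = True
            name, s, e, strand = (f.strip() for f in fields[:4])
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if end < start:
                raise FormatError(
                    f"{path}: line {lineno}: end {end} precedes start {start}"
                )
            try:
                feats.append(GeneFeature(name, gid, start, end, strand, rank=0))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    total = length if length is not None else max((f.end for f in feats), default=0)
    for f in feats:
        if f.end > total:
            raise FormatError(
                f"{path}: gene {f.gene_id!r} ends at {f.end}, beyond declared length {total}"
            )
    return Genome.from_features(gid, total, feats)


def _read_genome_gff3(
    path: str | os.PathLike, genome_id: str | None, length: int | None
) -> Genome:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    declared_len: int | None = None
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            declared_len = int(parts[3])
    feats: list[GeneFeature] = []
    gid = genome_id
    for ftype in ("gene", "CDS"):
        for f in db.features_of_type(ftype):
            gid = gid or f.seqid
            name = f.attributes.get("ID", [f.id])[0]
            product = f.attributes.get("product", [None])[0]
            if f.end < f.start:
                raise FormatError(f"{path}: feature {name!r}: end precedes start")
            strand = f.strand if f.strand in ("+", "-") else "+"
            feats.append(GeneFeature(name, gid or "genome", f.start, f.end, strand, 0, product))
        if feats:
            break  # prefer gene rows; fall back to CDS rows
    total = length or declared_len or max((f.end for f in feats), default=0)
    for f in feats:
        if f.end > total:
            raise FormatError(
                f"{path}: feature {f.gene_id!r} ends at {f.end}, beyond length {total}"
            )
    return Genome.from_features(gid or Path(path).stem, total, feats)


def write_genome(genome: Genome, path: str | os.PathLike) -> None:
    """Write a genome as the 4-column TSV dialect (with header and length comment)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# length={genome.length}\n")
        fh.write("gene_id\tstart\tend\tstrand\n")
        for f in genome.features:
            fh.write(f"{f.gene_id}\t{f.start}\t{f.end}\t{f.strand}\n")


def read_genome_tsv_with_length(path: str | os.PathLike, genome_id: str | None = None) -> Genome:
    """Read back a genome written by :func:`write_genome` (length taken from the comment)."""
    length = None
    with open(path, "rt", encoding="utf-8") as fh:
        first = fh.readline().strip()
    if first.startswith("# length="):
        length = int(first.split("=", 1)[1])
    return read_genome(path, fmt="tsv", genome_id=genome_id, length=length)


# ---------------------------------------------------------------------------
# family tables
# ---------------------------------------------------------------------------


def read_family_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a protein→family TSV into a DataFrame with columns
    ``protein_id, family_id, evalue`` (evalue NaN when absent)."""
    rows: list[tuple[str, str, float]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected >= 2 columns")
            if lineno == 1 and fields[0] == "protein_id":
                continue
            ev = math.nan
            if len(fields) >= 3 and fields[2]:
                try:
                    ev = float(fields[2])
                except ValueError as exc:
                    raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if not fields[1]:
                raise FormatError(f"{path}: line {lineno}: empty family id")
            rows.append((fields[0], fields[1], ev))
    return pd.DataFrame(rows, columns=["protein_id", "family_id", "evalue"])


def write_family_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("protein_id\tfamily_id\tevalue\n")
        for row in table.itertuples(index=False):
            ev = "" if pd.isna(row.evalue) else f"{row.evalue:.6g}"
            fh.write(f"{row.protein_id}\t{row.family_id}\t{ev}\n")


# ---------------------------------------------------------------------------
# labelled matrices (phyletic 0/1 matrices and distance matrices)
# ---------------------------------------------------------------------------


def write_matrix(matrix: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a labelled matrix as TSV.

    Binary/integer matrices round-trip bit-exactly; floating-point matrices
    (distances) are written to 12 significant digits.
    """
    if matrix.empty:
        raise ValueError("refusing to write an empty matrix")
    if matrix.index.duplicated().any() or matrix.columns.duplicated().any():
        raise ValueError("duplicate row or column labels")
    is_integral = all(
        pd.api.types.is_integer_dtype(dt) or pd.api.types.is_bool_dtype(dt)
        for dt in matrix.dtypes
    )
    if is_integral:
        matrix.to_csv(path, sep="\t")
    else:
        matrix.to_csv(path, sep="\t", float_format="%.12g")


def read_matrix(path: str | os.PathLike, binary: bool = False) -> pd.DataFrame:
    """Read a labelled TSV matrix back; ``binary=True`` coerces to int8."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if binary:
        df = df.astype("int8")
    return df


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike) -> int:
    return SeqIO.write(list(records), str(path), "fasta")


def make_seq_record(seq: str, seq_id: str, description: str = "") -> SeqRecord:
    return SeqRecord(Seq(seq), id=seq_id, description=description)
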