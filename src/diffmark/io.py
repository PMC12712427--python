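"""Readers and writers for the text formats the pipeline touches.

bedGraph, BED4/BED6, GFF3, chrom-sizes TSV, FASTA (via Biopython), gene
lists (one id per line) and generic TSV tables. All files are UTF-8;
tables are tab-delimited with a header row. Floats in tables are written
with 6 significant digits.

The only coordinate conversion in the package happens here: GFF3's
1-based closed intervals become 0-based half-open on read.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import ChromSizes, CoverageTrack, GenomicInterval, ValidationError

__all__ = [
    "FormatError",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bedgraph",
    "write_bedgraph",
    "read_features",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_gene_list",
    "write_gene_list",
    "write_table",
    "read_table",
]

FLOAT_FORMAT = "%.6g"


class FormatError(ValueError):
    """A malformed input file; carries the 1-based line number."""

    def __init__(self, path, lineno: int | None, message: str):
        self.path = str(path)
        self.lineno = lineno
        where = f"{path}:{lineno}" if lineno is not None else str(path)
        super().__init__(f"{where}: {message}")


def _data_lines(path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#") or line.startswith(("track", "browser")):
                continue
            yield lineno, line


def read_chrom_sizes(path) -> ChromSizes:
    """Read a two-column (chrom, length) TSV."""
    sizes: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(path, lineno, "expected 2 columns: chrom, length")
        try:
            sizes[fields[0]] = int(fields[1])
        except ValueError as exc:
            raise FormatError(path, lineno, f"bad length {fields[1]!r}") from exc
    try:
        return ChromSizes(sizes)
    except ValidationError as exc:
        raise FormatError(path, None, str(exc)) from exc


def write_chrom_sizes(chrom_sizes: ChromSizes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, length in chrom_sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bedgraph(path, chrom_sizes: ChromSizes | None = None) -> CoverageTrack:
    """Read a 4-column bedGraph into a validated :class:`CoverageTrack`.

    Records are sorted per chromosome; overlapping records are rejected
    (one coverage value per base). Intervals are validated against
    ``chrom_sizes`` when given.
    """
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) < 4:
            raise FormatError(path, lineno, "expected 4 columns: chrom, start, end, value")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
            value = float(fields[3])
        except ValueError as exc:
            raise FormatError(path, lineno, f"bad numeric field: {exc}") from exc
        if start < 0 or end <= start:
            raise FormatError(path, lineno, f"invalid interval [{start}, {end})")
        if value < 0 or not np.isfinite(value):
            raise FormatError(path, lineno, f"invalid coverage value {value}")
        if chrom_sizes is not None:
            if chrom not in chrom_sizes:
                raise FormatError(path, lineno, f"unknown chrom {chrom!r}")
            if end > chrom_sizes[chrom]:
                raise FormatError(
                    path, lineno, f"interval end {end} exceeds chrom length {chrom_sizes[chrom]}"
                )
        by_chrom.setdefault(chrom, []).append((start, end, value))
    data = {}
    for chrom, recs in by_chrom.items():
        recs.sort()
        starts = np.array([r[0] for r in recs], dtype=np.int64)
        ends = np.array([r[1] for r in recs], dtype=np.int64)
        values = np.array([r[2] for r in recs], dtype=np.float64)
        if np.any(starts[1:] < ends[:-1]):
            i = int(np.argmax(starts[1:] < ends[:-1]))
            raise FormatError(
                path, None,
                f"overlapping records on {chrom} near position {int(starts[i + 1])}",
            )
        data[chrom] = (starts, ends, values)
    return CoverageTrack(data, chrom_sizes)


def write_bedgraph(track: CoverageTrack, path, skip_zero: bool = True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, start, end, value in track.records():
            if skip_zero and value == 0:
                continue
            fh.write(f"{chrom}\t{start}\t{end}\t{FLOAT_FORMAT % value}\n")


def _detect_format(path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.upper()
        if fmt not in ("BED", "GFF3"):
            raise ValueError(f"unknown feature format {fmt!r}")
        return fmt
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".bed",):
        return "BED"
    if ext in (".gff", ".gff3"):
        return "GFF3"
    raise ValueError(f"cannot autodetect feature format from extension {ext!r}")


def read_features(
    path,
    fmt: str | None = None,
    feature_type: str = "gene",
    chrom_sizes: ChromSizes | None = None,
) -> list[GenomicInterval]:
    """Read gene/peak/anchor intervals from BED or GFF3.

    GFF3 rows are filtered to ``feature_type`` (default ``gene``) and the
    1-based closed coordinates are converted to 0-based half-open. BED
    coordinates pass through unchanged.
    """
    fmt = _detect_format(path, fmt)
    features: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        try:
            if fmt == "BED":
                if len(fields) < 3:
                    raise FormatError(path, lineno, "BED needs >= 3 columns")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 and fields[3] != "." else None
                strand = fields[5] if len(fields) > 5 else "."
            else:
                if len(fields) < 9:
                    raise FormatError(path, lineno, "GFF3 needs 9 columns")
                if fields[2] != feature_type:
                    continue
                chrom = fields[0]
                start, end = int(fields[3]) - 1, int(fields[4])
                strand = fields[6] if fields[6] in ("+", "-") else "."
                name = _gff3_id(fields[8])
        except FormatError:
            raise
        except ValueError as exc:
            raise FormatError(path, lineno, f"bad coordinate: {exc}") from exc
        try:
            interval = GenomicInterval(chrom, start, end, name=name, strand=strand)
        except ValidationError as exc:
            raise FormatError(path, lineno, str(exc)) from exc
        if chrom_sizes is not None:
            try:
                chrom_sizes.validate_interval(interval)
            except ValidationError as exc:
                raise FormatError(path, lineno, str(exc)) from exc
        features.append(interval)
    return features


def _gff3_id(attributes: str) -> str | None:
    pairs = {}
    for item in attributes.split(";"):
        item = item.strip()
        if "=" in item:
            key, value = item.split("=", 1)
            pairs[key] = value
    return pairs.get("ID") or pairs.get("Name")


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gene_list(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in genes:
            fh.write(f"{gene}\n")


def write_table(records, path, index: bool = False) -> None:
    """Write records (DataFrame or sequence of mappings) as a TSV table.

    Column order is deterministic: DataFrame order, or first-record key
    order for mappings. Floats use 6 significant digits.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        records = list(records)
        frame = pd.DataFrame(records)
        if records and isinstance(records[0], Mapping):
            frame = frame[list(records[0].keys())]
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
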