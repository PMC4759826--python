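"""Reading and writing of the interchange formats used by the pipeline.

All genomic intervals are normalised to 0-based, half-open coordinates
internally.  BED is already 0-based half-open; GFF3 is 1-based inclusive and
is converted on the way in and out.  Malformed records are reported with
their line number.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator


class FormatError(ValueError):
    """A malformed record in an input file; carries the offending line number."""

    def __init__(self, message: str, path: str | Path | None = None,
                 line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


@dataclass
class BedRecord:
    """One 6-column BED line (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    name: str
    score: float = 0.0
    strand: str = "+"

    def to_line(self) -> str:
        score = int(self.score) if float(self.score).is_integer() else self.score
        return f"{self.chrom}\t{self.start}\t{self.end}\t{self.name}\t{score}\t{self.strand}"


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Return [(record id, sequence)] from a FASTA file."""
    with open(path) as fh:
        return [(title.split()[0], seq.upper()) for title, seq in SimpleFastaParser(fh)]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Return [(read id, sequence, quality)] from a Sanger/Phred+33 FASTQ file.

    Quality strings containing characters outside the printable Phred+33
    range ('!' .. '~') are rejected with the line number of the record.
    """
    out = []
    with open(path) as fh:
        for i, (title, seq, qual) in enumerate(FastqGeneralIterator(fh)):
            if any(not ("!" <= c <= "~") for c in qual):
                raise FormatError(
                    f"quality string of read {title!r} contains non-Phred+33 characters",
                    path=path, line=4 * i + 4)
            out.append((title.split()[0], seq.upper(), qual))
    return out


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# BED / GFF3


def parse_bed_line(line: str, path: str | Path | None = None,
                   lineno: int | None = None) -> BedRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise FormatError(f"expected 6 BED columns, got {len(fields)}", path, lineno)
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise FormatError("BED start/end are not integers", path, lineno) from None
    if end <= start:
        raise FormatError(f"BED interval end {end} <= start {start}", path, lineno)
    if fields[5] not in {"+", "-", "."}:
        raise FormatError(f"bad strand {fields[5]!r}", path, lineno)
    try:
        score = float(fields[4])
    except ValueError:
        raise FormatError("BED score is not numeric", path, lineno) from None
    return BedRecord(fields[0], start, end, fields[3], score, fields[5])


def read_bed(path: str | Path) -> list[BedRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            records.append(parse_bed_line(line, path, lineno))
    return records


def write_bed(path: str | Path, records: Iterable[BedRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_line() + "\n")


def read_gff3_genes(path: str | Path, feature_types: tuple[str, ...] = ("gene",)
                    ) -> list[BedRecord]:
    """Read gene features from GFF3 and normalise to 0-based half-open.

    GFF3 intervals are 1-based inclusive: [start, end] maps to
    [start - 1, end).  The record name is taken from the ID attribute.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"expected 9 GFF3 columns, got {len(fields)}",
                                  path, lineno)
            if fields[2] not in feature_types:
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError:
                raise FormatError("GFF3 start/end are not integers", path, lineno) from None
            if start1 < 1 or end1 < start1:
                raise FormatError(f"bad GFF3 interval [{start1}, {end1}]", path, lineno)
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv)
            name = attrs.get("ID", attrs.get("Name", f"feature_{lineno}"))
            records.append(BedRecord(fields[0], start1 - 1, end1, name,
                                     0.0, fields[6] if fields[6] in "+-" else "+"))
    return records


def write_gff3_genes(path: str | Path, records: Iterable[BedRecord],
                     source: str = "triadpart") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            fh.write("\t".join([
                rec.chrom, source, "gene", str(rec.start + 1), str(rec.end),
                ".", rec.strand, ".", f"ID={rec.name}"]) + "\n")


# ---------------------------------------------------------------------------
# TSV tables


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def frame_to_tsv_text(df: pd.DataFrame, index: bool = False) -> str:
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=index)
    return buf.getvalue()
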