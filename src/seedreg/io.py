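"""Readers and writers for BED, GFF3, bedGraph, FASTA and TSV tables.

BED coordinates are kept as-is (0-based half-open). GFF3 is converted at the
boundary from 1-based closed to the internal 0-based half-open convention.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, GeneModel, IntervalSet


class ParseError(ValueError):
    """Malformed line in an annotation file; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


def _int_field(path, lineno, text, what):
    try:
        return int(text)
    except ValueError:
        raise ParseError(path, lineno, f"non-integer {what}: {text!r}") from None


def parse_bed(path) -> IntervalSet:
    """Parse BED3/BED6; extra columns beyond the sixth are ignored."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "fewer than 3 BED columns")
            start = _int_field(path, lineno, fields[1], "start")
            end = _int_field(path, lineno, fields[2], "end")
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand, name))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return IntervalSet(intervals)


def parse_gff3(path) -> IntervalSet:
    """Parse GFF3 features into intervals (1-based closed -> 0-based half-open).

    The feature label is taken from the ``ID`` or ``Name`` attribute when
    present, else left empty.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(path, lineno, "fewer than 9 GFF3 columns")
            start1 = _int_field(path, lineno, fields[3], "start")
            end1 = _int_field(path, lineno, fields[4], "end")
            attrs = parse_gff3_attributes(fields[8])
            name = attrs.get("ID", attrs.get("Name", ""))
            strand = fields[6] if fields[6] in {"+", "-"} else "."
            try:
                intervals.append(
                    GenomicInterval(fields[0], start1 - 1, end1, strand, name)
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return IntervalSet(intervals)


def parse_intervals(path, format: str) -> IntervalSet:
    if format == "BED":
        return parse_bed(path)
    if format == "GFF3":
        return parse_gff3(path)
    raise ValueError(f"unknown interval format {format!r} (expected BED or GFF3)")


def parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for item in text.split(";"):
        item = item.strip()
        if item and "=" in item:
            key, value = item.split("=", 1)
            attrs[key] = value
    return attrs


def write_bed(intervals: Iterable[GenomicInterval], path, score: str = "0") -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


def write_gff3(
    intervals: Iterable[GenomicInterval],
    path,
    source: str = "seedreg",
    feature_type: str = "region",
    extra_attributes: dict[str, dict[str, str]] | None = None,
) -> None:
    """Write intervals as GFF3 (converted back to 1-based closed).

    ``extra_attributes`` maps interval name -> additional column-9 attributes.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in intervals:
            attrs = {"ID": iv.name} if iv.name else {}
            if extra_attributes and iv.name in extra_attributes:
                attrs.update(extra_attributes[iv.name])
            attr_text = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            fh.write(
                f"{iv.chrom}\t{source}\t{feature_type}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attr_text}\n"
            )


def read_gene_models(path) -> list[GeneModel]:
    """GeneModel list from a GFF3 whose ``gene`` features carry ID attributes."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = parse_gff3_attributes(fields[8])
            gene_id = attrs.get("ID", f"gene_{lineno}")
            strand = fields[6]
            body = GenomicInterval(
                fields[0], int(fields[3]) - 1, int(fields[4]), strand, gene_id
            )
            genes.append(GeneModel(gene_id, body, strand))
    return genes


# --- bedGraph -------------------------------------------------------------

def read_bedgraph(path) -> pd.DataFrame:
    """bedGraph as a DataFrame with columns chrom/start/end/value."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split()[:4]
            rows.append((chrom, int(start), int(end), float(value)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in df.itertuples(index=False):
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


# --- FASTA ----------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def write_tsv(df: pd.DataFrame, path) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
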