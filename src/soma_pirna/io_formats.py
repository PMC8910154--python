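"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 0-based half-open internally; conversion from
1-based closed conventions (GTF) happens only here, at the parse/write
boundary. Chromosome names are matched exactly (no "chr" aliasing).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from . import __version__

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenomicInterval:
    """A labeled genomic interval, 0-based half-open.

    ``label`` carries the locus identity (piRNA id, repeat class, gene id);
    ``attrs`` carries format-specific extras (GTF feature kind, biotype, ...).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ParseError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ParseError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SampleSheet:
    """Cohort metadata: one row per sample with group/tissue/batch labels."""

    table: pd.DataFrame  # columns: sample, group, tissue, batch

    def __post_init__(self) -> None:
        required = {"sample", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise ParseError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table["sample"].duplicated().any():
            dupes = self.table.loc[self.table["sample"].duplicated(), "sample"]
            raise ParseError(f"duplicate sample ids: {sorted(set(dupes))}")
        if self.table["group"].nunique() < 1 or len(self.table) == 0:
            raise ParseError("sample sheet needs at least one sample and group")
        for col in ("tissue", "batch"):
            if col not in self.table.columns:
                self.table[col] = ""

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample"])

    def group_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample"] == sample_id]
        if row.empty:
            raise KeyError(f"unknown sample {sample_id!r}")
        return str(row["group"].iloc[0])

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "sample"])


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{chrom: uppercase sequence}``.

    Duplicate chromosome names and empty files are errors.
    """
    path = Path(path)
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ParseError(f"{path}: duplicate chromosome name {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise ParseError(f"{path}: no FASTA records found")
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED6(+) into intervals, kept 0-based half-open as stored.

    Columns beyond the sixth are preserved in ``attrs["extra"]``.
    """
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(
                    f"{path}:{lineno}: empty/inverted interval start={start} end={end}"
                )
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            attrs: dict = {}
            if len(fields) > 4:
                attrs["score"] = fields[4]
            if len(fields) > 6:
                attrs["extra"] = fields[6:]
            out.append(GenomicInterval(chrom, start, end, strand, name, attrs))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = iv.attrs.get("score", "0")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t{score}\t{iv.strand}\n")


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

# Ensembl feature names mapped onto the internal feature vocabulary.
_FEATURE_MAP = {
    "CDS": "CDS",
    "exon": "exon",
    "three_prime_utr": "3UTR",
    "five_prime_utr": "5UTR",
}

_KNOWN_BIOTYPES = {"protein_coding", "lncRNA", "pseudogene"}


def _normalize_biotype(raw: str) -> str:
    if raw in _KNOWN_BIOTYPES:
        return raw
    if raw.endswith("_pseudogene"):
        return "pseudogene"
    return "other"


def read_gtf_features(path: str | Path) -> list[GenomicInterval]:
    """Read Ensembl-dialect GTF feature lines (CDS/exon/UTRs) into intervals.

    GTF is 1-based closed; internal coordinates are 0-based half-open, so
    start is decremented. ``attrs`` carries ``feature`` (CDS/exon/3UTR/5UTR),
    ``gene_id``, and ``biotype`` (protein_coding/lncRNA/pseudogene/other).
    Features outside the recognized set are skipped; a missing gene_id is an
    error.
    """
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: fewer than 9 GTF columns")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields[:9]
            if feature not in _FEATURE_MAP:
                continue
            attrs = dict(_GTF_ATTR_RE.findall(attr_s))
            if "gene_id" not in attrs:
                raise ParseError(f"{path}:{lineno}: GTF record without gene_id")
            biotype = _normalize_biotype(attrs.get("gene_biotype", ""))
            out.append(
                GenomicInterval(
                    chrom,
                    int(start_s) - 1,
                    int(end_s),
                    strand if strand in STRANDS else ".",
                    attrs["gene_id"],
                    {"feature": _FEATURE_MAP[feature], "biotype": biotype},
                )
            )
    return out


def write_gtf_features(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals back out as Ensembl-dialect GTF (inverse of read)."""
    rev_feature = {v: k for k, v in _FEATURE_MAP.items()}
    with open(path, "w") as fh:
        for iv in intervals:
            feature = rev_feature.get(iv.attrs.get("feature", "exon"), "exon")
            biotype = iv.attrs.get("biotype", "other")
            attr = f'gene_id "{iv.label}"; gene_biotype "{biotype}";'
            fh.write(
                f"{iv.chrom}\tsoma_pirna\t{feature}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attr}\n"
            )


def read_alignments(path: str | Path):
    """Read SAM/BAM into :class:`~soma_pirna.align_annotate.AlignedRead` records.

    Multi-mapped placements reported as separate records sharing QNAME are
    grouped into a single read with a placement list; unmapped records are
    dropped. The placement count x is the number of reported placements.
    """
    import pysam

    from .align_annotate import AlignedRead, Placement

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mode = "rb" if path.suffix == ".bam" else "r"
    by_name: dict[str, AlignedRead] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(path), mode) as fh:
        if not fh.header.to_dict().get("SQ"):
            raise ParseError(f"{path}: SAM/BAM without sequence header")
        for rec in fh:
            if rec.is_unmapped:
                continue
            strand = "-" if rec.is_reverse else "+"
            seq = rec.query_sequence or ""
            if rec.is_reverse and seq:
                seq = _revcomp(seq)
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            pl = Placement(rec.reference_name, rec.reference_start, strand, int(nm))
            if rec.query_name not in by_name:
                by_name[rec.query_name] = AlignedRead(rec.query_name, seq.upper(), [pl])
                order.append(rec.query_name)
            else:
                by_name[rec.query_name].placements.append(pl)
    return [by_name[name] for name in order]


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file into ``{set_name: [genes]}``.

    Duplicate set names and empty gene lists are errors; duplicate genes
    within one set are de-duplicated preserving first occurrence.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line with no genes")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: GMT set {name!r} has no genes")
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = list(dict.fromkeys(genes))
    return sets


def read_sample_sheet(path: str | Path) -> SampleSheet:
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    return SampleSheet(table)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (read_id, sequence) pairs as FASTQ with constant quality."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    out = []
    for rec in SeqIO.parse(str(Path(path)), "fastq"):
        out.append((rec.id, str(rec.seq).upper()))
    return out


def write_tsv(df: pd.DataFrame, path: str | Path, params: Mapping | None = None,
              float_format: str = "%.6f") -> None:
    """Write a TSV with a '#' comment prologue recording version and parameters."""
    with open(path, "w") as fh:
        fh.write(f"# soma-pirna v{__version__}\n")
        for key, val in (params or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
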