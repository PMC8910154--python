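"""Read preprocessing, built-in alignment, and hierarchical piRNA annotation.

The identification strategy is deliberately strict: reads are size filtered to
the piRNA range (20-32 nt), placed on the genome allowing at most one
substitution and at most 50 distinct positions, reads touching any other
small-ncRNA locus at any placement are excluded outright, and only the
remainder overlapping piRNA loci are called piRNAs. The built-in aligner
exists so the pipeline never requires an external binary; real cohorts may
instead ingest SAM/BAM via :func:`soma_pirna.io_formats.read_alignments`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .intervals import AnnotationTrack
from .io_formats import _revcomp

MIN_LEN_DEFAULT = 20
MAX_LEN_DEFAULT = 32
MAX_MISMATCH_DEFAULT = 1
MAX_POSITIONS_DEFAULT = 50


@dataclass
class Placement:
    """One genomic placement of a read: 0-based leftmost start on plus strand."""

    chrom: str
    start: int
    strand: str
    mismatches: int = 0

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.start, self.strand)


@dataclass
class AlignedRead:
    """A read and all its genomic placements; x is the placement count."""

    read_id: str
    seq: str
    placements: list[Placement]

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def x(self) -> int:
        return len(self.placements)

    def five_prime(self, pl: Placement) -> int:
        """5' end genomic coordinate of this read at a placement."""
        return pl.start if pl.strand == "+" else pl.start + self.length - 1


CATEGORY_EXCLUDED = "excluded_ncRNA"
CATEGORY_PIRNA = "piRNA"
CATEGORY_UNANNOTATED = "unannotated"


@dataclass
class AnnotatedRead:
    """An aligned read with its annotation category and per-placement piRNA ids."""

    read: AlignedRead
    category: str
    pirna_ids: list[list[str]] = field(default_factory=list)  # parallel to placements


def trim_and_filter(
    reads: Iterable[tuple[str, str]],
    adapter: str = "",
    min_len: int = MIN_LEN_DEFAULT,
    max_len: int = MAX_LEN_DEFAULT,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Adapter-trim and size-filter raw reads.

    If an adapter is configured, the longest read suffix exactly matching an
    adapter prefix of at least 5 nt is removed before the length check. Reads
    outside [min_len, max_len] (inclusive) are dropped. Returns the kept
    (read_id, seq) list and a counts report.
    """
    if adapter and len(adapter) < 5:
        raise ValueError("adapter must be at least 5 nt")
    kept: list[tuple[str, str]] = []
    report = {"input": 0, "trimmed": 0, "length_filtered": 0, "kept": 0}
    for read_id, seq in reads:
        report["input"] += 1
        seq = seq.upper()
        if adapter:
            # longest suffix of the read equal to a prefix of the adapter
            max_k = min(len(seq), len(adapter))
            for k in range(max_k, 4, -1):
                if seq.endswith(adapter[:k]):
                    seq = seq[:-k]
                    report["trimmed"] += 1
                    break
        if min_len <= len(seq) <= max_len:
            kept.append((read_id, seq))
            report["kept"] += 1
        else:
            report["length_filtered"] += 1
    return kept, report


class GenomeIndex:
    """k-mer seed table over both strands of a genome for 1-mismatch seeding.

    With seed length k = min_len // 2, any alignment of a read of length
    >= 2k with at most one substitution has an exact match in at least one of
    the two seed windows [0, k) and [k, 2k) (pigeonhole), so seeded candidate
    verification finds every valid placement.
    """

    def __init__(self, genome: Mapping[str, str], seed_len: int = MIN_LEN_DEFAULT // 2):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.seed_len = seed_len
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.genome.items():
            for pos in range(len(seq) - seed_len + 1):
                kmer = seq[pos : pos + seed_len]
                self._index.setdefault(kmer, []).append((chrom, pos))

    def seed_hits(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def _hamming_le(a: str, b: str, limit: int) -> int:
    """Hamming distance of equal-length strings, or limit+1 once exceeded."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def mini_align(
    reads: Iterable[tuple[str, str]],
    genome: Mapping[str, str] | GenomeIndex,
    max_mismatch: int = MAX_MISMATCH_DEFAULT,
    max_positions: int = MAX_POSITIONS_DEFAULT,
) -> list[AlignedRead]:
    """Place reads on the genome with <= max_mismatch substitutions.

    All placements on both strands are reported; reads with more than
    max_positions distinct placements are discarded entirely. Minus-strand
    placements are found by aligning the read's reverse complement to the
    plus strand; Placement.start is always the leftmost plus-strand
    coordinate.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    k = index.seed_len
    out: list[AlignedRead] = []
    for read_id, seq in reads:
        seq = seq.upper()
        if len(seq) < 2 * k:
            continue
        found: dict[tuple[str, int, str], int] = {}
        for strand, query in (("+", seq), ("-", _revcomp(seq))):
            candidates: set[tuple[str, int]] = set()
            for offset in (0, k):
                for chrom, pos in index.seed_hits(query[offset : offset + k]):
                    start = pos - offset
                    if start >= 0:
                        candidates.add((chrom, start))
            for chrom, start in candidates:
                ref = index.genome[chrom][start : start + len(query)]
                if len(ref) < len(query):
                    continue
                d = _hamming_le(query, ref, max_mismatch)
                if d <= max_mismatch:
                    found[(chrom, start, strand)] = d
        if not found or len(found) > max_positions:
            continue
        placements = [
            Placement(chrom, start, strand, d)
            for (chrom, start, strand), d in sorted(found.items())
        ]
        out.append(AlignedRead(read_id, seq, placements))
    return out


def classify_reads(
    aligned: Iterable[AlignedRead],
    ncrna_track: AnnotationTrack,
    pirna_track: AnnotationTrack,
    min_pirna_overlap_frac: float = 0.5,
    exclusion_min_bp: int = 1,
) -> list[AnnotatedRead]:
    """Hierarchically annotate aligned reads: ncRNA exclusion, then piRNA.

    A read any of whose placements overlaps the ncRNA exclusion track by at
    least ``exclusion_min_bp`` (either strand) is excluded_ncRNA; exclusion
    strictly precedes piRNA annotation, so a read inside both a decoy ncRNA
    and a piRNA locus is excluded. Of the remainder, placements with at least
    ``min_pirna_overlap_frac`` of the read length inside a piRNA locus
    (strand-agnostic) assign that locus's id; reads with no such placement are
    unannotated.
    """
    if len(pirna_track) == 0:
        warnings.warn("empty piRNA track: all non-excluded reads will be unannotated")
    out: list[AnnotatedRead] = []
    for read in aligned:
        excluded = False
        for pl in read.placements:
            end = pl.start + read.length
            for hit in ncrna_track.overlapping(pl.chrom, pl.start, end):
                if min(hit.end, end) - max(hit.start, pl.start) >= exclusion_min_bp:
                    excluded = True
                    break
            if excluded:
                break
        if excluded:
            out.append(AnnotatedRead(read, CATEGORY_EXCLUDED))
            continue
        min_overlap = min_pirna_overlap_frac * read.length
        per_placement: list[list[str]] = []
        any_hit = False
        for pl in read.placements:
            end = pl.start + read.length
            ids = sorted(
                hit.label
                for hit in pirna_track.overlapping(pl.chrom, pl.start, end)
                if min(hit.end, end) - max(hit.start, pl.start) >= min_overlap
            )
            per_placement.append(ids)
            any_hit = any_hit or bool(ids)
        if any_hit:
            out.append(AnnotatedRead(read, CATEGORY_PIRNA, per_placement))
        else:
            out.append(AnnotatedRead(read, CATEGORY_UNANNOTATED))
    return out


def classification_summary(annotated: Iterable[AnnotatedRead]) -> dict[str, int]:
    """Per-category read counts (partition of the aligned input)."""
    counts = {CATEGORY_EXCLUDED: 0, CATEGORY_PIRNA: 0, CATEGORY_UNANNOTATED: 0}
    for ann in annotated:
        counts[ann.category] += 1
    counts["total"] = sum(counts.values())
    return counts
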