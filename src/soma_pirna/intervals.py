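"""Interval index over annotation tracks (intervaltree-backed)."""

from __future__ import annotations

from typing import Iterable

from intervaltree import IntervalTree

from .io_formats import GenomicInterval


class AnnotationTrack:
    """Per-chromosome interval index of labeled loci.

    Thin wrapper over :class:`intervaltree.IntervalTree` keyed by chromosome,
    returning the stored :class:`GenomicInterval` objects on overlap queries.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):  # noqa: D107
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        """All loci overlapping [start, end) on chrom by >= 1 bp, any strand."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(start, end)]

    def overlap_bp(self, iv: GenomicInterval, chrom: str, start: int, end: int) -> int:
        return max(0, min(iv.end, end) - max(iv.start, start))
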