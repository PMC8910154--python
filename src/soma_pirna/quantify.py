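"""piRNA count matrices, presence calling, chromosome RPKM, and set comparisons.

Multi-mapped reads are counted fractionally: a read with x placements
contributes 1/x per placement, split further across piRNA loci co-overlapping
one placement, so every read carries total weight at most 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .align_annotate import AnnotatedRead, CATEGORY_PIRNA
from .io_formats import SampleSheet

MT_NAMES = frozenset({"chrM", "chrMT", "MT", "M"})


@dataclass
class CountMatrix:
    """piRNA-by-sample fractional counts with library sizes and metadata.

    ``lib_size`` is the total aligned-read count per sample before ncRNA
    exclusion (the stable normalizer); counts-per-million normalization
    divides by it.
    """

    counts: pd.DataFrame  # index: pirna_id, columns: sample_id
    lib_size: pd.Series  # per-sample total aligned reads
    meta: SampleSheet

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.lib_size.index):
            raise ValueError("count columns and lib_size samples differ")
        missing = set(self.counts.columns) - set(self.meta.sample_ids)
        if missing:
            raise ValueError(f"samples absent from sample sheet: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def pirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def cpm(self) -> pd.DataFrame:
        """Counts per million library reads."""
        return self.counts * (1e6 / self.lib_size)


@dataclass
class PresenceRule:
    """Expression call thresholds: > min_all in ALL samples, or > min_half in
    at least half of the samples (strict inequalities, ceiling for odd n)."""

    min_all: int = 2
    min_half: int = 10

    def __post_init__(self) -> None:
        if self.min_all > self.min_half:
            raise ValueError("min_all must be <= min_half")


OVARY_RULE = PresenceRule(2, 5)
DEFAULT_RULE = PresenceRule(2, 10)


def build_counts(
    annotated: Mapping[str, list[AnnotatedRead]],
    meta: SampleSheet,
    lib_size: Mapping[str, int] | None = None,
) -> CountMatrix:
    """Aggregate annotated reads into a fractional piRNA x sample matrix.

    counts[p, s] = sum over reads assigned to p in s of 1/(x * loci at that
    placement). lib_size defaults to the number of aligned reads per sample
    (pre-exclusion).
    """
    missing = set(annotated) - set(meta.sample_ids)
    if missing:
        raise ValueError(f"samples not in sample sheet: {sorted(missing)}")
    samples = [s for s in meta.sample_ids if s in annotated]
    cells: dict[str, dict[str, float]] = {}
    sizes = {}
    for sample in samples:
        anns = annotated[sample]
        sizes[sample] = lib_size[sample] if lib_size is not None else len(anns)
        col = cells.setdefault(sample, {})
        for ann in anns:
            if ann.category != CATEGORY_PIRNA:
                continue
            x = ann.read.x
            for ids in ann.pirna_ids:
                if not ids:
                    continue
                w = 1.0 / (x * len(ids))
                for pid in ids:
                    col[pid] = col.get(pid, 0.0) + w
    all_ids = sorted({pid for col in cells.values() for pid in col})
    mat = pd.DataFrame(0.0, index=all_ids, columns=samples)
    for sample, col in cells.items():
        for pid, val in col.items():
            mat.loc[pid, sample] = val
    return CountMatrix(mat, pd.Series(sizes, dtype=float)[samples], meta)


def call_present(cm: CountMatrix, rule: PresenceRule = DEFAULT_RULE) -> set[str]:
    """piRNAs expressed under the presence rule (strict > on both branches)."""
    arr = cm.counts.to_numpy()
    n = arr.shape[1]
    all_branch = (arr > rule.min_all).all(axis=1)
    half_branch = (arr > rule.min_half).sum(axis=1) >= int(np.ceil(n / 2))
    keep = all_branch | half_branch
    return {pid for pid, k in zip(cm.counts.index, keep) if k}


@dataclass
class ChromosomeDistribution:
    """Per-chromosome piRNA read density.

    rpkm[c] = (fraction-weighted reads mapped to c x 1e6)
              / (number of present piRNAs x length of c).
    """

    rpkm: pd.Series
    reads: pd.Series  # fraction-weighted read mass per chromosome
    n_pirnas: int
    mito: pd.Series  # the mitochondrial rows, reported separately


def chromosome_rpkm(
    annotated: Iterable[AnnotatedRead],
    chrom_lengths: Mapping[str, int],
    present: set[str],
) -> ChromosomeDistribution:
    """Chromosome distribution of present-piRNA reads, 1/x weighted."""
    if not present:
        raise ValueError("present piRNA set is empty")
    mass = {c: 0.0 for c in chrom_lengths}
    for ann in annotated:
        if ann.category != CATEGORY_PIRNA:
            continue
        w = 1.0 / ann.read.x
        for pl, ids in zip(ann.read.placements, ann.pirna_ids):
            if any(pid in present for pid in ids):
                mass[pl.chrom] = mass.get(pl.chrom, 0.0) + w
    reads = pd.Series(mass, dtype=float)
    lengths = pd.Series({c: chrom_lengths[c] for c in reads.index}, dtype=float)
    rpkm = reads * 1e6 / (len(present) * lengths)
    is_mt = rpkm.index.isin(MT_NAMES)
    return ChromosomeDistribution(rpkm[~is_mt], reads, len(present), rpkm[is_mt])


def compare_sets(sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """All exclusive region cardinalities of the Venn partition of >= 2 sets."""
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = list(sets)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            rows.append({"region": "&".join(combo), "n_sets": r,
                         "exclusive_size": len(inside - outside),
                         "intersection_size": len(inside)})
    return pd.DataFrame(rows)
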