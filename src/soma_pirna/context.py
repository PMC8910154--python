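"""Genomic-context profiling of annotated piRNA reads.

Each piRNA read's placements are intersected with the repeat track and the
transcript track; the repeat panel (LINE/SINE/LTR/DNA/other_repeat), the
transcript-biotype panel (lncRNA/protein_coding/pseudogene) and the
feature panel (3UTR/5UTR/CDS/exon) are independently denominated views:
ratio = fraction-weighted reads in class / total annotated piRNA reads.
Orientation is feature-relative: sense when the read strand equals the
feature strand (unstranded '.' features count as sense).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align_annotate import AnnotatedRead, CATEGORY_PIRNA
from .intervals import AnnotationTrack
from .quantify import CountMatrix
from .synthetic_data import TRANSPOSON_CLASSES

REPEAT_PANEL = ("LINE", "SINE", "LTR", "DNA", "other_repeat")
BIOTYPE_PANEL = ("lncRNA", "protein_coding", "pseudogene")
FEATURE_PANEL = ("3UTR", "5UTR", "CDS", "exon")
FEATURE_PRIORITY = {"3UTR": 0, "5UTR": 1, "CDS": 2, "exon": 3}
ORIENTATIONS = ("sense", "antisense")


@dataclass
class ContextProfile:
    """Per-sample context ratios: ratio[class][orientation] in [0, 1]."""

    counts: pd.DataFrame  # index (class, orientation), column 'count'
    denominator: float  # total annotated piRNA reads (fraction-weighted)

    @property
    def ratio(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["ratio"] = out["count"] / self.denominator if self.denominator else 0.0
        return out

    def get(self, cls: str, orientation: str) -> float:
        try:
            count = float(self.counts.loc[(cls, orientation), "count"])
        except KeyError:
            return 0.0
        return count / self.denominator if self.denominator else 0.0

    def transposon_ratio(self, orientation: str | None = None) -> float:
        """Combined LINE+SINE+LTR+DNA ratio, optionally one orientation."""
        total = 0.0
        for cls in TRANSPOSON_CLASSES:
            if orientation is None:
                total += self.get(cls, "sense") + self.get(cls, "antisense")
            else:
                total += self.get(cls, orientation)
        return total


def _orientation(read_strand: str, feature_strand: str) -> str:
    if feature_strand == ".":
        return "sense"
    return "sense" if read_strand == feature_strand else "antisense"


def profile_context(
    annotated: Iterable[AnnotatedRead],
    repeat_track: AnnotationTrack,
    transcript_track: AnnotationTrack,
) -> ContextProfile:
    """Classify each piRNA read placement by repeat class, biotype and feature.

    A placement overlapping several classes within one panel splits its 1/x
    weight equally among them; panels are independent, so one placement may
    contribute to a repeat class, a biotype, and a feature simultaneously.
    Gene features overlapping at one placement resolve by the priority
    3UTR > 5UTR > CDS > exon per gene.
    """
    acc: dict[tuple[str, str], float] = {}
    denominator = 0.0
    for ann in annotated:
        if ann.category != CATEGORY_PIRNA:
            continue
        denominator += 1.0
        w = 1.0 / ann.read.x
        for pl in ann.read.placements:
            end = pl.start + ann.read.length

            rep_hits: dict[tuple[str, str], None] = {}
            for hit in repeat_track.overlapping(pl.chrom, pl.start, end):
                cls = hit.attrs.get("class", "other_repeat")
                if cls not in TRANSPOSON_CLASSES:
                    cls = "other_repeat"
                rep_hits[(cls, _orientation(pl.strand, hit.strand))] = None
            for key in rep_hits:
                acc[key] = acc.get(key, 0.0) + w / len(rep_hits)

            tx_hits = transcript_track.overlapping(pl.chrom, pl.start, end)
            bio_hits: dict[tuple[str, str], None] = {}
            by_gene: dict[str, tuple[int, str, str]] = {}
            for hit in tx_hits:
                biotype = hit.attrs.get("biotype", "other")
                ori = _orientation(pl.strand, hit.strand)
                if biotype in BIOTYPE_PANEL:
                    bio_hits[(biotype, ori)] = None
                feature = hit.attrs.get("feature", "")
                if biotype == "protein_coding" and feature in FEATURE_PRIORITY:
                    prio = FEATURE_PRIORITY[feature]
                    prev = by_gene.get(hit.label)
                    if prev is None or prio < prev[0]:
                        by_gene[hit.label] = (prio, feature, ori)
            for key in bio_hits:
                acc[key] = acc.get(key, 0.0) + w / len(bio_hits)
            feat_hits = {(feature, ori) for _, feature, ori in by_gene.values()}
            for key in feat_hits:
                acc[key] = acc.get(key, 0.0) + w / len(feat_hits)

    index = pd.MultiIndex.from_tuples(
        sorted(acc) or [("LINE", "sense")], names=["class", "orientation"]
    )
    counts = pd.DataFrame({"count": [acc.get(key, 0.0) for key in index]}, index=index)
    return ContextProfile(counts, denominator)


def gene_pirna_counts(
    annotated: Mapping[str, list[AnnotatedRead]],
    transcript_track: AnnotationTrack,
    biotype: str = "protein_coding",
) -> pd.DataFrame:
    """Gene x sample matrix of fraction-weighted piRNA reads on gene features.

    A placement overlapping any feature of a gene contributes 1/x to that
    gene once (features of one gene are not double counted).
    """
    cells: dict[str, dict[str, float]] = {}
    for sample, anns in annotated.items():
        col = cells.setdefault(sample, {})
        for ann in anns:
            if ann.category != CATEGORY_PIRNA:
                continue
            w = 1.0 / ann.read.x
            for pl in ann.read.placements:
                end = pl.start + ann.read.length
                genes = {
                    hit.label
                    for hit in transcript_track.overlapping(pl.chrom, pl.start, end)
                    if hit.attrs.get("biotype") == biotype
                }
                for gid in genes:
                    col[gid] = col.get(gid, 0.0) + w
    genes = sorted({g for col in cells.values() for g in col})
    out = pd.DataFrame(0.0, index=genes, columns=list(annotated))
    for sample, col in cells.items():
        for gid, val in col.items():
            out.loc[gid, sample] = val
    return out


@dataclass
class GeneAlignmentRule:
    """piRNA-aligned gene standard.

    stringent: count > 10 in at least 50% of samples OR > 2 in all samples;
    relaxed: count > 2 in strictly more than 10 samples. All strict
    inequalities.
    """

    mode: str = "stringent"

    def passes(self, row) -> bool:
        vals = np.asarray(row, dtype=float)
        n = len(vals)
        if self.mode == "stringent":
            return bool(
                (vals > 10).sum() >= int(np.ceil(n / 2)) or (vals > 2).all()
            )
        if self.mode == "relaxed":
            return bool((vals > 2).sum() > 10)
        raise ValueError(f"unknown mode {self.mode!r}")


def filter_genes(gene_counts: pd.DataFrame, rule: GeneAlignmentRule) -> list[str]:
    """Genes passing the alignment standard (rows with no reads never pass)."""
    return [gid for gid, row in gene_counts.iterrows() if rule.passes(row)]


def compare_context(
    group_a: Sequence[ContextProfile],
    group_b: Sequence[ContextProfile],
    cls: str,
    orientation: str,
) -> dict:
    """Two-sided Wilcoxon rank-sum on per-sample context ratios.

    Exact p-values when the combined sample count permits; significance
    stars at 0.05 / 0.01 / 0.001.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = [p.get(cls, orientation) for p in group_a]
    b = [p.get(cls, orientation) for p in group_b]
    from .stats import rank_sum_test

    w_stat, p = rank_sum_test(a, b)
    stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
    return {
        "class": cls,
        "orientation": orientation,
        "median_a": float(pd.Series(a).median()),
        "median_b": float(pd.Series(b).median()),
        "W": w_stat,
        "p_value": p,
        "stars": stars,
    }


def gene_counts_from_matrix(cm: CountMatrix, pirna_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Collapse a piRNA count matrix to genes via a piRNA -> gene map."""
    sub = cm.counts.loc[[p for p in cm.counts.index if p in pirna_to_gene]]
    if sub.empty:
        return pd.DataFrame(columns=cm.counts.columns)
    return sub.groupby([pirna_to_gene[p] for p in sub.index]).sum()
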