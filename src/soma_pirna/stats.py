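"""Differential piRNA expression and self-contained gene-set enrichment.

The differential engine is the two-sided Wilcoxon rank-sum test on
library-size-normalized counts (counts per million): exact null distribution
for small tie-free samples (combined n <= 20), normal approximation with tie
and continuity correction otherwise. Significance follows the raw p < alpha
rule; Benjamini-Hochberg q-values are reported alongside but do not drive the
significant flag. Enrichment is a hypergeometric upper-tail test against a
GMT gene-set collection with BH correction across sets.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import CountMatrix

EXACT_MAX_COMBINED_N = 20


def _has_ties(values: np.ndarray) -> np.ndarray:
    """Row-wise tie indicator for a 2-D array."""
    s = np.sort(values, axis=-1)
    return (np.diff(s, axis=-1) == 0).any(axis=-1)


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the rank-sum of the first sample. Exact p when the combined sample
    size is <= 20 and there are no ties; otherwise the normal approximation
    with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1 = len(a)
    combined = np.concatenate([a, b])
    exact = (len(combined) <= EXACT_MAX_COMBINED_N
             and len(np.unique(combined)) == len(combined))
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    w = float(res.statistic + n1 * (n1 + 1) / 2)
    return w, float(res.pvalue)


def diff_expression(
    cm: CountMatrix,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-piRNA Wilcoxon rank-sum between two groups of a count matrix.

    Counts are normalized to counts per million library reads before testing
    (the test is rank-based, so per-sample scaling is what matters). Returns
    one row per piRNA with group medians (CPM), W, p, BH q, and the raw-p
    significance flag.
    """
    for g in (group_a, group_b):
        if not cm.meta.samples_in_group(g):
            raise ValueError(f"group {g!r} absent from sample sheet")
    samples_a = [s for s in cm.meta.samples_in_group(group_a) if s in cm.sample_ids]
    samples_b = [s for s in cm.meta.samples_in_group(group_b) if s in cm.sample_ids]
    if len(samples_a) < 3 or len(samples_b) < 3:
        raise ValueError("each group needs at least 3 samples")
    data = cm.cpm() if normalize else cm.counts
    arr_a = data[samples_a].to_numpy()
    arr_b = data[samples_b].to_numpy()
    n1 = arr_a.shape[1]
    n_comb = n1 + arr_b.shape[1]

    p = np.empty(len(data))
    u = np.empty(len(data))
    tied = _has_ties(np.concatenate([arr_a, arr_b], axis=1))
    exact_rows = (~tied) & (n_comb <= EXACT_MAX_COMBINED_N)
    for mask, method in ((exact_rows, "exact"), (~exact_rows, "asymptotic")):
        if mask.any():
            res = stats.mannwhitneyu(arr_a[mask], arr_b[mask],
                                     alternative="two-sided", method=method, axis=-1)
            p[mask] = res.pvalue
            u[mask] = res.statistic
    q = stats.false_discovery_control(p, method="bh")
    return pd.DataFrame({
        "pirna_id": data.index,
        "median_a": np.median(arr_a, axis=1),
        "median_b": np.median(arr_b, axis=1),
        "W": u + n1 * (n1 + 1) / 2,
        "p_value": p,
        "q_value": q,
        "significant": p < alpha,
    }).reset_index(drop=True)


def multi_group_de(
    cm: CountMatrix,
    groups: Sequence[str],
    alpha: float = 0.05,
    pooled_reference: str | None = None,
) -> pd.DataFrame:
    """Kruskal-Wallis across >= 3 groups, plus the pooled two-group contrast.

    For each piRNA the pooled test compares ``pooled_reference`` (default the
    first listed group) against all remaining groups merged; piRNAs
    significant in the multi-group test but not in the pooled one are flagged
    (``staged_only``) — the pattern of stage-dependent expression that a
    two-group design would miss.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    sample_sets = []
    for g in groups:
        smp = [s for s in cm.meta.samples_in_group(g) if s in cm.sample_ids]
        if len(smp) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 usable samples")
        sample_sets.append(smp)
    reference = pooled_reference or groups[0]
    ref_idx = list(groups).index(reference)
    data = cm.cpm()
    arrays = [data[smp].to_numpy() for smp in sample_sets]

    rows = []
    for i, pid in enumerate(data.index):
        vals = [arr[i] for arr in arrays]
        if all(np.all(v == vals[0][0]) for v in vals):
            p_kw = 1.0
        else:
            p_kw = float(stats.kruskal(*vals).pvalue)
        pooled = np.concatenate([v for j, v in enumerate(vals) if j != ref_idx])
        _, p_pooled = rank_sum_test(vals[ref_idx], pooled)
        rows.append({"pirna_id": pid, "p_kruskal": p_kw, "p_pooled": p_pooled,
                     "significant_multi": p_kw < alpha,
                     "staged_only": p_kw < alpha and p_pooled >= alpha})
    return pd.DataFrame(rows)


def enrich(
    query: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    top_n: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of query genes in each gene set.

    p = P(X >= k) with X ~ Hypergeom(N, K, n) where N is the universe size,
    K the in-universe set size, n the query size, and k the overlap;
    gene_ratio = k / K. BH correction across sets; optionally keep the top_n
    sets by q then p.
    """
    query_set = set(query)
    if not query_set:
        raise ValueError("empty query gene list")
    universe_set = set(universe)
    if not query_set <= universe_set:
        raise ValueError("query genes must be a subset of the universe")
    rows = []
    for name, genes in gene_sets.items():
        in_universe = set(genes) & universe_set
        if not in_universe:
            import warnings

            warnings.warn(f"gene set {name!r} does not intersect the universe; skipped")
            continue
        k = len(query_set & in_universe)
        big_n, big_k, n = len(universe_set), len(in_universe), len(query_set)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n)) if k > 0 else 1.0
        rows.append({"set_name": name, "overlap": k, "query_size": n,
                     "set_size": big_k, "universe_size": big_n,
                     "p_value": min(p, 1.0), "gene_ratio": k / big_k})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q_value"] = stats.false_discovery_control(out["p_value"], method="bh")
    out = out.sort_values(["q_value", "p_value", "set_name"]).reset_index(drop=True)
    if top_n is not None:
        out = out.head(top_n)
    return out
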