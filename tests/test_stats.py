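import numpy as np
import pandas as pd
import pytest

from oracles import exact_hypergeom_p, exact_ranksum_p

from soma_pirna import stats as st
from soma_pirna.io_formats import SampleSheet
from soma_pirna.quantify import CountMatrix


def make_cm(counts: pd.DataFrame, groups: dict[str, str],
            lib: pd.Series | None = None) -> CountMatrix:
    sheet = SampleSheet(pd.DataFrame({"sample": list(counts.columns),
                                      "group": [groups[s] for s in counts.columns]}))
    if lib is None:
        lib = pd.Series(1e6, index=counts.columns)
    return CountMatrix(counts, lib, sheet)


class TestRankSumTest:
    def test_separated_triples_exact_p(self):
        w, p = st.rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert w == 6.0  # ranks 1+2+3

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 4), (5, 3), (6, 6), (8, 8)])
    def test_exact_branch_matches_enumeration(self, n1, n2):
        """Exact two-sided p equals exhaustive enumeration of all labelings
        for every tie-free draw at this group-size combination."""
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            vals = rng.permutation(np.arange(1, n1 + n2 + 1) * 1.0)
            a, b = list(vals[:n1]), list(vals[n1:])
            _, p = st.rank_sum_test(a, b)
            assert p == pytest.approx(exact_ranksum_p(a, b), abs=1e-12)

    def test_ties_fall_back_to_asymptotic(self):
        # just verifies the tied path runs and returns a sane p
        _, p = st.rank_sum_test([1, 1, 2, 3], [2, 2, 3, 4])
        assert 0 < p <= 1


class TestDiffExpression:
    def test_identical_constant_groups_p_one(self):
        counts = pd.DataFrame({f"s{i}": [5.0] for i in range(6)}, index=["p1"])
        cm = make_cm(counts, {f"s{i}": ("a" if i < 3 else "b") for i in range(6)})
        out = st.diff_expression(cm, "a", "b")
        assert out.loc[0, "p_value"] == pytest.approx(1.0)
        assert not out.loc[0, "significant"]

    def test_separated_groups_exact_p(self):
        counts = pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=["p1"],
                              columns=[f"s{i}" for i in range(6)], dtype=float)
        cm = make_cm(counts, {f"s{i}": ("a" if i < 3 else "b") for i in range(6)})
        out = st.diff_expression(cm, "a", "b")
        assert out.loc[0, "p_value"] == pytest.approx(0.1)

    def test_library_scaling_invariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(20, size=(10, 8)).astype(float),
                              index=[f"p{i}" for i in range(10)],
                              columns=[f"s{i}" for i in range(8)])
        groups = {f"s{i}": ("a" if i < 4 else "b") for i in range(8)}
        lib = pd.Series(rng.uniform(1e5, 1e6, 8), index=counts.columns)
        p1 = st.diff_expression(make_cm(counts, groups, lib), "a", "b")["p_value"]
        p2 = st.diff_expression(make_cm(counts * 2, groups, lib * 2), "a", "b")["p_value"]
        np.testing.assert_allclose(p1, p2)

    def test_missing_group_rejected(self):
        counts = pd.DataFrame({f"s{i}": [5.0] for i in range(6)}, index=["p1"])
        cm = make_cm(counts, {f"s{i}": "a" for i in range(6)})
        with pytest.raises(ValueError, match="absent"):
            st.diff_expression(cm, "a", "zz")

    def test_small_group_rejected(self):
        counts = pd.DataFrame({f"s{i}": [5.0] for i in range(4)}, index=["p1"])
        cm = make_cm(counts, {"s0": "a", "s1": "a", "s2": "b", "s3": "b"})
        with pytest.raises(ValueError, match="at least 3"):
            st.diff_expression(cm, "a", "b")

    def test_type_one_error_on_null_matrix(self):
        """At alpha=0.05 the fraction of false positives over many null
        piRNAs stays near nominal."""
        rng = np.random.default_rng(7)
        n_pirnas = 2000
        counts = pd.DataFrame(rng.poisson(30.0, size=(n_pirnas, 12)).astype(float),
                              index=[f"p{i}" for i in range(n_pirnas)],
                              columns=[f"s{i}" for i in range(12)])
        groups = {f"s{i}": ("a" if i < 6 else "b") for i in range(12)}
        out = st.diff_expression(make_cm(counts, groups), "a", "b")
        rate = out["significant"].mean()
        assert abs(rate - 0.05) < 0.015


class TestMultiGroupDe:
    def cm3(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.poisson(30.0, size=(20, 12)).astype(float)
        # trend on first 5 piRNAs: premotor down, motor up, control untouched,
        # so control and pooled disease share the same center
        base[:5, 4:8] -= shift
        base[:5, 8:] += shift
        counts = pd.DataFrame(np.clip(base, 0, None),
                              index=[f"p{i}" for i in range(20)],
                              columns=[f"s{i}" for i in range(12)])
        groups = {f"s{i}": ("ctl" if i < 4 else "pre" if i < 8 else "mot")
                  for i in range(12)}
        return make_cm(counts, groups)

    def test_identical_groups_p_one(self):
        counts = pd.DataFrame({f"s{i}": [4.0] for i in range(9)}, index=["p1"])
        cm = make_cm(counts, {f"s{i}": ["a", "b", "c"][i % 3] for i in range(9)})
        out = st.multi_group_de(cm, ["a", "b", "c"])
        assert out.loc[0, "p_kruskal"] == pytest.approx(1.0)

    def test_monotone_trend_flagged_by_three_group_only(self):
        """A control -> premotor -> motor trend with equal pooled means is
        caught by the 3-group test but not by control vs pooled disease."""
        cm = self.cm3(shift=18.0, seed=3)
        out = st.multi_group_de(cm, ["ctl", "pre", "mot"]).set_index("pirna_id")
        trended = out.loc[[f"p{i}" for i in range(5)]]
        assert trended["staged_only"].sum() >= 3

    def test_fewer_than_three_groups_rejected(self):
        cm = self.cm3()
        with pytest.raises(ValueError, match="3 groups"):
            st.multi_group_de(cm, ["ctl", "pre"])

    def test_null_pvalues_roughly_uniform(self):
        """Kruskal-Wallis p-values under the null pass a KS check at 5%."""
        from scipy.stats import kstest

        rng = np.random.default_rng(11)
        counts = pd.DataFrame(rng.normal(100, 10, size=(400, 12)),
                              index=[f"p{i}" for i in range(400)],
                              columns=[f"s{i}" for i in range(12)])
        counts = counts.clip(lower=0)
        groups = {f"s{i}": ["a", "b", "c"][i // 4] for i in range(12)}
        out = st.multi_group_de(make_cm(counts, groups), ["a", "b", "c"])
        # KW on small samples is discrete; compare against its own permutation
        # distribution quantiles loosely via KS on the continuous approximation
        stat = kstest(out["p_kruskal"], "uniform")
        assert stat.pvalue > 0.01


class TestEnrich:
    def test_exact_two_of_two_overlap(self):
        """Universe 10, set of 5, query of 2 fully inside: p = 10/45."""
        universe = [f"g{i}" for i in range(10)]
        out = st.enrich(["g0", "g1"], {"S": universe[:5]}, universe)
        expected = exact_hypergeom_p(2, 10, 5, 2)
        assert expected == pytest.approx(10 / 45)
        assert out.loc[0, "p_value"] == pytest.approx(expected)
        assert out.loc[0, "gene_ratio"] == pytest.approx(2 / 5)

    @pytest.mark.parametrize("n_universe", [8, 12, 20])
    def test_matches_enumeration_on_small_universes(self, n_universe):
        rng = np.random.default_rng(n_universe)
        universe = [f"g{i}" for i in range(n_universe)]
        for _ in range(10):
            k_set = int(rng.integers(1, n_universe))
            n_query = int(rng.integers(1, n_universe))
            gene_set = list(rng.choice(universe, size=k_set, replace=False))
            query = list(rng.choice(universe, size=n_query, replace=False))
            out = st.enrich(query, {"S": gene_set}, universe)
            k = len(set(query) & set(gene_set))
            expected = exact_hypergeom_p(k, n_universe, k_set, n_query) if k else 1.0
            assert out.loc[0, "p_value"] == pytest.approx(expected, abs=1e-12)

    def test_query_equals_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        out = st.enrich(universe, {"S": universe[:5]}, universe)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        out = st.enrich(["g9"], {"S": universe[:5]}, universe)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_bh_q_at_least_p(self):
        universe = [f"g{i}" for i in range(30)]
        sets = {f"S{j}": universe[j : j + 10] for j in range(10)}
        out = st.enrich(universe[:5], sets, universe)
        assert (out["q_value"] >= out["p_value"] - 1e-12).all()

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            st.enrich([], {"S": ["g1"]}, ["g1"])

    def test_disjoint_set_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            out = st.enrich(["g1"], {"S": ["zz"]}, ["g1", "g2"])
        assert out.empty
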