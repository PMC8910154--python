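import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from soma_pirna import classify as cl


def toy_dataset(seed=0, n=16, p=40, n_informative=3, delta=1.5, classes=("A", "B")):
    rng = np.random.default_rng(seed)
    y = np.array([classes[i % len(classes)] for i in range(n)])
    x = rng.normal(size=(n, p))
    for j in range(n_informative):
        x[:, j] += np.where(y == classes[0], delta, -delta) * (1 if j % 2 == 0 else -1)
    xdf = pd.DataFrame(x, columns=[f"f{j}" for j in range(p)],
                       index=[f"s{i}" for i in range(n)])
    return xdf, y


class TestFitSplsda:
    def test_dense_component_matches_svd_oracle(self):
        """With keepX = p the first x-weight vector equals the leading left
        singular vector of the centered, scaled X'Y cross-product."""
        x, y = toy_dataset(seed=1)
        model = cl.fit_splsda(x, y, n_components=1)
        xv = x.to_numpy()
        xs = (xv - xv.mean(0)) / xv.std(0, ddof=1)
        yi = (y[:, None] == np.array(sorted(set(y)))).astype(float)
        u = np.linalg.svd(xs.T @ (yi - yi.mean(0)), full_matrices=False)[0][:, 0]
        u *= np.sign(u[np.abs(u).argmax()])
        np.testing.assert_allclose(model.weights[:, 0], u, atol=1e-8)

    def test_unit_norm_and_sparsity_invariants(self):
        x, y = toy_dataset(seed=2)
        model = cl.fit_splsda(x, y, n_components=3, keepX=[5, 10, 40])
        for h, keep in enumerate(model.keepX):
            assert np.linalg.norm(model.weights[:, h]) == pytest.approx(1.0)
            assert np.count_nonzero(model.weights[:, h]) <= keep

    def test_scores_orthogonal_across_components(self):
        x, y = toy_dataset(seed=3)
        model = cl.fit_splsda(x, y, n_components=3, keepX=10)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_perfect_single_feature_selected_with_keepx_1(self):
        rng = np.random.default_rng(4)
        x = pd.DataFrame(rng.normal(0, 0.1, size=(10, 6)),
                         columns=[f"f{j}" for j in range(6)])
        y = np.array(["A"] * 5 + ["B"] * 5)
        x["f3"] = np.where(y == "A", 5.0, -5.0) + rng.normal(0, 0.1, 10)
        model = cl.fit_splsda(x, y, n_components=1, keepX=1)
        assert model.selected_features[0] == ["f3"]

    def test_zero_variance_features_dropped_with_warning(self):
        x, y = toy_dataset(seed=5)
        x["flat"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            model = cl.fit_splsda(x, y, 1)
        assert "flat" not in model.feature_ids

    def test_keepx_clipped_with_warning(self):
        x, y = toy_dataset(seed=6, p=10)
        with pytest.warns(UserWarning, match="clipped"):
            model = cl.fit_splsda(x, y, 1, keepX=500)
        assert model.keepX == [10]

    def test_single_class_rejected(self):
        x, _ = toy_dataset(seed=7)
        with pytest.raises(ValueError, match="two classes"):
            cl.fit_splsda(x, ["A"] * len(x), 1)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_loadings_match_mixomics(self, tmp_path):
        """Component loadings and selected features agree with the mixOmics
        reference implementation to machine precision on a dense toy."""
        rng = np.random.default_rng(42)
        n, p = 12, 8
        y = np.array(["A"] * 6 + ["B"] * 6)
        x = rng.normal(size=(n, p))
        x[:, 0] += np.where(y == "A", 1.5, -1.5)
        x[:, 1] += np.where(y == "A", -1.0, 1.0)
        np.savetxt(tmp_path / "X.csv", x, delimiter=",")
        (tmp_path / "y.csv").write_text("\n".join(y) + "\n")
        r_code = f'''
        suppressMessages(library(mixOmics))
        X <- as.matrix(read.csv("{tmp_path}/X.csv", header=FALSE))
        y <- factor(readLines("{tmp_path}/y.csv"))
        m <- splsda(X, y, ncomp=2, keepX=c(3, 3))
        write.csv(m$loadings$X, "{tmp_path}/loadings.csv")
        '''
        subprocess.run(["Rscript", "-e", r_code], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "loadings.csv", index_col=0)
        xdf = pd.DataFrame(x, columns=[f"V{j + 1}" for j in range(p)])
        model = cl.fit_splsda(xdf, y, 2, keepX=[3, 3])
        for h in range(2):
            u_ref = ref.iloc[:, h].to_numpy()
            u_ref *= np.sign(u_ref[np.abs(u_ref).argmax()])
            np.testing.assert_allclose(model.weights[:, h], u_ref, atol=1e-10)


class TestPredict:
    def test_training_set_of_separable_problem(self):
        x, y = toy_dataset(seed=8, delta=3.0)
        model = cl.fit_splsda(x, y, 2, keepX=10)
        labels, scores = cl.predict(model, x)
        assert (labels == y).all()
        assert list(scores.columns) == sorted(set(y))

    def test_training_mean_row_predicts_majority_class(self):
        x, y = toy_dataset(seed=9, n=15)  # 8 A vs 7 B
        model = cl.fit_splsda(x, y, 1)
        mean_row = pd.DataFrame([x.mean(0)], index=["m"])
        labels, scores = cl.predict(model, mean_row)
        # scaled input is the zero vector: prediction falls back to the
        # class-frequency centroid
        np.testing.assert_allclose(scores.loc["m"].to_numpy(), model.y_mean)
        assert labels[0] == "A"

    def test_feature_permutation_invariance(self):
        x, y = toy_dataset(seed=10)
        model = cl.fit_splsda(x, y, 2, keepX=10)
        shuffled = x[list(reversed(x.columns))]
        l1, s1 = cl.predict(model, x)
        l2, s2 = cl.predict(model, shuffled)
        assert (l1 == l2).all()
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy())

    def test_missing_features_rejected(self):
        x, y = toy_dataset(seed=11)
        model = cl.fit_splsda(x, y, 1)
        with pytest.raises(ValueError, match="missing features"):
            cl.predict(model, x.drop(columns=["f0"]))


class TestVip:
    def test_mean_vip_squared_is_one(self):
        x, y = toy_dataset(seed=12)
        for keepx in (None, 10):
            model = cl.fit_splsda(x, y, 2, keepX=keepx)
            v = cl.vip(model)
            assert (v**2).mean() == pytest.approx(1.0, abs=1e-6)

    def test_informative_feature_has_max_vip(self):
        rng = np.random.default_rng(13)
        x = pd.DataFrame(rng.normal(size=(12, 5)), columns=list("abcde"))
        y = np.array(["A"] * 6 + ["B"] * 6)
        x["c"] = np.where(y == "A", 2.0, -2.0) + rng.normal(0, 0.2, 12)
        model = cl.fit_splsda(x, y, 1)
        assert cl.vip(model).index[0] == "c"

    def test_vip_invariant_to_column_rescaling(self):
        x, y = toy_dataset(seed=14)
        v1 = cl.vip(cl.fit_splsda(x, y, 2))
        x2 = x.copy()
        x2["f0"] = x2["f0"] * 100.0
        x2["f1"] = x2["f1"] / 50.0
        v2 = cl.vip(cl.fit_splsda(x2, y, 2))
        np.testing.assert_allclose(v1.sort_index(), v2.sort_index(), atol=1e-8)


class TestTuneAndEvaluate:
    def test_perfectly_ranked_scores_give_auc_one(self):
        x, y = toy_dataset(seed=15, delta=4.0, n=12, p=20)
        report = cl.tune_and_evaluate(x, y, component_grid=[1, 2],
                                      keepx_grid=[5, 20])
        assert report.auc == pytest.approx(1.0)
        assert report.accuracy == pytest.approx(1.0)

    def test_deterministic_report(self):
        x, y = toy_dataset(seed=16)
        r1 = cl.tune_and_evaluate(x, y, component_grid=[1, 2], keepx_grid=[5, 40])
        r2 = cl.tune_and_evaluate(x, y, component_grid=[1, 2], keepx_grid=[5, 40])
        assert r1.chosen_components == r2.chosen_components
        assert r1.chosen_keepX == r2.chosen_keepX
        pd.testing.assert_frame_equal(r1.fold_predictions, r2.fold_predictions)

    def test_planted_features_recovered(self):
        rng = np.random.default_rng(17)
        n, p = 15, 200
        y = np.array(["PD"] * 8 + ["control"] * 7)
        x = rng.normal(size=(n, p))
        x[:, :6] += np.where(y == "PD", 1.5, -1.5)[:, None]
        xdf = pd.DataFrame(x, columns=[f"f{j}" for j in range(p)])
        report = cl.tune_and_evaluate(xdf, y, component_grid=[1, 2],
                                      keepx_grid=[5, 10, 25])
        selected = {f for comp in report.model.selected_features for f in comp}
        assert len(selected & {f"f{j}" for j in range(6)}) >= 5

    def test_three_class_cohort_auc(self):
        rng = np.random.default_rng(18)
        n_per, p = 6, 60
        y = np.array(["ctl"] * n_per + ["pre"] * n_per + ["mot"] * n_per)
        x = rng.normal(size=(3 * n_per, p))
        # three informative features per class
        for g in range(3):
            x[g * n_per : (g + 1) * n_per, 3 * g : 3 * g + 3] += 2.5
        xdf = pd.DataFrame(x, columns=[f"f{j}" for j in range(p)])
        report = cl.tune_and_evaluate(xdf, y, component_grid=[2, 3],
                                      keepx_grid=[5, 10])
        assert report.auc >= 0.9

    def test_too_few_samples_rejected(self):
        x, y = toy_dataset(seed=19, n=4)
        with pytest.raises(ValueError, match="at least 5"):
            cl.tune_and_evaluate(x, y)
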