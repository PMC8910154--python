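"""Sparse partial least squares discriminant analysis (sPLS-DA), from scratch.

PLS2 regression of a class-indicator matrix Y on standardized features X:
each component extracts the dominant singular pair of the deflated
cross-product X'Y by power iteration, with sparsity imposed by
soft-thresholding the x-weight vector so that exactly keepX entries stay
non-zero, followed by renormalization and deflation of X (and Y) on the
component scores. Prediction projects new samples through the regression
coefficients and assigns the class with the largest predicted indicator
value ("max.dist"). Model selection follows a two-stage protocol: the number
of components is chosen first by leave-one-out cross-validated accuracy over
a 1..10 grid, then the per-component keepX values are grid-searched
sequentially. Feature relevance is ranked by VIP scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_POWER_TOL = 1e-10
_POWER_MAX_ITER = 1000

DEFAULT_KEEPX_GRID = (5, 10, 25, 50, 100)


@dataclass
class SplsdaModel:
    """A fitted sparse PLS-DA model."""

    feature_ids: list[str]
    classes: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray  # p x H x-weights (unit norm, keepX-sparse)
    x_loadings: np.ndarray  # p x H
    y_loadings: np.ndarray  # g x H
    scores: np.ndarray  # n x H
    keepX: list[int]
    dropped_features: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def selected_features(self) -> list[list[str]]:
        """Features with non-zero weight, per component."""
        return [
            [fid for fid, w in zip(self.feature_ids, self.weights[:, h]) if w != 0.0]
            for h in range(self.n_components)
        ]

    def coefficients(self) -> np.ndarray:
        """Regression coefficients B (p x g) on the standardized scale."""
        w, p_load, c = self.weights, self.x_loadings, self.y_loadings
        inner = p_load.T @ w
        return w @ np.linalg.solve(inner, c.T)


def _soft_threshold_keep(u: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold u so at most ``keep`` entries remain non-zero."""
    if keep >= len(u):
        return u
    mags = np.abs(u)
    # threshold at the (keep+1)-th largest magnitude
    lam = np.partition(mags, -keep - 1)[-keep - 1]
    out = np.sign(u) * np.maximum(mags - lam, 0.0)
    return out


def _indicator(y: np.ndarray, classes: list[str]) -> np.ndarray:
    return (y[:, None] == np.asarray(classes)[None, :]).astype(float)


def fit_splsda(
    x: pd.DataFrame,
    y,
    n_components: int = 2,
    keepX: list[int] | int | None = None,
) -> SplsdaModel:
    """Fit sPLS-DA on a sample x feature matrix and group labels.

    ``x`` holds library-size-normalized counts (samples as rows). Columns are
    centered and scaled to unit variance; zero-variance features are dropped
    with a warning. ``keepX`` gives the number of features retained per
    component (scalar, list, or None for dense). keepX values above the
    feature count are clipped with a warning.
    """
    y = np.asarray(y, dtype=object).astype(str)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if len(x) < 4:
        raise ValueError("need at least 4 samples")

    xv = x.to_numpy(dtype=float)
    x_mean = xv.mean(axis=0)
    x_scale = xv.std(axis=0, ddof=1)
    keep_cols = x_scale > 0
    dropped = [fid for fid, k in zip(x.columns, keep_cols) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance features")
    feature_ids = [fid for fid, k in zip(x.columns, keep_cols) if k]
    xv = (xv[:, keep_cols] - x_mean[keep_cols]) / x_scale[keep_cols]
    p = xv.shape[1]

    if keepX is None:
        keep_list = [p] * n_components
    elif np.isscalar(keepX):
        keep_list = [int(keepX)] * n_components
    else:
        keep_list = [int(k) for k in keepX]
        if len(keep_list) < n_components:
            keep_list += [p] * (n_components - len(keep_list))
    clipped = [min(k, p) for k in keep_list]
    if clipped != keep_list[: n_components]:
        warnings.warn("keepX clipped to the feature count")
    keep_list = clipped

    yi = _indicator(y, classes)
    y_mean = yi.mean(axis=0)
    yd = yi - y_mean
    xd = xv.copy()

    cols_w, cols_p, cols_c, cols_t = [], [], [], []
    for h in range(n_components):
        m = xd.T @ yd  # p x g cross-product
        if np.linalg.norm(m) < 1e-12:
            warnings.warn(f"stopping at {h} components: deflated cross-product vanished")
            break
        v = np.ones(m.shape[1]) / np.sqrt(m.shape[1])
        u = np.zeros(p)
        for _ in range(_POWER_MAX_ITER):
            u_new = m @ v
            u_new = _soft_threshold_keep(u_new, keep_list[h])
            norm = np.linalg.norm(u_new)
            if norm == 0:
                u_new = m @ v
                norm = np.linalg.norm(u_new)
            u_new /= norm
            v = m.T @ u_new
            v /= np.linalg.norm(v)
            if np.linalg.norm(u_new - u) < _POWER_TOL:
                u = u_new
                break
            u = u_new
        # sign convention: largest-magnitude weight positive
        pivot = int(np.argmax(np.abs(u)))
        if u[pivot] < 0:
            u = -u
        t = xd @ u
        tt = float(t @ t)
        if tt == 0:
            warnings.warn(f"stopping at {h} components: degenerate scores")
            break
        p_load = xd.T @ t / tt
        c_load = yd.T @ t / tt
        xd = xd - np.outer(t, p_load)
        yd = yd - np.outer(t, c_load)
        cols_w.append(u)
        cols_p.append(p_load)
        cols_c.append(c_load)
        cols_t.append(t)

    if not cols_w:
        raise ValueError("no components could be extracted")
    return SplsdaModel(
        feature_ids=feature_ids,
        classes=classes,
        x_mean=x_mean[keep_cols],
        x_scale=x_scale[keep_cols],
        y_mean=y_mean,
        weights=np.column_stack(cols_w),
        x_loadings=np.column_stack(cols_p),
        y_loadings=np.column_stack(cols_c),
        scores=np.column_stack(cols_t),
        keepX=keep_list[: len(cols_w)],
        dropped_features=dropped,
    )


def predict(model: SplsdaModel, x_new: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Predict classes for new samples by maximum predicted indicator value.

    Features are aligned by id; unseen or missing feature ids are an error.
    Returns (labels, per-class continuous scores) — the scores feed ROC/AUC.
    """
    missing = [f for f in model.feature_ids if f not in x_new.columns]
    if missing:
        raise ValueError(f"missing features in prediction input: {missing[:5]}...")
    xv = x_new[model.feature_ids].to_numpy(dtype=float)
    xs = (xv - model.x_mean) / model.x_scale
    pred = xs @ model.coefficients() + model.y_mean
    labels = np.asarray(model.classes)[pred.argmax(axis=1)]
    return labels, pd.DataFrame(pred, index=x_new.index, columns=model.classes)


def vip(model: SplsdaModel) -> pd.Series:
    """Variable importance in projection, descending.

    VIP_j = sqrt( p * sum_h SS_h * (w_jh / ||w_h||)^2 / sum_h SS_h ) with
    SS_h the variance of Y explained by component h. For any fit the mean of
    VIP^2 over retained features is 1.
    """
    w = model.weights
    t = model.scores
    c = model.y_loadings
    ss = (c**2).sum(axis=0) * (t**2).sum(axis=0)  # per-component Y variance explained
    w_norm = w / np.linalg.norm(w, axis=0, keepdims=True)
    p = w.shape[0]
    vip2 = p * (w_norm**2 @ ss) / ss.sum()
    out = pd.Series(np.sqrt(vip2), index=model.feature_ids, name="VIP")
    return out.sort_values(ascending=False)


@dataclass
class CvReport:
    """Leave-one-out cross-validation report for the tuned model."""

    chosen_components: int
    chosen_keepX: list[int]
    accuracy: float
    auc: float
    component_grid: pd.DataFrame  # H, loo_accuracy
    keepx_grid: pd.DataFrame  # component, keepX, loo_accuracy
    fold_predictions: pd.DataFrame  # sample, truth, predicted + class scores
    model: SplsdaModel


def _loo_predictions(
    x: pd.DataFrame, y: np.ndarray, n_components: int, keepX: list[int] | None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Pooled LOO predictions (labels and class scores) for one candidate."""
    classes = sorted(set(y))
    labels = np.empty(len(x), dtype=object)
    scores = pd.DataFrame(np.nan, index=x.index, columns=classes)
    for i in range(len(x)):
        mask = np.ones(len(x), dtype=bool)
        mask[i] = False
        y_train = y[mask]
        if len(set(y_train)) < 2:
            warnings.warn(f"LOO fold {i} leaves a single class; skipped")
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_splsda(x.iloc[mask], y_train, n_components, keepX)
            lab, sc = predict(model, x.iloc[[i]])
        except ValueError:
            continue
        labels[i] = lab[0]
        for cls in model.classes:
            scores.iloc[i, scores.columns.get_loc(cls)] = sc.iloc[0][cls]
    return labels, scores


def _loo_accuracy(labels: np.ndarray, y: np.ndarray) -> float:
    valid = np.array([lab is not None for lab in labels])
    if not valid.any():
        return 0.0
    return float((labels[valid] == y[valid]).mean())


def _macro_auc(y: np.ndarray, scores: pd.DataFrame, classes: list[str]) -> float:
    """One-vs-rest macro AUC from pooled LOO class scores.

    For two classes, the AUC of the positive (last) class score is reported.
    """
    from sklearn.metrics import roc_auc_score

    valid = ~scores.isna().any(axis=1).to_numpy()
    yv = y[valid]
    sv = scores.loc[valid]
    if len(classes) == 2:
        return float(roc_auc_score((yv == classes[1]).astype(int), sv[classes[1]]))
    aucs = []
    for cls in classes:
        truth = (yv == cls).astype(int)
        if truth.min() == truth.max():
            continue
        aucs.append(roc_auc_score(truth, sv[cls]))
    return float(np.mean(aucs)) if aucs else float("nan")


def tune_and_evaluate(
    x: pd.DataFrame,
    y,
    component_grid: range | list[int] = range(1, 11),
    keepx_grid: list[int] | None = None,
    seed: int | None = None,
) -> CvReport:
    """Two-stage LOO tuning: number of components first, then keepX per component.

    Stage 1 fits dense models for each candidate component count and keeps
    the one with the best LOO accuracy (ties break toward fewer components).
    Stage 2 walks components in order, grid-searching keepX for the current
    component with earlier choices fixed and later components dense (ties
    break toward smaller keepX). The report carries pooled LOO accuracy and
    macro one-vs-rest AUC of the final configuration, per-fold predictions,
    and the model refit on all samples. ``seed`` is accepted for interface
    stability; the procedure is deterministic.
    """
    y = np.asarray(y, dtype=object).astype(str)
    if len(x) < 5:
        raise ValueError("need at least 5 samples for LOO tuning")
    classes = sorted(set(y))
    p = x.shape[1]
    if keepx_grid is None:
        keepx_grid = sorted({min(k, p) for k in (*DEFAULT_KEEPX_GRID, p)})
    else:
        keepx_grid = sorted({min(int(k), p) for k in keepx_grid})
    max_h = min(len(x) - 2, p)
    component_grid = [h for h in component_grid if 1 <= h <= max_h] or [1]

    comp_rows = []
    best_h, best_acc = component_grid[0], -1.0
    for h in component_grid:
        labels, _ = _loo_predictions(x, y, h, None)
        acc = _loo_accuracy(labels, y)
        comp_rows.append({"n_components": h, "loo_accuracy": acc})
        if acc > best_acc:  # strict: ties keep the smaller H
            best_h, best_acc = h, acc

    keepx_rows = []
    chosen: list[int] = []
    for h in range(1, best_h + 1):
        best_kx, best_kx_acc = None, -1.0
        for kx in keepx_grid:
            candidate = chosen + [kx] + [p] * (best_h - h)
            labels, _ = _loo_predictions(x, y, best_h, candidate)
            acc = _loo_accuracy(labels, y)
            keepx_rows.append({"component": h, "keepX": kx, "loo_accuracy": acc})
            if acc > best_kx_acc:  # ties keep the smaller keepX (grid is sorted)
                best_kx, best_kx_acc = kx, acc
        chosen.append(best_kx)

    labels, scores = _loo_predictions(x, y, best_h, chosen)
    accuracy = _loo_accuracy(labels, y)
    auc = _macro_auc(y, scores, classes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final_model = fit_splsda(x, y, best_h, chosen)
    folds = pd.DataFrame({"sample": x.index, "truth": y, "predicted": labels})
    folds = pd.concat([folds.reset_index(drop=True),
                       scores.reset_index(drop=True)], axis=1)
    return CvReport(
        chosen_components=best_h,
        chosen_keepX=chosen,
        accuracy=accuracy,
        auc=auc,
        component_grid=pd.DataFrame(comp_rows),
        keepx_grid=pd.DataFrame(keepx_rows),
        fold_predictions=folds,
        model=final_model,
    )
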