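"""Sparse PLS discriminant analysis for binary era labels.

Per component the full PLS weight vector is computed from the X/Y
cross-covariance, only the ``keep`` largest-magnitude entries are retained
(the rest soft-thresholded to zero), the retained block is renormalized and
the procedure iterated to convergence before deflating X.  Component-1
loadings drive variable selection; the sign convention fixes positive
loadings to the positive (COVID-era) class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from eradiff.feature_table import InputError

_TOL = 1e-9
_MAX_ITER = 500


@dataclass
class SplsdaModel:
    weights: np.ndarray  # features x components, unit-norm, sparse
    scores: np.ndarray  # samples x components
    selected: list[list[str]]  # per component, labels of nonzero loadings
    feature_labels: list[str]
    classes: tuple[str, str]  # (negative, positive)
    keep: list[int]
    x_mean: np.ndarray
    x_scale: np.ndarray
    scaled: bool
    n_iter: list[int] = field(default_factory=list)

    def transform(self, x_new: np.ndarray) -> np.ndarray:
        """Component-1 scores for new samples (no deflation needed)."""
        x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
        return (x_new - self.x_mean) / self.x_scale @ self.weights[:, 0]


@dataclass
class StabilityReport:
    frequencies: pd.Series  # per-feature selection frequency over folds
    n_folds: int
    stable_set: list[str]  # features selected in every fold
    predicted_scores: np.ndarray  # per-sample left-out component-1 score (nan if skipped)
    y: np.ndarray  # class labels aligned with predicted_scores


def _one_hot(y, positive_class) -> tuple[np.ndarray, tuple[str, str]]:
    y = np.asarray(y)
    classes = sorted(set(np.unique(y).tolist()))
    if len(classes) != 2:
        raise InputError(f"need exactly 2 classes, got {classes}")
    if positive_class is None:
        positive_class = "covid" if "covid" in classes else classes[1]
    if positive_class not in classes:
        raise InputError(f"positive class {positive_class!r} not among labels {classes}")
    negative = next(c for c in classes if c != positive_class)
    ind = np.column_stack([(y == negative).astype(float), (y == positive_class).astype(float)])
    return ind, (negative, positive_class)


def _sparse_weight(w: np.ndarray, keep: int, labels: list[str]) -> np.ndarray:
    """Retain the ``keep`` largest-magnitude entries, soft-threshold the rest.

    Boundary ties are broken lexicographically by feature label; a kept entry
    whose magnitude ties the threshold exactly is given a vanishing positive
    weight so the nonzero count is exactly ``keep``.
    """
    p = len(w)
    if keep >= p:
        return w / np.linalg.norm(w)
    mag = np.abs(w)
    order = sorted(range(p), key=lambda j: (-mag[j], labels[j]))
    kept = order[:keep]
    lam = mag[order[keep]]
    out = np.zeros_like(w)
    shrunk = mag[kept] - lam
    floor = max(mag.max(), 1.0) * 1e-15  # keeps exact boundary ties nonzero
    out[kept] = np.sign(w[kept]) * np.maximum(shrunk, floor)
    return out / np.linalg.norm(out)


def fit_splsda(
    x,
    y,
    n_components: int = 2,
    keep_per_component=None,
    scale: bool = True,
    positive_class: str | None = None,
    feature_labels: list[str] | None = None,
) -> SplsdaModel:
    """Fit a sparse PLS-DA model on a samples x features matrix.

    ``keep_per_component`` is an int (same keep for every component), a list
    per component, or None for dense PLS-DA.  Columns are centered and, by
    default, unit-variance scaled before fitting.  Deterministic given input
    order; boundary ties in the selection are broken lexicographically.
    """
    if isinstance(x, pd.DataFrame):
        feature_labels = feature_labels or [str(c) for c in x.columns]
        x = x.values
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if feature_labels is None:
        feature_labels = [f"feature_{j}" for j in range(p)]
    y_ind, classes = _one_hot(y, positive_class)
    pos_indicator = y_ind[:, 1]

    if keep_per_component is None:
        keeps = [p] * n_components
    elif np.isscalar(keep_per_component):
        keeps = [int(keep_per_component)] * n_components
    else:
        keeps = [int(k) for k in keep_per_component]
        if len(keeps) != n_components:
            raise InputError("keep_per_component length must equal n_components")
    for k in keeps:
        if k < 1 or k > p:
            raise InputError(f"keep must be in [1, n_features={p}], got {k}")

    x_mean = x.mean(axis=0)
    if scale:
        x_scale = x.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
    else:
        x_scale = np.ones(p)
    xc = (x - x_mean) / x_scale
    yc = y_ind - y_ind.mean(axis=0)

    weights = np.zeros((p, n_components))
    scores = np.zeros((n, n_components))
    selected: list[list[str]] = []
    n_iter: list[int] = []
    for h in range(n_components):
        m = xc.T @ yc  # p x 2 cross-covariance
        # initialize the y-side direction from the dominant right singular vector
        _, _, vt = np.linalg.svd(m, full_matrices=False)
        v = vt[0]
        w = np.zeros(p)
        iters = 0
        for iters in range(1, _MAX_ITER + 1):
            w_new = m @ v
            norm = np.linalg.norm(w_new)
            if norm == 0:
                w_new = np.zeros(p)
                w_new[0] = 1.0
            else:
                w_new = _sparse_weight(w_new, keeps[h], feature_labels)
            v_new = m.T @ w_new
            v_norm = np.linalg.norm(v_new)
            if v_norm > 0:
                v_new = v_new / v_norm
            if np.linalg.norm(w_new - w) < _TOL:
                w, v = w_new, v_new
                break
            w, v = w_new, v_new
        t = xc @ w
        # orient so higher component score tracks the positive class
        cov_pos = t @ (pos_indicator - pos_indicator.mean())
        if cov_pos < 0:
            w, t = -w, -t
        elif cov_pos == 0:
            j = int(np.argmax(np.abs(w)))
            if w[j] < 0:
                w, t = -w, -t
        weights[:, h] = w
        scores[:, h] = t
        selected.append([feature_labels[j] for j in np.flatnonzero(w)])
        n_iter.append(iters)
        tt = t @ t
        if tt > 0:
            c = xc.T @ t / tt
            xc = xc - np.outer(t, c)
            dvec = yc.T @ t / tt
            yc = yc - np.outer(t, dvec)

    return SplsdaModel(
        weights=weights,
        scores=scores,
        selected=selected,
        feature_labels=list(feature_labels),
        classes=classes,
        keep=keeps,
        x_mean=x_mean,
        x_scale=x_scale,
        scaled=scale,
        n_iter=n_iter,
    )


def top_loadings(model: SplsdaModel, component: int = 1, k: int = 50) -> pd.DataFrame:
    """The k largest-|loading| features of a component, with signs.

    Positive loading means higher abundance in the positive (COVID-era)
    class.  Equal magnitudes are ordered lexicographically by label.
    """
    if component < 1 or component > model.weights.shape[1]:
        raise InputError(f"component {component} not fitted")
    w = model.weights[:, component - 1]
    nz = np.flatnonzero(w)
    if k > len(nz):
        warnings.warn(
            f"requested top {k} but only {len(nz)} nonzero loadings; returning all",
            stacklevel=2,
        )
        k = len(nz)
    order = sorted(nz, key=lambda j: (-abs(w[j]), model.feature_labels[j]))[:k]
    return pd.DataFrame(
        {
            "feature": [model.feature_labels[j] for j in order],
            "loading": w[order],
            "era_direction": [model.classes[1] if w[j] > 0 else model.classes[0] for j in order],
        }
    )


def loocv_stability(
    x,
    y,
    n_components: int = 1,
    keep: int | None = None,
    scale: bool = True,
    positive_class: str | None = None,
) -> StabilityReport:
    """Leave-one-out selection stability and held-out component-1 scores.

    Each fold refits the model without one sample and records the
    component-1 selected set plus the left-out sample's predicted
    component-1 score.  Folds that would lose a class entirely are skipped
    with a warning.
    """
    if isinstance(x, pd.DataFrame):
        labels = [str(c) for c in x.columns]
        x = x.values
    else:
        x = np.asarray(x, dtype=float)
        labels = [f"feature_{j}" for j in range(x.shape[1])]
    y = np.asarray(y)
    n = x.shape[0]
    if n < 3:
        raise InputError("leave-one-out stability needs at least 3 samples")

    counts = pd.Series(0, index=labels, dtype=float)
    predicted = np.full(n, np.nan)
    n_folds = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(set(y[mask].tolist())) < 2:
            warnings.warn(f"fold {i} would remove a class entirely; skipped", stacklevel=2)
            continue
        model = fit_splsda(
            x[mask],
            y[mask],
            n_components=n_components,
            keep_per_component=keep,
            scale=scale,
            positive_class=positive_class,
            feature_labels=labels,
        )
        counts[model.selected[0]] += 1
        predicted[i] = model.transform(x[i])[0]
        n_folds += 1
    freqs = counts / n_folds
    stable = [f for f in labels if freqs[f] == 1.0]
    return StabilityReport(
        frequencies=freqs,
        n_folds=n_folds,
        stable_set=stable,
        predicted_scores=predicted,
        y=y,
    )


def auroc(scores, y, positive_class: str | None = None) -> float:
    """Area under the ROC curve by the Mann-Whitney formulation; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    ok = ~np.isnan(scores)
    scores, y = scores[ok], y[ok]
    _, classes = _one_hot(y, positive_class)
    pos = y == classes[1]
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("AUROC undefined with a single class")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
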