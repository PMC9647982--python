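"""PLS-DA screening of line-differential metabolites.

Two-class partial least squares discriminant analysis fitted by NIPALS on the
class label coded +/-1, with unit-variance (autoscaled) features.  Model
quality is summarised by R2X and R2Y (goodness of fit) and Q2Y (goodness of
prediction under sevenfold stratified cross-validation).  Per-feature variable
importance in projection (VIP) scores satisfy sum_j VIP_j^2 = p, and a feature
is called differential when VIP > 1 and the two-sided pooled-variance
Student's t-test gives P < 0.05 (strict inequalities, no multiplicity
correction by default; an optional Benjamini-Hochberg switch is provided).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .exceptions import (
    ConfigurationError,
    InputError,
    ModelError,
    StratificationError,
)

__all__ = [
    "autoscale",
    "PLSDA",
    "fit_plsda",
    "q2_sevenfold",
    "compute_vip",
    "student_t_per_feature",
    "call_differentials",
]


def autoscale(X):
    """Center each column to mean 0 and scale to unit variance (ddof=1).

    Constant columns cannot be scaled: they are dropped with a warning.

    Returns
    -------
    X_scaled : ndarray (n, p_kept)
    mean : ndarray (p,)
    scale : ndarray (p,)
    kept : ndarray of bool (p,)
        Mask of non-constant columns retained.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InputError("expected a 2-D matrix")
    if X.shape[0] < 2:
        raise InputError("autoscaling needs at least 2 samples")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    kept = scale > 0
    if not np.all(kept):
        warnings.warn(
            f"dropping {int((~kept).sum())} constant column(s) before PLS", stacklevel=2
        )
    Xs = (X[:, kept] - mean[kept]) / scale[kept]
    return Xs, mean, scale, kept


class PLSDA(ClassifierMixin, BaseEstimator):
    """Two-class PLS-DA fitted by NIPALS on a +/-1 class code.

    Parameters
    ----------
    n_components : int, default 2
        Number of latent components A.
    scale : bool, default True
        Autoscale features before fitting (recommended; makes VIP comparable
        across intensity scales).

    Attributes (after fit)
    ----------------------
    x_weights_ : ndarray (p_kept, A)   unit-norm weight vectors w_a
    x_scores_ : ndarray (n, A)         score vectors t_a (mutually orthogonal)
    x_loadings_ : ndarray (p_kept, A)  loadings p_a
    y_loadings_ : ndarray (A,)         scalars b_a
    r2x_, r2y_ : float                 cumulative variance explained
    vip_ : ndarray (p_kept,)           variable importance in projection
    classes_ : ndarray (2,)            label order; second class is coded +1
    """

    def __init__(self, n_components: int = 2, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def _encode(self, y):
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise InputError(f"PLS-DA needs exactly 2 classes, got {classes.size}")
        return classes, np.where(y == classes[1], 1.0, -1.0)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.classes_, y_coded = self._encode(y)
        n, p = X.shape
        A = self.n_components
        if A < 1 or A > min(n - 1, p):
            raise ConfigurationError(
                f"n_components={A} must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
            )
        if self.scale:
            Xw, self.x_mean_, self.x_scale_, self.kept_features_ = autoscale(X)
        else:
            self.x_mean_ = X.mean(axis=0)
            self.x_scale_ = np.ones(p)
            self.kept_features_ = np.ones(p, dtype=bool)
            Xw = X - self.x_mean_
        self.y_mean_ = y_coded.mean()
        yw = y_coded - self.y_mean_

        ssx0 = float(np.sum(Xw**2))
        ssy0 = float(np.sum(yw**2))
        if ssy0 == 0:
            raise InputError("class code has zero variance")
        W, T, P = [], [], []
        B = []
        r2x_cum, r2y_cum = [], []
        for _ in range(A):
            w = Xw.T @ yw
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ModelError("X carries no covariance with the class code")
            w /= norm
            t = Xw @ w
            tt = float(t @ t)
            if tt == 0:
                raise ModelError("degenerate component with zero score variance")
            p_load = Xw.T @ t / tt
            b = float(yw @ t / tt)
            Xw = Xw - np.outer(t, p_load)
            yw = yw - b * t
            W.append(w)
            T.append(t)
            P.append(p_load)
            B.append(b)
            r2x_cum.append(1.0 - np.sum(Xw**2) / ssx0)
            r2y_cum.append(1.0 - np.sum(yw**2) / ssy0)
        self.x_weights_ = np.column_stack(W)
        self.x_scores_ = np.column_stack(T)
        self.x_loadings_ = np.column_stack(P)
        self.y_loadings_ = np.array(B)
        self.r2x_per_component_ = np.array(r2x_cum)
        self.r2y_per_component_ = np.array(r2y_cum)
        self.r2x_ = float(r2x_cum[-1])
        self.r2y_ = float(r2y_cum[-1])
        self.vip_ = compute_vip(self)
        return self

    def _transform_scores(self, X):
        X = np.asarray(X, dtype=float)
        kept = self.kept_features_
        Xw = (X[:, kept] - self.x_mean_[kept]) / self.x_scale_[kept]
        scores = np.empty((X.shape[0], self.x_weights_.shape[1]))
        for a in range(self.x_weights_.shape[1]):
            t = Xw @ self.x_weights_[:, a]
            scores[:, a] = t
            Xw = Xw - np.outer(t, self.x_loadings_[:, a])
        return scores

    def transform(self, X):
        """Latent scores for new samples."""
        return self._transform_scores(X)

    def decision_function(self, X):
        """Continuous prediction of the +/-1 class code."""
        return self.y_mean_ + self._transform_scores(X) @ self.y_loadings_

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, self.classes_[1], self.classes_[0])


def fit_plsda(X, y, n_components: int = 2, scale: bool = True) -> PLSDA:
    """Convenience wrapper: fit a :class:`PLSDA` model."""
    return PLSDA(n_components=n_components, scale=scale).fit(X, y)


def compute_vip(model: PLSDA) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a * (w_ja / ||w_a||)^2 / sum_a SSY_a ) with
    SSY_a = b_a^2 * (t_a . t_a); satisfies sum_j VIP_j^2 = p exactly.
    """
    w = model.x_weights_
    t = model.x_scores_
    b = model.y_loadings_
    p = w.shape[0]
    ssy = b**2 * np.einsum("ia,ia->a", t, t)
    total = ssy.sum()
    if total <= 0:
        raise ModelError("zero explained class variance; VIP undefined")
    wnorm2 = (w / np.linalg.norm(w, axis=0, keepdims=True)) ** 2
    return np.sqrt(p * (wnorm2 @ ssy) / total)


def _stratified_folds(y, n_folds, rng):
    """Round-robin class-stratified fold assignment."""
    y = np.asarray(y)
    folds = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds


def q2_sevenfold(X, y, n_components: int = 2, seed: int = 0, n_folds: int = 7) -> float:
    """Cross-validated goodness of prediction Q2Y = 1 - PRESS/TSS.

    Samples are partitioned into ``n_folds`` (default seven) class-stratified
    folds; per fold a PLS-DA model (including the autoscaling) is refitted on
    the remaining folds and the held-out class code predicted.  TSS is taken
    about the training-fold mean of the code, PRESS and TSS accumulated over
    folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < n_folds:
        raise InputError(f"need at least {n_folds} samples for {n_folds}-fold CV")
    classes = np.unique(y)
    if classes.size != 2:
        raise InputError("Q2 requires exactly 2 classes")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, n_folds, rng)
    y_coded = np.where(y == classes[1], 1.0, -1.0)
    press = 0.0
    tss = 0.0
    for k in range(n_folds):
        test = folds == k
        train = ~test
        if not test.any():
            continue
        if np.unique(y[train]).size < 2:
            raise StratificationError(f"training fold {k} lost a class")
        model = PLSDA(n_components=n_components).fit(X[train], y[train])
        pred = model.decision_function(X[test])
        press += float(np.sum((y_coded[test] - pred) ** 2))
        tss += float(np.sum((y_coded[test] - y_coded[train].mean()) ** 2))
    if tss == 0:
        raise ModelError("zero total sum of squares in cross-validation")
    return 1.0 - press / tss


def student_t_per_feature(X, groups):
    """Two-sided pooled-variance Student's t-test per feature.

    Returns (t_statistics, p_values) with df = n1 + n2 - 2.
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise InputError("t-test requires exactly 2 groups")
    g1 = X[groups == labels[0]]
    g2 = X[groups == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise InputError("each group needs at least 2 birds")
    t, p = stats.ttest_ind(g1, g2, axis=0, equal_var=True)
    return np.asarray(t), np.asarray(p)


def call_differentials(
    feature_ids,
    vip,
    p_values,
    mean_fat,
    mean_lean,
    vip_threshold: float = 1.0,
    p_threshold: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Apply the differential rule VIP > 1 AND P < 0.05 (strict).

    Direction compares line means on the normalized scale.  With ``fdr=True``
    the p-values are Benjamini-Hochberg adjusted before thresholding (off by
    default, matching the plain P < 0.05 rule).
    """
    feature_ids = list(feature_ids)
    vip = np.asarray(vip, dtype=float)
    p_values = np.asarray(p_values, dtype=float)
    mean_fat = np.asarray(mean_fat, dtype=float)
    mean_lean = np.asarray(mean_lean, dtype=float)
    lengths = {len(feature_ids), len(vip), len(p_values), len(mean_fat), len(mean_lean)}
    if len(lengths) != 1:
        raise InputError(f"misaligned inputs with lengths {sorted(lengths)}")
    p_used = stats.false_discovery_control(p_values, method="bh") if fdr else p_values
    is_diff = (vip > vip_threshold) & (p_used < p_threshold)
    direction = np.where(mean_fat > mean_lean, "higher-in-fat", "higher-in-lean")
    return pd.DataFrame(
        {
            "feature_id": feature_ids,
            "vip": vip,
            "p_value": p_values,
            "mean_fat": mean_fat,
            "mean_lean": mean_lean,
            "direction": direction,
            "is_differential": is_diff,
        }
    )


def screen_matrix(
    matrix,
    lines,
    n_components: int = 2,
    seed: int = 0,
    use_log10: bool = False,
    fdr: bool = False,
):
    """Full screening of one ion-mode matrix: PLS-DA + VIP + t-test.

    Parameters
    ----------
    matrix : MetaboliteMatrix
        Normalized intensities.
    lines : array-like
        Per-bird line labels (``"lean"`` / ``"fat"``) aligned with the rows.

    Returns
    -------
    calls : pandas.DataFrame
        One row per feature with VIP, p-value, means and the differential flag
        (constant features get VIP 0 and are never differential).
    summary : dict
        R2X, R2Y, Q2Y and component count.
    """
    X = matrix.intensities.to_numpy(dtype=float)
    if use_log10:
        from .preprocess import log10_display

        X = log10_display(matrix).to_numpy()
    lines = np.asarray(lines)
    if len(lines) != X.shape[0]:
        raise InputError("line labels do not align with matrix rows")
    model = PLSDA(n_components=n_components).fit(X, lines)
    q2 = q2_sevenfold(X, lines, n_components=n_components, seed=seed)
    vip_full = np.zeros(X.shape[1])
    vip_full[model.kept_features_] = model.vip_
    tstat, pvals = student_t_per_feature(X, lines)
    mean_fat = X[lines == "fat"].mean(axis=0)
    mean_lean = X[lines == "lean"].mean(axis=0)
    calls = call_differentials(
        matrix.feature_ids, vip_full, pvals, mean_fat, mean_lean, fdr=fdr
    )
    calls.insert(1, "hmdb_id", [matrix.hmdb_ids.get(f, "") for f in matrix.feature_ids])
    summary = {
        "ion_mode": matrix.ion_mode,
        "n_components": model.x_weights_.shape[1],
        "r2x": model.r2x_,
        "r2y": model.r2y_,
        "q2y": q2,
        "n_differential": int(calls["is_differential"].sum()),
    }
    return calls, summary
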