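"""Pedigree animal-model REML: heritabilities and genetic correlations.

Model (one record per animal):  Y = Xb + Za + e, with fixed effects b
(population mean, sex, line; reference-level coding), additive genetic effects
a ~ N(0, A g) where A is the numerator relationship matrix, and residuals
e ~ N(0, I r).  Heritability is h2 = g / (g + r).  For two traits measured on
the same animals the bivariate model has Var(a) = G (x) A and Var(e) = R (x) I
with 2x2 genetic and residual covariance matrices, giving the genetic and
phenotypic correlations

    r_g = G12 / sqrt(G11 G22),      r_p = (G12 + R12) / sqrt((G11+R11)(G22+R22)).

Implementation: with M the relationship matrix restricted to the phenotyped
animals and M = U D U' its eigendecomposition, rotating records by U' makes
the phenotypic covariance diagonal (univariate: v_i = g d_i + r) or 2x2
block-diagonal (bivariate: V_i = G d_i + R), so each REML likelihood,
gradient and average-information (AI) evaluation is O(n).  The optimizer runs
parameter-scaled gradient (EM-form) warm-up steps followed by AI steps, all
safeguarded by step-halving so the accepted restricted log-likelihood never
decreases.  Standard errors come from the delta method applied to the inverse
AI matrix.  Non-convergence is a first-class outcome (flag, not exception):
non-converged estimates are reported missing, mirroring how such rows are
dropped from a genetic-parameter table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, InputError, ModelError
from .pedigree import Pedigree, RelationshipMatrix, build_a_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "RemlOptions",
    "VarianceComponents",
    "BivariateComponents",
    "EigenM",
    "design_matrix",
    "reml_univariate",
    "reml_bivariate",
    "AnimalModelREML",
    "BivariateREML",
    "estimate_genetic_parameters",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class RemlOptions:
    """Convergence and safeguard settings for the REML iterations."""

    max_iter: int = 200
    tol_loglik: float = 1e-8  # relative change in restricted log-likelihood
    tol_params: float = 1e-6  # relative change in variance parameters
    n_warmup: int = 15  # EM-form warm-up iterations before AI steps
    variance_floor_frac: float = 1e-10  # floor as a fraction of phenotypic variance
    max_halvings: int = 20
    corr_clamp: float = 0.999


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    h2: float
    se_h2: float
    loglik: float
    converged: bool
    n_iter: int
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class BivariateComponents:
    G: np.ndarray
    R: np.ndarray
    rg: float
    rp: float
    se_rg: float
    se_rp: float
    loglik: float
    converged: bool
    n_iter: int
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class EigenM:
    """Eigendecomposition of the record-level relationship matrix M = U D U'.

    Reusable across traits measured on the same animals; building it is the
    only O(n^3) step of a fit.
    """

    d: np.ndarray
    u: np.ndarray
    identity_like: bool

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "EigenM":
        m = np.asarray(m, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InputError("relationship matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise InputError("relationship matrix must be symmetric")
        d, u = np.linalg.eigh(m)
        if d.min() < -1e-8 * max(1.0, d.max()):
            raise ModelError(f"relationship matrix is not PSD (min eigenvalue {d.min():.3g})")
        # bend: tiny negative eigenvalues are numerical noise
        d = np.clip(d, 1e-12, None)
        ident = bool(np.abs(m - np.eye(len(m))).max() < 1e-8)
        return cls(d=d, u=u, identity_like=ident)


def design_matrix(table: pd.DataFrame, factors=("sex", "line")) -> np.ndarray:
    """Fixed-effect design: intercept plus reference-level dummies."""
    n = len(table)
    cols = [np.ones(n)]
    for f in factors:
        if f not in table.columns:
            continue
        levels = pd.unique(table[f])
        for level in levels[1:]:
            cols.append((table[f].to_numpy() == level).astype(float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("fixed-effect design is rank deficient after reference coding")
    return X


# ---------------------------------------------------------------- univariate


def _uni_loglik(theta, yt, Xt, d):
    """Restricted log-likelihood and GLS byproducts in the eigenbasis."""
    g, r = theta
    v = g * d + r
    if np.any(v <= 0):
        return -np.inf, None
    w = 1.0 / v
    Xw = Xt * w[:, None]
    C = Xt.T @ Xw
    rhs = Xw.T @ yt
    try:
        cf = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        return -np.inf, None
    beta = np.linalg.solve(C, rhs)
    e = yt - Xt @ beta
    py = e * w  # P y in the eigenbasis
    quad = float(e @ py)
    logdet_c = 2.0 * float(np.sum(np.log(np.diag(cf))))
    n, f = Xt.shape
    ll = -0.5 * (np.sum(np.log(v)) + logdet_c + quad + (n - f) * _LOG2PI)
    return ll, (v, w, py, C)


def _uni_grad_ai(theta, yt, Xt, d, aux):
    """Gradient and average-information matrix for (g, r)."""
    v, w, py, C = aux
    Cinv = np.linalg.inv(C)
    # tr(P V_j) = tr(V^-1 V_j) - tr(Cinv X' V^-1 V_j V^-1 X)
    grads = np.empty(2)
    us = []
    for j, deriv in enumerate((d, np.ones_like(d))):
        wd = w * deriv
        tr1 = float(np.sum(wd))
        Xwd = Xt * (wd * w)[:, None]
        tr2 = float(np.einsum("ij,ji->", Cinv, Xt.T @ Xwd))
        u = deriv * py  # V_j P y
        grads[j] = -0.5 * ((tr1 - tr2) - float(py @ u))
        us.append(u)

    def apply_p(x):
        wx = w * x
        return wx - (Xt * w[:, None]) @ (Cinv @ (Xt.T @ wx))

    pu = [apply_p(u) for u in us]
    ai = 0.5 * np.array([[us[j] @ pu[k] for k in range(2)] for j in range(2)])
    return grads, ai


def reml_univariate(
    y,
    X,
    M=None,
    *,
    eigen: EigenM | None = None,
    options: RemlOptions | None = None,
) -> VarianceComponents:
    """Univariate animal-model REML for one trait.

    Parameters
    ----------
    y : (n,) trait values, one record per animal.
    X : (n, f) fixed-effect design (full column rank).
    M : (n, n) relationship matrix among the recorded animals (ZAZ'), or pass
        a precomputed ``eigen`` instead.
    """
    opts = options or RemlOptions()
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, f = X.shape
    if len(y) != n:
        raise InputError("y and X have different lengths")
    if n < f + 2:
        raise InputError(f"need at least {f + 2} records for {f} fixed effects")
    if eigen is None:
        if M is None:
            raise InputError("provide M or its eigendecomposition")
        eigen = EigenM.from_matrix(M)
    if eigen.identity_like:
        warnings.warn(
            "relationship matrix is (numerically) the identity: genetic and residual "
            "variances are not separable",
            stacklevel=2,
        )
        vp = float(np.var(y, ddof=1))
        return VarianceComponents(0.0, vp, 0.0, np.nan, np.nan, False, 0)

    d, u = eigen.d, eigen.u
    yt = u.T @ y
    Xt = u.T @ X
    vp = float(np.var(y, ddof=1))
    if vp == 0:
        raise ModelError("trait has zero variance")
    floor = opts.variance_floor_frac * vp
    theta = np.array([0.5 * vp, 0.5 * vp])

    ll, aux = _uni_loglik(theta, yt, Xt, d)
    if not np.isfinite(ll):
        raise ModelError("could not evaluate the starting likelihood")
    path = [ll]
    converged = False
    it = 0
    ai = np.eye(2)
    for it in range(1, opts.max_iter + 1):
        grads, ai = _uni_grad_ai(theta, yt, Xt, d, aux)
        em_step = (theta**2 / n) * grads  # EM-form parameter-scaled gradient
        if it <= opts.n_warmup:
            steps = [em_step]
        else:
            try:
                steps = [np.linalg.solve(ai, grads), em_step]
            except np.linalg.LinAlgError:
                steps = [em_step]
        new_ll, new_theta, new_aux = -np.inf, theta, aux
        for step in steps:
            scale = 1.0
            for _ in range(opts.max_halvings):
                cand = np.maximum(theta + scale * step, floor)
                cll, caux = _uni_loglik(cand, yt, Xt, d)
                if np.isfinite(cll) and cll >= ll - 1e-12:
                    new_ll, new_theta, new_aux = cll, cand, caux
                    break
                scale *= 0.5
            if np.isfinite(new_ll):
                break
        if not np.isfinite(new_ll):
            # no uphill step: converged if each parameter satisfies the
            # first-order condition (zero gradient, or at the floor with the
            # gradient pointing outward)
            at_bound = theta <= floor * (1 + 1e-6)
            converged = bool(
                np.all((np.abs(grads) * np.maximum(theta, floor) < 1e-4) | (at_bound & (grads < 0)))
            )
            break
        dll = abs(new_ll - ll) / max(1.0, abs(new_ll))
        dpar = np.max(np.abs(new_theta - theta) / np.maximum(np.abs(theta), floor))
        theta, ll, aux = new_theta, new_ll, new_aux
        path.append(ll)
        if dll < opts.tol_loglik and dpar < opts.tol_params and it > opts.n_warmup:
            converged = True
            break

    g, r = theta
    h2 = g / (g + r)
    try:
        cov = np.linalg.inv(ai)
        grad_h2 = np.array([r, -g]) / (g + r) ** 2
        se_h2 = float(np.sqrt(max(grad_h2 @ cov @ grad_h2, 0.0)))
    except np.linalg.LinAlgError:
        se_h2 = np.nan
    return VarianceComponents(
        sigma2_a=float(g),
        sigma2_e=float(r),
        h2=float(h2),
        se_h2=se_h2,
        loglik=float(ll),
        converged=converged,
        n_iter=it,
        loglik_path=np.array(path),
    )


# ----------------------------------------------------------------- bivariate

# parameter order: (G11, G12, G22, R11, R12, R22)
_DERIV_BLOCKS = [
    (True, np.array([[1.0, 0.0], [0.0, 0.0]])),
    (True, np.array([[0.0, 1.0], [1.0, 0.0]])),
    (True, np.array([[0.0, 0.0], [0.0, 1.0]])),
    (False, np.array([[1.0, 0.0], [0.0, 0.0]])),
    (False, np.array([[0.0, 1.0], [1.0, 0.0]])),
    (False, np.array([[0.0, 0.0], [0.0, 1.0]])),
]


def _theta_to_gr(theta):
    G = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
    R = np.array([[theta[3], theta[4]], [theta[4], theta[5]]])
    return G, R


def _clamp_theta(theta, floor, clamp):
    """Force variances above the floor and correlations inside +/-clamp."""
    t = theta.copy()
    t[0] = max(t[0], floor[0])
    t[2] = max(t[2], floor[1])
    t[3] = max(t[3], floor[0])
    t[5] = max(t[5], floor[1])
    lim_g = clamp * np.sqrt(t[0] * t[2])
    t[1] = np.clip(t[1], -lim_g, lim_g)
    lim_r = clamp * np.sqrt(t[3] * t[5])
    t[4] = np.clip(t[4], -lim_r, lim_r)
    return t


def _bi_blocks(theta, d):
    G, R = _theta_to_gr(theta)
    V11 = G[0, 0] * d + R[0, 0]
    V12 = G[0, 1] * d + R[0, 1]
    V22 = G[1, 1] * d + R[1, 1]
    det = V11 * V22 - V12**2
    if np.any(det <= 0) or np.any(V11 <= 0) or np.any(V22 <= 0):
        return None
    W11 = V22 / det
    W22 = V11 / det
    W12 = -V12 / det
    return (V11, V12, V22, det, W11, W12, W22)


def _bi_loglik(theta, yt, Xt, d):
    """Restricted log-likelihood of the stacked two-trait model.

    yt: (n, 2) rotated records; Xt: (n, f) rotated per-trait design (shared
    structure, separate coefficients per trait).
    """
    blocks = _bi_blocks(theta, d)
    if blocks is None:
        return -np.inf, None
    V11, V12, V22, det, W11, W12, W22 = blocks
    n, f = Xt.shape
    # C = X' V^-1 X assembled from the 2x2 weights
    C11 = Xt.T @ (Xt * W11[:, None])
    C12 = Xt.T @ (Xt * W12[:, None])
    C22 = Xt.T @ (Xt * W22[:, None])
    C = np.block([[C11, C12], [C12, C22]])
    rhs1 = Xt.T @ (W11 * yt[:, 0] + W12 * yt[:, 1])
    rhs2 = Xt.T @ (W12 * yt[:, 0] + W22 * yt[:, 1])
    rhs = np.concatenate([rhs1, rhs2])
    try:
        cf = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        return -np.inf, None
    beta = np.linalg.solve(C, rhs)
    e1 = yt[:, 0] - Xt @ beta[:f]
    e2 = yt[:, 1] - Xt @ beta[f:]
    p1 = W11 * e1 + W12 * e2  # P y, trait-1 rows
    p2 = W12 * e1 + W22 * e2
    quad = float(e1 @ p1 + e2 @ p2)
    logdet_c = 2.0 * float(np.sum(np.log(np.diag(cf))))
    ll = -0.5 * (np.sum(np.log(det)) + logdet_c + quad + (2 * n - 2 * f) * _LOG2PI)
    return ll, (blocks, C, (p1, p2), (e1, e2))


def _bi_grad_ai(theta, yt, Xt, d, aux):
    blocks, C, (p1, p2), _ = aux
    V11, V12, V22, det, W11, W12, W22 = blocks
    n, f = Xt.shape
    Cinv = np.linalg.inv(C)
    W = (W11, W12, W22)

    def mul_w(a1, a2):
        return W11 * a1 + W12 * a2, W12 * a1 + W22 * a2

    def apply_p(a1, a2):
        w1, w2 = mul_w(a1, a2)
        rhs = np.concatenate([Xt.T @ w1, Xt.T @ w2])
        corr = Cinv @ rhs
        c1 = Xt @ corr[:f]
        c2 = Xt @ corr[f:]
        cw1, cw2 = mul_w(c1, c2)
        return w1 - cw1, w2 - cw2

    grads = np.empty(6)
    us = []
    for j, (is_g, E) in enumerate(_DERIV_BLOCKS):
        s = d if is_g else np.ones_like(d)
        # tr(V^-1 Phi_j) summed over blocks; Phi_j = s_i * E
        if E[0, 1] == 0:
            tr1 = float(np.sum(s * (W11 if E[0, 0] else W22)))
        else:
            tr1 = 2.0 * float(np.sum(s * W12))
        # B_i = W Phi W  (2x2 per record), then tr(Cinv * X' B X)
        if E[0, 1] == 0:
            if E[0, 0]:
                B11, B12, B22 = W11 * W11 * s, W11 * W12 * s, W12 * W12 * s
            else:
                B11, B12, B22 = W12 * W12 * s, W12 * W22 * s, W22 * W22 * s
        else:
            B11 = 2.0 * W11 * W12 * s
            B12 = (W11 * W22 + W12 * W12) * s
            B22 = 2.0 * W12 * W22 * s
        D11 = Xt.T @ (Xt * B11[:, None])
        D12 = Xt.T @ (Xt * B12[:, None])
        D22 = Xt.T @ (Xt * B22[:, None])
        D = np.block([[D11, D12], [D12, D22]])
        tr2 = float(np.einsum("ij,ji->", Cinv, D))
        # u_j = Phi_j P y
        if E[0, 1] == 0:
            if E[0, 0]:
                u = (s * p1, np.zeros_like(p2))
            else:
                u = (np.zeros_like(p1), s * p2)
        else:
            u = (s * p2, s * p1)
        grads[j] = -0.5 * ((tr1 - tr2) - float(p1 @ u[0] + p2 @ u[1]))
        us.append(u)
    pu = [apply_p(*u) for u in us]
    ai = 0.5 * np.array(
        [[us[j][0] @ pu[k][0] + us[j][1] @ pu[k][1] for k in range(6)] for j in range(6)]
    )
    return grads, ai


def reml_bivariate(
    y1,
    y2,
    X,
    M=None,
    *,
    eigen: EigenM | None = None,
    start: tuple | None = None,
    options: RemlOptions | None = None,
) -> BivariateComponents:
    """Bivariate animal-model REML for two traits on the same animals.

    ``start`` may supply ((g1, r1), (g2, r2)) from univariate fits; otherwise
    univariate fits are run internally to seed the variances.
    """
    opts = options or RemlOptions()
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    X = np.asarray(X, dtype=float)
    n, f = X.shape
    if len(y1) != n or len(y2) != n:
        raise InputError("traits must share the same records as the design")
    if eigen is None:
        if M is None:
            raise InputError("provide M or its eigendecomposition")
        eigen = EigenM.from_matrix(M)
    d, u = eigen.d, eigen.u
    yt = np.column_stack([u.T @ y1, u.T @ y2])
    Xt = u.T @ X

    if start is None:
        f1 = reml_univariate(y1, X, eigen=eigen, options=opts)
        f2 = reml_univariate(y2, X, eigen=eigen, options=opts)
        start = ((f1.sigma2_a, f1.sigma2_e), (f2.sigma2_a, f2.sigma2_e))
    (g1, r1), (g2, r2) = start
    vp1, vp2 = float(np.var(y1, ddof=1)), float(np.var(y2, ddof=1))
    floor = (opts.variance_floor_frac * vp1, opts.variance_floor_frac * vp2)
    g1 = max(g1, 1e-4 * vp1)
    g2 = max(g2, 1e-4 * vp2)
    # split the raw trait covariance between genetic and residual parts in
    # proportion to the univariate heritabilities
    c12 = float(np.cov(y1, y2, ddof=1)[0, 1])
    share = np.sqrt((g1 / (g1 + r1)) * (g2 / (g2 + r2)))
    theta = _clamp_theta(
        np.array([g1, 0.5 * share * c12, g2, r1, 0.5 * (1 - share) * c12, r2]),
        floor,
        opts.corr_clamp,
    )

    ll, aux = _bi_loglik(theta, yt, Xt, d)
    if not np.isfinite(ll):
        theta[1] = theta[4] = 0.0
        ll, aux = _bi_loglik(theta, yt, Xt, d)
    if not np.isfinite(ll):
        raise ModelError("could not evaluate the starting bivariate likelihood")
    path = [ll]
    converged = False
    it = 0
    ai = np.eye(6)
    scale_vec = np.array([vp1, np.sqrt(vp1 * vp2), vp2, vp1, np.sqrt(vp1 * vp2), vp2])
    for it in range(1, opts.max_iter + 1):
        grads, ai = _bi_grad_ai(theta, yt, Xt, d, aux)
        em_step = (scale_vec**2 / (2.0 * n)) * grads  # scaled-gradient warm-up
        if it <= opts.n_warmup:
            steps = [em_step]
        else:
            try:
                steps = [np.linalg.solve(ai + 1e-10 * np.eye(6), grads), em_step]
            except np.linalg.LinAlgError:
                steps = [em_step]
        new_ll, new_theta, new_aux = -np.inf, theta, aux
        for step in steps:
            scale = 1.0
            for _ in range(opts.max_halvings):
                cand = _clamp_theta(theta + scale * step, floor, opts.corr_clamp)
                cll, caux = _bi_loglik(cand, yt, Xt, d)
                if np.isfinite(cll) and cll >= ll - 1e-12:
                    new_ll, new_theta, new_aux = cll, cand, caux
                    break
                scale *= 0.5
            if np.isfinite(new_ll):
                break
        if not np.isfinite(new_ll):
            # stalled against a variance floor or the correlation clamp; treat
            # as converged only when the free-direction gradients are small
            rel = np.abs(grads) * scale_vec
            converged = bool(np.all(rel < 1e-3 * max(1.0, abs(ll) / n)))
            break
        dll = abs(new_ll - ll) / max(1.0, abs(new_ll))
        dpar = np.max(np.abs(new_theta - theta) / np.maximum(np.abs(theta), 1e-8 * scale_vec))
        theta, ll, aux = new_theta, new_ll, new_aux
        path.append(ll)
        if dll < opts.tol_loglik and dpar < opts.tol_params and it > opts.n_warmup:
            converged = True
            break

    G, R = _theta_to_gr(theta)
    rg = G[0, 1] / np.sqrt(G[0, 0] * G[1, 1])
    P = G + R
    rp = P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
    try:
        cov = np.linalg.inv(ai + 1e-12 * np.eye(6))
        grad_rg = np.array(
            [-rg / (2 * G[0, 0]), 1.0 / np.sqrt(G[0, 0] * G[1, 1]), -rg / (2 * G[1, 1]), 0, 0, 0]
        )
        se_rg = float(np.sqrt(max(grad_rg @ cov @ grad_rg, 0.0)))
        gp = np.array(
            [
                -rp / (2 * P[0, 0]),
                1.0 / np.sqrt(P[0, 0] * P[1, 1]),
                -rp / (2 * P[1, 1]),
                -rp / (2 * P[0, 0]),
                1.0 / np.sqrt(P[0, 0] * P[1, 1]),
                -rp / (2 * P[1, 1]),
            ]
        )
        se_rp = float(np.sqrt(max(gp @ cov @ gp, 0.0)))
    except np.linalg.LinAlgError:
        se_rg = se_rp = np.nan
    return BivariateComponents(
        G=G,
        R=R,
        rg=float(rg),
        rp=float(rp),
        se_rg=se_rg,
        se_rp=se_rp,
        loglik=float(ll),
        converged=converged,
        n_iter=it,
        loglik_path=np.array(path),
    )


class AnimalModelREML:
    """Estimator-style wrapper around :func:`reml_univariate`.

    fit(y, X, M) stores ``sigma2_a_``, ``sigma2_e_``, ``h2_``, ``se_h2_``,
    ``loglik_``, ``converged_`` and ``n_iter_``.
    """

    def __init__(self, options: RemlOptions | None = None):
        self.options = options

    def fit(self, y, X, M=None, eigen: EigenM | None = None):
        res = reml_univariate(y, X, M, eigen=eigen, options=self.options)
        self.sigma2_a_ = res.sigma2_a
        self.sigma2_e_ = res.sigma2_e
        self.h2_ = res.h2
        self.se_h2_ = res.se_h2
        self.loglik_ = res.loglik
        self.converged_ = res.converged
        self.n_iter_ = res.n_iter
        self.result_ = res
        return self


class BivariateREML:
    """Estimator-style wrapper around :func:`reml_bivariate`."""

    def __init__(self, options: RemlOptions | None = None):
        self.options = options

    def fit(self, y1, y2, X, M=None, eigen: EigenM | None = None, start=None):
        res = reml_bivariate(y1, y2, X, M, eigen=eigen, start=start, options=self.options)
        self.G_ = res.G
        self.R_ = res.R
        self.rg_ = res.rg
        self.rp_ = res.rp
        self.se_rg_ = res.se_rg
        self.se_rp_ = res.se_rp
        self.converged_ = res.converged
        self.result_ = res
        return self


def estimate_genetic_parameters(
    metabolites,
    traits: pd.DataFrame,
    pedigree: Pedigree,
    differential_ids=None,
    options: RemlOptions | None = None,
    use_log10: bool = False,
) -> pd.DataFrame:
    """Per-metabolite h2 and correlations with FCR and RFI under the animal model.

    Parameters
    ----------
    metabolites : MetaboliteMatrix
        Normalized intensities; rows must match ``traits['bird_id']``.
    traits : pandas.DataFrame
        Columns ``bird_id, fcr, rfi_g, line, sex`` (from feed_efficiency).
    pedigree : Pedigree
        Must contain every phenotyped bird.
    differential_ids : iterable, optional
        Feature ids to analyse (typically the differential set); all features
        by default.

    Returns
    -------
    pandas.DataFrame with one row per metabolite that converged at least in
    part: columns ``feature_id, hmdb_id, h2, se_h2, rg_fcr, se_rg_fcr, rg_rfi,
    se_rg_rfi, rp_fcr, se_rp_fcr, rp_rfi, se_rp_rfi, converged_h2,
    converged_fcr, converged_rfi``.  Non-converged cells are NaN; metabolites
    whose univariate fit fails entirely are excluded.
    """
    opts = options or RemlOptions()
    birds = traits["bird_id"].astype(str).tolist()
    mat_birds = metabolites.bird_ids
    if birds != mat_birds:
        common = [b for b in birds if b in set(mat_birds)]
        if len(common) != len(birds) or len(common) != len(mat_birds):
            raise AlignmentError("bird ids differ between metabolite matrix and trait table")
        metabolite_values = metabolites.intensities.loc[birds]
    else:
        metabolite_values = metabolites.intensities

    feature_ids = (
        [str(f) for f in differential_ids]
        if differential_ids is not None
        else metabolites.feature_ids
    )
    unknown = set(feature_ids) - set(metabolites.feature_ids)
    if unknown:
        raise AlignmentError(f"features not in matrix: {sorted(unknown)}")

    a_all = build_a_matrix(pedigree)
    M = a_all.submatrix(birds)
    eigen = EigenM.from_matrix(M)
    X = design_matrix(traits)

    mvals = metabolite_values.to_numpy(dtype=float)
    if use_log10:
        if np.any(mvals <= 0):
            raise ModelError("log10 scale requires positive intensities")
        mvals = np.log10(mvals)

    fits_fe = {}
    for trait_name, col in (("fcr", "fcr"), ("rfi", "rfi_g")):
        fits_fe[trait_name] = reml_univariate(
            traits[col].to_numpy(dtype=float), X, eigen=eigen, options=opts
        )

    col_index = {f: i for i, f in enumerate(metabolite_values.columns.astype(str))}
    rows = []
    for fid in feature_ids:
        y = mvals[:, col_index[fid]]
        if np.var(y, ddof=1) == 0:
            logger.warning("feature %s has zero variance; excluded", fid)
            continue
        try:
            uni = reml_univariate(y, X, eigen=eigen, options=opts)
        except ModelError as exc:
            logger.warning("feature %s: univariate REML failed (%s); excluded", fid, exc)
            continue
        row = {
            "feature_id": fid,
            "hmdb_id": metabolites.hmdb_ids.get(fid, ""),
            "h2": uni.h2 if uni.converged else np.nan,
            "se_h2": uni.se_h2 if uni.converged else np.nan,
            "converged_h2": uni.converged,
        }
        any_converged = uni.converged
        for fe in ("fcr", "rfi"):
            fe_col = "fcr" if fe == "fcr" else "rfi_g"
            ok = False
            try:
                bi = reml_bivariate(
                    y,
                    traits[fe_col].to_numpy(dtype=float),
                    X,
                    eigen=eigen,
                    start=(
                        (uni.sigma2_a, uni.sigma2_e),
                        (fits_fe[fe].sigma2_a, fits_fe[fe].sigma2_e),
                    ),
                    options=opts,
                )
                ok = bi.converged
            except ModelError:
                bi = None
            row[f"rg_{fe}"] = bi.rg if ok else np.nan
            row[f"se_rg_{fe}"] = bi.se_rg if ok else np.nan
            row[f"rp_{fe}"] = bi.rp if ok else np.nan
            row[f"se_rp_{fe}"] = bi.se_rp if ok else np.nan
            row[f"converged_{fe}"] = ok
            any_converged = any_converged or ok
        if not any_converged:
            logger.warning("feature %s: no fit converged; excluded from the table", fid)
            continue
        rows.append(row)
    return pd.DataFrame(rows)


def write_parameter_table(table: pd.DataFrame, path) -> None:
    """Write the genetic-parameter CSV, missing cells as '-'."""
    out = table.copy()
    num_cols = [c for c in out.columns if c.startswith(("h2", "se_", "rg_", "rp_"))]
    for c in num_cols:
        out[c] = out[c].map(lambda v: "-" if pd.isna(v) else f"{v:.4f}")
    out.to_csv(path, index=False)
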