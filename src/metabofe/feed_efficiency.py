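"""Feed-efficiency traits: BWG, MMBW, FCR and residual feed intake (RFI).

The test period runs from 4 to 7 weeks of age.  Body-weight gain is
BWG = BW7 - BW4, metabolic mid-test body weight is
MMBW = ((BW4 + BW7) / 2) ** 0.75, the feed conversion ratio is FCR = FI / BWG,
and RFI is the residual of the ordinary least-squares regression

    FI = b0 + b1 * MMBW + b2 * BWG + RFI,

so that the cohort-mean RFI is zero and RFI is orthogonal to both predictors.
Lower FCR and lower RFI both mean better feed efficiency.

The regression is fitted on the whole cohort pooled across lines and sexes by
default (line and sex are absorbed downstream as fixed effects of the genetic
model); per-group fitting is available for sensitivity checks.  Birds with
BWG <= 0 have undefined FCR/RFI: they are flagged and excluded from the
regression, never silently dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import CollinearityError, InputError, UndefinedTraitError

__all__ = [
    "compute_bwg",
    "compute_mmbw",
    "compute_fcr",
    "RFIRegression",
    "fit_rfi",
    "derive_traits",
]


def _check_positive(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise InputError(f"{name} must be positive and finite, got {value!r}")


def compute_bwg(bw4, bw7):
    """Body-weight gain BW7 - BW4 (grams); weights must be positive."""
    _check_positive("BW4", bw4)
    _check_positive("BW7", bw7)
    return np.asarray(bw7, dtype=float) - np.asarray(bw4, dtype=float)


def compute_mmbw(bw4, bw7):
    """Metabolic mid-test body weight ((BW4 + BW7)/2) ** 0.75 (g^0.75)."""
    _check_positive("BW4", bw4)
    _check_positive("BW7", bw7)
    mid = (np.asarray(bw4, dtype=float) + np.asarray(bw7, dtype=float)) / 2.0
    return mid**0.75


def compute_fcr(fi, bwg):
    """Feed conversion ratio FI / BWG; undefined when BWG <= 0."""
    fi = np.asarray(fi, dtype=float)
    bwg = np.asarray(bwg, dtype=float)
    if np.any(fi < 0):
        raise InputError("FI must be nonnegative")
    if np.any(bwg <= 0):
        raise UndefinedTraitError("FCR is undefined for BWG <= 0; flag the record instead")
    return fi / bwg


class RFIRegression(RegressorMixin, BaseEstimator):
    """OLS intake model FI ~ 1 + MMBW + BWG whose residual is the RFI.

    Parameters
    ----------
    by_group : bool, default False
        When True, :meth:`fit` accepts a ``groups`` argument and fits a
        separate regression per group (sensitivity-check mode).

    Attributes
    ----------
    intercept_ : float
        b0, grams.
    coef_ : ndarray of shape (2,)
        (b1, b2): partial regression coefficients of FI on MMBW (g per g^0.75)
        and on BWG (g/g).
    """

    _COLUMNS = ("MMBW", "BWG")

    def __init__(self, by_group: bool = False):
        self.by_group = by_group

    def _fit_one(self, mmbw, bwg, fi):
        n = len(fi)
        if n < 3:
            raise InputError(f"RFI regression needs >= 3 birds, got {n}")
        design = np.column_stack([np.ones(n), mmbw, bwg])
        rank = np.linalg.matrix_rank(design)
        if rank < 3:
            # name the offending predictor: the one whose removal restores rank
            for j, col in enumerate(self._COLUMNS, start=1):
                reduced = np.delete(design, j, axis=1)
                if np.linalg.matrix_rank(reduced) == rank:
                    raise CollinearityError(
                        f"design matrix [1, MMBW, BWG] is rank deficient: "
                        f"column {col} is collinear",
                        column=col,
                    )
            raise CollinearityError("design matrix [1, MMBW, BWG] is rank deficient")
        beta, *_ = np.linalg.lstsq(design, fi, rcond=None)
        return beta, fi - design @ beta

    def fit(self, X, y, groups=None):
        """Fit the intake regression.

        Parameters
        ----------
        X : array-like of shape (n, 2)
            Columns (MMBW, BWG).
        y : array-like of shape (n,)
            Total feed intake FI, grams.
        groups : array-like, optional
            Group labels; only honoured when ``by_group=True``.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise InputError(f"X must be (n, 2) = (MMBW, BWG), got shape {X.shape}")
        if len(y) != len(X):
            raise InputError("X and y have different lengths")
        if self.by_group and groups is not None:
            groups = np.asarray(groups)
            self.group_models_ = {}
            resid = np.empty(len(y))
            for g in pd.unique(groups):
                mask = groups == g
                beta, r = self._fit_one(X[mask, 0], X[mask, 1], y[mask])
                self.group_models_[g] = beta
                resid[mask] = r
            self.residuals_ = resid
            beta_pooled, _ = self._fit_one(X[:, 0], X[:, 1], y)
            self.intercept_, b1, b2 = beta_pooled
            self.coef_ = np.array([b1, b2])
        else:
            beta, resid = self._fit_one(X[:, 0], X[:, 1], y)
            self.intercept_, b1, b2 = beta
            self.coef_ = np.array([b1, b2])
            self.residuals_ = resid
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        """Expected intake b0 + b1*MMBW + b2*BWG."""
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    def transform(self, X, y):
        """RFI for new records: observed FI minus predicted FI."""
        return np.asarray(y, dtype=float) - self.predict(X)


def fit_rfi(records: pd.DataFrame, by_group: bool = False, group_col: str = "line"):
    """Fit the RFI regression on a feed-record table.

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``bird_id``, ``fi_g``, ``bw4_g``, ``bw7_g``.
    by_group : bool
        Fit separate regressions per ``group_col`` (pooled fit is the default).

    Returns
    -------
    model : RFIRegression
    traits : pandas.DataFrame
        Columns ``bird_id, bwg_g, mmbw, fcr, rfi_g, valid``; birds with
        BWG <= 0 are flagged ``valid=False`` with NaN FCR/RFI and are excluded
        from the regression.
    """
    required = {"bird_id", "fi_g", "bw4_g", "bw7_g"}
    missing = required - set(records.columns)
    if missing:
        raise InputError(f"feed records missing columns: {sorted(missing)}")
    bw4 = records["bw4_g"].to_numpy(dtype=float)
    bw7 = records["bw7_g"].to_numpy(dtype=float)
    fi = records["fi_g"].to_numpy(dtype=float)
    _check_positive("BW4", bw4)
    _check_positive("BW7", bw7)
    bwg = bw7 - bw4
    mmbw = ((bw4 + bw7) / 2.0) ** 0.75
    valid = bwg > 0

    traits = pd.DataFrame(
        {
            "bird_id": records["bird_id"].astype(str),
            "bwg_g": bwg,
            "mmbw": mmbw,
            "fcr": np.where(valid, fi / np.where(valid, bwg, 1.0), np.nan),
            "rfi_g": np.nan,
            "valid": valid,
        }
    )
    model = RFIRegression(by_group=by_group)
    Xv = np.column_stack([mmbw[valid], bwg[valid]])
    groups = records.loc[valid, group_col].to_numpy() if by_group else None
    model.fit(Xv, fi[valid], groups=groups)
    traits.loc[valid, "rfi_g"] = model.residuals_
    return model, traits


def derive_traits(phenotypes: pd.DataFrame, by_group: bool = False) -> pd.DataFrame:
    """Phenotype table -> traits table, keeping line and sex columns."""
    _, traits = fit_rfi(phenotypes, by_group=by_group)
    for col in ("line", "sex"):
        if col in phenotypes.columns:
            traits[col] = phenotypes[col].to_numpy()
    return traits
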