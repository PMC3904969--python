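"""Robust regression and feature selection estimators.

Two scikit-learn compatible estimators form the modeling core of the trait
association pipeline:

``LeastMedianSquaresRegressor``
    Least median of squares (LMS) linear regression: among candidate fits it
    keeps the one minimizing the *median* squared residual, which tolerates
    up to half the rows being arbitrary outliers.  Candidate fits are exact
    interpolations of random (p+1)-row subsamples (enumerated exhaustively
    when few enough), the classic PROGRESS strategy.  Missing values are
    imputed with column medians and the data are re-centered before fitting.

``CFSSelector``
    Correlation-based feature subset selection: greedy best-first forward
    search maximizing  merit(S) = k r_cf / sqrt(k + k (k-1) r_ff),  where
    r_cf is the mean absolute feature-target correlation of the k selected
    features and r_ff their mean absolute pairwise correlation.  The search
    stops after ``stall_limit`` consecutive expansions that fail to improve
    the best merit seen.

Both work inside sklearn pipelines and model selection utilities.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import (
    check_is_fitted,
    check_random_state,
    validate_data,
)

__all__ = ["LeastMedianSquaresRegressor", "CFSSelector"]


# --------------------------------------------------------------------------
# internal kernels (also used directly by the association pipeline, which
# needs them without estimator-validation overhead)


def _subsample_indices(
    n: int, q: int, n_subsamples: int, rng: np.random.Generator
) -> np.ndarray:
    """(S, q) row-index array: all q-subsets if few enough, else uniform draws."""
    if comb(n, q) <= n_subsamples:
        return np.array(list(combinations(range(n), q)))
    # q smallest of i.i.d. uniforms per row = a uniform random q-subset
    return np.argpartition(rng.random((n_subsamples, n)), q, axis=1)[:, :q]


def _ols(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares fit via the normal equations (tiny well-posed systems),
    falling back to SVD when the Gram matrix is singular."""
    try:
        return np.linalg.solve(A.T @ A, A.T @ y)
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        return beta


def _lms_fit_indexed(
    A: np.ndarray, y: np.ndarray, idx: np.ndarray
) -> tuple[np.ndarray, float]:
    """LMS fit given the design matrix and precomputed subsample indices."""
    As = A[idx]
    ys = y[idx]
    q = As.shape[1]
    if q == 2:
        dets = As[:, 0, 0] * As[:, 1, 1] - As[:, 0, 1] * As[:, 1, 0]
    elif q == 3:
        dets = (
            As[:, 0, 0] * (As[:, 1, 1] * As[:, 2, 2] - As[:, 1, 2] * As[:, 2, 1])
            - As[:, 0, 1] * (As[:, 1, 0] * As[:, 2, 2] - As[:, 1, 2] * As[:, 2, 0])
            + As[:, 0, 2] * (As[:, 1, 0] * As[:, 2, 1] - As[:, 1, 1] * As[:, 2, 0])
        )
    else:
        dets = np.linalg.det(As)
    dets = np.abs(dets)
    ok = dets > 1e-10 * (1.0 + np.abs(As).max())
    if not ok.any():
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        res = y - A @ beta
        return beta, float(np.median(res**2))
    sols = np.linalg.solve(As[ok], ys[ok][..., None])[..., 0]
    # two non-elemental candidates join the pool, judged by the same median
    # loss: the full-data OLS fit (so the winner is never worse than OLS on
    # that loss) and a reweighted refit — OLS on the inliers of the best
    # elemental fit at the usual 2.5-sigma robust cut — which keeps the
    # robustness of the elemental search but with far stabler coefficients
    ols = _ols(A, y)
    extras = [ols]
    resid2_elem = (y[None, :] - sols @ A.T) ** 2
    msr_elem = np.median(resid2_elem, axis=1)
    n_rows, q = A.shape
    b0 = sols[int(np.argmin(msr_elem))]
    sigma = 1.4826 * (1 + 5 / max(n_rows - q, 1)) * np.sqrt(max(msr_elem.min(), 0))
    inliers = np.abs(y - A @ b0) <= 2.5 * sigma if sigma > 0 else np.abs(y - A @ b0) == 0
    if inliers.sum() >= q + 1:
        extras.append(_ols(A[inliers], y[inliers]))
    sols = np.vstack([sols, *extras])
    resid2 = (y[None, :] - sols @ A.T) ** 2
    msr = np.median(resid2, axis=1)
    m0 = msr.min()
    # the median covers only half the rows, so ties at the minimum are
    # common (e.g. any fit through a zero-variance majority); break them by
    # the mean of the smallest 75% of squared residuals, preferring the fit
    # that also explains rows beyond the median
    cand = np.flatnonzero(msr <= m0 + 1e-9 * (1.0 + m0))
    if len(cand) > 1:
        h = int(np.ceil(0.75 * resid2.shape[1]))
        trimmed = np.partition(resid2[cand], h - 1, axis=1)[:, :h].mean(axis=1)
        best = int(cand[np.argmin(trimmed)])
    else:
        best = int(cand[0])
    return sols[best], float(msr[best])


def _lms_solve(
    X: np.ndarray,
    y: np.ndarray,
    n_subsamples: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Best (p+1)-subsample interpolation fit by median squared residual.

    Returns (beta, msr) with beta = (intercept, coefs).  Singular subsamples
    are dropped.  Falls back to ordinary least squares if every subsample is
    singular.
    """
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])
    q = p + 1
    if n <= q:
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        res = y - A @ beta
        return beta, float(np.median(res**2))

    idx = _subsample_indices(n, q, n_subsamples, rng)
    return _lms_fit_indexed(A, y, idx)


def _abs_corr(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """|Pearson r| of each column with y, and pairwise between columns.

    Constant columns get correlation 0.  NaNs are handled pairwise-complete.
    """
    n, p = X.shape
    if np.isnan(X).any() or np.isnan(y).any():
        import pandas as pd

        df = pd.DataFrame(np.column_stack([X, y]))
        c = df.corr().to_numpy()
        c = np.nan_to_num(c)
        return np.abs(c[:p, p]), np.abs(c[:p, :p])
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rcf = (Xc.T @ yc) / (sx * sy)
        rff = (Xc.T @ Xc) / np.outer(sx, sx)
    return np.abs(np.nan_to_num(rcf)), np.abs(np.nan_to_num(rff))


def _cfs_search(
    rcf: np.ndarray, rff: np.ndarray, stall_limit: int = 2
) -> list[int]:
    """Greedy best-first forward search over the CFS merit."""
    p = len(rcf)
    selected: list[int] = []
    sum_rcf = 0.0
    sum_rff = 0.0  # sum over unordered selected pairs
    rff_to_sel = np.zeros(p)  # sum of |r| from each feature to the selection
    best_merit = -np.inf
    best_sel: list[int] = []
    taken = np.zeros(p, dtype=bool)
    stall = 0
    while not taken.all() and stall < stall_limit:
        k = len(selected) + 1
        cand_rcf = sum_rcf + rcf
        cand_rff = sum_rff + rff_to_sel
        # merit = k * mean_rcf / sqrt(k + k(k-1) mean_rff), means over S+{j}
        merits = cand_rcf / np.sqrt(k + 2.0 * cand_rff)
        merits[taken] = -np.inf
        pick = int(np.argmax(merits))
        selected.append(pick)
        sum_rcf = float(cand_rcf[pick])
        sum_rff = float(cand_rff[pick])
        rff_to_sel = rff_to_sel + rff[pick]
        taken[pick] = True
        if merits[pick] > best_merit + 1e-12:
            best_merit = float(merits[pick])
            best_sel = list(selected)
            stall = 0
        else:
            stall += 1
    return sorted(best_sel)


def cfs_merit(rcf_mean: float, rff_mean: float, k: int) -> float:
    """The CFS merit of a k-feature subset from its mean correlations."""
    return k * rcf_mean / np.sqrt(k + k * (k - 1) * rff_mean)


# --------------------------------------------------------------------------


class LeastMedianSquaresRegressor(RegressorMixin, BaseEstimator):
    """Least median of squares robust linear regression.

    Parameters
    ----------
    n_subsamples : int, default=2000
        Maximum number of (p+1)-row subsamples; all subsamples are
        enumerated when their total count does not exceed this, making the
        fit deterministic.
    random_state : int, RandomState or None
        Controls subsample draws when sampling is needed.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
    intercept_ : float
    median_squared_error_ : float
        Median squared residual of the selected fit on the training rows.
    medians_ : ndarray
        Column medians used to impute missing values.
    """

    def __init__(self, n_subsamples: int = 2000, random_state=None):
        self.n_subsamples = n_subsamples
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(
            self, X, y, ensure_all_finite="allow-nan", ensure_min_samples=2,
            y_numeric=True,
        )
        if np.isnan(y).any():
            raise ValueError("y must not contain NaN")
        self.medians_ = np.nanmedian(X, axis=0)
        self.medians_ = np.nan_to_num(self.medians_)
        X = np.where(np.isnan(X), self.medians_, X)
        # re-center
        self.x_center_ = X.mean(axis=0)
        self.y_center_ = float(y.mean())
        Xc = X - self.x_center_
        yc = y - self.y_center_
        rs = check_random_state(self.random_state)
        rng = np.random.default_rng(rs.randint(np.iinfo(np.int32).max))
        beta, msr = _lms_solve(Xc, yc, self.n_subsamples, rng)
        self.coef_ = beta[1:]
        self.intercept_ = float(
            beta[0] + self.y_center_ - self.x_center_ @ self.coef_
        )
        self.median_squared_error_ = msr
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, ensure_all_finite="allow-nan")
        X = np.where(np.isnan(X), self.medians_, X)
        return X @ self.coef_ + self.intercept_


class CFSSelector(SelectorMixin, BaseEstimator):
    """Correlation-based feature subset selection (CFS).

    Greedy best-first forward search over the merit
    ``k r_cf / sqrt(k + k (k-1) r_ff)``; the search stops after
    ``stall_limit`` consecutive additions that do not improve the best merit
    found, and the best subset seen is returned.

    Attributes
    ----------
    support_ : boolean mask of selected features
    selected_indices_ : sorted indices of the selected features
    merit_ : merit of the selected subset
    """

    def __init__(self, stall_limit: int = 2):
        self.stall_limit = stall_limit

    def fit(self, X, y):
        X, y = validate_data(
            self, X, y, ensure_all_finite="allow-nan", y_numeric=True
        )
        rcf, rff = _abs_corr(X, np.asarray(y, dtype=float))
        if np.all(rcf == 0):
            warnings.warn("all features are constant or uncorrelated; empty selection")
            self.selected_indices_ = []
        else:
            self.selected_indices_ = _cfs_search(rcf, rff, self.stall_limit)
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.selected_indices_] = True
        if self.selected_indices_:
            k = len(self.selected_indices_)
            mr = rcf[self.selected_indices_].mean()
            if k > 1:
                sub = rff[np.ix_(self.selected_indices_, self.selected_indices_)]
                mf = sub[np.triu_indices(k, 1)].mean()
            else:
                mf = 0.0
            self.merit_ = float(cfs_merit(mr, mf, k))
        else:
            self.merit_ = 0.0
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_
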