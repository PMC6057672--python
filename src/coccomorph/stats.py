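"""Transect ecology statistics: Spearman rank correlations and CCA.

Spearman's rho is computed as the Pearson correlation of mid-ranks
(average ranks for ties).  Two-sided significance uses the t
approximation for n > 9 and the exact permutation distribution of the
rank correlation for n <= 9, with p <= 0.05 flagged significant.

Canonical correspondence analysis (CCA) relates a samples x taxa
abundance table to environmental predictors: the chi-square standardized
abundance residuals are projected, with row weights, onto the span of
the (weighted-standardized) environmental variables and the projection
is eigen-decomposed.  Eigenvalues partition the constrained inertia;
species scores, site scores (weighted-average by default,
linear-combination by flag) and intraset environment-axis correlations
describe the ordination.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

P_SIGNIFICANT = 0.05
#: exact permutation p-values below this sample size (n! enumerable)
EXACT_PERMUTATION_MAX_N = 9


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    significant: bool

    def __post_init__(self) -> None:
        if np.isfinite(self.rho) and abs(self.rho) > 1 + 1e-12:
            raise ValueError("|rho| must be <= 1")

    @property
    def stars(self) -> str:
        """Significance stars as in field correlation tables."""
        if not np.isfinite(self.p_value):
            return ""
        if self.p_value <= 0.01:
            return "**"
        if self.p_value <= 0.05:
            return "*"
        return ""


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return float("nan")
    return float(rx @ ry) / denom


def spearman(x, y) -> SpearmanResult:
    """Tie-corrected Spearman rank correlation with two-sided p-value.

    A constant input vector leaves rho undefined; the result carries
    rho = NaN, p = NaN and is flagged not significant rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")

    rx, ry = _midranks(x), _midranks(y)
    rho = _rank_corr(rx, ry)
    if not np.isfinite(rho):
        return SpearmanResult(float("nan"), float("nan"), n, False)

    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_p(rx, ry, rho)
    else:
        p = _t_approx_p(rho, n)
    return SpearmanResult(rho, p, n, bool(p <= P_SIGNIFICANT))


def _t_approx_p(rho: float, n: int) -> float:
    if abs(rho) >= 1:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided p: share of permutations with |rho| >= |rho_obs|."""
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = math.sqrt(float(rxc @ rxc)) * np.sqrt((ryc**2).sum(axis=1))
    rhos = (ryc @ rxc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_matrix(left: pd.DataFrame, right: pd.DataFrame) -> pd.DataFrame:
    """Battery of pairwise Spearman tests between two column sets.

    Returns a long table (left, right, rho, p, n, significant, stars),
    skipping pairs with fewer than 3 complete observations.  No
    multiple-testing correction is applied by default; see
    :func:`benjamini_hochberg` to adjust afterwards.
    """
    rows = []
    for lc in left.columns:
        for rc in right.columns:
            ok = left[lc].notna() & right[rc].notna()
            if ok.sum() < 3:
                continue
            res = spearman(left.loc[ok, lc].to_numpy(),
                           right.loc[ok, rc].to_numpy())
            rows.append({"left": lc, "right": rc, "rho": res.rho,
                         "p": res.p_value, "n": res.n,
                         "significant": res.significant, "stars": res.stars})
    return pd.DataFrame(rows)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional; off by default in the battery)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        i = n - rank_from_end  # 1-based rank
        running = min(running, p[idx] * n / i)
        adj[idx] = running
    return adj


# ---------------------------------------------------------------------------
# Canonical correspondence analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CCAResult:
    eigenvalues: np.ndarray  # per constrained axis, non-increasing
    percent_variance: np.ndarray  # % of constrained inertia per axis
    percent_total_variance: np.ndarray  # % of total inertia per axis
    species_scores: pd.DataFrame  # taxa x axes
    site_scores: pd.DataFrame  # samples x axes
    env_axis_scores: pd.DataFrame  # env variables x axes (intraset corr)
    total_inertia: float
    constrained_inertia: float
    dropped_env_columns: tuple = ()
    dropped_sample_rows: tuple = ()


class CanonicalCorrespondenceAnalysis(BaseEstimator):
    """CCA as a scikit-learn style estimator.

    ``fit(Y, X)`` takes the abundance table Y (samples x taxa,
    non-negative) and the environment table X (samples x variables).
    Environmental variables are standardized internally with the
    correspondence-analysis row weights; collinear columns are dropped
    with a warning.

    Parameters
    ----------
    n_axes:
        Number of constrained axes to keep (default: all available, at
        most min(taxa - 1, kept variables)).
    site_score_type:
        "wa" (weighted averages of species scores, default) or "lc"
        (linear combinations of the environmental variables).
    collinearity_tol:
        Relative tolerance below which an environmental column adds no
        rank and is dropped.

    Attributes (after fit)
    ----------------------
    eigenvalues_, percent_variance_, percent_total_variance_,
    species_scores_, site_scores_, env_axis_scores_, total_inertia_,
    constrained_inertia_, dropped_env_columns_, dropped_sample_rows_
    """

    def __init__(self, n_axes: int | None = None, site_score_type: str = "wa",
                 collinearity_tol: float = 1e-8):
        self.n_axes = n_axes
        self.site_score_type = site_score_type
        self.collinearity_tol = collinearity_tol

    def fit(self, Y, X) -> "CanonicalCorrespondenceAnalysis":
        if self.site_score_type not in ("wa", "lc"):
            raise ValueError("site_score_type must be 'wa' or 'lc'")
        Y = pd.DataFrame(Y).astype(float)
        X = pd.DataFrame(X).astype(float)
        if len(Y) != len(X):
            raise ValueError("Y and X must have the same number of samples")
        if (Y.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")

        # drop empty rows/columns of the abundance table
        row_tot = Y.sum(axis=1)
        dropped_rows = tuple(Y.index[row_tot == 0])
        if dropped_rows:
            warnings.warn(f"removing all-zero abundance rows: {dropped_rows}")
            keep = row_tot > 0
            Y, X = Y.loc[keep], X.loc[keep]
        col_tot = Y.sum(axis=0)
        if (col_tot == 0).any():
            warnings.warn(
                f"removing all-zero taxa: {tuple(Y.columns[col_tot == 0])}"
            )
            Y = Y.loc[:, col_tot > 0]
        if Y.shape[0] < 3 or Y.shape[1] < 2:
            raise ValueError("need >= 3 samples and >= 2 taxa after filtering")

        A = Y.to_numpy()
        total = A.sum()
        P = A / total
        r = P.sum(axis=1)  # row (sample) weights
        c = P.sum(axis=0)  # column (taxon) weights
        rc = np.outer(r, c)
        Qbar = (P - rc) / np.sqrt(rc)
        total_inertia = float((Qbar**2).sum())

        # weighted standardization of the environment
        Xv = X.to_numpy()
        if not np.isfinite(Xv).all():
            raise ValueError("environment table must be finite")
        xm = r @ Xv
        xc = Xv - xm
        xs = np.sqrt(r @ xc**2)
        keep_cols, dropped_cols = [], []
        basis = np.empty((len(r), 0))
        sqrt_r = np.sqrt(r)
        for j, name in enumerate(X.columns):
            if xs[j] <= self.collinearity_tol * max(abs(xm[j]), 1.0):
                dropped_cols.append(name)
                continue
            col = sqrt_r * (xc[:, j] / xs[j])
            resid = col - basis @ np.linalg.lstsq(basis, col, rcond=None)[0] \
                if basis.shape[1] else col
            if np.linalg.norm(resid) <= self.collinearity_tol * np.linalg.norm(col):
                dropped_cols.append(name)
                continue
            keep_cols.append(name)
            basis = np.column_stack([basis, col])
        if dropped_cols:
            warnings.warn(
                f"dropping constant/collinear environmental columns: {dropped_cols}"
            )
        if not keep_cols:
            raise ValueError("no usable environmental variables remain")
        Xw = basis  # sqrt(r)-weighted standardized predictors, full rank

        # weighted projection of Qbar onto the predictor span
        coef, *_ = np.linalg.lstsq(Xw, Qbar, rcond=None)
        Qhat = Xw @ coef

        U, w, Vt = np.linalg.svd(Qhat, full_matrices=False)
        eig = w**2
        max_axes = int(min(len(keep_cols), Y.shape[1] - 1, Y.shape[0] - 1))
        k = max_axes if self.n_axes is None else min(self.n_axes, max_axes)
        k = max(1, min(k, int((eig > 1e-12 * max(eig[0], 1e-300)).sum()) or 1))
        U, w, V, eig = U[:, :k], w[:k], Vt[:k].T, eig[:k]

        constrained = float((Qhat**2).sum())
        axes = [f"CCA{i + 1}" for i in range(k)]

        # scores (scaling type 2: species at their weighted-average optima)
        species = (V * w) / sqrt_c_col(c)
        site_lc = U / sqrt_r[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            site_wa = (Qbar @ V) / sqrt_r[:, None] / w
        site = site_wa if self.site_score_type == "wa" else site_lc
        intraset = Xw.T @ U  # weighted corr(env_j, lc axis k); |.| <= 1

        self.eigenvalues_ = eig
        self.percent_variance_ = 100.0 * eig / constrained
        self.percent_total_variance_ = 100.0 * eig / total_inertia
        self.species_scores_ = pd.DataFrame(species, index=Y.columns, columns=axes)
        self.site_scores_ = pd.DataFrame(site, index=Y.index, columns=axes)
        self.site_scores_lc_ = pd.DataFrame(site_lc, index=Y.index, columns=axes)
        self.env_axis_scores_ = pd.DataFrame(intraset, index=keep_cols,
                                             columns=axes)
        self.total_inertia_ = total_inertia
        self.constrained_inertia_ = constrained
        self.dropped_env_columns_ = tuple(dropped_cols)
        self.dropped_sample_rows_ = dropped_rows
        return self

    def result(self) -> CCAResult:
        return CCAResult(
            eigenvalues=self.eigenvalues_,
            percent_variance=self.percent_variance_,
            percent_total_variance=self.percent_total_variance_,
            species_scores=self.species_scores_,
            site_scores=self.site_scores_,
            env_axis_scores=self.env_axis_scores_,
            total_inertia=self.total_inertia_,
            constrained_inertia=self.constrained_inertia_,
            dropped_env_columns=self.dropped_env_columns_,
            dropped_sample_rows=self.dropped_sample_rows_,
        )

    def fit_result(self, Y, X) -> CCAResult:
        return self.fit(Y, X).result()


def sqrt_c_col(c: np.ndarray) -> np.ndarray:
    return np.sqrt(c)[:, None]


def cca(abundance, env, n_axes: int | None = None,
        site_score_type: str = "wa") -> CCAResult:
    """Functional wrapper around :class:`CanonicalCorrespondenceAnalysis`."""
    return CanonicalCorrespondenceAnalysis(
        n_axes=n_axes, site_score_type=site_score_type
    ).fit_result(abundance, env)
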