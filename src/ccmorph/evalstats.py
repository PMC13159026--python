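"""Evaluation metrics and downstream statistics.

Segmentation overlap (Dice), 95th-percentile Hausdorff boundary distance,
per-position OLS group models with Benjamini-Hochberg correction, and the
two-way absolute-agreement intraclass correlation for test-retest data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree


class StatsError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# segmentation quality

def dice(x: np.ndarray, y: np.ndarray) -> float:
    """Dice similarity coefficient 2|X ^ Y| / (|X| + |Y|)."""
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape:
        raise StatsError("masks must share a grid")
    sx, sy = int(x.sum()), int(y.sum())
    if sx + sy == 0:
        raise StatsError("both masks are empty")
    return 2.0 * int((x & y).sum()) / (sx + sy)


def _boundary_points(mask: np.ndarray, spacing) -> np.ndarray:
    """World coordinates (mm) of mask voxels with a background face-neighbor."""
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(mask.ndim, 1))
    boundary = mask & ~eroded
    idx = np.argwhere(boundary)
    return idx * np.asarray(spacing, dtype=float)


def hausdorff95(x: np.ndarray, y: np.ndarray, spacing=None,
                percentile: float = 95.0) -> float:
    """Symmetric 95th-percentile Hausdorff distance between mask boundaries.

    The supremum in the classic Hausdorff definition is replaced by the
    given percentile of the pooled directed boundary distances; reported
    in mm via the voxel spacing.
    """
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape:
        raise StatsError("masks must share a grid")
    if not x.any() or not y.any():
        raise StatsError("empty mask")
    if spacing is None:
        spacing = np.ones(x.ndim)
    bx = _boundary_points(x, spacing)
    by = _boundary_points(y, spacing)
    d_xy = cKDTree(by).query(bx)[0]
    d_yx = cKDTree(bx).query(by)[0]
    return float(np.percentile(np.concatenate([d_xy, d_yx]), percentile))


# ---------------------------------------------------------------------------
# multiple testing

def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values (q-values), order preserving."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise StatsError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# group models

@dataclass
class GroupModelResult:
    beta: np.ndarray       # group coefficient per response
    p_value: np.ndarray
    q_value: np.ndarray
    se: np.ndarray
    n_used: np.ndarray


def fit_group_models(group: np.ndarray, covariates: np.ndarray | None,
                     responses: np.ndarray) -> GroupModelResult:
    """Per-response OLS of response ~ group + covariates (+ intercept).

    ``group`` is 0/1 (patients = 1 so negative betas mean reduction in
    patients); responses is (n_subjects, n_positions) and may contain NaN,
    excluded listwise per position.  Two-sided t-test p-values for the
    group coefficient, BH-corrected across positions.
    """
    group = np.asarray(group, dtype=float)
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    if responses.shape[0] != len(group):
        responses = responses.T
    n, m = responses.shape
    if covariates is None:
        covariates = np.empty((n, 0))
    covariates = np.asarray(covariates, dtype=float)
    if np.unique(group).size < 2:
        raise StatsError("both groups must be present")
    X_full = np.column_stack([np.ones(n), group, covariates])
    k = X_full.shape[1]

    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pvals = np.full(m, np.nan)
    n_used = np.zeros(m, dtype=int)

    valid_all = ~np.isnan(responses).any(axis=0)
    # fast path: columns without missing data share one design factorization
    if valid_all.any():
        Y = responses[:, valid_all]
        coef, se_c, p_c = _ols_group(X_full, Y)
        beta[valid_all] = coef
        se[valid_all] = se_c
        pvals[valid_all] = p_c
        n_used[valid_all] = n
    for j in np.where(~valid_all)[0]:
        keep = ~np.isnan(responses[:, j])
        if keep.sum() <= k:
            continue
        if np.unique(group[keep]).size < 2:
            continue
        coef, se_c, p_c = _ols_group(X_full[keep], responses[keep, j][:, None])
        beta[j], se[j], pvals[j] = coef[0], se_c[0], p_c[0]
        n_used[j] = int(keep.sum())

    finite = np.isfinite(pvals)
    q = np.full(m, np.nan)
    if finite.any():
        q[finite] = benjamini_hochberg(pvals[finite])
    return GroupModelResult(beta=beta, p_value=pvals, q_value=q, se=se,
                            n_used=n_used)


def _ols_group(X: np.ndarray, Y: np.ndarray):
    """OLS of each column of Y on X; returns stats for coefficient 1."""
    n, k = X.shape
    if n <= k:
        raise StatsError("not enough observations for the design")
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < k:
        raise StatsError("design matrix is rank deficient")
    XtX_inv = np.linalg.inv(XtX)
    coefs = XtX_inv @ (X.T @ Y)
    resid = Y - X @ coefs
    dof = n - k
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = coefs[1] / se
    p = 2 * stats.t.sf(np.abs(tstat), dof)
    return coefs[1], se, p


# ---------------------------------------------------------------------------
# reliability

def icc_absolute(measurements: np.ndarray) -> float:
    """Two-way single-measure absolute-agreement ICC — ICC(A,1) / ICC(2,1).

    ``measurements`` is (n_subjects, k_raters); systematic offsets between
    occasions count against agreement (unlike consistency ICC).
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise StatsError("need an n_subjects x k matrix with k >= 2")
    m = m[~np.isnan(m).any(axis=1)]
    n, k = m.shape
    if n < 3:
        raise StatsError("need at least 3 subjects")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_total = ((m - grand) ** 2).sum()
    if ss_total < 1e-300:
        raise StatsError("zero total variance")
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-300:
        raise StatsError("degenerate variance decomposition")
    return float((msr - mse) / denom)


def icc_consistency(measurements: np.ndarray) -> float:
    """Two-way single-measure consistency ICC — ICC(C,1) / ICC(3,1)."""
    m = np.asarray(measurements, dtype=float)
    m = m[~np.isnan(m).any(axis=1)]
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_total = ((m - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    msr = ss_rows / (n - 1)
    mse = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse))
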