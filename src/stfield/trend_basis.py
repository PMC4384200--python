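"""Empirical smooth time trends from long-series monitoring sites.

The temporal structure of the field is captured by a small number (1 or 2)
of smooth basis functions shared across the region.  They are estimated
from the sites with long records: missing entries of the time-by-site data
matrix are filled by an EM/SVD iteration, the leading left singular
vectors give raw trends, and a natural cubic spline projection smooths
them, with smoothness set by a degrees-of-freedom-per-year parameter.

The constant trend f0 == 1 is implicit; ``m`` counts non-constant trends
only.  Each estimated trend is normalized to zero mean and unit root mean
square over the grid (the scale is otherwise absorbed by its coefficient
field), and its sign is fixed so the loading at the first source site is
positive, making estimation deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import LONG_SERIES_TYPES, STDataset, TimeAxis


@dataclass
class TrendBasis:
    """m smoothed temporal basis functions on the 2-week grid."""

    m: int
    values: np.ndarray          # T x m
    axis: TimeAxis
    df_per_year: int
    source_sites: list[str] = field(default_factory=list)
    singular_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.axis), self.m):
            raise ValueError("trend value matrix must be T x m")

    def design_matrix(self, t_idx: np.ndarray | None = None) -> np.ndarray:
        """[1, f_1(t), ..., f_m(t)] at the given period indices."""
        vals = self.values if t_idx is None else self.values[np.asarray(t_idx, int)]
        return np.column_stack([np.ones(len(vals)), vals])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"f_{i + 1}" for i in range(self.m)]
        )
        df.insert(0, "period_start", [d.isoformat() for d in self.axis.period_starts])
        return df


def _normalize(values: np.ndarray) -> np.ndarray:
    out = values - values.mean(axis=0)
    rms = np.sqrt((out**2).mean(axis=0))
    if np.any(rms == 0):
        raise ValueError("degenerate (constant) trend cannot be normalized")
    return out / rms


def em_impute(
    series_matrix: np.ndarray,
    k: int,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> np.ndarray:
    """Fill missing entries of a T-by-n matrix by iterated rank-k SVD.

    Missing cells start at their column means; each iteration replaces them
    with the rank-k reconstruction of the current completed matrix until
    the Frobenius change of the imputed block drops below ``tol`` (relative
    to the matrix scale).  Observed entries are never altered.
    """
    X = np.array(series_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("series matrix must be 2-D")
    if k < 1:
        raise ValueError("rank k must be >= 1")
    miss = ~np.isfinite(X)
    n_obs = (~miss).sum(axis=0)
    if np.any(n_obs < 2):
        bad = np.where(n_obs < 2)[0]
        raise ValueError(f"columns with < 2 observed entries: {bad.tolist()}")
    if not miss.any():
        return X
    col_means = np.nansum(np.where(miss, np.nan, X), axis=0) / n_obs
    X[miss] = np.broadcast_to(col_means, X.shape)[miss]
    scale = max(np.abs(X).max(), 1.0)
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        recon = (U[:, :k] * s[:k]) @ Vt[:k]
        delta = np.sqrt(np.sum((X[miss] - recon[miss]) ** 2))
        X[miss] = recon[miss]
        if delta < tol * scale:
            break
    return X


def derive_raw_trends(completed: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Leading left singular vectors of the column-centered matrix.

    Returns (T x m raw trends, singular values of the centered matrix).
    """
    X = np.asarray(completed, dtype=float)
    T, n = X.shape
    if m >= min(T, n):
        raise ValueError("m must be smaller than min(T, n_sites)")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("zero-variance matrix has no trends")
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    return U[:, :m], s


def natural_cubic_spline_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Natural cubic spline regression basis with ``df`` columns
    (intercept included), knots equally spaced over the range of ``x``.

    Uses the closed-form truncated-power construction with linear
    constraints beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    if df < 2:
        raise ValueError("natural spline basis needs df >= 2")
    K = df  # number of knots equals the number of basis functions
    knots = np.linspace(x.min(), x.max(), K)

    def d(j: int) -> np.ndarray:
        num = np.clip(x - knots[j], 0, None) ** 3 - np.clip(x - knots[-1], 0, None) ** 3
        return num / (knots[-1] - knots[j])

    cols = [np.ones_like(x), x]
    dK1 = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - dK1)
    return np.column_stack(cols)


def smooth_trends(
    raw: np.ndarray, axis: TimeAxis, df_per_year: int
) -> np.ndarray:
    """Least-squares projection of each raw trend onto a natural cubic
    spline basis with ``round(df_per_year * span_years)`` total df, then
    re-normalized to zero mean / unit RMS."""
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if raw.shape[0] != len(axis):
        raise ValueError("raw trend length must match the axis")
    total_df = int(round(df_per_year * axis.span_years))
    if total_df >= len(axis):
        raise ValueError(
            f"total spline df ({total_df}) must be below T ({len(axis)})"
        )
    B = natural_cubic_spline_basis(axis.years_elapsed(), total_df)
    coef, *_ = np.linalg.lstsq(B, raw, rcond=None)
    return _normalize(B @ coef)


def estimate_trend_basis(
    data: STDataset,
    m: int,
    df_per_year: int,
    em_tol: float = 1e-8,
    em_max_iter: int = 500,
) -> TrendBasis:
    """Estimate the trend basis from the long-series sites of ``data``.

    Composition: EM imputation (rank m+1, capped at n-1) -> SVD raw trends
    -> spline smoothing -> normalization and sign fix.  Requires a
    log-scale dataset restricted to (or containing) long-series site types.
    """
    source = [s.site_id for s in data.sites_of_type(*LONG_SERIES_TYPES)]
    if len(source) < 2:
        raise ValueError("need at least 2 long-series sites to estimate trends")
    mat = data.to_matrix(source).to_numpy()
    k = min(m + 1, len(source) - 1)
    completed = em_impute(mat, k=k, tol=em_tol, max_iter=em_max_iter)
    raw, svals = derive_raw_trends(completed, m)
    smoothed = smooth_trends(raw, data.axis, df_per_year)
    # sign convention: positive loading on the first source site
    first = completed[:, 0] - completed[:, 0].mean()
    for j in range(m):
        if float(first @ smoothed[:, j]) < 0:
            smoothed[:, j] = -smoothed[:, j]
    return TrendBasis(
        m=m,
        values=smoothed,
        axis=data.axis,
        df_per_year=df_per_year,
        source_sites=source,
        singular_values=svals[: m + 1],
    )


def lag1_residual_autocorrelation(data: STDataset, basis: TrendBasis) -> float:
    """Diagnostic: mean lag-1 autocorrelation of per-site residuals after
    regressing each long-series site on the trend basis.

    Under the model the residuals are independent across periods, so this
    should be near zero; a large value signals unmodeled temporal
    structure (too few trends or too little smoothing df).
    """
    acs = []
    for sid in basis.source_sites:
        sub = data.obs[data.obs["site_id"] == sid].sort_values("t")
        t = sub["t"].to_numpy(int)
        y = sub["value"].to_numpy(float)
        if len(y) < basis.m + 3:
            continue
        X = basis.design_matrix(t)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        # pair residuals at consecutive grid periods only
        keep = np.where(np.diff(t) == 1)[0]
        if len(keep) < 3:
            continue
        a, b = r[keep], r[keep + 1]
        denom = np.std(a) * np.std(b)
        if denom > 0:
            acs.append(float(np.mean((a - a.mean()) * (b - b.mean())) / denom))
    if not acs:
        raise ValueError("no site had enough consecutive observations")
    return float(np.mean(acs))
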