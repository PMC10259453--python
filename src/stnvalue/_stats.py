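"""Shared statistical machinery.

The sliding-window procedures need on the order of 1e5 two-way ANOVAs per
calibration run, so the two-factor ANOVA is implemented as a vectorized
type-II model comparison (QR projections shared across response columns)
rather than one general-linear-model fit per bin.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "two_way_anova",
    "rayleigh_test",
    "zscore_columns",
    "ols_betas",
]


def _design_matrices(a_codes: np.ndarray, b_codes: np.ndarray):
    """One-hot cell designs for the four nested models (intercept implicit).

    Returns QR orthonormal bases for: B-only, A-only, A+B additive, and the
    full cell-means model.
    """
    n = a_codes.size
    a_levels, a_idx = np.unique(a_codes, return_inverse=True)
    b_levels, b_idx = np.unique(b_codes, return_inverse=True)
    ka, kb = a_levels.size, b_levels.size
    if ka < 2 or kb < 2:
        raise ValueError("each factor needs at least two levels")

    ones = np.ones((n, 1))
    A = np.zeros((n, ka))
    A[np.arange(n), a_idx] = 1.0
    B = np.zeros((n, kb))
    B[np.arange(n), b_idx] = 1.0
    AB = np.zeros((n, ka * kb))
    AB[np.arange(n), a_idx * kb + b_idx] = 1.0

    def q_of(X):
        q, r = np.linalg.qr(X)
        keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
        return q[:, keep]

    q_b = q_of(np.hstack([ones, B[:, :-1]]))
    q_a = q_of(np.hstack([ones, A[:, :-1]]))
    q_ab = q_of(np.hstack([ones, A[:, :-1], B[:, :-1]]))
    q_full = q_of(AB)
    dfs = {
        "a": ka - 1,
        "b": kb - 1,
        "ab": (ka - 1) * (kb - 1),
        "resid": n - q_full.shape[1],
    }
    return q_b, q_a, q_ab, q_full, dfs


def two_way_anova(y: np.ndarray, a_codes, b_codes):
    """Type-II two-way ANOVA with interaction, vectorized over columns of y.

    Parameters
    ----------
    y : (n,) or (n, m) array
        Response(s); each column is tested independently.
    a_codes, b_codes : (n,) arrays
        Factor level codes (any hashable dtype).

    Returns
    -------
    dict with keys 'reward'/'delay'/'interaction' mapping to
    ``(F, df_effect, df_resid, p)`` tuples (arrays of shape (m,) or scalars).
    Columns with zero residual variance yield NaN statistics.
    """
    y = np.asarray(y, dtype=float)
    scalar = y.ndim == 1
    if scalar:
        y = y[:, None]
    a_codes = np.asarray(a_codes)
    b_codes = np.asarray(b_codes)
    q_b, q_a, q_ab, q_full, dfs = _design_matrices(a_codes, b_codes)

    yss = np.sum(y * y, axis=0)

    def rss(q):
        proj = q.T @ y
        return np.maximum(yss - np.sum(proj * proj, axis=0), 0.0)

    rss_b, rss_a, rss_ab, rss_full = rss(q_b), rss(q_a), rss(q_ab), rss(q_full)
    ss = {
        "reward": (np.maximum(rss_b - rss_ab, 0.0), dfs["a"]),
        "delay": (np.maximum(rss_a - rss_ab, 0.0), dfs["b"]),
        "interaction": (np.maximum(rss_ab - rss_full, 0.0), dfs["ab"]),
    }
    df_res = dfs["resid"]
    with np.errstate(divide="ignore", invalid="ignore"):
        mse = rss_full / df_res
        degenerate = mse <= 1e-12 * np.maximum(yss, 1.0)
        out = {}
        for name, (ss_eff, df_eff) in ss.items():
            F = (ss_eff / df_eff) / mse
            F = np.where(degenerate, np.nan, F)
            p = stats.f.sf(F, df_eff, df_res)
            if scalar:
                out[name] = (float(F[0]), df_eff, df_res, float(p[0]))
            else:
                out[name] = (F, df_eff, df_res, p)
    return out


def rayleigh_test(angles_deg: np.ndarray):
    """Rayleigh test of circular uniformity.

    z = n * Rbar^2 with the standard small-sample p approximation
    (Zar, Biostatistical Analysis, eq. 27.4).

    Returns (z, p, mean_angle_deg, resultant_length_rbar).
    """
    ang = np.deg2rad(np.asarray(angles_deg, dtype=float))
    n = ang.size
    if n == 0:
        raise ValueError("no angles supplied")
    C = np.cos(ang).sum()
    S = np.sin(ang).sum()
    R = np.hypot(C, S)
    rbar = R / n
    z = n * rbar**2
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - R**2)) - (1 + 2 * n))
    p = float(min(max(p, 0.0), 1.0))
    mean_angle = float(np.rad2deg(np.arctan2(S, C)))
    return float(z), p, mean_angle, float(rbar)


def zscore_columns(x: np.ndarray):
    """Z-score columns; zero-variance columns are zeroed and reported.

    Returns (z, mean, sd, degenerate_mask); sd has ddof=0.
    """
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    degenerate = sd <= 0
    safe_sd = np.where(degenerate, 1.0, sd)
    z = (x - mean) / safe_sd
    if x.ndim == 1:
        if degenerate:
            z = np.zeros_like(x)
    else:
        z[:, degenerate] = 0.0
    return z, mean, sd, degenerate


def ols_betas(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients via lstsq; y may have multiple columns."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta
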