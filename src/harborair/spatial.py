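"""Spatial statistics for airborne-concentration fields.

Distance-decay regression (OLS on log10 distance), Moran's I with
permutation inference, ordinary kriging with a WLS-fitted exponential
semivariogram and leave-one-out cross-validation, and the two-sided
Wilcoxon rank-sum test (exact by full enumeration for small samples).

Moran's I and the kriging system are implemented directly: the weight
scheme (row-standardized inverse distance by default), the Cressie-weighted
variogram fit and the unbiasedness (weights-sum-to-one) constraint are all
part of the contract being tested.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, spatial as sp_spatial, stats


# ---------------------------------------------------------------------------
# distance-decay regression

def distance_regression(obs: pd.DataFrame, value_col: str = "value",
                        distance_col: str = "distance_to_water") -> dict:
    """OLS of concentration on log10(distance): slope, intercept, r2, p."""
    if len(obs) < 3:
        raise ValueError("need at least 3 observations")
    d = obs[distance_col].to_numpy(float)
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    x = np.log10(d)
    if np.ptp(x) == 0:
        raise ValueError("singular design: all distances equal")
    y = obs[value_col].to_numpy(float)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    r2 = 0.0 if np.ptp(y) == 0 else float(model.rsquared)
    return {
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "r2": r2,
        "p": float(model.pvalues[1]),
    }


# ---------------------------------------------------------------------------
# Moran's I

def inverse_distance_weights(xy: np.ndarray) -> np.ndarray:
    """Row-standardized inverse-distance weight matrix (zero diagonal)."""
    dist = sp_spatial.distance_matrix(xy, xy)
    off = dist[~np.eye(len(xy), dtype=bool)]
    if np.any(off == 0):
        raise ValueError("coincident points: inverse-distance weights undefined")
    with np.errstate(divide="ignore"):
        w = 1.0 / dist
    np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)


def morans_i(obs: pd.DataFrame, weights: np.ndarray | None = None,
             n_perm: int = 999, seed: int | None = None,
             value_col: str = "value") -> dict:
    """Moran's I with expectation -1/(n-1) and a permutation p-value.

    I = (n / S0) * (z' W z) / (z' z) for centred values z; the default W
    is row-standardized inverse distance.  The permutation p is one-sided
    (positive autocorrelation), p = (1 + #{I_perm >= I_obs}) / (n_perm+1).
    """
    z = obs[value_col].to_numpy(float)
    n = len(z)
    if n < 5:
        raise ValueError("need at least 5 observations")
    if weights is None:
        weights = inverse_distance_weights(obs[["x", "y"]].to_numpy(float))
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    s0 = w.sum()
    zc = z - z.mean()
    denom = zc @ zc
    if denom == 0:
        raise ValueError("constant field: Moran's I undefined")

    def moran(v):
        return (n / s0) * (v @ w @ v) / (v @ v)

    i_obs = float(moran(zc))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if moran(rng.permutation(zc)) >= i_obs:
            count += 1
    return {
        "I": i_obs,
        "expected_I": -1.0 / (n - 1),
        "p_perm": (1.0 + count) / (n_perm + 1.0),
        "n_perm": n_perm,
    }


# ---------------------------------------------------------------------------
# ordinary kriging with exponential variogram

def empirical_variogram(xy: np.ndarray, z: np.ndarray,
                        n_bins: int = 15) -> pd.DataFrame:
    """Binned empirical semivariogram: lag, gamma, pair count per bin.

    Lags are cut off at one third of the maximum separation, the usual
    convention (distant pairs carry little structural information but
    huge pair counts).
    """
    d = sp_spatial.distance.pdist(xy)
    g = 0.5 * sp_spatial.distance.pdist(z[:, None], "sqeuclidean")
    edges = np.linspace(0.0, d.max() / 3.0, n_bins + 1)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (d > lo) & (d <= hi)
        if m.sum() > 0:
            rows.append({"lag": d[m].mean(), "gamma": g[m].mean(),
                         "n_pairs": int(m.sum())})
    return pd.DataFrame(rows)


def exponential_variogram(h, nugget, psill, range_):
    """gamma(h) = nugget + psill * (1 - exp(-h / range_))."""
    return nugget + psill * (1.0 - np.exp(-np.asarray(h, float) / range_))


def fit_variogram(emp: pd.DataFrame, nugget_floor: float = 0.0) -> dict:
    """WLS (Cressie weights n_pairs/gamma_model^2) exponential-model fit."""
    h = emp["lag"].to_numpy(float)
    g = emp["gamma"].to_numpy(float)
    npair = emp["n_pairs"].to_numpy(float)

    def resid(params):
        nug, psill, rng_ = params
        model = exponential_variogram(h, nug, psill, rng_)
        w = np.sqrt(npair) / np.maximum(model, 1e-12)
        return w * (g - model)

    p0 = [nugget_floor, max(g.max() - nugget_floor, 1e-9), max(h.max() / 3.0, 1e-6)]
    res = optimize.least_squares(
        resid, p0, bounds=([0.0, 1e-12, 1e-9], [np.inf] * 3))
    nug, psill, rng_ = res.x
    return {"nugget": float(nug), "psill": float(psill), "range": float(rng_),
            "sill": float(nug + psill)}


def _krige_weights(xy_obs: np.ndarray, xy_pred: np.ndarray,
                   vgm: dict) -> np.ndarray:
    """Ordinary-kriging weights (n_pred, n_obs); rows sum to one."""
    n = len(xy_obs)
    d_oo = sp_spatial.distance_matrix(xy_obs, xy_obs)
    gam = exponential_variogram(d_oo, vgm["nugget"], vgm["psill"], vgm["range"])
    np.fill_diagonal(gam, 0.0)
    a = np.ones((n + 1, n + 1))
    a[:n, :n] = gam
    a[n, n] = 0.0
    d_po = sp_spatial.distance_matrix(xy_pred, xy_obs)
    gam0 = exponential_variogram(d_po, vgm["nugget"], vgm["psill"], vgm["range"])
    gam0[d_po == 0.0] = 0.0  # prediction at a datum: zero semivariance to itself
    b = np.hstack([gam0, np.ones((len(xy_pred), 1))])
    try:
        lam = np.linalg.solve(a, b.T).T
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"kriging system singular (cond ~ {np.linalg.cond(a):.2e}); "
            "check for duplicate points or a degenerate variogram") from exc
    return lam[:, :-1]


def ordinary_kriging(obs: pd.DataFrame, grid: pd.DataFrame | None = None,
                     variogram: dict | None = None,
                     value_col: str = "value") -> dict:
    """Ordinary kriging with leave-one-out cross-validation.

    Fits an exponential variogram to the observations unless one is
    supplied, predicts at ``grid`` (columns x, y; default: the observation
    locations), and reports LOO r2 and rmse.  Kriging weights sum to one
    at every prediction point (unbiasedness constraint).
    """
    if len(obs) < 5:
        raise ValueError("need at least 5 observations")
    xy = obs[["x", "y"]].to_numpy(float)
    z = obs[value_col].to_numpy(float)
    if variogram is None:
        if np.ptp(z) == 0:
            variogram = {"nugget": 0.0, "psill": 1e-12,
                         "range": float(np.ptp(xy) or 1.0), "sill": 1e-12}
        else:
            variogram = fit_variogram(empirical_variogram(xy, z))

    xy_pred = xy if grid is None else grid[["x", "y"]].to_numpy(float)
    lam = _krige_weights(xy, xy_pred, variogram)
    pred = lam @ z

    loo = np.empty(len(z))
    idx = np.arange(len(z))
    for i in idx:
        keep = idx != i
        lam_i = _krige_weights(xy[keep], xy[i:i + 1], variogram)
        loo[i] = float(lam_i[0] @ z[keep])
    resid = z - loo
    ss_tot = float(((z - z.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return {
        "predictions": pred,
        "weights": lam,
        "variogram": variogram,
        "loo_predictions": loo,
        "loo_r2": r2,
        "loo_rmse": float(np.sqrt((resid ** 2).mean())),
    }


def simulate_gaussian_field(xy: np.ndarray, nugget: float, psill: float,
                            range_: float, seed: int) -> np.ndarray:
    """Gaussian random field with an exponential covariance (test truth)."""
    d = sp_spatial.distance_matrix(xy, xy)
    cov = psill * np.exp(-d / range_) + nugget * np.eye(len(xy))
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(xy)))
    rng = np.random.default_rng(seed)
    return chol @ rng.standard_normal(len(xy))


# ---------------------------------------------------------------------------
# rank-sum test

def ranksum_test(group_a, group_b) -> dict:
    """Two-sided Wilcoxon rank-sum test.

    Exact by full enumeration of rank assignments for combined n <= 12
    (ties handled with midranks); tie-corrected normal approximation
    (Mann-Whitney) otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    n, na = len(a) + len(b), len(a)
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    w_obs = float(ranks[:na].sum())
    if n <= 12:
        mean_w = na * (n + 1) / 2.0
        count = total = 0
        for pick in combinations(range(n), na):
            w = ranks[list(pick)].sum()
            total += 1
            if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
                count += 1
        return {"statistic": w_obs, "p": count / total, "method": "exact"}
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return {"statistic": w_obs, "p": float(res.pvalue), "method": "normal"}
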