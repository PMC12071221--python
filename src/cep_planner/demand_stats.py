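"""Rank-based tests and regression diagnostics for demand patterns.

Implements, from their defining formulas, the nonparametric toolkit used to
compare areas, weeks and weekdays of the station-level demand data:

* Kruskal–Wallis H (tie-corrected, chi-square reference distribution),
* Dunn's pairwise post-hoc z tests with Bonferroni adjustment,
* Spearman rank correlation with mid-ranks and the t approximation,
* simple least-squares fit with R², adjusted R² and the Durbin–Watson
  autocorrelation diagnostic (p-value by null simulation).

scipy supplies only the reference distributions (chi-square, normal, t);
the statistics themselves are computed here so that tie handling and the
adjustment conventions are explicit and testable against brute-force
oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p: float
    group_sizes: tuple[int, ...]


@dataclass(frozen=True)
class DunnPair:
    group_a: int
    group_b: int
    z: float
    p_raw: float
    p_adj: float


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    n: int
    p: float


@dataclass(frozen=True)
class OLSDiagnostics:
    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    p_slope: float
    dw_stat: float
    dw_p: float


def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrs):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    if sum(g.size for g in arrs) < 3:
        raise ValueError("need at least three observations in total")
    return arrs


def _tie_term(pooled_ranks_source: np.ndarray) -> float:
    """Sum of t^3 - t over tied value groups."""
    _, counts = np.unique(pooled_ranks_source, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Tie-corrected Kruskal–Wallis H test.

    Mid-ranks are assigned to ties; H is divided by the correction factor
    ``1 - sum(t^3 - t) / (N^3 - N)``; the p-value is the upper tail of the
    chi-square distribution with ``groups - 1`` degrees of freedom.
    """
    arrs = _check_groups(groups)
    pooled = np.concatenate(arrs)
    n = pooled.size
    ranks = _sps.rankdata(pooled)
    df = len(arrs) - 1
    if np.all(pooled == pooled[0]):
        # all observations identical: no evidence of any difference
        return KWResult(H=0.0, df=df, p=1.0, group_sizes=tuple(g.size for g in arrs))
    h = 0.0
    offset = 0
    for g in arrs:
        r = ranks[offset : offset + g.size]
        h += r.sum() ** 2 / g.size
        offset += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    h /= correction
    p = float(_sps.chi2.sf(h, df))
    return KWResult(
        H=float(h), df=df, p=p, group_sizes=tuple(g.size for g in arrs)
    )


def dunn_bonferroni(
    groups: Sequence[Sequence[float]], m: int | None = None
) -> list[DunnPair]:
    """Dunn's post-hoc pairwise comparisons with Bonferroni adjustment.

    ``z_ij = (meanRank_i - meanRank_j) / sqrt(V * (1/n_i + 1/n_j))`` with the
    tie-corrected variance term ``V = N(N+1)/12 - sum(t^3 - t)/(12(N-1))``.
    Raw p-values are two-sided normal probabilities; the adjustment
    multiplies by the number of pairwise comparisons ``m = g(g-1)/2``
    (per family, capped at 1).
    """
    arrs = _check_groups(groups)
    g = len(arrs)
    if m is None:
        m = g * (g - 1) // 2
    pooled = np.concatenate(arrs)
    n = pooled.size
    ranks = _sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    offset = 0
    for arr in arrs:
        mean_ranks.append(ranks[offset : offset + arr.size].mean())
        sizes.append(arr.size)
        offset += arr.size
    variance = n * (n + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n - 1))
    out = []
    for i in range(g):
        for j in range(i + 1, g):
            denom = math.sqrt(variance * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if denom == 0.0:
                z, p_raw = 0.0, 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / denom
                p_raw = float(2 * _sps.norm.sf(abs(z)))
            out.append(
                DunnPair(
                    group_a=i,
                    group_b=j,
                    z=float(z),
                    p_raw=p_raw,
                    p_adj=min(1.0, p_raw * m),
                )
            )
    return out


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with mid-ranks for ties.

    rho is the Pearson correlation of the rank vectors (equals the classic
    ``1 - 6 sum d^2 / (n(n^2-1))`` when there are no ties); the p-value uses
    the t approximation with ``n - 2`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least three pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant sequence")
    rx = _sps.rankdata(x)
    ry = _sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2 * _sps.t.sf(abs(t), n - 2))
    return SpearmanResult(rho=rho, n=n, p=p)


def durbin_watson_statistic(residuals: np.ndarray) -> float:
    """DW = sum (e_t - e_{t-1})^2 / sum e_t^2, in [0, 4]."""
    e = np.asarray(residuals, dtype=float)
    denom = float(np.dot(e, e))
    if denom == 0.0:
        return 2.0  # zero residuals: no autocorrelation evidence either way
    return float(np.sum(np.diff(e) ** 2) / denom)


def ols_with_durbin_watson(
    x: Sequence[float],
    y: Sequence[float],
    n_null: int = 1000,
    seed: int = 0,
) -> OLSDiagnostics:
    """Simple least-squares fit of y on x with autocorrelation diagnostics.

    Reports slope, intercept, R², adjusted R² ``= 1 - (1-R²)(n-1)/(n-2)``,
    the two-sided slope p-value, the Durbin–Watson statistic of the
    residuals in time order, and a lower-tail DW p-value (evidence of
    positive autocorrelation) obtained by simulating the null distribution
    of DW for the same design with ``n_null`` seeded Gaussian replicates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least three observations")
    if np.all(x == x[0]):
        raise ValueError("degenerate regressor: x is constant")
    X = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    intercept, slope = float(coef[0]), float(coef[1])
    fitted = X @ coef
    resid = y - fitted
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    if ss_res == 0.0 or r2 >= 1.0:
        p_slope = 0.0
    else:
        sigma2 = ss_res / (n - 2)
        se_slope = math.sqrt(sigma2 / np.sum((x - x.mean()) ** 2))
        t = slope / se_slope
        p_slope = float(2 * _sps.t.sf(abs(t), n - 2))
    dw = durbin_watson_statistic(resid)
    # null distribution of DW depends only on the design matrix
    rng = np.random.default_rng(seed)
    hat = X @ np.linalg.pinv(X)
    annihilator = np.eye(n) - hat
    noise = rng.standard_normal((n_null, n))
    null_resid = noise @ annihilator.T
    num = np.sum(np.diff(null_resid, axis=1) ** 2, axis=1)
    den = np.sum(null_resid**2, axis=1)
    dw_null = num / den
    dw_p = float(np.mean(dw_null <= dw))
    return OLSDiagnostics(
        slope=slope,
        intercept=intercept,
        r_squared=float(r2),
        adj_r_squared=float(adj_r2),
        p_slope=p_slope,
        dw_stat=dw,
        dw_p=dw_p,
    )
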