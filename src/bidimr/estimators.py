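"""MR estimators: Wald ratio, IVW, Egger, median, Cochran's Q, MR-PRESSO.

All estimators consume harmonized (bx, sx, by, sy) quadruples.  Confidence
intervals and p-values follow the normal-approximation convention
(estimate ± 1.959964·se, p = 2·Φ(−|z|)), except Egger regression whose
tests use the t reference on n − 2 degrees of freedom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .harmonize import HarmonizedPair, HarmonizedPairs

logger = logging.getLogger(__name__)

#: normal 0.975 quantile at the precision the CI convention fixes
Z95 = 1.959964

MIN_PAIRS_SENSITIVITY = 3
MIN_PAIRS_PRESSO = 4
MIN_PRESSO_SIM = 100


class EstimationError(Exception):
    """Domain error in an estimator (bad input, not infeasibility)."""


@dataclass(frozen=True, slots=True)
class NotFeasible:
    """Analysis not feasible (too few instruments); rendered as NA."""

    method: str
    reason: str
    n_snps: int


@dataclass(frozen=True, slots=True)
class MREstimate:
    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int


def ci_and_p(estimate: float, se: float) -> tuple[float, float, float]:
    """95% normal interval and two-sided normal p-value."""
    if se <= 0:
        raise EstimationError(f"se must be > 0, got {se}")
    half = Z95 * se
    pvalue = 2.0 * sps.norm.sf(abs(estimate) / se)
    return estimate - half, estimate + half, float(pvalue)


def _estimate(method: str, estimate: float, se: float, n_snps: int) -> MREstimate:
    ci_low, ci_high, pvalue = ci_and_p(estimate, se)
    return MREstimate(method, float(estimate), float(se), ci_low, ci_high, pvalue, n_snps)


def _as_pairs(pairs: HarmonizedPairs | Iterable[HarmonizedPair]) -> list[HarmonizedPair]:
    return list(pairs)


def _arrays(
    pairs: HarmonizedPairs | Iterable[HarmonizedPair], drop_zero_bx: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Extract (bx, sx, by, sy, rsids); pairs with bx = 0 are excluded and logged."""
    kept = []
    for p in _as_pairs(pairs):
        if drop_zero_bx and p.bx == 0:
            logger.warning("%s: excluded from estimation (zero exposure effect)", p.rsid)
            continue
        kept.append(p)
    bx = np.array([p.bx for p in kept], dtype=float)
    sx = np.array([p.sx for p in kept], dtype=float)
    by = np.array([p.by for p in kept], dtype=float)
    sy = np.array([p.sy for p in kept], dtype=float)
    return bx, sx, by, sy, [p.rsid for p in kept]


def wald_ratio(pair: HarmonizedPair, order: int = 1) -> MREstimate:
    """Single-instrument causal estimate by/bx with delta-method SE.

    order 1: se = sy/|bx|; order 2 adds the exposure-uncertainty term
    sqrt(sy²/bx² + by²·sx²/bx⁴).
    """
    if pair.bx == 0:
        raise EstimationError(f"{pair.rsid}: instrument has no exposure effect (bx = 0)")
    if order not in (1, 2):
        raise EstimationError(f"delta-method order must be 1 or 2, got {order}")
    estimate = pair.by / pair.bx
    if order == 1:
        se = pair.sy / abs(pair.bx)
    else:
        se = math.sqrt(
            pair.sy**2 / pair.bx**2 + pair.by**2 * pair.sx**2 / pair.bx**4
        )
    return _estimate("wald_ratio", estimate, se, 1)


def ivw(
    pairs: HarmonizedPairs | Iterable[HarmonizedPair], mode: str = "fixed"
) -> MREstimate:
    """Inverse-variance-weighted combination of per-instrument Wald ratios.

    First-order weights wᵢ = bxᵢ²/syᵢ²; equivalent to weighted regression
    of by on bx through the origin.  ``multiplicative-random`` inflates the
    fixed-effect SE by sqrt(max(1, Q/(n−1))).
    """
    if mode not in ("fixed", "multiplicative-random"):
        raise EstimationError(f"unknown IVW mode {mode!r}")
    bx, _sx, by, sy, _ = _arrays(pairs)
    n = len(bx)
    if n == 0:
        raise EstimationError("IVW requires at least one usable pair")
    w = bx**2 / sy**2
    r = by / bx
    if n == 1:  # exact reduction to the first-order Wald ratio
        estimate = float(r[0])
        se = float(sy[0] / abs(bx[0]))
    else:
        estimate = float(np.sum(w * r) / np.sum(w))
        se = float(1.0 / math.sqrt(np.sum(w)))
    if mode == "multiplicative-random" and n > 1:
        q = float(np.sum(w * (r - estimate) ** 2))
        se *= math.sqrt(max(1.0, q / (n - 1)))
    return _estimate("ivw" if mode == "fixed" else "ivw_mre", estimate, se, n)


@dataclass(frozen=True, slots=True)
class EggerResult:
    """Egger regression: pleiotropy-adjusted slope plus intercept test.

    Both tests use the t reference on n − 2 df; the slope block's CI keeps
    the package-wide normal convention.
    """

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float
    df: int


def egger(pairs: HarmonizedPairs | Iterable[HarmonizedPair]) -> EggerResult | NotFeasible:
    """Weighted regression of by on bx with intercept, weights 1/sy².

    Pairs are first oriented so bx ≥ 0 (negating both effects where
    needed); requires at least 3 instruments.
    """
    bx, _sx, by, sy, _ = _arrays(pairs)
    n = len(bx)
    if n < MIN_PAIRS_SENSITIVITY:
        return NotFeasible("egger", f"requires >= {MIN_PAIRS_SENSITIVITY} instruments", n)
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / sy**2
    # weighted normal equations for [intercept, slope]
    sw = np.sum(w)
    swx = np.sum(w * x)
    swxx = np.sum(w * x * x)
    swy = np.sum(w * y)
    swxy = np.sum(w * x * y)
    det = sw * swxx - swx**2
    if det <= 0:
        raise EstimationError("degenerate design: instruments have identical |bx|")
    intercept = (swxx * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    resid = y - intercept - slope * x
    df = n - 2
    sigma2 = float(np.sum(w * resid**2) / df)
    var_intercept = sigma2 * swxx / det
    var_slope = sigma2 * sw / det
    slope_se = math.sqrt(var_slope)
    intercept_se = math.sqrt(var_intercept)
    slope_p = float(2.0 * sps.t.sf(abs(slope) / slope_se, df))
    intercept_p = float(2.0 * sps.t.sf(abs(intercept) / intercept_se, df))
    ci_low = slope - Z95 * slope_se
    ci_high = slope + Z95 * slope_se
    slope_block = MREstimate("egger", float(slope), slope_se, ci_low, ci_high, slope_p, n)
    return EggerResult(slope_block, float(intercept), intercept_se, intercept_p, df)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: where cumulative weight crosses 1/2."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / np.sum(weights)
    cum = np.cumsum(w) - 0.5 * w
    if cum[0] >= 0.5:
        return float(v[0])
    if cum[-1] < 0.5:
        return float(v[-1])
    idx = int(np.searchsorted(cum, 0.5, side="left")) - 1
    # linear interpolation between the straddling order statistics
    frac = (0.5 - cum[idx]) / (cum[idx + 1] - cum[idx])
    return float(v[idx] + frac * (v[idx + 1] - v[idx]))


def _weighted_median_rows(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise interpolated weighted median for (m, n) arrays."""
    order = np.argsort(values, axis=1)
    v = np.take_along_axis(values, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / np.sum(w, axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) - 0.5 * w
    m, n = v.shape
    out = np.empty(m)
    for i in range(m):  # small n: simple loop over rows' interpolation
        ci = cum[i]
        if ci[0] >= 0.5:
            out[i] = v[i, 0]
        elif ci[-1] < 0.5:
            out[i] = v[i, -1]
        else:
            idx = int(np.searchsorted(ci, 0.5, side="left")) - 1
            frac = (0.5 - ci[idx]) / (ci[idx + 1] - ci[idx])
            out[i] = v[i, idx] + frac * (v[i, idx + 1] - v[i, idx])
    return out


def median_estimate(
    pairs: HarmonizedPairs | Iterable[HarmonizedPair],
    weighted: bool = True,
    n_boot: int = 5000,
    seed: int = 0,
) -> MREstimate | NotFeasible:
    """Simple or weighted median of per-instrument ratio estimates.

    The SE is the standard deviation of the estimate over ``n_boot``
    parametric bootstrap resamples of (bx, by) from their normal sampling
    distributions; consistent when valid instruments carry a majority of
    the weight.
    """
    bx, sx, by, sy, _ = _arrays(pairs)
    n = len(bx)
    if n < MIN_PAIRS_SENSITIVITY:
        method = "weighted_median" if weighted else "simple_median"
        return NotFeasible(method, f"requires >= {MIN_PAIRS_SENSITIVITY} instruments", n)
    if n_boot < 2:
        raise EstimationError("n_boot must be >= 2")
    ratios = by / bx

    def point(r: np.ndarray, b: np.ndarray, s: np.ndarray) -> float:
        if weighted:
            return _weighted_median(r, b**2 / s**2)
        return float(np.median(r))

    estimate = point(ratios, bx, sy)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, n))
    by_star = rng.normal(by, sy, size=(n_boot, n))
    bx_star = np.where(bx_star == 0, np.finfo(float).tiny, bx_star)
    r_star = by_star / bx_star
    if weighted:
        boots = _weighted_median_rows(r_star, bx_star**2 / sy**2)
    else:
        boots = np.median(r_star, axis=1)
    se = float(np.std(boots, ddof=1))
    method = "weighted_median" if weighted else "simple_median"
    return _estimate(method, estimate, se, n)


@dataclass(frozen=True, slots=True)
class QResult:
    """Cochran's Q heterogeneity of ratio estimates around a reference."""

    q: float
    df: int
    pvalue: float


def cochran_q(
    pairs: HarmonizedPairs | Iterable[HarmonizedPair], reference: MREstimate
) -> QResult:
    """Q = Σ wᵢ (rᵢ − θ̂)² with first-order weights; chi-square on n − 1 df."""
    bx, _sx, by, sy, _ = _arrays(pairs)
    n = len(bx)
    if n < 2:
        raise EstimationError("Cochran's Q requires at least two pairs")
    w = bx**2 / sy**2
    r = by / bx
    q = float(np.sum(w * (r - reference.estimate) ** 2))
    df = n - 1
    pvalue = float(sps.chi2.sf(q, df))
    return QResult(q, df, pvalue)


@dataclass(frozen=True, slots=True)
class PressoResult:
    """MR-PRESSO output: global test, per-SNP outlier tests, corrected IVW."""

    rss_obs: float
    global_p: float
    outlier_p: dict[str, float]
    outliers: tuple[str, ...]
    corrected: MREstimate | None
    distortion_p: float | None
    n_sim: int
    seed: int


def _loo_ivw(w: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates, vectorized (works on 1-D or row-wise 2-D)."""
    sw = np.sum(w, axis=-1, keepdims=True)
    swr = np.sum(w * r, axis=-1, keepdims=True)
    return (swr - w * r) / (sw - w)


def mr_presso(
    pairs: HarmonizedPairs | Iterable[HarmonizedPair],
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult | NotFeasible:
    """Simulation-based pleiotropy residual sum of squares and outlier test.

    The observed statistic sums, over instruments, the weighted squared
    residual of each instrument against the leave-one-out IVW fit.  The
    null distribution comes from ``n_sim`` parametric draws
    bx* ~ N(bx, sx), by* ~ N(θ̂₋ᵢ·bx, sy).  Per-SNP empirical p-values are
    Bonferroni-corrected by the instrument count before flagging; the
    corrected estimate is IVW on the unflagged subset.
    """
    if n_sim < MIN_PRESSO_SIM:
        raise EstimationError(
            f"n_sim must be >= {MIN_PRESSO_SIM} for a usable empirical p-value"
        )
    pair_list = _as_pairs(pairs)
    bx, sx, by, sy, rsids = _arrays(pair_list)
    n = len(bx)
    if n < MIN_PAIRS_PRESSO:
        return NotFeasible("mr_presso", f"requires >= {MIN_PAIRS_PRESSO} instruments", n)

    w = bx**2 / sy**2
    r = by / bx
    theta_loo = _loo_ivw(w, r)
    rss_i = w * (by - theta_loo * bx) ** 2
    rss_obs = float(np.sum(rss_i))

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_sim, n))
    by_star = rng.normal(theta_loo * bx, sy, size=(n_sim, n))
    bx_star = np.where(bx_star == 0, np.finfo(float).tiny, bx_star)
    w_star = bx_star**2 / sy**2
    r_star = by_star / bx_star
    theta_loo_star = _loo_ivw(w_star, r_star)
    rss_i_star = w_star * (by_star - theta_loo_star * bx_star) ** 2
    rss_star = np.sum(rss_i_star, axis=1)

    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))
    outlier_p_arr = (1 + np.sum(rss_i_star >= rss_i, axis=0)) / (n_sim + 1)
    outlier_p = dict(zip(rsids, outlier_p_arr.astype(float)))
    flagged = tuple(
        rsid for rsid, p in outlier_p.items() if p * n < outlier_alpha
    )

    keep = [p for p in pair_list if p.rsid not in flagged and p.bx != 0]
    corrected = ivw(keep) if keep else None

    distortion_p: float | None = None
    if flagged and corrected is not None:
        # informational distortion test: corrected-vs-full shift compared
        # with random removals of the same number of instruments
        full = ivw(pair_list)
        d_obs = abs(corrected.estimate - full.estimate)
        k = len(flagged)
        d_null = np.empty(n_sim)
        idx = np.arange(n)
        for b in range(n_sim):
            drop = rng.choice(idx, size=k, replace=False)
            mask = np.ones(n, dtype=bool)
            mask[drop] = False
            w_b = w[mask]
            r_b = r[mask]
            d_null[b] = abs(np.sum(w_b * r_b) / np.sum(w_b) - full.estimate)
        distortion_p = float((1 + np.sum(d_null >= d_obs)) / (n_sim + 1))

    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        outlier_p=outlier_p,
        outliers=flagged,
        corrected=corrected,
        distortion_p=distortion_p,
        n_sim=n_sim,
        seed=seed,
    )
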