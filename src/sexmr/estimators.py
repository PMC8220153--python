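"""Causal-effect estimators for two-sample Mendelian randomization.

The primary estimator is the inverse-variance weighted (IVW) combination of
per-instrument Wald ratios,

    theta_hat = sum_i w_i beta_y_i beta_x_i / sum_i w_i beta_x_i^2,
    var(theta_hat) = 1 / sum_i w_i beta_x_i^2,   w_i = se_y_i^{-2},

which for a single instrument reduces to the ratio beta_y / beta_x. A
multiplicative random-effects variant inflates the standard error by
max(1, sqrt(Q/(k-1))) where Q is the between-instrument heterogeneity
statistic. Sensitivity estimators: weighted median (bootstrap SE), joint
normal maximum likelihood, MR-Egger regression (pleiotropy intercept), an
RSS-based outlier test with a parametric null (MR-PRESSO style), and
leave-one-out re-estimation.

All p-values and confidence intervals use the two-sided normal convention
(theta -/+ 1.96 se).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from sexmr.sumstats import HarmonizedInstruments

logger = logging.getLogger(__name__)

Z975 = float(stats.norm.ppf(0.975))


class DegenerateInstrumentsError(ValueError):
    """Instruments carry no exposure signal (all beta_x zero)."""


class EstimationError(RuntimeError):
    """An iterative estimator failed to converge."""


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate with normal-theory uncertainty.

    ``theta`` is on the outcome scale per SD of exposure (log-odds for a
    binary outcome, hence ``odds_ratio = exp(theta)``). ``q_ivs`` is the
    between-instrument heterogeneity Q (df k-1), defined for k >= 2.
    """

    theta: float
    se: float
    pvalue: float
    method: str
    k: int
    q_ivs: float | None = None

    @property
    def var_theta(self) -> float:
        return self.se**2

    @property
    def ci_low(self) -> float:
        return self.theta - Z975 * self.se

    @property
    def ci_high(self) -> float:
        return self.theta + Z975 * self.se

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.theta))


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger regression: causal slope plus the pleiotropy intercept test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float

    @property
    def intercept_ci_low(self) -> float:
        return self.intercept - Z975 * self.intercept_se

    @property
    def intercept_ci_high(self) -> float:
        return self.intercept + Z975 * self.intercept_se


@dataclass(frozen=True)
class PressoResult:
    """Global RSS outlier test with a parametric simulated null."""

    global_rss: float
    global_pvalue: float
    outlier_pvalues: dict[str, float]
    outliers: list[str]
    n_sim: int


def _normal_p(z: float) -> float:
    return float(2 * stats.norm.sf(abs(z)))


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float, float]:
    """(theta, var_theta, q) for fixed-effects IVW with weights sy^-2."""
    w = sy**-2.0
    denom = float(np.sum(w * bx**2))
    if denom == 0:
        raise DegenerateInstrumentsError("all exposure effects are zero")
    theta = float(np.sum(w * by * bx)) / denom
    var_theta = 1.0 / denom
    q = float(np.sum(w * (by - theta * bx) ** 2))
    return theta, var_theta, q


def ivw_fixed(h: HarmonizedInstruments) -> MREstimate:
    """Fixed-effects inverse-variance weighted estimate."""
    bx, _, by, sy = h.arrays()
    theta, var_theta, q = _ivw_core(bx, by, sy)
    se = float(np.sqrt(var_theta))
    return MREstimate(
        theta=theta,
        se=se,
        pvalue=_normal_p(theta / se),
        method="ivw_fixed",
        k=h.k,
        q_ivs=q if h.k >= 2 else None,
    )


def ivw_random(h: HarmonizedInstruments) -> MREstimate:
    """Multiplicative random-effects IVW.

    The point estimate equals the fixed-effects one; the SE is inflated by
    max(1, sqrt(Q/(k-1))) to account for between-instrument heterogeneity.
    """
    if h.k < 2:
        raise ValueError("random-effects IVW requires k >= 2 instruments")
    fixed = ivw_fixed(h)
    assert fixed.q_ivs is not None
    inflation = max(1.0, float(np.sqrt(fixed.q_ivs / (h.k - 1))))
    if inflation > 1:
        logger.info("ivw_random: SE inflation factor %.3f (Q=%.3f, k=%d)", inflation, fixed.q_ivs, h.k)
    se = fixed.se * inflation
    return MREstimate(
        theta=fixed.theta,
        se=se,
        pvalue=_normal_p(fixed.theta / se),
        method="ivw_random",
        k=h.k,
        q_ivs=fixed.q_ivs,
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weight-interpolated 50th percentile of per-instrument ratios.

    Ratios are sorted; the cumulative normalized weight assigns each sorted
    ratio the midpoint coordinate (cum_i - w_i/2) / sum(w), and the estimate
    interpolates linearly where that coordinate crosses 0.5.
    """
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def weighted_median(
    h: HarmonizedInstruments, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of per-instrument Wald ratios.

    Per-instrument ratios r_i = beta_y_i / beta_x_i carry weights
    (beta_x_i / se_y_i)^2; the estimate is consistent when instruments
    contributing half the weight are valid. The SE comes from a seeded
    parametric bootstrap (instrument effects resampled from their normal
    sampling distributions).
    """
    if h.k < 3:
        raise ValueError("weighted median requires k >= 3 instruments")
    bx, sx, by, sy = h.arrays()
    zero = bx == 0
    if zero.any():
        bad = list(h.data.loc[zero, "snp"])
        raise DegenerateInstrumentsError(f"zero exposure effect, ratio undefined for: {bad}")
    ratios = by / bx
    weights = (bx / sy) ** 2
    theta = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        ok = bxb != 0
        boot[b] = _weighted_median_point(byb[ok] / bxb[ok], (bxb[ok] / sy[ok]) ** 2)
    se = float(boot.std(ddof=1))
    return MREstimate(
        theta=theta,
        se=se,
        pvalue=_normal_p(theta / se) if se > 0 else 1.0,
        method="weighted_median",
        k=h.k,
        q_ivs=None,
    )


def max_likelihood(
    h: HarmonizedInstruments, tol: float = 1e-10, max_iter: int = 500
) -> MREstimate:
    """Joint normal maximum-likelihood estimate of the causal effect.

    Model: beta_x_i ~ N(xi_i, se_x_i^2), beta_y_i ~ N(theta xi_i, se_y_i^2)
    with free instrument effects xi_i. The xi_i are profiled out in closed
    form, leaving a one-dimensional optimization in theta initialized at the
    fixed-effects IVW estimate; the SE comes from the observed information
    at the optimum (block inversion over the xi).
    """
    if h.k < 2:
        raise ValueError("maximum likelihood requires k >= 2 instruments")
    bx, sx, by, sy = h.arrays()
    vx, vy = sx**2, sy**2

    def profile_xi(theta: float) -> np.ndarray:
        return (bx / vx + theta * by / vy) / (1.0 / vx + theta**2 / vy)

    def nll(theta: float) -> float:
        xi = profile_xi(theta)
        return float(
            np.sum((bx - xi) ** 2 / (2 * vx) + (by - theta * xi) ** 2 / (2 * vy))
        )

    theta0 = ivw_fixed(h).theta
    res = optimize.minimize_scalar(
        nll,
        bracket=(theta0 - 1.0, theta0, theta0 + 1.0),
        method="brent",
        options={"xtol": tol, "maxiter": max_iter},
    )
    if not res.success:
        raise EstimationError(f"maximum-likelihood optimization failed: {res}")
    theta = float(res.x)

    # Observed information for theta after eliminating the xi block.
    xi = profile_xi(theta)
    h_tt = float(np.sum(xi**2 / vy))
    h_txi = (2 * theta * xi - by) / vy
    h_xixi = 1.0 / vx + theta**2 / vy
    info = h_tt - float(np.sum(h_txi**2 / h_xixi))
    if info <= 0:
        raise EstimationError("non-positive observed information at the ML optimum")
    se = float(1.0 / np.sqrt(info))
    return MREstimate(
        theta=theta,
        se=se,
        pvalue=_normal_p(theta / se),
        method="max_likelihood",
        k=h.k,
        q_ivs=None,
    )


def mr_egger(h: HarmonizedInstruments) -> EggerResult:
    """MR-Egger: weighted regression of outcome on exposure effects with intercept.

    Instruments are first re-signed so every exposure effect is
    non-negative (Egger regression is not orientation-invariant; this is
    the conventional orientation). Weights are se_y^-2. The slope is the
    causal estimate; a nonzero intercept indicates directional pleiotropy.
    """
    if h.k < 3:
        raise ValueError("MR-Egger requires k >= 3 instruments")
    bx, _, by, sy = h.arrays()
    sign = np.where(bx < 0, -1.0, 1.0)
    bx = bx * sign
    by = by * sign
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=sy**-2.0).fit()
    intercept, slope = map(float, fit.params)
    se_int, se_slope = map(float, fit.bse)
    slope_est = MREstimate(
        theta=slope,
        se=se_slope,
        pvalue=_normal_p(slope / se_slope) if se_slope > 0 else 1.0,
        method="mr_egger",
        k=h.k,
        q_ivs=None,
    )
    return EggerResult(
        slope=slope_est,
        intercept=intercept,
        intercept_se=se_int,
        intercept_pvalue=_normal_p(intercept / se_int) if se_int > 0 else 1.0,
    )


def _loo_thetas(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Vector of leave-one-out IVW estimates (i-th excludes instrument i)."""
    w = sy**-2.0
    s_num = np.sum(w * by * bx)
    s_den = np.sum(w * bx**2)
    return (s_num - w * by * bx) / (s_den - w * bx**2)


def mr_presso(
    h: HarmonizedInstruments,
    n_sim: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """RSS-based global and per-instrument outlier test (MR-PRESSO style).

    The observed residual of instrument i uses the leave-one-out IVW
    estimate: r_i = beta_y_i - theta_hat_{-i} beta_x_i, with global RSS the
    sum of r_i^2. The null distribution is simulated parametrically:
    beta_y*_i ~ N(theta_hat_{-i} beta_x_i, se_y_i^2) with the leave-one-out
    estimates recomputed on each simulated dataset. P-values use the
    add-one empirical estimator (count + 1)/(n_sim + 1); per-instrument
    p-values are Bonferroni-adjusted before flagging at ``alpha``.
    """
    if h.k < 4:
        raise ValueError("the outlier test requires k >= 4 instruments")
    if n_sim < 100:
        logger.warning("mr_presso: n_sim=%d is small; p-values will be coarse", n_sim)
    bx, _, by, sy = h.arrays()
    k = h.k
    loo = _loo_thetas(bx, by, sy)
    resid2 = (by - loo * bx) ** 2
    global_rss = float(np.sum(resid2))

    rng = np.random.default_rng(seed)
    by_sim = rng.normal(loo * bx, sy, size=(n_sim, k))
    w = sy**-2.0
    s_num = np.sum(w * by_sim * bx, axis=1, keepdims=True)
    s_den = float(np.sum(w * bx**2))
    loo_sim = (s_num - w * by_sim * bx) / (s_den - w * bx**2)
    resid2_sim = (by_sim - loo_sim * bx) ** 2
    rss_sim = resid2_sim.sum(axis=1)

    global_pvalue = float((np.sum(rss_sim >= global_rss) + 1) / (n_sim + 1))
    per_iv_p = (np.sum(resid2_sim >= resid2, axis=0) + 1) / (n_sim + 1)
    per_iv_p_adj = np.minimum(1.0, per_iv_p * k)
    snps = list(h.data["snp"])
    outlier_pvalues = dict(zip(snps, map(float, per_iv_p_adj)))
    outliers = [s for s, p in outlier_pvalues.items() if p < alpha]
    return PressoResult(
        global_rss=global_rss,
        global_pvalue=global_pvalue,
        outlier_pvalues=outlier_pvalues,
        outliers=outliers,
        n_sim=n_sim,
    )


ESTIMATORS: dict[str, Callable[[HarmonizedInstruments], MREstimate]] = {
    "ivw_fixed": ivw_fixed,
    "ivw_random": ivw_random,
    "weighted_median": weighted_median,
    "max_likelihood": max_likelihood,
}


def loo_estimates(
    h: HarmonizedInstruments,
    estimator: str | Callable[[HarmonizedInstruments], MREstimate] = "ivw_fixed",
) -> list[tuple[str, MREstimate]]:
    """Leave-one-out re-estimation: one estimate per excluded instrument."""
    if h.k < 2:
        raise ValueError("leave-one-out requires k >= 2 instruments")
    fn = ESTIMATORS[estimator] if isinstance(estimator, str) else estimator
    out = []
    for snp in h.data["snp"]:
        try:
            out.append((snp, fn(h.drop(snp))))
        except Exception as exc:  # annotate with the excluded SNP
            raise EstimationError(f"leave-one-out failed excluding {snp}: {exc}") from exc
    return out
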