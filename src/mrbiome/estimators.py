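"""Causal-effect estimators operating on harmonized SNP pairs.

Six methods: the single-SNP Wald ratio; multiplicative random-effects
inverse-variance-weighted (IVW) regression through the origin (the primary
estimator); MR-Egger regression with an intercept capturing directional
pleiotropy; the weighted median, consistent when up to half the instrument
weight is invalid; and simple/weighted mode estimators built on a kernel
density of the per-SNP Wald ratios.

All causal estimates live on the log-odds scale for disease outcomes, so
``exp(beta)`` is an odds ratio; confidence intervals use the 1.959964
normal multiplier throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import InsufficientInstrumentsError, UndefinedRatioError
from .instruments import HarmonizedPair

Z95 = 1.959964

METHODS = (
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "simple_mode",
    "weighted_mode",
)


@dataclass
class MREstimate:
    """One method's causal estimate for one exposure-outcome pair."""

    method: str
    nsnp: int
    beta: float
    se: float
    pvalue: float
    extra: dict = field(default_factory=dict)

    @property
    def or_value(self) -> float:
        return math.exp(self.beta)

    @property
    def ci95(self) -> tuple[float, float]:
        return (math.exp(self.beta - Z95 * self.se), math.exp(self.beta + Z95 * self.se))


def _arrays(pairs: list[HarmonizedPair]):
    bx = np.array([p.beta_exposure for p in pairs])
    sx = np.array([p.se_exposure for p in pairs])
    by = np.array([p.beta_outcome for p in pairs])
    sy = np.array([p.se_outcome for p in pairs])
    return bx, sx, by, sy


def _ratios(pairs: list[HarmonizedPair]):
    """Per-SNP Wald ratios and their first-order delta-method SEs."""
    bx, _, by, sy = _arrays(pairs)
    if np.any(bx == 0):
        raise UndefinedRatioError("Wald ratio undefined for beta_exposure = 0")
    return by / bx, sy / np.abs(bx)


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Single-SNP causal estimate: outcome effect over exposure effect."""
    if pair.beta_exposure == 0:
        raise UndefinedRatioError(f"{pair.snp_id}: beta_exposure is 0")
    beta = pair.beta_outcome / pair.beta_exposure
    se = pair.se_outcome / abs(pair.beta_exposure)
    p = 2.0 * stats.norm.sf(abs(beta / se))
    return MREstimate("wald_ratio", 1, float(beta), float(se), float(p))


def ivw(pairs: list[HarmonizedPair]) -> MREstimate:
    """Multiplicative random-effects IVW regression through the origin.

    Weighted least squares of outcome on exposure betas with weights
    ``1/se_outcome^2``; the slope SE is inflated by the residual standard
    error when it exceeds 1 (never deflated below the fixed-effect SE).
    The p-value is two-sided normal.
    """
    if len(pairs) < 2:
        raise InsufficientInstrumentsError("IVW requires at least 2 SNPs")
    bx, _, by, sy = _arrays(pairs)
    w = 1.0 / sy**2
    sxx = np.sum(w * bx * bx)
    beta = np.sum(w * bx * by) / sxx
    resid = by - beta * bx
    scale2 = np.sum(w * resid**2) / (len(pairs) - 1)
    se = math.sqrt(1.0 / sxx) * max(1.0, math.sqrt(scale2))
    p = 2.0 * stats.norm.sf(abs(beta / se))
    return MREstimate(
        "ivw", len(pairs), float(beta), float(se), float(p),
        extra={"residual_scale": float(max(1.0, math.sqrt(scale2)))},
    )


def mr_egger(pairs: list[HarmonizedPair]) -> MREstimate:
    """MR-Egger: weighted regression with an intercept for pleiotropy.

    Pairs are oriented so every exposure beta is non-negative before the
    fit (the intercept is orientation-dependent); both coefficient SEs are
    inflated by the residual standard error floored at 1, and p-values use
    a t distribution with nsnp - 2 degrees of freedom. The intercept and
    its test live in ``extra``.
    """
    n = len(pairs)
    if n < 3:
        raise InsufficientInstrumentsError("MR-Egger requires at least 3 SNPs")
    bx, _, by, sy = _arrays(pairs)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2

    X = np.column_stack([np.ones(n), bx])
    WX = X * w[:, None]
    xtx = X.T @ WX
    coef = np.linalg.solve(xtx, WX.T @ by)
    resid = by - X @ coef
    scale2 = np.sum(w * resid**2) / (n - 2)
    cov = np.linalg.inv(xtx) * max(1.0, scale2)
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    intercept, slope = coef
    df = n - 2
    p_slope = 2.0 * stats.t.sf(abs(slope / se_slope), df)
    p_int = 2.0 * stats.t.sf(abs(intercept / se_int), df)
    return MREstimate(
        "mr_egger", n, float(slope), float(se_slope), float(p_slope),
        extra={
            "intercept": float(intercept),
            "intercept_se": float(se_int),
            "intercept_p": float(p_int),
            "residual_scale": float(max(1.0, math.sqrt(scale2))),
        },
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - 0.5 * w  # standardized mid-cumulative weight
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] < 0.5:
        return float(r[-1])
    below = int(np.max(np.nonzero(s < 0.5)[0]))
    return float(
        r[below] + (r[below + 1] - r[below]) * (0.5 - s[below]) / (s[below + 1] - s[below])
    )


def weighted_median(
    pairs: list[HarmonizedPair], n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Inverse-variance-weighted median of the per-SNP Wald ratios.

    The point estimate interpolates where the standardized cumulative
    weight crosses one half; the SE comes from a seeded parametric
    bootstrap resampling each ratio from its normal sampling distribution.
    """
    if len(pairs) < 3:
        raise InsufficientInstrumentsError("weighted median requires at least 3 SNPs")
    ratios, ratio_se = _ratios(pairs)
    weights = 1.0 / ratio_se**2
    beta = _weighted_median_point(ratios, weights)
    rng = np.random.default_rng(seed)
    draws = rng.normal(ratios, ratio_se, size=(n_boot, len(pairs)))
    boot = np.array([_weighted_median_point(d, weights) for d in draws])
    se = float(np.std(boot, ddof=1))
    p = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else float(beta == 0)
    return MREstimate("weighted_median", len(pairs), float(beta), se, float(p))


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float) -> float:
    """Argmax of a weighted normal-kernel density; ties break low."""
    w = weights / np.sum(weights)
    mad = np.median(np.abs(ratios - np.median(ratios))) * 1.4826
    spread = min(np.std(ratios, ddof=1) if len(ratios) > 1 else 0.0, mad)
    h = bandwidth_factor * 0.9 * spread / len(ratios) ** 0.2
    if h <= 0:  # degenerate: all ratios (or more than half) identical
        vals, idx = np.unique(ratios, return_inverse=True)
        mass = np.bincount(idx, weights=w)
        return float(vals[int(np.argmax(mass))])
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 1024)
    dens = np.sum(w[:, None] * stats.norm.pdf(grid[None, :], ratios[:, None], h), axis=0)
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    pairs: list[HarmonizedPair],
    weighted: bool = True,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode-based estimate: peak of the Wald-ratio kernel density.

    The bandwidth is ``bandwidth_factor`` times a modified Silverman scale
    built on the median absolute deviation of the ratios. The weighted
    variant weights the density by normalized inverse-variance weights;
    the simple variant uses equal weights. SE by parametric bootstrap.
    """
    if len(pairs) < 3:
        raise InsufficientInstrumentsError("mode estimators require at least 3 SNPs")
    ratios, ratio_se = _ratios(pairs)
    weights = 1.0 / ratio_se**2 if weighted else np.ones_like(ratios)
    beta = _kde_mode(ratios, weights, bandwidth_factor)
    rng = np.random.default_rng(seed)
    draws = rng.normal(ratios, ratio_se, size=(n_boot, len(pairs)))
    boot = np.array([_kde_mode(d, weights, bandwidth_factor) for d in draws])
    se = float(np.std(boot, ddof=1))
    p = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else float(beta == 0)
    method = "weighted_mode" if weighted else "simple_mode"
    return MREstimate(method, len(pairs), float(beta), se, float(p))


@dataclass
class EstimatorConfig:
    """Bootstrap and bandwidth settings shared by median/mode estimators."""

    n_boot: int = 1000
    bandwidth_factor: float = 1.0
    seed: int = 0


def run_all_methods(
    pairs: list[HarmonizedPair], config: EstimatorConfig | None = None
) -> list[MREstimate]:
    """Dispatch on instrument count.

    One SNP gives the Wald ratio alone; two give IVW alone; three or more
    give all five methods, with IVW flagged primary in ``extra``.
    """
    if not pairs:
        raise InsufficientInstrumentsError("no harmonized pairs supplied")
    cfg = config or EstimatorConfig()
    if len(pairs) == 1:
        return [wald_ratio(pairs[0])]
    if len(pairs) == 2:
        est = ivw(pairs)
        est.extra["primary"] = True
        return [est]
    est_ivw = ivw(pairs)
    est_ivw.extra["primary"] = True
    return [
        est_ivw,
        mr_egger(pairs),
        weighted_median(pairs, cfg.n_boot, cfg.seed),
        mode_estimate(pairs, False, cfg.bandwidth_factor, cfg.n_boot, cfg.seed),
        mode_estimate(pairs, True, cfg.bandwidth_factor, cfg.n_boot, cfg.seed),
    ]
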