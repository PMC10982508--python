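"""Sensitivity suite: Cochran's Q, Egger intercept, MR-PRESSO, leave-one-out.

Each diagnostic answers a different failure mode of the instrumental
assumptions: Q measures heterogeneity of per-SNP effects around the fitted
model; the MR-Egger intercept tests directional pleiotropy; MR-PRESSO
detects pleiotropy globally through a simulated residual-sum-of-squares
null, flags individual outlier SNPs, and tests whether removing them
distorts the estimate; leave-one-out detects single-variant dominance.

Diagnostics that need more SNPs than are available are reported as
explicitly not-evaluable (``None`` fields / ``"NA"`` verdicts), never as
silently passing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import MREstimate, Z95, ivw, mr_egger
from .exceptions import InsufficientInstrumentsError
from .instruments import HarmonizedPair


@dataclass
class QResult:
    q: float
    df: int
    pvalue: float


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    outliers: list[str]
    distortion_p: float | None
    corrected: MREstimate | None
    n_sim: int


@dataclass
class LooEntry:
    left_out: str
    beta: float
    se: float
    ci_low: float  # log scale
    ci_high: float


@dataclass
class SensitivityReport:
    """All diagnostics for one exposure-outcome pair.

    Verdicts use ``True`` (problem detected), ``False`` (clean) or
    ``"NA"`` (not evaluable with this instrument count).
    """

    q_ivw: QResult | None
    q_egger: QResult | None
    egger_intercept: tuple[float, float, float] | None  # value, se, p
    presso: PressoResult | None
    loo: list[LooEntry] | None
    verdicts: dict = field(default_factory=dict)


def _arrays(pairs):
    bx = np.array([p.beta_exposure for p in pairs])
    by = np.array([p.beta_outcome for p in pairs])
    sy = np.array([p.se_outcome for p in pairs])
    return bx, by, sy


def cochran_q(pairs: list[HarmonizedPair], model: str = "ivw") -> QResult:
    """Weighted heterogeneity statistic around the fixed-effect fit.

    ``Q = sum_j w_j (beta_outcome_j - fitted_j)^2`` with ``w = 1/se_out^2``
    and fitted values from the fixed-effect IVW slope (df = nsnp - 1) or
    the MR-Egger line (df = nsnp - 2); p is the upper chi-square tail.
    """
    n = len(pairs)
    if model == "ivw":
        if n < 2:
            raise InsufficientInstrumentsError("Q (IVW) requires at least 2 SNPs")
        bx, by, sy = _arrays(pairs)
        w = 1.0 / sy**2
        slope = np.sum(w * bx * by) / np.sum(w * bx * bx)
        fitted = slope * bx
        df = n - 1
    elif model == "egger":
        if n < 3:
            raise InsufficientInstrumentsError("Q (Egger) requires at least 3 SNPs")
        est = mr_egger(pairs)
        bx, by, sy = _arrays(pairs)
        flip = np.sign(bx)
        flip[flip == 0] = 1.0
        bx, by = bx * flip, by * flip
        w = 1.0 / sy**2
        fitted = est.extra["intercept"] + est.beta * bx
        df = n - 2
    else:
        raise ValueError(f"unknown model {model!r}")
    q = float(np.sum(w * (by - fitted) ** 2))
    return QResult(q, df, float(stats.chi2.sf(q, df)))


def egger_intercept_test(pairs: list[HarmonizedPair]) -> tuple[float, float, float]:
    """MR-Egger intercept with its t-test (df nsnp - 2).

    A small p indicates directional horizontal pleiotropy.
    """
    est = mr_egger(pairs)
    return est.extra["intercept"], est.extra["intercept_se"], est.extra["intercept_p"]


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Fixed-effect IVW slope with each SNP left out, vectorized."""
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx * bx)
    return (s_xy - w * bx * by) / (s_xx - w * bx * bx)


def mr_presso(
    pairs: list[HarmonizedPair],
    n_sim: int = 1000,
    seed: int = 0,
    sig: float = 0.05,
) -> PressoResult:
    """Simulation-based pleiotropy residual sum of squares and outlier test.

    The observed RSS sums, over SNPs, the squared deviation of each
    outcome beta from its prediction under the leave-one-out IVW slope.
    The null distribution comes from ``n_sim`` parametric simulations of
    outcome betas around the full-set fixed-effect fit (the no-pleiotropy
    model) at their reported standard errors, with the leave-one-out RSS
    recomputed within each simulated dataset; the global p uses an
    add-one numerator so it is never exactly zero. Per-SNP outliers are flagged by comparing observed to simulated
    squared residuals at the Bonferroni level ``sig/nsnp``; the distortion
    test compares the outlier-corrected IVW estimate against the
    distribution of estimates after removing equally many random SNPs.

    Results are invariant to the order of the input pairs (pairs are
    sorted internally by snp_id before any random draw).
    """
    if len(pairs) < 4:
        raise InsufficientInstrumentsError("MR-PRESSO requires at least 4 SNPs")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    pairs = sorted(pairs, key=lambda p: p.snp_id)
    n = len(pairs)
    bx, by, sy = _arrays(pairs)
    w = 1.0 / sy**2

    loo = _loo_slopes(bx, by, w)
    pred = loo * bx
    obs_res2 = (by - pred) ** 2
    obs_rss = float(np.sum(obs_res2))

    full_slope = np.sum(w * bx * by) / np.sum(w * bx * bx)
    rng = np.random.default_rng(seed)
    sim_by = (full_slope * bx)[None, :] + rng.normal(0.0, 1.0, size=(n_sim, n)) * sy[None, :]
    # recompute LOO predictions within each simulated dataset
    s_xy = np.sum(w * bx * sim_by, axis=1, keepdims=True)
    s_xx = np.sum(w * bx * bx)
    sim_loo = (s_xy - w * bx * sim_by) / (s_xx - w * bx * bx)
    sim_res2 = (sim_by - sim_loo * bx) ** 2
    sim_rss = np.sum(sim_res2, axis=1)

    global_p = float((np.sum(sim_rss >= obs_rss) + 1) / (n_sim + 1))

    # per-SNP empirical p without the add-one: it must be able to undercut
    # the Bonferroni threshold sig/nsnp even when nsnp is large
    per_snp_p = np.sum(sim_res2 >= obs_res2[None, :], axis=0) / n_sim
    outlier_mask = per_snp_p < sig / n
    outliers = [pairs[j].snp_id for j in np.nonzero(outlier_mask)[0]]

    distortion_p = None
    corrected = None
    if outliers and n - len(outliers) >= 2:
        keep = [p for p, o in zip(pairs, outlier_mask) if not o]
        corrected = ivw(keep)
        full = ivw(list(pairs))
        obs_shift = abs(corrected.beta - full.beta)
        n_out = len(outliers)
        n_perm = min(n_sim, 500)
        shifts = np.empty(n_perm)
        for k in range(n_perm):
            drop = rng.choice(n, size=n_out, replace=False)
            mask = np.ones(n, bool)
            mask[drop] = False
            slope = np.sum(w[mask] * bx[mask] * by[mask]) / np.sum(
                w[mask] * bx[mask] * bx[mask]
            )
            shifts[k] = abs(slope - full.beta)
        distortion_p = float((np.sum(shifts >= obs_shift) + 1) / (n_perm + 1))

    return PressoResult(obs_rss, global_p, outliers, distortion_p, corrected, n_sim)


def leave_one_out(pairs: list[HarmonizedPair]) -> list[LooEntry]:
    """Random-effects IVW re-estimated with each SNP removed in turn."""
    if len(pairs) < 3:
        raise InsufficientInstrumentsError("leave-one-out requires at least 3 SNPs")
    entries = []
    for j, left in enumerate(pairs):
        est = ivw([p for k, p in enumerate(pairs) if k != j])
        entries.append(
            LooEntry(
                left_out=left.snp_id,
                beta=est.beta,
                se=est.se,
                ci_low=est.beta - Z95 * est.se,
                ci_high=est.beta + Z95 * est.se,
            )
        )
    return entries


def sensitivity_suite(
    pairs: list[HarmonizedPair],
    n_sim: int = 1000,
    seed: int = 0,
    sig: float = 0.05,
) -> SensitivityReport:
    """Run every diagnostic the instrument count allows.

    The heterogeneity verdict is true when either Q test rejects at 0.05;
    the pleiotropy verdict when the Egger intercept or the PRESSO global
    test rejects; the leave-one-out instability verdict when any left-out
    CI lies entirely on the opposite sign of the full-set estimate.
    """
    n = len(pairs)
    q_i = cochran_q(pairs, "ivw") if n >= 2 else None
    q_e = cochran_q(pairs, "egger") if n >= 3 else None
    intercept = egger_intercept_test(pairs) if n >= 3 else None
    presso = mr_presso(pairs, n_sim, seed, sig) if n >= 4 else None
    loo = leave_one_out(pairs) if n >= 3 else None

    verdicts: dict = {}
    if q_i is None and q_e is None:
        verdicts["heterogeneity"] = "NA"
    else:
        verdicts["heterogeneity"] = any(
            q is not None and q.pvalue < 0.05 for q in (q_i, q_e)
        )
    if intercept is None and presso is None:
        verdicts["pleiotropy"] = "NA"
    else:
        flag = False
        if intercept is not None and intercept[2] < 0.05:
            flag = True
        if presso is not None and presso.global_p < 0.05:
            flag = True
        verdicts["pleiotropy"] = flag
    if loo is None:
        verdicts["loo_instability"] = "NA"
    else:
        full = ivw(pairs)
        sign = math.copysign(1.0, full.beta)
        verdicts["loo_instability"] = any(
            (sign > 0 and e.ci_high < 0) or (sign < 0 and e.ci_low > 0) for e in loo
        )
    return SensitivityReport(q_i, q_e, intercept, presso, loo, verdicts)
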