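"""Bidirectional screening pipeline: forward MR, FDR tiers, reverse MR.

The forward screen runs every exposure taxon against a disease outcome
through instrument selection, the five estimators and the sensitivity
suite, removes MR-PRESSO outliers once and re-estimates, then applies
Benjamini-Hochberg FDR within (outcome x taxonomic rank) families and
tiers each pair as significant (p < 0.05 and p_FDR < 0.05), suggestive
(p < 0.05 but p_FDR >= 0.05) or null. Pairs whose IVW and MR-Egger
estimates point in opposite directions, or with pleiotropy persisting
after outlier removal, are excluded with an explicit reason. The reverse
screen re-runs the same machinery with the disease as exposure under
per-disease instrument p-value thresholds.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .estimators import EstimatorConfig, MREstimate, Z95, run_all_methods
from .exceptions import ConfigurationError, ValidationError
from .gwas_io import LDMatrix, SummaryDataset
from .instruments import InstrumentSet, Thresholds, build_instrument_set
from .sensitivity import SensitivityReport, sensitivity_suite

#: taxon census of the 16S exposure GWAS this screen is modelled on:
#: 196 analyzable taxa (of 211, 15 unclassified ones dropped) split by rank.
MIBIOGEN_RANK_SIZES = {"genus": 119, "family": 32, "order": 20, "class": 16, "phylum": 9}

TIERS = ("significant", "suggestive", "null", "excluded")


@dataclass
class ScreenConfig:
    """Thresholds and seeds for one screening run."""

    thresholds: Thresholds = field(default_factory=Thresholds)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    presso_n_sim: int = 1000
    seed: int = 0
    #: family size per taxonomic rank for BH adjustment; None means use the
    #: number of taxa actually tested at that rank
    rank_sizes: dict | None = None


@dataclass
class ReverseThresholdPolicy:
    """Per-disease instrument p-value thresholds for the reverse screen.

    Diseases with too few genome-wide significant hits get a relaxed
    threshold; everything else uses the conventional 5e-8.
    """

    default: float = 5e-8
    overrides: dict = field(
        default_factory=lambda: {
            "rosacea": 5e-7,
            "seborrheic dermatitis": 5e-7,
            "hidradenitis suppurativa": 5e-6,
        }
    )

    def resolve(self, disease_label: str) -> float:
        key = disease_label.strip().lower().replace("_", " ")
        for name, thr in self.overrides.items():
            if name in key:
                return thr
        return self.default


@dataclass
class PairResult:
    """Everything the screen knows about one exposure-outcome pair."""

    exposure_label: str
    taxon_rank: str | None
    outcome_label: str
    instruments: InstrumentSet | None
    estimates: list[MREstimate] = field(default_factory=list)
    sensitivity: SensitivityReport | None = None
    outliers_removed: list[str] = field(default_factory=list)
    p_fdr: float | None = None
    tier: str | None = None
    exclusion_reason: str | None = None

    @property
    def primary(self) -> MREstimate | None:
        """The headline estimate: IVW when available, else the Wald ratio."""
        for est in self.estimates:
            if est.extra.get("primary") or est.method == "wald_ratio":
                return est
        return None


@dataclass
class FdrFamily:
    """One multiple-testing family: an outcome at one taxonomic rank."""

    outcome_label: str
    taxon_rank: str | None
    pvalues: list[float]
    m: int

    def __post_init__(self) -> None:
        if self.m < len(self.pvalues):
            raise ValidationError(
                f"family size m={self.m} smaller than member count {len(self.pvalues)}"
            )


def bh_adjust(pvalues: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` is the family size; members absent from ``pvalues`` (tests never
    run) count as p = 1, so ``m`` may exceed ``len(pvalues)``. Adjusted
    values are ``min_{j>=k} p_(j) * m / j`` capped at 1, returned in the
    original order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    k = p.size
    if m is None:
        m = k
    if m < k:
        raise ValidationError(f"family size m={m} smaller than member count {k}")
    if k == 0:
        return np.array([])
    # pad with p=1 for never-run members: they occupy the top ranks and
    # never lower the running minimum, so only ranks 1..k matter
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    # padded entries would contribute 1 * m / j >= 1 at ranks k+1..m
    tail_min = 1.0
    adjusted_sorted = np.minimum.accumulate(np.concatenate([[tail_min], ranked[::-1]]))[1:][::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(k)
    out[order] = adjusted_sorted
    return out


def adjust_family(family: FdrFamily) -> np.ndarray:
    return bh_adjust(family.pvalues, family.m)


def classify_tier(ivw_p: float, p_fdr: float) -> str:
    """Tier a pair by its raw and FDR-adjusted primary p-value."""
    if not (0 <= ivw_p <= 1 and 0 <= p_fdr <= 1):
        raise ValidationError("p-values must lie in [0, 1]")
    if ivw_p < 0.05 and p_fdr < 0.05:
        return "significant"
    if ivw_p < 0.05:
        return "suggestive"
    return "null"


def apply_exclusion_rules(result: PairResult) -> PairResult:
    """Demote untrustworthy hits to the excluded tier.

    A pair that would be reported (significant or suggestive) is excluded
    when IVW and MR-Egger disagree on the direction of effect, or when
    pleiotropy (Egger intercept p < 0.05 or PRESSO global p < 0.05)
    persists after the single outlier-removal rerun.
    """
    if result.tier in (None, "excluded") or not result.estimates:
        return result
    sens = result.sensitivity
    pleio = False
    if sens is not None:
        if sens.egger_intercept is not None and sens.egger_intercept[2] < 0.05:
            pleio = True
        if sens.presso is not None and sens.presso.global_p < 0.05:
            pleio = True
    if pleio:
        result.tier = "excluded"
        result.exclusion_reason = "pleiotropy"
        return result
    if result.tier in ("significant", "suggestive"):
        ivw_est = next((e for e in result.estimates if e.method == "ivw"), None)
        egger_est = next((e for e in result.estimates if e.method == "mr_egger"), None)
        if ivw_est is not None and egger_est is not None:
            if math.copysign(1, ivw_est.beta) != math.copysign(1, egger_est.beta):
                result.tier = "excluded"
                result.exclusion_reason = "direction-discordance"
    return result


def _analyze_pair(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LDMatrix,
    config: ScreenConfig,
    thresholds: Thresholds,
) -> PairResult:
    """Instrument selection, estimation, sensitivity, one outlier rerun."""
    iset = build_instrument_set(exposure, outcome, ld, thresholds)
    result = PairResult(
        exposure_label=exposure.trait_label,
        taxon_rank=exposure.taxon_rank,
        outcome_label=outcome.trait_label,
        instruments=iset,
    )
    if iset.empty:
        result.tier = "excluded"
        result.exclusion_reason = "no-instruments"
        return result
    pairs = iset.pairs
    result.estimates = run_all_methods(pairs, config.estimator)
    if iset.nsnp >= 2:
        result.sensitivity = sensitivity_suite(
            pairs, config.presso_n_sim, config.seed
        )
        presso = result.sensitivity.presso
        if presso is not None and presso.outliers:
            keep = [p for p in pairs if p.snp_id not in set(presso.outliers)]
            if len(keep) >= 1:
                result.outliers_removed = list(presso.outliers)
                iset.pairs = keep
                result.estimates = run_all_methods(keep, config.estimator)
                if len(keep) >= 2:
                    result.sensitivity = sensitivity_suite(
                        keep, config.presso_n_sim, config.seed
                    )
    return result


def _assign_fdr(results: list[PairResult], config: ScreenConfig) -> None:
    """BH-adjust primary p-values within (outcome x rank) families."""
    groups: dict[tuple, list[PairResult]] = {}
    for r in results:
        if r.tier == "excluded" or r.primary is None:
            continue
        groups.setdefault((r.outcome_label, r.taxon_rank), []).append(r)
    for (outcome, rank), members in groups.items():
        m = len(members)
        if config.rank_sizes and rank in config.rank_sizes:
            m = max(m, config.rank_sizes[rank])
        family = FdrFamily(outcome, rank, [r.primary.pvalue for r in members], m)
        adjusted = adjust_family(family)
        for r, padj in zip(members, adjusted):
            r.p_fdr = float(padj)
            r.tier = classify_tier(r.primary.pvalue, padj)
            apply_exclusion_rules(r)


def run_forward_screen(
    exposures: list[SummaryDataset],
    outcome: SummaryDataset,
    ld: LDMatrix,
    config: ScreenConfig | None = None,
) -> list[PairResult]:
    """Screen every exposure taxon against one disease outcome."""
    if not exposures:
        raise ConfigurationError("no exposure datasets supplied")
    config = config or ScreenConfig()
    results = [
        _analyze_pair(exp, outcome, ld, config, config.thresholds) for exp in exposures
    ]
    _assign_fdr(results, config)
    return results


def run_reverse(
    disease: SummaryDataset,
    taxa: list[SummaryDataset],
    ld: LDMatrix,
    policy: ReverseThresholdPolicy | None = None,
    config: ScreenConfig | None = None,
) -> list[PairResult]:
    """Reverse screen: the disease as exposure, taxa as outcomes.

    The instrument p-value threshold comes from the per-disease policy
    (genome-wide 5e-8 by default); single-SNP instrument sets fall back to
    the Wald ratio inside the estimator dispatch.
    """
    if not taxa:
        raise ConfigurationError("no taxon datasets supplied")
    config = config or ScreenConfig()
    policy = policy or ReverseThresholdPolicy()
    th = Thresholds(
        exposure_p=policy.resolve(disease.trait_label),
        outcome_p=config.thresholds.outcome_p,
        clump_r2=config.thresholds.clump_r2,
        clump_window_kb=config.thresholds.clump_window_kb,
        f_min=config.thresholds.f_min,
    )
    results = [_analyze_pair(disease, taxon, ld, config, th) for taxon in taxa]
    # reverse FDR family: all taxa tested against this disease
    members = [r for r in results if r.tier != "excluded" and r.primary is not None]
    if members:
        adjusted = bh_adjust([r.primary.pvalue for r in members], len(members))
        for r, padj in zip(members, adjusted):
            r.p_fdr = float(padj)
            r.tier = classify_tier(r.primary.pvalue, padj)
            apply_exclusion_rules(r)
    return results


def significance_from_estimate(
    or_value: float, ci95: tuple[float, float]
) -> tuple[float, float, float]:
    """Recover (se_log, z, p) from a printed odds ratio and 95% CI.

    ``se_log = (ln hi - ln lo) / (2 * 1.959964)``; the two-sided normal
    p-value follows from ``z = ln(OR) / se_log``. Useful for consistency
    checks of reported tables.
    """
    lo, hi = ci95
    if not (0 < lo < or_value < hi):
        raise ValidationError(f"CI ordering violated: {lo} < {or_value} < {hi} required")
    se_log = (math.log(hi) - math.log(lo)) / (2.0 * Z95)
    z = math.log(or_value) / se_log
    p = 2.0 * stats.norm.sf(abs(z))
    return se_log, z, p


def _estimates_frame(results: list[PairResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for est in r.estimates:
            lo, hi = est.ci95
            rows.append(
                {
                    "exposure": r.exposure_label,
                    "taxon_rank": r.taxon_rank or "",
                    "outcome": r.outcome_label,
                    "method": est.method,
                    "nsnp": est.nsnp,
                    "beta": est.beta,
                    "se": est.se,
                    "or": est.or_value,
                    "ci_low": lo,
                    "ci_high": hi,
                    "pvalue": est.pvalue,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "exposure", "taxon_rank", "outcome", "method", "nsnp",
            "beta", "se", "or", "ci_low", "ci_high", "pvalue",
        ],
    )


def _sensitivity_frame(results: list[PairResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        s = r.sensitivity
        row = {
            "exposure": r.exposure_label,
            "outcome": r.outcome_label,
            "q_ivw": s.q_ivw.q if s and s.q_ivw else None,
            "q_ivw_p": s.q_ivw.pvalue if s and s.q_ivw else None,
            "q_egger": s.q_egger.q if s and s.q_egger else None,
            "q_egger_p": s.q_egger.pvalue if s and s.q_egger else None,
            "egger_intercept": s.egger_intercept[0] if s and s.egger_intercept else None,
            "egger_intercept_p": s.egger_intercept[2] if s and s.egger_intercept else None,
            "presso_global_p": s.presso.global_p if s and s.presso else None,
            "presso_outliers": ",".join(s.presso.outliers) if s and s.presso else "",
            "heterogeneity": str(s.verdicts.get("heterogeneity")) if s else "NA",
            "pleiotropy": str(s.verdicts.get("pleiotropy")) if s else "NA",
            "loo_instability": str(s.verdicts.get("loo_instability")) if s else "NA",
        }
        rows.append(row)
    return pd.DataFrame(rows)


def _tiers_frame(results: list[PairResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "exposure": r.exposure_label,
                "taxon_rank": r.taxon_rank or "",
                "outcome": r.outcome_label,
                "nsnp": r.instruments.nsnp if r.instruments else 0,
                "ivw_p": r.primary.pvalue if r.primary else None,
                "p_fdr": r.p_fdr,
                "tier": r.tier,
                "exclusion_reason": r.exclusion_reason or "",
                "outliers_removed": ",".join(r.outliers_removed),
            }
        )
    return pd.DataFrame(rows)


def _audit_frame(results: list[PairResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        if r.instruments is None:
            continue
        for stage, count in r.instruments.audit.items():
            rows.append(
                {
                    "exposure": r.exposure_label,
                    "outcome": r.outcome_label,
                    "stage": stage,
                    "count": count,
                }
            )
    return pd.DataFrame(rows)


def _loo_frame(results: list[PairResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        if r.sensitivity is None or r.sensitivity.loo is None:
            continue
        for e in r.sensitivity.loo:
            rows.append(
                {
                    "exposure": r.exposure_label,
                    "outcome": r.outcome_label,
                    "left_out": e.left_out,
                    "beta": e.beta,
                    "se": e.se,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                }
            )
    return pd.DataFrame(rows)


def export_report(
    results: list[PairResult], out_dir, config: ScreenConfig | None = None
) -> dict[str, str]:
    """Write the tab-delimited result tables plus a run manifest.

    Emits ``estimates.tsv``, ``sensitivity.tsv``, ``tiers.tsv``,
    ``audit.tsv``, ``loo.tsv`` and ``manifest.json``; reruns with the same
    inputs and seeds produce byte-identical tables.
    """
    if not results:
        raise ValidationError("no results to export")
    os.makedirs(out_dir, exist_ok=True)
    frames = {
        "estimates": _estimates_frame(results),
        "sensitivity": _sensitivity_frame(results),
        "tiers": _tiers_frame(results),
        "audit": _audit_frame(results),
        "loo": _loo_frame(results),
    }
    paths = {}
    for name, df in frames.items():
        path = os.path.join(out_dir, f"{name}.tsv")
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path
    manifest = {
        "package": "mrbiome",
        "version": __version__,
        "n_results": len(results),
        "config": asdict(config) if config else None,
    }
    mpath = os.path.join(out_dir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = mpath
    return paths
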