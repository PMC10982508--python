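"""Instrumental-variable selection, LD clumping, harmonization and strength.

The selection cascade, applied in this fixed order, is:

1. locus-wide exposure significance (p < 1e-5, strict);
2. greedy LD clumping (r2 < 0.001 within a 10,000 kb window);
3. exclusion of SNPs directly associated with the outcome (p < 1e-5);
4. harmonization to a common effect allele, dropping all palindromic
   (A/T, C/G) SNPs and any irreconcilable allele configuration;
5. weak-instrument filtering at F >= 10 with
   R2 = beta^2 / (beta^2 + se^2 * N) and F = R2 * (N - 2) / (1 - R2).

Every drop is audited with a reason so the per-stage counts always sum
back to the initial candidate count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .exceptions import ValidationError
from .gwas_io import LDMatrix, SummaryDataset, VariantAssociation

#: rejection reasons, in cascade order
REASONS = (
    "exposure-p",
    "clumped",
    "missing-in-outcome",
    "outcome-associated",
    "palindromic",
    "mismatch",
    "weak",
)


@dataclass
class Thresholds:
    """Selection thresholds; defaults are the screen's operating point."""

    exposure_p: float = 1e-5
    outcome_p: float = 1e-5
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0


@dataclass
class InstrumentRecord:
    """One exposure SNP's fate in the selection cascade."""

    variant: VariantAssociation
    r2_explained: float | None = None
    f_stat: float | None = None
    retained: bool = True
    reason: str | None = None


@dataclass(frozen=True)
class HarmonizedPair:
    """Per-SNP exposure and outcome effects aligned to one effect allele."""

    snp_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValidationError(f"{self.snp_id}: standard errors must be positive")
        if {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"}):
            raise ValidationError(f"{self.snp_id}: palindromic pair cannot be harmonized")


@dataclass
class InstrumentSet:
    """Final instruments for one exposure-outcome pair, with audit trail."""

    exposure_label: str
    taxon_rank: str | None
    outcome_label: str
    pairs: list[HarmonizedPair]
    audit: dict[str, int] = field(default_factory=dict)

    @property
    def nsnp(self) -> int:
        return len(self.pairs)

    @property
    def empty(self) -> bool:
        return not self.pairs

    def audit_frame(self) -> pd.DataFrame:
        rows = [{"stage": k, "count": v} for k, v in self.audit.items()]
        return pd.DataFrame(rows)


def filter_exposure_pvalue(
    dataset: SummaryDataset, threshold: float = 1e-5
) -> list[VariantAssociation]:
    """Candidates with exposure p strictly below the locus-wide threshold."""
    return [r for r in dataset.records.values() if r.pvalue < threshold]


def ld_clump(
    candidates: list[VariantAssociation],
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000.0,
) -> list[VariantAssociation]:
    """Greedy p-value-ordered clumping.

    Candidates are visited in ascending p (ties broken by chrom, pos,
    snp_id); each retained index SNP discards every remaining candidate on
    the same chromosome within ``window_kb`` whose r2 with it is at or
    above ``r2_threshold``. Cross-chromosome pairs are never clumped.
    """
    for c in candidates:
        if c.snp_id not in ld:
            raise ValidationError(f"candidate {c.snp_id} absent from LD matrix")
    window_bp = window_kb * 1_000.0
    order = sorted(candidates, key=lambda r: (r.pvalue, r.chrom, r.pos, r.snp_id))
    retained: list[VariantAssociation] = []
    discarded: set[str] = set()
    for cand in order:
        if cand.snp_id in discarded:
            continue
        retained.append(cand)
        for other in order:
            if other.snp_id == cand.snp_id or other.snp_id in discarded:
                continue
            if other.chrom != cand.chrom:
                continue
            if abs(other.pos - cand.pos) > window_bp:
                continue
            if ld.lookup(cand.snp_id, other.snp_id) >= r2_threshold:
                discarded.add(other.snp_id)
    return retained


def exclude_outcome_associated(
    candidates: list[VariantAssociation],
    outcome: SummaryDataset,
    threshold: float = 1e-5,
) -> tuple[list[VariantAssociation], dict[str, str]]:
    """Drop candidates directly associated with the outcome (p < threshold).

    Returns the survivors and a ``snp_id -> reason`` map for the dropped
    ones; candidates missing from the outcome dataset are dropped with the
    distinct reason ``missing-in-outcome``.
    """
    kept: list[VariantAssociation] = []
    dropped: dict[str, str] = {}
    for cand in candidates:
        if cand.snp_id not in outcome:
            dropped[cand.snp_id] = "missing-in-outcome"
        elif outcome.records[cand.snp_id].pvalue < threshold:
            dropped[cand.snp_id] = "outcome-associated"
        else:
            kept.append(cand)
    return kept, dropped


def harmonize(
    candidates: list[VariantAssociation], outcome: SummaryDataset
) -> tuple[list[HarmonizedPair], dict[str, str]]:
    """Align outcome effects to the exposure effect allele.

    Identical allele order copies the outcome effect; a swapped pair
    (outcome EA == exposure OA and vice versa) negates the outcome beta.
    Palindromic SNPs are dropped unconditionally — allele frequency is
    never consulted — and any other configuration is dropped as a
    mismatch. Candidates absent from the outcome are dropped too.
    """
    pairs: list[HarmonizedPair] = []
    dropped: dict[str, str] = {}
    for cand in candidates:
        if cand.snp_id not in outcome:
            dropped[cand.snp_id] = "missing-in-outcome"
            continue
        if cand.is_palindromic:
            dropped[cand.snp_id] = "palindromic"
            continue
        out = outcome.records[cand.snp_id]
        if (out.effect_allele, out.other_allele) == (cand.effect_allele, cand.other_allele):
            beta_out = out.beta
        elif (out.effect_allele, out.other_allele) == (cand.other_allele, cand.effect_allele):
            beta_out = -out.beta
        else:
            dropped[cand.snp_id] = "mismatch"
            continue
        pairs.append(
            HarmonizedPair(
                snp_id=cand.snp_id,
                beta_exposure=cand.beta,
                se_exposure=cand.se,
                beta_outcome=beta_out,
                se_outcome=out.se,
                effect_allele=cand.effect_allele,
                other_allele=cand.other_allele,
            )
        )
    return pairs, dropped


def instrument_strength(record: VariantAssociation) -> tuple[float, float]:
    """Variance explained and F-statistic of one instrument.

    R2 = beta^2 / (beta^2 + se^2 * N); F = R2 * (N - 2) / (1 - R2).
    Instruments with F < 10 are conventionally considered weak.
    """
    if record.n < 3:
        raise ValidationError(f"{record.snp_id}: N must be >= 3 to compute F")
    b2 = record.beta**2
    r2 = b2 / (b2 + record.se**2 * record.n)
    f = r2 * (record.n - 2) / (1.0 - r2)
    return r2, f


def build_instrument_set(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LDMatrix,
    thresholds: Thresholds | None = None,
) -> InstrumentSet:
    """Run the full selection cascade and return harmonized instruments.

    The audit dict records the initial record count (``total``), the
    post-significance candidate count (``candidates``), one entry per drop
    reason, and ``retained``; the reason counts plus ``retained`` always
    sum to ``total``.
    """
    th = thresholds or Thresholds()
    fates: dict[str, str] = {}

    total = len(exposure.records)
    candidates = filter_exposure_pvalue(exposure, th.exposure_p)
    initial = len(candidates)
    for r in exposure.records.values():
        if r.pvalue >= th.exposure_p:
            fates[r.snp_id] = "exposure-p"

    clumped = ld_clump(candidates, ld, th.clump_r2, th.clump_window_kb)
    clumped_ids = {c.snp_id for c in clumped}
    for c in candidates:
        if c.snp_id not in clumped_ids:
            fates[c.snp_id] = "clumped"

    survivors, dropped = exclude_outcome_associated(clumped, outcome, th.outcome_p)
    fates.update(dropped)

    pairs, dropped = harmonize(survivors, outcome)
    fates.update(dropped)

    strong: list[HarmonizedPair] = []
    by_id = {c.snp_id: c for c in survivors}
    for pair in pairs:
        _, f = instrument_strength(by_id[pair.snp_id])
        if f < th.f_min:
            fates[pair.snp_id] = "weak"
        else:
            strong.append(pair)

    audit = {"total": total, "candidates": initial}
    for reason in REASONS:
        audit[reason] = sum(1 for r in fates.values() if r == reason)
    audit["retained"] = len(strong)
    return InstrumentSet(
        exposure_label=exposure.trait_label,
        taxon_rank=exposure.taxon_rank,
        outcome_label=outcome.trait_label,
        pairs=strong,
        audit=audit,
    )
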