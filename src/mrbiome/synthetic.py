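"""Synthetic linked exposure/outcome GWAS pairs with known ground truth.

The generator works entirely at the summary level. For SNP ``j`` with minor
allele frequency ``maf_j`` and a standardized trait, the standard error of
a per-allele GWAS effect is approximately ``1/sqrt(2*maf*(1-maf)*N)``; true
instrument effects ``gamma_j`` on the exposure are drawn from a centred
normal, direct (pleiotropic) outcome effects ``alpha_j`` per the chosen
regime, and observed effects add sampling noise at the analytic standard
error. The true outcome model is ``theta * gamma_j + alpha_j`` on the
log-odds scale, so exponentiated downstream estimates are odds ratios.

Defaults emulate the study setting this package is built around: a
16S-abundance exposure GWAS of ~18k participants yielding weak-to-moderate
instruments (F roughly 17-85 after locus-wide p < 1e-5 selection) against a
disease GWAS of hundreds of thousands, with LD blocks and a fraction of
strand-ambiguous (A/T, C/G) SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .exceptions import ConfigurationError
from .gwas_io import LDMatrix, SummaryDataset, VariantAssociation, validate_ld

PLEIOTROPY_MODES = ("none", "balanced", "directional", "correlated")

# non-palindromic vs palindromic allele pairs (effect, other)
_PLAIN_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))
_PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))


@dataclass
class SimulationConfig:
    """Knobs of the summary-level generating model.

    ``theta`` is the true causal effect of the exposure on the outcome
    log-odds. ``instrument_effect_sd`` (standardized units per allele) sets
    instrument strength; 0.06 at n_exposure=18340 puts selected instruments
    in the F 17-85 range. For ``correlated`` pleiotropy, ``pleio_mean``
    doubles as the slope of alpha on gamma (an InSIDE violation) and
    ``pleio_sd`` as the residual spread.
    """

    n_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exposure: int = 18340
    n_outcome: int = 300000
    theta: float = 0.0
    instrument_effect_sd: float = 0.06
    pleiotropy_mode: str = "none"
    pleio_mean: float = 0.05
    pleio_sd: float = 0.02
    frac_invalid: float = 0.3
    ld_blocks: list[tuple[int, float]] = field(default_factory=list)
    frac_palindromic: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range {self.maf_range} not within (0, 0.5]")
        if lo == hi == 0.0:
            raise ConfigurationError("degenerate maf_range at 0")
        if not (0.0 <= self.frac_invalid <= 1.0):
            raise ConfigurationError("frac_invalid must lie in [0, 1]")
        if not (0.0 <= self.frac_palindromic <= 1.0):
            raise ConfigurationError("frac_palindromic must lie in [0, 1]")
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise ConfigurationError("sample sizes must be >= 2")
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ConfigurationError(
                f"pleiotropy_mode {self.pleiotropy_mode!r} not in {PLEIOTROPY_MODES}"
            )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "maf_range" in raw:
            raw["maf_range"] = tuple(raw["maf_range"])
        if "ld_blocks" in raw:
            raw["ld_blocks"] = [tuple(b) for b in raw["ld_blocks"]]
        return cls(**raw)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated pair, for parameter-recovery tests."""

    gamma: np.ndarray  # true per-SNP exposure effects
    alpha: np.ndarray  # true per-SNP direct outcome effects
    maf: np.ndarray
    theta: float
    ld_block: np.ndarray  # block index per SNP, -1 for unblocked
    snp_ids: list[str]


def _se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def simulate_pair(
    config: SimulationConfig,
) -> tuple[SummaryDataset, SummaryDataset, LDMatrix, SimulationTruth]:
    """Generate one exposure/outcome dataset pair with shared SNPs.

    Deterministic in ``config.seed``: the same config always yields
    bit-identical outputs. Palindromic-SNP and invalid-instrument counts
    are exact (``round(frac * n_snps)``), not binomial, so small fixtures
    have predictable composition.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    snp_ids = [f"rs{j + 1:06d}" for j in range(m)]

    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    gamma = rng.normal(0.0, config.instrument_effect_sd, size=m)

    # direct (pleiotropic) effects on the outcome
    alpha = np.zeros(m)
    n_invalid = int(round(config.frac_invalid * m))
    if config.pleiotropy_mode != "none" and n_invalid > 0:
        invalid = rng.choice(m, size=n_invalid, replace=False)
        if config.pleiotropy_mode == "balanced":
            alpha[invalid] = rng.normal(0.0, config.pleio_sd, size=n_invalid)
        elif config.pleiotropy_mode == "directional":
            # directional relative to the exposure-increasing allele: allele
            # coding signs are arbitrary in summary data, so a direct effect
            # is only meaningfully "directional" in that orientation
            alpha[invalid] = np.sign(gamma[invalid]) * rng.normal(
                config.pleio_mean, config.pleio_sd, size=n_invalid
            )
        else:  # correlated: alpha tracks instrument strength, violating InSIDE
            alpha[invalid] = config.pleio_mean * gamma[invalid] + rng.normal(
                0.0, config.pleio_sd, size=n_invalid
            )

    se_x = _se(maf, config.n_exposure)
    se_y = _se(maf, config.n_outcome)
    beta_x = gamma + rng.normal(0.0, 1.0, size=m) * se_x
    beta_y = config.theta * gamma + alpha + rng.normal(0.0, 1.0, size=m) * se_y
    p_x = 2.0 * stats.norm.sf(np.abs(beta_x / se_x))
    p_y = 2.0 * stats.norm.sf(np.abs(beta_y / se_y))

    # allele pairs: an exact count of palindromic SNPs
    n_pal = int(round(config.frac_palindromic * m))
    pal_idx = set(rng.choice(m, size=n_pal, replace=False).tolist()) if n_pal else set()
    alleles = []
    for j in range(m):
        pool = _PALINDROMIC_PAIRS if j in pal_idx else _PLAIN_PAIRS
        alleles.append(pool[int(rng.integers(len(pool)))])

    # LD blocks laid out consecutively; blocked SNPs share a chromosome
    # within clumping range, singletons are spaced far apart
    block_of = np.full(m, -1, dtype=int)
    r2 = np.eye(m)
    cursor = 0
    for b, (size, rho) in enumerate(config.ld_blocks):
        idx = np.arange(cursor, min(cursor + size, m))
        block_of[idx] = b
        for i in idx:
            for j in idx:
                if i != j:
                    r2[i, j] = rho
        cursor += size
    chrom = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=int)
    for j in range(m):
        if block_of[j] >= 0:
            chrom[j] = "1"
            pos[j] = 1_000_000 * (block_of[j] + 1) + 1_000 * (j + 1)
        else:
            chrom[j] = str(2 + (j % 21))
            pos[j] = 50_000_000 + 20_000_000 * (j // 21) + 1_000 * j

    def _dataset(beta, se, p, n, label, kind, rank):
        recs = [
            VariantAssociation(
                snp_id=snp_ids[j],
                chrom=str(chrom[j]),
                pos=int(pos[j]),
                effect_allele=alleles[j][0],
                other_allele=alleles[j][1],
                beta=float(beta[j]),
                se=float(se[j]),
                pvalue=float(min(1.0, p[j])),
                eaf=float(maf[j]),
                n=n,
            )
            for j in range(m)
        ]
        return SummaryDataset.from_records(recs, label, kind, rank)

    exposure = _dataset(
        beta_x, se_x, p_x, config.n_exposure, "synthetic_taxon", "exposure-taxon", "genus"
    )
    outcome = _dataset(
        beta_y, se_y, p_y, config.n_outcome, "synthetic_disease", "outcome-disease", None
    )
    positions = pd.DataFrame({"CHR": list(chrom), "POS": list(pos)}, index=snp_ids)
    ld = validate_ld(LDMatrix(snp_ids=list(snp_ids), r2=r2, positions=positions))
    truth = SimulationTruth(
        gamma=gamma, alpha=alpha, maf=maf, theta=config.theta,
        ld_block=block_of, snp_ids=list(snp_ids),
    )
    return exposure, outcome, ld, truth


def truth_report(truth: SimulationTruth) -> pd.DataFrame:
    """One row per SNP: true effects and a validity flag (no direct effect)."""
    return pd.DataFrame(
        {
            "SNP": truth.snp_ids,
            "gamma": truth.gamma,
            "alpha": truth.alpha,
            "maf": truth.maf,
            "ld_block": truth.ld_block,
            "valid_instrument": truth.alpha == 0.0,
        }
    )
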