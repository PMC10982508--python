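# Methods

## Setting and model

`mrbiome` operates entirely on GWAS summary statistics. The causal model
is the standard linear instrumental-variable model at the summary level:
for SNP *j*, the true effect on the exposure (a standardized bacterial
abundance) is γ_j, the direct (pleiotropic) effect on the outcome is
α_j, and the true outcome effect on the log-odds scale is

    b_Yj = θ · γ_j + α_j

where θ is the causal effect of interest. Observed effects add sampling
noise at the per-SNP standard errors reported by the source GWAS. All
estimators consume harmonized pairs (β̂_Xj, σ_Xj, β̂_Yj, σ_Yj) aligned to
a common effect allele; exponentiated estimates are odds ratios because
outcome effects live on the log-odds scale.

## Instrument selection

The cascade order is normative, not interchangeable: locus-wide exposure
significance (p < 1e-5, strict inequality), greedy LD clumping, exclusion
of outcome-associated SNPs (p < 1e-5), harmonization, then the F ≥ 10
strength filter. Clumping before the outcome filter matters — a lead SNP
that later fails the outcome filter still removes its LD partners — and
the test suite pins this with an adversarial fixture.

Clumping is greedy by ascending p-value (ties broken by chromosome,
position, then SNP id, making the output deterministic): each retained
index SNP discards every remaining candidate on the same chromosome
within ±10,000 kb whose r² with it is ≥ 0.001. Cross-chromosome pairs are
never clumped regardless of the r² entry. LD is an input (a matrix or
block specification); the package does not compute it from genotypes.

Harmonization uses allele identity only: identical allele order copies
the outcome effect, a swapped pair negates it, palindromic (A/T, C/G)
SNPs are dropped unconditionally — allele frequencies are never consulted
to rescue them — and any other configuration is dropped as a mismatch.
Instrument strength uses R² = β²/(β² + Se²·N) and F = R²(N−2)/(1−R²);
the weak-instrument cut is strict (F < 10 excluded, F = 10 retained).
Every drop is audited with a reason; reason counts plus the retained
count always equal the initial candidate count.

## Estimators

* **IVW** (primary): weighted least squares of β̂_Y on β̂_X through the
  origin, weights 1/σ_Y². Multiplicative random effects: the slope SE is
  multiplied by max(1, residual standard error), so it is never narrower
  than the fixed-effect SE. Two-sided normal p. When the floor binds, IVW
  coincides exactly with the fixed-effect inverse-variance meta-analysis
  of the per-SNP Wald ratios (tested against that oracle, and verified
  against R's `metafor::rma(method="FE")` and weighted `lm` during
  development).
* **MR-Egger**: the same weighted regression with an intercept, fitted
  after orienting every pair so β̂_X ≥ 0 (the intercept is
  orientation-dependent; this is the standard convention). Both SEs carry
  the max(1, RSE) floor; p-values use t with nsnp − 2 df.
* **Weighted median**: Wald ratios ordered ascending with normalized
  inverse-variance weights (delta-method ratio variances σ_Y²/β̂_X²); the
  estimate interpolates where the standardized mid-cumulative weight
  crosses 0.5. SE from a seeded parametric bootstrap (default 1000
  resamples of the ratios from their normal sampling distributions).
* **Modes**: weighted kernel density of the Wald ratios with a normal
  kernel; bandwidth = bandwidth_factor × 0.9 · min(sd, MAD·1.4826) ·
  n^{−1/5} (a modified Silverman rule on the ratio scale; factor default
  1). The weighted variant uses the normalized inverse-variance weights,
  the simple variant equal weights. Degenerate bandwidth (MAD = 0) falls
  back to the highest-mass value, ties broken toward the smaller value.
  SE by the same parametric bootstrap; p-values two-sided normal.
* **Dispatch**: one instrument → Wald ratio only; two → IVW only; three or
  more → all five methods with IVW flagged primary.

Confidence intervals use the multiplier 1.959964 throughout.

## Sensitivity suite

Cochran's Q uses fixed-effect fitted values (the conventional
definition): Q = Σ w_j (β̂_Yj − fitted_j)² with w = 1/σ_Y², df = nsnp − 1
for the IVW model and nsnp − 2 for the Egger model, upper-tail chi-square
p. The Egger intercept test is the t-test of the intercept (df nsnp − 2).

MR-PRESSO reproduces the published procedure statistically, not bitwise.
The observed RSS sums squared deviations of each outcome beta from its
prediction under the leave-one-out IVW slope. The null distribution comes
from parametric simulations (default 1000, seeded) of outcome betas
around the full-set fixed-effect fit — the no-pleiotropy model — with the
leave-one-out RSS recomputed within each simulated dataset; simulating
around the per-SNP leave-one-out predictions instead would inflate the
null (their spread is estimation noise, not signal) and makes the test
noticeably conservative. The global p carries an add-one numerator so it
is never exactly zero; the per-SNP outlier p-values deliberately do not,
since they must be able to undercut the Bonferroni threshold sig/nsnp
even when nsnp exceeds sig × n_sim. The distortion test compares the
outlier-corrected IVW estimate against estimates after removing equally
many random SNPs. Pairs are sorted by SNP id before any random draw, so
results are invariant to input order. The pipeline removes flagged
outliers and re-runs estimation and sensitivity exactly once, not
iterated to convergence.

Leave-one-out re-estimates IVW with each SNP removed; instability is
flagged when any left-out CI lies entirely on the opposite sign of the
full-set estimate. Diagnostics that need more SNPs than available
(Q ≥ 2, Egger/LOO ≥ 3, PRESSO ≥ 4) are reported as explicit "NA"
verdicts, never as silent passes.

## FDR tiering and exclusions

Primary p-values are BH-adjusted within (outcome × taxonomic rank)
families. The family size is the number of taxa tested at that rank —
for the 16S exposure panel this screen is modelled on, 119 genera, 32
families, 20 orders, 16 classes and 9 phyla (196 taxa of 211 profiled;
15 unclassified ones are not analyzable). The reported adjusted values of
that screen are only reproducible under exactly this family definition,
which is why it is built in as the default census. Absent tests pad the
family at p = 1, handled analytically by the step-up. Tiers: significant
(p < 0.05 and p_FDR < 0.05), suggestive (p < 0.05, p_FDR ≥ 0.05), null
otherwise. A would-be hit is excluded when IVW and MR-Egger disagree in
direction (other method disagreements are reported, not excluded) or when
pleiotropy persists after the outlier-removal rerun.

The reverse screen reuses the full cascade with the disease as exposure;
instrument thresholds come from a per-disease policy (5e-8 default;
rosacea and seborrheic dermatitis 5e-7; hidradenitis suppurativa 5e-6 —
diseases with too few genome-wide hits). Reverse FDR uses the set of
tested taxa per disease as the family; published reverse adjusted values
do not pin down a unique family rule, so no stronger claim is made.

## Synthetic generator

`synthetic.simulate_pair` emulates the study design at the summary level:
an abundance exposure GWAS of n = 18,340 against a binary outcome GWAS of
n = 300,000 (defaults). Per SNP: maf ~ Uniform(0.05, 0.5); γ ~
N(0, instrument_effect_sd²) with default sd 0.06, which after locus-wide
selection puts instrument F-statistics in the weak-to-moderate 17–85
range typical of 16S abundance GWAS; standard errors follow the
standardized-trait approximation 1/√(2·maf(1−maf)·N); observed betas add
normal noise at those SEs; p-values are two-sided normal. Pleiotropy
regimes: none; balanced (α ~ N(0, pleio_sd)); directional (α =
sign(γ)·N(pleio_mean, pleio_sd) — directional *relative to the
exposure-increasing allele*, the only orientation-invariant notion of
directionality in summary data, and the form MR-Egger's oriented
intercept can detect); correlated (α = pleio_mean·γ + N(0, pleio_sd),
violating InSIDE; pleio_mean doubles as the slope rather than adding a
config field). Invalid-instrument and palindromic-SNP counts are exact
(round(frac·n)), so small fixtures have predictable composition. LD
blocks are laid out block-diagonally with constant within-block r²;
blocked SNPs share a chromosome within clumping range, singletons are
spaced across chromosomes. One seed drives the whole pair; identical
configs give bit-identical outputs.

What the generator does not emulate: individual-level genotypes,
case-control ascertainment, realistic (zero-inflated, compositional)
abundance distributions, allele-frequency differences between cohorts,
or realistic LD decay. Passing calibration tests therefore demonstrate
correctness of the estimators under the additive summary-level model,
not robustness to every pathology of real consortium data.

## Numerical choices and problem sizes

LD validation tolerance 1e-8 (symmetry, unit diagonal, range). Bootstrap
default 1000 resamples, always explicitly seeded; MR-PRESSO default 1000
simulations. Calibration suites run at deliberately modest sizes chosen
to make the Monte Carlo error small relative to the tested bands: IVW
type-I error over 2000 null 30-SNP replicates (band 0.035–0.065),
coverage over 1000 replicates of 50 strong instruments (band 93–97%),
bias over 500 generator replicates at θ = 0.3 (|bias| < 0.02), PRESSO
null rejection over 500 replicates of 300 simulations each (0.05 ±
0.02). Combinatorial components are checked against brute-force oracles:
BH step-up against the naive min-over-ranks definition on every vector of
length ≤ 6 over a coarse grid (and against
`statsmodels.stats.multitest.multipletests` on random vectors), and
greedy clumping against an independently coded best-p-first scan on
random ≤ 10-SNP panels.

## Known limitations

* The outcome-association filter (p < 1e-5) removes genuinely causal
  instruments when the true effect and outcome GWAS are large; this is a
  faithful property of the screen's design, visible in the synthetic
  end-to-end tests, not a bug.
* MR-PRESSO's distortion test uses random subset removal as its
  reference distribution; with very few instruments its permutation p is
  coarse.
* No Steiger filtering, multivariable MR, proxy-SNP lookup or LD
  estimation from reference panels; LD must be supplied.
* Reverse-screen FDR families are the tested-taxa sets; other family
  conventions exist and give different adjusted values.
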