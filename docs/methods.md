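# Methods

This note documents the statistical machinery in `mrtaxa`: the estimators
and their assumptions, the defaults and why they were chosen, what the
synthetic generator does and does not emulate, numerical details, and known
limitations.

## Study design

The package implements a bidirectional two-sample MR screen. Exposure
associations (per-SD abundance of a microbial taxon) and outcome
associations (log-odds of a binary disease) come from *non-overlapping*
GWAS. The inference design is: (1) a discovery screen across taxa gated
solely on the primary estimator's p-value at α = 0.05; (2) replication of
discovery hits in an independent outcome cohort, declared successful when
the replication primary estimate is significant at α *and* has the same
sign as in discovery; (3) fixed-effect inverse-variance meta-analysis of
the two primary estimates, with a DerSimonian–Laird random-effects version
reported alongside whenever between-cohort Cochran's Q has p < 0.10;
(4) reverse MR with disease as exposure and taxon abundance as outcome,
whose expected output on a forward-only causal structure is a null report.
No multiple-testing correction is applied across taxa by default (the
screen is a raw p < 0.05 gate); a Benjamini–Hochberg option exists
(`MRConfig(bh_correction=True)`).

## Instrument selection and harmonization

Instruments are taken at p < 1e-5 by default — the locus-wide threshold
conventional in microbiota MR, where genome-wide 5e-8 leaves too few
variants per taxon — with an approximate-F filter (β/se)² ≥ 10 against weak
instruments. The reverse direction defaults to 5e-8 because disease GWAS
are well powered. Both are configurable.

**The package's input contract is that instruments are LD-independent**
(pre-clumped upstream or synthetic). No clumping, proxy lookup, position
matching or liftover is performed; variants are matched by identifier only.

Harmonization aligns the outcome row of each shared variant onto the
exposure's effect allele: identical allele pairs are kept; swapped pairs
have the outcome beta negated and EAF mapped to 1−EAF; strand-complement
reports are complemented first and then resolved the same way. Palindromic
variants (A/T, C/G) are special: the allele strings cannot distinguish a
strand flip from an allele swap, so orientation is decided by allele
frequency alone — the variant is kept (as reported) only when both EAFs are
present, outside 0.5 ± 0.08, and on the same side of 0.5; otherwise it is
dropped as ambiguous. A missing EAF on a palindromic variant drops it. The
0.08 window is a common practical choice; it is exposed as
`palindrome_eaf_window`. Every variant in the id-intersection carries a
provenance flag (`kept`, `sign_flipped`, `dropped_palindromic`,
`dropped_incompatible`), and harmonization fails loudly with per-category
counts when nothing survives.

## Estimators

All estimators consume harmonized per-variant effects
(γ̂ⱼ, σ_γⱼ, Γ̂ⱼ, σ_Γⱼ) and return the causal slope β on the log-odds scale
with a two-sided normal p-value. They are scikit-learn-style classes
(`fit`, fitted attributes, `get_params`); sign and scale equivariance and
the algebraic identities below are enforced by tests.

### Radial IVW (primary)

β̂ = Σwⱼβ̂ⱼ/Σwⱼ over Wald ratios β̂ⱼ = Γ̂ⱼ/γ̂ⱼ. Three weighting schemes:

* first-order: wⱼ = γ̂ⱼ²/σ_Γⱼ² (default);
* second-order: wⱼ = 1/(σ_Γⱼ²/γ̂ⱼ² + Γ̂ⱼ²σ_γⱼ²/γ̂ⱼ⁴), a delta-method
  refinement;
* modified second-order: the delta term uses (β̂_F γ̂ⱼ)² with β̂_F iterated
  from the first-order fit to a 1e-8 fixed point (max 100 iterations).

The closed-form weighted mean is identical (to 1e-10, tested) to the slope
of the origin-constrained regression of β̂ⱼ√wⱼ on √wⱼ — the radial
formulation — whose per-variant squared residuals are the Cochran's Q
contributions Qⱼ = wⱼ(β̂ⱼ−β̂)² exposed for outlier diagnostics. The fixed
SE is (Σwⱼ)^(−1/2); the default multiplicative-random-effects model
inflates it by max(1, √(Q/(J−1))), which makes the test slightly
conservative when Q < J−1 and absorbs balanced pleiotropy otherwise. A
single surviving instrument falls back to its Wald ratio with first-order
SE rather than failing, flagged in the output.

First-order weighting with multiplicative random effects is the default
"radial IVW" because it is the standard choice when no weighting is
specified; both alternatives are implemented and selectable.

### Weighted median

Ratios are sorted; with first-order weights normalized to sum 1, the
cumulative midpoints sⱼ = Σ_{k≤j} w′ₖ − w′ⱼ/2 define a piecewise-linear
quantile function whose value at 0.5 is the estimate (equal weights reduce
it to the sample median, tested against a dense-grid inversion oracle).
The SE is the standard deviation of the estimate over `n_boot` parametric
resamples γ̂ⱼ* ~ N(γ̂ⱼ, σ_γⱼ²), Γ̂ⱼ* ~ N(Γ̂ⱼ, σ_Γⱼ²); the default
n_boot = 10,000 keeps the Monte-Carlo error of the SE near 1%, and the seed
is mandatory. Consistent when at least half the total weight comes from
valid instruments.

### MR-RAPS

With standardized residual tⱼ(β, τ²) = (Γ̂ⱼ − βγ̂ⱼ)/√(σ_Γⱼ² + β²σ_γⱼ² + τ²),
the estimator solves the profile score equations

    Σⱼ ψ(tⱼ) ∂tⱼ/∂β = 0,
    Σⱼ (ψ(tⱼ)tⱼ − c_ψ)/(σ_Γⱼ² + β²σ_γⱼ² + τ²) = 0,  τ² ≥ 0,

where ψ is the identity (l2) or the Huber function with k = 1.345 (the
classical 95%-efficiency constant; default), and c_ψ = E[ψ(Z)Z] under a
standard normal (1 for l2; 1-D quadrature for Huber, cached). Defaults:
overdispersion on, Huber loss. The solver alternates bracketed scalar
root-finding in β and τ² (tolerance 1e-8, max 200 alternations) starting at
the first-order IVW slope. Two numerical points matter: the Huber β-score
saturates toward zero at large |β|, and a gross outlier creates a spurious
score crossing that is a likelihood *minimum*; the β-solver therefore scans
an expanding grid and brackets only upward score crossings (maxima),
choosing the one nearest the current iterate. τ² is clamped at zero when
the overdispersion score is already non-positive there. The SE is a
numerically differentiated sandwich at the solution. With σ_γ = 0, l2 loss
and no overdispersion, the estimate equals first-order IVW (tested to
1e-6).

### MR-PRESSO

For each variant, the leave-one-out first-order IVW slope β̂₍₋ⱼ₎ gives a
residual rⱼ = Γ̂ⱼ − β̂₍₋ⱼ₎γ̂ⱼ; the observed statistic is
RSS = Σⱼ rⱼ²/σ_Γⱼ². K parametric replicates (default 1000) drawn under the
no-pleiotropy null — Γ̂ⱼ* ~ N(β̂₍₋ⱼ₎γ̂ⱼ, σ_Γⱼ²), γ̂ⱼ* ~ N(γ̂ⱼ, σ_γⱼ²) —
yield the global empirical p by the add-one rule (#{RSS* ≥ RSS}+1)/(K+1),
so the smallest attainable p is 1/(K+1). Per-variant outlier p-values use
the same simulation stream on rⱼ², Bonferroni-multiplied by J (note the
adjusted floor is J/(K+1): K must exceed J/α − 1 for any flag to be
possible at level α). The distortion test compares the first-order fixed
IVW slope with and without flagged outliers as a percent change, with a
null built by removing random same-size subsets of non-outlier variants
(a simplification of the published bootstrap, chosen for determinism and
speed) and a two-sided empirical p on the magnitude of the statistic —
again with the add-one rule, so an extreme statistic at n_boot = 99 gives
exactly 1/100. Residuals are standardized by σ_Γⱼ only, consistent with
the first-order weighting of the primary IVW. Identical (data, K, seed)
give bit-identical results.

The global test is calibrated under *its* null (no horizontal pleiotropy):
under a balanced-pleiotropy scenario with σ_α comparable to σ_Γ it
correctly concentrates its p near zero — that scenario is an alternative,
not a null, for this test. The test suite checks both behaviours.

### Meta-analysis

Fixed effect: β_meta = Σ β_c/se_c² / Σ 1/se_c², se_meta = (Σ1/se_c²)^(−1/2),
which is always smaller than each cohort SE. DerSimonian–Laird:
τ²_DL = max(0, (Q_b − (C−1))/(Σw_c − Σw_c²/Σw_c)) with w_c = 1/se_c²,
then inverse-variance with weights 1/(se_c² + τ²_DL); it reduces exactly to
fixed when Q_b ≤ C−1. Fixed-effect is primary (two well-defined cohorts of
the same phenotype); DL is attached when between-cohort Q has p < 0.10.

### Reporting

Odds ratios are exp(β) with CI bounds exp(β ± z·se); β is the log-OR per
unit of the exposure GWAS scale (per SD of log abundance in microbiota
GWAS convention) — interpretation of the unit is left to the user. The
forest table renders one row per (exposure, cohort, method) with 6
significant digits, tab-delimited, fixed column order, so outputs diff
cleanly; run manifests record config, seeds, input digests and versions,
and `mrtaxa replay` reproduces outputs byte-identically.

## Synthetic data generator

`simulate_study` draws, per variant: MAF pⱼ ~ U(0.10, 0.40); true effect
γⱼ ~ N(0, 0.10²) resampled until the implied F = (γⱼ/se_γⱼ)² ≥ 10;
standard errors from the summary-level logistic/linear approximations

    se_γⱼ = 1/√(2pⱼ(1−pⱼ)·n_exposure),
    se_Γⱼ = √(1/(2pⱼ(1−pⱼ)) · (1/n_cases + 1/n_controls)),

with cohort-size defaults 18,040 (exposure), 12,366/33,609 (discovery
outcome) and 4,320/210,300 (replication outcome) — the scale of the
consortium microbiota GWAS and the two ulcerative-colitis case–control
GWAS this generator emulates. True outcome effects are Γⱼ = βγⱼ + αⱼ with
pleiotropy αⱼ per regime: none; balanced N(0, σ_α²); directional
N(μ_α, σ_α²); or a single planted offset on one random variant. αⱼ is
drawn independently of γⱼ, so the InSIDE condition (instrument strength
independent of direct effect) holds by construction in the balanced and
directional regimes — estimator behaviour in tests therefore matches the
theory that assumes it. Observed effects add N(0, se²) noise; reported SEs
are the true ones. gamma_sd = 0.10 makes the typical true F ≈ 75
("strong instruments"); demonstration causal effects use |β| = 0.3
(OR ≈ 0.74, a plausibly protective magnitude — a choice, not a measured
value).

To exercise harmonization, 30% of outcome rows are reported with swapped
alleles (beta negated, EAF complemented) and 10% of variants are
palindromic. Palindromic variants are never swapped: for A/T and C/G pairs
a swap is indistinguishable from a strand flip, and orientation is
conventionally conveyed by frequency. With MAF below 0.40 the palindromic
variants stay outside the ambiguity window and are retained, so end-to-end
estimates are identical between swap fractions 0 and 0.5 (tested).

`make_screen_panel` builds a multi-taxon discovery panel: each taxon has
its own instrument set; one shared discovery and one shared replication
outcome table hold all variants, the replication cohort re-drawing outcome
noise from the same latent truth at its own (smaller-case-count, hence
noisier) SEs. Exactly `n_causal` taxa get nonzero β with alternating
protective/risk signs. `simulate_study` also supports a binary exposure
(disease-as-exposure for reverse MR, using case/control SEs on the
exposure side; the reverse scenario uses gamma_sd = 0.15 so instruments
clear the 5e-8 threshold) and a quantitative outcome.

What the generator does **not** emulate: LD between variants (instruments
are independent by design, matching the input contract), winner's-curse
bias from instrument discovery in the same sample, sample overlap between
exposure and outcome GWAS, allele-frequency differences between cohorts,
population stratification, and non-normal effect distributions. Passing
tests therefore demonstrate correctness of the estimators and pipeline
under the stated two-sample assumptions, not robustness to these
real-data violations.

## Simulation sizes and thresholds used in validation

The validation suite (and `scripts/acceptance.py`) uses: 1000 reps for the
IVW type-I error under the balanced-pleiotropy null (σ_α = 0.02, J = 15,
discovery cohort sizes), accepting an empirical rate in [0.03, 0.08];
200 reps at K = 500 for the Kolmogorov–Smirnov uniformity of the PRESSO
global p under the pleiotropy-free null; 500 reps of the causal scenario
(β = −0.3, J = 20) for mean bias (< 0.05) and 95% CI coverage (≥ 0.90) of
all four estimators and for fixed-meta SE dominance; 200 reps each for
PRESSO detection (planted offset 0.5, flagged ≥ 80%), specificity (no
flags in ≥ 90% of clean reps) and correction (closer to truth in ≥ 80%);
100 seven-taxon panels (3 causal) for the screen logic; and 200 reps for
the reverse-MR null-report rate (≈ 95%). These sizes keep the full suite
around one minute on a single CPU while leaving Monte-Carlo error well
inside the acceptance bands.

## Known limitations

* No MR-Egger, mode-based estimation, or Steiger directionality filtering.
* No LD awareness anywhere: correlated instruments will silently violate
  the independence assumption and understate SEs.
* The distortion-test null (subset resampling from non-outliers) is a
  deliberate simplification of the published bootstrap.
* The weighted-median SE is a parametric bootstrap and inherits
  Monte-Carlo noise of order 1/√(2·n_boot).
* With a gross outlier, the unbounded-loss (l2) RAPS solution can migrate
  to the outlier-dominated likelihood maximum; this is the expected
  behaviour that motivates the Huber default, not a solver defect.
* Exposure units are whatever the exposure GWAS used; odds ratios are per
  that unit and are not rescaled.
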