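# mrtaxa

Bidirectional two-sample Mendelian randomization (MR) for microbiome–disease
screens: harmonize GWAS summary statistics, estimate causal effects with a
radial inverse-variance-weighted (IVW) primary analysis plus
pleiotropy-robust sensitivity estimators, detect outlying instruments with
MR-PRESSO, and run a discovery → replication → meta-analysis design with a
reverse-direction check.

## Who this is for

Epidemiologists and statistical geneticists who have *summary-level* GWAS
associations for an exposure (e.g. per-SD abundance of a gut bacterial genus
from a microbiota GWAS of ~18,000 individuals) and a binary outcome (e.g. an
ulcerative-colitis case–control GWAS), and who want to test whether the
exposure causally affects disease risk using genetic variants as
instruments. No individual-level data are needed, and no network access:
the package ships a synthetic two-sample GWAS generator that reproduces the
statistical structure of such studies (instrument strength, case/control
sampling noise, horizontal pleiotropy) so every stage is testable offline.

## The model

For variant *j*, let γ̂ⱼ (SE σ_γⱼ) be its exposure association and Γ̂ⱼ (SE
σ_Γⱼ) its outcome association on the log-odds scale, harmonized to a common
effect allele. Under the instrumental-variable assumptions each Wald ratio
β̂ⱼ = Γ̂ⱼ/γ̂ⱼ estimates the causal slope β (log-OR of disease per unit of
exposure), and the IVW estimate is the weighted mean

    β̂ = Σⱼ wⱼ β̂ⱼ / Σⱼ wⱼ ,   wⱼ = γ̂ⱼ²/σ_Γⱼ²  (first-order weights),

algebraically identical to the slope of the radial regression of β̂ⱼ√wⱼ on
√wⱼ through the origin; Cochran's Q = Σⱼ wⱼ(β̂ⱼ − β̂)² decomposes into
per-variant contributions used for heterogeneity diagnosis, and the default
multiplicative-random-effects SE inflates the fixed SE by max(1, √(Q/(J−1))).
Sensitivity analyses: the **weighted median** (consistent when ≥50% of
weight comes from valid instruments), **MR-RAPS** (robust adjusted profile
score with Huber loss and an overdispersion parameter τ² for systematic
pleiotropy), and **MR-PRESSO** (simulation-based global residual-sum test,
per-variant outlier test, and distortion test). Two cohorts are combined by
fixed-effect inverse-variance meta-analysis (DerSimonian–Laird alongside
when between-cohort heterogeneity is material).

Inputs are assumed LD-independent (pre-clumped); the package performs no
clumping and matches variants by identifier.

## Worked example

A protective exposure (true OR ≈ 0.74 per exposure SD) simulated at the
default cohort sizes, analysed end to end:

```python
from mrtaxa import (ScenarioConfig, simulate_study, simulate_outcome_from_truth,
                    select_instruments, harmonize, ivw, weighted_median, raps,
                    MRPresso, meta_fixed, to_odds_ratio)

cfg = ScenarioConfig(n_snp=20, beta_true=-0.3,
                     exposure_label="Lactobacillus-like", seed=7)
exposure, outcome, truth = simulate_study(cfg)
replication = simulate_outcome_from_truth(truth, seed=8)

instruments = select_instruments(exposure, p_threshold=1e-5, f_min=10)
h = harmonize(instruments, outcome)
print(f"instruments kept after harmonization: {h.n_snp}")

for e in (ivw(h), weighted_median(h, n_boot=10_000, seed=1), raps(h)):
    or_, lo, hi = to_odds_ratio(e)
    print(f"{e.method:16s} OR {or_:.3f} (95% CI {lo:.3f}-{hi:.3f})  p={e.pval:.2e}")

presso = MRPresso(n_sim=1000, seed=2).fit_harmonized(h)
print(f"MR-PRESSO global p = {presso.result_.global_pval:.3f}, "
      f"outliers: {list(presso.outlier_ids_)}")

e_repl = ivw(harmonize(instruments, replication))
meta = meta_fixed([ivw(h), e_repl])
import numpy as np
print(f"meta OR {np.exp(meta.beta_meta):.3f}, p = {meta.pval_meta:.2e}")
```

Output:

```
instruments kept after harmonization: 17
ivw_radial       OR 0.724 (95% CI 0.683-0.767)  p=6.44e-28
weighted_median  OR 0.725 (95% CI 0.670-0.785)  p=1.69e-15
raps             OR 0.723 (95% CI 0.696-0.751)  p=3.70e-61
MR-PRESSO global p = 0.978, outliers: []
meta OR 0.761, p = 3.26e-29
```

All three estimators agree on a protective effect close to the simulated
truth (OR 0.74); the non-significant MR-PRESSO global p and empty outlier
list say the instrument set shows no pleiotropic heterogeneity; the
meta-analysed OR combines the discovery and replication cohorts with a
smaller standard error than either alone.

The estimators follow the scikit-learn protocol (`RadialIVW`,
`WeightedMedianMR`, `RAPSEstimator`, `MRPresso` expose `fit`,
`get_params`/`set_params` and fitted `beta_`, `se_`, `pval_` attributes);
the functions above are thin wrappers over them.

## Command line

```sh
mrtaxa simulate --scenario causal --seed 3 --out sim/
mrtaxa screen --exposure sim/exposure.tsv --outcome sim/outcome_discovery.tsv \
              --n-cases 12366 --n-controls 33609 --seed 1 --out run/
mrtaxa replay run/manifest.json --out run2/   # byte-identical re-run
```

Each run writes a forest-plot-ready TSV (`forest.tsv`), a log, and a
`manifest.json` from which `mrtaxa replay` reproduces the outputs
byte-identically. Subcommands: `simulate`, `screen`, `replicate`, `reverse`,
`meta`, `replay`.

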