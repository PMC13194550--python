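"""Synthetic two-sample GWAS summary statistics.

Emulates the statistical structure of a microbiota-exposure / disease-outcome
MR study: per-variant true instrument effects γⱼ with sampling noise at the
scale of an 18,040-individual exposure GWAS, a binary outcome on the log-odds
scale with case/control sampling noise (defaults 12,366/33,609 for the
discovery cohort and 4,320/210,300 for the replication cohort), and optional
horizontal pleiotropy αⱼ drawn independently of γⱼ (so the InSIDE condition —
instrument strength independent of direct effect — holds by construction in
the balanced and directional regimes).

Standard-error model (logistic approximation at summary level):

    se_γⱼ = 1 / sqrt(2 pⱼ(1−pⱼ) · n_exposure)                  (quantitative)
    se_Γⱼ = sqrt( 1/(2 pⱼ(1−pⱼ)) · (1/n_cases + 1/n_controls) ) (binary)

True outcome effects are Γⱼ = β γⱼ + αⱼ.  Observed effects add
N(0, se²) noise (scaled by ``noise_scale``); reported SEs are the true ones.
Allele pairs are assigned so a configurable fraction of outcome rows are
reported in swapped orientation and a fraction of variants are palindromic,
exercising harmonization end-to-end.

No LD is simulated: instruments are independent by design, matching the
package's pre-clumped-input contract.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .gwas_io import CANONICAL_COLUMNS, SummaryStatsTable

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

PLEIOTROPY_REGIMES = ("none", "balanced", "directional", "single_outlier")


@dataclass
class ScenarioConfig:
    """Generative model parameters for one synthetic two-sample study.

    Cohort-size defaults are the study conditions this generator emulates:
    exposure GWAS of 18,040 individuals, discovery outcome of 12,366 cases /
    33,609 controls.  ``replication()`` switches the outcome to 4,320 cases /
    210,300 controls.
    """

    n_snp: int = 15
    beta_true: float = 0.0
    n_exposure: int = 18_040
    n_cases: int = 12_366
    n_controls: int = 33_609
    gamma_sd: float = 0.10
    maf_range: tuple[float, float] = (0.10, 0.40)
    pleiotropy: str = "none"
    pleio_sd: float = 0.0
    pleio_mean: float = 0.0
    outlier_offset: float = 0.0
    swap_fraction: float = 0.3
    palindromic_fraction: float = 0.1
    weak_instruments: bool = False
    noise_scale: float = 1.0
    exposure_binary: bool = False
    exposure_n_cases: int | None = None
    exposure_n_controls: int | None = None
    outcome_binary: bool = True
    n_outcome: int = 18_040
    exposure_label: str = "taxon"
    outcome_label: str = "UC"
    variant_prefix: str = "rs"
    seed: int = 0

    def __post_init__(self):
        if self.n_snp < 1:
            raise ConfigurationError("n_snp must be positive")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo < hi <= 0.5")
        if self.pleiotropy not in PLEIOTROPY_REGIMES:
            raise ConfigurationError(
                f"pleiotropy must be one of {PLEIOTROPY_REGIMES}, got {self.pleiotropy!r}"
            )
        if self.pleio_sd < 0 or self.noise_scale < 0:
            raise ConfigurationError("pleio_sd and noise_scale must be >= 0")
        for n in (self.n_exposure, self.n_cases, self.n_controls, self.n_outcome):
            if n < 1:
                raise ConfigurationError("cohort sizes must be positive")
        if self.exposure_binary and not (self.exposure_n_cases and self.exposure_n_controls):
            raise ConfigurationError("binary exposure needs exposure_n_cases/controls")

    def replication(self, n_cases: int = 4320, n_controls: int = 210_300,
                    seed_offset: int = 1_000_003) -> "ScenarioConfig":
        """Same truth dimensions, replication-cohort outcome sizes, fresh seed."""
        return replace(self, n_cases=n_cases, n_controls=n_controls,
                       seed=self.seed + seed_offset)


def _se_binary(p: np.ndarray, n_cases: int, n_controls: int) -> np.ndarray:
    return np.sqrt(1.0 / (2 * p * (1 - p)) * (1.0 / n_cases + 1.0 / n_controls))


def _se_quantitative(p: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2 * p * (1 - p) * n)


def _draw_alleles(rng: np.random.Generator, n: int, palindromic_fraction: float):
    n_pal = int(round(palindromic_fraction * n))
    pal_idx = rng.choice(n, size=n_pal, replace=False) if n_pal else np.array([], dtype=int)
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    pick_np = rng.integers(0, len(_NONPALINDROMIC), size=n)
    pick_p = rng.integers(0, len(_PALINDROMIC), size=n)
    is_pal = np.zeros(n, dtype=bool)
    is_pal[pal_idx] = True
    for i in range(n):
        ea[i], oa[i] = _PALINDROMIC[pick_p[i]] if is_pal[i] else _NONPALINDROMIC[pick_np[i]]
    return ea, oa, is_pal


def simulate_study(config: ScenarioConfig):
    """Draw one two-sample study: (exposure table, outcome table, truth record).

    True γⱼ ~ N(0, gamma_sd²), resampled until the implied F = (γⱼ/se_γⱼ)²
    is at least 10 (skipped when ``weak_instruments``); pleiotropy per regime;
    Γⱼ = β γⱼ + αⱼ.  The truth record retains γⱼ, αⱼ, β, MAFs and the planted
    outlier index (or None).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    J = cfg.n_snp
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=J)

    if cfg.exposure_binary:
        se_g = _se_binary(p, cfg.exposure_n_cases, cfg.exposure_n_controls)
    else:
        se_g = _se_quantitative(p, cfg.n_exposure)
    if cfg.outcome_binary:
        se_G = _se_binary(p, cfg.n_cases, cfg.n_controls)
    else:
        se_G = _se_quantitative(p, cfg.n_outcome)

    gamma = np.empty(J)
    for j in range(J):
        for attempt in range(10_000):
            cand = rng.normal(0.0, cfg.gamma_sd)
            if cfg.weak_instruments or (cand / se_g[j]) ** 2 >= 10.0:
                gamma[j] = cand
                break
        else:
            raise ConfigurationError(
                "could not draw an instrument with F >= 10 after 10000 tries; "
                "increase gamma_sd"
            )

    alpha = np.zeros(J)
    outlier_index = None
    if cfg.pleiotropy == "balanced":
        alpha = rng.normal(0.0, cfg.pleio_sd, size=J)
    elif cfg.pleiotropy == "directional":
        alpha = rng.normal(cfg.pleio_mean, cfg.pleio_sd, size=J)
    elif cfg.pleiotropy == "single_outlier":
        outlier_index = int(rng.integers(0, J))
        alpha[outlier_index] = cfg.outlier_offset

    Gamma = cfg.beta_true * gamma + alpha
    gamma_hat = gamma + cfg.noise_scale * rng.normal(0.0, se_g)
    Gamma_hat = Gamma + cfg.noise_scale * rng.normal(0.0, se_G)

    snp = np.array([f"{cfg.variant_prefix}{j}" for j in range(J)])
    ea, oa, is_pal = _draw_alleles(rng, J, cfg.palindromic_fraction)

    pval_g = 2 * stats.norm.sf(np.abs(gamma_hat) / se_g)
    pval_G = 2 * stats.norm.sf(np.abs(Gamma_hat) / se_G)

    exposure_df = pd.DataFrame({
        "snp": snp, "effect_allele": ea, "other_allele": oa, "eaf": p,
        "beta": gamma_hat, "se": se_g, "pval": np.clip(pval_g, 1e-300, 1.0),
        "n": (cfg.exposure_n_cases + cfg.exposure_n_controls) if cfg.exposure_binary
             else cfg.n_exposure,
    })[CANONICAL_COLUMNS]

    # swapped outcome rows report the other allele as effect allele;
    # palindromic rows are never swapped (orientation is frequency-conventional)
    swap = (rng.random(J) < cfg.swap_fraction) & ~is_pal
    out_ea = np.where(swap, oa, ea)
    out_oa = np.where(swap, ea, oa)
    out_beta = np.where(swap, -Gamma_hat, Gamma_hat)
    out_eaf = np.where(swap, 1.0 - p, p)
    outcome_df = pd.DataFrame({
        "snp": snp, "effect_allele": out_ea, "other_allele": out_oa, "eaf": out_eaf,
        "beta": out_beta, "se": se_G, "pval": np.clip(pval_G, 1e-300, 1.0),
        "n": (cfg.n_cases + cfg.n_controls) if cfg.outcome_binary else cfg.n_outcome,
    })[CANONICAL_COLUMNS]

    exposure = SummaryStatsTable(
        trait_label=cfg.exposure_label,
        trait_type="binary" if cfg.exposure_binary else "quantitative",
        records=exposure_df,
        n_cases=cfg.exposure_n_cases, n_controls=cfg.exposure_n_controls,
    )
    outcome = SummaryStatsTable(
        trait_label=cfg.outcome_label,
        trait_type="binary" if cfg.outcome_binary else "quantitative",
        records=outcome_df,
        n_cases=cfg.n_cases if cfg.outcome_binary else None,
        n_controls=cfg.n_controls if cfg.outcome_binary else None,
    )
    truth = {
        "beta_true": cfg.beta_true,
        "gamma": gamma,
        "alpha": alpha,
        "maf": p,
        "snp": snp,
        "effect_allele": ea,
        "other_allele": oa,
        "outlier_index": outlier_index,
        "swapped": swap,
        "palindromic": is_pal,
        "config": asdict(cfg),
    }
    return exposure, outcome, truth


def simulate_outcome_from_truth(truth: dict, n_cases: int = 4320,
                                n_controls: int = 210_300, seed: int = 1,
                                outcome_label: str = "UC_replication",
                                swap_fraction: float | None = None,
                                noise_scale: float | None = None) -> SummaryStatsTable:
    """Outcome table for an independent cohort sharing an existing latent truth.

    The same variants, MAFs, true γⱼ/αⱼ and causal β as in ``truth``, with
    outcome sampling noise re-drawn at this cohort's case/control sizes —
    i.e. a replication cohort for the study that produced ``truth``.
    """
    cfg_dict = truth["config"]
    if swap_fraction is None:
        swap_fraction = cfg_dict["swap_fraction"]
    if noise_scale is None:
        noise_scale = cfg_dict["noise_scale"]
    rng = np.random.default_rng(seed)
    p = np.asarray(truth["maf"], dtype=float)
    gamma = np.asarray(truth["gamma"], dtype=float)
    alpha = np.asarray(truth["alpha"], dtype=float)
    snp = np.asarray(truth["snp"])
    ea = np.asarray(truth["effect_allele"])
    oa = np.asarray(truth["other_allele"])
    J = len(snp)
    se_G = _se_binary(p, n_cases, n_controls)
    Gamma = truth["beta_true"] * gamma + alpha
    Gamma_hat = Gamma + noise_scale * rng.normal(0.0, se_G)
    pval_G = np.clip(2 * stats.norm.sf(np.abs(Gamma_hat) / se_G), 1e-300, 1.0)
    is_pal = np.asarray(truth["palindromic"], dtype=bool)
    swap = (rng.random(J) < swap_fraction) & ~is_pal
    df = pd.DataFrame({
        "snp": snp,
        "effect_allele": np.where(swap, oa, ea),
        "other_allele": np.where(swap, ea, oa),
        "eaf": np.where(swap, 1.0 - p, p),
        "beta": np.where(swap, -Gamma_hat, Gamma_hat),
        "se": se_G, "pval": pval_G, "n": n_cases + n_controls,
    })[CANONICAL_COLUMNS]
    return SummaryStatsTable(trait_label=outcome_label, trait_type="binary",
                             records=df, n_cases=n_cases, n_controls=n_controls)


def make_screen_panel(n_taxa: int = 7, n_causal: int = 3,
                      template: ScenarioConfig | None = None,
                      seed: int = 0, causal_beta: float = 0.3):
    """A multi-taxon discovery panel sharing one discovery and one replication
    outcome realization.

    Exactly ``n_causal`` taxa receive a nonzero causal effect, with signs
    alternating protective/risk (−, +, −, ...).  Each taxon has its own
    instrument variants; the two outcome tables concatenate all variants, the
    replication cohort re-drawing outcome noise at its own (FinnGen-scale)
    standard errors from the same latent truth.

    Returns ``(exposures, outcome_discovery, outcome_replication, truth)``.
    """
    if n_causal > n_taxa:
        raise ConfigurationError("n_causal must be <= n_taxa")
    template = template or ScenarioConfig()
    betas = np.zeros(n_taxa)
    sign = -1.0
    for i in range(n_causal):
        betas[i] = sign * causal_beta
        sign *= -1.0
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_taxa)
    betas = betas[order]

    exposures = []
    disc_parts, repl_parts = [], []
    truth_taxa = {}
    repl_template = template.replication()
    for i in range(n_taxa):
        label = f"taxon_{i}"
        cfg_d = replace(template, beta_true=float(betas[i]), exposure_label=label,
                        seed=seed * 10_007 + i, variant_prefix=f"t{i}rs")
        exp_tab, out_d, truth = simulate_study(cfg_d)
        out_r = simulate_outcome_from_truth(
            truth, n_cases=repl_template.n_cases, n_controls=repl_template.n_controls,
            seed=cfg_d.seed + 1_000_003,
            outcome_label=template.outcome_label + "_replication",
        )
        exposures.append(exp_tab)
        disc_parts.append(out_d.records)
        repl_parts.append(out_r.records)
        truth_taxa[label] = {"beta_true": float(betas[i]), "truth": truth}

    outcome_discovery = SummaryStatsTable(
        trait_label=template.outcome_label, trait_type="binary",
        records=pd.concat(disc_parts, ignore_index=True),
        n_cases=template.n_cases, n_controls=template.n_controls,
    )
    outcome_replication = SummaryStatsTable(
        trait_label=template.outcome_label + "_replication", trait_type="binary",
        records=pd.concat(repl_parts, ignore_index=True),
        n_cases=repl_template.n_cases, n_controls=repl_template.n_controls,
    )
    panel_truth = {"taxa": truth_taxa, "n_causal": n_causal, "seed": seed}
    return exposures, outcome_discovery, outcome_replication, panel_truth
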