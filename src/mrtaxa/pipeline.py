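"""Discovery → replication → meta-analysis orchestration, and reverse MR.

The inference design mirrors a bidirectional two-sample microbiome–disease
screen: every exposure (taxon) is tested against the binary outcome in a
discovery cohort with the full method battery (radial IVW as primary,
weighted median and MR-RAPS as pleiotropy-robust sensitivity analyses,
MR-PRESSO for outlier diagnostics); taxa whose *primary-method* p-value
clears ``alpha`` are re-tested in an independent replication cohort; a taxon
replicates when the replication primary estimate is significant with the
same sign; the two cohort estimates are combined by inverse-variance
meta-analysis (fixed-effect primary, DerSimonian–Laird alongside when
between-cohort heterogeneity is material).  Reverse MR runs the identical
machinery with the disease as exposure and the taxon as outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from . import gwas_io
from .errors import (
    ConfigurationError,
    EmptyInstrumentError,
    HarmonizationError,
    InputError,
    InsufficientInstrumentsError,
    MRTaxaError,
)
from .estimators import MREstimate, RadialIVW, RAPSEstimator, WeightedMedianMR
from .gwas_io import HarmonizedSet, SummaryStatsTable, harmonize, select_instruments
from .presso import MRPresso, PressoResult

logger = logging.getLogger(__name__)

PRIMARY_METHOD = "ivw_radial"


@dataclass
class MRConfig:
    """Thresholds and method options for a full pipeline run."""

    p_threshold: float = 1e-5            # forward instrument threshold
    reverse_p_threshold: float = 5e-8    # disease-as-exposure threshold
    f_min: float = 10.0
    palindrome_eaf_window: float = 0.08
    alpha: float = 0.05
    ivw_weighting: str = "first_order"
    ivw_model: str = "multiplicative_random"
    median_n_boot: int = 10_000
    raps_overdispersion: bool = True
    raps_loss: str = "huber"
    raps_huber_k: float = 1.345
    presso_n_sim: int = 1000
    presso_outlier_alpha: float = 0.05
    presso_n_boot: int = 1000
    run_presso: bool = True
    bh_correction: bool = False          # Benjamini-Hochberg across taxa, off by default
    dl_q_pval: float = 0.10              # report DL meta when between-cohort Q p < this
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MRConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


@dataclass
class MetaResult:
    """Inverse-variance combination of per-cohort causal estimates."""

    beta_meta: float
    se_meta: float
    pval_meta: float
    model: str                      # "fixed" or "dersimonian_laird"
    cochran_q_between: float
    q_pval_between: float
    tau2_between: float
    cohort_betas: tuple[float, ...]
    cohort_ses: tuple[float, ...]


@dataclass
class ScreenResult:
    """Everything computed for one exposure in one direction."""

    exposure_label: str
    direction: str = "forward"            # or "reverse"
    cohort: str = "discovery"             # discovery / replication / meta
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    presso: PressoResult | None = None
    passed_discovery: bool = False
    replicated: bool | None = None
    replication_estimates: dict[str, MREstimate] = field(default_factory=dict)
    replication_presso: PressoResult | None = None
    meta: MetaResult | None = None
    meta_dl_result: MetaResult | None = None
    status: str = "ok"                    # ok / harmonization_failed / ...
    status_detail: str = ""
    n_snp: int = 0
    exposure_table: SummaryStatsTable | None = field(default=None, repr=False)

    @property
    def primary(self) -> MREstimate | None:
        return self.estimates.get(PRIMARY_METHOD)

    @property
    def replication_primary(self) -> MREstimate | None:
        return self.replication_estimates.get(PRIMARY_METHOD)


def to_odds_ratio(e: MREstimate, ci_level: float = 0.95):
    """Map a log-odds estimate to (OR, CI low, CI high)."""
    if not 0 < ci_level < 1:
        raise ConfigurationError("ci_level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    return (float(np.exp(e.beta)),
            float(np.exp(e.beta - z * e.se)),
            float(np.exp(e.beta + z * e.se)))


def meta_fixed(estimates: list[MREstimate] | tuple[MREstimate, ...]) -> MetaResult:
    """Fixed-effect inverse-variance meta-analysis of cohort estimates."""
    return _meta(estimates, model="fixed")


def meta_dl(estimates: list[MREstimate] | tuple[MREstimate, ...]) -> MetaResult:
    """DerSimonian–Laird random-effects meta-analysis (reduces to fixed at τ²=0)."""
    return _meta(estimates, model="dersimonian_laird")


def _meta(estimates, model: str) -> MetaResult:
    if len(estimates) < 2:
        raise InputError("meta-analysis needs >= 2 estimates (single estimate passes through)")
    b = np.array([e.beta for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise InputError("meta-analysis requires positive SEs")
    w = 1.0 / se**2
    beta_f = float(np.sum(w * b) / np.sum(w))
    qb = float(np.sum(w * (b - beta_f) ** 2))
    dfb = len(b) - 1
    q_pval = float(stats.chi2.sf(qb, dfb))
    tau2 = 0.0
    if model == "dersimonian_laird":
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (qb - dfb) / c) if c > 0 else 0.0
        w = 1.0 / (se**2 + tau2)
    beta_m = float(np.sum(w * b) / np.sum(w))
    se_m = float(np.sum(w) ** -0.5)
    return MetaResult(
        beta_meta=beta_m, se_meta=se_m,
        pval_meta=float(2 * stats.norm.sf(abs(beta_m) / se_m)),
        model=model, cochran_q_between=qb, q_pval_between=q_pval,
        tau2_between=tau2,
        cohort_betas=tuple(map(float, b)), cohort_ses=tuple(map(float, se)),
    )


def _method_battery(h: HarmonizedSet, config: MRConfig, seed: int):
    """Run primary + sensitivity estimators on one harmonized set."""
    estimates: dict[str, MREstimate] = {}
    ivw_est = RadialIVW(weighting=config.ivw_weighting, model=config.ivw_model)
    ivw_est.fit_harmonized(h)
    estimates[PRIMARY_METHOD] = ivw_est.to_estimate()
    try:
        wm = WeightedMedianMR(n_boot=config.median_n_boot, seed=seed).fit_harmonized(h)
        estimates["weighted_median"] = wm.to_estimate()
    except InsufficientInstrumentsError as exc:
        logger.info("weighted median skipped: %s", exc)
    try:
        rp = RAPSEstimator(overdispersion=config.raps_overdispersion,
                           loss=config.raps_loss, huber_k=config.raps_huber_k)
        rp.fit_harmonized(h)
        estimates["raps"] = rp.to_estimate()
    except MRTaxaError as exc:
        logger.info("RAPS skipped: %s", exc)
    presso = None
    if config.run_presso:
        try:
            pr = MRPresso(n_sim=config.presso_n_sim,
                          outlier_alpha=config.presso_outlier_alpha,
                          n_boot=config.presso_n_boot, seed=seed)
            pr.fit_harmonized(h)
            presso = pr.result_
        except InsufficientInstrumentsError as exc:
            logger.info("MR-PRESSO skipped: %s", exc)
    return estimates, presso


def _prepare(exposure: SummaryStatsTable, outcome: SummaryStatsTable,
             config: MRConfig, p_threshold: float) -> HarmonizedSet:
    instruments = select_instruments(exposure, p_threshold=p_threshold,
                                     f_min=config.f_min)
    return harmonize(instruments, outcome,
                     palindrome_eaf_window=config.palindrome_eaf_window)


def run_forward_screen(exposures, outcome: SummaryStatsTable,
                       alpha: float | None = None,
                       config: MRConfig | None = None) -> list[ScreenResult]:
    """Discovery screen: full battery per exposure, gate on the primary method.

    ``passed_discovery`` is decided solely by the radial-IVW p-value against
    ``alpha``; exposures that fail instrument selection or harmonization are
    returned with a status instead of being silently dropped.
    """
    config = config or MRConfig()
    alpha = config.alpha if alpha is None else alpha
    exposures = list(exposures)
    if not exposures:
        raise ConfigurationError("empty exposure collection")
    if outcome.trait_type != "binary":
        raise ConfigurationError("discovery outcome must be a binary trait")
    results: list[ScreenResult] = []
    for i, exposure in enumerate(exposures):
        res = ScreenResult(exposure_label=exposure.trait_label, direction="forward",
                           cohort="discovery", exposure_table=exposure)
        try:
            h = _prepare(exposure, outcome, config, config.p_threshold)
        except (EmptyInstrumentError, HarmonizationError, InputError) as exc:
            res.status = "harmonization_failed"
            res.status_detail = str(exc)
            results.append(res)
            continue
        res.n_snp = h.n_snp
        res.estimates, res.presso = _method_battery(h, config, seed=config.seed + 7919 * i)
        res.passed_discovery = res.primary.pval < alpha
        results.append(res)
    if config.bh_correction:
        _apply_bh(results, alpha)
    return results


def _apply_bh(results: list[ScreenResult], alpha: float) -> None:
    ok = [r for r in results if r.status == "ok"]
    if not ok:
        return
    pvals = np.array([r.primary.pval for r in ok])
    order = np.argsort(pvals)
    m = len(pvals)
    passed = np.zeros(m, dtype=bool)
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = pvals[order] <= thresh
    if below.any():
        k = int(np.max(np.flatnonzero(below)))
        passed[order[: k + 1]] = True
    for r, p in zip(ok, passed):
        r.passed_discovery = bool(p)


def replicate_and_meta(screen: list[ScreenResult],
                       replication_outcome: SummaryStatsTable,
                       config: MRConfig | None = None,
                       exposures=None) -> list[ScreenResult]:
    """Replication + meta-analysis for every exposure that passed discovery.

    ``replicated`` requires the replication primary-method p-value below
    ``alpha`` *and* the same sign as the discovery estimate.  The fixed-effect
    meta of the two primary estimates is always attached; a DerSimonian–Laird
    meta is attached alongside when between-cohort Q has p < ``dl_q_pval``.
    Exposure tables default to those cached on the screen results.
    """
    config = config or MRConfig()
    exp_by_label = {e.trait_label: e for e in (exposures or [])}
    for i, res in enumerate(screen):
        if res.status != "ok" or not res.passed_discovery:
            continue
        exposure = exp_by_label.get(res.exposure_label, res.exposure_table)
        if exposure is None:
            res.status = "replication_input_missing"
            res.status_detail = "no exposure table supplied for replication"
            continue
        try:
            h = _prepare(exposure, replication_outcome, config, config.p_threshold)
        except (EmptyInstrumentError, HarmonizationError, InputError) as exc:
            res.replicated = False
            res.status = "non_replicable"
            res.status_detail = str(exc)
            continue
        res.replication_estimates, res.replication_presso = _method_battery(
            h, config, seed=config.seed + 104_729 + 7919 * i
        )
        rp = res.replication_primary
        dp = res.primary
        res.replicated = bool(rp.pval < config.alpha and np.sign(rp.beta) == np.sign(dp.beta))
        res.meta = meta_fixed([dp, rp])
        if res.meta.q_pval_between < config.dl_q_pval:
            res.meta_dl_result = meta_dl([dp, rp])
    return screen


def reverse_mr(outcome_as_exposure: SummaryStatsTable,
               taxon_as_outcome: SummaryStatsTable,
               config: MRConfig | None = None) -> ScreenResult:
    """Reverse-direction MR: disease as exposure, taxon abundance as outcome.

    Uses the (stricter) ``reverse_p_threshold`` for instrument selection since
    disease GWAS are well powered.  The headline contract is a null report
    when the latent truth has no disease→taxon effect.
    """
    config = config or MRConfig()
    if outcome_as_exposure.trait_type != "binary":
        raise ConfigurationError("reverse MR expects the disease (binary) trait as exposure")
    res = ScreenResult(exposure_label=outcome_as_exposure.trait_label,
                       direction="reverse", cohort="discovery")
    try:
        h = _prepare(outcome_as_exposure, taxon_as_outcome, config,
                     config.reverse_p_threshold)
    except (EmptyInstrumentError, HarmonizationError, InputError) as exc:
        res.status = "non_replicable"
        res.status_detail = str(exc)
        return res
    res.n_snp = h.n_snp
    res.estimates, res.presso = _method_battery(h, config, seed=config.seed + 15_485_863)
    res.passed_discovery = res.primary.pval < config.alpha
    return res
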