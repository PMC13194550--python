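"""MR-PRESSO: simulation-based pleiotropy residual-sum and outlier testing.

Three linked tests on a harmonized variant set:

* **global** — the observed leave-one-out residual sum of squares
  RSS_obs = Σⱼ rⱼ²/σ_Γⱼ² with rⱼ = Γ̂ⱼ − β̂₍₋ⱼ₎γ̂ⱼ (β̂₍₋ⱼ₎ the first-order
  IVW slope without variant j), compared against K parametric replicates
  drawn under the no-pleiotropy null;
* **outlier** — per-variant empirical p-values for each rⱼ² against the same
  simulation stream, Bonferroni-adjusted;
* **distortion** — the percent change of the IVW slope after removing the
  flagged outliers, with an empirical null from random same-size subsets of
  the non-outlier pool.

All empirical p-values use the add-one rule (#{extreme}+1)/(K+1), so the
smallest attainable p is 1/(K+1).  Identical (data, K, seed) give
bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .errors import ConfigurationError, InputError, InsufficientInstrumentsError
from .gwas_io import HarmonizedSet

NOT_APPLICABLE = "not_applicable"


@dataclass
class PressoResult:
    """Global / outlier / distortion test output."""

    rss_obs: float
    global_pval: float
    n_sim: int
    seed: int
    snp: np.ndarray
    outlier_pvals: np.ndarray | None = None
    outlier_pvals_adj: np.ndarray | None = None
    outlier_ids: tuple[str, ...] = ()
    beta_raw: float | None = None
    beta_corrected: float | None = None
    distortion_pct: float | None = None
    distortion_pval: float | None = None
    distortion_status: str = NOT_APPLICABLE

    def __post_init__(self):
        if self.rss_obs < 0:
            raise InputError("rss_obs must be >= 0")
        if not (0 < self.global_pval <= 1):
            raise InputError("global_pval must lie in (0, 1]")


def _empirical_p(n_extreme: int, n_sim: int) -> float:
    """Add-one empirical p-value: (#extreme + 1) / (K + 1)."""
    return (n_extreme + 1) / (n_sim + 1)


def _loo_slopes(gamma: np.ndarray, Gamma: np.ndarray, se_G: np.ndarray) -> np.ndarray:
    """First-order IVW slope excluding each variant in turn (vectorized).

    With w = γ²/σ_Γ² and wb = γΓ/σ_Γ², the slope without j is
    (Σwb − wbⱼ)/(Σw − wⱼ).  Supports a leading simulation axis.
    """
    w = gamma**2 / se_G**2
    wb = gamma * Gamma / se_G**2
    return (wb.sum(axis=-1, keepdims=True) - wb) / (w.sum(axis=-1, keepdims=True) - w)


def _rss(gamma: np.ndarray, Gamma: np.ndarray, se_G: np.ndarray):
    slopes = _loo_slopes(gamma, Gamma, se_G)
    r = Gamma - slopes * gamma
    return (r**2 / se_G**2).sum(axis=-1), r


def _ivw_fixed_slope(gamma, Gamma, se_G) -> float:
    w = gamma**2 / se_G**2
    return float(np.sum(w * (Gamma / gamma)) / np.sum(w))


class MRPresso(BaseEstimator):
    """MR-PRESSO test battery as a scikit-learn-style estimator.

    Parameters
    ----------
    n_sim : int
        Number K of parametric null replicates for the global/outlier tests.
    outlier_alpha : float
        Threshold on the Bonferroni-adjusted per-variant p-value.
    n_boot : int
        Resamples for the distortion-test null.
    seed : int
        Seed for the single RNG stream driving all three tests.
    run_distortion : bool
        Skip the distortion test when False.

    After ``fit``: ``result_`` (:class:`PressoResult`), ``beta_raw_``,
    ``beta_corrected_``, ``outlier_ids_``.
    """

    def __init__(self, n_sim: int = 1000, outlier_alpha: float = 0.05,
                 n_boot: int = 1000, seed: int = 0, run_distortion: bool = True):
        self.n_sim = n_sim
        self.outlier_alpha = outlier_alpha
        self.n_boot = n_boot
        self.seed = seed
        self.run_distortion = run_distortion

    def fit_harmonized(self, h: HarmonizedSet):
        return self.fit(h.gamma_hat, h.Gamma_hat, X_se=h.se_gamma, y_se=h.se_Gamma,
                        snp=h.snp)

    def fit(self, X, y, X_se=None, y_se=None, snp=None):
        if self.n_sim < 1:
            raise ConfigurationError("n_sim must be >= 1")
        g = np.ravel(np.asarray(X, dtype=float))
        G = np.ravel(np.asarray(y, dtype=float))
        sg = np.zeros_like(g) if X_se is None else np.ravel(np.asarray(X_se, dtype=float))
        if y_se is None:
            raise InputError("y_se (outcome standard errors) is required")
        sG = np.ravel(np.asarray(y_se, dtype=float))
        J = len(g)
        if J < 4:
            raise InsufficientInstrumentsError(
                f"MR-PRESSO needs >= 4 variants (leave-one-out IVW needs >= 3), got {J}"
            )
        if snp is None:
            snp = np.array([f"v{i}" for i in range(J)])
        snp = np.asarray(snp)

        rng = np.random.default_rng(self.seed)
        loo = _loo_slopes(g, G, sG)
        r_obs = G - loo * g
        rss_obs = float((r_obs**2 / sG**2).sum())

        # K parametric null replicates: Γ* centred on the LOO-predicted value
        K = self.n_sim
        G_star = rng.normal(loo * g, sG, size=(K, J))
        g_star = rng.normal(g, sg, size=(K, J))
        rss_star, r_star = _rss(g_star, G_star, sG)
        global_pval = _empirical_p(int((rss_star >= rss_obs).sum()), K)

        pvals = np.array([
            _empirical_p(int((r_star[:, j] ** 2 >= r_obs[j] ** 2).sum()), K)
            for j in range(J)
        ])
        pvals_adj = np.minimum(pvals * J, 1.0)
        out_mask = pvals_adj < self.outlier_alpha
        outlier_ids = tuple(snp[out_mask])

        beta_raw = _ivw_fixed_slope(g, G, sG)
        result = PressoResult(
            rss_obs=rss_obs, global_pval=global_pval, n_sim=K, seed=self.seed,
            snp=snp, outlier_pvals=pvals, outlier_pvals_adj=pvals_adj,
            outlier_ids=outlier_ids, beta_raw=beta_raw,
        )

        n_keep = J - len(outlier_ids)
        if outlier_ids and n_keep >= 3:
            keep = ~out_mask
            beta_corr = _ivw_fixed_slope(g[keep], G[keep], sG[keep])
            result.beta_corrected = beta_corr
            if self.run_distortion:
                result = self._distortion(result, g, G, sG, out_mask, rng)
        elif not outlier_ids:
            result.beta_corrected = beta_raw

        self.result_ = result
        self.beta_raw_ = result.beta_raw
        self.beta_corrected_ = result.beta_corrected
        self.outlier_ids_ = outlier_ids
        return self

    def _distortion(self, result: PressoResult, g, G, sG, out_mask, rng) -> PressoResult:
        if self.n_boot < 1:
            raise ConfigurationError("n_boot must be >= 1")
        n_out = int(out_mask.sum())
        pool = np.flatnonzero(~out_mask)
        if len(pool) < 3 or n_out == 0 or len(pool) <= n_out:
            return result
        obs = 100.0 * (result.beta_corrected - result.beta_raw) / abs(result.beta_raw)
        stats_null = np.empty(self.n_boot)
        all_idx = np.arange(len(g))
        for b in range(self.n_boot):
            drop = rng.choice(pool, size=n_out, replace=False)
            keep = np.setdiff1d(all_idx, drop, assume_unique=True)
            b_sub = _ivw_fixed_slope(g[keep], G[keep], sG[keep])
            stats_null[b] = 100.0 * (b_sub - result.beta_raw) / abs(result.beta_raw)
        # two-sided on magnitude: smallest attainable p is 1/(n_boot+1)
        result.distortion_pct = float(obs)
        result.distortion_pval = _empirical_p(
            int((np.abs(stats_null) >= abs(obs)).sum()), self.n_boot)
        result.distortion_status = "ok"
        return result


# --------------------------------------------------------------------------
# functional wrappers mirroring the three test stages
# --------------------------------------------------------------------------

def presso_global(h: HarmonizedSet, n_sim: int = 1000, seed: int = 0) -> PressoResult:
    """Global RSS test only."""
    est = MRPresso(n_sim=n_sim, seed=seed, run_distortion=False,
                   outlier_alpha=0.0)  # alpha 0: nothing flagged, global fields only
    est.fit_harmonized(h)
    return est.result_

def presso_outliers(h: HarmonizedSet, n_sim: int = 1000, outlier_alpha: float = 0.05,
                    seed: int = 0) -> PressoResult:
    """Global + per-variant outlier test (no distortion)."""
    est = MRPresso(n_sim=n_sim, outlier_alpha=outlier_alpha, seed=seed,
                   run_distortion=False)
    est.fit_harmonized(h)
    return est.result_


def presso_distortion(h: HarmonizedSet, n_sim: int = 1000, outlier_alpha: float = 0.05,
                      n_boot: int = 1000, seed: int = 0) -> PressoResult:
    """Full battery: global, outlier and distortion tests."""
    est = MRPresso(n_sim=n_sim, outlier_alpha=outlier_alpha, n_boot=n_boot,
                   seed=seed, run_distortion=True)
    est.fit_harmonized(h)
    return est.result_
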