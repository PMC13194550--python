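"""Two-sample MR estimators: radial IVW, weighted median and MR-RAPS.

All estimators consume per-variant exposure effects γ̂ⱼ (SE σ_γⱼ) and outcome
effects Γ̂ⱼ (SE σ_Γⱼ) on a shared effect-allele convention and estimate the
causal slope β — log-odds of the outcome per unit of the exposure when the
outcome is binary.  The shared primitive is the Wald ratio β̂ⱼ = Γ̂ⱼ/γ̂ⱼ with
an inverse-variance weight wⱼ; IVW is the weighted mean of the ratios, which
is algebraically identical to the slope of the radial (origin-constrained)
regression of β̂ⱼ√wⱼ on √wⱼ.

The classes follow the scikit-learn estimator protocol: ``fit(X, y, X_se=,
y_se=)`` with 1-D effect arrays, fitted attributes with trailing underscores
(``beta_``, ``se_``, ``pval_``, ...), ``get_params``/``set_params`` inherited
from :class:`sklearn.base.BaseEstimator`, and ``predict(X) = beta_ * X``.
``fit_harmonized`` accepts a :class:`~mrtaxa.gwas_io.HarmonizedSet` directly.
Module-level functions (:func:`ivw`, :func:`weighted_median`, :func:`raps`,
:func:`cochran_q`) are thin wrappers returning :class:`MREstimate` records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import EstimationError, InputError, InsufficientInstrumentsError
from .gwas_io import HarmonizedSet

WEIGHTINGS = ("first_order", "second_order", "modified_second_order")


@dataclass
class MREstimate:
    """One estimator's output on the log-odds scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    tau2: float | None = None
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        if self.se <= 0:
            raise InputError(f"MREstimate se must be > 0, got {self.se}")


@dataclass
class RatioSet:
    """Per-variant Wald ratios β̂ⱼ = Γ̂ⱼ/γ̂ⱼ and weights wⱼ."""

    snp: np.ndarray
    ratio: np.ndarray
    weight: np.ndarray
    weighting: str

    def __post_init__(self):
        if len(self.ratio) != len(self.weight):
            raise InputError("ratio/weight length mismatch")
        if not np.all(np.isfinite(self.weight)) or np.any(self.weight <= 0):
            raise InputError("weights must be strictly positive and finite")


def _two_sided_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _as_arrays(X, y, X_se, y_se):
    X = np.ravel(np.asarray(X, dtype=float))
    y = np.ravel(np.asarray(y, dtype=float))
    if X.shape != y.shape:
        raise InputError(f"X and y length mismatch: {X.shape} vs {y.shape}")
    X_se = np.zeros_like(X) if X_se is None else np.ravel(np.asarray(X_se, dtype=float))
    if y_se is None:
        raise InputError("y_se (outcome standard errors) is required")
    y_se = np.ravel(np.asarray(y_se, dtype=float))
    if np.any(y_se <= 0):
        raise InputError("y_se must be strictly positive")
    if np.any(X_se < 0):
        raise InputError("X_se must be non-negative")
    return X, y, X_se, y_se


def _drop_zero_gamma(gamma, Gamma, se_g, se_G, snp=None):
    nz = gamma != 0
    if not nz.any():
        raise InputError("all exposure effects are zero: Wald ratios undefined")
    if not nz.all():
        warnings.warn(f"dropping {int((~nz).sum())} variants with zero exposure effect")
    if snp is None:
        snp = np.array([f"v{i}" for i in range(len(gamma))])
    return gamma[nz], Gamma[nz], se_g[nz], se_G[nz], np.asarray(snp)[nz]


def _weights(gamma, Gamma, se_g, se_G, weighting: str, max_iter: int = 100,
             tol: float = 1e-8) -> np.ndarray:
    if weighting == "first_order":
        return gamma**2 / se_G**2
    if weighting == "second_order":
        return 1.0 / (se_G**2 / gamma**2 + Gamma**2 * se_g**2 / gamma**4)
    if weighting == "modified_second_order":
        # iterate the IVW slope into the delta term: Γ̂² -> (β_F γ̂)²
        w = gamma**2 / se_G**2
        ratio = Gamma / gamma
        beta = np.sum(w * ratio) / np.sum(w)
        for _ in range(max_iter):
            w = 1.0 / (se_G**2 / gamma**2 + (beta * gamma) ** 2 * se_g**2 / gamma**4)
            beta_new = np.sum(w * ratio) / np.sum(w)
            if abs(beta_new - beta) < tol:
                beta = beta_new
                break
            beta = beta_new
        return 1.0 / (se_G**2 / gamma**2 + (beta * gamma) ** 2 * se_g**2 / gamma**4)
    raise InputError(f"unknown weighting {weighting!r}; choose from {WEIGHTINGS}")


def wald_ratios(h: HarmonizedSet, weighting: str = "first_order") -> RatioSet:
    """Per-variant Wald ratios Γ̂ⱼ/γ̂ⱼ with the selected radial weighting.

    Variants with γ̂ⱼ = 0 are dropped with a warning; an all-zero exposure is
    a degenerate-input error.
    """
    g, G, sg, sG, snp = _drop_zero_gamma(
        h.gamma_hat, h.Gamma_hat, h.se_gamma, h.se_Gamma, h.snp
    )
    return RatioSet(snp=snp, ratio=G / g, weight=_weights(g, G, sg, sG, weighting),
                    weighting=weighting)


class _MRRegressor(RegressorMixin, BaseEstimator):
    """Shared fit plumbing: validates arrays and stores kept variants."""

    _min_snp = 1

    def _validate(self, X, y, X_se, y_se, snp=None):
        X, y, X_se, y_se = _as_arrays(X, y, X_se, y_se)
        g, G, sg, sG, snp = _drop_zero_gamma(X, y, X_se, y_se, snp)
        if len(g) < self._min_snp:
            raise InsufficientInstrumentsError(
                f"{type(self).__name__} needs >= {self._min_snp} variants, got {len(g)}"
            )
        self.snp_ = snp
        self.n_snp_ = len(g)
        return g, G, sg, sG

    def fit_harmonized(self, h: HarmonizedSet):
        """Fit from a harmonized exposure/outcome set."""
        return self.fit(h.gamma_hat, h.Gamma_hat, X_se=h.se_gamma, y_se=h.se_Gamma,
                        snp=h.snp)

    def predict(self, X):
        return self.beta_ * np.ravel(np.asarray(X, dtype=float))

    def _finalize(self, beta: float, se: float):
        self.beta_ = float(beta)
        self.se_ = float(se)
        self.pval_ = _two_sided_p(self.beta_, self.se_)
        return self


class RadialIVW(_MRRegressor):
    """Radial inverse-variance-weighted estimator (the primary method).

    β̂ = Σ wⱼ β̂ⱼ / Σ wⱼ over Wald ratios β̂ⱼ, identical to the slope of the
    origin-constrained regression of β̂ⱼ√wⱼ on √wⱼ.  ``model="fixed"`` uses
    SE = (Σwⱼ)^(−1/2); ``"multiplicative_random"`` inflates it by
    max(1, √(Q/(J−1))) where Q = Σ wⱼ(β̂ⱼ−β̂)² is Cochran's Q.  Per-variant
    radial Q contributions are exposed as ``q_contributions_`` for outlier
    diagnostics.

    A single instrument falls back to its Wald ratio with first-order SE,
    recorded in ``warnings_``.
    """

    _min_snp = 1

    def __init__(self, weighting: str = "first_order",
                 model: str = "multiplicative_random"):
        self.weighting = weighting
        self.model = model

    def fit(self, X, y, X_se=None, y_se=None, snp=None):
        if self.model not in ("fixed", "multiplicative_random"):
            raise InputError(f"unknown IVW model {self.model!r}")
        g, G, sg, sG = self._validate(X, y, X_se, y_se, snp)
        w = _weights(g, G, sg, sG, self.weighting)
        ratio = G / g
        beta = float(np.sum(w * ratio) / np.sum(w))
        se_fixed = float(np.sum(w) ** -0.5)
        self.warnings_: tuple[str, ...] = ()
        if self.n_snp_ == 1:
            self.method_ = "ivw_fe"
            self.warnings_ = ("single instrument: Wald-ratio fallback",)
            self.q_stat_ = None
            self.q_df_ = None
            self.q_pval_ = None
            self.q_contributions_ = np.zeros(1)
            return self._finalize(beta, se_fixed)
        qj = w * (ratio - beta) ** 2
        q = float(qj.sum())
        df = self.n_snp_ - 1
        self.q_stat_ = q
        self.q_df_ = df
        self.q_pval_ = float(stats.chi2.sf(q, df))
        self.q_contributions_ = qj
        if self.model == "multiplicative_random":
            se = se_fixed * max(1.0, np.sqrt(q / df))
            self.method_ = "ivw_radial"
        else:
            se = se_fixed
            self.method_ = "ivw_fe"
        return self._finalize(beta, se)

    def to_estimate(self) -> MREstimate:
        return MREstimate(
            method=self.method_, beta=self.beta_, se=self.se_, pval=self.pval_,
            n_snp=self.n_snp_, q_stat=self.q_stat_, q_df=self.q_df_,
            q_pval=self.q_pval_, warnings=self.warnings_,
        )


def _weighted_median_sorted(ratio_sorted: np.ndarray, w_sorted: np.ndarray) -> float:
    """Interpolated weighted median from value-sorted ratios and weights."""
    wn = w_sorted / w_sorted.sum()
    s = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, s, ratio_sorted))


def _weighted_median(ratio: np.ndarray, weight: np.ndarray) -> float:
    order = np.argsort(ratio, kind="stable")
    return _weighted_median_sorted(ratio[order], weight[order])


class WeightedMedianMR(_MRRegressor):
    """Weighted-median estimator, consistent when ≥50% of weight is valid.

    Ratios are sorted; with first-order weights normalized to sum 1 the
    cumulative midpoints sⱼ = Σ_{k≤j} w'ₖ − w'ⱼ/2 define a piecewise-linear
    quantile function, evaluated at 0.5.  The SE is the standard deviation of
    the estimate over ``n_boot`` parametric resamples γ̂ⱼ* ~ N(γ̂ⱼ, σ_γⱼ²),
    Γ̂ⱼ* ~ N(Γ̂ⱼ, σ_Γⱼ²).
    """

    _min_snp = 3

    def __init__(self, n_boot: int = 10_000, seed: int = 0):
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, X, y, X_se=None, y_se=None, snp=None):
        if self.n_boot < 2:
            raise InputError("n_boot must be >= 2")
        g, G, sg, sG = self._validate(X, y, X_se, y_se, snp)
        w = g**2 / sG**2
        beta = _weighted_median(G / g, w)
        rng = np.random.default_rng(self.seed)
        gs = rng.normal(g, sg, size=(self.n_boot, len(g)))
        Gs = rng.normal(G, sG, size=(self.n_boot, len(g)))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = Gs / gs
            wb = gs**2 / sG**2
        # a resampled γ* of exactly 0 has probability 0; guard regardless
        bad = ~np.isfinite(ratios)
        if bad.any():
            ratios[bad] = 0.0
            wb[bad] = 1e-300
        order = np.argsort(ratios, axis=1, kind="stable")
        r_s = np.take_along_axis(ratios, order, axis=1)
        w_s = np.take_along_axis(wb, order, axis=1)
        w_s = w_s / w_s.sum(axis=1, keepdims=True)
        s = np.cumsum(w_s, axis=1) - w_s / 2.0
        boots = np.empty(self.n_boot)
        below = (s < 0.5).sum(axis=1)  # index of first midpoint >= 0.5
        J = len(g)
        for k in range(self.n_boot):
            j = below[k]
            if j == 0:
                boots[k] = r_s[k, 0]
            elif j == J:
                boots[k] = r_s[k, -1]
            else:
                s0, s1 = s[k, j - 1], s[k, j]
                boots[k] = r_s[k, j - 1] + (0.5 - s0) / (s1 - s0) * (r_s[k, j] - r_s[k, j - 1])
        self.boot_estimates_ = boots
        self.method_ = "weighted_median"
        return self._finalize(beta, boots.std(ddof=1))

    def to_estimate(self) -> MREstimate:
        return MREstimate(method="weighted_median", beta=self.beta_, se=self.se_,
                          pval=self.pval_, n_snp=self.n_snp_)


@lru_cache(maxsize=8)
def _huber_c_psi(k: float) -> float:
    """c_ψ = E[ψ(Z)Z] for the Huber ψ with tuning constant k, Z ~ N(0,1)."""
    val, _ = integrate.quad(
        lambda z: np.clip(z, -k, k) * z * stats.norm.pdf(z), -np.inf, np.inf
    )
    return float(val)


class RAPSEstimator(_MRRegressor):
    """Robust adjusted profile score (MR-RAPS).

    With standardized residual tⱼ(β, τ²) = (Γ̂ⱼ − βγ̂ⱼ)/√(σ_Γⱼ² + β²σ_γⱼ² + τ²),
    the plain l2 fit maximizes the profile log-likelihood −½Σtⱼ(β,0)².  With
    overdispersion, (β̂, τ̂²) jointly solve

        Σ ψ(tⱼ) ∂tⱼ/∂β = 0,
        Σ (ψ(tⱼ)tⱼ − c_ψ) / (σ_Γⱼ² + β²σ_γⱼ² + τ²) = 0,   τ² ≥ 0,

    where ψ is the identity (l2) or the Huber function with ``huber_k``
    (default 1.345) and c_ψ = E[ψ(Z)Z] under a standard normal (1 for l2,
    quadrature for Huber).  SE from a numerically differentiated sandwich at
    the solution.  Root-finding is bracketed scalar iteration starting at the
    first-order IVW slope, tolerance 1e-8, up to 200 alternations.
    """

    _min_snp = 3

    def __init__(self, overdispersion: bool = True, loss: str = "huber",
                 huber_k: float = 1.345, tol: float = 1e-8, max_iter: int = 200):
        self.overdispersion = overdispersion
        self.loss = loss
        self.huber_k = huber_k
        self.tol = tol
        self.max_iter = max_iter

    # --- loss pieces -----------------------------------------------------
    def _psi(self, t):
        if self.loss == "l2":
            return t
        if self.loss == "huber":
            return np.clip(t, -self.huber_k, self.huber_k)
        raise InputError(f"unknown loss {self.loss!r}")

    def _c_psi(self) -> float:
        return 1.0 if self.loss == "l2" else _huber_c_psi(self.huber_k)

    @staticmethod
    def _t(beta, tau2, g, G, sg, sG):
        v = sG**2 + beta**2 * sg**2 + tau2
        return (G - beta * g) / np.sqrt(v), v

    def _score_beta(self, beta, tau2, g, G, sg, sG):
        t, v = self._t(beta, tau2, g, G, sg, sG)
        dt = -g / np.sqrt(v) - (G - beta * g) * beta * sg**2 * v**-1.5
        return float(np.sum(self._psi(t) * dt)), t, dt

    def _score_tau2(self, tau2, beta, g, G, sg, sG):
        t, v = self._t(beta, tau2, g, G, sg, sG)
        return float(np.sum((self._psi(t) * t - self._c_psi()) / v))

    def _solve_beta(self, tau2, beta0, g, G, sg, sG) -> float:
        f = lambda b: self._score_beta(b, tau2, g, G, sg, sG)[0]
        # the Huber score saturates toward 0 at large |β|, so expand a grid
        # around the iterate and bracket the sign change nearest to it
        width = 0.5 + abs(beta0)
        for _ in range(40):
            grid = beta0 + np.linspace(-width, width, 81)
            vals = np.array([f(b) for b in grid])
            sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
            # score is the negative gradient: only upward crossings are
            # likelihood maxima (a gross outlier creates a spurious minimum)
            sign_change = sign_change[(vals[sign_change] < 0) & (vals[sign_change + 1] > 0)]
            if len(sign_change):
                # pick the bracket closest to the current iterate
                mid = grid[sign_change] + (grid[1] - grid[0]) / 2
                i = sign_change[np.argmin(np.abs(mid - beta0))]
                # inner solves run well below the outer tolerance, otherwise
                # the (β, τ²) alternation stalls in a root-precision limit cycle
                return float(optimize.brentq(f, grid[i], grid[i + 1],
                                             xtol=self.tol * 1e-4))
            exact = np.flatnonzero(vals == 0)
            if len(exact):
                return float(grid[exact[0]])
            width *= 2.0
        raise EstimationError("could not bracket the profile-score root",
                              last_iterate=beta0)

    def _solve_tau2(self, beta, g, G, sg, sG) -> float:
        # score is decreasing in τ²; clamp at 0 when already non-positive there
        f = lambda t2: self._score_tau2(t2, beta, g, G, sg, sG)
        if f(0.0) <= 0:
            return 0.0
        hi = float(np.mean(sG**2) + 1.0)
        n_expand = 0
        while f(hi) > 0 and n_expand < 200:
            hi *= 2.0
            n_expand += 1
        if f(hi) > 0:
            raise EstimationError("overdispersion score has no root", last_iterate=beta)
        return float(optimize.brentq(f, 0.0, hi, xtol=self.tol * 1e-4))

    # ---------------------------------------------------------------------
    def fit(self, X, y, X_se=None, y_se=None, snp=None):
        g, G, sg, sG = self._validate(X, y, X_se, y_se, snp)
        w1 = g**2 / sG**2
        beta = float(np.sum(w1 * (G / g)) / np.sum(w1))  # first-order IVW start
        tau2 = 0.0
        converged = False
        for _ in range(self.max_iter):
            beta_new = self._solve_beta(tau2, beta, g, G, sg, sG)
            tau2_new = self._solve_tau2(beta_new, g, G, sg, sG) if self.overdispersion else 0.0
            if abs(beta_new - beta) < self.tol and abs(tau2_new - tau2) < self.tol:
                beta, tau2 = beta_new, tau2_new
                converged = True
                break
            beta, tau2 = beta_new, tau2_new
        if not converged:
            raise EstimationError(
                f"RAPS did not converge in {self.max_iter} iterations",
                last_iterate=(beta, tau2),
            )
        self.tau2_ = tau2
        self.converged_ = True
        self.method_ = "raps"
        # sandwich: A = ds/dβ by central difference (score is the negative
        # log-likelihood gradient, so A > 0 at a maximum), B = Σ score_j²
        eps = 1e-5 * (1.0 + abs(beta))
        s_plus = self._score_beta(beta + eps, tau2, g, G, sg, sG)[0]
        s_minus = self._score_beta(beta - eps, tau2, g, G, sg, sG)[0]
        A = (s_plus - s_minus) / (2 * eps)
        _, t, dt = self._score_beta(beta, tau2, g, G, sg, sG)
        B = float(np.sum((self._psi(t) * dt) ** 2))
        if A <= 0:
            raise EstimationError("non-positive curvature at RAPS solution",
                                  last_iterate=(beta, tau2))
        return self._finalize(beta, np.sqrt(B) / A)

    def to_estimate(self) -> MREstimate:
        return MREstimate(method="raps", beta=self.beta_, se=self.se_, pval=self.pval_,
                          n_snp=self.n_snp_, tau2=self.tau2_)


# --------------------------------------------------------------------------
# functional wrappers
# --------------------------------------------------------------------------

def ivw(h: HarmonizedSet, weighting: str = "first_order",
        model: str = "multiplicative_random") -> MREstimate:
    """Radial IVW estimate from a harmonized set (see :class:`RadialIVW`)."""
    return RadialIVW(weighting=weighting, model=model).fit_harmonized(h).to_estimate()


def weighted_median(h: HarmonizedSet, n_boot: int = 10_000, seed: int = 0) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap SE."""
    return WeightedMedianMR(n_boot=n_boot, seed=seed).fit_harmonized(h).to_estimate()


def raps(h: HarmonizedSet, overdispersion: bool = True, loss: str = "huber",
         huber_k: float = 1.345) -> MREstimate:
    """MR-RAPS estimate (see :class:`RAPSEstimator`)."""
    est = RAPSEstimator(overdispersion=overdispersion, loss=loss, huber_k=huber_k)
    return est.fit_harmonized(h).to_estimate()


def cochran_q(h: HarmonizedSet, weighting: str = "first_order"):
    """Cochran's Q about the IVW slope with per-variant radial contributions.

    Returns ``(q_stat, q_df, q_pval, contributions)``; requires ≥2 variants.
    """
    if h.n_snp < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 variants")
    est = RadialIVW(weighting=weighting, model="fixed").fit_harmonized(h)
    return est.q_stat_, est.q_df_, est.q_pval_, est.q_contributions_
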