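"""Two-component Gaussian mixture fitting for screen LGR distributions.

The screen model is a five-parameter bimodal normal mixture

    f(x) = (1 - rho2) * N(x; mu1, sigma1^2) + rho2 * N(x; mu2, sigma2^2)

where Component 1 is the central (null) peak — an empirical null whose
spread reflects measurement noise — and Component 2 is the right-shifted hit
peak.  Fitting is by EM with unequal variances, multiple starts (quantile
split plus random restarts), a variance floor against singular collapse, and
relabeling so mu2 >= mu1.  Fits are classified as hit_peak / no_hit_peak /
high_variance; posterior-based cutoffs downstream are only offered for
hit_peak fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

HIT_PEAK = "hit_peak"
NO_HIT_PEAK = "no_hit_peak"
HIGH_VARIANCE = "high_variance"

_MIN_N = 50
_LOG_2PI = math.log(2.0 * math.pi)


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class FitConfig:
    """EM fitting and classification settings."""

    tol: float = 1e-8
    max_iter: int = 1000
    n_starts: int = 10
    variance_floor: float | None = None  # absolute; default 1e-4 * sample variance
    seed: int = 0
    classify_mu2_min: float = 2.0   # (mu2 - mu1)/sigma1 below this -> no_hit_peak
    classify_sigma2_max: float = 4.0  # sigma2/sigma1 above this -> high_variance
    classify_rho2_min: float = 0.01  # hit peak must carry >= 1% of strains

    def __post_init__(self) -> None:
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class MixtureFit:
    """Fitted five-parameter bimodal normal mixture with diagnostics."""

    rho2: float
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    loglik: float
    n: int
    n_iter: int
    converged: bool
    classification: str = ""
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    @property
    def rho1(self) -> float:
        return 1.0 - self.rho2

    def params(self) -> tuple[float, float, float, float, float]:
        return (self.rho2, self.mu1, self.sigma1, self.mu2, self.sigma2)


def component_density(x, fit: MixtureFit, k: int):
    """Density of component k (1 = central/null, 2 = hit) at x, without its weight."""
    if k == 1:
        return norm.pdf(x, fit.mu1, fit.sigma1)
    if k == 2:
        return norm.pdf(x, fit.mu2, fit.sigma2)
    raise ValueError("component k must be 1 or 2")


def mixture_density(x, fit: MixtureFit):
    """Mixture density (1-rho2)*N(mu1,sigma1^2) + rho2*N(mu2,sigma2^2) at x."""
    return fit.rho1 * component_density(x, fit, 1) + fit.rho2 * component_density(x, fit, 2)


def _log_weighted_densities(x: np.ndarray, rho2: float, mu: np.ndarray,
                            var: np.ndarray) -> np.ndarray:
    """(n, 2) array of log(rho_k) + log N(x; mu_k, var_k)."""
    log_rho = np.log(np.clip([1.0 - rho2, rho2], 1e-300, None))
    z2 = (x[:, None] - mu[None, :]) ** 2 / var[None, :]
    return log_rho[None, :] - 0.5 * (np.log(var)[None, :] + _LOG_2PI + z2)


def _em_once(x: np.ndarray, rho2: float, mu: np.ndarray, var: np.ndarray,
             config: FitConfig, var_floor: float) -> MixtureFit:
    n = x.size
    trace: list[float] = []
    converged = False
    ll_prev = -np.inf
    it = 0
    for it in range(1, config.max_iter + 1):
        log_wd = _log_weighted_densities(x, rho2, mu, var)
        log_norm = logsumexp(log_wd, axis=1)
        ll = float(log_norm.sum())
        trace.append(ll)
        if np.isfinite(ll_prev):
            denom = max(abs(ll_prev), 1.0)
            if abs(ll - ll_prev) / denom < config.tol:
                converged = True
                break
        ll_prev = ll
        resp = np.exp(log_wd - log_norm[:, None])  # (n, 2) responsibilities
        nk = resp.sum(axis=0)
        nk = np.clip(nk, 1e-12, None)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, var_floor)
        rho2 = float(nk[1] / n)

    # relabel so component 2 is the right peak
    if mu[1] < mu[0]:
        mu = mu[::-1].copy()
        var = var[::-1].copy()
        rho2 = 1.0 - rho2

    return MixtureFit(
        rho2=rho2, mu1=float(mu[0]), sigma1=float(math.sqrt(var[0])),
        mu2=float(mu[1]), sigma2=float(math.sqrt(var[1])),
        loglik=trace[-1], n=n, n_iter=it, converged=converged,
        loglik_trace=np.asarray(trace),
    )


def _initializations(x: np.ndarray, config: FitConfig):
    """Quantile-split starts: Component 2 seeded from the top-q tail."""
    rng = np.random.default_rng(config.seed)
    quantiles = np.array([0.05, 0.10, 0.15, 0.20, 0.25, 0.30])
    sample_var = float(x.var(ddof=1))
    for start in range(config.n_starts):
        q = quantiles[start % len(quantiles)] if start < len(quantiles) \
            else float(rng.choice(quantiles))
        cut = np.quantile(x, 1.0 - q)
        top = x[x >= cut]
        rest = x[x < cut]
        if top.size < 2 or rest.size < 2:
            mu = np.array([x.mean() - 0.5 * x.std(), x.mean() + 0.5 * x.std()])
            var = np.array([sample_var, sample_var])
            rho2 = 0.5
        else:
            mu = np.array([rest.mean(), top.mean()])
            var = np.array([max(rest.var(), 1e-12), max(top.var(), 1e-12)])
            rho2 = q
        if start >= len(quantiles):  # random restart: jitter the seeds
            mu = mu + rng.normal(0, 0.25 * x.std(), size=2)
            var = var * rng.uniform(0.5, 2.0, size=2)
        yield rho2, mu, var


def fit_mixture(lgrs, config: FitConfig | None = None) -> MixtureFit:
    """Best-of-n_starts EM fit of the two-component mixture to smoothed LGRs.

    Requires >= 50 finite values.  Ties in best log-likelihood (within 1e-9)
    are broken toward the smallest rho2 (most conservative hit fraction).
    The returned fit carries its per-iteration log-likelihood trace, which is
    non-decreasing, and a classification from :func:`classify_fit`.
    """
    config = config or FitConfig()
    x = np.asarray(lgrs, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < _MIN_N:
        raise InsufficientDataError(
            f"insufficient data: {x.size} finite values, need >= {_MIN_N}"
        )
    sample_var = float(x.var(ddof=1))
    if sample_var == 0:
        raise InsufficientDataError("insufficient data: zero variance")
    var_floor = config.variance_floor if config.variance_floor is not None \
        else 1e-4 * sample_var

    best: MixtureFit | None = None
    for rho2, mu, var in _initializations(x, config):
        fit = _em_once(x, rho2, mu.copy(), np.maximum(var, var_floor), config, var_floor)
        if best is None or fit.loglik > best.loglik + 1e-9 or (
                abs(fit.loglik - best.loglik) <= 1e-9 and fit.rho2 < best.rho2):
            best = fit
    assert best is not None

    degenerate = (min(best.sigma1, best.sigma2) ** 2 <= var_floor * (1 + 1e-9)
                  and best.rho2 < 1.0 / best.n)
    if degenerate:
        best.converged = False
    best.classification = classify_fit(best, config)
    return best


def classify_fit(fit: MixtureFit, config: FitConfig | None = None) -> str:
    """Label a fit by hit-peak quality.

    no_hit_peak when the hit peak is too close to the central peak
    ((mu2-mu1)/sigma1 < classify_mu2_min) or carries negligible weight
    (rho2 below 1/n and below classify_rho2_min — on near-normal data EM
    happily assigns a few extreme tail points to a well-separated but
    meaningless second component); high_variance when sigma2/sigma1 >
    classify_sigma2_max (validation prediction unreliable); else hit_peak.
    """
    config = config or FitConfig()
    if (fit.mu2 - fit.mu1) / fit.sigma1 < config.classify_mu2_min:
        return NO_HIT_PEAK
    rho2_floor = max(1.0 / fit.n if fit.n else 0.0, config.classify_rho2_min)
    if fit.rho2 < rho2_floor:
        return NO_HIT_PEAK
    if fit.sigma2 / fit.sigma1 > config.classify_sigma2_max:
        return HIGH_VARIANCE
    return HIT_PEAK


@dataclass(frozen=True)
class ModelComparison:
    """Mixture vs single-normal comparison; negative delta_bic favors the mixture."""

    loglik_mixture: float
    loglik_normal: float
    delta_loglik: float
    bic_mixture: float
    bic_normal: float
    delta_bic: float


def compare_unimodal(lgrs, fit: MixtureFit) -> ModelComparison:
    """Compare the 5-parameter mixture against a 2-parameter normal by BIC."""
    x = np.asarray(lgrs, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    mu, sd = x.mean(), x.std(ddof=0)  # MLE
    ll_normal = float(norm.logpdf(x, mu, sd).sum())
    ll_mix = fit.loglik
    bic_mix = -2.0 * ll_mix + 5.0 * math.log(n)
    bic_normal = -2.0 * ll_normal + 2.0 * math.log(n)
    return ModelComparison(
        loglik_mixture=ll_mix, loglik_normal=ll_normal,
        delta_loglik=ll_mix - ll_normal,
        bic_mixture=bic_mix, bic_normal=bic_normal,
        delta_bic=bic_mix - bic_normal,
    )


def normal_interval_mass(lo: float, hi: float) -> float:
    """Probability mass of the standard normal on (lo, hi)."""
    return float(norm.cdf(hi) - norm.cdf(lo))
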