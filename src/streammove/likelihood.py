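"""Joint likelihood of the dispersal-observation model.

Movement: the end location of replicate ``i`` follows a location-scale
Student-t centred on the start location,

    X1_i | X0_i ~ t_nu(X0_i, sigma_i),

with the *dispersion* (not the mean) linked to predictors on the log scale,

    ln sigma_i = beta0 + sum_k beta_k x_ki + ln eta_i,

where ``eta_i`` is the elapsed days between occasions, entering as an offset
so ``exp(beta0)`` reads as a per-day scale.  ``sigma`` is the t *scale*
parameter (the BUGS/JAGS convention ``dt(mu, 1/sigma^2, nu)``); for nu = 5
the kernel's true standard deviation is ``sigma * sqrt(5/3)``.

Observation: a fish is recaptured (Y = 1) only if it stayed in the reach
(z = 1, i.e. 0 <= X1 <= L) *and* survived, kept its tag and was detected —
a compound probability ``phi``:

    Y_i ~ Bernoulli(phi * z_i).

For unrecaptured replicates the latent X1 can be marginalized in closed
form, ``P(Y=0) = 1 - phi * P(0 <= X1 <= L)``, which is the primary
computational path; the augmented path (explicit latent-X1 draws) lives in
the sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import gammaln, stdtr

from .io import MovementReplicate

_LOG_FLOOR = 1e-300


class ClipCounter:
    """Counts likelihood evaluations whose log argument hit the numeric
    floor (1e-300), e.g. ln(1 - phi*z) with phi*z -> 1.  A non-zero count
    flags a sampler excursion into a numerically degenerate corner."""

    def __init__(self):
        self.count = 0

    def reset(self):
        self.count = 0


clip_counter = ClipCounter()


def _safe_log(a: np.ndarray | float) -> np.ndarray | float:
    a = np.asarray(a, dtype=float)
    clipped = a < _LOG_FLOOR
    if np.any(clipped):
        clip_counter.count += int(np.sum(clipped))
        a = np.clip(a, _LOG_FLOOR, None)
    return np.log(a)


@dataclass
class ModelParams:
    """Movement and observation parameters for one species' model."""

    beta0: float
    beta: np.ndarray
    phi: float
    beta_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.beta_names and len(self.beta_names) != self.beta.size:
            raise ValueError("beta_names length does not match beta")


@dataclass
class ModelConfig:
    """Fixed model constants and prior hyperparameters.

    nu is fixed (not estimated); nu > 2 keeps the kernel variance finite.
    Priors are weakly informative: N(0, 2.5^2) intercept, N(0, 1) slopes,
    and a Normal(0.5, 1) truncated to (0, 1) for phi.
    """

    nu: float = 5.0
    L: float = 430.0
    prior_sd_intercept: float = 2.5
    prior_sd_beta: float = 1.0
    phi_prior_mean: float = 0.5
    phi_prior_sd: float = 1.0
    phi_lower: float = 0.0
    phi_upper: float = 1.0

    def __post_init__(self):
        if self.nu <= 0 or self.L <= 0:
            raise ValueError("nu and L must be positive")

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("nu", "L", "prior_sd_intercept", "prior_sd_beta"):
            if key in raw:
                kwargs[key] = float(raw[key])
        phi = raw.get("phi_prior", {})
        if "mean" in phi:
            kwargs["phi_prior_mean"] = float(phi["mean"])
        if "sd" in phi:
            kwargs["phi_prior_sd"] = float(phi["sd"])
        if "lower" in phi:
            kwargs["phi_lower"] = float(phi["lower"])
        if "upper" in phi:
            kwargs["phi_upper"] = float(phi["upper"])
        return cls(**kwargs)


def log_sigma(params: ModelParams, x, eta_days: float) -> float:
    """Linear predictor of the log dispersion: beta0 + beta.x + ln(eta)."""
    x = np.asarray(x, dtype=float)
    if x.shape != params.beta.shape:
        raise ValueError(
            f"covariate vector length {x.size} does not match beta "
            f"length {params.beta.size}"
        )
    if eta_days <= 0:
        raise ValueError("eta_days must be positive")
    return float(params.beta0 + params.beta @ x + math.log(eta_days))


def t_logpdf(x1, x0, sigma, nu):
    """Log density of a location-scale Student-t at x1 (location x0)."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    if nu <= 0:
        raise ValueError("nu must be positive")
    z = (np.asarray(x1, dtype=float) - np.asarray(x0, dtype=float)) / sigma
    out = (
        gammaln((nu + 1) / 2.0)
        - gammaln(nu / 2.0)
        - 0.5 * math.log(nu * math.pi)
        - np.log(sigma)
        - (nu + 1) / 2.0 * np.log1p(z * z / nu)
    )
    return out if out.shape else float(out)


def t_cdf(z, nu):
    """CDF of the standard Student-t (vectorized, via scipy.special.stdtr)."""
    return stdtr(nu, np.asarray(z, dtype=float))


def stay_prob(x0, sigma, nu, L):
    """P(0 <= X1 <= L | X0 = x0) under the t kernel: the chance the fish
    is still inside the reach at the next occasion."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    x0 = np.asarray(x0, dtype=float)
    out = stdtr(nu, (L - x0) / sigma) - stdtr(nu, (0.0 - x0) / sigma)
    return out if out.shape else float(out)


def stay_indicator(x1: float, L: float) -> int:
    """1 iff the end location lies inside the closed reach [0, L]."""
    return int(0.0 <= x1 <= L)


def replicate_loglik(
    rep: MovementReplicate, params: ModelParams, cfg: ModelConfig
) -> float:
    """Log-likelihood contribution of one replicate.

    Recaptured (Y=1): ln(phi) + t kernel log density at the observed X1.
    Unrecaptured (Y=0): ln(1 - phi * P(stay)), the closed-form marginal
    over the latent end location.
    """
    names = params.beta_names or tuple(rep.covariates)
    x = np.array([rep.covariates[k] for k in names], dtype=float)
    sigma = math.exp(log_sigma(params, x, rep.eta_days))
    if rep.y == 1:
        if rep.x1 is None:
            raise ValueError(f"replicate {rep.replicate_id}: y=1 but x1 missing")
        return float(
            _safe_log(params.phi) + t_logpdf(rep.x1, rep.x0, sigma, cfg.nu)
        )
    p_stay = stay_prob(rep.x0, sigma, cfg.nu, cfg.L)
    return float(_safe_log(1.0 - params.phi * p_stay))


def _normal_logpdf(x, sd):
    return -0.5 * math.log(2.0 * math.pi) - math.log(sd) - 0.5 * (x / sd) ** 2


def log_prior(params: ModelParams, cfg: ModelConfig) -> float:
    """Sum of log prior densities; -inf for phi outside its support."""
    if not (cfg.phi_lower < params.phi < cfg.phi_upper):
        return -math.inf
    lp = _normal_logpdf(params.beta0, cfg.prior_sd_intercept)
    lp += sum(_normal_logpdf(b, cfg.prior_sd_beta) for b in params.beta)
    # truncated normal for phi, with the truncation normalizer
    m, s = cfg.phi_prior_mean, cfg.phi_prior_sd
    z_lo = (cfg.phi_lower - m) / s
    z_hi = (cfg.phi_upper - m) / s
    norm = 0.5 * (1 + math.erf(z_hi / math.sqrt(2))) - 0.5 * (
        1 + math.erf(z_lo / math.sqrt(2))
    )
    lp += _normal_logpdf(params.phi - m, s) - math.log(norm)
    return float(lp)


def log_posterior(
    data: list[MovementReplicate], params: ModelParams, cfg: ModelConfig
) -> float:
    """Log posterior over a species' replicates (vectorized internally)."""
    lp = log_prior(params, cfg)
    if not math.isfinite(lp):
        return -math.inf
    if not data:
        import warnings

        warnings.warn("log_posterior called with no data; returning prior only")
        return lp
    names = params.beta_names or tuple(data[0].covariates)
    rd = ReplicateData.from_replicates(data, beta_names=names)
    return lp + marginal_loglik(rd, params.beta0, params.beta, params.phi, cfg)


# ---------------------------------------------------------------------------
# Vectorized replicate container used by the sampler


@dataclass
class ReplicateData:
    """Column-major view of a species' replicates for fast likelihood
    evaluation: start/end locations, recapture states, offsets and the
    covariate matrix (rows aligned, columns in ``beta_names`` order)."""

    x0: np.ndarray
    x1: np.ndarray  # NaN where latent
    y: np.ndarray  # bool
    eta: np.ndarray
    X: np.ndarray  # (n, k)
    beta_names: tuple[str, ...]
    replicate_ids: tuple[str, ...] = ()

    @classmethod
    def from_replicates(
        cls,
        replicates: list[MovementReplicate],
        beta_names: tuple[str, ...] | None = None,
    ) -> "ReplicateData":
        if beta_names is None:
            beta_names = tuple(replicates[0].covariates) if replicates else ()
        n = len(replicates)
        x0 = np.empty(n)
        x1 = np.full(n, np.nan)
        y = np.zeros(n, dtype=bool)
        eta = np.empty(n)
        X = np.empty((n, len(beta_names)))
        for i, rep in enumerate(replicates):
            x0[i] = rep.x0
            if rep.x1 is not None:
                x1[i] = rep.x1
            y[i] = bool(rep.y)
            eta[i] = rep.eta_days
            for j, name in enumerate(beta_names):
                X[i, j] = rep.covariates[name]
        return cls(
            x0=x0,
            x1=x1,
            y=y,
            eta=eta,
            X=X,
            beta_names=beta_names,
            replicate_ids=tuple(r.replicate_id for r in replicates),
        )

    @property
    def n(self) -> int:
        return self.x0.size

    def __post_init__(self):
        if self.y.any() and np.isnan(self.x1[self.y]).any():
            raise ValueError("recaptured replicates must have observed x1")


def _sigma_vector(data: ReplicateData, beta0, beta) -> np.ndarray:
    lin = beta0 + data.X @ np.asarray(beta, dtype=float) + np.log(data.eta)
    return np.exp(lin)


def marginal_loglik(
    data: ReplicateData, beta0, beta, phi, cfg: ModelConfig
) -> float:
    """Vectorized marginalized log-likelihood over all replicates."""
    sigma = _sigma_vector(data, beta0, beta)
    ll = 0.0
    if data.y.any():
        obs = data.y
        ll += float(
            np.sum(t_logpdf(data.x1[obs], data.x0[obs], sigma[obs], cfg.nu))
        ) + obs.sum() * float(_safe_log(phi))
    if (~data.y).any():
        mis = ~data.y
        p_stay = stay_prob(data.x0[mis], sigma[mis], cfg.nu, cfg.L)
        ll += float(np.sum(_safe_log(1.0 - phi * p_stay)))
    return ll


def augmented_loglik(
    data: ReplicateData, x1_latent: np.ndarray, beta0, beta, phi, cfg: ModelConfig
) -> float:
    """Joint log-likelihood given imputed end locations for Y=0 replicates.

    ``x1_latent`` holds one value per unrecaptured replicate (in data
    order restricted to ``y == 0``).
    """
    sigma = _sigma_vector(data, beta0, beta)
    ll = 0.0
    if data.y.any():
        obs = data.y
        ll += float(
            np.sum(t_logpdf(data.x1[obs], data.x0[obs], sigma[obs], cfg.nu))
        ) + obs.sum() * float(_safe_log(phi))
    mis = ~data.y
    if mis.any():
        z = (x1_latent >= 0.0) & (x1_latent <= cfg.L)
        ll += float(
            np.sum(t_logpdf(x1_latent, data.x0[mis], sigma[mis], cfg.nu))
        )
        ll += float(np.sum(_safe_log(1.0 - phi * z)))
    return ll
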