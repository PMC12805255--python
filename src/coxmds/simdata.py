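"""Synthetic mediation-survival data.

Generates datasets from the working models

    M_ij = c_j + alpha_j X_i + vartheta' Z_i + eps_ij                (mediator model)
    lambda_i(t) = lambda_0 exp{gamma X_i + theta' Z_i + beta' M_i}   (Cox model)

with a binary exposure X ~ Ber(0.6), covariates Z = (Ber(0.3), U(0,1)),
mediator errors either Gaussian with AR(1) Toeplitz correlation rho^|k-l|
or beta-distributed with logit-linear means, exponential event times with
constant baseline hazard, and independent exponential censoring whose rate
c0 is calibrated by Monte Carlo to hit a target average censoring
proportion.

Ground truth: the first ten exposure-mediator coefficients follow the
pattern kappa_alpha*(1,1,1,1,-1,-1,-1,-1,1,-1) and the first twelve
mediator-outcome coefficients kappa_beta*(1,1,1,1,1,1,1,1,0,0,1,-1), so
the true mediator set (both coefficients non-zero) is {1,...,8} in
1-based terms.  Indices are 0-based everywhere in code; only reports and
mediator labels use 1-based numbering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize, signal

logger = logging.getLogger(__name__)

#: 1-based pattern of the first ten exposure->mediator signs
_ALPHA_PATTERN = np.array([1, 1, 1, 1, -1, -1, -1, -1, 1, -1], dtype=float)
#: 1-based pattern of the first twelve mediator->outcome signs
_BETA_PATTERN = np.array([1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 1, -1], dtype=float)

_MIN_P = 12
_LINPRED_CLIP = 50.0
_CALIBRATION_SEED = 20260101  # fixed: c0 must not depend on the run seed
_CALIBRATION_N = 100_000


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


def _default_phi_sampler(rng: np.random.Generator, p: int) -> np.ndarray:
    """Log-uniform precision parameters on [2, 100].

    Spans the range of typical array-methylation beta-value precisions;
    pluggable through :class:`SimConfig`.
    """
    return np.exp(rng.uniform(np.log(2.0), np.log(100.0), size=p))


@dataclass
class SimTruth:
    """Generating coefficients and the induced true mediator set."""

    alpha: np.ndarray
    beta: np.ndarray
    H1: np.ndarray  # 0-based indices with alpha_j != 0 and beta_j != 0
    H0: np.ndarray

    @property
    def h1_labels(self) -> list[str]:
        return [f"M{j + 1}" for j in self.H1]


@dataclass
class MediationDataset:
    """Exposure, covariates, mediators and survival outcome for n subjects."""

    X: np.ndarray
    Z: np.ndarray
    M: np.ndarray
    time: np.ndarray
    event: np.ndarray
    mediator_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.X)
        if self.Z.shape[0] != n or self.M.shape[0] != n:
            raise ValueError("X, Z and M must have the same number of rows")
        if len(self.time) != n or len(self.event) != n:
            raise ValueError("time and event must have length n")
        if self.M.shape[1] != len(self.mediator_ids):
            raise ValueError("mediator_ids must match the number of mediator columns")
        if not np.all(self.time > 0):
            raise ValueError("all observed times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")
        for name, arr in (("X", self.X), ("Z", self.Z), ("M", self.M)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains missing or non-finite values")

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def p(self) -> int:
        return self.M.shape[1]


@dataclass
class SimConfig:
    """Parameters of one simulated study condition.

    Defaults follow the simulation design used throughout: gamma = 0.5,
    theta = vartheta = (0.3, -0.2), baseline exponential hazard 0.5.
    ``kappa_alpha`` and ``kappa_beta`` scale the fixed coefficient
    patterns so power stays away from 1.
    """

    n: int = 500
    p: int = 2000
    rho: float = 0.6
    kappa_alpha: float = 0.50
    kappa_beta: float = 0.35
    gamma: float = 0.5
    theta: tuple[float, ...] = (0.3, -0.2)
    vartheta: tuple[float, ...] = (0.3, -0.2)
    baseline_rate: float = 0.5
    target_censoring: float = 0.3
    mediator_family: str = "gaussian"
    intercepts: float = 0.0
    phi_sampler: Callable[[np.random.Generator, int], np.ndarray] = field(
        default=_default_phi_sampler
    )
    exposure_prob: float = 0.6
    z1_prob: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ConfigurationError(f"rho must be in [0, 1), got {self.rho}")
        if self.n < 2:
            raise ConfigurationError("n must be at least 2")
        if self.p < _MIN_P:
            raise ConfigurationError(
                f"p must be at least {_MIN_P} to hold the fixed coefficient patterns"
            )
        if not 0 < self.target_censoring < 1:
            raise ConfigurationError("target_censoring must be in (0, 1)")
        if self.baseline_rate <= 0:
            raise ConfigurationError("baseline_rate must be positive")
        if self.mediator_family not in ("gaussian", "beta"):
            raise ConfigurationError(
                f"unknown mediator_family {self.mediator_family!r}"
            )


def default_coefficients(
    p: int, kappa_alpha: float, kappa_beta: float
) -> tuple[np.ndarray, np.ndarray, SimTruth]:
    """Fixed sparse coefficient patterns and the implied truth.

    The first ten alpha entries and first twelve beta entries follow the
    fixed sign patterns scaled by kappa; everything else is zero.
    """
    if p < _MIN_P:
        raise ConfigurationError(
            f"p must be at least {_MIN_P} to hold the fixed coefficient patterns"
        )
    alpha = np.zeros(p)
    beta = np.zeros(p)
    alpha[:10] = kappa_alpha * _ALPHA_PATTERN
    beta[:12] = kappa_beta * _BETA_PATTERN
    H1 = np.flatnonzero((alpha != 0) & (beta != 0))
    H0 = np.setdiff1d(np.arange(p), H1)
    return alpha, beta, SimTruth(alpha=alpha, beta=beta, H1=H1, H0=H0)


def simulate_exposure_covariates(
    config: SimConfig, rng: np.random.Generator, n: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Binary exposure and (binary, uniform) covariates."""
    n = config.n if n is None else n
    X = rng.binomial(1, config.exposure_prob, size=n).astype(float)
    Z1 = rng.binomial(1, config.z1_prob, size=n).astype(float)
    Z2 = rng.uniform(0.0, 1.0, size=n)
    return X, np.column_stack([Z1, Z2])


def _ar1_errors(n: int, p: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """AR(1) Gaussian errors: stationary, corr(eps_k, eps_l) = rho^|k-l|.

    Built by the O(np) recursion eps_1 ~ N(0,1),
    eps_k = rho*eps_{k-1} + sqrt(1-rho^2)*N(0,1), run across columns.
    """
    innov = rng.standard_normal((n, p))
    if rho == 0.0:
        return innov
    innov[:, 1:] *= np.sqrt(1.0 - rho * rho)
    return signal.lfilter([1.0], [1.0, -rho], innov, axis=1)


def mediator_linear_predictor(
    X: np.ndarray,
    Z: np.ndarray,
    alpha: np.ndarray,
    vartheta: np.ndarray,
    intercepts: float | np.ndarray = 0.0,
) -> np.ndarray:
    """n x p matrix c_j + alpha_j X_i + vartheta' Z_i."""
    return intercepts + np.outer(X, alpha) + (Z @ np.asarray(vartheta))[:, None]


def simulate_gaussian_mediators(
    config: SimConfig,
    X: np.ndarray,
    Z: np.ndarray,
    alpha: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mediators with Toeplitz-AR(1) Gaussian errors."""
    mu = mediator_linear_predictor(
        X, Z, alpha, np.asarray(config.vartheta), config.intercepts
    )
    return mu + _ar1_errors(len(X), len(alpha), config.rho, rng)


def simulate_beta_mediators(
    config: SimConfig,
    X: np.ndarray,
    Z: np.ndarray,
    alpha: np.ndarray,
    rng: np.random.Generator,
    phi: np.ndarray | None = None,
) -> np.ndarray:
    """Beta-distributed mediators with logit-linear means.

    mu_ij = expit(c_j + alpha_j X_i + vartheta' Z_i); M_ij ~
    Beta(phi_j mu_ij, phi_j (1 - mu_ij)).  The shared exposure and
    covariates induce marginal correlation across mediators.
    """
    p = len(alpha)
    if phi is None:
        phi = config.phi_sampler(rng, p)
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0):
        raise ValueError("beta precision parameters phi must be positive")
    eta = mediator_linear_predictor(
        X, Z, alpha, np.asarray(config.vartheta), config.intercepts
    )
    mu = 1.0 / (1.0 + np.exp(-eta))
    a = phi[None, :] * mu
    b = phi[None, :] * (1.0 - mu)
    M = rng.beta(a, b)
    # rng.beta can return exact 0/1 for tiny shapes; keep strictly interior
    tiny = np.finfo(float).tiny
    return np.clip(M, tiny, 1.0 - tiny)


def simulate_mediators(
    config: SimConfig,
    X: np.ndarray,
    Z: np.ndarray,
    alpha: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    if config.mediator_family == "gaussian":
        return simulate_gaussian_mediators(config, X, Z, alpha, rng)
    return simulate_beta_mediators(config, X, Z, alpha, rng)


def hazard_rates(
    X: np.ndarray,
    Z: np.ndarray,
    M: np.ndarray,
    gamma: float,
    theta: np.ndarray,
    beta: np.ndarray,
    baseline_rate: float,
) -> np.ndarray:
    """Per-subject exponential event rate lambda_i = lambda_0 exp(linpred)."""
    linpred = gamma * X + Z @ np.asarray(theta) + M @ beta
    if np.any(np.abs(linpred) > _LINPRED_CLIP):
        logger.warning(
            "clipping %d linear predictors beyond +/-%g to avoid overflow",
            int(np.sum(np.abs(linpred) > _LINPRED_CLIP)),
            _LINPRED_CLIP,
        )
        linpred = np.clip(linpred, -_LINPRED_CLIP, _LINPRED_CLIP)
    return baseline_rate * np.exp(linpred)


def simulate_survival(
    X: np.ndarray,
    Z: np.ndarray,
    M: np.ndarray,
    gamma: float,
    theta: np.ndarray,
    beta: np.ndarray,
    baseline_rate: float,
    c0: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times, exponential censoring, observed (T, Delta)."""
    if c0 <= 0:
        raise ValueError("censoring rate c0 must be positive")
    lam = hazard_rates(X, Z, M, gamma, theta, beta, baseline_rate)
    D = rng.exponential(1.0 / lam)
    C = rng.exponential(1.0 / c0, size=len(lam))
    T = np.minimum(D, C)
    Delta = (D <= C).astype(int)
    return T, Delta


def _calibration_hazards(config: SimConfig, n: int) -> np.ndarray:
    """A large fixed-seed sample of subject hazards for censoring calibration.

    Only the mediator columns carrying non-zero outcome coefficients are
    generated, which leaves the hazard distribution unchanged.
    """
    rng = np.random.default_rng(_CALIBRATION_SEED)
    alpha, beta, _ = default_coefficients(
        config.p, config.kappa_alpha, config.kappa_beta
    )
    nz = np.flatnonzero(beta)
    X, Z = simulate_exposure_covariates(config, rng, n=n)
    sub = SimConfig(
        n=n,
        p=max(_MIN_P, len(nz)),
        rho=config.rho,
        kappa_alpha=config.kappa_alpha,
        kappa_beta=config.kappa_beta,
        gamma=config.gamma,
        theta=config.theta,
        vartheta=config.vartheta,
        baseline_rate=config.baseline_rate,
        target_censoring=config.target_censoring,
        mediator_family=config.mediator_family,
        intercepts=config.intercepts,
        phi_sampler=config.phi_sampler,
    )
    # The AR(1) recursion makes the first k columns of a p-column draw
    # distributionally identical to a k-column draw, so generating only the
    # leading block is exact for the leading non-zero beta pattern.
    M = simulate_mediators(sub, X, Z, alpha[: sub.p], rng)
    return hazard_rates(
        X, Z, M, config.gamma, np.asarray(config.theta), beta[: sub.p],
        config.baseline_rate,
    )


def expected_censoring_rate(lam: np.ndarray, c0: float) -> float:
    """Mean P(censored) for exponential event/censoring competition.

    For independent Exp(lam_i) events and Exp(c0) censoring,
    P(C_i < D_i) = c0 / (c0 + lam_i).
    """
    return float(np.mean(c0 / (c0 + lam)))


def calibrate_censoring(config: SimConfig, target_rate: float | None = None) -> float:
    """Censoring rate c0 hitting the target average censoring proportion.

    Uses a large fixed-seed Monte-Carlo sample of subject hazards and the
    closed-form competing-exponentials censoring probability, solved by
    root bracketing on c0.
    """
    target = config.target_censoring if target_rate is None else target_rate
    if not 0 < target < 1:
        raise ConfigurationError("target censoring rate must be in (0, 1)")
    lam = _calibration_hazards(config, _CALIBRATION_N)
    lo, hi = 1e-6, 1e6
    f = lambda c0: expected_censoring_rate(lam, c0) - target
    if f(lo) > 0 or f(hi) < 0:
        raise RuntimeError(
            "failed to bracket the censoring rate within [1e-6, 1e6]"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))


def simulate_dataset(
    config: SimConfig,
    seed: int | np.random.Generator | None = None,
    c0: float | None = None,
) -> tuple[MediationDataset, SimTruth]:
    """One full dataset + truth from the configured study condition."""
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    alpha, beta, truth = default_coefficients(
        config.p, config.kappa_alpha, config.kappa_beta
    )
    if c0 is None:
        c0 = calibrate_censoring(config)
    X, Z = simulate_exposure_covariates(config, rng)
    M = simulate_mediators(config, X, Z, alpha, rng)
    T, Delta = simulate_survival(
        X, Z, M, config.gamma, np.asarray(config.theta), beta,
        config.baseline_rate, c0, rng,
    )
    ids = [f"M{j + 1}" for j in range(config.p)]
    data = MediationDataset(X=X, Z=Z, M=M, time=T, event=Delta, mediator_ids=ids)
    return data, truth


SCENARIOS: dict[str, dict] = {
    # Correlated-Gaussian design used for the rho grid
    "correlated": dict(n=500, p=2000, rho=0.6, kappa_alpha=0.50,
                       kappa_beta=0.35, target_censoring=0.3,
                       mediator_family="gaussian"),
    # Split-proportion study: same generative design, rho fixed at 0.6
    "split-prop": dict(n=500, p=2000, rho=0.6, kappa_alpha=0.50,
                       kappa_beta=0.35, target_censoring=0.3,
                       mediator_family="gaussian"),
    # Sample-size study: rho=0.6, heavy censoring
    "sample-size": dict(n=100, p=2000, rho=0.6, kappa_alpha=0.50,
                        kappa_beta=0.35, target_censoring=0.6,
                        mediator_family="gaussian"),
    # Non-Gaussian design: beta-distributed mediators
    "beta": dict(n=500, p=2000, rho=0.0, kappa_alpha=0.90,
                 kappa_beta=0.80, target_censoring=0.3,
                 mediator_family="beta"),
}


def scenario_config(name: str, **overrides) -> SimConfig:
    """SimConfig for a named scenario with overrides merged on top."""
    if name not in SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        )
    params = {**SCENARIOS[name], **overrides}
    return SimConfig(**params)


def make_scenario(
    name: str,
    seed: int | None = None,
    c0: float | None = None,
    **overrides,
) -> tuple[MediationDataset, SimTruth]:
    """Generate a dataset from a named scenario; see :data:`SCENARIOS`."""
    config = scenario_config(name, **overrides)
    return simulate_dataset(config, seed=seed, c0=c0)
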