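"""Prior specification and the joint log-posterior.

Continuous parameters carry independent univariate priors (uniform, Gaussian,
or central t).  Age effects on the log hazard carry an intrinsic first-order
random-walk (RW1) prior — a Gaussian Markov random field penalizing squared
differences of adjacent age intervals — with a sum-to-zero constraint for
identifiability against the intercept.  Missing binary covariates are handled
by data augmentation: each missing value is a discrete parameter with a
Bernoulli prior whose success probability itself carries a Gaussian
hyperprior.

Out-of-support parameter values yield ``-inf`` (rejection semantics), never
an exception, so Metropolis samplers can propose freely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .likelihood import ModelParams, SurveySchedule, joint_loglik

__all__ = [
    "UniformPrior",
    "GaussianPrior",
    "TPrior",
    "PriorSpec",
    "prior_preset",
    "build_neighborhood_matrix",
    "rw_age_log_prior",
    "log_prior",
    "log_posterior",
]


@dataclass(frozen=True)
class UniformPrior:
    lo: float
    hi: float

    def logpdf(self, x: float) -> float:
        if self.lo <= x <= self.hi:
            return -math.log(self.hi - self.lo)
        return -np.inf

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.lo, self.hi))


@dataclass(frozen=True)
class GaussianPrior:
    mu: float
    sigma: float

    def logpdf(self, x: float) -> float:
        z = (x - self.mu) / self.sigma
        return -0.5 * z * z - math.log(self.sigma) - 0.5 * math.log(2 * math.pi)

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.normal(self.mu, self.sigma))


@dataclass(frozen=True)
class TPrior:
    """Central Student-t prior with ``df`` degrees of freedom."""

    df: float
    scale: float = 1.0

    def logpdf(self, x: float) -> float:
        return float(stats.t.logpdf(x, self.df, scale=self.scale))

    def sample(self, rng: np.random.Generator) -> float:
        return float(self.scale * rng.standard_t(self.df))


def prior_preset(name: str):
    """Named weakly-informative prior families for sensitivity analysis."""
    presets = {
        "uniform5": UniformPrior(-5.0, 5.0),
        "t5": TPrior(df=5.0, scale=1.0),
        "gauss224": GaussianPrior(0.0, 2.24),
    }
    try:
        return presets[name]
    except KeyError:
        raise KeyError(
            f"unknown prior preset {name!r}; choose from {sorted(presets)}"
        ) from None


@dataclass
class PriorSpec:
    """Prior declarations for every free parameter, keyed by name.

    ``priors`` covers continuous parameters (log rates, coefficients, the
    detection probability under the Bayes–Laplace uniform(0,1), ...).
    ``tau_prior`` governs the RW1 increment standard deviation when age
    effects are present.  ``imputation_hyperprior`` is the prior on each
    Bernoulli success probability used to impute a missing binary covariate.
    """

    priors: dict = field(default_factory=dict)
    tau_prior: UniformPrior = field(default_factory=lambda: UniformPrior(0.0, 5.0))
    imputation_hyperprior: GaussianPrior = field(
        default_factory=lambda: GaussianPrior(0.5, 0.05)
    )

    def logpdf(self, name: str, x: float) -> float:
        try:
            prior = self.priors[name]
        except KeyError:
            raise KeyError(f"no prior declared for parameter {name!r}") from None
        return prior.logpdf(x)


def build_neighborhood_matrix(k: int) -> np.ndarray:
    """Row-stochastic neighborhood matrix of the 1-D age chain.

    Interior intervals split weight 1/2 between their two neighbors; the two
    boundary intervals give full weight 1 to their single neighbor.  Every
    row sums to one — which is also why ``I - H`` is singular and the implied
    Gaussian ``(I-H)^{-1} M`` covariance is improper (intrinsic).
    """
    if k < 2:
        raise ValueError("need at least two intervals")
    H = np.zeros((k, k))
    H[0, 1] = 1.0
    H[k - 1, k - 2] = 1.0
    for i in range(1, k - 1):
        H[i, i - 1] = 0.5
        H[i, i + 1] = 0.5
    return H


def rw_age_log_prior(age_effects: np.ndarray, tau: float) -> float:
    """Intrinsic RW1 log-density of age effects, up to an additive constant.

        -(k-1) ln(tau) - (1 / (2 tau^2)) * sum_i (age_{i+1} - age_i)^2

    The density lives on the sum-to-zero subspace (rank ``k-1`` precision
    ``D'D / tau^2`` with ``D`` the first-difference matrix); the overall
    level is not identified and is absorbed by the intercept.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    age = np.asarray(age_effects, dtype=float)
    if age.size < 2:
        raise ValueError("need at least two age effects")
    increments = np.diff(age)
    k = age.size
    return float(
        -(k - 1) * math.log(tau) - 0.5 * np.sum(increments**2) / tau**2
    )


def _params_values(params: ModelParams) -> dict:
    """Flatten a ModelParams into named scalar values for prior lookup."""
    values = {}
    for i, lr in enumerate(np.atleast_1d(params.hazard.log_rates)):
        values[f"log_rate_{i}"] = float(lr)
    if params.effect is not None:
        for name, beta in zip(params.effect.names, params.effect.coefficients):
            values[f"beta_{name}"] = float(beta)
    values["p"] = float(params.detection_p)
    return values


def log_prior(params: ModelParams, spec: PriorSpec, tau: float | None = None) -> float:
    """Sum of independent prior log-densities for a parameter bundle.

    Adds the RW1 term for age offsets (when present, with ``tau``), Bernoulli
    log-masses for imputed binary covariate values, and the Gaussian
    hyperprior terms for the imputation probabilities.  Returns ``-inf`` for
    out-of-support values.
    """
    total = 0.0
    for name, value in _params_values(params).items():
        total += spec.logpdf(name, value)
        if total == -np.inf:
            return -np.inf
    if params.hazard.age_offsets is not None:
        if tau is None:
            raise ValueError("age offsets present but no tau supplied")
        total += spec.tau_prior.logpdf(tau)
        if total == -np.inf:
            return -np.inf
        total += rw_age_log_prior(params.hazard.age_offsets, tau)
    for cov_name, pi in params.imputation_probs.items():
        if not 0.0 < pi < 1.0:
            return -np.inf
        total += spec.imputation_hyperprior.logpdf(pi)
        for assignments in params.imputed.values():
            if cov_name in assignments:
                v = assignments[cov_name]
                total += math.log(pi) if v else math.log(1.0 - pi)
    return float(total)


def log_posterior(
    params: ModelParams,
    dataset,
    spec: PriorSpec,
    schedule: SurveySchedule,
    tau: float | None = None,
    include_detection: bool = False,
) -> float:
    """Joint log-posterior: ``joint_loglik + log_prior`` (data augmentation).

    ``dataset`` is a ``(radio_records, mark_records)`` pair.  Imputed
    covariate values inside ``params`` are substituted into the likelihood.
    Propagates ``-inf`` from the priors without evaluating the likelihood.
    """
    lp = log_prior(params, spec, tau=tau)
    if lp == -np.inf:
        return -np.inf
    radio_records, mark_records = dataset
    return lp + joint_loglik(
        radio_records, mark_records, params, schedule, include_detection
    )
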