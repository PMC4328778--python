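"""MCMC machinery: adaptive Metropolis samplers and convergence diagnostics.

The default sampler is an adaptive random-walk Metropolis with block-wise
Gaussian proposals (each block's step scale is tuned toward a target
acceptance rate during burn-in and frozen afterwards, preserving detailed
balance for the retained draws).  A hit-and-run variant — a uniformly random
direction followed by a one-dimensional Metropolis step — is available via
``algorithm="harm"``.

Diagnostics are pure functions of the draws: Geweke's single-chain
stationarity z-score, the (Brooks–)Gelman–Rubin potential scale reduction
factor with its multivariate version, DIC, batch-means posterior summaries,
and posterior predictive checks for failure-age discrepancy statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "McmcConfig",
    "PosteriorSamples",
    "run_chains",
    "geweke_z",
    "psrf",
    "dic",
    "posterior_summary",
    "posterior_predictive_check",
]


@dataclass
class McmcConfig:
    """Sampler settings.  ``burn_in`` defaults to half of ``n_iter``."""

    n_iter: int = 10_000
    burn_in: int | None = None
    n_chains: int = 1
    seed: int = 0
    algorithm: str = "arwm"  # "arwm" (block random walk) or "harm" (hit & run)
    target_accept: float = 0.30
    adapt_interval: int = 50

    def __post_init__(self) -> None:
        if self.burn_in is None:
            self.burn_in = self.n_iter // 2
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.algorithm not in ("arwm", "harm"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


@dataclass
class PosteriorSamples:
    """Post-burn-in draws indexed by (chain, iteration, parameter)."""

    draws: np.ndarray
    names: list[str]
    acceptance: np.ndarray
    config: McmcConfig
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.draws.ndim != 3:
            raise ValueError("draws must be (chain, iteration, parameter)")
        if self.draws.shape[2] != len(self.names):
            raise ValueError("parameter names do not match draw dimension")
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("non-finite draws after burn-in")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def stacked(self) -> np.ndarray:
        """All chains concatenated: (chain * iteration, parameter)."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def mean(self) -> np.ndarray:
        return self.stacked().mean(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        n_chains, n_draws, _ = self.draws.shape
        frame = pd.DataFrame(self.stacked(), columns=self.names)
        frame.insert(0, "iteration", np.tile(np.arange(n_draws), n_chains))
        frame.insert(0, "chain", np.repeat(np.arange(n_chains), n_draws))
        return frame


def _resolve_init(init_strategy, rng, d, tries=200):
    if callable(init_strategy):
        return np.asarray(init_strategy(rng), dtype=float)
    arr = np.asarray(init_strategy, dtype=float)
    return arr


def _run_single_chain(
    log_post,
    theta0: np.ndarray,
    config: McmcConfig,
    rng: np.random.Generator,
    blocks,
    scales,
    interleave,
):
    d = theta0.size
    theta = theta0.copy()
    lp = float(log_post(theta))
    if not np.isfinite(lp):
        raise ValueError("log posterior not finite at the initial point")
    n_blocks = len(blocks)
    log_scale = np.zeros(n_blocks)
    kept = np.empty((config.n_iter - config.burn_in, d))
    acc = np.zeros(n_blocks)
    acc_window = np.zeros(n_blocks)
    history = np.empty((min(config.burn_in, 1000) or 1, d))
    hist_n = 0
    harm = config.algorithm == "harm"
    for it in range(config.n_iter):
        adapting = it < config.burn_in
        for b, idx in enumerate(blocks):
            step = scales[b] * math.exp(log_scale[b])
            prop = theta.copy()
            if harm:
                # random direction on the sphere, one Gaussian step along it
                # (componentwise base scales make the proposal elliptical;
                # the increment density stays symmetric, so plain Metropolis)
                direction = rng.standard_normal(d)
                direction /= np.linalg.norm(direction)
                prop += direction * step * rng.standard_normal()
            else:
                prop[idx] += step * rng.standard_normal(len(idx))
            lp_prop = float(log_post(prop))
            if lp_prop - lp > math.log(rng.uniform() + 1e-320):
                theta = prop
                lp = lp_prop
                acc_window[b] += 1
                if not adapting:
                    acc[b] += 1
        if interleave is not None:
            theta = interleave(theta, rng)
            lp = float(log_post(theta))
        if adapting:
            history[it % history.shape[0]] = theta
            hist_n = min(hist_n + 1, history.shape[0])
            if (it + 1) % config.adapt_interval == 0:
                rate = acc_window / config.adapt_interval
                log_scale += 0.66 * (rate - config.target_accept)
                acc_window[:] = 0.0
            # halfway through burn-in: reshape per-component scales from the
            # observed sample spread, then let the global factor re-adapt
            if not harm and (it + 1) == config.burn_in // 2 and hist_n > 50:
                sds = history[:hist_n].std(axis=0)
                floor = max(float(sds.max()), 1e-8) * 1e-3
                sds = np.maximum(sds, floor)
                for b, idx in enumerate(blocks):
                    scales[b] = sds[idx] * (2.38 / math.sqrt(len(idx)))
                    log_scale[b] = 0.0
        if it >= config.burn_in:
            kept[it - config.burn_in] = theta
    post_iters = config.n_iter - config.burn_in
    return kept, acc / max(post_iters, 1)


def run_chains(
    log_post,
    init_strategy,
    config: McmcConfig,
    names: list[str] | None = None,
    blocks=None,
    init_scales=None,
    interleave=None,
) -> PosteriorSamples:
    """Sample the posterior with independent adaptive Metropolis chains.

    Parameters
    ----------
    log_post
        Callable mapping a parameter vector to the log posterior density.
    init_strategy
        Either a callable ``rng -> theta0`` (dispersed random starts) or an
        explicit starting vector / per-chain array.
    blocks
        Partition of parameter indices updated jointly; default is
        componentwise (one block per parameter).
    init_scales
        Initial proposal standard deviation per parameter (adapted during
        burn-in); default 0.1.
    interleave
        Optional ``(theta, rng) -> theta`` hook run once per iteration for
        model-specific discrete updates (e.g. Gibbs imputation steps); the
        posterior is re-evaluated afterwards.
    """
    seed_seq = np.random.SeedSequence(config.seed)
    child_seqs = seed_seq.spawn(config.n_chains)
    all_draws = []
    all_acc = []
    warnings: list[str] = []
    d = None
    for chain, sub in enumerate(child_seqs):
        rng = np.random.default_rng(sub)
        init = _resolve_init(init_strategy, rng, d)
        if init.ndim == 2:
            theta0 = init[chain]
        else:
            theta0 = init
        if d is None:
            d = theta0.size
        if config.algorithm == "harm":
            chain_blocks = [np.arange(d)]
        elif blocks is None:
            chain_blocks = [np.array([i]) for i in range(d)]
        else:
            chain_blocks = [np.asarray(b, dtype=int) for b in blocks]
        if init_scales is None:
            base = np.full(d, 0.1)
        else:
            base = np.asarray(init_scales, dtype=float).copy()
        chain_scales = [base[idx].copy() for idx in chain_blocks]
        kept, acc = _run_single_chain(
            log_post, theta0, config, rng, chain_blocks, chain_scales, interleave
        )
        if np.any(acc < 1e-3):
            warnings.append(
                f"chain {chain}: block acceptance below 1e-3 after adaptation"
            )
        all_draws.append(kept)
        all_acc.append(acc)
    if names is None:
        names = [f"param_{i}" for i in range(d)]
    return PosteriorSamples(
        draws=np.stack(all_draws),
        names=list(names),
        acceptance=np.stack(all_acc),
        config=config,
        warnings=warnings,
    )


def _spectral_var_zero(x: np.ndarray) -> float:
    """Spectral density of ``x`` at frequency zero via a Bartlett lag window."""
    n = x.size
    x = x - x.mean()
    gamma0 = float(x @ x) / n
    if gamma0 == 0.0:
        raise ValueError("degenerate (constant) chain segment")
    M = max(int(4 * math.sqrt(n / 100.0)), 1)
    s = gamma0
    for k in range(1, min(M, n - 1) + 1):
        gamma_k = float(x[:-k] @ x[k:]) / n
        s += 2.0 * (1.0 - k / (M + 1.0)) * gamma_k
    return max(s, 1e-12 * gamma0)


def geweke_z(
    samples,
    first_frac: float = 0.1,
    last_frac: float = 0.5,
    chain: int = 0,
) -> np.ndarray:
    """Geweke stationarity z-score per parameter for one chain.

    Compares the mean of the first ``first_frac`` of the chain with the mean
    of the last ``last_frac``, scaling by spectral-density-at-zero variance
    estimates of each window.  Approximately standard normal for a
    stationary chain.
    """
    draws = samples.draws[chain] if isinstance(samples, PosteriorSamples) else samples
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.ndim == 2 and draws.shape[0] < draws.shape[1] and draws.shape[0] == 1:
        draws = draws.T
    n = draws.shape[0]
    n_first = int(n * first_frac)
    n_last = int(n * last_frac)
    if n_first < 10 or n_last < 10:
        raise ValueError("chain too short for the requested Geweke windows")
    zs = np.empty(draws.shape[1])
    for j in range(draws.shape[1]):
        a = draws[:n_first, j]
        b = draws[n - n_last:, j]
        var = _spectral_var_zero(a) / n_first + _spectral_var_zero(b) / n_last
        zs[j] = (a.mean() - b.mean()) / math.sqrt(var)
    return zs


def psrf(samples) -> tuple[np.ndarray, float]:
    """(Brooks–)Gelman–Rubin corrected scale reduction factors.

    Returns per-parameter corrected PSRFs (with the sampling-variability
    degrees-of-freedom correction) and the multivariate factor.  Values
    approach 1 as the chains mix.
    """
    draws = samples.draws if isinstance(samples, PosteriorSamples) else np.asarray(samples)
    if draws.ndim != 3 or draws.shape[0] < 2:
        raise ValueError("PSRF needs >= 2 chains of equal length")
    m, n, d = draws.shape
    chain_means = draws.mean(axis=1)
    chain_vars = draws.var(axis=1, ddof=1)
    W = chain_vars.mean(axis=0)
    B = n * chain_means.var(axis=0, ddof=1)
    sigma2 = (n - 1) / n * W + B / n
    V = sigma2 + B / (m * n)
    out = np.empty(d)
    for j in range(d):
        if W[j] <= 0:
            out[j] = np.inf if B[j] > 0 else 1.0
            continue
        # method-of-moments df for the t-approximation of V
        var_V = (
            ((n - 1) / n) ** 2 / m * chain_vars[:, j].var(ddof=1)
            + ((m + 1) / (m * n)) ** 2 * 2 / (m - 1) * B[j] ** 2
        )
        df = 2 * V[j] ** 2 / var_V if var_V > 0 else np.inf
        correction = (df + 3) / (df + 1) if np.isfinite(df) else 1.0
        out[j] = math.sqrt(correction * V[j] / W[j])
    # multivariate factor: largest eigenvalue of W^-1 B / n
    Wm = np.zeros((d, d))
    Bm = np.zeros((d, d))
    grand = chain_means.mean(axis=0)
    for c in range(m):
        dev = draws[c] - chain_means[c]
        Wm += dev.T @ dev / (n - 1)
        diff = chain_means[c] - grand
        Bm += np.outer(diff, diff)
    Wm /= m
    Bm = n * Bm / (m - 1)
    eigs = np.linalg.eigvals(np.linalg.solve(Wm + 1e-12 * np.eye(d), Bm / n))
    lam = float(np.max(eigs.real))
    mpsrf = math.sqrt((n - 1) / n + (m + 1) / m * lam)
    return out, mpsrf


def dic(
    samples: PosteriorSamples,
    loglik_fn,
    max_evals: int = 1000,
) -> tuple[float, float, float]:
    """Deviance information criterion: ``(DIC, pD, Dbar)``.

    ``Dbar`` is the posterior mean deviance (``-2 loglik`` averaged over a
    deterministic thinning of the draws), ``pD = Dbar - D(posterior mean)``,
    and ``DIC = Dbar + pD``.
    """
    stacked = samples.stacked()
    step = max(stacked.shape[0] // max_evals, 1)
    subset = stacked[::step]
    devs = np.array([-2.0 * loglik_fn(theta) for theta in subset])
    if not np.all(np.isfinite(devs)):
        bad = subset[np.flatnonzero(~np.isfinite(devs))[0]]
        raise ValueError(f"non-finite deviance at draw {bad}")
    dbar = float(devs.mean())
    theta_bar = stacked.mean(axis=0)
    dhat = -2.0 * float(loglik_fn(theta_bar))
    if not np.isfinite(dhat):
        raise ValueError(
            f"non-finite deviance at the posterior mean {theta_bar}"
        )
    pd_ = dbar - dhat
    return dbar + pd_, pd_, dbar


def _batch_mc_error(x: np.ndarray) -> float:
    n = x.size
    b = max(int(math.sqrt(n)), 1)
    n_batches = n // b
    if n_batches < 2:
        return float("nan")
    means = x[: n_batches * b].reshape(n_batches, b).mean(axis=1)
    return float(means.std(ddof=1) / math.sqrt(n_batches))


def posterior_summary(samples: PosteriorSamples) -> pd.DataFrame:
    """Mean, SD, batch-means MC error, and 2.5/50/97.5 percent quantiles."""
    stacked = samples.stacked()
    rows = []
    for j, name in enumerate(samples.names):
        x = stacked[:, j]
        q = np.quantile(x, [0.025, 0.5, 0.975])
        rows.append(
            {
                "parameter": name,
                "mean": x.mean(),
                "sd": x.std(ddof=1) if x.size > 1 else 0.0,
                "mc_error": _batch_mc_error(x),
                "q2.5": q[0],
                "median": q[1],
                "q97.5": q[2],
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def posterior_predictive_check(
    samples: PosteriorSamples,
    dataset,
    schedule,
    statistic: str,
    draw_to_params,
    seed: int = 0,
    n_draws: int = 200,
) -> float:
    """Bayesian p-value for a failure-age discrepancy statistic.

    For each retained draw, replicate failure ages are simulated from the
    fitted hazard.  ``statistic`` is one of:

    * ``"mean-failure-age"`` — the whole death process is replicated for
      every known-fate individual (death time from entry; deaths after the
      study end censored out), and the replicated mean failure age of the
      individuals that die in replicate is compared with the observed mean
      failure age (death-interval midpoints) of the known deaths;
    * ``"per-individual-age-difference"`` — for each individual known to
      die, a replicate failure age is drawn conditional on death within the
      study, and the mean of the paired differences (replicated − observed)
      is compared with zero.

    The p-value is the fraction of draws whose replicated statistic is >= the
    observed one; values near 0 or 1 flag misfit.
    """
    from .simulation import draw_death_time, draw_death_time_conditional

    radio_records, mark_records = dataset
    deaths = [r for r in radio_records if np.isfinite(r.first_dead)]
    deaths += [m for m in mark_records if np.isfinite(m.first_dead)]
    if not deaths:
        raise ValueError("posterior predictive check needs known deaths")
    obs_ages = np.array(
        [0.5 * (r.last_alive + r.first_dead) for r in radio_records
         if np.isfinite(r.first_dead)]
        + [0.5 * (m.last_known_alive + m.first_dead) for m in mark_records
           if np.isfinite(m.first_dead)]
    )
    if statistic not in ("mean-failure-age", "per-individual-age-difference"):
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    stacked = samples.stacked()
    step = max(stacked.shape[0] // n_draws, 1)
    subset = stacked[::step][:n_draws]
    end = schedule.study_end
    known_fate = list(radio_records)
    exceed = 0
    total = 0
    for theta in subset:
        params = draw_to_params(theta)
        if statistic == "mean-failure-age":
            reps = []
            for rec in known_fate:
                cov = params.covariate_values(rec)
                t = draw_death_time(
                    params.hazard, rec.entry, end, rng,
                    multiplier=(
                        np.exp(params.effect.linear_predictor(cov))
                        if params.effect is not None else 1.0
                    ),
                )
                if np.isfinite(t):
                    reps.append(t)
            if not reps:
                continue
            stat_rep, stat_obs = float(np.mean(reps)), float(obs_ages.mean())
        else:
            diffs = np.empty(obs_ages.size)
            for i, rec in enumerate(deaths):
                cov = params.covariate_values(rec)
                diffs[i] = draw_death_time_conditional(
                    params.hazard, rec.entry, end, rng,
                    effect=params.effect, covariates=cov,
                ) - obs_ages[i]
            stat_rep, stat_obs = float(diffs.mean()), 0.0
        exceed += stat_rep >= stat_obs
        total += 1
    return exceed / max(total, 1)
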