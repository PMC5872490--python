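"""Metropolis-within-Gibbs sampler over the cell-count vector.

The posterior over counts N is known only up to a constant: the CLT
Gaussian likelihood of the aggregate observation times a flat prior on
[0, M] per component.  Each full conditional P(N_i | rest) is therefore
sampled by Metropolis steps with a symmetric uniform proposal
N_i* ~ uniform(N_i - delta_i, N_i + delta_i), accepted with probability
min(r, 1) where r is the posterior ratio.  One *sweep* updates every
component once, in a fixed order (systematic scan).

The proposal half-width delta controls mixing: too small and successive
samples are nearly identical, too large and almost every proposal is
rejected.  By default each delta_i is adapted during burn-in only (doubled
when the recent acceptance fraction exceeds 0.5, halved when it falls
below 0.3) and frozen afterwards, so the retained chain is a valid
Metropolis chain with a fixed kernel.

Counts are treated as continuous reals constrained to [EPS_N, M]; the tiny
positivity floor EPS_N keeps the count-weighted variance of the likelihood
strictly positive even when every other component sits at the boundary.
Out-of-support proposals are rejected (r = 0) rather than reflected, which
preserves proposal symmetry without Jacobian corrections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.optimize

from ._errors import InvalidStateError, ValidationError
from .likelihood import (
    LOG_ZERO,
    AggregateObservation,
    PriorConfig,
    _check_attributes,
    _default_var_floor,
    log_unnormalized_posterior,
)
from .profiles import CellLineProfile

__all__ = [
    "EPS_N",
    "SamplerConfig",
    "PosteriorChain",
    "propose",
    "acceptance_ratio",
    "initial_counts",
    "run_chain",
]

#: Positivity floor on each count inside the sampler (cells).
EPS_N = 1e-3

# delta adaptation (burn-in only): keep recent acceptance within this band
_ACC_LOW, _ACC_HIGH = 0.3, 0.5
_ADAPT_WINDOW = 100  # sweeps between adaptation steps


@dataclass
class SamplerConfig:
    """Tuning parameters for the Metropolis-within-Gibbs chain.

    ``delta`` may be a positive scalar (fixed half-width for every
    component), an array of per-component half-widths, or ``"auto"``
    (the default) to adapt per-component half-widths during burn-in.
    """

    delta: float | str | np.ndarray = "auto"
    n_burnin: int = 5000
    n_samples: int = 10000
    thin: int = 1
    seed: int | None = None
    prior: PriorConfig = field(default_factory=PriorConfig)
    init: str = "nnls"

    def __post_init__(self) -> None:
        if isinstance(self.delta, str):
            if self.delta != "auto":
                raise ValidationError(f"delta must be positive or 'auto', got {self.delta!r}")
        else:
            d = np.asarray(self.delta, dtype=float)
            if np.any(d <= 0):
                raise ValidationError("delta must be > 0")
        if self.n_burnin < 0:
            raise ValidationError("n_burnin must be >= 0")
        if self.n_samples < 2:
            raise ValidationError("n_samples must be >= 2")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if self.init not in ("nnls", "flat"):
            raise ValidationError(f"unknown init strategy {self.init!r}")


@dataclass
class PosteriorChain:
    """Retained posterior samples of the counts vector.

    ``samples`` has one row per retained sweep and one column per cell
    line; ``acceptance_rate`` is the post-burn-in acceptance fraction per
    component; ``delta`` is the (possibly adapted, then frozen) proposal
    half-width per component.
    """

    samples: np.ndarray
    acceptance_rate: np.ndarray
    cell_line_names: list[str]
    config: SamplerConfig
    seed: int | None
    delta: np.ndarray

    @property
    def n_retained(self) -> int:
        return self.samples.shape[0]

    def to_csv(self, path: str | Path) -> None:
        """One row per retained sweep, one column per cell line."""
        import pandas as pd

        pd.DataFrame(self.samples, columns=self.cell_line_names).to_csv(path, index=False)

    def sidecar(self) -> dict:
        """JSON-serializable run metadata (seed, config, acceptance)."""
        return {
            "seed": self.seed,
            "n_burnin": self.config.n_burnin,
            "n_samples": self.config.n_samples,
            "thin": self.config.thin,
            "prior_upper_bound": self.config.prior.upper_bound,
            "init": self.config.init,
            "delta": self.delta.tolist(),
            "acceptance_rate": self.acceptance_rate.tolist(),
            "cell_line_names": self.cell_line_names,
        }


def propose(current: float, delta: float, rng: np.random.Generator) -> float:
    """Symmetric uniform proposal on (current - delta, current + delta)."""
    if not delta > 0:
        raise ValidationError(f"delta must be > 0, got {delta}")
    return float(rng.uniform(current - delta, current + delta))


def acceptance_ratio(
    proposal: Sequence[float] | np.ndarray,
    current: Sequence[float] | np.ndarray,
    obs: AggregateObservation,
    profile: CellLineProfile,
    prior: PriorConfig,
    eps_n: float = EPS_N,
) -> float:
    """Metropolis acceptance ratio r = post(proposal) / post(current).

    Computed as an exponentiated difference of unnormalized log-posteriors,
    so the prior bound M cancels exactly.  Proposals outside [eps_n, M]
    give r = 0; a *current* state outside the support indicates chain
    corruption and raises :class:`InvalidStateError`.
    """
    cur = np.asarray(current, dtype=float).ravel()
    prop = np.asarray(proposal, dtype=float).ravel()
    if np.any(cur < eps_n) or np.any(cur > prior.upper_bound):
        raise InvalidStateError(
            f"current chain state {cur} lies outside [{eps_n}, {prior.upper_bound}]"
        )
    if np.any(prop < eps_n) or np.any(prop > prior.upper_bound):
        return 0.0
    log_r = log_unnormalized_posterior(prop, obs, profile, prior) - log_unnormalized_posterior(
        cur, obs, profile, prior
    )
    # cap to avoid inf -> the accept rule only needs min(r, 1)
    return math.exp(min(log_r, 0.0)) if log_r < 0 else math.exp(min(log_r, 700.0))


def initial_counts(
    obs: AggregateObservation,
    profile: CellLineProfile,
    prior: PriorConfig,
    strategy: str = "nnls",
    eps_n: float = EPS_N,
) -> np.ndarray:
    """Starting state for the chain.

    ``"nnls"`` solves the mean equations e_sum ~ mu_hat^T N by nonnegative
    least squares and clips into [eps_n, M]; this starts the chain near the
    posterior mass and shortens burn-in.  ``"flat"`` (also the fallback
    when NNLS degenerates) puts every component at the count that matches
    the total signal, sum_j e_sumj / sum_ij mu_ij.
    """
    n = profile.n_lines
    if strategy == "nnls":
        try:
            sol, _ = scipy.optimize.nnls(profile.mu_hat.T, obs.e_sum)
            if np.all(np.isfinite(sol)):
                return np.clip(sol, eps_n, prior.upper_bound)
        except Exception:
            pass
    total_mu = float(np.sum(profile.mu_hat))
    level = float(np.sum(obs.e_sum)) / total_mu if total_mu > 0 else eps_n
    return np.clip(np.full(n, level), eps_n, prior.upper_bound)


def run_chain(
    obs: AggregateObservation,
    profile: CellLineProfile,
    config: SamplerConfig | None = None,
) -> PosteriorChain:
    """Run the Metropolis-within-Gibbs chain and return retained samples.

    Per sweep, every component is updated once (propose, compute the
    acceptance ratio, accept with probability min(r, 1)).  The first
    ``n_burnin`` sweeps are discarded; afterwards every ``thin``-th sweep
    is retained until ``n_samples`` rows are collected.  Fully
    deterministic for a fixed seed.
    """
    config = config or SamplerConfig()
    _check_attributes(obs, profile)
    n = profile.n_lines
    M = config.prior.upper_bound
    rng = np.random.default_rng(config.seed)

    mu = profile.mu_hat  # (n, m)
    sig2 = profile.sigma_hat**2  # (n, m)
    e = obs.e_sum  # (m,)
    # columns whose count-weighted variance would vanish get a permanent floor
    col_dead = np.all(sig2 == 0.0, axis=0)
    floor = np.where(col_dead, _default_var_floor(e), 0.0)

    state = initial_counts(obs, profile, config.prior, config.init)
    mean = state @ mu
    var = state @ sig2 + floor
    if np.any(var <= 0):
        # possible when some (not all) rows of a column are zero-variance
        var = np.where(var <= 0, var + _default_var_floor(e), var)

    def loglik(mean_vec: np.ndarray, var_vec: np.ndarray) -> float:
        return float(
            -0.5 * np.sum(np.log(2.0 * np.pi * var_vec) + (e - mean_vec) ** 2 / var_vec)
        )

    cur_ll = loglik(mean, var)

    if isinstance(config.delta, str):  # "auto"
        # start near the per-component posterior SD scale implied by the profile
        scale = np.maximum(np.abs(state), 1.0)
        delta = 0.2 * scale
        adapt = config.n_burnin > 0
    else:
        delta = np.broadcast_to(np.asarray(config.delta, dtype=float), (n,)).copy()
        adapt = False

    total_sweeps = config.n_burnin + config.n_samples * config.thin
    retained = np.empty((config.n_samples, n))
    accepted_post = np.zeros(n)
    proposed_post = np.zeros(n)
    accepted_win = np.zeros(n)
    kept = 0

    for sweep in range(total_sweeps):
        in_burnin = sweep < config.n_burnin
        for i in range(n):
            prop_i = rng.uniform(state[i] - delta[i], state[i] + delta[i])
            u = rng.random()  # drawn unconditionally to keep the stream aligned
            if prop_i < EPS_N or prop_i > M:
                if not in_burnin:
                    proposed_post[i] += 1
                continue
            d = prop_i - state[i]
            new_mean = mean + d * mu[i]
            new_var = var + d * sig2[i]
            new_ll = loglik(new_mean, new_var)
            log_r = new_ll - cur_ll
            if log_r >= 0.0 or u < math.exp(log_r):
                state[i] = prop_i
                mean, var, cur_ll = new_mean, new_var, new_ll
                accepted_win[i] += 1
                if not in_burnin:
                    accepted_post[i] += 1
            if not in_burnin:
                proposed_post[i] += 1
        if adapt and in_burnin and (sweep + 1) % _ADAPT_WINDOW == 0:
            rate = accepted_win / _ADAPT_WINDOW
            delta = np.where(rate > _ACC_HIGH, delta * 2.0, delta)
            delta = np.where(rate < _ACC_LOW, delta * 0.5, delta)
            accepted_win[:] = 0.0
        if not in_burnin and (sweep - config.n_burnin + 1) % config.thin == 0:
            retained[kept] = state
            kept += 1

    assert kept == config.n_samples
    with np.errstate(invalid="ignore"):
        acc_rate = np.where(proposed_post > 0, accepted_post / proposed_post, 0.0)
    return PosteriorChain(
        samples=retained,
        acceptance_rate=acc_rate,
        cell_line_names=list(profile.cell_line_names),
        config=config,
        seed=config.seed,
        delta=delta,
    )
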