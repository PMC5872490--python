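"""Aggregate-observation likelihood and unnormalized posterior.

The aggregate attribute vector of a mixture is the per-attribute sum of the
single-cell attribute values over all cells in the mixture.  With N_i cells
of line i, the contribution of line i to attribute j is a sum of N_i i.i.d.
draws, so by the central limit theorem the total for attribute j is
approximately Gaussian with

    mean      sum_i N_i * mu_ij
    variance  sum_i N_i * sigma_ij^2

and attributes are modelled as independent, so the log-likelihood of the
whole aggregate vector is the sum of per-attribute Gaussian log-densities.
Counts carry a flat prior on [0, M]; the prior constant cancels in
Metropolis ratios, making the sampler independent of M.

All likelihood math is in log space: with many attributes and thousands of
cells the raw densities underflow double precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._errors import DegenerateVarianceError, SchemaError, ValidationError
from .profiles import CellLineProfile

__all__ = [
    "AggregateObservation",
    "PriorConfig",
    "LOG_ZERO",
    "component_log_likelihood",
    "aggregate_log_likelihood",
    "log_unnormalized_posterior",
]

#: Explicit log-zero sentinel for out-of-support counts.
LOG_ZERO = -math.inf

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class AggregateObservation:
    """One mixture's aggregate attribute vector (length m)."""

    e_sum: np.ndarray
    attribute_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.e_sum = np.asarray(self.e_sum, dtype=float).ravel()
        if not self.attribute_names:
            self.attribute_names = [f"attr{j + 1}" for j in range(self.e_sum.size)]
        self.attribute_names = [str(a) for a in self.attribute_names]
        if len(self.attribute_names) != self.e_sum.size:
            raise SchemaError(
                f"{len(self.attribute_names)} attribute names for "
                f"{self.e_sum.size} aggregate values"
            )
        if not np.all(np.isfinite(self.e_sum)):
            raise ValidationError("aggregate observation contains non-finite values")

    @property
    def n_attributes(self) -> int:
        return self.e_sum.size


@dataclass
class PriorConfig:
    """Flat prior on each count: uniform on [0, upper_bound].

    The bound M only truncates the support; Metropolis acceptance ratios
    are exactly independent of its value.
    """

    upper_bound: float = 1e6

    def __post_init__(self) -> None:
        if not self.upper_bound > 0:
            raise ValidationError(f"prior upper_bound must be > 0, got {self.upper_bound}")


def _as_counts(counts: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(counts, dtype=float).ravel()
    if arr.size == 0:
        raise ValidationError("counts vector is empty")
    return arr


def component_log_likelihood(
    e_sumj: float,
    counts: Sequence[float] | np.ndarray,
    mu_col: Sequence[float] | np.ndarray,
    sigma_col: Sequence[float] | np.ndarray,
    var_floor: float = 0.0,
) -> float:
    """Log Gaussian density of one aggregate attribute given counts.

    Evaluates log N(e_sumj; sum_i N_i mu_ij, sum_i N_i sigma_ij^2), the
    CLT approximation for a single attribute.  ``var_floor`` is added to
    the variance when the count-weighted variance is not positive.
    """
    n = _as_counts(counts)
    mu = np.asarray(mu_col, dtype=float).ravel()
    sigma = np.asarray(sigma_col, dtype=float).ravel()
    if not (n.size == mu.size == sigma.size):
        raise SchemaError(
            f"counts ({n.size}), mu ({mu.size}) and sigma ({sigma.size}) "
            "must have equal length"
        )
    mean = float(n @ mu)
    var = float(n @ (sigma**2))
    if var <= 0.0:
        if var_floor > 0.0:
            var = var + var_floor
        else:
            raise DegenerateVarianceError(
                "aggregate variance sum_i N_i sigma_ij^2 is not positive and "
                "no variance floor is enabled"
            )
    return -0.5 * (_LOG_2PI + math.log(var) + (float(e_sumj) - mean) ** 2 / var)


def _default_var_floor(e_sum: np.ndarray) -> np.ndarray:
    # 1e-12 x squared scale of each aggregate component (floor of 1e-12 for zeros)
    return 1e-12 * np.maximum(np.abs(e_sum), 1.0) ** 2


def _check_attributes(obs: AggregateObservation, profile: CellLineProfile) -> None:
    if obs.attribute_names != profile.attribute_names:
        raise SchemaError(
            "aggregate observation attributes "
            f"{obs.attribute_names} do not match profile attributes "
            f"{profile.attribute_names}"
        )


def aggregate_log_likelihood(
    obs: AggregateObservation,
    counts: Sequence[float] | np.ndarray,
    profile: CellLineProfile,
    var_floor: np.ndarray | float | None = None,
) -> float:
    """Log-likelihood of the full aggregate vector given counts.

    Attributes are independent, so this is the sum over attributes of
    :func:`component_log_likelihood`.  ``var_floor`` may be a scalar or a
    per-attribute vector; by default a floor of ``1e-12 * scale^2`` is
    applied (with a warning) only to attributes whose count-weighted
    variance is not positive.
    """
    _check_attributes(obs, profile)
    n = _as_counts(counts)
    if n.size != profile.n_lines:
        raise SchemaError(
            f"counts length {n.size} does not match {profile.n_lines} cell lines"
        )
    mean = n @ profile.mu_hat
    var = n @ (profile.sigma_hat**2)
    if var_floor is None:
        if np.any(var <= 0.0):
            floor = _default_var_floor(obs.e_sum)
            warnings.warn(
                "non-positive aggregate variance for attribute(s) "
                f"{[obs.attribute_names[j] for j in np.nonzero(var <= 0.0)[0]]}; "
                "applying default variance floor",
                stacklevel=2,
            )
            var = np.where(var <= 0.0, var + floor, var)
    else:
        floor = np.broadcast_to(np.asarray(var_floor, dtype=float), var.shape)
        var = np.where(var <= 0.0, var + floor, var)
    if np.any(var <= 0.0):
        raise DegenerateVarianceError(
            "aggregate variance is not positive for at least one attribute "
            "and the variance floor did not lift it above zero"
        )
    resid = obs.e_sum - mean
    return float(-0.5 * np.sum(_LOG_2PI + np.log(var) + resid**2 / var))


def log_unnormalized_posterior(
    counts: Sequence[float] | np.ndarray,
    obs: AggregateObservation,
    profile: CellLineProfile,
    prior: PriorConfig,
    var_floor: np.ndarray | float | None = None,
) -> float:
    """Unnormalized log-posterior of the counts vector.

    Inside the prior box [0, M]^n this equals the aggregate log-likelihood
    plus a constant (n log 1/M) that cancels in any difference of two
    values, so it is omitted; outside the box it is ``LOG_ZERO``.
    Out-of-support is a value, never an error.
    """
    n = _as_counts(counts)
    if np.any(n < 0.0) or np.any(n > prior.upper_bound):
        return LOG_ZERO
    return aggregate_log_likelihood(obs, n, profile, var_floor=var_floor)
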