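"""End-to-end composition estimation and summary quantities.

The estimator pipeline is: run the Metropolis-within-Gibbs chain on the
aggregate observation, take each component's marginal MAP from the KDE of
its chain samples, and normalize the MAP count vector into the composition
ratio pi = N / sum(N).  Estimation quality against a known truth is
measured by the root square error

    e = sqrt( sum_i (pi_i - pi_hat_i)^2 ),

the Euclidean distance between ratio vectors.  Unlike a root *mean* square
error this does not shrink automatically as the number of cell lines
grows, because the ratios are constrained to sum to one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._errors import SchemaError, ValidationError
from .density import MarginalDensity, map_estimate
from .likelihood import AggregateObservation
from .profiles import CellLineProfile
from .sampler import PosteriorChain, SamplerConfig, run_chain

__all__ = [
    "CompositionEstimate",
    "ratio",
    "root_square_error",
    "estimate_composition",
]


def ratio(counts: Sequence[float] | np.ndarray) -> np.ndarray:
    """Composition ratio pi = N / sum(N).

    Requires a strictly positive total; an all-zero count vector has no
    defined composition.
    """
    n = np.asarray(counts, dtype=float).ravel()
    if np.any(n < 0):
        raise ValidationError("counts must be >= 0")
    total = n.sum()
    if not total > 0:
        raise ValidationError("composition ratio undefined for all-zero counts")
    return n / total


def root_square_error(
    pi_true: Sequence[float] | np.ndarray, pi_est: Sequence[float] | np.ndarray
) -> float:
    """Euclidean distance between two composition-ratio vectors."""
    a = np.asarray(pi_true, dtype=float).ravel()
    b = np.asarray(pi_est, dtype=float).ravel()
    if a.size != b.size:
        raise SchemaError(f"ratio vectors have different lengths ({a.size} vs {b.size})")
    return float(np.linalg.norm(a - b))


@dataclass
class CompositionEstimate:
    """Full output of the composition estimator for one mixture.

    ``n_hat`` holds the per-component marginal MAP counts, ``pi_hat`` the
    corresponding composition ratios, ``densities`` the marginal posterior
    density of each component, and ``chain`` the posterior chain the
    estimates were extracted from.  ``error`` is filled only when the true
    composition is known (simulation studies).
    """

    cell_line_names: list[str]
    n_hat: np.ndarray
    pi_hat: np.ndarray
    densities: list[MarginalDensity]
    chain: PosteriorChain
    error: float | None = None

    def quantiles(self, q: Sequence[float] = (0.025, 0.975)) -> np.ndarray:
        """Empirical chain quantiles per component (rows: quantile levels).

        A convenience interval summary; it is a raw chain quantile, not a
        density-based credible interval.
        """
        return np.quantile(self.chain.samples, q, axis=0)

    def to_json(self) -> str:
        lo, hi = self.quantiles()
        return json.dumps(
            {
                name: {
                    "n_hat": float(self.n_hat[i]),
                    "pi_hat": float(self.pi_hat[i]),
                    "ci_low": float(lo[i]),
                    "ci_high": float(hi[i]),
                }
                for i, name in enumerate(self.cell_line_names)
            },
            indent=2,
        )

    def report(self, pi_true: Sequence[float] | None = None) -> str:
        """Human-readable table: MAP counts and 3-decimal ratios per line."""
        lines = [f"{'cell line':<16}{'N_hat':>10}{'pi_hat':>10}"]
        for i, name in enumerate(self.cell_line_names):
            lines.append(f"{name:<16}{self.n_hat[i]:>10.0f}{self.pi_hat[i]:>10.3f}")
        if pi_true is not None:
            e = root_square_error(pi_true, self.pi_hat)
            lines.append(f"root square error e = {e:.4f}")
        return "\n".join(lines)


def estimate_composition(
    obs: AggregateObservation,
    profile: CellLineProfile,
    config: SamplerConfig | None = None,
    pi_true: Sequence[float] | np.ndarray | None = None,
) -> CompositionEstimate:
    """Estimate the cell-count composition behind one aggregate observation.

    Runs the Metropolis-within-Gibbs chain, extracts each component's
    marginal MAP via KDE, and normalizes the MAP vector into ratios.
    Deterministic for a fixed ``config.seed``.  If ``pi_true`` is given
    the root square error of the estimated ratios is attached.
    """
    chain = run_chain(obs, profile, config)
    n_hat = np.empty(profile.n_lines)
    densities: list[MarginalDensity] = []
    for i in range(profile.n_lines):
        n_hat[i], dens = map_estimate(chain.samples[:, i])
        densities.append(dens)
    pi_hat = ratio(n_hat)
    err = None if pi_true is None else root_square_error(pi_true, pi_hat)
    return CompositionEstimate(
        cell_line_names=list(profile.cell_line_names),
        n_hat=n_hat,
        pi_hat=pi_hat,
        densities=densities,
        chain=chain,
        error=err,
    )
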