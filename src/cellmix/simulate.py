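"""Synthetic mixture simulation.

Generates the study design used to validate the estimator: a square
system of n cell lines and n attributes whose mean matrix is *cyclic*
(each row a left rotation of the first), per-cell attribute values drawn
from Gaussians with a constant coefficient of variation (sigma = cv * mu),
cell-by-cell profiling datasets, and aggregate observations built by
literally summing per-cell draws for the true count vector.

Two sweeps probe the estimator's failure modes:

* similarity: the first row runs linearly from 1000*k up to 1000, so k
  near 1 makes the cell lines' attribute profiles nearly identical and
  the deconvolution ill-posed;
* coefficient of variation: larger cv inflates the aggregate variance and
  widens the posterior.

Profiling draws and aggregate draws come from separate RNG streams spawned
from the master seed, so tests can vary one while holding the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import DegenerateDesignError, ValidationError
from .composition import CompositionEstimate, estimate_composition, ratio, root_square_error
from .likelihood import AggregateObservation
from .profiles import CellByCellData, CellLineProfile, estimate_profile
from .sampler import SamplerConfig

__all__ = [
    "SimulationConfig",
    "cyclic_mean_matrix",
    "similarity_first_row",
    "generate_cell_by_cell",
    "generate_aggregate",
    "simulate_dataset",
    "run_pipeline",
    "run_sweep",
]

_DEFAULT_FIRST_ROW = tuple(100.0 * (j + 1) for j in range(10))


@dataclass
class SimulationConfig:
    """One synthetic-mixture scenario.

    The mean matrix comes either from ``first_row`` directly or from the
    similarity parameterisation (``similarity`` = k, top value 1000).
    ``cv`` is the constant coefficient of variation sigma/mu; ``p_profile``
    the number of profiling cells per line; ``n_true`` the true count
    vector the aggregate observation is generated from.
    """

    n_lines: int = 10
    n_attrs: int = 10
    first_row: Sequence[float] | None = None
    similarity: float | None = None
    cv: float = 1.0
    p_profile: int = 2000
    n_true: Sequence[float] = field(default_factory=lambda: [500.0] * 10)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cv <= 0:
            raise ValidationError(f"cv must be > 0, got {self.cv}")
        if self.first_row is not None and self.similarity is not None:
            raise ValidationError("give first_row or similarity, not both")
        if self.first_row is not None and np.any(np.asarray(self.first_row) <= 0):
            raise ValidationError("first_row entries must be > 0")
        if len(self.n_true) != self.n_lines:
            raise ValidationError(
                f"n_true has {len(self.n_true)} entries for {self.n_lines} lines"
            )

    def mean_matrix(self) -> np.ndarray:
        if self.similarity is not None:
            row = similarity_first_row(self.similarity, self.n_attrs)
        elif self.first_row is not None:
            row = np.asarray(self.first_row, dtype=float)
        else:
            row = np.asarray(_DEFAULT_FIRST_ROW[: self.n_attrs])
        if row.size != self.n_attrs:
            raise ValidationError(
                f"first row has {row.size} entries for {self.n_attrs} attributes"
            )
        if self.n_lines != self.n_attrs:
            raise ValidationError("cyclic design requires n_lines == n_attrs")
        return cyclic_mean_matrix(row)


def cyclic_mean_matrix(first_row: Sequence[float] | np.ndarray) -> np.ndarray:
    """Square cyclic matrix: row i is the first row rotated left by i.

    Only the square construction is defined (n lines need n attributes);
    the rotation direction is fixed so designs are reproducible — either
    direction gives an equivalent design up to relabeling the lines.
    """
    row = np.asarray(first_row, dtype=float).ravel()
    m = row.size
    return np.vstack([np.roll(row, -i) for i in range(m)])


def similarity_first_row(k: float, m: int, top: float = 1000.0) -> np.ndarray:
    """First row under the similarity parameterisation.

    An arithmetic sequence of m values from ``top * k`` to ``top``;
    k close to 1 compresses the spread of attribute means across lines.
    At k = 1 all cell lines share one profile and cannot be told apart,
    so k >= 1 is rejected.
    """
    if not 0 <= k < 1:
        raise DegenerateDesignError(
            f"similarity k must lie in [0, 1), got {k}: at k = 1 all cell lines "
            "have identical attribute profiles and cannot be distinguished"
        )
    if m < 2:
        raise ValidationError(f"need at least 2 attributes, got {m}")
    return np.linspace(top * k, top, m)


def generate_cell_by_cell(
    mu: np.ndarray,
    cv: float,
    p: int,
    seed: int | np.random.SeedSequence | None = None,
    cell_line_names: Sequence[str] | None = None,
    attribute_names: Sequence[str] | None = None,
) -> list[CellByCellData]:
    """Draw p profiling cells per line from N(mu_ij, (cv * mu_ij)^2).

    Draws are used as-is: at cv around 1 a Gaussian attribute can go
    negative, and no truncation is applied — the estimator only consumes
    means and variances.
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    if cv <= 0:
        raise ValidationError(f"cv must be > 0, got {cv}")
    if p < 2:
        raise ValidationError(f"p must be >= 2, got {p}")
    n, m = mu.shape
    rng = np.random.default_rng(seed)
    names = list(cell_line_names) if cell_line_names else [f"line{i + 1}" for i in range(n)]
    attrs = list(attribute_names) if attribute_names else [f"attr{j + 1}" for j in range(m)]
    return [
        CellByCellData(
            cell_line_id=names[i],
            samples=rng.normal(loc=mu[i], scale=cv * mu[i], size=(p, m)),
            attribute_names=attrs,
        )
        for i in range(n)
    ]


def generate_aggregate(
    mu: np.ndarray,
    cv: float,
    n_true: Sequence[float] | np.ndarray,
    seed: int | np.random.SeedSequence | None = None,
    attribute_names: Sequence[str] | None = None,
) -> AggregateObservation:
    """Aggregate observation: sum per-cell draws over the true mixture.

    For line i, draws ``n_true[i]`` cells from N(mu_ij, (cv*mu_ij)^2) per
    attribute and adds everything — exactly how a plate-level fluorescence
    total arises from single-cell contributions.  Non-integer counts are
    rounded with a warning (cells are whole at generation time).
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    n_true = np.asarray(n_true, dtype=float).ravel()
    if n_true.size != mu.shape[0]:
        raise ValidationError(
            f"n_true has {n_true.size} entries for {mu.shape[0]} cell lines"
        )
    if np.any(n_true < 0):
        raise ValidationError("n_true entries must be >= 0")
    counts = n_true
    if not np.allclose(counts, np.round(counts)):
        warnings.warn("non-integer true counts rounded for aggregate generation",
                      stacklevel=2)
    counts = np.round(counts).astype(int)
    rng = np.random.default_rng(seed)
    n, m = mu.shape
    e_sum = np.zeros(m)
    for i in range(n):
        if counts[i] == 0:
            continue
        draws = rng.normal(loc=mu[i], scale=cv * mu[i], size=(counts[i], m))
        e_sum += draws.sum(axis=0)
    attrs = list(attribute_names) if attribute_names else [f"attr{j + 1}" for j in range(m)]
    return AggregateObservation(e_sum=e_sum, attribute_names=attrs)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[CellByCellData], CellLineProfile, AggregateObservation]:
    """Generate profiling data, the estimated profile, and the aggregate.

    The profiling and aggregate draws use independent RNG streams spawned
    from ``config.seed``.
    """
    mu = config.mean_matrix()
    ss_profile, ss_agg = np.random.SeedSequence(config.seed).spawn(2)
    cbc = generate_cell_by_cell(mu, config.cv, config.p_profile, seed=ss_profile)
    profile = estimate_profile(cbc)
    obs = generate_aggregate(mu, config.cv, config.n_true, seed=ss_agg,
                             attribute_names=profile.attribute_names)
    return cbc, profile, obs


def run_pipeline(
    config: SimulationConfig,
    sampler_config: SamplerConfig | None = None,
) -> CompositionEstimate:
    """Simulate a scenario end to end and estimate its composition.

    The root square error against the true ratios is attached to the
    returned estimate.  The sampler seed, if unset, is derived from the
    simulation seed so the whole pipeline is reproducible from one seed.
    """
    _, profile, obs = simulate_dataset(config)
    if sampler_config is None:
        sampler_config = SamplerConfig()
    if sampler_config.seed is None:
        child = np.random.SeedSequence(config.seed).spawn(3)[2]
        sampler_config = SamplerConfig(
            delta=sampler_config.delta,
            n_burnin=sampler_config.n_burnin,
            n_samples=sampler_config.n_samples,
            thin=sampler_config.thin,
            seed=int(child.generate_state(1)[0] % (2**31)),
            prior=sampler_config.prior,
            init=sampler_config.init,
        )
    pi_true = ratio(np.asarray(config.n_true, dtype=float))
    return estimate_composition(obs, profile, sampler_config, pi_true=pi_true)


def run_sweep(
    configs: Sequence[SimulationConfig],
    replicates: int = 10,
    sampler_config: SamplerConfig | None = None,
    parameter: str = "auto",
) -> pd.DataFrame:
    """Run a parameter sweep and tabulate the error per configuration.

    For each config, runs ``replicates`` independent end-to-end pipelines
    (replicate r uses seed ``config.seed + r``) and reports the mean and
    SD of the root square error.  A failing replicate is recorded as NaN
    and the sweep continues.  With a single replicate the SD column is NaN
    (not available).

    ``parameter`` picks the value labelling each row: ``"similarity"``,
    ``"cv"``, or ``"auto"`` (similarity when set, else cv).
    """
    if replicates < 1:
        raise ValidationError(f"replicates must be >= 1, got {replicates}")
    rows = []
    for config in configs:
        if parameter == "similarity" or (parameter == "auto" and config.similarity is not None):
            label = config.similarity
        else:
            label = config.cv
        errors = []
        for r in range(replicates):
            base = 0 if config.seed is None else config.seed
            rep_config = SimulationConfig(
                n_lines=config.n_lines,
                n_attrs=config.n_attrs,
                first_row=config.first_row,
                similarity=config.similarity,
                cv=config.cv,
                p_profile=config.p_profile,
                n_true=config.n_true,
                seed=base + r,
            )
            try:
                est = run_pipeline(rep_config, sampler_config)
                errors.append(est.error)
            except Exception as exc:  # keep sweeping; record the failure
                warnings.warn(f"replicate {r} of {label} failed: {exc}", stacklevel=2)
                errors.append(np.nan)
        errors = np.asarray(errors, dtype=float)
        ok = errors[np.isfinite(errors)]
        rows.append(
            {
                "parameter": label,
                "mean_e": float(np.mean(ok)) if ok.size else np.nan,
                "sd_e": float(np.std(ok, ddof=1)) if ok.size > 1 else np.nan,
                "n_ok": int(ok.size),
            }
        )
    return pd.DataFrame(rows)
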