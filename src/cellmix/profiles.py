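"""Cell-line attribute profiling.

A *profile* is the one-time, high-cost product of cell-by-cell measurement:
for each cell line and each measurable attribute (e.g. red/green/blue
fluorescence) it stores the sample mean and the Bessel-corrected sample
standard deviation of the single-cell attribute values.  Once built, the
profile serves as the database against which any number of low-cost
aggregate mixture measurements can be deconvolved.

The profile database is persisted as a long-format CSV
(``cell_line, attribute, mu, sigma``) so it is diffable and versionable;
a JSON export mirrors the same fields.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._errors import InsufficientSamplesError, ParseError, SchemaError, ValidationError

__all__ = [
    "CellByCellData",
    "CellLineProfile",
    "estimate_profile",
    "save_profile",
    "load_profile",
    "read_cell_by_cell_csv",
    "PROFILING_SIZE_WARNING_THRESHOLD",
]

#: Below this many cells per line, profiling emits a warning (not an error).
PROFILING_SIZE_WARNING_THRESHOLD = 100


@dataclass
class CellByCellData:
    """Single-cell attribute measurements for one cell line.

    Parameters
    ----------
    cell_line_id :
        Name of the cell line.
    samples :
        ``(p, m)`` array; row ``k`` holds the m attribute values measured
        on cell ``k``.  At least two cells are required (the SD estimator
        divides by ``p - 1``).
    attribute_names :
        The m attribute names, in column order.
    """

    cell_line_id: str
    samples: np.ndarray
    attribute_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError(
                f"samples for {self.cell_line_id!r} must be 2-D (cells x attributes), "
                f"got shape {self.samples.shape}"
            )
        p, m = self.samples.shape
        if not self.attribute_names:
            self.attribute_names = [f"attr{j + 1}" for j in range(m)]
        self.attribute_names = [str(a) for a in self.attribute_names]
        if len(self.attribute_names) != m:
            raise SchemaError(
                f"{len(self.attribute_names)} attribute names for {m} columns "
                f"in cell line {self.cell_line_id!r}"
            )
        if p < 2:
            raise InsufficientSamplesError(
                f"cell line {self.cell_line_id!r} has {p} cell(s); "
                "at least 2 are required to estimate a standard deviation"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError(
                f"non-finite attribute values in cell line {self.cell_line_id!r}"
            )

    @property
    def n_cells(self) -> int:
        return self.samples.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.samples.shape[1]


@dataclass
class CellLineProfile:
    """Per-cell-line attribute means and standard deviations.

    ``mu_hat`` and ``sigma_hat`` are ``(n_lines, m)`` arrays in attribute
    units.  Attribute order is significant and must match between the
    profiling phase and any aggregate observation analysed against the
    profile.
    """

    cell_line_names: list[str]
    mu_hat: np.ndarray
    sigma_hat: np.ndarray
    attribute_names: list[str]

    def __post_init__(self) -> None:
        self.cell_line_names = [str(c) for c in self.cell_line_names]
        self.attribute_names = [str(a) for a in self.attribute_names]
        self.mu_hat = np.atleast_2d(np.asarray(self.mu_hat, dtype=float))
        self.sigma_hat = np.atleast_2d(np.asarray(self.sigma_hat, dtype=float))
        n, m = len(self.cell_line_names), len(self.attribute_names)
        if self.mu_hat.shape != (n, m) or self.sigma_hat.shape != (n, m):
            raise SchemaError(
                f"profile shapes {self.mu_hat.shape}/{self.sigma_hat.shape} "
                f"inconsistent with {n} cell lines x {m} attributes"
            )
        if not (np.all(np.isfinite(self.mu_hat)) and np.all(np.isfinite(self.sigma_hat))):
            raise ValidationError("profile contains non-finite entries")
        if np.any(self.sigma_hat < 0):
            raise ValidationError("sigma_hat entries must be >= 0")

    @property
    def n_lines(self) -> int:
        return len(self.cell_line_names)

    @property
    def n_attributes(self) -> int:
        return len(self.attribute_names)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per (cell_line, attribute)."""
        rows = [
            (c, a, self.mu_hat[i, j], self.sigma_hat[i, j])
            for i, c in enumerate(self.cell_line_names)
            for j, a in enumerate(self.attribute_names)
        ]
        return pd.DataFrame(rows, columns=["cell_line", "attribute", "mu", "sigma"])

    def to_json(self) -> str:
        return json.dumps(
            {
                "cell_line_names": self.cell_line_names,
                "attribute_names": self.attribute_names,
                "mu_hat": self.mu_hat.tolist(),
                "sigma_hat": self.sigma_hat.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CellLineProfile":
        d = json.loads(text)
        return cls(
            cell_line_names=d["cell_line_names"],
            mu_hat=np.asarray(d["mu_hat"], dtype=float),
            sigma_hat=np.asarray(d["sigma_hat"], dtype=float),
            attribute_names=d["attribute_names"],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CellLineProfile):
            return NotImplemented
        return (
            self.cell_line_names == other.cell_line_names
            and self.attribute_names == other.attribute_names
            and np.array_equal(self.mu_hat, other.mu_hat)
            and np.array_equal(self.sigma_hat, other.sigma_hat)
        )


def estimate_profile(data: Iterable[CellByCellData]) -> CellLineProfile:
    """Estimate per-line attribute means and SDs from cell-by-cell data.

    For cell line i and attribute j with single-cell values
    ``e_ij1, ..., e_ijp``:

    .. math::

        \\hat\\mu_{ij} = \\frac1p \\sum_k e_{ijk}, \\qquad
        \\hat\\sigma_{ij} = \\sqrt{\\frac{\\sum_k (e_{ijk}-\\hat\\mu_{ij})^2}{p-1}}

    All datasets must share the same attribute names in the same order.
    Zero-variance attributes are allowed but trigger a warning; they are
    handled downstream by the likelihood's variance floor.
    """
    datasets = list(data)
    if not datasets:
        raise ValidationError("estimate_profile needs at least one cell line dataset")
    names = datasets[0].attribute_names
    for d in datasets[1:]:
        if d.attribute_names != names:
            raise SchemaError(
                f"attribute names of cell line {d.cell_line_id!r} "
                f"({d.attribute_names}) do not match {names}"
            )
    mu = np.vstack([d.samples.mean(axis=0) for d in datasets])
    sigma = np.vstack([d.samples.std(axis=0, ddof=1) for d in datasets])
    for d in datasets:
        if d.n_cells < PROFILING_SIZE_WARNING_THRESHOLD:
            warnings.warn(
                f"cell line {d.cell_line_id!r} profiled from only {d.n_cells} cells; "
                f"estimates may be noisy (suggested minimum "
                f"{PROFILING_SIZE_WARNING_THRESHOLD})",
                stacklevel=2,
            )
    if np.any(sigma == 0):
        zero = [
            (datasets[i].cell_line_id, names[j])
            for i, j in zip(*np.nonzero(sigma == 0))
        ]
        warnings.warn(
            f"zero-variance attribute(s) in profile: {zero}; the likelihood "
            "will apply a variance floor for affected attributes",
            stacklevel=2,
        )
    return CellLineProfile(
        cell_line_names=[d.cell_line_id for d in datasets],
        mu_hat=mu,
        sigma_hat=sigma,
        attribute_names=list(names),
    )


def save_profile(profile: CellLineProfile, path: str | Path) -> None:
    """Write a profile database as long-format CSV (or JSON for ``.json``)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(profile.to_json())
    else:
        profile.to_frame().to_csv(path, index=False)


def load_profile(path: str | Path) -> CellLineProfile:
    """Read a profile database written by :func:`save_profile`.

    Round-trips exactly: names and all matrix entries are preserved at
    full float precision.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        try:
            return CellLineProfile.from_json(path.read_text())
        except (KeyError, json.JSONDecodeError) as exc:
            raise ParseError(f"{path}: malformed profile JSON: {exc}") from exc
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pandas raises several parser exception types
        raise ParseError(f"{path}: could not parse CSV: {exc}") from exc
    required = {"cell_line", "attribute", "mu", "sigma"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(
            f"{path}: profile CSV is missing column(s) {sorted(missing)}; "
            f"header was {list(frame.columns)}"
        )
    cell_lines = list(dict.fromkeys(frame["cell_line"].astype(str)))
    attributes = list(dict.fromkeys(frame["attribute"].astype(str)))
    n, m = len(cell_lines), len(attributes)
    if len(frame) != n * m:
        raise ParseError(
            f"{path}: expected {n * m} rows for {n} cell lines x {m} attributes, "
            f"found {len(frame)}"
        )
    mu = np.empty((n, m))
    sigma = np.empty((n, m))
    line_index = {c: i for i, c in enumerate(cell_lines)}
    attr_index = {a: j for j, a in enumerate(attributes)}
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            i = line_index[str(row.cell_line)]
            j = attr_index[str(row.attribute)]
            mu[i, j] = float(row.mu)
            sigma[i, j] = float(row.sigma)
        except (ValueError, KeyError) as exc:
            raise ParseError(f"{path}, line {row_no}: bad profile row: {exc}") from exc
    return CellLineProfile(cell_lines, mu, sigma, attributes)


def read_cell_by_cell_csv(
    path: str | Path,
    cell_line_id: str | None = None,
    cell_line_column: str = "cell_line",
) -> list[CellByCellData]:
    """Read cell-by-cell attribute tables from delimited text.

    Two layouts are accepted: one file per cell line (every column is an
    attribute; ``cell_line_id`` defaults to the file stem), or one long
    file carrying a ``cell_line`` column that splits rows into lines.
    The header row names the attributes; each data row is one cell.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: could not parse CSV: {exc}") from exc
    if frame.empty:
        raise ParseError(f"{path}: no data rows")
    if cell_line_column in frame.columns:
        out = []
        for line_id, group in frame.groupby(cell_line_column, sort=False):
            values = group.drop(columns=[cell_line_column])
            out.append(
                CellByCellData(
                    cell_line_id=str(line_id),
                    samples=values.to_numpy(dtype=float),
                    attribute_names=[str(c) for c in values.columns],
                )
            )
        return out
    return [
        CellByCellData(
            cell_line_id=cell_line_id or path.stem,
            samples=frame.to_numpy(dtype=float),
            attribute_names=[str(c) for c in frame.columns],
        )
    ]
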