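import numpy as np
import pytest

from cellmix import (
    AggregateObservation,
    CellByCellData,
    CellLineProfile,
    estimate_profile,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def small_profile():
    """Hand-built 3-line x 2-attribute profile with known entries."""
    return CellLineProfile(
        cell_line_names=["A", "B", "C"],
        mu_hat=np.array([[100.0, 400.0], [250.0, 150.0], [50.0, 600.0]]),
        sigma_hat=np.array([[10.0, 40.0], [25.0, 15.0], [5.0, 60.0]]),
        attribute_names=["red", "green"],
    )


@pytest.fixture
def small_obs(small_profile):
    """Aggregate observation at the exact mean of counts [100, 200, 300]."""
    counts = np.array([100.0, 200.0, 300.0])
    return AggregateObservation(
        e_sum=counts @ small_profile.mu_hat,
        attribute_names=small_profile.attribute_names,
    )


@pytest.fixture
def gaussian_cbc(rng):
    """Two cell lines of Gaussian cell-by-cell data with known parameters."""
    mu = np.array([[200.0, 800.0], [700.0, 300.0]])
    sigma = 0.2 * mu
    return [
        CellByCellData(
            cell_line_id=f"line{i + 1}",
            samples=rng.normal(mu[i], sigma[i], size=(500, 2)),
            attribute_names=["red", "green"],
        )
        for i in range(2)
    ]


@pytest.fixture
def gaussian_profile(gaussian_cbc):
    return estimate_profile(gaussian_cbc)
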