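"""Shared fixtures: small seeded series and panels, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from ugca import SimulationConfig, TimeSeriesPanel


def ar2_series(n: int, seed: int, coeffs=(0.5, -0.3)) -> np.ndarray:
    """Stationary AR(2) with unit-variance Gaussian innovations (burn-in 100)."""
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(n + 100)
    x = np.zeros(n + 100)
    for t in range(2, n + 100):
        x[t] = coeffs[0] * x[t - 1] + coeffs[1] * x[t - 2] + eps[t]
    return x[100:]


def white_panel(n: int, n_vars: int, seed: int) -> TimeSeriesPanel:
    rng = np.random.default_rng(seed)
    return TimeSeriesPanel(
        values=rng.standard_normal((n, n_vars)),
        names=[f"W{i + 1}" for i in range(n_vars)],
    )


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(n_time=300, noise_variance=0.2, seed=42, burn_in=200)
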