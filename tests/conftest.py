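"""Shared fixtures: printed example data and seeded synthetic experiments."""

from __future__ import annotations

import numpy as np
import pytest

from soilmfc import (
    ExperimentData,
    GeneratorConfig,
    VoltageSeries,
    Window,
    WindowedDataset,
    simulate_experiment,
)

# The published worked example: ten twice-daily control-replicate voltages
# (mV) from day 6 AM through day 10 PM, used to illustrate staggering.
TABLE2_VALUES = (253.7, 245.1, 244.4, 259.9, 259.0, 250.4, 241.9, 252.6, 250.2, 253.4)
TABLE2_DAYS = tuple(6.0 + 0.5 * i for i in range(10))


@pytest.fixture
def table2_series() -> VoltageSeries:
    return VoltageSeries(
        tmfc_id="control-R1",
        treatment="control",
        times=np.array(TABLE2_DAYS),
        voltages=np.array(TABLE2_VALUES),
        missing_mask=np.zeros(10, dtype=bool),
    )


@pytest.fixture(scope="session")
def default_experiment() -> ExperimentData:
    """Full 6x6 design at the default generator settings."""
    return simulate_experiment(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def small_experiment() -> ExperimentData:
    """Reduced design (shorter run, fewer replicates) for fast pipeline tests."""
    cfg = GeneratorConfig(seed=7, n_replicates=3, duration_days=16.0)
    return simulate_experiment(cfg)


def make_cluster_dataset(
    n_per_class: int = 30,
    w: int = 6,
    separation: float = 50.0,
    spread: float = 1.0,
    labels: tuple[str, ...] = ("A", "B"),
    seed: int = 0,
) -> WindowedDataset:
    """Well-separated Gaussian clusters, one per label (class means spaced
    ``separation`` apart per component, within-class SD ``spread``)."""
    rng = np.random.default_rng(seed)
    windows = []
    for ci, label in enumerate(labels):
        centre = np.full(w, ci * separation)
        for i in range(n_per_class):
            windows.append(
                Window(centre + rng.normal(0, spread, w), label, f"{label}-{i}", 0)
            )
    return WindowedDataset(windows, w)
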