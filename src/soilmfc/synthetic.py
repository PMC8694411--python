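"""Synthetic tMFC voltage time series.

Soil terrestrial microbial fuel cells (tMFCs) produce a voltage trace that,
after an establishment transient, is well described by a linear mixed-effects
model: each cell follows its own line whose intercept and slope are the sum
of a treatment-level fixed effect and a cell-level random effect, plus
measurement noise.  This module simulates that generative model so that every
downstream stage (stability detection, windowing, classification, model
fitting) can be exercised and validated without laboratory data.

The default configuration reproduces the study design the analysis assumes:
six treatments (control plus five anthropogenic compounds) x six replicate
cells, voltage read twice a day for 31 days, with treatment intercept/slope
offsets taken from the published treatment-model fit and per-treatment
variability scaled to the published within-treatment standard errors.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "TREATMENTS",
    "DEFAULT_OFFSETS",
    "DEFAULT_VARIANCE_SCALE",
    "TransientConfig",
    "GeneratorConfig",
    "VoltageSeries",
    "ExperimentData",
    "simulate_tmfc",
    "simulate_experiment",
    "inject_gaps",
]

#: Canonical treatment labels: soil-only control plus five anthropogenic
#: compounds (gasoline, petroleum, 2,4-dinitrotoluene, urea, NPK fertilizer).
TREATMENTS: tuple[str, ...] = (
    "control",
    "gasoline",
    "DNT",
    "urea",
    "fertilizer",
    "petroleum",
)

#: Treatment (intercept offset mV, slope offset mV/day) relative to control,
#: from the published treatment-model fit.  Control is the reference (0, 0).
DEFAULT_OFFSETS: dict[str, tuple[float, float]] = {
    "control": (0.0, 0.0),
    "gasoline": (-472.09, 1.65),
    "DNT": (-12.19, -0.79),
    "urea": (15.7, 7.08),
    "fertilizer": (-290.22, 0.24),
    "petroleum": (-216.33, 8.31),
}

#: Per-treatment multiplier applied to the random-effect SDs, proportional to
#: the published within-treatment intercept SEs relative to control's
#: (24.78 mV): fertilizer/urea least variable, petroleum/gasoline most.
DEFAULT_VARIANCE_SCALE: dict[str, float] = {
    "control": 1.0,
    "gasoline": 1.19,
    "DNT": 0.71,
    "urea": 0.45,
    "fertilizer": 0.18,
    "petroleum": 2.02,
}


@dataclass(frozen=True)
class TransientConfig:
    """Establishment transient: cells start near ``onset_level`` and ramp
    linearly onto their mixed-model line by ``ramp_end_day``."""

    onset_level: float = 100.0
    ramp_end_day: float = 5.0


def _default_offsets() -> dict[str, tuple[float, float]]:
    return dict(DEFAULT_OFFSETS)


def _default_scales() -> dict[str, float]:
    return dict(DEFAULT_VARIANCE_SCALE)


@dataclass
class GeneratorConfig:
    """Parameters of the generative mixed-effects model.

    Voltage of cell *i* at time *t* (days since start):

        y_i(t) = (alpha + off_int + a_i) + (beta + off_slope + b_i) * t + eps

    with (a_i, b_i) a single bivariate-normal draw per cell (SDs ``sd_a``,
    ``sd_b``, correlation ``rho_ab``, both scaled by the treatment's
    ``variance_scale`` entry) and eps i.i.d. N(0, sd_eps^2) per time point.
    Intercepts are interpreted at ``intercept_at_day`` (default day 0).
    """

    alpha: float = 339.94  # control intercept, mV
    beta: float = 1.73  # control slope, mV/day
    treatment_offsets: dict[str, tuple[float, float]] = field(
        default_factory=_default_offsets
    )
    sd_a: float = 60.0  # SD of random intercept, mV
    sd_b: float = 1.7  # SD of random slope, mV/day
    rho_ab: float = 0.0
    sd_eps: float = 7.0  # residual SD, mV (twice-daily fluctuation scale)
    n_replicates: int = 6
    duration_days: float = 31.0
    measurements_per_day: int = 2
    transient: TransientConfig | None = field(default_factory=TransientConfig)
    variance_scale: dict[str, float] = field(default_factory=_default_scales)
    intercept_at_day: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha", "beta", "sd_a", "sd_b", "rho_ab", "sd_eps",
                     "duration_days", "intercept_at_day"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"GeneratorConfig.{name} must be finite, got {v!r}")
        if self.sd_a < 0 or self.sd_b < 0 or self.sd_eps < 0:
            raise ValueError("standard deviations must be non-negative")
        if abs(self.rho_ab) > 1:
            raise ValueError(f"|rho_ab| must be <= 1, got {self.rho_ab}")
        if self.duration_days <= 0:
            raise ValueError("duration_days must be positive")
        if self.measurements_per_day < 1:
            raise ValueError("measurements_per_day must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for label, off in self.treatment_offsets.items():
            if len(off) != 2 or not all(np.isfinite(o) for o in off):
                raise ValueError(f"offset for {label!r} must be two finite numbers")

    @property
    def treatments(self) -> tuple[str, ...]:
        return tuple(self.treatment_offsets)


@dataclass
class VoltageSeries:
    """One tMFC's voltage trace.

    ``times`` are days since experiment start (strictly increasing),
    ``voltages`` are mV, and ``missing_mask`` flags interrupted measurements
    (True = missing; the voltage value at a flagged point is unreliable).
    """

    tmfc_id: str
    treatment: str
    times: np.ndarray
    voltages: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if not (len(self.times) == len(self.voltages) == len(self.missing_mask)):
            raise ValueError(
                f"series {self.tmfc_id!r}: times/voltages/missing_mask lengths differ"
            )
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"series {self.tmfc_id!r}: times must be strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.times)

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and voltages at non-missing points."""
        keep = ~self.missing_mask
        return self.times[keep], self.voltages[keep]

    def restrict(self, start_day: float, end_day: float) -> "VoltageSeries":
        """Sub-series with start_day <= t <= end_day."""
        keep = (self.times >= start_day) & (self.times <= end_day)
        return VoltageSeries(
            self.tmfc_id,
            self.treatment,
            self.times[keep],
            self.voltages[keep],
            self.missing_mask[keep],
        )


@dataclass
class ExperimentData:
    """A collection of voltage series, one per tMFC."""

    series: list[VoltageSeries]

    def __post_init__(self) -> None:
        ids = [s.tmfc_id for s in self.series]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate tmfc_id in experiment")

    @property
    def treatments(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.series:
            if s.treatment not in seen:
                seen.append(s.treatment)
        return tuple(seen)

    @property
    def n_tmfc(self) -> int:
        return len(self.series)

    @property
    def n_per_series(self) -> list[int]:
        return [s.n_points for s in self.series]

    def subset(self, treatments: Sequence[str]) -> "ExperimentData":
        keep = set(treatments)
        return ExperimentData([s for s in self.series if s.treatment in keep])


def _series_rng(seed: int, treatment: str, replicate_index: int) -> np.random.Generator:
    # CRC32 of the label gives a stable (non-salted) per-treatment stream key,
    # so adding a treatment never perturbs another's draws.
    key = zlib.crc32(treatment.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, key, replicate_index]))


def simulate_tmfc(
    config: GeneratorConfig,
    treatment: str,
    replicate_index: int,
    rng: np.random.Generator | None = None,
) -> VoltageSeries:
    """Simulate one tMFC's voltage trace under the mixed-effects model.

    The per-cell random effects (a_i, b_i) are drawn once per series; the
    residual is drawn per time point.  If a transient is configured, the
    deterministic line is blended linearly from ``onset_level`` at day 0 to
    the mixed-model line at ``ramp_end_day`` before noise is added.
    """
    config.validate()
    if treatment not in config.treatment_offsets:
        raise KeyError(
            f"unknown treatment {treatment!r}; known: {sorted(config.treatment_offsets)}"
        )
    if rng is None:
        rng = _series_rng(config.seed, treatment, replicate_index)

    m = config.measurements_per_day
    n = int(round(config.duration_days * m)) + 1
    times = np.arange(n, dtype=float) / m

    scale = config.variance_scale.get(treatment, 1.0)
    sa, sb = config.sd_a * scale, config.sd_b * scale
    # explicit Cholesky of the 2x2 covariance; degenerates cleanly when a SD is 0
    z1, z2 = rng.standard_normal(2)
    a_i = sa * z1
    b_i = sb * (config.rho_ab * z1 + np.sqrt(1.0 - config.rho_ab**2) * z2)

    off_int, off_slope = config.treatment_offsets[treatment]
    intercept = config.alpha + off_int + a_i
    slope = config.beta + off_slope + b_i
    line = intercept + slope * (times - config.intercept_at_day)

    if config.transient is not None and config.transient.ramp_end_day > 0:
        ramp = config.transient.ramp_end_day
        u = np.clip(times / ramp, 0.0, 1.0)
        line = (1.0 - u) * config.transient.onset_level + u * line

    eps = rng.normal(0.0, config.sd_eps, size=n) if config.sd_eps > 0 else 0.0
    voltages = line + eps

    return VoltageSeries(
        tmfc_id=f"{treatment}-R{replicate_index + 1}",
        treatment=treatment,
        times=times,
        voltages=voltages,
        missing_mask=np.zeros(n, dtype=bool),
    )


def simulate_experiment(config: GeneratorConfig) -> ExperimentData:
    """Simulate the full design: one series per (treatment, replicate).

    Deterministic for a fixed ``config.seed``; the default configuration
    yields 6 treatments x 6 replicates = 36 tMFCs.
    """
    config.validate()
    series = [
        simulate_tmfc(config, treatment, r)
        for treatment in config.treatment_offsets
        for r in range(config.n_replicates)
    ]
    return ExperimentData(series)


def inject_gaps(series: VoltageSeries, gap_positions: Sequence[int]) -> VoltageSeries:
    """Return a copy with the given time points flagged as missing.

    Emulates measurement interruptions; times are unchanged, only the
    missing mask is set.
    """
    mask = series.missing_mask.copy()
    for pos in gap_positions:
        if not 0 <= pos < series.n_points:
            raise IndexError(
                f"gap position {pos} out of range for series of {series.n_points} points"
            )
        mask[pos] = True
    return replace(series, missing_mask=mask)
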