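"""Stable observation window detection.

Fresh tMFCs pass through an establishment phase before voltage settles onto
a near-linear trajectory.  Stability is judged by grouping each replicate's
measurements into consecutive, non-overlapping blocks of 3-6 points and
computing the slope within each block: once most replicates' block slopes sit
within 0 +/- 0.5 mV per measurement, the signal is considered established.
All downstream analysis is restricted to the observation window that starts
at that point (days 6-31 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synthetic import ExperimentData, VoltageSeries

__all__ = [
    "SlopeGroup",
    "ObservationWindow",
    "DEFAULT_WINDOW",
    "group_slopes",
    "find_stable_onset",
]

logger = logging.getLogger(__name__)

VALID_GROUP_SIZES = (3, 4, 5, 6)


@dataclass(frozen=True)
class SlopeGroup:
    """OLS slope of one block of consecutive measurements.

    ``slope`` is in mV per measurement interval (or mV/day when computed
    with ``per_day=True``); ``group_index`` is 1-based.
    """

    tmfc_id: str
    group_index: int
    group_size: int
    start_day: float
    slope: float


@dataclass(frozen=True)
class ObservationWindow:
    """Day range [start_day, end_day] used for downstream analysis."""

    start_day: float
    end_day: float
    criterion_threshold: float = 0.5
    quorum: float = 0.5
    onset_found: bool = True

    def __post_init__(self) -> None:
        if not self.start_day < self.end_day:
            raise ValueError(
                f"start_day ({self.start_day}) must be < end_day ({self.end_day})"
            )


#: The study's fixed observation window: day 6 through day 31.
DEFAULT_WINDOW = ObservationWindow(start_day=6.0, end_day=31.0)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        return 0.0
    return float(xc @ (y - y.mean()) / denom)


def group_slopes(
    series: VoltageSeries, group_size: int, per_day: bool = False
) -> list[SlopeGroup]:
    """Partition a series into consecutive non-overlapping blocks and return
    the OLS slope of each.

    Missing points are dropped before grouping; a trailing remainder shorter
    than ``group_size`` is discarded.  With ``per_day=False`` the regressor is
    the within-block measurement index (slope in mV per measurement); with
    ``per_day=True`` it is the measurement day (slope in mV/day).
    """
    if group_size not in VALID_GROUP_SIZES:
        raise ValueError(f"group_size must be one of {VALID_GROUP_SIZES}, got {group_size}")
    times, volts = series.observed()
    n = len(times)
    if n < group_size:
        logger.warning(
            "series %s has %d non-missing points (< group_size %d); no groups",
            series.tmfc_id, n, group_size,
        )
        return []
    out: list[SlopeGroup] = []
    for g, start in enumerate(range(0, n - group_size + 1, group_size), start=1):
        t = times[start : start + group_size]
        v = volts[start : start + group_size]
        x = t if per_day else np.arange(group_size, dtype=float)
        out.append(
            SlopeGroup(
                tmfc_id=series.tmfc_id,
                group_index=g,
                group_size=group_size,
                start_day=float(t[0]),
                slope=_ols_slope(x, v),
            )
        )
    return out


def find_stable_onset(
    experiment: ExperimentData,
    group_size: int,
    threshold: float = 0.5,
    quorum: float = 0.5,
    per_replicate: bool = True,
    per_day: bool = False,
) -> ObservationWindow:
    """Earliest group boundary from which the voltage is stable.

    For each group index, the fraction of replicate block-slopes with
    |slope| <= ``threshold`` is computed; the onset is the earliest group
    such that this fraction strictly exceeds ``quorum`` for that group and
    every later one.  With ``per_replicate=False``, slopes are computed on
    per-treatment mean traces instead of individual replicates.

    Returns the full range flagged ``onset_found=False`` if no such group
    exists.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not 0 < quorum <= 1:
        raise ValueError("quorum must be in (0, 1]")
    if not experiment.series:
        raise ValueError("empty experiment")

    if per_replicate:
        sources = experiment.series
    else:
        sources = [_treatment_mean_series(experiment, t) for t in experiment.treatments]

    by_index: dict[int, list[SlopeGroup]] = {}
    for s in sources:
        for grp in group_slopes(s, group_size, per_day=per_day):
            by_index.setdefault(grp.group_index, []).append(grp)
    if not by_index:
        raise ValueError("no series has enough points for the requested group size")

    indices = sorted(by_index)
    frac_ok = {
        g: float(np.mean([abs(grp.slope) <= threshold for grp in by_index[g]]))
        for g in indices
    }
    end_day = max(float(s.times[-1]) for s in experiment.series if s.n_points)

    onset: int | None = None
    for g in reversed(indices):
        if frac_ok[g] > quorum:
            onset = g
        else:
            break
    if onset is None:
        start = min(float(s.times[0]) for s in experiment.series if s.n_points)
        return ObservationWindow(start, end_day, threshold, quorum, onset_found=False)

    start_day = min(grp.start_day for grp in by_index[onset])
    return ObservationWindow(start_day, end_day, threshold, quorum, onset_found=True)


def _treatment_mean_series(experiment: ExperimentData, treatment: str) -> VoltageSeries:
    """Mean trace across a treatment's replicates (requires shared time grid)."""
    members = [s for s in experiment.series if s.treatment == treatment]
    base = members[0]
    for s in members[1:]:
        if not np.array_equal(s.times, base.times):
            raise ValueError(
                f"treatment {treatment!r}: replicates are not on a shared time grid"
            )
    volts = np.vstack([np.where(s.missing_mask, np.nan, s.voltages) for s in members])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(volts, axis=0)
    return VoltageSeries(
        tmfc_id=f"{treatment}-mean",
        treatment=treatment,
        times=base.times,
        voltages=np.nan_to_num(mean),
        missing_mask=np.isnan(mean),
    )
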