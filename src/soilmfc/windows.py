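"""Staggered windowing and the train/test split.

The classifier consumes fixed-length voltage windows, not whole traces.
Training data are augmented by "staggering": every stride-1 window of w
consecutive measurements is extracted, so a gap-free run of n points yields
n - w + 1 overlapping windows, each preserving the short-term voltage
fluctuation.  At twice-daily sampling, w = 4, 5, 6 points corresponds to
2-, 2.5-, and 3-day segments.  Windows that contain a flagged missing point
or span a timing gap are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .stability import DEFAULT_WINDOW, ObservationWindow
from .synthetic import ExperimentData, VoltageSeries

__all__ = ["Window", "WindowedDataset", "stagger", "build_dataset", "split"]

logger = logging.getLogger(__name__)

PREFERRED_WINDOW_LENGTHS = (4, 5, 6)


@dataclass
class Window:
    """One fixed-length slice of a voltage series, with its label."""

    values: np.ndarray
    label: str
    source_id: str
    start_index: int  # position of the first point in the source series

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class WindowedDataset:
    """A labelled collection of equal-length windows."""

    windows: list[Window]
    w: int
    standardization: str = "raw"
    observation_window: ObservationWindow | None = None

    def __post_init__(self) -> None:
        for win in self.windows:
            if len(win.values) != self.w:
                raise ValueError(
                    f"window from {win.source_id} has length {len(win.values)}, expected {self.w}"
                )

    def __len__(self) -> int:
        return len(self.windows)

    def matrix(self) -> np.ndarray:
        """(n_windows, w) array of voltage values."""
        if not self.windows:
            return np.empty((0, self.w))
        return np.vstack([win.values for win in self.windows])

    def labels(self) -> list[str]:
        return [win.label for win in self.windows]

    @property
    def label_set(self) -> tuple[str, ...]:
        seen: list[str] = []
        for win in self.windows:
            if win.label not in seen:
                seen.append(win.label)
        return tuple(seen)

    def subset(self, indices: np.ndarray | list[int]) -> "WindowedDataset":
        return WindowedDataset(
            [self.windows[i] for i in indices],
            self.w,
            self.standardization,
            self.observation_window,
        )


def stagger(
    series: VoltageSeries,
    w: int,
    window_range: ObservationWindow | None = None,
) -> list[Window]:
    """Extract every valid stride-1 window of ``w`` consecutive points.

    The series is first restricted to ``window_range`` (if given).  A start
    position is valid when none of its ``w`` points is flagged missing and no
    adjacent pair of points is separated by more than 1.5x the series'
    nominal sampling interval (a timing gap).  ``start_index`` refers to the
    restricted series.
    """
    if w < 2:
        raise ValueError(f"window length must be >= 2, got {w}")
    if w not in PREFERRED_WINDOW_LENGTHS:
        logger.warning("window length %d is outside the usual range %s", w, PREFERRED_WINDOW_LENGTHS)
    if window_range is not None:
        series = series.restrict(window_range.start_day, window_range.end_day)
    n = series.n_points
    if n < w:
        return []

    diffs = np.diff(series.times)
    nominal = float(np.median(diffs)) if len(diffs) else 0.0
    gap_after = diffs > 1.5 * nominal if nominal > 0 else np.zeros(max(n - 1, 0), bool)

    out: list[Window] = []
    for start in range(n - w + 1):
        sl = slice(start, start + w)
        if series.missing_mask[sl].any():
            continue
        if gap_after[start : start + w - 1].any():
            continue
        out.append(
            Window(
                values=series.voltages[sl].copy(),
                label=series.treatment,
                source_id=series.tmfc_id,
                start_index=start,
            )
        )
    return out


def build_dataset(
    experiment: ExperimentData,
    w: int,
    window_range: ObservationWindow | None = DEFAULT_WINDOW,
) -> WindowedDataset:
    """Stagger every series in the experiment and pool the windows."""
    if not experiment.series:
        raise ValueError("empty experiment")
    windows: list[Window] = []
    for series in experiment.series:
        windows.extend(stagger(series, w, window_range))
    logger.info(
        "windowed %d series into %d windows of length %d",
        experiment.n_tmfc, len(windows), w,
    )
    return WindowedDataset(windows, w, observation_window=window_range)


def split(
    dataset: WindowedDataset,
    test_fraction: float = 0.2,
    mode: str = "window",
    seed: int = 0,
) -> tuple[WindowedDataset, WindowedDataset]:
    """Partition into train and test sets.

    ``mode="window"`` samples individual windows uniformly without
    replacement, with |test| = round(test_fraction * n).  Because staggered
    windows overlap, this leaks shared measurements between the partitions;
    ``mode="replicate"`` instead assigns whole tMFCs to the test set (in
    seeded random order) until the window fraction first reaches
    ``test_fraction``, which keeps overlapping windows on one side.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(dataset)
    rng = np.random.default_rng(seed)

    if mode == "window":
        n_test = int(round(test_fraction * n))
        if n_test == 0 or n_test == n:
            raise ValueError(
                f"dataset of {n} windows cannot support test_fraction={test_fraction}"
            )
        perm = rng.permutation(n)
        test_idx = np.sort(perm[:n_test])
        train_idx = np.sort(perm[n_test:])
    elif mode == "replicate":
        sources = list(dict.fromkeys(win.source_id for win in dataset.windows))
        order = [sources[i] for i in rng.permutation(len(sources))]
        counts = {src: 0 for src in sources}
        for win in dataset.windows:
            counts[win.source_id] += 1
        test_sources: set[str] = set()
        covered = 0
        for src in order:
            if covered / n >= test_fraction:
                break
            test_sources.add(src)
            covered += counts[src]
        if not test_sources or len(test_sources) == len(sources):
            raise ValueError(
                f"cannot split {len(sources)} replicates at test_fraction={test_fraction}"
            )
        test_idx = [i for i, win in enumerate(dataset.windows) if win.source_id in test_sources]
        train_idx = [i for i, win in enumerate(dataset.windows) if win.source_id not in test_sources]
    else:
        raise ValueError(f"unknown split mode {mode!r}")

    return dataset.subset(train_idx), dataset.subset(test_idx)
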