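"""Staggered windowing and z-score standardization of voltage segments.

Ten consecutive twice-daily voltages (the published worked example) are
spliced into every overlapping six-point window — ten points give five
windows — then a pooled z-score is fitted on a training split and applied.
"""

import numpy as np

from soilmfc import (
    ExperimentData,
    VoltageSeries,
    apply_standardizer,
    build_dataset,
    fit_standardizer,
    split,
    stagger,
)

values = [253.7, 245.1, 244.4, 259.9, 259.0, 250.4, 241.9, 252.6, 250.2, 253.4]
series = VoltageSeries(
    "control-R1", "control",
    times=6.0 + 0.5 * np.arange(10), voltages=np.array(values),
    missing_mask=np.zeros(10, bool),
)

windows = stagger(series, w=6, window_range=None)
print(f"{len(series.times)} points at w=6 -> {len(windows)} staggered windows")
for win in windows:
    print(f"  start {win.start_index}: {win.values}")

# a larger synthetic experiment for the split + standardization step
from soilmfc import GeneratorConfig, simulate_experiment

dataset = build_dataset(simulate_experiment(GeneratorConfig(seed=1)), w=6)
train, test = split(dataset, test_fraction=0.2, seed=1)
std = fit_standardizer(train, "all")
train_std = apply_standardizer(train, std)
values = train_std.matrix().ravel()
print(f"\n{len(dataset)} windows total; {len(test)} (20%) held out for testing")
print(f"pooled z-score on training values: mean {values.mean():+.2e}, "
      f"sd {values.std(ddof=1):.6f}")
print(
    "\nEvery window is a verbatim slice of its trace, so the short-term"
    "\nfluctuation the classifier keys on survives the augmentation."
)
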