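"""Simulate the full tMFC incubation and summarise the voltage regimes.

Generates the default design — six treatments x six replicate cells, voltage
read twice a day for 31 days — and prints each treatment's mean voltage at
day 10 and at the end of the run.
"""

import numpy as np

from soilmfc import GeneratorConfig, simulate_experiment

experiment = simulate_experiment(GeneratorConfig(seed=1))
print(f"simulated {experiment.n_tmfc} tMFCs, "
      f"{experiment.series[0].n_points} measurements each\n")

print(f"{'treatment':<12}{'day 10 mean (mV)':>18}{'day 31 mean (mV)':>18}")
for treatment in experiment.treatments:
    members = [s for s in experiment.series if s.treatment == treatment]
    at10 = np.mean([s.voltages[np.argmin(np.abs(s.times - 10.0))] for s in members])
    at31 = np.mean([s.voltages[-1] for s in members])
    print(f"{treatment:<12}{at10:>18.1f}{at31:>18.1f}")

print(
    "\nUrea cells run highest and gasoline lowest (negative), with control,"
    "\nDNT and petroleum converging to similar levels — the separation the"
    "\nclassifier and the mixed models exploit."
)
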