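"""Mixed-effects analysis of treatment effects on voltage trajectories.

Fits the baseline model (Voltage ~ Days + (1|tMFC)) and the treatment model
(Voltage ~ Days * Treatment + (1|tMFC)) by maximum likelihood over the
stable window (days 6-31), compares them, and runs the end-state ANOVA.
"""

from soilmfc import (
    GeneratorConfig,
    compare_models,
    end_state_anova,
    fit_baseline,
    fit_single_treatment,
    fit_treatment,
    simulate_experiment,
)

experiment = simulate_experiment(GeneratorConfig(seed=1))

baseline = fit_baseline(experiment)
treatment = fit_treatment(experiment)
lrt = compare_models(treatment, baseline)

print("baseline:  ", baseline.summary_frame().round(2).to_string(index=False))
print(f"\ntreatment model contrasts vs control (estimate +/- SE):")
for fe in treatment.fixed_effects:
    if fe.name.endswith(("_intercept", "_slope")):
        print(f"  {fe.name:<22}{fe.estimate:>9.2f} +/- {fe.se:.2f}   p={fe.p:.2g}")

print(f"\nLRT: chi2={lrt.statistic:.1f} (df={lrt.df}), p={lrt.p:.2g} "
      f"-> preferred: {lrt.preferred}")
print(f"R2 (fixed effects): baseline {baseline.r2_marginal:.2f} "
      f"-> treatment {treatment.r2_marginal:.2f}; "
      f"R2 (fixed+random) ~ {treatment.r2_conditional:.2f}")

urea = fit_single_treatment(experiment, "urea")
print(f"\nurea-only fit: slope {urea.fixed_effect('slope').estimate:.2f} "
      f"+/- {urea.fixed_effect('slope').se:.2f} mV/day")

anova = end_state_anova(experiment)
print(f"\nend-state ANOVA: F={anova.f_stat:.1f}, p={anova.p_value:.2g}")
print(anova.tukey[anova.tukey["group1"].eq("control") | anova.tukey["group2"].eq("control")]
      .to_string(index=False))

print(
    "\nTreatment terms absorb most of the pooled variance (the marginal R2"
    "\njump), and Tukey separates urea/gasoline/fertilizer from control at"
    "\nthe final time point while DNT does not differ."
)
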