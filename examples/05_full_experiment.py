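"""Simulate and analyse a complete incubation experiment.

Generates the default factorial design — 4 meiofauna treatments × 3 cores
× 3 solutes × 3 replicate profiles × 3 weekly time points = 324 profiles —
and runs the whole chain: speciation, horizon detection, flux fitting and
oxygen budgets, aggregated to treatment level.
"""

from sedflux import RunConfig, analyze_experiment, simulate_experiment

experiment, truths = simulate_experiment(seed=1)
print(f"simulated {len(experiment)} profiles, {len(truths)} core×week ground truths\n")

result = analyze_experiment(experiment, RunConfig(seed=1))

cols = ["treatment", "timepoint_day", "opd_mm_mean", "sulfide_horizon_mm_mean",
        "flux_o2_mean", "flux_h2s_mean", "sulfide_fraction_pct_mean"]
print(result.per_treatment[cols].round(2).to_string(index=False))

print("\n" + result.log)
print(
    "\nRead the first week's rows: dense meiofauna deepen the sulfide "
    "horizon and collapse the sulfide efflux relative to the control; by "
    "the later weeks the treatments converge as sulfide oxidizers "
    "establish in all cores — the pattern the generator encodes."
)
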