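"""Simulate a mixed registry and run the classification algorithm.

Generates 2,000 synthetic patients (true PD trajectories, confounder
archetypes for every exclusion rule, untreated mimics), classifies each
one, and prints the status breakdown plus the selection funnel.
"""

from pdmedalgo import classify_cohort, default_codebook
from pdmedalgo.simulate import ScenarioConfig, simulate_cohort

codebook = default_codebook()
sim = simulate_cohort(ScenarioConfig(n_patients=2000, seed=1), codebook)
table, funnel, outcomes = classify_cohort(sim.dataset, codebook)

print("Status breakdown (probable/possible are algorithm-PD):")
print(table["status"].value_counts().to_string())

print("\nSelection funnel (patients surviving each step):")
print(funnel.to_string(index=False))

merged = table.merge(sim.truth, on="patient_id")
agreement = (merged["status"] == merged["intended_status"]).mean()
print(f"\nAgreement with generator ground truth: {100 * agreement:.1f}%")
print("Each archetype is built to satisfy exactly one rule, so agreement")
print("near 100% means no rule leaks into another's territory.")
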