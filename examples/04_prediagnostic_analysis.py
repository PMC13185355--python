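"""Pre-diagnostic matched case-control analysis.

Generates cases with constipation codes enriched from 10 years before
the index date, matches never-APM/never-PD controls 1:4 on sex and age,
and reports in which offset-years the case-control difference is
significant after FDR correction.
"""

from datetime import date

from pdmedalgo.prediagnostic import (
    MatchSpec, add_fdr, annual_dx_prevalence, compare_groups, select_controls,
)
from pdmedalgo.simulate import ProdromalModel, simulate_prediagnostic_scenario

model = ProdromalModel(baselines={"K59": 0.06}, divergence_onset={"K59": 10},
                       peak_ratio={"K59": 2.0}, shape="step")
sim = simulate_prediagnostic_scenario(n_cases=400, controls_per_case=6,
                                      model=model, seed=4)
ds = sim.dataset

cases = sim.truth[sim.truth["truth"] == "pd"][["patient_id", "anchor_date"]]
cases = cases.rename(columns={"anchor_date": "index_date"})
cases["index_date"] = cases["index_date"].map(date.fromisoformat)
pool = sim.truth[sim.truth["truth"] == "non_pd"][["patient_id"]]

cohort = select_controls(cases, pool, ds.patients, ds.extraction_date,
                         MatchSpec(ratio=4, seed=4))
print(f"Matched {len(cohort.matches)} cases 1:4 "
      f"({len(cohort.unmatched)} under-matched)")

points = annual_dx_prevalence(cohort, ds.diagnoses, ds.patients, "K59")
results = add_fdr(compare_groups(points))
sig = results[results["p_adj"] < 0.05].sort_values("offset")
print("\nOffset-years with FDR-significant constipation excess in future cases")
print("(offset 0 = the year immediately before the index date):")
print(sig[["offset", "case_proportion", "control_proportion", "diff", "p_adj"]]
      .to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print("\nThe significant block should begin near offset -10, where the")
print("generator planted the start of the divergence.")
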