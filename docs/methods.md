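# Methods

This note documents the models and conventions behind `pdmedalgo`: what
the classification rules compute, how the day-level ambiguities of a
calendar-phrased rule set were resolved, what the synthetic generator
does and does not emulate, and the numerical choices in the statistical
machinery.

## The classification model

The algorithm assumes two things about PD in an insured population with
comprehensive pharmacy capture: (1) essentially all PD patients
eventually receive sustained antiparkinsonian medication (APM), so
repeated APM purchases are a high-sensitivity signal; and (2) the other
indications for dopaminergic drugs (hyperprolactinemia and pituitary
adenoma, postpartum lactation suppression, hydrocephalus, brain injury,
atypical parkinsonism, restless legs, drug-induced parkinsonism) leave
their own diagnostic and purchasing fingerprints, so specificity can be
recovered by rules rather than by requiring specialist codes.

Pipeline order is fixed: inclusion → exclusions (any firing rule
excludes) → certainty grading → index date. Exclusion precedes
certainty, so a patient with both an exclusion fingerprint and a
"possible" weakness is excluded. Every evaluated criterion is retained
in a per-patient audit trail so cohort funnels and individual verdicts
are traceable.

### Temporal conventions

The rules are phrased in calendar language; the day-level boundaries are
centralized in `config.AlgorithmConfig` and shared by the engine, the
generator and the test oracle:

| phrase | days | note |
|---|---|---|
| one month | 30 | post-FPD grace for hospital-logged diagnoses |
| six months | 183 | brain-injury look-back; "less than six months" of APM |
| one year / "year prior" | 365 | `[FPD − 365 d, FPD)`, half-open |
| N years | round(N × 365.25) | 731, 1096, 1826 for 2, 3, 5 years |

"Two separate occasions" means two distinct purchase dates (same-day
multi-drug purchases are one clinical event). "Exceeding N years" means
a strictly larger day count. Elapsed-time clauses (time since last APM
purchase, follow-up length) run to the patient's observation end: the
earliest of death, HMO exit (last insurance end) and data extraction.
Age is completed years. "Exclusively purchased X" is evaluated over APM
purchases only; non-APM drugs never break exclusivity. A subsequent PD
diagnosis "rescues" an atypical-parkinsonism or RLS trail only if
strictly later than the last such diagnosis (a same-day tie does not).

Two readings were genuinely open and are resolved as follows. The
combined antipsychotic + levodopa "possible" rule is read as:
antipsychotic purchase in the year before the FPD, levodopa purchased at
*any* time, and a PD diagnosis present — applying the one-year window to
the levodopa clause too would make the rule unsatisfiable, since no APM
purchase can precede the first APM purchase. Under this reading the rule
is exactly the complement of the drug-induced-parkinsonism rescue
clause, which matches its intent (keep psychiatric patients with real PD
in the cohort, flagged as possible). Second, the two printed
purchase-count/duration bullets for MAO-inhibitor and amantadine
monotherapy are treated as alternative sufficient conditions (logical
OR), making the >8-purchases-or->2-years bullet binding; both thresholds
stay configurable.

### Drug and diagnosis semantics

Rules reference semantic classes, never raw codes. The default codebook
splits ATC group N04 into six APM subclasses (levodopa compounds,
dopamine agonists, MAO-B inhibitors, amantadine, COMT inhibitors,
anticholinergics) and lists common N05A antipsychotics; ICD-10 matching
is dot-insensitive prefix matching (K59 matches K59.0), since registries
mix 3- and 4-character codes. Anticholinergics do not count toward
inclusion or the FPD (they only matter for the index-date exception);
COMT inhibitors do count. Both switches are configurable. Quetiapine at
or below 50 mg does not count as an antipsychotic trigger; a quetiapine
row with missing strength counts (conservative toward exclusion), with a
config switch to invert. The codebook is a reconstruction from the
public ATC/ICD-10 hierarchies, fully overridable per deployment — the
code lists, not the rules, are the deployment-specific part.

### Index date

Default: the earlier of the FPD and the first PD diagnosis. Exception 1:
a hyperprolactinemia/pituitary-adenoma diagnosis before the FPD switches
to the *later* of the two (the early agonist use was for the pituitary
indication). Exception 2: an anticholinergic purchase in the year before
the FPD switches to the earliest of the first anticholinergic purchase
and the PD diagnosis. When both apply, the pituitary rule wins (the more
specific indication correction; configurable). With no PD diagnosis the
min/max degenerate to the available date.

## The synthetic generator

Real claims registries cannot be shared, so the generator emulates the
event structure the algorithm consumes, with ground truth attached to
every patient. True-PD trajectories: onset age ~ N(72, 9²) clipped to
[40, 94], 56.5% male, PD diagnosis up to 120 days before the first APM
purchase, monotherapy (MAO-B inhibitor or agonist) escalating to
levodopa with probability 0.9 after an exponential delay (mean 2 years),
refills every 90 ± 20 days (prescriptions run up to three months, so
quarterly refills are the realistic cadence), post-onset mortality at an
exponential hazard of 0.055/year, 70% of PD diagnoses assigned by a
neurologist and 25% of cases with a movement-disorder-clinic contact.
One archetype per exclusion rule and per possible-grade rule is
generated to satisfy exactly its target rule and, by construction, no
other — this is what makes archetype routing a meaningful test. Two
deliberately dirty archetypes (a treated, misdiagnosed vascular
parkinsonism mimic; a true-PD patient with an unresolved late RLS code)
keep synthetic sensitivity and specificity away from 1 so the validation
machinery measures something real. The default mixed scenario weights
are 48% textbook PD, 12% untreated mimics, 2% for each of the 18 clean
confounder archetypes and 2% for each dirty archetype.

Randomness is a PCG64 generator with per-patient substreams keyed by
(seed, patient index), so editing one archetype never reshuffles another
patient's events and cohorts are byte-reproducible across runs.

Pre-diagnostic codes are planted per offset-year for future cases
(probability = baseline × rate-ratio(offset) in the offset-year window
before the patient's own index date) and as a stationary annual process
at baseline for everyone else. The default enrichment schedules ramp
linearly from 1 at the divergence onset to their peak in the final year
(constipation 1.8× from 10 years out, depressive episode 2.0× from 9,
tremor codes 3–4× from 16, smoking codes constant at 0.6–0.65×); these
are illustrative shapes, not calibrated claims. A step-shaped schedule
is available for localization experiments where the planted onset must
carry full effect size.

What the generator does **not** emulate: real demographic composition
or SES/ethnicity gradients (categorical draws only), seasonality,
coding-practice drift over calendar time, multi-gap insurance histories
(single continuous periods), or correlated comorbidity structure.
Passing tests therefore demonstrate that the rules compute what they
claim on data with the stated event structure — not that the published
operating characteristics transfer to any particular registry.

## Statistical machinery

- **Rates.** Annual counts over annual insured population (taken as an
  approximation of person-time), per 100,000, in decadal age groups
  [20–40) … [90–100). Interval estimates are exact Garwood intervals
  from chi-square quantiles: lower = χ²(α/2, 2k)/2 (0 at k = 0), upper =
  χ²(1 − α/2, 2k + 2)/2.
- **Standardization.** Direct method against the WHO world standard in
  5-year bands (the open 85+ share split 0.44/0.15/0.04 across 85–99 and
  the table renormalized to sum exactly 1). The truncated (≥ 20)
  variant renormalizes the retained bands. The CI treats band counts as
  independent Poisson draws: Var = Σ wᵢ² cᵢ/dᵢ², normal limits clipped
  at 0. With the data's own population shares as weights the AAIR
  reproduces the crude rate to 1e-9 (identity test).
- **Trends.** Incidence: Poisson GLM of counts on centered calendar year
  with a log-population offset; deviance/df > 1 triggers quasi-Poisson
  scaling (SEs multiplied by √(Pearson χ²/df)). Prevalence: binomial GLM
  on annual proportions weighted by population, log link by default so
  the slope is directly an annual percent change (logit available).
  APC = 100·(exp(β) − 1) with Wald limits on β. Strata with zero cases
  throughout are reported as missing rather than fitted. Fits require
  ≥ 3 distinct years.
- **Validation.** Probable + possible combined count as algorithm-PD.
  Wilson score intervals are the default; exact Clopper–Pearson
  intervals are always computed alongside because the two can disagree
  in the first decimal at n ≈ 100, and reports print both. Percentages
  display at one decimal, half-up.
- **Matching.** Exact on sex and age within ±1 year at the case's index
  date, 1:4 without replacement, controls drawn from never-APM/never-PD
  members, required to be alive at the case's index date, insured at it,
  with observation ending no earlier than the case's and history
  starting no later. Cases are processed in seeded random order with
  seeded tie-breaks, so matching is reproducible; under-matched cases
  are reported, not dropped. Ethnicity/SES propensity balancing is out
  of scope for the default matcher (exact matching is reproducible; the
  generator draws those attributes independently anyway).
- **Pre-diagnostic comparisons.** Offset-year k covers days
  [365k, 365(k+1)) before the index date; controls inherit the matched
  case's index date. A subject contributes to an offset's denominator
  only when insured at least one day in the window and the window does
  not reach before their first insurance start. 2×2 chi-squared without
  continuity correction; Wald CI on the difference in proportions;
  degenerate tables (zero margin) are flagged and skipped.
  Benjamini–Hochberg adjustment is applied within one diagnosis code's
  family of offsets (per stratum) — the families are the per-code curves
  a reader inspects. In localization summaries the divergence onset is
  the start of the contiguous significant block ending at offset 0;
  isolated deeper rejections are the α-level noise FDR admits.

## Problem sizes

The test suite and acceptance script run the oracle-equivalence check on
1,000 mixed-archetype patients, archetype routing at 50 patients per
clean archetype, operating characteristics on a 5,000-patient mixed
cohort, APC recovery over 500 replicates of a 20-year Poisson series at
a 5-million denominator, Wilson coverage over 10,000 binomial draws, the
null-calibrated pre-diagnostic pipeline at 250 cases (1:4) and the
planted-divergence run at 800 cases. These sizes give Monte-Carlo error
well inside every asserted band while keeping a full run in the minutes
range.

## Known limitations

Sensitivity/specificity measured on the synthetic mixture reflect the
chosen archetype weights, not any registry's case mix. The rule set
cannot, by design, see never-treated PD (early cases before first
purchase are invisible until treated, which biases incidence
conservatively in the final study years). The exclusion rules trade a
small number of true PD patients with overlapping conditions (e.g.,
comorbid RLS without a refreshed PD code) for specificity — the dirty
archetypes quantify exactly this trade on synthetic data. The default
codebook is a public-hierarchy reconstruction and should be reviewed
against local dispensing lists before deployment.
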