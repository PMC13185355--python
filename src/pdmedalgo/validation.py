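"""Validation of algorithm output against a reference standard.

Sensitivity is estimated on specialist-confirmed PD cohorts (probable and
possible grades combined count as PD); specificity and the false positive
rate on a non-PD neurological mimic cohort.  Binomial proportion
confidence intervals come in two flavours: the Wilson score interval
(the default) and the exact Clopper-Pearson interval, which can disagree
in the second decimal at cohort sizes around a hundred - reports print
both when they differ after rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

POSITIVE_STATUSES = frozenset({"probable_pd", "possible_pd"})


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Display rounding: half-up at the given decimal place."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def false_positive_rate(self) -> float:
        return self.fp / (self.tn + self.fp)


@dataclass(frozen=True)
class ProportionCI:
    estimate: float
    lower: float
    upper: float
    level: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.upper <= 1.0):
            raise ValueError("CI bounds must satisfy 0 <= lower <= upper <= 1")
        if not (self.lower - 1e-12 <= self.estimate <= self.upper + 1e-12):
            raise ValueError("estimate outside its interval")


def confusion(
    predicted: Mapping[str, str],
    truth: Mapping[str, str],
    positive_statuses: frozenset[str] = POSITIVE_STATUSES,
) -> ConfusionCounts:
    """Cross-tabulate predicted status against reference labels.

    ``truth`` maps patient id to ``"pd"`` / ``"non_pd"``; a predicted
    status in ``positive_statuses`` counts as algorithm-PD.  Every labeled
    patient must have exactly one prediction.
    """
    missing = set(truth) - set(predicted)
    if missing:
        raise ValueError(f"{len(missing)} labeled patients without a prediction")
    tp = fn = tn = fp = 0
    for pid, t in truth.items():
        pos = predicted[pid] in positive_statuses
        if t == "pd":
            tp, fn = tp + pos, fn + (not pos)
        else:
            fp, tn = fp + pos, tn + (not pos)
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


def wilson_ci(successes: int, n: int, level: float = 0.95) -> ProportionCI:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    # the Wilson bounds are exactly 0/1 at the boundaries; snap float fuzz
    lo = 0.0 if successes == 0 else float(lo)
    hi = 1.0 if successes == n else float(hi)
    return ProportionCI(successes / n, lo, hi, level, "wilson")


def exact_binomial_ci(successes: int, n: int, level: float = 0.95) -> ProportionCI:
    """Clopper-Pearson interval by inversion of the binomial CDF."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="beta")
    lo = 0.0 if successes == 0 else float(lo)
    hi = 1.0 if successes == n else float(hi)
    return ProportionCI(successes / n, lo, hi, level, "exact_binomial")


def performance_report(
    cohorts: Mapping[str, ConfusionCounts],
    level: float = 0.95,
) -> pd.DataFrame:
    """Sensitivity/specificity table with CIs, one row per cohort metric."""
    rows = []
    for name, cc in cohorts.items():
        if cc.tp + cc.fn > 0:
            n = cc.tp + cc.fn
            w = wilson_ci(cc.tp, n, level)
            e = exact_binomial_ci(cc.tp, n, level)
            rows.append(_report_row(name, "sensitivity", cc.tp, n, w, e))
        if cc.tn + cc.fp > 0:
            n = cc.tn + cc.fp
            w = wilson_ci(cc.tn, n, level)
            e = exact_binomial_ci(cc.tn, n, level)
            rows.append(_report_row(name, "specificity", cc.tn, n, w, e))
            wf = wilson_ci(cc.fp, n, level)
            ef = exact_binomial_ci(cc.fp, n, level)
            rows.append(_report_row(name, "false_positive_rate", cc.fp, n, wf, ef))
    return pd.DataFrame(rows)


def _report_row(cohort, metric, k, n, w: ProportionCI, e: ProportionCI) -> dict:
    return {
        "cohort": cohort, "metric": metric, "k": k, "n": n,
        "estimate_pct": round_half_up(100 * k / n),
        "wilson_lower_pct": round_half_up(100 * w.lower),
        "wilson_upper_pct": round_half_up(100 * w.upper),
        "exact_lower_pct": round_half_up(100 * e.lower),
        "exact_upper_pct": round_half_up(100 * e.upper),
    }


# ---------------------------------------------------- ascertainment audit

def ascertainment_audit(dataset, outcomes: Iterable) -> dict:
    """Diagnosis-based completeness audit of PD case ascertainment.

    For patients with any PD diagnosis code: the share with no
    neurologist-assigned PD diagnosis and no movement-disorder-clinic
    visit, the share never purchasing an APM (overall and within the
    specialist / no-specialist subgroups), and per-calendar-year shares of
    algorithm-PD patients whose first neurologist PD diagnosis falls
    within a year of their index date.  Empty denominators are flagged
    rather than silently divided.
    """
    from .codebook import default_codebook
    codebook = default_codebook()

    dx = dataset.diagnoses
    is_pd_code = dx["icd10_code"].map(lambda c: codebook.dx_matches(c, "pd")).astype(bool)
    pd_dx = dx[is_pd_code]
    pd_patients = set(pd_dx["patient_id"])

    neuro_ids = set(pd_dx.loc[pd_dx["provider_type"] == "neurologist", "patient_id"])
    mdc_ids = set(dx.loc[dx["provider_type"] == "mdc", "patient_id"])
    specialist_ids = (neuro_ids | mdc_ids) & pd_patients
    no_specialist_ids = pd_patients - specialist_ids

    apm_ids = set(dataset.purchases.loc[dataset.purchases["apm_class"].notna()
                                        & (dataset.purchases["apm_class"] != "antipsychotic"),
                                        "patient_id"])

    def share(num: set, den: set) -> Optional[float]:
        return len(num & den) / len(den) if den else None

    report = {
        "n_pd_diagnosed": len(pd_patients),
        "share_no_specialist": share(no_specialist_ids, pd_patients),
        "share_never_apm": share(pd_patients - apm_ids, pd_patients),
        "share_never_apm_specialist": share(specialist_ids - apm_ids, specialist_ids),
        "share_never_apm_no_specialist": share(no_specialist_ids - apm_ids, no_specialist_ids),
        "empty_denominators": [k for k, v in {
            "pd_diagnosed": pd_patients, "specialist": specialist_ids,
            "no_specialist": no_specialist_ids}.items() if not v],
    }

    neuro_first = (pd_dx[pd_dx["provider_type"] == "neurologist"]
                   .groupby("patient_id")["dx_date"].min())
    per_year: dict[int, dict] = {}
    for o in outcomes:
        if getattr(o, "status", None) in POSITIVE_STATUSES and o.index_date is not None:
            y = o.index_date.year
            cell = per_year.setdefault(y, {"n": 0, "neuro_within_1y": 0})
            cell["n"] += 1
            first = neuro_first.get(o.patient_id)
            if first is not None and 0 <= (first - o.index_date).days <= 365:
                cell["neuro_within_1y"] += 1
    report["neurologist_within_first_year_by_index_year"] = {
        y: {"n": c["n"], "proportion": c["neuro_within_1y"] / c["n"]}
        for y, c in sorted(per_year.items())
    }
    return report
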