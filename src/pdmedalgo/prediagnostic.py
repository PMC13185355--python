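"""Matched case-control analysis of pre-diagnostic diagnosis codes.

Controls (never purchased APM, never diagnosed with PD) are exact-matched
to cases 1:``ratio`` without replacement on sex and age (within a year),
required to be alive at the case's index date and to have at least the
case's follow-up; each matched control inherits the case's index date as
an artificial index date.  For every diagnosis code and every offset-year
before the index date (offset 0 = the 365 days immediately preceding it,
down to offset -17), the share of subjects with at least one code in that
window is compared between groups with chi-squared tests, a Wald CI on
the difference in proportions, and Benjamini-Hochberg FDR adjustment
within each code's family of offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .codebook import _norm
from .dataset import PatientRecord, observation_end

OFFSET_YEAR_DAYS = 365
DEFAULT_OFFSETS = tuple(range(0, -18, -1))


@dataclass(frozen=True)
class MatchSpec:
    ratio: int = 4
    age_tolerance_years: int = 1
    require_alive_at_index: bool = True
    require_equal_followup: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")
        if self.age_tolerance_years < 0:
            raise ValueError("age tolerance must be >= 0")


@dataclass
class MatchedCohort:
    matches: list[tuple[str, tuple[str, ...], date]]   # (case, controls, index)
    unmatched: list[str]                               # cases with < ratio controls
    spec: MatchSpec

    @property
    def case_ids(self) -> list[str]:
        return [c for c, _, _ in self.matches]

    @property
    def control_ids(self) -> list[str]:
        return [k for _, ks, _ in self.matches for k in ks]

    def assignments(self) -> pd.DataFrame:
        rows = []
        for case, controls, idx in self.matches:
            rows.append({"patient_id": case, "group": "case", "index_date": idx,
                         "matched_case": case})
            for k in controls:
                rows.append({"patient_id": k, "group": "control", "index_date": idx,
                             "matched_case": case})
        return pd.DataFrame(rows, columns=["patient_id", "group", "index_date", "matched_case"])


def select_controls(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    patients: dict[str, PatientRecord],
    extraction_date: date,
    spec: MatchSpec = MatchSpec(),
) -> MatchedCohort:
    """Draw up to ``spec.ratio`` controls per case, without replacement.

    ``cases`` needs columns ``patient_id`` and ``index_date``; ``pool``
    needs ``patient_id`` and must already be restricted to never-APM,
    never-PD individuals.  Cases are processed in seeded random order and
    ties among eligible controls are broken by seeded draws, so the
    matching is reproducible.  Cases that cannot be fully matched are
    reported, not dropped silently.
    """
    rng = np.random.default_rng(spec.seed)
    pool_ids = list(pool["patient_id"])
    used: set[str] = set()
    matches, unmatched = [], []

    case_rows = list(cases.itertuples(index=False))
    order = rng.permutation(len(case_rows))
    for i in order:
        row = case_rows[i]
        case = patients[row.patient_id]
        idx = row.index_date if isinstance(row.index_date, date) else date.fromisoformat(str(row.index_date))
        case_age = case.age_on(idx)
        case_end = observation_end(case, extraction_date)
        eligible = []
        for pid in pool_ids:
            if pid in used or pid == row.patient_id:
                continue
            cand = patients[pid]
            if cand.sex != case.sex:
                continue
            if abs(cand.age_on(idx) - case_age) > spec.age_tolerance_years:
                continue
            if spec.require_alive_at_index and cand.death_date is not None \
                    and cand.death_date < idx:
                continue
            if spec.require_equal_followup:
                if observation_end(cand, extraction_date) < case_end:
                    continue
                if not cand.insured_on(idx):
                    continue
            eligible.append(pid)
        take = min(spec.ratio, len(eligible))
        chosen = tuple(sorted(rng.choice(eligible, size=take, replace=False))) if take else ()
        used.update(chosen)
        matches.append((row.patient_id, chosen, idx))
        if take < spec.ratio:
            unmatched.append(row.patient_id)

    matches.sort(key=lambda m: m[0])
    return MatchedCohort(matches=matches, unmatched=sorted(unmatched), spec=spec)


# ------------------------------------------------------------- prevalence

def _offset_window(index_date: date, offset: int) -> tuple[date, date]:
    """Half-open [start, end) day window of offset-year ``offset`` (<= 0)."""
    k = -offset
    end = index_date - timedelta(days=OFFSET_YEAR_DAYS * k)
    start = index_date - timedelta(days=OFFSET_YEAR_DAYS * (k + 1))
    return start, end


def _available(patient: PatientRecord, window: tuple[date, date]) -> bool:
    """Data availability: insured at least one day in the window and the
    window does not reach back before the first insurance start."""
    start, end = window
    if start < patient.first_insurance_start:
        return False
    return any(s < end and e >= start for s, e in patient.insurance_periods)


def annual_dx_prevalence(
    cohort: MatchedCohort,
    diagnoses: pd.DataFrame,
    patients: dict[str, PatientRecord],
    code: str,
    offsets: Sequence[int] = DEFAULT_OFFSETS,
) -> pd.DataFrame:
    """Share of subjects with >=1 matching diagnosis per offset-year and group.

    ``code`` is a dot-insensitive ICD-10 prefix.  Denominators count only
    subjects with available data in that offset-year, so they shrink as
    offsets reach further back.
    """
    prefix = _norm(code)
    if not prefix:
        raise ValueError("empty diagnosis code")
    dx = diagnoses[diagnoses["icd10_code"].map(
        lambda c: _norm(c).startswith(prefix)).astype(bool)]
    dx_by_patient: dict[str, list[date]] = {
        pid: sorted(g["dx_date"]) for pid, g in dx.groupby("patient_id")}

    assign = cohort.assignments()
    rows = []
    for offset in offsets:
        for group in ("case", "control"):
            num = den = 0
            sub = assign[assign["group"] == group]
            for row in sub.itertuples(index=False):
                window = _offset_window(row.index_date, offset)
                if not _available(patients[row.patient_id], window):
                    continue
                den += 1
                dates = dx_by_patient.get(row.patient_id, ())
                if any(window[0] <= d < window[1] for d in dates):
                    num += 1
            rows.append({"code": code, "offset": offset, "group": group,
                         "numerator": num, "denominator": den,
                         "proportion": num / den if den else np.nan})
    return pd.DataFrame(rows)


def compare_groups(points: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Chi-squared case/control comparison per (code, offset).

    Produces one row per comparison with the 2x2 chi-squared statistic
    (no continuity correction), its p-value and a Wald CI for the
    case-minus-control difference in proportions; zero denominators or
    degenerate tables are flagged and skipped.
    """
    z = stats.norm.ppf(1 - (1 - level) / 2)
    rows = []
    for (code, offset), sub in points.groupby(["code", "offset"], sort=False):
        g = sub.set_index("group")
        try:
            a, n1 = int(g.loc["case", "numerator"]), int(g.loc["case", "denominator"])
            b, n2 = int(g.loc["control", "numerator"]), int(g.loc["control", "denominator"])
        except KeyError:
            continue
        row = {"code": code, "offset": offset,
               "case_numerator": a, "case_denominator": n1,
               "control_numerator": b, "control_denominator": n2,
               "case_proportion": a / n1 if n1 else np.nan,
               "control_proportion": b / n2 if n2 else np.nan}
        table = np.array([[a, n1 - a], [b, n2 - b]])
        if n1 == 0 or n2 == 0 or table.sum(axis=0).min() == 0:
            row.update({"chi2": np.nan, "p": np.nan, "diff": np.nan,
                        "diff_ci_lower": np.nan, "diff_ci_upper": np.nan,
                        "skipped": True})
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            p1, p2 = a / n1, b / n2
            diff = p1 - p2
            se = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
            row.update({"chi2": float(chi2), "p": float(p), "diff": diff,
                        "diff_ci_lower": diff - z * se, "diff_ci_upper": diff + z * se,
                        "skipped": False})
        rows.append(row)
    return pd.DataFrame(rows)


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def add_fdr(comparisons: pd.DataFrame, family: str = "code") -> pd.DataFrame:
    """Attach BH-adjusted p-values, one family per diagnosis code."""
    out = comparisons.copy()
    out["p_adj"] = np.nan
    for _, idx in out.groupby(family).groups.items():
        out.loc[idx, "p_adj"] = fdr_adjust(out.loc[idx, "p"])
    return out


def stratified_run(
    cohort: MatchedCohort,
    diagnoses: pd.DataFrame,
    patients: dict[str, PatientRecord],
    codes: Sequence[str],
    offsets: Sequence[int] = DEFAULT_OFFSETS,
    age_cut: int = 75,
) -> pd.DataFrame:
    """Full comparison set: overall plus sex and age-at-index strata.

    Stratification keeps matched sets intact by filtering on the case's
    stratum.  Empty strata are skipped (the stratum simply produces no
    rows).  The overall result is a pooled recomputation, not an average
    of strata.
    """
    def subcohort(predicate) -> MatchedCohort:
        kept = [(c, ks, idx) for c, ks, idx in cohort.matches if predicate(c, idx)]
        return MatchedCohort(matches=kept, unmatched=[], spec=cohort.spec)

    strata = {
        "overall": cohort,
        "male": subcohort(lambda c, i: patients[c].sex == "male"),
        "female": subcohort(lambda c, i: patients[c].sex == "female"),
        f"age<={age_cut}": subcohort(lambda c, i: patients[c].age_on(i) <= age_cut),
        f"age>{age_cut}": subcohort(lambda c, i: patients[c].age_on(i) > age_cut),
    }
    frames = []
    for name, sub in strata.items():
        if not sub.matches:
            continue
        for code in codes:
            pts = annual_dx_prevalence(sub, diagnoses, patients, code, offsets)
            cmp_df = add_fdr(compare_groups(pts))
            cmp_df.insert(0, "stratum", name)
            frames.append(cmp_df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
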