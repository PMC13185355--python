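"""The medication-based PD classification algorithm.

Pipeline per patient: four inclusion checks (two antiparkinsonian
medication purchase occasions, insurance at the first purchase date,
study-period and age bounds), fourteen exclusion rules targeting
alternative indications for antiparkinsonian drugs (hyperprolactinemia /
pituitary adenoma, postpartum lactation suppression, hydrocephalus and
brain injury, atypical parkinsonism, restless legs, drug-induced
parkinsonism, non-continuous use), a two-tier certainty grading
(probable vs. possible), and an index date approximating disease onset.

Every evaluated criterion leaves a :class:`CriterionResult` in the audit
trail, so cohort-level selection funnels can be reconstructed and any
individual verdict can be traced to the events that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional, Sequence

import pandas as pd

from .codebook import Codebook
from .config import AlgorithmConfig, DEFAULT_CONFIG
from .dataset import EHRDataset, PatientRecord, observation_end, treatment_span

INCLUSION_IDS = ("INC1", "INC2", "INC3", "INC4")
EXCLUSION_IDS = tuple(f"EXC{i}" for i in range(1, 15))
POSSIBLE_IDS = ("POS1", "POS2", "POS3", "POS4")
INDEX_RULES = ("IDX_DEFAULT", "IDX_PITUITARY", "IDX_ANTICHOLINERGIC")

STATUSES = ("probable_pd", "possible_pd", "excluded", "not_eligible")


@dataclass(frozen=True)
class CriterionResult:
    criterion_id: str
    fired: bool
    evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.fired and not self.evidence:
            raise ValueError(f"{self.criterion_id}: fired without evidence")


@dataclass(frozen=True)
class ClassificationOutcome:
    patient_id: str
    status: str
    fpd: Optional[date]
    index_date: Optional[date]
    index_rule: Optional[str]
    age_at_index: Optional[int]
    fired: tuple[CriterionResult, ...]

    @property
    def fired_ids(self) -> tuple[str, ...]:
        """Triggered exclusion/possible rules (the audit trail in ``fired``
        additionally keeps inclusion checks and the index-date rule)."""
        return tuple(r.criterion_id for r in self.fired
                     if r.fired and r.criterion_id.startswith(("EXC", "POS")))

    @property
    def is_pd(self) -> bool:
        return self.status in ("probable_pd", "possible_pd")


@dataclass
class _PatientView:
    """Per-patient event arrays the rules operate on."""

    patient: PatientRecord
    # APM purchases that count toward inclusion/FPD/exclusivity
    apm: list[tuple[date, str, str]]            # (date, atc, apm_class)
    anticholinergic_dates: list[date]
    antipsychotic_dates: list[date]             # quetiapine dose rule applied
    levodopa_dates: list[date]
    dx: list[tuple[date, str]]                  # (date, icd10)
    obs_end: date

    @property
    def fpd(self) -> Optional[date]:
        return min((d for d, _, _ in self.apm), default=None)

    @property
    def apm_dates(self) -> list[date]:
        return [d for d, _, _ in self.apm]

    def dx_dates(self, codebook: Codebook, condition: str) -> list[date]:
        return [d for d, code in self.dx if codebook.dx_matches(code, condition)]


def _inclusion_classes(config: AlgorithmConfig) -> frozenset[str]:
    classes = {"levodopa", "dopamine_agonist", "mao_inhibitor", "amantadine"}
    if config.comt_counts_for_inclusion:
        classes.add("comt_inhibitor")
    if config.anticholinergics_count_for_inclusion:
        classes.add("anticholinergic")
    return frozenset(classes)


def build_patient_view(
    patient: PatientRecord,
    purchases: pd.DataFrame,
    diagnoses: pd.DataFrame,
    codebook: Codebook,
    extraction_date: date,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> _PatientView:
    incl = _inclusion_classes(config)
    apm, antichol, antipsy, levo = [], [], [], []
    for row in purchases.itertuples(index=False):
        cls = row.apm_class
        if cls in incl:
            apm.append((row.purchase_date, row.atc_code, cls))
        if cls == "anticholinergic":
            antichol.append(row.purchase_date)
        if cls == "antipsychotic":
            antipsy.append(row.purchase_date)
        if cls == "levodopa":
            levo.append(row.purchase_date)
    dx = [(row.dx_date, row.icd10_code) for row in diagnoses.itertuples(index=False)]
    return _PatientView(
        patient=patient,
        apm=sorted(apm),
        anticholinergic_dates=sorted(antichol),
        antipsychotic_dates=sorted(antipsy),
        levodopa_dates=sorted(levo),
        dx=sorted(dx),
        obs_end=observation_end(patient, extraction_date),
    )


def first_purchase_date(view: _PatientView) -> Optional[date]:
    """Earliest APM purchase date (FPD), or None without any APM purchase."""
    return view.fpd


# ------------------------------------------------------------- inclusion

def check_inclusion(
    view: _PatientView, config: AlgorithmConfig = DEFAULT_CONFIG
) -> tuple[bool, list[CriterionResult]]:
    """Evaluate the four inclusion requirements.

    ``fired`` on an INC result means the requirement is met.
    """
    results: list[CriterionResult] = []
    fpd = view.fpd
    occasions, _ = treatment_span(view.apm_dates)

    ok1 = occasions >= config.min_apm_occasions
    results.append(CriterionResult("INC1", ok1, (f"apm_occasions={occasions}",) if ok1 else ()))
    if fpd is None:
        results.append(CriterionResult("INC2", False))
        results.append(CriterionResult("INC3", False))
        results.append(CriterionResult("INC4", False))
        return False, results

    ok2 = view.patient.insured_on(fpd)
    results.append(CriterionResult("INC2", ok2, (f"insured_on_fpd={fpd}",) if ok2 else ()))
    ok3 = fpd >= config.min_fpd
    results.append(CriterionResult("INC3", ok3, (f"fpd={fpd}",) if ok3 else ()))
    age = view.patient.age_on(fpd)
    ok4 = config.min_age_at_fpd <= age <= config.max_age_at_fpd
    results.append(CriterionResult("INC4", ok4, (f"age_at_fpd={age}",) if ok4 else ()))
    return all(r.fired for r in results), results


# ------------------------------------------------------------- exclusions

def _exclusive_atc(view: _PatientView, codes: frozenset[str]) -> bool:
    """All APM purchases drawn from the given ATC code set (vacuously False
    without any APM purchase)."""
    return bool(view.apm) and all(atc.upper().replace(".", "") in codes for _, atc, _ in view.apm)


def _exclusive_class(view: _PatientView, cls: str) -> bool:
    return bool(view.apm) and all(c == cls for _, _, c in view.apm)


def evaluate_exclusion(
    view: _PatientView,
    criterion_id: str,
    codebook: Codebook,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> CriterionResult:
    """Evaluate one named exclusion rule against a patient's events."""
    fpd = view.fpd
    assert fpd is not None, "exclusions are evaluated after inclusion"
    has_pd = bool(view.dx_dates(codebook, "pd"))
    occasions, span = treatment_span(view.apm_dates)
    last_apm = max(view.apm_dates)
    gap_days = (view.obs_end - last_apm).days
    ev: tuple[str, ...] = ()
    fired = False

    if criterion_id == "EXC1":
        hits = view.dx_dates(codebook, "hyperprolactinemia") + view.dx_dates(codebook, "pituitary_adenoma")
        fired = bool(hits) and not has_pd
        ev = tuple(f"dx={d}" for d in sorted(hits)[:3])
    elif criterion_id == "EXC2":
        fired = (bool(view.dx_dates(codebook, "pituitary_adenoma")) and has_pd
                 and _exclusive_atc(view, codebook.bromocriptine_codes | codebook.pergolide_codes))
        ev = ("exclusive bromocriptine/pergolide with pituitary adenoma and PD dx",)
    elif criterion_id == "EXC3":
        fired = (bool(view.dx_dates(codebook, "pituitary_adenoma")) and has_pd
                 and fpd >= config.cabergoline_fpd_cutoff
                 and _exclusive_atc(view, codebook.cabergoline_codes))
        ev = (f"exclusive cabergoline, fpd={fpd}",)
    elif criterion_id == "EXC4":
        lo = fpd - timedelta(days=config.pregnancy_window_days)
        hits = [d for d in view.dx_dates(codebook, "pregnancy_or_birth") if lo <= d < fpd]
        fired = (view.patient.sex == "female"
                 and _exclusive_class(view, "dopamine_agonist")
                 and not has_pd and bool(hits))
        ev = tuple(f"pregnancy/birth dx={d}" for d in hits[:3])
    elif criterion_id == "EXC5":
        cutoff = fpd + timedelta(days=config.hydro_anoxia_after_fpd_days)
        hits = [d for d in (view.dx_dates(codebook, "hydrocephalus")
                            + view.dx_dates(codebook, "anoxic_brain_injury")) if d <= cutoff]
        fired = bool(hits)
        ev = tuple(f"dx={d}" for d in sorted(hits)[:3])
    elif criterion_id == "EXC6":
        lo = fpd - timedelta(days=config.tbi_coma_window_days)
        tbi = [d for d in view.dx_dates(codebook, "tbi") if lo <= d < fpd]
        coma = [d for d in view.dx_dates(codebook, "coma") if lo <= d < fpd]
        fired = bool(tbi) and bool(coma)
        ev = tuple(f"dx={d}" for d in sorted(tbi + coma)[:4])
    elif criterion_id in ("EXC7", "EXC8"):
        if criterion_id == "EXC7":
            hits = (view.dx_dates(codebook, "psp") + view.dx_dates(codebook, "msa")
                    + view.dx_dates(codebook, "cbd"))
        else:
            hits = view.dx_dates(codebook, "rls")
        if hits:
            last_hit = max(hits)
            pd_after = any(d > last_hit for d in view.dx_dates(codebook, "pd"))
            fired = not pd_after
            ev = (f"last competing dx={last_hit}, no subsequent PD dx",)
    elif criterion_id == "EXC9":
        lo = fpd - timedelta(days=config.antipsychotic_window_days)
        anti = [d for d in view.antipsychotic_dates if lo <= d < fpd]
        bought_levodopa = bool(view.levodopa_dates)
        fired = bool(anti) and ((not bought_levodopa) or (bought_levodopa and not has_pd))
        ev = tuple(f"antipsychotic={d}" for d in anti[:3])
    elif criterion_id in ("EXC10", "EXC11"):
        cls = "mao_inhibitor" if criterion_id == "EXC10" else "amantadine"
        over = any(occasions > n or span > dur for n, dur in config.mono_thresholds)
        fired = _exclusive_class(view, cls) and over and not has_pd
        ev = (f"exclusive {cls}: occasions={occasions}, span={span}d",)
    elif criterion_id == "EXC12":
        lo = fpd - timedelta(days=config.falls_window_before_days)
        hi = fpd + timedelta(days=config.falls_window_after_days)
        hits = [d for cond in ("recurrent_falls", "lethargy", "general_deterioration")
                for d in view.dx_dates(codebook, cond) if lo <= d <= hi]
        fired = (not has_pd) and span > config.exc12_min_span_days and bool(hits)
        ev = tuple(f"dx={d}" for d in sorted(hits)[:3])
    elif criterion_id == "EXC13":
        fired = ((not has_pd) and span < config.exc13_max_span_days
                 and gap_days > config.exc13_gap_days)
        ev = (f"span={span}d, gap_since_last_apm={gap_days}d",)
    elif criterion_id == "EXC14":
        fired = span < config.exc14_max_span_days and gap_days > config.exc14_gap_days
        ev = (f"span={span}d, gap_since_last_apm={gap_days}d",)
    else:
        raise ValueError(f"unknown exclusion criterion {criterion_id!r}")

    return CriterionResult(criterion_id, fired, ev if fired else ())


# ------------------------------------------------------------- certainty

def assign_certainty(
    view: _PatientView,
    codebook: Codebook,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> tuple[str, list[CriterionResult]]:
    """Grade an included, non-excluded patient as probable or possible."""
    fpd = view.fpd
    assert fpd is not None
    has_pd = bool(view.dx_dates(codebook, "pd"))
    _, span = treatment_span(view.apm_dates)
    last_apm = max(view.apm_dates)
    gap_days = (view.obs_end - last_apm).days
    results = []

    f1 = not has_pd
    results.append(CriterionResult("POS1", f1, ("no PD diagnosis on record",) if f1 else ()))
    followup = (view.obs_end - fpd).days
    f2 = followup < config.pos2_followup_days
    results.append(CriterionResult("POS2", f2, (f"followup={followup}d",) if f2 else ()))
    f3 = span > config.pos3_min_span_days and gap_days > config.pos3_gap_days
    results.append(CriterionResult("POS3", f3, (f"span={span}d, gap={gap_days}d",) if f3 else ()))
    lo = fpd - timedelta(days=config.antipsychotic_window_days)
    anti = [d for d in view.antipsychotic_dates if lo <= d < fpd]
    f4 = has_pd and bool(anti) and bool(view.levodopa_dates)
    results.append(CriterionResult(
        "POS4", f4, tuple(f"antipsychotic={d}" for d in anti[:3]) if f4 else ()))

    status = "possible" if any(r.fired for r in results) else "probable"
    return status, results


# ------------------------------------------------------------- index date

def compute_index_date(
    view: _PatientView,
    codebook: Codebook,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> tuple[date, str]:
    """Index date (disease-onset surrogate) and the rule that produced it.

    Default: the earlier of the FPD and the first PD diagnosis.  Two
    exceptions: a hyperprolactinemia/pituitary-adenoma diagnosis before
    the FPD switches to the *later* of FPD and PD diagnosis (the early
    agonist use was for the pituitary indication); an anticholinergic
    purchase in the year before the FPD switches to the earliest of the
    first anticholinergic purchase and the PD diagnosis (anticholinergics
    can precede other APM as early symptomatic treatment).
    """
    fpd = view.fpd
    assert fpd is not None
    pd_dates = view.dx_dates(codebook, "pd")
    first_pd = min(pd_dates) if pd_dates else None

    pituitary = any(
        d < fpd for d in (view.dx_dates(codebook, "hyperprolactinemia")
                          + view.dx_dates(codebook, "pituitary_adenoma")))
    lo = fpd - timedelta(days=config.anticholinergic_window_days)
    antichol_trigger = any(lo <= d < fpd for d in view.anticholinergic_dates)

    rules = []
    if pituitary:
        rules.append("IDX_PITUITARY")
    if antichol_trigger:
        rules.append("IDX_ANTICHOLINERGIC")
    if not rules:
        rule = "IDX_DEFAULT"
    elif len(rules) == 1:
        rule = rules[0]
    else:
        rule = "IDX_PITUITARY" if config.pituitary_exception_wins else "IDX_ANTICHOLINERGIC"

    if rule == "IDX_PITUITARY":
        idx = max(d for d in (fpd, first_pd) if d is not None)
    elif rule == "IDX_ANTICHOLINERGIC":
        first_antichol = min(view.anticholinergic_dates)
        idx = min(d for d in (first_antichol, first_pd) if d is not None)
    else:
        idx = min(d for d in (fpd, first_pd) if d is not None)
    return idx, rule


# ------------------------------------------------------------- pipeline

def classify_patient(
    patient: PatientRecord,
    purchases: pd.DataFrame,
    diagnoses: pd.DataFrame,
    codebook: Codebook,
    extraction_date: date,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> ClassificationOutcome:
    """Run the full pipeline for one patient."""
    view = build_patient_view(patient, purchases, diagnoses, codebook, extraction_date, config)
    eligible, audit = check_inclusion(view, config)
    if not eligible:
        return ClassificationOutcome(patient.patient_id, "not_eligible",
                                     view.fpd, None, None, None, tuple(audit))

    excluded = False
    for cid in EXCLUSION_IDS:
        res = evaluate_exclusion(view, cid, codebook, config)
        audit.append(res)
        excluded = excluded or res.fired
    if excluded:
        return ClassificationOutcome(patient.patient_id, "excluded",
                                     view.fpd, None, None, None, tuple(audit))

    certainty, pos_results = assign_certainty(view, codebook, config)
    audit.extend(pos_results)
    idx, idx_rule = compute_index_date(view, codebook, config)
    audit.append(CriterionResult(idx_rule, True, (f"index_date={idx}",)))
    status = "probable_pd" if certainty == "probable" else "possible_pd"
    return ClassificationOutcome(
        patient.patient_id, status, view.fpd, idx, idx_rule,
        patient.age_on(idx), tuple(audit))


def classify_cohort(
    dataset: EHRDataset,
    codebook: Codebook,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> tuple[pd.DataFrame, pd.DataFrame, list[ClassificationOutcome]]:
    """Classify every patient; return (outcome table, selection funnel, outcomes).

    The funnel counts, in pipeline order, how many patients survive each
    criterion, mirroring the shape of an algorithmic selection report.
    """
    pur_groups = {pid: g for pid, g in dataset.purchases.groupby("patient_id")}
    dx_groups = {pid: g for pid, g in dataset.diagnoses.groupby("patient_id")}
    empty_pur = dataset.purchases.iloc[0:0]
    empty_dx = dataset.diagnoses.iloc[0:0]

    outcomes = []
    for pid in sorted(dataset.patients):
        outcomes.append(classify_patient(
            dataset.patients[pid],
            pur_groups.get(pid, empty_pur),
            dx_groups.get(pid, empty_dx),
            codebook, dataset.extraction_date, config))

    rows = [{
        "patient_id": o.patient_id,
        "status": o.status,
        "fpd": o.fpd.isoformat() if o.fpd else "",
        "index_date": o.index_date.isoformat() if o.index_date else "",
        "index_rule": o.index_rule or "",
        "age_at_index": o.age_at_index if o.age_at_index is not None else "",
        "fired_criteria": ";".join(o.fired_ids),
    } for o in outcomes]
    table = pd.DataFrame(rows, columns=["patient_id", "status", "fpd", "index_date",
                                        "index_rule", "age_at_index", "fired_criteria"])

    funnel_rows = [{"step": "total", "surviving": len(outcomes)}]
    eligible = [o for o in outcomes if o.status != "not_eligible"]
    funnel_rows.append({"step": "eligible", "surviving": len(eligible)})
    surviving = list(eligible)
    for cid in EXCLUSION_IDS:
        surviving = [o for o in surviving if cid not in o.fired_ids]
        funnel_rows.append({"step": cid, "surviving": len(surviving)})
    funnel_rows.append({"step": "probable_pd",
                        "surviving": sum(o.status == "probable_pd" for o in outcomes)})
    funnel_rows.append({"step": "possible_pd",
                        "surviving": sum(o.status == "possible_pd" for o in outcomes)})
    funnel = pd.DataFrame(funnel_rows, columns=["step", "surviving"])
    return table, funnel, outcomes
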