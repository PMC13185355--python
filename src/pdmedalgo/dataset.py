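"""Longitudinal EHR tables: domain types, CSV I/O and date utilities.

Three event streams drive everything downstream: patients (with insurance
periods), medication purchases (ATC-5 coded, optional strength in mg) and
diagnoses (ICD-10 coded, with provider type).  A fourth table holds annual
population denominators for rate estimation.  Dates are ISO-8601
throughout; insurance periods are encoded in ``patients.csv`` as
``start:end`` pairs joined by ``;``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .codebook import Codebook
from .config import AlgorithmConfig, DEFAULT_CONFIG

log = logging.getLogger(__name__)

SEXES = ("male", "female")
PROVIDER_TYPES = ("neurologist", "primary_care", "hospital", "mdc", "other")
ETHNIC_GROUPS = ("ashkenazi", "yemenite", "iranian_iraqi", "north_african",
                 "israeli_born", "other", "unknown")
SES_STRATA = ("very_low", "low", "medium", "high", "very_high", "unknown")


class SchemaError(ValueError):
    """A required column is missing or a table is structurally invalid."""


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    sex: str
    birth_date: date
    death_date: Optional[date]
    insurance_periods: tuple[tuple[date, date], ...]
    ethnic_group: str = "unknown"
    ses_stratum: str = "unknown"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"{self.patient_id}: sex must be one of {SEXES}")
        if self.death_date is not None and not self.birth_date < self.death_date:
            raise ValueError(f"{self.patient_id}: birth_date must precede death_date")
        periods = sorted(self.insurance_periods)
        for (s, e) in periods:
            if s > e:
                raise ValueError(f"{self.patient_id}: insurance period start after end")
        for (_, e0), (s1, _) in zip(periods, periods[1:]):
            if s1 <= e0:
                raise ValueError(f"{self.patient_id}: overlapping insurance periods")
        object.__setattr__(self, "insurance_periods", tuple(periods))

    @property
    def first_insurance_start(self) -> date:
        return self.insurance_periods[0][0]

    @property
    def last_insurance_end(self) -> date:
        return self.insurance_periods[-1][1]

    def insured_on(self, day: date) -> bool:
        return any(s <= day <= e for s, e in self.insurance_periods)

    def age_on(self, day: date) -> int:
        """Age in completed years (floor)."""
        years = day.year - self.birth_date.year
        if (day.month, day.day) < (self.birth_date.month, self.birth_date.day):
            years -= 1
        return years


@dataclass(frozen=True)
class MedicationPurchase:
    patient_id: str
    purchase_date: date
    atc_code: str
    strength_mg: Optional[float] = None
    apm_class: Optional[str] = None   # annotated at load time

    def __post_init__(self) -> None:
        if not self.atc_code:
            raise ValueError("atc_code must be non-empty")
        if self.strength_mg is not None and self.strength_mg < 0:
            raise ValueError("strength_mg must be non-negative")


@dataclass(frozen=True)
class DiagnosisEvent:
    patient_id: str
    dx_date: date
    icd10_code: str
    provider_type: str = "other"

    def __post_init__(self) -> None:
        code = self.icd10_code.strip()
        if not (code and code[0].isalpha() and any(ch.isdigit() for ch in code)):
            raise ValueError(f"not an ICD-10-shaped code: {self.icd10_code!r}")
        if self.provider_type not in PROVIDER_TYPES:
            raise ValueError(f"unknown provider_type {self.provider_type!r}")


@dataclass
class EHRDataset:
    """A validated in-memory registry extract."""

    patients: dict[str, PatientRecord]
    purchases: pd.DataFrame       # patient_id, purchase_date, atc_code, strength_mg, apm_class
    diagnoses: pd.DataFrame       # patient_id, dx_date, icd10_code, provider_type
    population: pd.DataFrame      # year, age_low, age_high, sex, count
    extraction_date: date
    row_errors: list[str] = field(default_factory=list)

    def purchases_of(self, patient_id: str) -> pd.DataFrame:
        return self.purchases[self.purchases["patient_id"] == patient_id]

    def diagnoses_of(self, patient_id: str) -> pd.DataFrame:
        return self.diagnoses[self.diagnoses["patient_id"] == patient_id]


# ---------------------------------------------------------------- operations

def classify_purchase(
    atc_code: str,
    strength_mg: Optional[float],
    codebook: Codebook,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> Optional[str]:
    """Resolve a purchase row to an APM subclass, ``"antipsychotic"`` or None.

    Quetiapine at or below the dose threshold does not count as an
    antipsychotic trigger (low-dose quetiapine is commonly prescribed for
    non-psychotic indications).  A quetiapine row with missing strength
    counts as an antipsychotic by default (conservative toward exclusion);
    flip ``config.missing_quetiapine_strength_counts`` to invert.
    """
    apm = codebook.apm_class_of(atc_code)
    if apm is not None:
        return apm
    if codebook.is_antipsychotic(atc_code):
        if codebook.is_quetiapine(atc_code):
            if strength_mg is None:
                return "antipsychotic" if config.missing_quetiapine_strength_counts else None
            if strength_mg <= config.quetiapine_dose_threshold_mg:
                return None
        return "antipsychotic"
    return None


def observation_end(patient: PatientRecord, extraction_date: date) -> date:
    """End of a patient's observation: death, HMO exit or data extraction."""
    if not patient.insurance_periods:
        raise ValueError(f"{patient.patient_id}: no insurance period")
    candidates = [patient.last_insurance_end, extraction_date]
    if patient.death_date is not None:
        candidates.append(patient.death_date)
    return min(candidates)


def treatment_span(
    purchase_dates: Sequence[date],
) -> tuple[int, int]:
    """Occasions and duration of a purchase stream.

    Returns ``(occasion_count, duration_days)`` where an occasion is a
    distinct calendar date (same-day multi-drug purchases are one clinical
    event) and the duration is last minus first distinct date in days
    (0 for a single occasion or an empty stream).
    """
    distinct = sorted(set(purchase_dates))
    if not distinct:
        return (0, 0)
    return (len(distinct), (distinct[-1] - distinct[0]).days)


# ---------------------------------------------------------------- CSV I/O

_PATIENT_COLS = ["patient_id", "sex", "birth_date", "death_date",
                 "insurance_periods", "ethnic_group", "ses_stratum"]
_PURCHASE_COLS = ["patient_id", "purchase_date", "atc_code", "strength_mg"]
_DX_COLS = ["patient_id", "dx_date", "icd10_code", "provider_type"]
_POP_COLS = ["year", "age_low", "age_high", "sex", "count"]


def _parse_date(s) -> Optional[date]:
    if s is None or (isinstance(s, float) and pd.isna(s)) or s == "":
        return None
    return date.fromisoformat(str(s))


def _parse_periods(s: str) -> tuple[tuple[date, date], ...]:
    out = []
    for chunk in str(s).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        start_s, end_s = chunk.split(":")
        out.append((date.fromisoformat(start_s), date.fromisoformat(end_s)))
    return tuple(out)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required columns {missing}")


def load_dataset(
    data_dir: str | Path,
    codebook: Codebook,
    extraction_date: date,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> EHRDataset:
    """Load and validate the four CSV tables from ``data_dir``.

    Rows violating row-level invariants (unparseable dates, unknown
    patient ids in event tables, malformed codes) are rejected and
    reported in ``row_errors`` with their row number; structural problems
    (missing columns) raise :class:`SchemaError`.  Purchase rows are
    annotated with their semantic drug class.
    """
    data_dir = Path(data_dir)
    errors: list[str] = []

    pat_df = pd.read_csv(data_dir / "patients.csv", dtype=str, keep_default_na=False)
    _require_columns(pat_df, _PATIENT_COLS[:5], "patients.csv")
    patients: dict[str, PatientRecord] = {}
    for i, row in enumerate(pat_df.itertuples(index=False), start=2):
        try:
            rec = PatientRecord(
                patient_id=row.patient_id,
                sex=row.sex,
                birth_date=date.fromisoformat(row.birth_date),
                death_date=_parse_date(row.death_date),
                insurance_periods=_parse_periods(row.insurance_periods),
                ethnic_group=getattr(row, "ethnic_group", "unknown") or "unknown",
                ses_stratum=getattr(row, "ses_stratum", "unknown") or "unknown",
            )
            if rec.patient_id in patients:
                raise ValueError(f"duplicate patient_id {rec.patient_id}")
            patients[rec.patient_id] = rec
        except (ValueError, KeyError) as exc:
            errors.append(f"patients.csv row {i}: {exc}")

    pur_df = pd.read_csv(data_dir / "purchases.csv", dtype=str, keep_default_na=False)
    _require_columns(pur_df, _PURCHASE_COLS, "purchases.csv")
    pur_rows = []
    for i, row in enumerate(pur_df.itertuples(index=False), start=2):
        try:
            d = date.fromisoformat(row.purchase_date)
            if row.patient_id not in patients:
                raise ValueError(f"unknown patient_id {row.patient_id}")
            if d > extraction_date:
                raise ValueError(f"purchase after extraction date: {d}")
            strength = float(row.strength_mg) if row.strength_mg != "" else None
            if strength is not None and strength < 0:
                raise ValueError("negative strength_mg")
            if not row.atc_code:
                raise ValueError("empty atc_code")
            pur_rows.append((row.patient_id, d, row.atc_code, strength,
                             classify_purchase(row.atc_code, strength, codebook, config)))
        except ValueError as exc:
            errors.append(f"purchases.csv row {i}: {exc}")
    purchases = pd.DataFrame(
        pur_rows, columns=["patient_id", "purchase_date", "atc_code", "strength_mg", "apm_class"]
    )

    dx_df = pd.read_csv(data_dir / "diagnoses.csv", dtype=str, keep_default_na=False)
    _require_columns(dx_df, _DX_COLS, "diagnoses.csv")
    dx_rows = []
    for i, row in enumerate(dx_df.itertuples(index=False), start=2):
        try:
            ev = DiagnosisEvent(
                patient_id=row.patient_id,
                dx_date=date.fromisoformat(row.dx_date),
                icd10_code=row.icd10_code,
                provider_type=row.provider_type or "other",
            )
            if ev.patient_id not in patients:
                raise ValueError(f"unknown patient_id {ev.patient_id}")
            if ev.dx_date > extraction_date:
                raise ValueError(f"diagnosis after extraction date: {ev.dx_date}")
            dx_rows.append((ev.patient_id, ev.dx_date, ev.icd10_code, ev.provider_type))
        except ValueError as exc:
            errors.append(f"diagnoses.csv row {i}: {exc}")
    diagnoses = pd.DataFrame(dx_rows, columns=_DX_COLS)

    pop_path = data_dir / "population.csv"
    if pop_path.exists():
        population = pd.read_csv(pop_path)
        _require_columns(population, _POP_COLS, "population.csv")
    else:
        population = pd.DataFrame(columns=_POP_COLS)

    if errors:
        log.warning("load_dataset: rejected %d rows (%s ...)", len(errors), errors[0])
    return EHRDataset(
        patients=patients,
        purchases=purchases,
        diagnoses=diagnoses,
        population=population,
        extraction_date=extraction_date,
        row_errors=errors,
    )


def write_dataset(dataset: EHRDataset, out_dir: str | Path) -> None:
    """Write a dataset back to the four-CSV on-disk layout."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in dataset.patients.values():
        rows.append({
            "patient_id": p.patient_id,
            "sex": p.sex,
            "birth_date": p.birth_date.isoformat(),
            "death_date": p.death_date.isoformat() if p.death_date else "",
            "insurance_periods": ";".join(
                f"{s.isoformat()}:{e.isoformat()}" for s, e in p.insurance_periods
            ),
            "ethnic_group": p.ethnic_group,
            "ses_stratum": p.ses_stratum,
        })
    pd.DataFrame(rows, columns=_PATIENT_COLS).to_csv(out_dir / "patients.csv", index=False)

    pur = dataset.purchases.copy()
    if len(pur):
        pur["purchase_date"] = pur["purchase_date"].map(lambda d: d.isoformat())
    pur.drop(columns=["apm_class"], errors="ignore").to_csv(out_dir / "purchases.csv", index=False)

    dx = dataset.diagnoses.copy()
    if len(dx):
        dx["dx_date"] = dx["dx_date"].map(lambda d: d.isoformat())
    dx.to_csv(out_dir / "diagnoses.csv", index=False)

    dataset.population.to_csv(out_dir / "population.csv", index=False)
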