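"""Seeded synthetic-EHR generator with known ground truth.

Real pharmacy-claims registries cannot be shared, so this module emulates
the event structure the classification algorithm consumes: true-PD
treatment trajectories (quarterly refills, escalation from monotherapy to
levodopa, diagnosis streams with specialist involvement), one cleanly
constructed confounder archetype per exclusion rule and per
possible-grade rule, non-PD mimics, population denominators, Poisson
incidence series with an embedded trend, and planted pre-diagnostic
diagnosis-code enrichment.

Every archetype is generated so that it deterministically satisfies its
target rule's firing conditions and, by construction, no other exclusion
rule — which is what makes archetype-routing and oracle-equivalence
checks meaningful.  Randomness is a PCG64 generator with per-patient
substreams derived from ``(seed, patient_index)``, so editing one
archetype never reshuffles another patient's events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

from .codebook import Codebook, default_codebook
from .config import AlgorithmConfig, DEFAULT_CONFIG
from .dataset import EHRDataset, PatientRecord, classify_purchase

# ATC codes used by the generator (all present in the default codebook)
LEVODOPA = "N04BA02"
AGONIST = "N04BC05"        # pramipexole
BROMOCRIPTINE = "N04BC01"
CABERGOLINE = "N04BC06"
MAO_I = "N04BD02"          # rasagiline
AMANTADINE = "N04BB01"
ANTICHOLINERGIC = "N04AA01"
HALOPERIDOL = "N05AD01"

PRODROMAL_CODES = ("K59", "G25.0", "R52.1", "F32", "F17", "Z72.0")


@dataclass
class ProdromalModel:
    """Annual probabilities of pre-diagnostic codes and their case enrichment.

    ``baselines`` is the per-year probability of receiving each code in
    controls; ``rate_ratio(code, offset)`` multiplies it for future cases
    in the offset-year before their index date (offset 0 = the year
    immediately before).  Smoking-related codes carry ratios < 1.
    """

    baselines: Mapping[str, float] = field(default_factory=lambda: {
        "K59": 0.05, "G25.0": 0.004, "R52.1": 0.006,
        "F32": 0.06, "F17": 0.04, "Z72.0": 0.05,
    })
    max_offset: int = 17
    divergence_onset: Mapping[str, int] = field(default_factory=lambda: {
        "K59": 10, "G25.0": 16, "R52.1": 16, "F32": 9,
    })
    peak_ratio: Mapping[str, float] = field(default_factory=lambda: {
        "K59": 1.8, "G25.0": 4.0, "R52.1": 3.0, "F32": 2.0,
    })
    smoking_ratio: Mapping[str, float] = field(default_factory=lambda: {
        "F17": 0.6, "Z72.0": 0.65,
    })
    shape: str = "ramp"  # "ramp": gradual divergence; "step": constant from onset
    null: bool = False   # force all rate ratios to 1 (calibration runs)

    def rate_ratio(self, code: str, offset: int) -> float:
        if self.null:
            return 1.0
        if code in self.smoking_ratio:
            return self.smoking_ratio[code]
        onset = self.divergence_onset.get(code)
        if onset is None or offset > onset:
            return 1.0
        peak = self.peak_ratio[code]
        if self.shape == "step":
            return peak
        # linear ramp from 1 at the divergence onset to the peak at offset 0
        return 1.0 + (peak - 1.0) * (onset - offset) / onset


@dataclass
class ScenarioConfig:
    """Study conditions of the default mixed synthetic scenario."""

    n_patients: int = 5000
    archetype_weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    extraction_date: date = date(2025, 3, 31)
    study_start_year: int = 2005
    study_end_year: int = 2024
    fpd_year_range: tuple[int, int] = (2008, 2016)
    onset_age_mean: float = 72.0
    onset_age_sd: float = 9.0
    onset_age_bounds: tuple[int, int] = (40, 94)
    male_fraction: float = 0.565
    purchase_interval_days: int = 90        # quarterly refills
    purchase_jitter_days: int = 20
    escalation_mean_days: float = 730.0     # monotherapy -> levodopa
    escalation_prob: float = 0.9
    dx_delay_max_days: int = 120            # PD dx precedes first APM by up to this
    neurologist_fraction: float = 0.7       # PD dx assigned by a neurologist
    mdc_visit_fraction: float = 0.25
    annual_death_hazard: float = 0.055      # true-PD mortality after onset
    history_days: int = 12 * 365
    prodromal: ProdromalModel = field(default_factory=ProdromalModel)
    seed: int = 0


def _rng_for(seed: int, patient_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, patient_index]))


def _rand_day_in_year(rng: np.random.Generator, year: int) -> date:
    return date(year, 1, 1) + timedelta(days=int(rng.integers(0, 360)))


def _purchase_dates(rng: np.random.Generator, start: date, end: date,
                    interval: int, jitter: int) -> list[date]:
    """Refill dates every ``interval`` +/- ``jitter`` days from start to end."""
    out, d = [], start
    while d <= end:
        out.append(d)
        d = d + timedelta(days=int(interval + rng.integers(-jitter, jitter + 1)))
    return out


@dataclass
class _Draft:
    """Mutable scratchpad an archetype fills in before assembly."""

    pid: str
    sex: str
    fpd: date
    age_at_fpd: int
    death: Optional[date] = None
    purchases: list[tuple[date, str, Optional[float]]] = field(default_factory=list)
    diagnoses: list[tuple[date, str, str]] = field(default_factory=list)
    history_days: int = 12 * 365
    archetype_id: str = ""
    intended_status: str = "excluded"
    intended_criterion: str = ""
    truth: str = "non_pd"
    onset_year: Optional[int] = None
    anchor_date: Optional[date] = None   # index-date surrogate for prodromal planting


def _base(pid: str, rng: np.random.Generator, cfg: ScenarioConfig,
          sex: Optional[str] = None,
          age_bounds: Optional[tuple[int, int]] = None,
          fpd_years: Optional[tuple[int, int]] = None) -> _Draft:
    if sex is None:
        sex = "male" if rng.random() < cfg.male_fraction else "female"
    lo, hi = fpd_years or cfg.fpd_year_range
    fpd = _rand_day_in_year(rng, int(rng.integers(lo, hi + 1)))
    b_lo, b_hi = age_bounds or cfg.onset_age_bounds
    age = int(np.clip(round(rng.normal(cfg.onset_age_mean, cfg.onset_age_sd)), b_lo, b_hi))
    return _Draft(pid=pid, sex=sex, fpd=fpd, age_at_fpd=age, history_days=cfg.history_days)


def _finish(draft: _Draft, rng: np.random.Generator, cfg: ScenarioConfig) -> tuple[
        PatientRecord, list, list, dict]:
    """Assemble a PatientRecord + event rows from a filled draft."""
    # birth date chosen so that completed-years age at FPD equals the draft age
    extra = int(rng.integers(draft.age_at_fpd // 4 + 10, 330))
    birth = draft.fpd - timedelta(days=365 * draft.age_at_fpd + extra)
    ins_start = draft.fpd - timedelta(days=draft.history_days + int(rng.integers(0, 700)))
    ins_end = min(cfg.extraction_date, draft.death) if draft.death else cfg.extraction_date
    patient = PatientRecord(
        patient_id=draft.pid, sex=draft.sex, birth_date=birth,
        death_date=draft.death,
        insurance_periods=((ins_start, ins_end),),
        ethnic_group=("ashkenazi", "yemenite", "iranian_iraqi", "north_african",
                      "israeli_born", "other")[int(rng.integers(0, 6))],
        ses_stratum=("very_low", "low", "medium", "high", "very_high")[int(rng.integers(0, 5))],
    )
    obs_end = min(ins_end, cfg.extraction_date)
    purchases = [(draft.pid, d, atc, mg) for d, atc, mg in draft.purchases
                 if ins_start <= d <= obs_end]
    diagnoses = [(draft.pid, d, code, prov) for d, code, prov in draft.diagnoses
                 if ins_start <= d <= obs_end]
    label = {
        "patient_id": draft.pid,
        "truth": draft.truth,
        "archetype_id": draft.archetype_id,
        "intended_status": draft.intended_status,
        "intended_criterion": draft.intended_criterion,
        "onset_year": draft.onset_year if draft.onset_year is not None else "",
        "anchor_date": draft.anchor_date.isoformat() if draft.anchor_date else "",
    }
    return patient, purchases, diagnoses, label


def _continuous(draft: _Draft, rng, cfg: ScenarioConfig, atc: str, mg: float,
                until: Optional[date] = None) -> None:
    end = until or (min(cfg.extraction_date, draft.death) if draft.death else cfg.extraction_date)
    for d in _purchase_dates(rng, draft.fpd, end,
                             cfg.purchase_interval_days, cfg.purchase_jitter_days):
        draft.purchases.append((d, atc, mg))


def _pd_dx(draft: _Draft, rng, cfg: ScenarioConfig, when: date) -> None:
    prov = "neurologist" if rng.random() < cfg.neurologist_fraction else "primary_care"
    draft.diagnoses.append((when, "G20", prov))
    if rng.random() < cfg.mdc_visit_fraction:
        draft.diagnoses.append((when + timedelta(days=int(rng.integers(10, 200))), "G20", "mdc"))


# ------------------------------------------------------------- archetypes

def _arch_pd_textbook(draft, rng, cfg):
    """True PD: diagnosis, monotherapy start, escalation to levodopa."""
    dx_date = draft.fpd - timedelta(days=int(rng.integers(0, cfg.dx_delay_max_days + 1)))
    _pd_dx(draft, rng, cfg, dx_date)
    draft.truth = "pd"
    draft.onset_year = dx_date.year
    draft.anchor_date = min(dx_date, draft.fpd)

    t_death = rng.exponential(1.0 / cfg.annual_death_hazard) * 365.0
    t_death = max(t_death, 220.0)
    if 700.0 <= t_death <= 762.0:          # keep clear of the 2-year certainty boundary
        t_death = 800.0
    death = draft.fpd + timedelta(days=int(t_death))
    draft.death = death if death <= cfg.extraction_date else None

    end = min(cfg.extraction_date, draft.death) if draft.death else cfg.extraction_date
    esc_at = draft.fpd + timedelta(days=int(rng.exponential(cfg.escalation_mean_days)) + 30) \
        if rng.random() < cfg.escalation_prob else None
    mono = MAO_I if rng.random() < 0.5 else AGONIST
    for d in _purchase_dates(rng, draft.fpd, end,
                             cfg.purchase_interval_days, cfg.purchase_jitter_days):
        if esc_at is not None and d >= esc_at:
            draft.purchases.append((d, LEVODOPA, 250.0))
            if rng.random() < 0.4:          # same-day multi-drug purchase
                draft.purchases.append((d, mono, 1.0))
        else:
            draft.purchases.append((d, mono, 1.0))
    obs_end = min(end, cfg.extraction_date)
    followup = (obs_end - draft.fpd).days
    draft.intended_status = "probable_pd" if followup >= 762 else "possible_pd"
    draft.intended_criterion = "" if followup >= 762 else "POS2"


def _arch_exc1(draft, rng, cfg):
    draft.diagnoses.append((draft.fpd - timedelta(days=int(rng.integers(30, 700))),
                            "E22.1", "other"))
    _continuous(draft, rng, cfg, AGONIST, 0.5)
    draft.intended_criterion = "EXC1"


def _arch_exc2(draft, rng, cfg):
    draft.diagnoses.append((draft.fpd - timedelta(days=int(rng.integers(100, 800))),
                            "D35.2", "hospital"))
    _pd_dx(draft, rng, cfg, draft.fpd + timedelta(days=int(rng.integers(100, 500))))
    _continuous(draft, rng, cfg, BROMOCRIPTINE, 2.5)
    draft.intended_criterion = "EXC2"


def _arch_exc3(draft, rng, cfg):
    draft.fpd = _rand_day_in_year(rng, int(rng.integers(2015, 2019)))
    draft.diagnoses.append((draft.fpd - timedelta(days=int(rng.integers(100, 800))),
                            "D35.2", "hospital"))
    _pd_dx(draft, rng, cfg, draft.fpd + timedelta(days=int(rng.integers(100, 500))))
    _continuous(draft, rng, cfg, CABERGOLINE, 0.5)
    draft.intended_criterion = "EXC3"


def _arch_exc4(draft, rng, cfg):
    draft.sex = "female"
    draft.age_at_fpd = int(rng.integers(26, 41))
    draft.diagnoses.append((draft.fpd - timedelta(days=int(rng.integers(60, 700))),
                            "O80", "hospital"))
    _continuous(draft, rng, cfg, BROMOCRIPTINE, 2.5)
    draft.intended_criterion = "EXC4"


def _arch_exc5(draft, rng, cfg):
    draft.diagnoses.append((draft.fpd - timedelta(days=int(rng.integers(10, 200))),
                            "G91.0", "hospital"))
    _pd_dx(draft, rng, cfg, draft.fpd + timedelta(days=int(rng.integers(30, 300))))
    _continuous(draft, rng, cfg, LEVODOPA, 250.0)
    draft.intended_criterion = "EXC5"


def _arch_exc6(draft, rng, cfg):
    at = draft.fpd - timedelta(days=int(rng.integers(30, 180)))
    draft.diagnoses.append((at, "S06.2", "hospital"))
    draft.diagnoses.append((at + timedelta(days=1), "R40.2", "hospital"))
    _pd_dx(draft, rng, cfg, draft.fpd + timedelta(days=int(rng.integers(30, 300))))
    _continuous(draft, rng, cfg, LEVODOPA, 250.0)
    draft.intended_criterion = "EXC6"


def _arch_exc7(draft, rng, cfg):
    _pd_dx(draft, rng, cfg, draft.fpd - timedelta(days=30))
    draft.diagnoses.append((draft.fpd + timedelta(days=int(rng.integers(200, 900))),
                            "G90.3", "neurologist"))
    _continuous(draft, rng, cfg, LEVODOPA, 250.0)
    draft.intended_criterion = "EXC7"


def _arch_exc8(draft, rng, cfg):
    draft.diagnoses.append((draft.fpd - timedelta(days=int(rng.integers(0, 500))),
                            "G25.8", "neurologist"))
    _continuous(draft, rng, cfg, AGONIST, 0.5)
    draft.intended_criterion = "EXC8"


def _arch_exc9(draft, rng, cfg):
    draft.purchases.append((draft.fpd - timedelta(days=int(rng.integers(30, 300))),
                            HALOPERIDOL, 5.0))
    _continuous(draft, rng, cfg, AGONIST, 0.5)
    draft.intended_criterion = "EXC9"


def _arch_exc10(draft, rng, cfg):
    _continuous(draft, rng, cfg, MAO_I, 1.0)
    draft.intended_criterion = "EXC10"


def _arch_exc11(draft, rng, cfg):
    _continuous(draft, rng, cfg, AMANTADINE, 100.0)
    draft.intended_criterion = "EXC11"


def _arch_exc12(draft, rng, cfg):
    draft.diagnoses.append((draft.fpd + timedelta(days=int(rng.integers(0, 1500))),
                            "R29.6", "primary_care"))
    _continuous(draft, rng, cfg, LEVODOPA, 250.0)
    draft.intended_criterion = "EXC12"


def _arch_exc13(draft, rng, cfg):
    # span kept in [330, 390] d: under two years, but comfortably over six
    # months so the very-short-use rule (EXC14) cannot also fire
    for offset in (0, 90, 180, 270, 330):
        at = draft.fpd + timedelta(days=offset + (int(rng.integers(0, 60)) if offset == 330 else
                                                  int(rng.integers(-10, 11)) if offset else 0))
        draft.purchases.append((at, LEVODOPA, 250.0))
    draft.intended_criterion = "EXC13"


def _arch_exc14(draft, rng, cfg):
    draft.purchases.append((draft.fpd, LEVODOPA, 250.0))
    draft.purchases.append((draft.fpd + timedelta(days=int(rng.integers(60, 110))),
                            LEVODOPA, 250.0))
    _pd_dx(draft, rng, cfg, draft.fpd - timedelta(days=int(rng.integers(0, 60))))
    draft.intended_criterion = "EXC14"


def _arch_pos1(draft, rng, cfg):
    _continuous(draft, rng, cfg, LEVODOPA, 250.0)
    draft.truth = "pd"
    draft.onset_year = draft.fpd.year
    draft.anchor_date = draft.fpd
    draft.intended_status = "possible_pd"
    draft.intended_criterion = "POS1"


def _arch_pos2(draft, rng, cfg):
    draft.fpd = cfg.extraction_date - timedelta(days=int(rng.integers(400, 700)))
    dx = draft.fpd - timedelta(days=int(rng.integers(0, 60)))
    _pd_dx(draft, rng, cfg, dx)
    _continuous(draft, rng, cfg, LEVODOPA, 250.0)
    draft.truth = "pd"
    draft.onset_year = dx.year
    draft.anchor_date = min(dx, draft.fpd)
    draft.intended_status = "possible_pd"
    draft.intended_criterion = "POS2"


def _arch_pos3(draft, rng, cfg):
    draft.fpd = _rand_day_in_year(rng, int(rng.integers(2008, 2015)))
    dx = draft.fpd - timedelta(days=int(rng.integers(0, 60)))
    _pd_dx(draft, rng, cfg, dx)
    stop = draft.fpd + timedelta(days=int(rng.integers(1200, 1600)))
    _continuous(draft, rng, cfg, LEVODOPA, 250.0, until=stop)
    draft.truth = "pd"
    draft.onset_year = dx.year
    draft.anchor_date = min(dx, draft.fpd)
    draft.intended_status = "possible_pd"
    draft.intended_criterion = "POS3"


def _arch_pos4(draft, rng, cfg):
    dx = draft.fpd + timedelta(days=int(rng.integers(0, 200)))
    _pd_dx(draft, rng, cfg, dx)
    draft.purchases.append((draft.fpd - timedelta(days=int(rng.integers(30, 300))),
                            HALOPERIDOL, 5.0))
    _continuous(draft, rng, cfg, LEVODOPA, 250.0)
    draft.truth = "pd"
    draft.onset_year = min(dx, draft.fpd).year
    draft.anchor_date = min(dx, draft.fpd)
    draft.intended_status = "possible_pd"
    draft.intended_criterion = "POS4"


def _arch_mimic_no_apm(draft, rng, cfg):
    """Essential tremor managed without APM: never passes inclusion."""
    draft.diagnoses.append((draft.fpd - timedelta(days=int(rng.integers(0, 2000))),
                            "G25.0", "neurologist"))
    draft.intended_status = "not_eligible"
    draft.intended_criterion = ""


def _arch_mimic_vascular(draft, rng, cfg):
    """Vascular parkinsonism misdiagnosed and treated as PD: an
    irreducible false positive for a medication-based rule set."""
    _pd_dx(draft, rng, cfg, draft.fpd - timedelta(days=int(rng.integers(0, 120))))
    _continuous(draft, rng, cfg, LEVODOPA, 250.0)
    draft.intended_status = "probable_pd"
    draft.intended_criterion = ""


def _arch_pd_excluded_rls(draft, rng, cfg):
    """True PD with a late unresolved RLS code trail: an algorithm miss."""
    _pd_dx(draft, rng, cfg, draft.fpd - timedelta(days=60))
    draft.diagnoses.append((draft.fpd + timedelta(days=int(rng.integers(300, 900))),
                            "G25.8", "primary_care"))
    _continuous(draft, rng, cfg, LEVODOPA, 250.0)
    draft.truth = "pd"
    draft.onset_year = (draft.fpd - timedelta(days=60)).year
    draft.anchor_date = draft.fpd - timedelta(days=60)
    draft.intended_status = "excluded"
    draft.intended_criterion = "EXC8"


ARCHETYPES: dict[str, Callable] = {
    "pd_textbook": _arch_pd_textbook,
    "mimic_no_apm": _arch_mimic_no_apm,
    "mimic_vascular_misdx": _arch_mimic_vascular,
    "pd_excluded_rls": _arch_pd_excluded_rls,
    "EXC1": _arch_exc1, "EXC2": _arch_exc2, "EXC3": _arch_exc3, "EXC4": _arch_exc4,
    "EXC5": _arch_exc5, "EXC6": _arch_exc6, "EXC7": _arch_exc7, "EXC8": _arch_exc8,
    "EXC9": _arch_exc9, "EXC10": _arch_exc10, "EXC11": _arch_exc11, "EXC12": _arch_exc12,
    "EXC13": _arch_exc13, "EXC14": _arch_exc14,
    "POS1": _arch_pos1, "POS2": _arch_pos2, "POS3": _arch_pos3, "POS4": _arch_pos4,
}

#: Clean one-rule confounder archetypes (used by routing checks).
CRITERION_ARCHETYPES = tuple(f"EXC{i}" for i in range(1, 15)) + tuple(
    f"POS{i}" for i in range(1, 5))

DEFAULT_WEIGHTS: dict[str, float] = {
    "pd_textbook": 0.48,
    "mimic_no_apm": 0.12,
    "mimic_vascular_misdx": 0.02,
    "pd_excluded_rls": 0.02,
    **{a: 0.02 for a in CRITERION_ARCHETYPES},
}


def simulate_archetype(pid: str, archetype_id: str, cfg: ScenarioConfig,
                       rng: np.random.Generator):
    """Generate one patient of the named archetype."""
    if archetype_id not in ARCHETYPES:
        raise KeyError(f"unknown archetype {archetype_id!r}")
    draft = _base(pid, rng, cfg)
    if archetype_id.startswith(("EXC", "POS")):
        draft.intended_status = "excluded" if archetype_id.startswith("EXC") else "possible_pd"
    draft.archetype_id = archetype_id
    ARCHETYPES[archetype_id](draft, rng, cfg)
    return _finish(draft, rng, cfg)


# ------------------------------------------------------------- population

def generate_population(years: range | list[int],
                        base_count: int = 40_000,
                        growth_per_year: float = 0.0) -> pd.DataFrame:
    """Annual insured-population denominators in 5-year bands by sex.

    A smooth declining pyramid: counts fall off exponentially with age,
    roughly emulating an insured adult population.  Deterministic.
    """
    rows = []
    for year in years:
        for lo in range(0, 100, 5):
            count = base_count * np.exp(-lo / 45.0) * (1 + growth_per_year) ** (year - min(years))
            for sex in ("male", "female"):
                rows.append({"year": year, "age_low": lo, "age_high": lo + 5,
                             "sex": sex, "count": int(round(count / 2))})
    return pd.DataFrame(rows)


def simulate_incidence_counts(
    rng: np.random.Generator,
    years: range | list[int],
    base_rate_per_100k: float,
    apc_percent: float,
    population: float,
) -> pd.DataFrame:
    """Poisson annual case counts with an embedded annual percent change.

    The expected rate in year ``t`` is ``base * (1 + APC/100)**(t - t0)``,
    so a log-linear trend fit should recover ``apc_percent``.
    """
    years = list(years)
    t0 = years[0]
    rows = []
    for y in years:
        rate = base_rate_per_100k * (1 + apc_percent / 100.0) ** (y - t0)
        mu = rate / 1e5 * population
        rows.append({"year": y, "count": int(rng.poisson(mu)), "population": population})
    return pd.DataFrame(rows)


# ------------------------------------------------------------- prodromal

def plant_prodromal_codes(
    patients: Mapping[str, PatientRecord],
    labels: pd.DataFrame,
    model: ProdromalModel,
    rng: np.random.Generator,
) -> list[tuple[str, date, str, str]]:
    """Plant pre-diagnostic diagnosis codes for cases and controls.

    Cases (``truth == "pd"`` with an anchor date) receive each code in
    offset-year ``k`` before their anchor with probability
    ``baseline * rate_ratio(code, k)``; everyone else receives codes as a
    stationary annual process at the baseline probability within their
    insurance years.  Returns diagnosis rows
    ``(patient_id, date, code, provider)``.
    """
    rows: list[tuple[str, date, str, str]] = []
    lab = labels.set_index("patient_id")
    for pid in sorted(patients):
        p = patients[pid]
        is_case = False
        anchor: Optional[date] = None
        if pid in lab.index:
            rec = lab.loc[pid]
            anchor_s = rec.get("anchor_date", "")
            if rec.get("truth") == "pd" and anchor_s:
                is_case = True
                anchor = anchor_s if isinstance(anchor_s, date) else date.fromisoformat(str(anchor_s))
        start = p.first_insurance_start
        end = p.last_insurance_end
        if is_case and anchor is not None:
            for code, baseline in model.baselines.items():
                for k in range(0, model.max_offset + 1):
                    w_end = anchor - timedelta(days=365 * k)
                    w_start = anchor - timedelta(days=365 * (k + 1))
                    if w_start < start or w_end > end + timedelta(days=1):
                        continue
                    prob = min(1.0, baseline * model.rate_ratio(code, k))
                    if rng.random() < prob:
                        at = w_start + timedelta(days=int(rng.integers(0, 365)))
                        rows.append((pid, at, code, "primary_care"))
        else:
            for code, baseline in model.baselines.items():
                y = start.year
                while y <= end.year:
                    if rng.random() < baseline:
                        at = _rand_day_in_year(rng, y)
                        if start <= at <= end:
                            rows.append((pid, at, code, "primary_care"))
                    y += 1
    return rows


# ------------------------------------------------------------- cohort

@dataclass
class SimulatedCohort:
    dataset: EHRDataset
    truth: pd.DataFrame


def simulate_cohort(
    cfg: ScenarioConfig,
    codebook: Optional[Codebook] = None,
    algo_config: AlgorithmConfig = DEFAULT_CONFIG,
    plant_prodromal: bool = False,
) -> SimulatedCohort:
    """Generate a full synthetic registry under the scenario config."""
    codebook = codebook or default_codebook()
    names = sorted(cfg.archetype_weights)
    weights = np.array([cfg.archetype_weights[n] for n in names], dtype=float)
    if (weights < 0).any():
        raise ValueError("archetype weights must be non-negative")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("archetype weights must sum to 1")

    assign_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2**20]))
    assignments = assign_rng.choice(len(names), size=cfg.n_patients, p=weights)

    patients: dict[str, PatientRecord] = {}
    pur_rows, dx_rows, labels = [], [], []
    for i in range(cfg.n_patients):
        pid = f"P{i:06d}"
        rng = _rng_for(cfg.seed, i)
        patient, purchases, diagnoses, label = simulate_archetype(
            pid, names[assignments[i]], cfg, rng)
        patients[pid] = patient
        pur_rows.extend(purchases)
        dx_rows.extend(diagnoses)
        labels.append(label)

    truth = pd.DataFrame(labels, columns=["patient_id", "truth", "archetype_id",
                                          "intended_status", "intended_criterion",
                                          "onset_year", "anchor_date"])
    if plant_prodromal:
        prod_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2**21]))
        dx_rows.extend(plant_prodromal_codes(patients, truth, cfg.prodromal, prod_rng))

    purchases = pd.DataFrame(pur_rows, columns=["patient_id", "purchase_date",
                                                "atc_code", "strength_mg"])
    purchases = purchases.sort_values(["patient_id", "purchase_date", "atc_code"],
                                      kind="mergesort").reset_index(drop=True)
    purchases["apm_class"] = [
        classify_purchase(a, s, codebook, algo_config)
        for a, s in zip(purchases["atc_code"], purchases["strength_mg"])
    ]
    diagnoses = pd.DataFrame(dx_rows, columns=["patient_id", "dx_date",
                                               "icd10_code", "provider_type"])
    diagnoses = diagnoses.sort_values(["patient_id", "dx_date", "icd10_code"],
                                      kind="mergesort").reset_index(drop=True)

    population = generate_population(range(cfg.study_start_year, cfg.study_end_year + 1))
    dataset = EHRDataset(patients=patients, purchases=purchases, diagnoses=diagnoses,
                         population=population, extraction_date=cfg.extraction_date)
    return SimulatedCohort(dataset=dataset, truth=truth)


def simulate_prediagnostic_scenario(
    n_cases: int,
    controls_per_case: int = 6,
    model: Optional[ProdromalModel] = None,
    seed: int = 0,
    index_year: int = 2023,
    extraction_date: date = date(2025, 3, 31),
) -> SimulatedCohort:
    """Cases and a matchable control pool with planted pre-diagnostic codes.

    Every subject carries ~19 years of insurance history before the case
    index year so that all 18 offset-years have available data.  Controls
    are demographic near-clones of the cases (same sex, age within a
    year), guaranteeing the exact-matching step has an adequate pool.
    """
    model = model or ProdromalModel()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    patients: dict[str, PatientRecord] = {}
    pur_rows, dx_rows, labels = [], [], []

    case_meta = []
    for i in range(n_cases):
        pid = f"C{i:06d}"
        sex = "male" if rng.random() < 0.55 else "female"
        age = int(np.clip(round(rng.normal(72, 8)), 45, 92))
        anchor = _rand_day_in_year(rng, index_year)
        birth = anchor - timedelta(days=365 * age + int(rng.integers(age // 4 + 10, 330)))
        ins_start = anchor - timedelta(days=int(19.2 * 365) + int(rng.integers(0, 300)))
        patients[pid] = PatientRecord(pid, sex, birth, None,
                                      ((ins_start, extraction_date),))
        # a minimal treated-PD trail so the case is algorithm-identifiable
        pur_rows.append((pid, anchor, LEVODOPA, 250.0))
        pur_rows.append((pid, anchor + timedelta(days=90), LEVODOPA, 250.0))
        dx_rows.append((pid, anchor, "G20", "neurologist"))
        labels.append({"patient_id": pid, "truth": "pd", "archetype_id": "prediag_case",
                       "intended_status": "possible_pd", "intended_criterion": "",
                       "onset_year": anchor.year, "anchor_date": anchor.isoformat()})
        case_meta.append((sex, age, anchor))

    for j in range(n_cases * controls_per_case):
        pid = f"K{j:06d}"
        sex, age, anchor = case_meta[j % n_cases]
        birth = anchor - timedelta(days=365 * age + int(rng.integers(age // 4 + 10, 330)))
        ins_start = anchor - timedelta(days=int(19.5 * 365) + int(rng.integers(0, 300)))
        patients[pid] = PatientRecord(pid, sex, birth, None,
                                      ((ins_start, extraction_date),))
        labels.append({"patient_id": pid, "truth": "non_pd", "archetype_id": "prediag_control",
                       "intended_status": "not_eligible", "intended_criterion": "",
                       "onset_year": "", "anchor_date": ""})

    truth = pd.DataFrame(labels, columns=["patient_id", "truth", "archetype_id",
                                          "intended_status", "intended_criterion",
                                          "onset_year", "anchor_date"])
    plant_rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    dx_rows.extend(plant_prodromal_codes(patients, truth, model, plant_rng))

    codebook = default_codebook()
    purchases = pd.DataFrame(pur_rows, columns=["patient_id", "purchase_date",
                                                "atc_code", "strength_mg"])
    purchases["apm_class"] = [classify_purchase(a, s, codebook)
                              for a, s in zip(purchases["atc_code"], purchases["strength_mg"])]
    diagnoses = pd.DataFrame(dx_rows, columns=["patient_id", "dx_date",
                                               "icd10_code", "provider_type"])
    diagnoses = diagnoses.sort_values(["patient_id", "dx_date", "icd10_code"],
                                      kind="mergesort").reset_index(drop=True)
    dataset = EHRDataset(patients=patients, purchases=purchases, diagnoses=diagnoses,
                         population=generate_population(range(2005, 2025)),
                         extraction_date=extraction_date)
    return SimulatedCohort(dataset=dataset, truth=truth)
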