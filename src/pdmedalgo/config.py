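"""Tunable constants of the classification algorithm.

The published rule set speaks in calendar language ("one month", "two
years", "the year prior to the first purchase date") without fixing
day-level window boundaries.  All such conventions are centralized here so
that every rule, the synthetic generator and the independent test oracle
share a single definition, and so that users running the algorithm against
a registry with different local conventions can override any of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date
from typing import Any, Mapping


def years_to_days(n_years: float) -> int:
    """Convert a year count to whole days, half-up, at 365.25 d/year."""
    return int(n_years * 365.25 + 0.5)


#: "one month" in days wherever a rule says so.
MONTH_DAYS = 30
#: "six months" in days.
HALF_YEAR_DAYS = 183
#: "one year" (the year prior to the FPD) in days.
YEAR_DAYS = 365


@dataclass(frozen=True)
class AlgorithmConfig:
    """Thresholds and switches of the medication-based rule algorithm.

    Defaults reproduce the published rule set.  Durations are in days;
    ``years_to_days`` gives 731 d for "two years", 1096 d for "three
    years" and 1826 d for "five years", so "exceeding N years" means a
    strictly larger day count.
    """

    # inclusion
    min_fpd: date = date(2005, 1, 1)          # FPD must be after 2004-12-31
    min_age_at_fpd: int = 25                  # inclusive
    max_age_at_fpd: int = 100                 # inclusive
    min_apm_occasions: int = 2                # distinct purchase dates

    # exclusion windows / thresholds
    quetiapine_dose_threshold_mg: float = 50.0
    missing_quetiapine_strength_counts: bool = True   # missing dose -> antipsychotic
    pregnancy_window_days: int = years_to_days(2)     # EXC4 look-back
    hydro_anoxia_after_fpd_days: int = MONTH_DAYS     # EXC5 "up to one month after"
    tbi_coma_window_days: int = HALF_YEAR_DAYS        # EXC6 look-back
    antipsychotic_window_days: int = YEAR_DAYS        # EXC9 / POS4 look-back
    cabergoline_fpd_cutoff: date = date(2014, 1, 1)   # EXC3 "FPD >= 2014"
    # EXC10/EXC11 alternative sufficient conditions, evaluated as an OR:
    mono_thresholds: tuple[tuple[int, int], ...] = (
        (20, years_to_days(5)),   # >20 purchases or duration exceeding 5 y
        (8, years_to_days(2)),    # >8 purchases or duration exceeding 2 y
    )
    falls_window_before_days: int = YEAR_DAYS          # EXC12 window start
    falls_window_after_days: int = years_to_days(5)    # EXC12 window end
    exc12_min_span_days: int = years_to_days(2)        # "purchased APMs for >2 years"
    exc13_max_span_days: int = years_to_days(2)        # "less than two years"
    exc13_gap_days: int = YEAR_DAYS                    # ">1 year since last purchase"
    exc14_max_span_days: int = HALF_YEAR_DAYS          # "less than six months"
    exc14_gap_days: int = years_to_days(3)             # ">3 years since last purchase"

    # certainty
    pos2_followup_days: int = years_to_days(2)         # "<2 years of follow-up"
    pos3_min_span_days: int = years_to_days(3)         # ">3 years of APM"
    pos3_gap_days: int = years_to_days(2)              # ">2 years since last purchase"

    # index date
    anticholinergic_window_days: int = YEAR_DAYS
    pituitary_exception_wins: bool = True              # precedence when both apply

    # which purchase classes count toward inclusion / FPD / exclusivity
    comt_counts_for_inclusion: bool = True
    anticholinergics_count_for_inclusion: bool = False

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, date):
                d[k] = v.isoformat()
        return d

    @classmethod
    def from_mapping(cls, m: Mapping[str, Any]) -> "AlgorithmConfig":
        kwargs: dict[str, Any] = {}
        for k, v in m.items():
            if k not in cls.__dataclass_fields__:
                raise KeyError(f"unknown algorithm option: {k!r}")
            f = cls.__dataclass_fields__[k]
            if f.type in ("date", date) and isinstance(v, str):
                v = date.fromisoformat(v)
            if k == "mono_thresholds":
                v = tuple(tuple(x) for x in v)
            kwargs[k] = v
        return cls(**kwargs)


DEFAULT_CONFIG = AlgorithmConfig()
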