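"""Incidence, prevalence and trend estimation.

Crude annual rates per 100,000 are case counts over annual insured
population (annual counts taken as an approximation of person-time).
Interval estimates on counts are exact Poisson (Garwood chi-square)
intervals.  Age standardization is the direct method against the WHO
world standard population in 5-year bands, optionally truncated at a
minimum age and renormalized.  Trends are log-linear regressions of
counts on calendar year (Poisson with a log-population offset, switching
to quasi-Poisson scaling when the deviance/df ratio flags
overdispersion) or weighted binomial regressions for prevalence; the
annual percent change is ``100 * (exp(beta) - 1)`` for the per-year
coefficient ``beta``.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: WHO world standard population, 5-year bands 0-4 ... 95-99 (per-cent
#: shares; the open-ended 85+ share split across 85-89/90-94/95-99).
#: Renormalized to sum exactly to 1 on construction.
WHO_STANDARD_5Y = {
    (0, 5): 8.86, (5, 10): 8.69, (10, 15): 8.60, (15, 20): 8.47,
    (20, 25): 8.22, (25, 30): 7.93, (30, 35): 7.61, (35, 40): 7.15,
    (40, 45): 6.59, (45, 50): 6.04, (50, 55): 5.37, (55, 60): 4.55,
    (60, 65): 3.72, (65, 70): 2.96, (70, 75): 2.21, (75, 80): 1.52,
    (80, 85): 0.91, (85, 90): 0.44, (90, 95): 0.15, (95, 100): 0.04,
}

#: Decadal age groups used for crude incidence reporting.
DEFAULT_AGE_GROUPS = ((20, 40), (40, 50), (50, 60), (60, 70),
                      (70, 80), (80, 90), (90, 100))


@dataclass(frozen=True)
class StandardPopulation:
    """Age-band weights of a standard population (direct standardization)."""

    bands: tuple[tuple[int, int], ...]
    weights: tuple[float, ...]
    provenance: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError("standard-population weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("standard-population weights must sum to 1")

    @classmethod
    def who_world(cls) -> "StandardPopulation":
        bands = tuple(sorted(WHO_STANDARD_5Y))
        w = np.array([WHO_STANDARD_5Y[b] for b in bands], dtype=float)
        w = w / w.sum()
        return cls(bands=bands, weights=tuple(w),
                   provenance="WHO world standard population (5-year bands)")

    def truncated(self, min_age: int) -> "StandardPopulation":
        """Drop bands below ``min_age`` and renormalize to 100%."""
        keep = [(b, w) for b, w in zip(self.bands, self.weights) if b[0] >= min_age]
        if not keep:
            raise ValueError(f"no bands at or above age {min_age}")
        bands, w = zip(*keep)
        w = np.asarray(w) / np.sum(w)
        return StandardPopulation(bands=tuple(bands), weights=tuple(w),
                                  provenance=f"{self.provenance}, truncated at {min_age}, renormalized")


@dataclass(frozen=True)
class TrendFit:
    family: str           # poisson | quasi_poisson | binomial
    link: str
    beta: float           # per-calendar-year coefficient (log scale)
    se: float
    dispersion: float     # deviance / df
    deviance: float
    df_resid: int
    level: float = 0.95

    @property
    def apc(self) -> float:
        return 100.0 * (np.exp(self.beta) - 1.0)

    @property
    def apc_ci(self) -> tuple[float, float]:
        z = stats.norm.ppf(1 - (1 - self.level) / 2)
        return (100.0 * (np.exp(self.beta - z * self.se) - 1.0),
                100.0 * (np.exp(self.beta + z * self.se) - 1.0))


# ------------------------------------------------------------- intervals

def poisson_exact_ci(count: int, person_denominator: float,
                     level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) Poisson interval for a rate per 100,000."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if person_denominator <= 0:
        raise ValueError("denominator must be positive")
    alpha = 1 - level
    lo = 0.0 if count == 0 else stats.chi2.ppf(alpha / 2, 2 * count) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2
    scale = 1e5 / person_denominator
    return lo * scale, hi * scale


# ------------------------------------------------------------- crude rates

def _age_group_of(age: int, groups: Sequence[tuple[int, int]]) -> Optional[tuple[int, int]]:
    for lo, hi in groups:
        if lo <= age < hi:
            return (lo, hi)
    return None


def aggregate_population(population: pd.DataFrame, year: int,
                         lo: int, hi: int, sex: Optional[str] = None) -> float:
    """Sum 5-year-band denominators into [lo, hi) for one year."""
    sel = population[(population["year"] == year)
                     & (population["age_low"] >= lo)
                     & (population["age_high"] <= hi)]
    if sex is not None:
        sel = sel[sel["sex"] == sex]
    if sel.empty:
        raise KeyError(f"no population denominator for year={year}, ages [{lo},{hi}), sex={sex}")
    return float(sel["count"].sum())


def crude_incidence(
    outcomes: Iterable,
    patients: dict,
    population: pd.DataFrame,
    age_groups: Sequence[tuple[int, int]] = DEFAULT_AGE_GROUPS,
    by_sex: bool = False,
    level: float = 0.95,
) -> pd.DataFrame:
    """Annual incidence rate table; a case counts in the calendar year and
    age group of its index date."""
    cells: dict[tuple, int] = {}
    for o in outcomes:
        if not getattr(o, "is_pd", False) or o.index_date is None:
            continue
        p = patients[o.patient_id]
        grp = _age_group_of(p.age_on(o.index_date), age_groups)
        if grp is None:
            continue
        sex = p.sex if by_sex else "all"
        cells[(o.index_date.year, grp, sex)] = cells.get((o.index_date.year, grp, sex), 0) + 1

    case_years = {year for (year, _, _) in cells}
    years = sorted(set(population["year"].unique()) | case_years)
    sexes = ["male", "female"] if by_sex else ["all"]
    rows = []
    for year in years:
        for grp in age_groups:
            for sex in sexes:
                denom = aggregate_population(population, year, grp[0], grp[1],
                                             None if sex == "all" else sex)
                count = cells.get((year, grp, sex), 0)
                lo, hi = poisson_exact_ci(count, denom, level)
                rows.append({
                    "year": year, "age_low": grp[0], "age_high": grp[1], "sex": sex,
                    "count": count, "population": denom,
                    "rate_per_100k": 1e5 * count / denom,
                    "ci_lower": lo, "ci_upper": hi,
                })
    return pd.DataFrame(rows)


def aair(
    band_counts: Sequence[int],
    band_denominators: Sequence[float],
    standard: StandardPopulation,
    level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Directly age-standardized rate per 100,000 with a Poisson-variance CI.

    ``band_counts``/``band_denominators`` must align with the standard's
    bands.  The variance of the weighted rate sum treats band counts as
    independent Poisson draws.
    """
    counts = np.asarray(band_counts, dtype=float)
    denoms = np.asarray(band_denominators, dtype=float)
    w = np.asarray(standard.weights)
    if not (len(counts) == len(denoms) == len(w)):
        raise ValueError("band structure does not match the standard population")
    if (denoms <= 0).any():
        raise ValueError("band denominators must be positive")
    rate = float(np.sum(w * counts / denoms) * 1e5)
    var = float(np.sum(w ** 2 * counts / denoms ** 2) * 1e10)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    half = z * np.sqrt(var)
    return rate, (max(0.0, rate - half), rate + half)


def aair_by_year(
    outcomes: Iterable,
    patients: dict,
    population: pd.DataFrame,
    standard: Optional[StandardPopulation] = None,
    truncate_at: Optional[int] = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Annual age-adjusted incidence rates against the WHO standard."""
    standard = standard or StandardPopulation.who_world()
    if truncate_at is not None:
        standard = standard.truncated(truncate_at)
    counts: dict[tuple[int, tuple[int, int]], int] = {}
    for o in outcomes:
        if not getattr(o, "is_pd", False) or o.index_date is None:
            continue
        age = patients[o.patient_id].age_on(o.index_date)
        band = _age_group_of(age, standard.bands)
        if band is None:
            continue
        counts[(o.index_date.year, band)] = counts.get((o.index_date.year, band), 0) + 1
    rows = []
    for year in sorted(population["year"].unique()):
        band_counts = [counts.get((year, b), 0) for b in standard.bands]
        denoms = [aggregate_population(population, year, b[0], b[1]) for b in standard.bands]
        rate, (lo, hi) = aair(band_counts, denoms, standard, level)
        rows.append({"year": year, "aair_per_100k": rate, "ci_lower": lo, "ci_upper": hi,
                     "n_cases": int(sum(band_counts))})
    return pd.DataFrame(rows)


# ------------------------------------------------------------- prevalence

def point_prevalence(
    outcomes: Iterable,
    patients: dict,
    population: pd.DataFrame,
    year: int,
) -> dict:
    """Algorithm-PD patients alive and insured in ``year`` with an index
    date on or before Dec 31, over the annual insured population.

    A patient dying mid-year still counts in that year.  Cases remain
    prevalent until death or exit (no remission).
    """
    year_start, year_end = date(year, 1, 1), date(year, 12, 31)
    numerator = 0
    for o in outcomes:
        if not getattr(o, "is_pd", False) or o.index_date is None:
            continue
        if o.index_date > year_end:
            continue
        p = patients[o.patient_id]
        if p.death_date is not None and p.death_date < year_start:
            continue
        insured = any(s <= year_end and e >= year_start for s, e in p.insurance_periods)
        if insured:
            numerator += 1
    denom = aggregate_population(population, year, 0, 100)
    return {"year": year, "count": numerator, "population": denom,
            "prevalence_per_100k": 1e5 * numerator / denom}


def prevalence_by_year(outcomes, patients, population) -> pd.DataFrame:
    years = sorted(population["year"].unique())
    return pd.DataFrame([point_prevalence(outcomes, patients, population, y) for y in years])


# ------------------------------------------------------------- trends

def fit_incidence_trend(
    counts: Sequence[int] | pd.Series,
    populations: Sequence[float] | pd.Series,
    years: Sequence[int] | pd.Series,
    overdispersion_threshold: float = 1.0,
    level: float = 0.95,
) -> TrendFit:
    """Log-linear Poisson trend of annual counts with a population offset.

    When the deviance/df ratio exceeds the threshold the fit is rescaled
    quasi-Poisson style (standard errors multiplied by the square root of
    the Pearson dispersion).
    """
    counts = np.asarray(counts, dtype=float)
    pops = np.asarray(populations, dtype=float)
    yrs = np.asarray(years, dtype=float)
    if len(set(yrs)) < 3:
        raise ValueError("trend fitting needs at least 3 distinct years")
    if counts.sum() == 0:
        raise ValueError("cannot fit a trend on all-zero counts")
    X = sm.add_constant(yrs - yrs.mean())
    model = sm.GLM(counts, X, family=sm.families.Poisson(), offset=np.log(pops))
    res = model.fit()
    df = int(res.df_resid)
    dispersion = float(res.deviance / df) if df > 0 else 0.0
    se = float(res.bse[1])
    family = "poisson"
    if df > 0 and dispersion > overdispersion_threshold:
        scale = float(res.pearson_chi2 / df)
        se *= np.sqrt(scale)
        family = "quasi_poisson"
    return TrendFit(family=family, link="log", beta=float(res.params[1]), se=se,
                    dispersion=dispersion, deviance=float(res.deviance),
                    df_resid=df, level=level)


def fit_prevalence_trend(
    cases: Sequence[int] | pd.Series,
    populations: Sequence[float] | pd.Series,
    years: Sequence[int] | pd.Series,
    link: str = "log",
    level: float = 0.95,
) -> TrendFit:
    """Binomial regression of annual prevalence on calendar year,
    weighted by population size (log link by default so the slope is an
    annual percent change; logit available)."""
    cases = np.asarray(cases, dtype=float)
    pops = np.asarray(populations, dtype=float)
    yrs = np.asarray(years, dtype=float)
    if len(set(yrs)) < 3:
        raise ValueError("trend fitting needs at least 3 distinct years")
    if (cases >= pops).any():
        raise ValueError("prevalence cell at or above 1")
    props = cases / pops
    import warnings

    linkfun = sm.families.links.Log() if link == "log" else sm.families.links.Logit()
    X = sm.add_constant(yrs - yrs.mean())
    eta0 = np.log(props.mean()) if link == "log" else np.log(props.mean() / (1 - props.mean()))
    with warnings.catch_warnings():
        # log is a non-canonical Binomial link by design (APC interpretability)
        warnings.simplefilter("ignore", category=sm.tools.sm_exceptions.DomainWarning)
        model = sm.GLM(props, X, family=sm.families.Binomial(link=linkfun), var_weights=pops)
        res = model.fit(start_params=[eta0, 0.0], maxiter=200)
    df = int(res.df_resid)
    dispersion = float(res.deviance / df) if df > 0 else 0.0
    return TrendFit(family="binomial", link=link, beta=float(res.params[1]),
                    se=float(res.bse[1]), dispersion=dispersion,
                    deviance=float(res.deviance), df_resid=df, level=level)


def incidence_trends_by_age_group(rate_table: pd.DataFrame,
                                  level: float = 0.95) -> pd.DataFrame:
    """Per-stratum APC fits from a crude_incidence table (plus overall)."""
    rows = []
    overall = (rate_table.groupby("year")
               .agg(count=("count", "sum"), population=("population", "sum"))
               .reset_index())
    fit = fit_incidence_trend(overall["count"], overall["population"], overall["year"],
                              level=level)
    lo, hi = fit.apc_ci
    rows.append({"stratum": "overall", "beta": fit.beta, "se": fit.se,
                 "dispersion": fit.dispersion, "family": fit.family,
                 "apc_pct": fit.apc, "apc_ci_lower": lo, "apc_ci_upper": hi})
    for (alo, ahi), sub in rate_table.groupby(["age_low", "age_high"]):
        agg = sub.groupby("year").agg(count=("count", "sum"),
                                      population=("population", "sum")).reset_index()
        if agg["count"].sum() == 0:     # no cases ever in this stratum
            rows.append({"stratum": f"[{alo}-{ahi})", "beta": np.nan, "se": np.nan,
                         "dispersion": np.nan, "family": "none",
                         "apc_pct": np.nan, "apc_ci_lower": np.nan,
                         "apc_ci_upper": np.nan})
            continue
        fit = fit_incidence_trend(agg["count"], agg["population"], agg["year"], level=level)
        lo, hi = fit.apc_ci
        rows.append({"stratum": f"[{alo}-{ahi})", "beta": fit.beta, "se": fit.se,
                     "dispersion": fit.dispersion, "family": fit.family,
                     "apc_pct": fit.apc, "apc_ci_lower": lo, "apc_ci_upper": hi})
    return pd.DataFrame(rows)
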