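from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from pdmedalgo import classify_cohort, classify_patient, default_codebook
from pdmedalgo.config import AlgorithmConfig
from pdmedalgo.dataset import classify_purchase
from pdmedalgo.simulate import ScenarioConfig, simulate_cohort

from conftest import make_patient

CB = default_codebook()
EXTRACTION = date(2025, 3, 31)
LEVODOPA, AGONIST, MAO_I = "N04BA02", "N04BC05", "N04BD02"


def purchases_df(rows):
    """rows: (date, atc[, strength]) -> annotated purchases frame."""
    recs = []
    for row in rows:
        d, atc = row[0], row[1]
        mg = row[2] if len(row) > 2 else None
        recs.append(("P1", d, atc, mg, classify_purchase(atc, mg, CB)))
    return pd.DataFrame(recs, columns=["patient_id", "purchase_date", "atc_code",
                                       "strength_mg", "apm_class"])


def dx_df(rows):
    return pd.DataFrame([("P1", d, code, prov if len(row) > 2 else "other")
                         for row in rows for d, code, *rest in [row] for prov in
                         [row[2] if len(row) > 2 else "other"]],
                        columns=["patient_id", "dx_date", "icd10_code", "provider_type"])


def run(patient=None, purchases=(), diagnoses=(), config=AlgorithmConfig()):
    patient = patient or make_patient()
    return classify_patient(patient, purchases_df(purchases), dx_df(diagnoses),
                            CB, EXTRACTION, config)


def quarterly(start, end, atc=LEVODOPA):
    """Steady 90-day refills: the continuity the algorithm expects."""
    out, d = [], start
    while d <= end:
        out.append((d, atc, 250.0))
        d += timedelta(days=90)
    return out


class TestInclusion:
    def test_textbook_patient_is_probable(self):
        o = run(purchases=quarterly(date(2012, 1, 1), date(2025, 1, 1)),
                diagnoses=[(date(2011, 11, 15), "G20", "neurologist")])
        assert o.status == "probable_pd"
        assert o.fpd == date(2012, 1, 1)

    def test_single_occasion_not_eligible(self):
        o = run(purchases=[(date(2012, 1, 1), LEVODOPA, 250.0),
                           (date(2012, 1, 1), MAO_I, 1.0)])   # same-day pair = 1 occasion
        assert o.status == "not_eligible"
        assert not [r for r in o.fired if r.criterion_id == "INC1" and r.fired]

    def test_fpd_before_2005_not_eligible(self):
        o = run(purchases=quarterly(date(2004, 11, 15), date(2015, 1, 1)),
                diagnoses=[(date(2004, 10, 1), "G20")])
        assert o.status == "not_eligible"

    def test_age_below_25_not_eligible(self):
        young = make_patient(birth=date(1990, 6, 1))   # age 24 at FPD
        o = run(patient=young, purchases=quarterly(date(2015, 1, 1), date(2020, 1, 1)),
                diagnoses=[(date(2015, 1, 1), "G20")])
        assert o.status == "not_eligible"

    def test_age_100_is_inclusive(self):
        old = make_patient(birth=date(1915, 1, 1))
        o = run(patient=old, purchases=quarterly(date(2015, 6, 1), date(2018, 1, 1)),
                diagnoses=[(date(2015, 6, 1), "G20")])
        assert o.status != "not_eligible"

    def test_uninsured_at_fpd_not_eligible(self):
        p = make_patient(periods=((date(2013, 1, 1), date(2025, 3, 31)),))
        o = run(patient=p, purchases=quarterly(date(2012, 1, 1), date(2020, 1, 1)),
                diagnoses=[(date(2012, 1, 1), "G20")])
        assert o.status == "not_eligible"

    def test_no_apm_at_all_not_eligible(self):
        o = run(purchases=[(date(2015, 1, 1), "N05AD01", 5.0)])
        assert o.status == "not_eligible" and o.fpd is None


class TestExclusions:
    def test_exc4_postpartum_agonist(self):
        p = make_patient(sex="female", birth=date(1985, 3, 1))
        o = run(patient=p,
                purchases=quarterly(date(2015, 1, 1), date(2020, 1, 1), atc="N04BC01"),
                diagnoses=[(date(2013, 11, 1), "O80", "hospital")])  # birth 14 months pre-FPD
        assert o.status == "excluded" and o.fired_ids == ("EXC4",)

    def test_exc7_rescued_by_subsequent_pd_dx(self):
        o = run(purchases=quarterly(date(2011, 1, 1), date(2020, 1, 1)),
                diagnoses=[(date(2012, 3, 1), "G90.3"),       # MSA
                           (date(2014, 6, 1), "G20")])        # later PD dx
        assert "EXC7" not in o.fired_ids
        assert o.status in ("probable_pd", "possible_pd")

    def test_exc7_fires_without_subsequent_pd(self):
        o = run(purchases=quarterly(date(2011, 1, 1), date(2020, 1, 1)),
                diagnoses=[(date(2014, 6, 1), "G20"), (date(2015, 3, 1), "G23.1")])
        assert o.fired_ids == ("EXC7",)

    def test_exc7_same_day_tie_does_not_rescue(self):
        o = run(purchases=quarterly(date(2011, 1, 1), date(2020, 1, 1)),
                diagnoses=[(date(2015, 3, 1), "G90.3"), (date(2015, 3, 1), "G20")])
        assert "EXC7" in o.fired_ids

    def test_exc10_mao_monotherapy_nine_occasions(self):
        # 9 distinct dates over ~2.5 years, never PD-diagnosed
        rows = [(date(2012, 1, 1) + timedelta(days=100 * i), MAO_I, 1.0) for i in range(9)]
        o = run(purchases=rows + quarterly(date(2014, 6, 1), date(2024, 12, 1), atc=MAO_I)[:0])
        assert "EXC10" in o.fired_ids

    def test_exc10_needs_exclusivity(self):
        rows = [(date(2012, 1, 1) + timedelta(days=100 * i), MAO_I, 1.0) for i in range(9)]
        rows += quarterly(date(2014, 6, 1), date(2024, 12, 1))   # levodopa breaks exclusivity
        o = run(purchases=rows, diagnoses=[(date(2012, 1, 1), "G20")])
        assert "EXC10" not in o.fired_ids

    def test_exc13_short_use_long_gap(self):
        # 1.5-year APM span, last purchase 14+ months before observation end
        rows = quarterly(date(2015, 1, 1), date(2016, 6, 1))
        o = run(purchases=rows)
        assert "EXC13" in o.fired_ids and o.status == "excluded"

    def test_exc9_rescue_for_psychiatric_pd(self):
        rows = [(date(2014, 7, 1), "N05AD01", 5.0)] + quarterly(date(2015, 1, 1), date(2022, 1, 1))
        o = run(purchases=rows, diagnoses=[(date(2015, 2, 1), "G20", "neurologist")])
        assert "EXC9" not in o.fired_ids
        assert o.status == "possible_pd"          # flagged POS4 instead
        assert "POS4" in o.fired_ids

    def test_exc9_fires_without_levodopa(self):
        rows = [(date(2014, 7, 1), "N05AD01", 5.0)] + \
            quarterly(date(2015, 1, 1), date(2022, 1, 1), atc=AGONIST)
        o = run(purchases=rows, diagnoses=[(date(2015, 2, 1), "G20")])
        assert "EXC9" in o.fired_ids

    def test_low_dose_quetiapine_does_not_trigger_exc9(self):
        rows = [(date(2014, 7, 1), "N05AH04", 25.0)] + \
            quarterly(date(2015, 1, 1), date(2022, 1, 1), atc=AGONIST)
        o = run(purchases=rows, diagnoses=[(date(2015, 2, 1), "G20")])
        assert "EXC9" not in o.fired_ids

    def test_exc1_hyperprolactinemia_without_pd(self):
        o = run(purchases=quarterly(date(2012, 1, 1), date(2020, 1, 1), atc=AGONIST),
                diagnoses=[(date(2010, 5, 1), "E22.1")])
        assert o.fired_ids == ("EXC1",) and o.status == "excluded"


class TestCertainty:
    def test_continuous_apm_without_pd_dx_is_possible(self):
        o = run(purchases=quarterly(date(2012, 1, 1), date(2025, 1, 1)))
        assert o.status == "possible_pd" and o.fired_ids[-1:] == () or "POS1" in o.fired_ids

    def test_short_followup_is_possible(self):
        o = run(purchases=quarterly(date(2024, 1, 1), date(2025, 3, 1)),
                diagnoses=[(date(2024, 1, 1), "G20")])
        assert o.status == "possible_pd" and "POS2" in o.fired_ids

    def test_long_use_then_stop_is_possible(self):
        o = run(purchases=quarterly(date(2012, 1, 1), date(2016, 1, 1)),
                diagnoses=[(date(2012, 1, 1), "G20")])
        assert o.status == "possible_pd" and "POS3" in o.fired_ids

    def test_probable_when_no_possible_criterion(self):
        o = run(purchases=quarterly(date(2012, 1, 1), date(2025, 1, 1)),
                diagnoses=[(date(2011, 12, 1), "G20", "neurologist")])
        assert o.status == "probable_pd" and o.fired_ids[:0] == ()
        assert not any(f.startswith("POS") for f in o.fired_ids)


class TestIndexDate:
    def test_default_earlier_of_fpd_and_pd_dx(self):
        o = run(purchases=quarterly(date(2012, 5, 1), date(2020, 1, 1)),
                diagnoses=[(date(2011, 9, 1), "G20")])
        assert o.index_date == date(2011, 9, 1) and o.index_rule == "IDX_DEFAULT"

    def test_pituitary_exception_takes_later(self):
        o = run(purchases=quarterly(date(2010, 1, 1), date(2020, 1, 1)),
                diagnoses=[(date(2008, 1, 1), "D35.2"), (date(2012, 1, 1), "G20")])
        # pituitary adenoma precedes FPD -> later of FPD / PD dx
        assert o.index_date == date(2012, 1, 1) and o.index_rule == "IDX_PITUITARY"

    def test_anticholinergic_exception_takes_earliest(self):
        rows = [(date(2010, 6, 1), "N04AA01", 2.0)] + quarterly(date(2011, 2, 1), date(2020, 1, 1))
        o = run(purchases=rows, diagnoses=[(date(2011, 3, 1), "G20")])
        assert o.index_date == date(2010, 6, 1) and o.index_rule == "IDX_ANTICHOLINERGIC"

    def test_index_equals_fpd_without_exceptions_or_earlier_dx(self):
        o = run(purchases=quarterly(date(2012, 5, 1), date(2020, 1, 1)),
                diagnoses=[(date(2013, 1, 1), "G20")])
        assert o.index_date == date(2012, 5, 1)


class TestCohortPipeline:
    def test_empty_cohort(self, codebook):
        sim = simulate_cohort(ScenarioConfig(n_patients=0, seed=0), codebook)
        table, funnel, outcomes = classify_cohort(sim.dataset, codebook)
        assert len(table) == 0 and len(outcomes) == 0
        assert funnel.loc[0, "surviving"] == 0

    def test_pure_exc4_cohort_fully_excluded(self, codebook):
        cfg = ScenarioConfig(n_patients=40, seed=5, archetype_weights={"EXC4": 1.0})
        sim = simulate_cohort(cfg, codebook)
        table, _, _ = classify_cohort(sim.dataset, codebook)
        assert (table["status"] == "excluded").all()
        assert (table["fired_criteria"] == "EXC4").all()

    def test_rerun_is_deterministic(self, mixed_cohort, codebook):
        t1, f1, _ = classify_cohort(mixed_cohort.dataset, codebook)
        t2, f2, _ = classify_cohort(mixed_cohort.dataset, codebook)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(f1, f2)

    def test_status_partition(self, mixed_outcomes):
        table, _, outcomes = mixed_outcomes
        assert set(table["status"]).issubset(
            {"probable_pd", "possible_pd", "excluded", "not_eligible"})
        assert table["patient_id"].is_unique
        for o in outcomes:
            if o.status in ("probable_pd", "possible_pd"):
                assert o.fpd is not None and o.index_date is not None
            if o.status == "excluded":
                assert any(f.startswith("EXC") for f in o.fired_ids)
            if o.status == "possible_pd":
                assert any(f.startswith("POS") for f in o.fired_ids)
            if o.status == "probable_pd":
                assert not any(f.startswith("POS") for f in o.fired_ids)

    def test_index_date_never_after_fpd_under_default_rule(self, mixed_outcomes):
        _, _, outcomes = mixed_outcomes
        for o in outcomes:
            if o.index_rule == "IDX_DEFAULT":
                assert o.index_date <= o.fpd


class TestMonotonicityInPDDiagnosis:
    """Adding a PD diagnosis can never newly fire the never-diagnosed-gated rules."""

    GATED = {"EXC1", "EXC7", "EXC8", "EXC10", "EXC11", "EXC12", "EXC13", "EXC14", "POS1"}

    def test_adding_pd_dx_never_fires_gated_rules(self, mixed_cohort, codebook):
        ds = mixed_cohort.dataset
        rng = np.random.default_rng(99)
        pids = rng.choice(sorted(ds.patients), size=60, replace=False)
        for pid in pids:
            pur = ds.purchases_of(pid)
            dx = ds.diagnoses_of(pid)
            before = classify_patient(ds.patients[pid], pur, dx, codebook, ds.extraction_date)
            extra_date = date(2005, 1, 1) + timedelta(days=int(rng.integers(0, 7000)))
            dx2 = pd.concat([dx, pd.DataFrame(
                [(pid, extra_date, "G20", "neurologist")], columns=dx.columns)],
                ignore_index=True)
            after = classify_patient(ds.patients[pid], pur, dx2, codebook, ds.extraction_date)
            newly = (set(after.fired_ids) - set(before.fired_ids)) & self.GATED
            assert not newly, f"{pid}: adding PD dx newly fired {newly}"
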