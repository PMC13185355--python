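from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pdmedalgo import MatchSpec, fdr_adjust, select_controls
from pdmedalgo.prediagnostic import (
    MatchedCohort, _offset_window, add_fdr, annual_dx_prevalence, compare_groups,
    stratified_run,
)

from conftest import make_patient

EXTRACTION = date(2025, 3, 31)


def _cases(*rows):
    return pd.DataFrame(rows, columns=["patient_id", "index_date"])


def _pool(*ids):
    return pd.DataFrame({"patient_id": list(ids)})


class TestSelectControls:
    def test_perfect_clones_all_selected(self):
        case = make_patient(pid="case", birth=date(1950, 1, 1))
        patients = {"case": case}
        for i in range(4):
            patients[f"k{i}"] = make_patient(pid=f"k{i}", birth=date(1950, 3, 1))
        cohort = select_controls(_cases(("case", date(2015, 6, 1))),
                                 _pool(*[f"k{i}" for i in range(4)]),
                                 patients, EXTRACTION, MatchSpec(ratio=4, seed=1))
        assert cohort.matches[0][1] == ("k0", "k1", "k2", "k3")
        assert cohort.unmatched == []

    def test_dead_candidate_ineligible(self):
        patients = {
            "case": make_patient(pid="case"),
            "dead": make_patient(pid="dead", death=date(2014, 1, 1),
                                 periods=((date(2000, 1, 1), date(2014, 1, 1)),)),
        }
        cohort = select_controls(_cases(("case", date(2015, 6, 1))), _pool("dead"),
                                 patients, EXTRACTION, MatchSpec(ratio=1, seed=1))
        assert cohort.matches[0][1] == ()
        assert cohort.unmatched == ["case"]

    def test_sex_and_age_must_match(self):
        patients = {
            "case": make_patient(pid="case", sex="male", birth=date(1950, 1, 1)),
            "wrong_sex": make_patient(pid="wrong_sex", sex="female", birth=date(1950, 1, 1)),
            "too_old": make_patient(pid="too_old", birth=date(1945, 1, 1)),
        }
        cohort = select_controls(_cases(("case", date(2015, 6, 1))),
                                 _pool("wrong_sex", "too_old"),
                                 patients, EXTRACTION, MatchSpec(ratio=2, seed=1))
        assert cohort.matches[0][1] == ()

    def test_without_replacement_under_competition(self):
        """Two cases sharing 4 eligible controls at ratio 4: no reuse, one
        case under-matched and reported."""
        patients = {f"c{i}": make_patient(pid=f"c{i}", birth=date(1950, 1, 1))
                    for i in range(2)}
        patients.update({f"k{i}": make_patient(pid=f"k{i}", birth=date(1950, 6, 1))
                         for i in range(4)})
        cohort = select_controls(
            _cases(("c0", date(2015, 6, 1)), ("c1", date(2015, 7, 1))),
            _pool("k0", "k1", "k2", "k3"), patients, EXTRACTION,
            MatchSpec(ratio=4, seed=3))
        all_controls = [k for _, ks, _ in cohort.matches for k in ks]
        assert len(all_controls) == len(set(all_controls)) == 4
        assert len(cohort.unmatched) >= 1

    def test_deterministic_under_seed(self):
        patients = {"case": make_patient(pid="case", birth=date(1950, 1, 1))}
        patients.update({f"k{i}": make_patient(pid=f"k{i}", birth=date(1950, 6, 1))
                         for i in range(10)})
        a = select_controls(_cases(("case", date(2015, 6, 1))),
                            _pool(*patients.keys() - {"case"}), patients, EXTRACTION,
                            MatchSpec(ratio=4, seed=7))
        b = select_controls(_cases(("case", date(2015, 6, 1))),
                            _pool(*patients.keys() - {"case"}), patients, EXTRACTION,
                            MatchSpec(ratio=4, seed=7))
        assert a.matches == b.matches

    def test_empty_pool_warns_not_raises(self):
        patients = {"case": make_patient(pid="case")}
        cohort = select_controls(_cases(("case", date(2015, 6, 1))), _pool(),
                                 patients, EXTRACTION, MatchSpec(ratio=4, seed=1))
        assert cohort.unmatched == ["case"]


class TestOffsetWindows:
    def test_year_zero_is_the_365_days_before_index(self):
        start, end = _offset_window(date(2020, 1, 1), 0)
        assert end == date(2020, 1, 1)
        assert (end - start).days == 365

    def test_dx_400_days_before_lands_in_offset_minus_one(self):
        idx = date(2020, 1, 1)
        dx = idx - timedelta(days=400)
        w0 = _offset_window(idx, 0)
        w1 = _offset_window(idx, -1)
        assert not (w0[0] <= dx < w0[1])
        assert w1[0] <= dx < w1[1]


class TestAnnualPrevalence:
    def _cohort(self, patients):
        matches = [("case", ("k0",), date(2020, 1, 1))]
        return MatchedCohort(matches=matches, unmatched=[], spec=MatchSpec(ratio=1))

    def test_no_diagnoses_all_zero(self):
        patients = {"case": make_patient(pid="case"), "k0": make_patient(pid="k0")}
        dx = pd.DataFrame([], columns=["patient_id", "dx_date", "icd10_code", "provider_type"])
        tab = annual_dx_prevalence(self._cohort(patients), dx, patients, "K59",
                                   offsets=(0, -1, -2))
        assert (tab["numerator"] == 0).all()
        assert (tab["proportion"].fillna(0) == 0).all()

    def test_short_history_excluded_from_deep_offsets(self):
        patients = {
            "case": make_patient(pid="case"),
            "k0": make_patient(pid="k0",
                               periods=((date(2017, 2, 1), date(2025, 3, 31)),)),
        }
        dx = pd.DataFrame([], columns=["patient_id", "dx_date", "icd10_code", "provider_type"])
        tab = annual_dx_prevalence(self._cohort(patients), dx, patients, "K59",
                                   offsets=(0, -1, -2, -3, -4))
        ctrl = tab[tab["group"] == "control"].set_index("offset")
        assert ctrl.loc[0, "denominator"] == 1       # insured since Feb 2017
        assert ctrl.loc[-3, "denominator"] == 0      # window predates insurance
        assert ctrl.loc[-4, "denominator"] == 0

    def test_dot_insensitive_code_matching(self):
        patients = {"case": make_patient(pid="case"), "k0": make_patient(pid="k0")}
        dx = pd.DataFrame([("case", date(2019, 6, 1), "K59.0", "primary_care")],
                          columns=["patient_id", "dx_date", "icd10_code", "provider_type"])
        tab = annual_dx_prevalence(self._cohort(patients), dx, patients, "K59", offsets=(0,))
        case_row = tab[(tab["group"] == "case")].iloc[0]
        assert case_row["numerator"] == 1


class TestCompareGroups:
    def _points(self, a, n1, b, n2):
        return pd.DataFrame([
            {"code": "K59", "offset": 0, "group": "case",
             "numerator": a, "denominator": n1, "proportion": a / n1 if n1 else np.nan},
            {"code": "K59", "offset": 0, "group": "control",
             "numerator": b, "denominator": n2, "proportion": b / n2 if n2 else np.nan},
        ])

    def test_identical_proportions_give_zero_statistic(self):
        out = compare_groups(self._points(10, 100, 10, 100)).iloc[0]
        assert out["chi2"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_hand_computed_chi_squared(self):
        # 2x2 (30,70 / 10,90): n(ad-bc)^2 / row/col products = 12.5
        out = compare_groups(self._points(30, 100, 10, 100)).iloc[0]
        assert out["chi2"] == pytest.approx(12.5)

    def test_zero_denominator_flagged(self):
        out = compare_groups(self._points(0, 0, 10, 100)).iloc[0]
        assert out["skipped"] and np.isnan(out["p"])

    def test_difference_ci_brackets_difference(self):
        out = compare_groups(self._points(30, 100, 10, 100)).iloc[0]
        assert out["diff"] == pytest.approx(0.2)
        assert out["diff_ci_lower"] < 0.2 < out["diff_ci_upper"]

    def test_null_chi_squared_calibration(self):
        """Equal planted rates: the rejection share at alpha=0.05 stays
        within Monte-Carlo bounds of 5%."""
        rng = np.random.default_rng(17)
        n, p, reps = 400, 0.10, 800
        rejections = 0
        tested = 0
        for _ in range(reps):
            a, b = rng.binomial(n, p), rng.binomial(n, p)
            out = compare_groups(self._points(a, n, b, n)).iloc[0]
            if not out["skipped"]:
                tested += 1
                rejections += out["p"] < 0.05
        # 3 MC sigmas around 0.05 at 800 replicates
        assert rejections / tested < 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


class TestFDR:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_hand_calculation(self):
        adj = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert fdr_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_nan_passthrough(self):
        adj = fdr_adjust([0.01, np.nan, 0.04])
        assert np.isnan(adj[1]) and not np.isnan(adj[0])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_bh_monotone_and_bounded(self, ps):
        adj = fdr_adjust(ps)
        assert ((0 <= adj) & (adj <= 1)).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()
        # adjusted values never fall below the raw p
        assert (adj >= np.asarray(ps) - 1e-12).all()


class TestStratifiedRun:
    def _setup(self):
        patients = {}
        matches = []
        rng = np.random.default_rng(5)
        dx_rows = []
        for i in range(40):
            sex = "male" if i % 2 else "female"
            birth = date(1950 if i % 4 else 1935, 1, 1)
            cid, kid = f"c{i}", f"k{i}"
            patients[cid] = make_patient(pid=cid, sex=sex, birth=birth)
            patients[kid] = make_patient(pid=kid, sex=sex, birth=birth)
            idx = date(2018, 6, 1)
            matches.append((cid, (kid,), idx))
            if rng.random() < 0.5:
                dx_rows.append((cid, date(2017, 9, 1), "K59", "primary_care"))
            if rng.random() < 0.2:
                dx_rows.append((kid, date(2017, 9, 1), "K59", "primary_care"))
        cohort = MatchedCohort(matches=matches, unmatched=[], spec=MatchSpec(ratio=1))
        dx = pd.DataFrame(dx_rows, columns=["patient_id", "dx_date", "icd10_code",
                                            "provider_type"])
        return cohort, dx, patients

    def test_overall_equals_pooled_recomputation(self):
        cohort, dx, patients = self._setup()
        res = stratified_run(cohort, dx, patients, codes=["K59"], offsets=(0, -1))
        overall = res[res["stratum"] == "overall"]
        males = res[res["stratum"] == "male"]
        females = res[res["stratum"] == "female"]
        for off in (0, -1):
            o = overall[overall["offset"] == off].iloc[0]
            m = males[males["offset"] == off].iloc[0]
            f = females[females["offset"] == off].iloc[0]
            assert o["case_numerator"] == m["case_numerator"] + f["case_numerator"]
            assert o["case_denominator"] == m["case_denominator"] + f["case_denominator"]

    def test_single_sex_cohort_skips_empty_stratum(self):
        cohort, dx, patients = self._setup()
        male_only = MatchedCohort(
            matches=[m for m in cohort.matches if patients[m[0]].sex == "male"],
            unmatched=[], spec=cohort.spec)
        res = stratified_run(male_only, dx, patients, codes=["K59"], offsets=(0,))
        assert "female" not in set(res["stratum"])

    def test_fdr_family_is_per_code(self):
        cohort, dx, patients = self._setup()
        res = stratified_run(cohort, dx, patients, codes=["K59", "F32"], offsets=(0, -1))
        overall = res[res["stratum"] == "overall"]
        # F32 has no diagnoses at all -> degenerate tables skipped, while
        # every tested K59 comparison gets an adjusted p
        k59 = overall[(overall["code"] == "K59") & (~overall["skipped"])]
        assert len(k59) >= 1 and k59["p_adj"].notna().all()
        f32 = overall[overall["code"] == "F32"]
        assert f32["skipped"].all()
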