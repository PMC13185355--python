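"""Independent naive transcription of the classification rules.

This is a deliberately unsophisticated re-statement of every rule as a
separate literal sentence over raw event tuples, sharing no code with the
engine in ``pdmedalgo.rules``.  It exists purely as a test oracle: on any
synthetic patient the engine and this transcription must agree on the
status and the set of fired criteria.
"""

from __future__ import annotations

from datetime import date, timedelta

DAY = timedelta(days=1)
ONE_MONTH = timedelta(days=30)
SIX_MONTHS = timedelta(days=183)
ONE_YEAR = timedelta(days=365)
TWO_YEARS = timedelta(days=731)
THREE_YEARS = timedelta(days=1096)
FIVE_YEARS = timedelta(days=1826)


def _matches(code: str, prefixes) -> bool:
    c = code.replace(".", "").upper()
    return any(c.startswith(p) for p in prefixes)


def naive_classify(patient, purchases, diagnoses, codebook, extraction_date):
    """Return (status, sorted fired EXC/POS ids) for one patient.

    ``purchases`` are (date, atc, strength) tuples; ``diagnoses`` are
    (date, icd10) tuples.
    """
    # --- vocabulary ------------------------------------------------
    def drug_class(atc):
        a = atc.replace(".", "").upper()
        for cls, codes in codebook.apm_classes.items():
            if a in codes:
                return cls
        return None

    apm_purchases = []           # purchases that count as APM
    anticholinergics = []
    levodopa = []
    antipsychotics = []
    for (d, atc, mg) in purchases:
        cls = drug_class(atc)
        if cls in ("levodopa", "dopamine_agonist", "mao_inhibitor", "amantadine",
                   "comt_inhibitor"):
            apm_purchases.append((d, atc.replace(".", "").upper(), cls))
        if cls == "levodopa":
            levodopa.append(d)
        if cls == "anticholinergic":
            anticholinergics.append(d)
        a = atc.replace(".", "").upper()
        if cls is None and a in codebook.antipsychotics:
            if a in codebook.quetiapine_codes:
                if mg is not None and mg <= 50:
                    continue
            antipsychotics.append(d)

    def dx_dates(condition):
        return sorted(d for d, code in diagnoses
                      if _matches(code, codebook.dx_sets[condition]))

    pd_dx = dx_dates("pd")
    ever_pd = len(pd_dx) > 0

    apm_dates = sorted({d for d, _, _ in apm_purchases})
    if not apm_dates:
        return "not_eligible", []
    fpd = apm_dates[0]
    last = apm_dates[-1]
    span = (last - fpd).days
    n_occasions = len(apm_dates)

    death = patient.death_date
    hmo_exit = patient.insurance_periods[-1][1]
    obs_end = min([x for x in (death, hmo_exit, extraction_date) if x is not None])

    # --- inclusion -------------------------------------------------
    if n_occasions < 2:
        return "not_eligible", []
    if not any(s <= fpd <= e for s, e in patient.insurance_periods):
        return "not_eligible", []
    if not fpd > date(2004, 12, 31):
        return "not_eligible", []
    age = fpd.year - patient.birth_date.year
    if (fpd.month, fpd.day) < (patient.birth_date.month, patient.birth_date.day):
        age -= 1
    if not (25 <= age <= 100):
        return "not_eligible", []

    def exclusively(pred):
        return all(pred(atc, cls) for _, atc, cls in apm_purchases)

    fired = []
    # 1. hyperprolactinemia or pituitary adenoma without a PD diagnosis
    if (dx_dates("hyperprolactinemia") or dx_dates("pituitary_adenoma")) and not ever_pd:
        fired.append("EXC1")
    # 2. pituitary adenoma and PD, exclusively bromocriptine or pergolide
    if dx_dates("pituitary_adenoma") and ever_pd and exclusively(
            lambda atc, cls: atc in codebook.bromocriptine_codes or atc in codebook.pergolide_codes):
        fired.append("EXC2")
    # 3. pituitary adenoma and PD, FPD >= 2014, exclusively cabergoline
    if dx_dates("pituitary_adenoma") and ever_pd and fpd >= date(2014, 1, 1) \
            and exclusively(lambda atc, cls: atc in codebook.cabergoline_codes):
        fired.append("EXC3")
    # 4. female, exclusively dopamine agonists, no PD dx, pregnancy/birth
    #    within two years prior to the FPD
    if patient.sex == "female" and exclusively(lambda atc, cls: cls == "dopamine_agonist") \
            and not ever_pd \
            and any(fpd - TWO_YEARS <= d < fpd for d in dx_dates("pregnancy_or_birth")):
        fired.append("EXC4")
    # 5. hydrocephalus or anoxic brain injury before or up to one month after FPD
    if any(d <= fpd + ONE_MONTH for d in dx_dates("hydrocephalus") + dx_dates("anoxic_brain_injury")):
        fired.append("EXC5")
    # 6. TBI and coma within six months before the FPD
    if any(fpd - SIX_MONTHS <= d < fpd for d in dx_dates("tbi")) \
            and any(fpd - SIX_MONTHS <= d < fpd for d in dx_dates("coma")):
        fired.append("EXC6")
    # 7. PSP/MSA/CBD without a subsequent PD dx following the last such dx
    atypical = dx_dates("psp") + dx_dates("msa") + dx_dates("cbd")
    if atypical and not any(p > max(atypical) for p in pd_dx):
        fired.append("EXC7")
    # 8. RLS without a subsequent PD dx following the last such dx
    rls = dx_dates("rls")
    if rls and not any(p > max(rls) for p in pd_dx):
        fired.append("EXC8")
    # 9. antipsychotic in the year prior to the FPD (quetiapine <= 50 mg
    #    excluded) and: never levodopa, or levodopa but never PD-diagnosed
    anti_year_before = [d for d in antipsychotics if fpd - ONE_YEAR <= d < fpd]
    if anti_year_before:
        if not levodopa:
            fired.append("EXC9")
        elif levodopa and not ever_pd:
            fired.append("EXC9")
    # 10/11. exclusive MAO-I (resp. amantadine), heavy/long use, never PD
    for cid, cls_name in (("EXC10", "mao_inhibitor"), ("EXC11", "amantadine")):
        if exclusively(lambda atc, cls, cls_name=cls_name: cls == cls_name) and not ever_pd:
            if (n_occasions > 20 or span > FIVE_YEARS.days) \
                    or (n_occasions > 8 or span > TWO_YEARS.days):
                fired.append(cid)
    # 12. never PD, APM > 2 years, falls/lethargy/deterioration in
    #     [FPD - 1y, FPD + 5y]
    if not ever_pd and span > TWO_YEARS.days:
        window_dx = (dx_dates("recurrent_falls") + dx_dates("lethargy")
                     + dx_dates("general_deterioration"))
        if any(fpd - ONE_YEAR <= d <= fpd + FIVE_YEARS for d in window_dx):
            fired.append("EXC12")
    # 13. never PD, APM < 2 years, > 1 year since last APM purchase
    if not ever_pd and span < TWO_YEARS.days and (obs_end - last).days > ONE_YEAR.days:
        fired.append("EXC13")
    # 14. APM < six months, > 3 years since last purchase
    if span < SIX_MONTHS.days and (obs_end - last).days > THREE_YEARS.days:
        fired.append("EXC14")

    if fired:
        return "excluded", sorted(fired)

    # --- certainty -------------------------------------------------
    pos = []
    if not ever_pd:
        pos.append("POS1")
    if (obs_end - fpd).days < TWO_YEARS.days:
        pos.append("POS2")
    if span > THREE_YEARS.days and (obs_end - last).days > TWO_YEARS.days:
        pos.append("POS3")
    if ever_pd and anti_year_before and levodopa:
        pos.append("POS4")

    status = "possible_pd" if pos else "probable_pd"
    return status, sorted(pos)
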