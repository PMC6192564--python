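"""Renal phenotyping: eGFR, incident CKD, prevalent-CKD exclusion, covariates.

Incident chronic kidney disease is a binary outcome defined on laboratory
determinations: eGFR < 60 mL/min/1.73 m2 and/or UACR >= 30 mg/g, in two or
more determinations spanning at least 3 months (90 days).  The event date
defaults to the confirming (second qualifying) determination, since
chronicity is only established then; the first qualifying date is available
as a configuration switch and is also stored on the status object.

eGFR is computed from serum creatinine with the CKD-EPI 2009 creatinine
equation.  The race factor defaults to non-black (Spanish primary-care
setting) but is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EGFR_THRESHOLD = 60.0    # mL/min/1.73 m2
UACR_THRESHOLD = 30.0    # mg/g
MIN_SPAN_DAYS = 90       # "a minimum of 3 months", 30-day months

# CKD-EPI 2009 creatinine equation constants
_KAPPA = {"F": 0.7, "M": 0.9}
_ALPHA = {"F": -0.329, "M": -0.411}
_SEX_FACTOR = {"F": 1.018, "M": 1.0}
_RACE_FACTOR_BLACK = 1.159


def ckd_epi_egfr(creatinine, age, female, black=False):
    """CKD-EPI 2009 estimated GFR in mL/min/1.73 m2 (vectorised).

    Parameters
    ----------
    creatinine : serum creatinine in mg/dL, > 0
    age : age in years at the determination date (>= 15 in this cohort)
    female : boolean (scalar or array)
    black : boolean race indicator; defaults to non-black
    """
    scr = np.asarray(creatinine, dtype=float)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be positive")
    age = np.asarray(age, dtype=float)
    female = np.asarray(female, dtype=bool)
    black = np.asarray(black, dtype=bool)
    kappa = np.where(female, _KAPPA["F"], _KAPPA["M"])
    alpha = np.where(female, _ALPHA["F"], _ALPHA["M"])
    ratio = scr / kappa
    egfr = (141.0
            * np.minimum(ratio, 1.0) ** alpha
            * np.maximum(ratio, 1.0) ** -1.209
            * 0.993 ** age
            * np.where(female, _SEX_FACTOR["F"], _SEX_FACTOR["M"])
            * np.where(black, _RACE_FACTOR_BLACK, 1.0))
    return egfr if egfr.shape else float(egfr)


def creatinine_for_egfr(egfr, age, female, black=False):
    """Invert the CKD-EPI 2009 equation: creatinine giving target ``egfr``.

    Used by the synthetic-cohort generator to materialise lab records whose
    recomputed eGFR reproduces a latent trajectory exactly.
    """
    egfr = np.asarray(egfr, dtype=float)
    if np.any(egfr <= 0):
        raise ValueError("target eGFR must be positive")
    age = np.asarray(age, dtype=float)
    female = np.asarray(female, dtype=bool)
    black = np.asarray(black, dtype=bool)
    kappa = np.where(female, _KAPPA["F"], _KAPPA["M"])
    alpha = np.where(female, _ALPHA["F"], _ALPHA["M"])
    base = (141.0 * 0.993 ** age
            * np.where(female, _SEX_FACTOR["F"], _SEX_FACTOR["M"])
            * np.where(black, _RACE_FACTOR_BLACK, 1.0))
    # at scr = kappa both spline terms are 1 and eGFR = base
    scr = np.where(egfr >= base,
                   kappa * (egfr / base) ** (1.0 / alpha),
                   kappa * (egfr / base) ** (1.0 / -1.209))
    return scr if scr.shape else float(scr)


@dataclass
class CkdStatus:
    """Outcome of incident-CKD detection for one participant."""

    participant_id: object
    incident: bool
    event_day: float | None          # days since study start (confirming rule)
    first_qualifying_day: float | None
    qualifying_days: list = field(default_factory=list)
    censor_day: float = np.nan
    censor_reason: str = ""          # "end of follow-up" / "loss" / "no labs"


def detect_incident_ckd(days, egfr, uacr, followup_start: float,
                        followup_end: float, *,
                        event_rule: str = "confirming",
                        censor_reason: str = "end of follow-up") -> CkdStatus:
    """Apply the two-determination / 90-day chronicity rule to one participant.

    ``days`` are determination times in days since study start; ``egfr`` and
    ``uacr`` are aligned arrays (NaN where the analyte was not measured).  A
    determination qualifies if eGFR < 60 or UACR >= 30 (either analyte, a
    day with both counts once).  The participant is incident iff some
    qualifying determination lies >= 90 days after the earliest qualifying
    one, both within [followup_start, followup_end].  Qualifying
    determinations need not be consecutive; intervening normal values do
    not reset the clock.
    """
    days = np.asarray(days, dtype=float)
    egfr = np.asarray(egfr, dtype=float)
    uacr = np.asarray(uacr, dtype=float)
    if event_rule not in ("confirming", "first"):
        raise ValueError(f"unknown event_rule {event_rule!r}")
    order = np.argsort(days, kind="stable")
    days, egfr, uacr = days[order], egfr[order], uacr[order]
    in_window = (days >= followup_start) & (days <= followup_end)
    qual = in_window & (
        (np.nan_to_num(egfr, nan=np.inf) < EGFR_THRESHOLD)
        | (np.nan_to_num(uacr, nan=-np.inf) >= UACR_THRESHOLD))
    qdays = np.unique(days[qual])
    status = CkdStatus(participant_id=None, incident=False, event_day=None,
                       first_qualifying_day=None,
                       qualifying_days=list(qdays),
                       censor_day=followup_end,
                       censor_reason="no labs" if days.size == 0 else censor_reason)
    if qdays.size >= 2:
        first = qdays[0]
        confirming = qdays[qdays >= first + MIN_SPAN_DAYS]
        if confirming.size:
            status.incident = True
            status.first_qualifying_day = float(first)
            status.event_day = float(confirming[0] if event_rule == "confirming"
                                     else first)
            status.censor_day = status.event_day
            status.censor_reason = ""
    return status


def detect_cohort_ckd(labs: pd.DataFrame, participants: pd.DataFrame, *,
                      followup_start_col: str = "analysis_entry_day",
                      followup_end_col: str = "censor_day",
                      event_rule: str = "confirming") -> pd.DataFrame:
    """Vectorised cohort-level incident-CKD detection.

    ``labs`` needs columns participant_id, day, egfr, uacr; ``participants``
    needs participant_id plus the per-participant follow-up window columns.
    Returns one row per participant: incident flag, event_day,
    first_qualifying_day, censor_day, censor_reason.
    """
    out = []
    lab_groups = dict(iter(labs.groupby("participant_id", sort=False)))
    for row in participants.itertuples(index=False):
        pid = row.participant_id
        start = getattr(row, followup_start_col)
        end = getattr(row, followup_end_col)
        g = lab_groups.get(pid)
        if g is None:
            st = CkdStatus(pid, False, None, None, [], end, "no labs")
        else:
            st = detect_incident_ckd(g["day"].to_numpy(),
                                     g["egfr"].to_numpy(),
                                     g["uacr"].to_numpy(),
                                     start, end, event_rule=event_rule)
            st.participant_id = pid
        out.append({"participant_id": pid,
                    "incident": st.incident,
                    "event_day": st.event_day if st.incident else np.nan,
                    "first_qualifying_day": (st.first_qualifying_day
                                             if st.incident else np.nan),
                    "censor_day": st.censor_day,
                    "censor_reason": st.censor_reason})
    return pd.DataFrame(out)


def exclude_prevalent_ckd(participants: pd.DataFrame, labs: pd.DataFrame, *,
                          window_days: float = 365.0
                          ) -> tuple[pd.DataFrame, int]:
    """Remove participants meeting the CKD definition on first-year labs.

    The full two-determination / 90-day rule is applied to determinations
    within [0, window_days) of study start (day 0).  Survivors' incidence
    follow-up starts at max(entry, window_days): the first year is a
    screening window, not at-risk time.

    Returns the filtered participant table (with ``analysis_entry_day``
    set) and the number excluded.
    """
    first_year = labs[labs["day"] < window_days]
    excluded: set = set()
    for pid, g in first_year.groupby("participant_id", sort=False):
        st = detect_incident_ckd(g["day"].to_numpy(), g["egfr"].to_numpy(),
                                 g["uacr"].to_numpy(), 0.0,
                                 window_days - 1e-9)
        if st.incident:
            excluded.add(pid)
    keep = ~participants["participant_id"].isin(excluded)
    kept = participants[keep].copy()
    kept["analysis_entry_day"] = np.maximum(kept["entry_day"], window_days)
    return kept, int((~keep).sum())


# --- clinical covariates -------------------------------------------------

UNKNOWN = None  # three-valued flags: True / False / None (insufficient data)


def _at_least_two(values: np.ndarray, predicate) -> bool:
    return int(predicate(values).sum()) >= 2


@dataclass
class CovariateProfile:
    """Clinical covariates; flags are True / False / None (unknown)."""

    female: bool | None = UNKNOWN
    born_spain: bool | None = UNKNOWN
    age70_crossing_day: float | None = None   # day the participant turns 70
    hypertension: bool | None = UNKNOWN
    high_normal_bp: bool | None = UNKNOWN
    diabetes: bool | None = UNKNOWN
    impaired_fasting_glucose: bool | None = UNKNOWN
    obesity: bool | None = UNKNOWN
    low_hdl: bool | None = UNKNOWN
    hypertriglyceridemia: bool | None = UNKNOWN
    metabolic_syndrome: bool | None = UNKNOWN
    n_chronic_diseases: int = 0
    smoking: int | None = UNKNOWN     # 0 non, 1 smoker, 2 former
    alcohol: int | None = UNKNOWN     # 0 non, 1 alcoholic, 2 ex-alcoholic
    antihypertensive: bool | None = UNKNOWN
    antidiabetic: bool | None = UNKNOWN
    lipid_lowering: bool | None = UNKNOWN
    nsaid: bool | None = UNKNOWN


def derive_covariates(*,
                      female: bool | None = UNKNOWN,
                      born_spain: bool | None = UNKNOWN,
                      birth_day: float | None = None,
                      bp_readings: np.ndarray | None = None,
                      fasting_glucose: np.ndarray | None = None,
                      random_glucose_with_symptoms: bool = False,
                      hba1c: np.ndarray | None = None,
                      bmi: float | None = None,
                      hdl: float | None = None,
                      triglycerides: float | None = None,
                      diagnosed_hypertension: bool = False,
                      diagnosed_diabetes: bool = False,
                      antihypertensive: bool | None = UNKNOWN,
                      antidiabetic: bool | None = UNKNOWN,
                      lipid_lowering: bool | None = UNKNOWN,
                      nsaid: bool | None = UNKNOWN,
                      smoking: int | None = UNKNOWN,
                      alcohol: int | None = UNKNOWN,
                      n_chronic_diseases: int = 0) -> CovariateProfile:
    """Derive the covariate profile from raw measurements and flags.

    Rules (units: BP mmHg, glucose mg/dL, BMI kg/m2, lipids mg/dL):

    * hypertension: >= 2 BP readings with systolic >= 140 and/or diastolic
      >= 90, or a prior diagnosis, or antihypertensive treatment;
    * high-normal BP: >= 2 readings with systolic 130-139 and/or diastolic
      85-89 (not meeting the hypertension thresholds);
    * type-2 diabetes: symptoms + random glucose >= 200, or two fasting
      glucose >= 126, or two HbA1c >= 6.5%, or diagnosis/treatment;
    * impaired fasting glucose: basal glucose >= 110 (below diabetes);
    * obesity: BMI > 30; low HDL: < 40 (men) / < 50 (women);
    * hypertriglyceridemia: >= 150;
    * metabolic syndrome: >= 3 of {diabetes or impaired glucose,
      hypertension or high-normal BP, low HDL, hypertriglyceridemia,
      obesity}.

    Missing inputs leave the corresponding flag ``None`` (unknown), never
    silently False.
    """
    prof = CovariateProfile(female=female, born_spain=born_spain,
                            smoking=smoking, alcohol=alcohol,
                            antihypertensive=antihypertensive,
                            antidiabetic=antidiabetic,
                            lipid_lowering=lipid_lowering, nsaid=nsaid,
                            n_chronic_diseases=n_chronic_diseases)
    if birth_day is not None:
        prof.age70_crossing_day = birth_day + 70 * 365.25

    if bp_readings is not None and len(bp_readings):
        bp = np.atleast_2d(np.asarray(bp_readings, dtype=float))  # (k, 2) sys, dia
        high = (bp[:, 0] >= 140) | (bp[:, 1] >= 90)
        prof.hypertension = (int(high.sum()) >= 2 or diagnosed_hypertension
                             or antihypertensive is True)
        hn = (~high) & (((bp[:, 0] >= 130) & (bp[:, 0] <= 139))
                        | ((bp[:, 1] >= 85) & (bp[:, 1] <= 89)))
        prof.high_normal_bp = int(hn.sum()) >= 2
    elif diagnosed_hypertension or antihypertensive is True:
        prof.hypertension = True

    fg = (np.asarray(fasting_glucose, dtype=float)
          if fasting_glucose is not None else np.array([]))
    a1c = np.asarray(hba1c, dtype=float) if hba1c is not None else np.array([])
    dm = (random_glucose_with_symptoms
          or _at_least_two(fg, lambda v: v >= 126)
          or _at_least_two(a1c, lambda v: v >= 6.5)
          or diagnosed_diabetes or antidiabetic is True)
    if dm:
        prof.diabetes = True
    elif fg.size or a1c.size or diagnosed_diabetes:
        prof.diabetes = False
    if fg.size:
        prof.impaired_fasting_glucose = bool(np.any(fg >= 110)) and prof.diabetes is not True

    if bmi is not None:
        if bmi <= 0:
            raise ValueError("BMI must be positive")
        prof.obesity = bmi > 30.0
    if hdl is not None:
        if female is UNKNOWN:
            raise ValueError("sex required to classify HDL")
        prof.low_hdl = hdl < (50.0 if female else 40.0)
    if triglycerides is not None:
        prof.hypertriglyceridemia = triglycerides >= 150.0

    components = [
        prof.diabetes is True or prof.impaired_fasting_glucose is True,
        prof.hypertension is True or prof.high_normal_bp is True,
        prof.low_hdl is True,
        prof.hypertriglyceridemia is True,
        prof.obesity is True,
    ]
    known = [
        prof.diabetes is not UNKNOWN or prof.impaired_fasting_glucose is not UNKNOWN,
        prof.hypertension is not UNKNOWN or prof.high_normal_bp is not UNKNOWN,
        prof.low_hdl is not UNKNOWN,
        prof.hypertriglyceridemia is not UNKNOWN,
        prof.obesity is not UNKNOWN,
    ]
    if sum(components) >= 3:
        prof.metabolic_syndrome = True
    elif all(known):
        prof.metabolic_syndrome = False
    return prof
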