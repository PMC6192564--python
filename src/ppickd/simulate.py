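"""Synthetic EHR cohort generator with known ground truth.

Generates the four tables the pipeline consumes (participants,
prescriptions, laboratory records, diagnoses) with the statistical
structure the analysis assumes:

* staggered entry over an 8-year study window, with administrative
  censoring at the end and random loss to follow-up;
* covariate-dependent PPI initiation (confounding by age and
  comorbidity), dose mix, and log-normal episode lengths realised as
  dated prescription records;
* latent CKD event times drawn exactly (inversion of the piecewise
  cumulative hazard) from a piecewise-exponential model
  exp(lambda_bin(t) + x(t)'beta + u_i + s_i) with individual frailty u
  and a Matérn spatial field s over practice locations;
* lab visit trajectories built so the phenotyping rules recover the
  latent event (eGFR drops below 60 — or UACR rises above 30 for a
  configurable fraction of events — from the event time on, never
  before, up to measurement noise);
* a fraction of participants with prevalent (pre-existing) low eGFR to
  exercise the first-year exclusion.

All randomness flows through one ``numpy`` Generator seeded from the
config, so identical configs give byte-identical tables.  Time unit is
days since study start (2005-01-01); a month is 30 days.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .phenotype import creatinine_for_egfr
from .spatial import simulate_matern_field

STUDY_START = "2005-01-01"
DAYS_IN_YEAR = 365.25


def _default_true_log_hr() -> dict:
    # generator defaults follow the magnitude of effects reported for
    # comparable primary-care cohorts
    return {"ppi": float(np.log(1.3)),
            "age70": float(np.log(2.39)),
            "female": float(np.log(1.04)),
            "hypertension": float(np.log(1.17)),
            "diabetes": float(np.log(1.43))}


def _default_exposure_coefs() -> dict:
    return {"age70": 0.8, "hypertension": 0.7, "diabetes": 0.5,
            "female": 0.1}


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults define the study conditions."""

    n_participants: int = 2000
    study_days: int = 2922                 # 8 calendar years 2005-2012
    seed: int = 0
    # entry process
    frac_entry_at_start: float = 0.6
    late_entry_span_days: float = 2190.0   # late entrants uniform over 6 y
    # lab visit process
    visit_rate_per_year: float = 6.0
    uacr_measured_prob: float = 1.0
    # demographics / covariates
    age_mean: float = 45.0
    age_sd: float = 20.0
    age_min: float = 15.0
    age_max: float = 100.0
    p_female: float = 0.5
    p_born_spain: float = 0.9
    hypertension_intercept: float = -4.0
    hypertension_age_slope: float = 0.045
    diabetes_intercept: float = -4.3
    diabetes_age_slope: float = 0.045
    # exposure model: ~25% baseline users, ~7% follow-up initiators
    baseline_use_intercept: float = -1.45
    baseline_use_coefs: dict = field(default_factory=_default_exposure_coefs)
    followup_use_intercept: float = -2.55
    followup_use_coefs: dict = field(default_factory=_default_exposure_coefs)
    # loading of the spatial field on the PPI-initiation logit; with a
    # non-zero spatial_sd this makes the field a true (unobserved)
    # confounder rather than mere hazard heterogeneity
    exposure_spatial_coef: float = 1.0
    episode_length_log_mean: float = float(np.log(120.0))
    episode_length_log_sd: float = 0.7
    episode_gap_log_mean: float = float(np.log(150.0))
    episode_gap_log_sd: float = 0.8
    p_repeat_episode: float = 0.5
    p_high_dose: float = 0.2
    prescription_days: int = 28
    p_quantity_representation: float = 0.3
    # outcome model
    true_log_hr: dict = field(default_factory=_default_true_log_hr)
    baseline_log_hazard: list | None = None   # per bin; default gentle trend
    n_baseline_bins: int = 16
    frailty_sd: float = 0.3
    spatial_sd: float = 0.0
    spatial_range: float = 0.3
    spatial_nu: float = 1.0
    n_sites: int = 64
    loss_rate_per_year: float = 0.02
    prevalent_frac: float = 0.03
    # lab trajectories
    p_uacr_event_path: float = 0.2
    egfr_healthy_mean: float = 90.0
    egfr_noise_sd: float = 4.0
    egfr_event_mean: float = 52.0
    egfr_event_sd: float = 3.0
    egfr_event_slope_per_year: float = 1.0
    uacr_healthy_mean: float = 10.0
    uacr_healthy_sd: float = 6.0
    uacr_event_mean: float = 60.0
    uacr_event_sd: float = 15.0

    def __post_init__(self):
        if self.study_days <= 0:
            raise ValueError("study window must be positive")
        for name in ("frac_entry_at_start", "p_female", "p_born_spain",
                     "p_high_dose", "p_repeat_episode", "prevalent_frac",
                     "p_uacr_event_path", "uacr_measured_prob",
                     "p_quantity_representation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.frailty_sd < 0 or self.spatial_sd < 0:
            raise ValueError("random-effect SDs must be non-negative")
        if self.baseline_log_hazard is not None and not np.all(
                np.isfinite(self.baseline_log_hazard)):
            raise ValueError("baseline log hazard must be finite")

    def baseline(self) -> np.ndarray:
        if self.baseline_log_hazard is not None:
            return np.asarray(self.baseline_log_hazard, dtype=float)
        return np.linspace(-9.1, -8.7, self.n_baseline_bins)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationTruth:
    """Ground truth sidecar for parameter-recovery tests."""

    config: SimulationConfig
    per_participant: pd.DataFrame   # frailty, spatial, event_day, exposure
    episodes: pd.DataFrame          # true exposure episodes

    def true_hr(self, name: str) -> float:
        return float(np.exp(self.config.true_log_hr.get(name, 0.0)))


def _sample_piecewise_event(seg_lo, seg_hi, seg_log_h, rng) -> float | None:
    """Exact inversion sampling from a piecewise-constant hazard."""
    target = rng.exponential()
    cum = 0.0
    for lo, hi, lh in zip(seg_lo, seg_hi, seg_log_h):
        h = np.exp(lh)
        if not np.isfinite(h):
            raise FloatingPointError("non-finite hazard in event sampling")
        seg = (hi - lo) * h
        if cum + seg >= target:
            return lo + (target - cum) / h
        cum += seg
    return None


def simulate_cohort(config: SimulationConfig):
    """Generate one cohort.

    Returns (participants, prescriptions, labs, diagnoses, truth).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    W = float(config.study_days)
    lam = config.baseline()
    bin_edges = np.linspace(0.0, W, len(lam) + 1)

    if n == 0:
        empty = pd.DataFrame()
        return (empty, empty, empty, empty,
                SimulationTruth(config, empty, empty))

    # --- participants ---------------------------------------------------
    at_start = rng.random(n) < config.frac_entry_at_start
    entry = np.where(at_start, 0.0,
                     rng.uniform(0.0, config.late_entry_span_days, n))
    age0 = np.clip(rng.normal(config.age_mean, config.age_sd, n),
                   config.age_min, config.age_max)
    birth_day = -age0 * DAYS_IN_YEAR
    age70_day = birth_day + 70.0 * DAYS_IN_YEAR
    female = rng.random(n) < config.p_female
    born_spain = rng.random(n) < config.p_born_spain
    hyperten = rng.random(n) < _sigmoid(config.hypertension_intercept
                                        + config.hypertension_age_slope * age0)
    diabetes = rng.random(n) < _sigmoid(config.diabetes_intercept
                                        + config.diabetes_age_slope * age0)

    site_coords = rng.random((config.n_sites, 2))
    site_id = rng.integers(0, config.n_sites, n)
    if config.spatial_sd > 0:
        s_field = simulate_matern_field(site_coords, config.spatial_sd,
                                        config.spatial_range,
                                        config.spatial_nu, rng)
    else:
        s_field = np.zeros(config.n_sites)
    s_i = s_field[site_id]
    u_i = (rng.normal(0.0, config.frailty_sd, n) if config.frailty_sd > 0
           else np.zeros(n))
    prevalent = (rng.random(n) < config.prevalent_frac) & (entry == 0.0)
    loss_day = entry + rng.exponential(
        DAYS_IN_YEAR / max(config.loss_rate_per_year, 1e-12), n)
    followup_end = np.minimum(W, loss_day)

    # --- PPI exposure ----------------------------------------------------
    x70_now = (age0 >= 70.0).astype(float)
    cov_arrays = {"age70": x70_now, "hypertension": hyperten.astype(float),
                  "diabetes": diabetes.astype(float),
                  "female": female.astype(float)}

    def _logistic_p(intercept: float, coefs: dict) -> np.ndarray:
        lin = np.full(n, intercept)
        for name, coef in coefs.items():
            lin += coef * cov_arrays[name]
        lin += config.exposure_spatial_coef * s_i
        return _sigmoid(lin)

    p_base = _logistic_p(config.baseline_use_intercept,
                         config.baseline_use_coefs)
    p_follow = _logistic_p(config.followup_use_intercept,
                           config.followup_use_coefs)
    is_base_user = rng.random(n) < p_base
    is_follow_user = (~is_base_user) & (rng.random(n) < p_follow)
    ppi_start = np.full(n, np.nan)
    ppi_start[is_base_user] = rng.uniform(0.0, 365.0, int(is_base_user.sum()))
    ppi_start[is_follow_user] = rng.uniform(
        365.0, max(W - 180.0, 366.0), int(is_follow_user.sum()))

    episode_rows = []
    drug_names = np.array(["omeprazole", "esomeprazole", "lansoprazole",
                           "pantoprazole", "rabeprazole"])
    drug_probs = np.array([0.55, 0.10, 0.10, 0.18, 0.07])
    standard_mg = {"omeprazole": 20.0, "esomeprazole": 20.0,
                   "pantoprazole": 20.0, "lansoprazole": 15.0,
                   "rabeprazole": 10.0}
    for i in np.flatnonzero(~np.isnan(ppi_start)):
        t = float(ppi_start[i])
        while t < W:
            length = max(7.0, float(rng.lognormal(
                config.episode_length_log_mean, config.episode_length_log_sd)))
            length = float(np.round(length))
            drug = str(rng.choice(drug_names, p=drug_probs))
            high = bool(rng.random() < config.p_high_dose)
            episode_rows.append((i, t, min(t + length, W), drug, high))
            if rng.random() >= config.p_repeat_episode:
                break
            gap = float(rng.lognormal(config.episode_gap_log_mean,
                                      config.episode_gap_log_sd))
            t = t + length + max(1.0, np.round(gap))
    episodes = pd.DataFrame(episode_rows, columns=[
        "participant_id", "start_day", "end_day", "drug", "high_dose"])

    # --- prescriptions realising the episodes ----------------------------
    presc_rows = []
    for rec in episodes.itertuples(index=False):
        dose = standard_mg[rec.drug] * (2.0 if rec.high_dose else 1.0)
        t = rec.start_day
        remaining = int(round(rec.end_day - rec.start_day))
        while remaining > 0:
            days = min(config.prescription_days, remaining)
            if rng.random() < config.p_quantity_representation:
                daily_units = 2.0 if rec.high_dose else 1.0
                presc_rows.append((rec.participant_id, rec.drug, dose, t,
                                   np.nan, days * daily_units, daily_units))
            else:
                presc_rows.append((rec.participant_id, rec.drug, dose, t,
                                   float(days), np.nan, np.nan))
            t += days
            remaining -= days
    prescriptions = pd.DataFrame(presc_rows, columns=[
        "participant_id", "drug", "daily_dose_mg", "start_day",
        "treatment_days", "quantity", "daily_units"])
    prescriptions.insert(0, "prescription_id", np.arange(len(prescriptions)))

    # --- latent event times ----------------------------------------------
    beta = config.true_log_hr
    const_part = (u_i + s_i
                  + beta.get("female", 0.0) * female
                  + beta.get("hypertension", 0.0) * hyperten
                  + beta.get("diabetes", 0.0) * diabetes)
    event_day = np.full(n, np.nan)
    for i in range(n):
        if prevalent[i]:
            event_day[i] = entry[i]
            continue
        brks = [entry[i], W]
        brks.extend(e for e in bin_edges[1:-1] if entry[i] < e < W)
        for extra in (ppi_start[i], age70_day[i]):
            if np.isfinite(extra) and entry[i] < extra < W:
                brks.append(float(extra))
        brks = np.unique(brks)
        lo, hi = brks[:-1], brks[1:]
        mid = 0.5 * (lo + hi)
        lh = (lam[np.clip(np.searchsorted(bin_edges, mid) - 1, 0,
                          len(lam) - 1)]
              + const_part[i]
              + beta.get("ppi", 0.0) * (np.isfinite(ppi_start[i])
                                        & (mid >= ppi_start[i]))
              + beta.get("age70", 0.0) * (mid >= age70_day[i]))
        t = _sample_piecewise_event(lo, hi, lh, rng)
        if t is not None:
            event_day[i] = t

    # --- laboratory records ----------------------------------------------
    uacr_path = rng.random(n) < config.p_uacr_event_path
    lab_rows = []
    slope_per_day = config.egfr_event_slope_per_year / DAYS_IN_YEAR
    for i in range(n):
        span = followup_end[i] - entry[i]
        if span <= 0:
            continue
        # scheduled check-ups: regular spacing with a random phase, so the
        # first determination after a latent event is at most one visit
        # interval late (the phenotype round-trip guarantee)
        interval = DAYS_IN_YEAR / config.visit_rate_per_year
        phase = rng.uniform(0.0, interval)
        days = np.arange(entry[i] + phase, followup_end[i], interval)
        k = len(days)
        if k == 0:
            continue
        post = np.isfinite(event_day[i]) & (days >= event_day[i])
        egfr = np.where(
            post & ~uacr_path[i],
            config.egfr_event_mean
            - slope_per_day * np.maximum(days - np.nan_to_num(event_day[i]), 0)
            + rng.normal(0.0, config.egfr_event_sd, k),
            config.egfr_healthy_mean + rng.normal(0.0, config.egfr_noise_sd, k))
        egfr = np.maximum(egfr, 5.0)
        uacr = np.where(
            post & uacr_path[i],
            np.maximum(rng.normal(config.uacr_event_mean,
                                  config.uacr_event_sd, k), 0.0),
            # healthy UACR truncated just below the 30 mg/g threshold so
            # noise never produces a false qualifying determination
            np.clip(rng.normal(config.uacr_healthy_mean,
                               config.uacr_healthy_sd, k), 0.0, 28.0))
        has_uacr = rng.random(k) < config.uacr_measured_prob
        age_at = age0[i] + days / DAYS_IN_YEAR
        scr = creatinine_for_egfr(egfr, age_at, female[i])
        for j in range(k):
            lab_rows.append((i, float(days[j]), float(scr[j]),
                             float(uacr[j]) if has_uacr[j] else np.nan))
    labs = pd.DataFrame(lab_rows, columns=["participant_id", "day",
                                           "creatinine", "uacr"])

    # --- diagnoses / treatment flags -------------------------------------
    diag_rows = []
    for i in range(n):
        if hyperten[i]:
            diag_rows.append((i, "hypertension", float(entry[i])))
        if diabetes[i]:
            diag_rows.append((i, "diabetes", float(entry[i])))
    diagnoses = pd.DataFrame(diag_rows, columns=["participant_id",
                                                 "condition", "onset_day"])

    start_ts = pd.Timestamp(STUDY_START)
    participants = pd.DataFrame({
        "participant_id": np.arange(n),
        "female": female.astype(int),
        "born_spain": born_spain.astype(int),
        "age_at_start": age0,
        "birth_day": birth_day,
        "age70_day": age70_day,
        "entry_day": entry,
        "entry_date": start_ts + pd.to_timedelta(np.round(entry), unit="D"),
        "followup_end_day": followup_end,
        "site_id": site_id,
        "site_x": site_coords[site_id, 0],
        "site_y": site_coords[site_id, 1],
        "hypertension": hyperten.astype(int),
        "diabetes": diabetes.astype(int),
    })
    truth_df = pd.DataFrame({
        "participant_id": np.arange(n),
        "frailty": u_i,
        "spatial": s_i,
        "event_day": event_day,
        "ppi_start_day": ppi_start,
        "prevalent": prevalent.astype(int),
        "uacr_event_path": uacr_path.astype(int),
    })
    truth = SimulationTruth(config=config, per_participant=truth_df,
                            episodes=episodes)
    # non-prevalent events must postdate entry (sampler guarantees it)
    ok = truth_df["prevalent"].astype(bool) | truth_df["event_day"].isna() \
        | (truth_df["event_day"] > participants["entry_day"])
    assert bool(ok.all())
    return participants, prescriptions, labs, diagnoses, truth


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))
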