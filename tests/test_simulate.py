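"""Synthetic cohort generator: determinism, null effects, oracles, round trip."""

import numpy as np
import pandas as pd
import pytest

from ppickd.pipeline import labs_with_egfr
from ppickd.phenotype import detect_cohort_ckd, exclude_prevalent_ckd
from ppickd.simulate import SimulationConfig, simulate_cohort

from conftest import make_cohort


def crude_rates(truth, W=2922.0):
    """Events and person-time by ever-use state, from the ground truth."""
    tp = truth.per_participant
    ev = tp["event_day"].to_numpy()
    t0 = tp["ppi_start_day"].to_numpy()
    end = np.where(np.isfinite(ev), ev, W)
    exp_start = np.where(np.isfinite(t0), np.clip(t0, None, end), end)
    pt_unexp = exp_start
    pt_exp = end - exp_start
    d_exp = np.nansum((np.isfinite(ev) & np.isfinite(t0) & (ev >= t0)))
    d_unexp = np.nansum(np.isfinite(ev)) - d_exp
    return (d_exp / pt_exp.sum(), d_unexp / pt_unexp.sum())


class TestBasics:
    def test_seed_reproducibility_byte_identical(self):
        a = make_cohort(seed=9, n=150)
        b = make_cohort(seed=9, n=150)
        for ta, tb in zip(a[:4], b[:4]):
            assert ta.to_csv() == tb.to_csv()
        assert a[4].per_participant.to_csv() == b[4].per_participant.to_csv()

    def test_different_seed_differs(self):
        a = make_cohort(seed=9, n=150)
        b = make_cohort(seed=10, n=150)
        assert a[0].to_csv() != b[0].to_csv()

    def test_empty_cohort(self):
        parts, presc, labs, diag, truth = make_cohort(seed=0, n=0)
        assert len(parts) == 0 and len(truth.per_participant) == 0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(p_female=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(frailty_sd=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(baseline_log_hazard=[0.0, np.inf])

    def test_event_times_after_entry(self):
        _, _, _, _, truth = make_cohort(seed=3, n=300)
        tp = truth.per_participant
        nonprev = tp[tp["prevalent"] == 0].dropna(subset=["event_day"])
        parts = make_cohort(seed=3, n=300)[0]
        entry = parts.set_index("participant_id")["entry_day"]
        assert (nonprev["event_day"].to_numpy()
                > entry.loc[nonprev["participant_id"]].to_numpy()).all()


class TestRates:
    def test_null_exposure_effect_equal_rates(self):
        """With all log hazard ratios at 0 and no heterogeneity the crude
        exposed and unexposed event rates coincide up to Monte Carlo error."""
        cfg = SimulationConfig(
            seed=21, n_participants=4000, frailty_sd=0.0, spatial_sd=0.0,
            prevalent_frac=0.0,
            true_log_hr={k: 0.0 for k in
                         ("ppi", "age70", "female", "hypertension",
                          "diabetes")})
        *_, truth = simulate_cohort(cfg)
        r_exp, r_unexp = crude_rates(truth)
        assert r_exp / r_unexp == pytest.approx(1.0, abs=0.15)

    def test_crude_irr_matches_discrete_time_oracle(self):
        """Continuous-time inversion sampling agrees with an independent
        one-day-step Bernoulli simulation run at the same rates."""
        log_hr = {"ppi": float(np.log(1.5))}
        cfg = SimulationConfig(seed=31, n_participants=3000, frailty_sd=0.0,
                               spatial_sd=0.0, prevalent_frac=0.0,
                               loss_rate_per_year=0.0, true_log_hr=log_hr)
        parts, _, _, _, truth = simulate_cohort(cfg)
        r_exp, r_unexp = crude_rates(truth)
        irr = r_exp / r_unexp

        # oracle: same participants, same per-day hazards, 1-day steps
        rng = np.random.default_rng(99)
        W = int(cfg.study_days)
        lam = cfg.baseline()
        edges = np.linspace(0, W, len(lam) + 1)
        tp = truth.per_participant
        entry = parts["entry_day"].to_numpy()
        t0 = tp["ppi_start_day"].to_numpy()
        days = np.arange(W) + 0.5
        bin_of_day = np.clip(np.searchsorted(edges, days) - 1, 0, len(lam) - 1)
        d_exp = d_unexp = 0
        pt_exp = pt_unexp = 0.0
        for i in range(len(parts)):
            at_risk = days >= entry[i]
            exposed = np.isfinite(t0[i]) & (days >= t0[i])
            h = np.exp(lam[bin_of_day]
                       + log_hr["ppi"] * exposed) * at_risk
            event = rng.random(W) < h
            idx = np.flatnonzero(event)
            t_ev = idx[0] if idx.size else W
            ex_start = t0[i] if np.isfinite(t0[i]) else np.inf
            end = min(t_ev + 1, W)
            pt_u = min(end, max(ex_start, entry[i])) - entry[i]
            pt_u = max(pt_u, 0.0)
            pt_e = end - entry[i] - pt_u
            pt_unexp += pt_u
            pt_exp += pt_e
            if idx.size:
                if days[t_ev] >= ex_start:
                    d_exp += 1
                else:
                    d_unexp += 1
        irr_oracle = (d_exp / pt_exp) / (d_unexp / pt_unexp)
        assert irr == pytest.approx(irr_oracle, rel=0.12)

    def test_km_matches_analytic_piecewise_survival(self):
        """No heterogeneity, no covariate effects: the empirical survival
        of latent event times equals the analytic piecewise-exponential
        survival function within binomial error."""
        cfg = SimulationConfig(
            seed=41, n_participants=4000, frailty_sd=0.0, spatial_sd=0.0,
            prevalent_frac=0.0, frac_entry_at_start=1.0,
            loss_rate_per_year=0.0,
            true_log_hr={})
        *_, truth = simulate_cohort(cfg)
        ev = truth.per_participant["event_day"].to_numpy()
        W = float(cfg.study_days)
        lam = cfg.baseline()
        edges = np.linspace(0, W, len(lam) + 1)
        for t in (500.0, 1500.0, 2500.0):
            H = float(np.sum(np.exp(lam) * np.clip(t - edges[:-1], 0,
                                                   np.diff(edges))))
            s_true = np.exp(-H)
            s_emp = np.mean(~(np.isfinite(ev) & (ev <= t)))
            se = np.sqrt(s_true * (1 - s_true) / len(ev))
            assert abs(s_emp - s_true) < 4 * se + 1e-9


class TestRoundTrip:
    def test_phenotype_recovers_latent_events(self):
        """Running the phenotyping rules on generated labs finds >= 95% of
        latent events, with the first qualifying determination at most one
        visit interval after the true event time."""
        cfg = SimulationConfig(seed=51, n_participants=800)
        parts, _, labs, _, truth = simulate_cohort(cfg)
        labs_e = labs_with_egfr(labs, parts)
        kept, _ = exclude_prevalent_ckd(parts, labs_e)
        kept["censor_day"] = kept["followup_end_day"]
        ckd = detect_cohort_ckd(labs_e, kept)
        tp = truth.per_participant.set_index("participant_id")
        interval = 365.25 / cfg.visit_rate_per_year
        # events with room for confirmation before follow-up ends
        margin = 90 + 2 * interval
        merged = kept.merge(ckd, on="participant_id",
                            suffixes=("", "_ckd"))
        true_ev = tp.loc[merged["participant_id"], "event_day"].to_numpy()
        prevalent = tp.loc[merged["participant_id"], "prevalent"].to_numpy()
        detectable = (np.isfinite(true_ev) & (prevalent == 0)
                      & (true_ev > merged["analysis_entry_day"].to_numpy())
                      & (true_ev < merged["censor_day"].to_numpy() - margin))
        det = merged[detectable]
        ev = true_ev[detectable]
        found = det["incident"].to_numpy()
        assert found.mean() >= 0.95
        delay = det.loc[found, "first_qualifying_day"].to_numpy() - ev[found]
        assert np.all(delay >= 0)
        assert np.quantile(delay, 0.95) <= interval + 1e-9

    def test_detection_never_precedes_latent_event(self):
        cfg = SimulationConfig(seed=61, n_participants=600,
                               prevalent_frac=0.0)
        parts, _, labs, _, truth = simulate_cohort(cfg)
        labs_e = labs_with_egfr(labs, parts)
        kept, _ = exclude_prevalent_ckd(parts, labs_e)
        kept["censor_day"] = kept["followup_end_day"]
        ckd = detect_cohort_ckd(labs_e, kept)
        tp = truth.per_participant.set_index("participant_id")
        inc = ckd[ckd["incident"]]
        true_ev = tp.loc[inc["participant_id"], "event_day"].to_numpy()
        # no detected case without a latent event, none detected early
        assert np.isfinite(true_ev).all()
        assert (inc["first_qualifying_day"].to_numpy()
                >= true_ev - 1e-9).all()


class TestStrataProportions:
    def test_user_strata_near_design_targets(self):
        *_, truth = make_cohort(seed=71, n=6000)
        t0 = truth.per_participant["ppi_start_day"]
        frac_base = (t0 < 365).mean()
        frac_follow = (t0 >= 365).mean()
        assert frac_base == pytest.approx(0.26, abs=0.04)
        assert frac_follow == pytest.approx(0.07, abs=0.03)
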