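"""Laplace engine: Poisson expansion, closed forms, GLM oracle, priors."""

import numpy as np
import pandas as pd
import pytest

from ppickd.hazard import (ModelSpec, PCPrior, _Design, default_bin_edges,
                           fit_latent, hazard_ratio, optimize_hyperparameters,
                           poisson_expand)

from conftest import random_counting_table


def simple_spec(edges, covariates=(), **kw):
    kw.setdefault("frailty", False)
    kw.setdefault("spatial", False)
    kw.setdefault("rw1", False)
    return ModelSpec(bin_edges=np.asarray(edges, float),
                     covariates=tuple(covariates), **kw)


def fit_fixed(table, edges, covariates=(), **kw):
    spec = simple_spec(edges, covariates, **kw)
    data = poisson_expand(table, spec)
    return optimize_hyperparameters(data, spec)


class TestPoissonExpand:
    def test_row_split_at_boundary(self):
        t = pd.DataFrame([{"participant_id": 0, "start": 0.0, "stop": 100.0,
                           "status": 1}])
        d = poisson_expand(t, simple_spec([0, 50, 100]))
        assert list(d.E) == [50.0, 50.0]
        assert list(d.d) == [0.0, 1.0]

    def test_row_inside_single_bin(self):
        t = pd.DataFrame([{"participant_id": 0, "start": 10.0, "stop": 40.0,
                           "status": 1}])
        d = poisson_expand(t, simple_spec([0, 50, 100]))
        assert list(d.E) == [30.0] and list(d.d) == [1.0]

    def test_row_outside_bins_rejected(self):
        t = pd.DataFrame([{"participant_id": 0, "start": 0.0, "stop": 200.0,
                           "status": 0}])
        with pytest.raises(ValueError):
            poisson_expand(t, simple_spec([0, 100]))

    def test_conservation_against_per_day_oracle(self):
        """Total exposure and event count conserved on random tables;
        per-bin exposure matches brute-force one-day accumulation."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            table = random_counting_table(rng, n_subjects=15)
            edges = np.linspace(0, 100, rng.integers(2, 9))
            d = poisson_expand(table, simple_spec(edges))
            assert d.E.sum() == pytest.approx(
                (table["stop"] - table["start"]).sum(), rel=1e-12)
            assert d.d.sum() == table["status"].sum()
            # brute force: accumulate at-risk time in fine steps per bin
            step = 0.01
            grid = np.arange(0, 100, step) + step / 2
            oracle = np.zeros(len(edges) - 1)
            for r in table.itertuples(index=False):
                inside = (grid > r.start) & (grid < r.stop)
                oracle += np.histogram(grid[inside], bins=edges)[0] * step
            got = np.bincount(d.bin_idx, weights=d.E, minlength=len(edges) - 1)
            # grid discretisation error: up to one step per row and boundary
            np.testing.assert_allclose(got, oracle,
                                       atol=step * (len(table) + 2))


class TestClosedForms:
    def test_single_bin_rate_mle(self):
        # d events in total exposure T: posterior mode of lambda = log(d/T)
        rng = np.random.default_rng(0)
        t = pd.DataFrame({
            "participant_id": np.arange(50),
            "start": np.zeros(50),
            "stop": rng.uniform(1, 10, 50),
            "status": (rng.random(50) < 0.5).astype(int)})
        fit = fit_fixed(t, [0, 10.0])
        d, T = t["status"].sum(), t["stop"].sum()
        assert fit.mode.lam[0] == pytest.approx(np.log(d / T), abs=1e-6)

    def test_two_group_rate_ratio(self):
        rng = np.random.default_rng(1)
        n = 80
        x = (np.arange(n) % 2).astype(float)
        t = pd.DataFrame({"participant_id": np.arange(n),
                          "start": np.zeros(n),
                          "stop": rng.uniform(1, 10, n),
                          "status": (rng.random(n) < 0.6).astype(int),
                          "x": x})
        fit = fit_fixed(t, [0, 10.0], ["x"])
        d1 = t.loc[t.x == 1, "status"].sum()
        T1 = t.loc[t.x == 1, "stop"].sum()
        d0 = t.loc[t.x == 0, "status"].sum()
        T0 = t.loc[t.x == 0, "stop"].sum()
        expected = (d1 / T1) / (d0 / T0)
        hr, lo, hi = hazard_ratio(fit, "x")
        assert hr == pytest.approx(expected, abs=1e-6)
        assert lo < hr < hi
        # Wald interval on the log scale from the closed-form variance
        se = np.sqrt(1 / d1 + 1 / d0)
        assert lo == pytest.approx(expected * np.exp(-1.96 * se), rel=1e-3)

    def test_glm_oracle_fixed_effects(self):
        """No-random-effects fits match an independent Poisson GLM with
        log-exposure offset (bin factors + covariates) to 1e-6."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        for rep in range(5):
            n = 300
            x1 = rng.binomial(1, 0.4, n).astype(float)
            x2 = rng.normal(0, 1, n)
            rate = 0.2 * np.exp(0.5 * x1 - 0.3 * x2)
            time = rng.exponential(1 / rate)
            cens = rng.uniform(0.5, 6.0, n)
            stop = np.minimum(time, cens)
            status = (time <= cens).astype(int)
            t = pd.DataFrame({"participant_id": np.arange(n),
                              "start": np.zeros(n), "stop": stop,
                              "status": status, "x1": x1, "x2": x2})
            edges = np.linspace(0, stop.max(), 4)
            spec = simple_spec(edges, ["x1", "x2"])
            data = poisson_expand(t, spec)
            fit = optimize_hyperparameters(data, spec)
            X = np.column_stack([
                (data.bin_idx[:, None] == np.arange(3)).astype(float),
                data.X])
            glm = sm.GLM(data.d, X, family=sm.families.Poisson(),
                         offset=np.log(data.E)).fit(tol=1e-12)
            np.testing.assert_allclose(fit.mode.beta, glm.params[3:],
                                       atol=1e-6)
            np.testing.assert_allclose(fit.mode.lam, glm.params[:3],
                                       atol=1e-6)
            np.testing.assert_allclose(fit.beta_sd, glm.bse[3:], rtol=1e-4)

    def test_init_at_solution_is_fixed_point(self):
        rng = np.random.default_rng(4)
        t = pd.DataFrame({"participant_id": np.arange(40),
                          "start": np.zeros(40),
                          "stop": rng.uniform(1, 5, 40),
                          "status": np.ones(40, dtype=int)})
        spec = simple_spec([0, 5.0])
        data = poisson_expand(t, spec)
        fit = optimize_hyperparameters(data, spec)
        design = _Design(data, spec)
        c, u, _, _, iters, gnorm, *_ = fit_latent(
            design, fit.hyper, init=fit.mode)
        assert iters == 1 and gnorm < 1e-6
        assert c[0] == pytest.approx(fit.mode.lam[0], abs=1e-12)


class TestPriorsAndHyper:
    def test_pc_prior_tail_mass(self):
        # P(sigma > sigma0) = alpha by construction of the exponential law
        for sigma0, alpha in [(1.0, 0.01), (0.5, 0.1), (2.0, 0.05)]:
            prior = PCPrior(sigma0, alpha)
            assert np.exp(-prior.rate * sigma0) == pytest.approx(alpha)

    def test_rw1_precision_shrinks_baseline_variation(self):
        rng = np.random.default_rng(6)
        n = 400
        time = rng.exponential(5.0, n)
        stop = np.minimum(time, 10.0)
        status = (time <= 10.0).astype(int)
        t = pd.DataFrame({"participant_id": np.arange(n),
                          "start": np.zeros(n), "stop": stop,
                          "status": status})
        variances = []
        for rw_sd in (1.0, 0.1, 0.01):
            fit = fit_fixed(t, np.linspace(0, 10, 9), rw1=True,
                            fixed_hyper={"rw_sd": rw_sd})
            variances.append(np.var(fit.mode.lam))
        assert variances[0] >= variances[1] >= variances[2]
        assert variances[2] < 1e-3  # effectively constant baseline

    def test_frailty_sd_shrinks_on_homogeneous_data(self):
        """With no heterogeneity in the generator the estimated frailty SD
        collapses toward zero."""
        rng = np.random.default_rng(8)
        n = 3000
        time = rng.exponential(5.0, n)
        stop = np.minimum(time, 8.0)
        status = (time <= 8.0).astype(int)
        t = pd.DataFrame({"participant_id": np.arange(n),
                          "start": np.zeros(n), "stop": stop,
                          "status": status})
        spec = ModelSpec(bin_edges=np.array([0.0, 8.0]), covariates=(),
                         frailty=True, spatial=False, rw1=False)
        data = poisson_expand(t, spec)
        fit = optimize_hyperparameters(data, spec)
        assert fit.hyper["frailty_sd"] < 0.1

    def test_degenerate_hr_interval(self):
        rng = np.random.default_rng(9)
        n = 60
        t = pd.DataFrame({"participant_id": np.arange(n),
                          "start": np.zeros(n),
                          "stop": rng.uniform(1, 4, n),
                          "status": np.ones(n, dtype=int),
                          "x": (np.arange(n) % 2).astype(float)})
        fit = fit_fixed(t, [0, 4.0], ["x"])
        with pytest.raises(KeyError):
            hazard_ratio(fit, "not_in_model")

    def test_default_bin_edges_cover_range(self):
        t = pd.DataFrame({"participant_id": [0, 1], "start": [2.0, 5.0],
                          "stop": [9.0, 20.0], "status": [0, 1]})
        edges = default_bin_edges(t, 10)
        assert edges[0] == 2.0 and edges[-1] == 20.0 and len(edges) == 11
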