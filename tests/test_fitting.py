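"""Joint normalized fitting: objective, initialization, optimizer and Modes."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import least_squares
from scipy.special import expit

from elmfit import (
    ExtendedLogisticModel,
    ResponseSeries,
    SiteParams,
    count_parameters,
    fit,
    fit_logistic_series,
    init_params,
    logistic_response,
    normalized_sse,
)
from elmfit.fitting import _ParamMap
from elmfit.simulate import TrialDesign, generate

N5 = np.array([0.0, 56.0, 112.0, 168.0, 224.0])


def _site_series(sp, n=N5):
    out = []
    for fr in ("grain", "total"):
        for resp in ("biomass", "n_uptake"):
            out.append(ResponseSeries(
                site_id=sp.site_id, fraction=fr, response=resp,
                n_applied=n, values=logistic_response(n, sp.logistic(fr, resp)),
            ))
    return out


class TestCountParameters:
    @pytest.mark.parametrize("mode,n_sites,expected", [
        ("I", 3, 21), ("II", 3, 19), ("III", 3, 15),
        ("I", 1, 7), ("II", 2, 13), ("III", 5, 23),
    ])
    def test_counts(self, mode, n_sites, expected):
        assert count_parameters(mode, n_sites) == expected

    def test_errors(self):
        with pytest.raises(ValueError):
            count_parameters("IV", 3)
        with pytest.raises(ValueError):
            count_parameters("I", 0)


class TestNormalizedSSE:
    def test_perfect_predictions_give_zero(self, noiseless_series, mode_iii_truth):
        assert normalized_sse(noiseless_series, mode_iii_truth.by_id()) == pytest.approx(0.0, abs=1e-24)

    def test_five_percent_residuals(self, dothan):
        # one 5-point series whose residuals are all exactly 5% of the
        # observed series mean: nrss = 5 * 0.05**2 = 0.0125
        yhat = logistic_response(N5, dothan.logistic("grain", "biomass"))
        delta = np.mean(yhat) * 0.05 / 0.95  # so that delta = 0.05 * mean(y)
        y = yhat + delta
        s = ResponseSeries("Dothan", "grain", "biomass", N5, y)
        got = normalized_sse([s], {"Dothan": dothan})
        assert got == pytest.approx(0.0125, rel=1e-12)

    def test_additive_over_duplicated_series(self, noisy_series, mode_iii_truth):
        params = mode_iii_truth.by_id()
        one = normalized_sse(noisy_series, params)
        two = normalized_sse(list(noisy_series) + [dataclasses.replace(s) for s in noisy_series], params)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_unit_rescaling_invariance(self, noisy_series, mode_iii_truth):
        """Converting a series Mg -> kg together with its amplitude leaves the
        dimensionless objective unchanged."""
        params = dict(mode_iii_truth.by_id())
        base = normalized_sse(noisy_series, params)
        scaled = []
        for s in noisy_series:
            if s.response == "biomass":
                scaled.append(ResponseSeries(s.site_id, s.fraction, s.response,
                                             s.n_applied, s.values * 1000.0))
            else:
                scaled.append(s)
        params_scaled = {
            k: dataclasses.replace(v, A_g=v.A_g * 1000.0, A_t=v.A_t * 1000.0)
            for k, v in params.items()
        }
        assert normalized_sse(scaled, params_scaled) == pytest.approx(base, rel=1e-12)

    def test_unknown_site_and_degenerate_series(self, dothan):
        s = ResponseSeries("Elsewhere", "grain", "biomass", N5, np.ones(5))
        with pytest.raises(KeyError):
            normalized_sse([s], {"Dothan": dothan})
        z = ResponseSeries("Dothan", "grain", "biomass", N5, np.zeros(5))
        with pytest.raises(ValueError, match="degenerate"):
            normalized_sse([z], {"Dothan": dothan})


class TestInitParams:
    def test_exact_recovery_with_true_amplitude(self):
        """With the provisional A equal to the true A, the linearization is an
        exact straight line and (b, c) come back to 1e-10."""
        # identical shifts for biomass and uptake so max(y)/A is the same for
        # all four series and one a_factor maps every provisional A to truth
        b, b_N, c = 0.3, 0.3, 0.015
        sp = SiteParams("s1", A_g=10.0, A_t=20.0, A_Ng=150.0, A_Nt=190.0,
                        b=b, b_N=b_N, c=c)
        series = _site_series(sp)
        ratio = np.max(series[0].values) / sp.A_g
        init = init_params(series, a_factor=1.0 / ratio)
        est = init.sites["s1"]
        assert est.c == pytest.approx(c, rel=1e-10)
        assert est.b == pytest.approx(b, abs=1e-10)
        assert est.b_N == pytest.approx(b_N, abs=1e-10)

    def test_initial_c_within_quarter_of_truth(self, noiseless_series, mode_iii_truth):
        init = init_params(noiseless_series)
        for sid, sp in mode_iii_truth.by_id().items():
            # pooled c: all sites share one initial value
            assert init.sites[sid].c == init.sites[next(iter(init.sites))].c
        cs = [sp.c for sp in mode_iii_truth.by_id().values()]
        assert abs(init.sites["Dothan"].c - np.mean(cs)) / np.mean(cs) < 0.25

    def test_twelve_c_estimates_and_bounds(self, noiseless_series):
        init = init_params(noiseless_series)
        assert len(init.c_estimates) == 12
        lo, hi = init.c_bounds
        assert lo == min(init.c_estimates) and hi == max(init.c_estimates)
        for site in ("Dothan", "Goldsboro", "Portsmouth"):
            blo, bhi = init.b_bounds[site]
            assert blo <= init.sites[site].b <= bhi

    def test_zero_values_excluded_with_warning(self, dothan):
        series = _site_series(dothan)
        # zero out the control plot of one series: the log transform must skip it
        s0 = series[0]
        vals = s0.values.copy()
        vals[0] = 0.0
        series[0] = ResponseSeries(s0.site_id, s0.fraction, s0.response, s0.n_applied, vals)
        with pytest.warns(UserWarning, match="excluded"):
            init = init_params(series)
        assert np.isfinite(init.sites["Dothan"].b)

    def test_incomplete_site_rejected(self, dothan):
        series = _site_series(dothan)[:3]
        with pytest.raises(ValueError, match="missing"):
            init_params(series)


class TestJointFit:
    def test_mode_iii_noiseless_recovery(self, noiseless_series, mode_iii_truth):
        res = fit(noiseless_series, mode="III")
        assert res.converged
        truth = mode_iii_truth.by_id()
        for sid, est in res.params.items():
            for name in ("A_g", "A_t", "A_Ng", "A_Nt", "b", "b_N", "c"):
                assert getattr(est, name) == pytest.approx(
                    getattr(truth[sid], name), rel=1e-5), (sid, name)
        assert res.shared["delta_b"] == pytest.approx(0.660, rel=1e-5)
        assert res.shared["N_cm_g"] == pytest.approx(14.0, rel=1e-5)
        assert res.shared["N_cm_t"] == pytest.approx(9.18, rel=1e-5)

    def test_mode_i_recovers_common_delta_b(self, common_db_truth):
        series, _ = generate(TrialDesign(noise_cv=0.0), common_db_truth)
        res = fit(series, mode="I")
        for sid, est in res.params.items():
            assert est.delta_b == pytest.approx(0.660, abs=1e-3)

    def test_nesting_of_mode_objectives(self, mode_iii_truth):
        for seed in (7, 8):
            series, _ = generate(TrialDesign(noise_cv=0.02, seed=seed), mode_iii_truth)
            m = ExtendedLogisticModel(series)
            r1, r2, r3 = (m.fit(mode=md) for md in ("I", "II", "III"))
            slack = 1e-9 * (1 + r1.nrss)
            assert r1.nrss <= r2.nrss + slack
            assert r2.nrss <= r3.nrss + slack

    def test_constraints_hold_exactly(self, noisy_series):
        m = ExtendedLogisticModel(noisy_series)
        r2 = m.fit(mode="II")
        dbs = [sp.delta_b for sp in r2.params.values()]
        assert max(dbs) - min(dbs) < 1e-12
        r3 = m.fit(mode="III")
        for sp in r3.params.values():
            assert sp.A_Ng / sp.A_g == pytest.approx(r3.shared["N_cm_g"], rel=1e-12)
            assert sp.A_Nt / sp.A_t == pytest.approx(r3.shared["N_cm_t"], rel=1e-12)

    def test_deterministic_trace(self, noisy_series):
        r_a = ExtendedLogisticModel(noisy_series).fit(mode="II")
        r_b = ExtendedLogisticModel(noisy_series).fit(mode="II")
        assert np.array_equal(r_a.trace, r_b.trace)
        assert np.array_equal(r_a.theta, r_b.theta)

    def test_df_accounting(self, noisy_series):
        res = fit(noisy_series, mode="I")
        assert res.n_obs == 60
        assert res.n_params == 21
        assert res.df == 39

    def test_not_worse_than_initializer(self, noisy_series):
        m = ExtendedLogisticModel(noisy_series)
        init = m.initialize()
        start_nrss = normalized_sse(noisy_series, init.sites)
        res = m.fit(mode="I")
        assert res.nrss <= start_nrss

    def test_matches_scipy_least_squares(self, noisy_series):
        """Independent optimizer cross-check: scipy.optimize.least_squares
        started at our solution finds no lower normalized SS."""
        m = ExtendedLogisticModel(noisy_series)
        res = m.fit(mode="I")
        pmap = _ParamMap("I", m.site_ids)
        idx = {s: i for i, s in enumerate(m.site_ids)}

        def resid(theta):
            parts = []
            for s in m.series:
                amp, shift, c, *_ = pmap.terms(theta, idx[s.site_id], s.fraction, s.response)
                parts.append((s.values - amp * expit(c * s.n_applied - shift))
                             / m._scales[s.key()])
            return np.concatenate(parts)

        ls = least_squares(resid, res.theta * 1.2, method="lm", xtol=1e-14, ftol=1e-14)
        assert res.nrss == pytest.approx(2 * ls.cost, rel=1e-8)

    def test_analytic_jacobian_matches_finite_differences(self, noisy_series):
        m = ExtendedLogisticModel(noisy_series)
        res = m.fit(mode="III", max_iter=3)
        pmap = _ParamMap("III", m.site_ids)
        idx = {s: i for i, s in enumerate(m.site_ids)}
        theta = res.theta

        def resid(th):
            parts = []
            for s in m.series:
                amp, shift, c, *_ = pmap.terms(th, idx[s.site_id], s.fraction, s.response)
                parts.append((s.values - amp * expit(c * s.n_applied - shift))
                             / m._scales[s.key()])
            return np.concatenate(parts)

        def jac(th):
            J = np.zeros((60, pmap.n_params))
            row = 0
            for s in m.series:
                amp, shift, c, a_cols, s_cols, c_col = pmap.terms(th, idx[s.site_id], s.fraction, s.response)
                sc = m._scales[s.key()]
                L = expit(c * s.n_applied - shift)
                LL = L * (1 - L)
                rows = slice(row, row + len(s))
                for col, fac in a_cols:
                    J[rows, col] += fac * (-L / sc)
                for col, fac in s_cols:
                    J[rows, col] += fac * (amp * LL / sc)
                J[rows, c_col] += -amp * s.n_applied * LL / sc
                row += len(s)
            return J

        J = jac(theta)
        for j in range(pmap.n_params):
            h = 1e-6 * max(1.0, abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            fd = (resid(tp) - resid(tm)) / (2 * h)
            np.testing.assert_allclose(J[:, j], fd, rtol=2e-5, atol=1e-8)

    def test_scale_options(self, noisy_series):
        for scale in ("mean", "max", "A"):
            res = fit(noisy_series, mode="III", scale=scale)
            assert res.converged
        with pytest.raises(ValueError, match="scale"):
            fit(noisy_series, mode="III", scale="median")

    def test_summary_mentions_key_facts(self, noisy_series):
        res = fit(noisy_series, mode="II")
        text = res.summary()
        assert "Mode: II" in text
        assert "delta_b" in text
        assert "normalized residual SS" in text


class TestSingleSeriesFit:
    def test_matches_grid_search_oracle(self, dothan):
        """The single-curve fit lands on the same minimum as an exhaustive
        coarse-to-fine grid search over (A, b, c)."""
        rng = np.random.default_rng(5)
        y_true = logistic_response(N5, dothan.logistic("grain", "n_uptake"))
        y = y_true * (1 + rng.normal(0, 0.01, size=5))
        res = fit_logistic_series(N5, y)
        sc = np.mean(y)

        def objective(A, b, c):
            return float(np.sum(((y - A * expit(c * N5 - b)) / sc) ** 2))

        A_rng = (np.max(y), 1.6 * np.max(y))
        b_rng = (-1.0, 2.5)
        c_rng = (0.004, 0.05)
        best = (0.0, 0.0, 0.0, np.inf)
        for _ in range(6):
            As = np.linspace(*A_rng, 13)
            bs = np.linspace(*b_rng, 13)
            cs = np.linspace(*c_rng, 13)
            for A in As:
                for b in bs:
                    for c in cs:
                        f = objective(A, b, c)
                        if f < best[3]:
                            best = (A, b, c, f)

            def shrink(rng_, v):
                w = (rng_[1] - rng_[0]) / 4
                return (v - w, v + w)

            spacing = tuple((hi - lo) / 12 for lo, hi in (A_rng, b_rng, c_rng))
            A_rng, b_rng, c_rng = shrink(A_rng, best[0]), shrink(b_rng, best[1]), shrink(c_rng, best[2])
        # the descent minimum is at least as good as the exhaustive search,
        # and the two minimizers agree to the final grid resolution
        assert res.nrss <= best[3] + 1e-12
        assert abs(res.params.A - best[0]) <= spacing[0]
        assert abs(res.params.b - best[1]) <= spacing[1]
        assert abs(res.params.c - best[2]) <= spacing[2]

    def test_noiseless_exact(self, dothan):
        y = logistic_response(N5, dothan.logistic("total", "biomass"))
        res = fit_logistic_series(N5, y)
        assert res.converged
        assert res.params.A == pytest.approx(dothan.A_t, rel=1e-6)
        assert res.params.b == pytest.approx(dothan.b, abs=1e-6)
        assert res.params.c == pytest.approx(dothan.c, rel=1e-6)
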