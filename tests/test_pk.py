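"""Unit and property tests of the tracer pharmacokinetics module."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

from csfclear import pk


def param_strategy():
    logu = lambda lo, hi: st.floats(math.log(lo), math.log(hi)).map(math.exp)
    return st.builds(
        pk.PKParameters,
        ka=logu(0.02, 2.0), tlag=st.floats(0.0, 3.0), cl=logu(0.2, 20.0),
        vc=logu(2.0, 50.0), q=logu(0.05, 10.0), vp=logu(2.0, 80.0),
        dose=st.floats(0.1, 2.0),
    )


class TestConcAt:
    def test_zero_before_lag(self, example_params):
        assert pk.conc_at(example_params, example_params.tlag / 2) == 0.0
        assert pk.conc_at(example_params, 0.0) == 0.0

    def test_zero_dose_gives_zero(self, example_params):
        p = replace(example_params, dose=0.0)
        assert pk.conc_at(p, 6.0) == 0.0

    def test_matches_ode_oracle_at_example(self, example_params, ode_oracle):
        t = np.array([6.0])
        expected = ode_oracle(example_params, t)[0]
        assert pk.conc_at(example_params, 6.0) == pytest.approx(expected,
                                                                abs=1e-9)

    def test_negative_time_rejected(self, example_params):
        with pytest.raises(ValueError):
            pk.conc_at(example_params, -1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(pk.ParameterDomainError):
            pk.PKParameters(ka=-0.1, tlag=0.0, cl=1.0, vc=1.0, q=0.0, vp=1.0,
                            dose=0.5)

    @given(params=param_strategy())
    def test_dose_linearity(self, params):
        t = np.linspace(0.0, 72.0, 40)
        single = pk.conc_at(params, t)
        double = pk.conc_at(replace(params, dose=2 * params.dose), t)
        np.testing.assert_allclose(double, 2 * single, rtol=1e-12)

    @given(params=param_strategy())
    def test_nonnegative_and_vanishing(self, params):
        t = np.linspace(0.0, 200.0, 300)
        c = pk.conc_at(params, t)
        assert np.all(c >= 0.0)
        assert pk.conc_at(params, 1e5) < 1e-10

    def test_continuity_at_lag(self, example_params):
        eps = 1e-9
        after = pk.conc_at(example_params, example_params.tlag + eps)
        assert after < 1e-6  # continuous: starts from zero right after lag

    def test_eigenvalue_coincidence_is_finite(self, ode_oracle):
        # choose disposition constants, then set ka exactly on an eigenvalue
        cl, vc, q, vp = 4.0, 10.0, 2.0, 15.0
        k10, k12, k21 = cl / vc, q / vc, q / vp
        s, prod = k10 + k12 + k21, k10 * k21
        alpha = 0.5 * (s + math.sqrt(s * s - 4 * prod))
        p = pk.PKParameters(ka=alpha, tlag=0.5, cl=cl, vc=vc, q=q, vp=vp,
                            dose=0.5)
        t = np.linspace(0.5, 48.0, 50)
        c = pk.conc_at(p, t)
        assert np.all(np.isfinite(c))
        np.testing.assert_allclose(c, ode_oracle(p, t), atol=1e-7)


class TestDeriveMetrics:
    def test_absorption_half_life_inversion(self):
        # a 3.5 h absorption half-life corresponds to ka = ln2/3.5
        p = pk.PKParameters(ka=math.log(2) / 3.5, tlag=0.8, cl=4.0, vc=10.0,
                            q=2.0, vp=15.0, dose=0.5)
        assert pk.derive_metrics(p).t_half_abs == pytest.approx(3.5)

    def test_auc_is_dose_over_clearance(self):
        p = pk.PKParameters(ka=0.3, tlag=0.0, cl=1.0, vc=5.0, q=1.0, vp=10.0,
                            dose=1.0)
        assert pk.derive_metrics(p).auc == pytest.approx(1.0)

    def test_peak_matches_dense_grid_argmax(self, example_params):
        m = pk.derive_metrics(example_params)
        grid = np.arange(0.001, 96.0, 0.001)
        conc = pk.conc_at(example_params, grid)
        i = int(np.argmax(conc))
        assert m.tmax == pytest.approx(grid[i], abs=0.002)
        assert m.cmax == pytest.approx(conc[i], rel=1e-6)
        assert m.tmax > example_params.tlag

    @given(params=param_strategy())
    def test_tmax_always_after_lag(self, params):
        m = pk.derive_metrics(params)
        assert m.tmax > params.tlag
        assert m.cmax > 0


class TestAucTrapezoid:
    def test_agrees_with_analytic_auc(self, example_params):
        t = np.arange(0.0, 500.0, 0.01)
        curve = np.column_stack([t, pk.conc_at(example_params, t)])
        analytic = pk.derive_metrics(example_params).auc
        assert pk.auc_trapezoid(curve) == pytest.approx(analytic, rel=5e-3)

    def test_zero_curve(self):
        assert pk.auc_trapezoid([(0.0, 0.0), (1.0, 0.0)]) == 0.0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            pk.auc_trapezoid([(0.0, 1.0)])

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            pk.auc_trapezoid([(0.0, 0.0), (2.0, 1.0), (1.0, 0.5)])


class TestFitIndividual:
    def test_noise_free_round_trip(self, example_params):
        t = np.array([1, 2, 4, 6, 8, 12, 24, 36, 48, 72], float)
        y = pk.conc_at(example_params, t)
        fit = pk.fit_individual(list(zip(t, y)), dose=example_params.dose)
        assert fit.converged
        for name in ("ka", "tlag", "cl", "vc", "q", "vp"):
            est = getattr(fit.params, name)
            truth = getattr(example_params, name)
            assert est == pytest.approx(truth, rel=1e-4, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(pk.InsufficientDataError):
            pk.fit_individual([(1.0, 0.1), (2.0, 0.2), (3.0, 0.1)], dose=0.5)

    def test_all_zero_concentrations_rejected(self):
        obs = [(float(t), 0.0) for t in range(1, 8)]
        with pytest.raises(pk.DegenerateDataError):
            pk.fit_individual(obs, dose=0.5)


class TestFitPopulation:
    def test_two_subjects_rejected(self, example_params):
        t = np.array([1, 2, 4, 8, 24], float)
        obs = []
        for sid in ("A", "B"):
            for ti, ci in zip(t, pk.conc_at(example_params, t)):
                obs.append(pk.PKObservation(sid, float(ti), float(ci)))
        with pytest.raises(pk.InsufficientDataError, match="fit_individual"):
            pk.fit_population(obs, 0.5)

    def test_small_cohort_smoke(self, example_params):
        rng = np.random.default_rng(42)
        t = np.array([1, 2, 4, 6, 8, 24, 32, 48], float)
        obs = []
        for i in range(8):
            p = replace(example_params,
                        ka=example_params.ka * math.exp(rng.normal(0, 0.2)),
                        cl=example_params.cl * math.exp(rng.normal(0, 0.2)),
                        vc=example_params.vc * math.exp(rng.normal(0, 0.2)))
            y = np.maximum(pk.conc_at(p, t)
                           * (1 + 0.1 * rng.normal(size=len(t))), 0.0)
            obs += [pk.PKObservation(f"S{i}", float(a), float(b))
                    for a, b in zip(t, y)]
        model = pk.fit_population(obs, 0.5, seed=0)
        assert model.converged
        assert len(model.individual_estimates) == 8
        assert model.typical.ka > 0 and model.sigma_prop > 0
        # empirical-Bayes estimates track the population typical values
        kas = [q.ka for q in model.individual_estimates.values()]
        assert np.ptp(kas) > 0  # random effects actually differ

    def test_typical_value_standard_errors_cover_truth(self, example_params):
        rng = np.random.default_rng(9)
        t = np.array([1, 2, 4, 6, 8, 24, 32, 48], float)
        obs = []
        for i in range(60):
            p = replace(example_params,
                        ka=example_params.ka * math.exp(rng.normal(0, 0.2)),
                        cl=example_params.cl * math.exp(rng.normal(0, 0.2)),
                        vc=example_params.vc * math.exp(rng.normal(0, 0.2)))
            y = np.maximum(pk.conc_at(p, t)
                           * (1 + 0.1 * rng.normal(size=len(t))), 0.0)
            obs += [pk.PKObservation(f"S{i:02d}", float(a), float(b))
                    for a, b in zip(t, y)]
        model = pk.fit_population(obs, 0.5, seed=0, compute_se=True)
        assert model.se is not None
        for name in ("ka", "cl"):
            se = model.se[name]
            est = getattr(model.typical, name)
            truth = getattr(example_params, name)
            assert 0 < se < est  # finite, positive, informative
            assert abs(est - truth) < 3.5 * se

    def test_zero_iiv_recovered_at_boundary(self, example_params):
        rng = np.random.default_rng(3)
        t = np.array([1, 2, 4, 6, 8, 24, 32, 48], float)
        obs = []
        for i in range(30):
            y = np.maximum(pk.conc_at(example_params, t)
                           * (1 + 0.05 * rng.normal(size=len(t))), 0.0)
            obs += [pk.PKObservation(f"S{i:02d}", float(a), float(b))
                    for a, b in zip(t, y)]
        model = pk.fit_population(obs, 0.5, seed=0)
        for name in ("ka", "cl", "vc"):
            assert model.iiv_sd[name] <= 0.02
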