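"""Ensemble Kalman filter: moments, gain, analysis update, augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abmassim.box import BoxParams, mean_solution
from abmassim.enkf import (
    BoxAugmentedModel,
    BoxEvolutionModel,
    Ensemble,
    FunctionModel,
    ObservationModel,
    StatePacking,
    StateVector,
    assimilate,
    ensemble_moments,
    forecast_ensemble,
    inverse_log_transform,
    kalman_gain,
    log_transform,
    run_filter,
)


def identity_model():
    return FunctionModel(lambda v, t0, t1, rng: v)


class TestMoments:
    def test_identical_members_have_zero_covariance(self):
        ens = Ensemble(names=("a", "b"), values=np.tile([1.0, 2.0], (5, 1)))
        mean, cov = ensemble_moments(ens)
        np.testing.assert_allclose(mean, [1.0, 2.0])
        np.testing.assert_allclose(cov, 0.0)

    def test_two_member_scalar_variance_uses_n_minus_one(self):
        mean, cov = ensemble_moments(np.array([[0.0], [2.0]]))
        assert mean[0] == pytest.approx(1.0)
        assert cov[0, 0] == pytest.approx(2.0)

    def test_matches_two_pass_summation(self, rng):
        values = rng.normal(size=(50, 4))
        mean, cov = ensemble_moments(values)
        ref_mean = values.sum(axis=0) / 50
        dev = values - ref_mean
        ref_cov = sum(np.outer(d, d) for d in dev) / 49
        np.testing.assert_allclose(mean, ref_mean, atol=1e-12)
        np.testing.assert_allclose(cov, ref_cov, atol=1e-12)

    def test_single_member_rejected(self):
        with pytest.raises(ValueError):
            ensemble_moments(np.array([[1.0, 2.0]]))


class TestKalmanGain:
    def test_scalar_half(self):
        obs = ObservationModel(H=[[1.0]], R=[[1.0]])
        assert kalman_gain([[1.0]], obs)[0, 0] == pytest.approx(0.5)

    def test_infinite_noise_kills_the_gain(self):
        obs = ObservationModel(H=[[1.0]], R=[[1e12]])
        assert abs(kalman_gain([[1.0]], obs)[0, 0]) < 1e-10

    def test_defining_equation_residual(self, rng):
        A = rng.normal(size=(4, 4))
        P = A @ A.T
        H = rng.normal(size=(2, 4))
        R = np.diag(rng.uniform(0.5, 2.0, size=2))
        K = kalman_gain(P, ObservationModel(H=H, R=R))
        residual = K @ (H @ P @ H.T + R) - P @ H.T
        assert np.linalg.norm(residual) < 1e-10


class TestForecast:
    def test_identity_model_preserves_members(self, rng):
        ens = Ensemble(names=("a",), values=rng.normal(size=(10, 1)))
        out = forecast_ensemble(ens, identity_model(), 1.0, rng)
        np.testing.assert_allclose(out.values, ens.values)
        assert out.time == 1.0

    def test_member_permutation_commutes(self):
        # members evolve independently: permuting inputs permutes outputs
        model = FunctionModel(lambda v, t0, t1, rng: v + rng.normal(size=v.shape))
        values = np.arange(8.0).reshape(4, 2)
        perm = np.array([2, 0, 3, 1])
        a = model.evolve_batch(values, 0.0, 1.0, np.random.default_rng(3))
        b = model.evolve_batch(values[perm], 0.0, 1.0, np.random.default_rng(3))
        # same spawned streams in order; outputs differ by inputs only
        np.testing.assert_allclose(b - values[perm], a - values)

    def test_box_forecast_mean_follows_transient(self, rng):
        p = BoxParams(52.52, 0.2580)
        ens = Ensemble(names=("x",), values=np.full((1000, 1), 200.0))
        out = forecast_ensemble(ens, BoxEvolutionModel(p), 1.0, rng)
        expected = mean_solution(p, 200.0, 1.0)
        assert expected == pytest.approx(200.81, abs=0.005)
        se = out.values.std(ddof=1) / np.sqrt(1000)
        assert abs(out.values.mean() - expected) < 3 * se

    def test_nonfinite_model_output_names_member(self, rng):
        def bad(v, t0, t1, r):
            return v * np.nan

        ens = Ensemble(names=("a",), values=np.ones((3, 1)))
        with pytest.raises(FloatingPointError, match="member"):
            forecast_ensemble(ens, FunctionModel(bad), 1.0, rng)


class TestAssimilate:
    def test_zero_noise_identity_obs_pins_members_to_observation(self, rng):
        ens = Ensemble(names=("a",), values=rng.normal(10.0, 2.0, (50, 1)), time=1.0)
        obs = ObservationModel(H=[[1.0]], R=[[1e-12]])
        step = assimilate(ens, [7.0], obs, rng, virtual_noise=False)
        np.testing.assert_allclose(step.analysis_members, 7.0, atol=1e-4)

    def test_huge_noise_leaves_forecast_untouched(self, rng):
        ens = Ensemble(names=("a",), values=rng.normal(10.0, 2.0, (50, 1)), time=1.0)
        obs = ObservationModel(H=[[1.0]], R=[[1e16]])
        step = assimilate(ens, [7.0], obs, rng)
        np.testing.assert_allclose(
            step.analysis_members, step.forecast_members, atol=1e-6
        )

    def test_scalar_analysis_variance_contracts_by_one_minus_gain(self, rng):
        P, R = 4.0, 16.0
        ens = Ensemble(names=("a",), values=rng.normal(0.0, np.sqrt(P), (2000, 1)),
                       time=1.0)
        obs = ObservationModel(H=[[1.0]], R=[[R]])
        step = assimilate(ens, [1.0], obs, rng)
        K = step.gain[0, 0]
        expected = (1.0 - K) * step.forecast_cov[0, 0]
        assert step.analysis_cov[0, 0] == pytest.approx(expected, rel=0.05)

    def test_analysis_variance_below_forecast_variance_on_average(self, rng):
        obs = ObservationModel(H=[[1.0]], R=[[1.0]])
        f_vars, a_vars = [], []
        for _ in range(100):
            ens = Ensemble(names=("a",), values=rng.normal(0.0, 1.0, (40, 1)),
                           time=1.0)
            step = assimilate(ens, [0.3], obs, rng)
            f_vars.append(step.forecast_cov[0, 0])
            a_vars.append(step.analysis_cov[0, 0])
        assert np.mean(a_vars) < np.mean(f_vars)

    def test_virtual_noise_moments_approach_r(self, rng):
        R = np.array([[4.0, 1.0], [1.0, 2.0]])
        ens = Ensemble(names=("a", "b"), values=rng.normal(size=(10_000, 2)),
                       time=1.0)
        obs = ObservationModel(H=np.eye(2), R=R)
        step = assimilate(ens, [0.0, 0.0], obs, rng)
        noise = step.virtual_obs
        assert np.all(np.abs(noise.mean(axis=0)) < 0.05 * np.sqrt(np.diag(R)) + 0.02)
        np.testing.assert_allclose(np.cov(noise, rowvar=False), R, rtol=0.05)

    def test_dimension_mismatch_rejected(self, rng):
        ens = Ensemble(names=("a",), values=np.ones((5, 1)), time=1.0)
        obs = ObservationModel(H=[[1.0]], R=[[1.0]])
        with pytest.raises(ValueError):
            assimilate(ens, [1.0, 2.0], obs, rng)


class TestKalmanEquivalence:
    def test_enkf_matches_exact_filter_on_linear_gaussian_system(self):
        """Analysis mean/variance track the exact Kalman filter at N=1e4."""
        a, b, Q, R = 0.9, 2.0, 1.0, 1.0
        m0, P0 = 10.0, 2.0
        n_steps, N, n_rep = 10, 10_000, 6

        rng = np.random.default_rng(7)
        truth = [m0 + rng.normal() * np.sqrt(P0)]
        for _ in range(n_steps):
            truth.append(a * truth[-1] + b + rng.normal() * np.sqrt(Q))
        zs = np.array(truth[1:]) + rng.normal(size=n_steps) * np.sqrt(R)

        # independent oracle: the exact Kalman recursion
        kf_means, kf_vars = [], []
        m, P = m0, P0
        for z in zs:
            m, P = a * m + b, a * a * P + Q
            K = P / (P + R)
            m, P = m + K * (z - m), (1.0 - K) * P
            kf_means.append(m)
            kf_vars.append(P)

        model = FunctionModel(
            lambda v, t0, t1, r: a * v + b + r.normal(size=v.shape) * np.sqrt(Q),
            batch_fn=lambda v, t0, t1, r: a * v + b
            + r.normal(size=v.shape) * np.sqrt(Q),
        )
        obs = ObservationModel(H=[[1.0]], R=[[R]])
        means = np.zeros((n_rep, n_steps))
        variances = np.zeros((n_rep, n_steps))
        for rep in range(n_rep):
            rep_rng = np.random.default_rng([rep, 77])
            init = Ensemble(
                names=("x",),
                values=(m0 + rep_rng.normal(size=(N, 1)) * np.sqrt(P0)),
            )
            run = run_filter(model, np.arange(1.0, n_steps + 1), zs, obs,
                             init, rep_rng)
            means[rep] = run.analysis_means()[:, 0]
            variances[rep] = run.analysis_variances()[:, 0]
        np.testing.assert_allclose(means.mean(axis=0), kf_means, rtol=0.02)
        np.testing.assert_allclose(variances.mean(axis=0), kf_vars, rtol=0.02)


class TestLogTransform:
    def test_round_trip_above_floor(self, rng):
        x = rng.uniform(2.0, 50.0, size=12)
        logged, clamped = log_transform(x)
        assert clamped == 0
        np.testing.assert_allclose(inverse_log_transform(logged), x, rtol=1e-12)

    def test_floor_clamps_and_counts(self):
        logged, clamped = log_transform(np.array([0.0, 0.5, 3.0]))
        assert clamped == 2
        np.testing.assert_allclose(logged, [0.0, 0.0, np.log(3.0)])

    def test_unmasked_component_passes_through_state(self):
        from abmassim.enkf import transform_state, untransform_state

        sv = StateVector(
            names=("c", "mu"), values=np.array([10.0, -0.7]),
            log_mask=np.array([True, False]),
        )
        logged, _ = transform_state(sv)
        assert logged["mu"] == pytest.approx(-0.7)
        back = untransform_state(logged)
        np.testing.assert_allclose(back.values, sv.values, rtol=1e-12)


class TestPacking:
    packing = StatePacking(model_names=("x",), param_names=("alpha", "beta"))

    def test_round_trip(self):
        v = self.packing.augment([3.0], [50.0, 0.25])
        model, params = self.packing.project_back(v)
        np.testing.assert_allclose(model, [3.0])
        np.testing.assert_allclose(params, [50.0, 0.25])

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            self.packing.index("nope")

    def test_whirs_packing_matches_documented_layout(self):
        from abmassim.whirs import whirs_packing_names

        assert whirs_packing_names(tie_gamma=True) == (
            "S", "I", "H", "C", "N", "Nw", "alpha", "beta", "epsilon",
            "gamma", "delta_plus", "delta_minus", "sigma", "mu",
        )
        # the split-gamma layout keeps both worker base rates
        names = whirs_packing_names(tie_gamma=False)
        assert "gamma_minus" in names and "gamma_plus" in names
        assert names[-1] == "mu"


class TestRunFilter:
    def test_empty_observations_is_pure_forecast(self, rng):
        ens = Ensemble(names=("a",), values=rng.normal(size=(10, 1)))
        obs = ObservationModel(H=[[1.0]], R=[[1.0]])
        run = run_filter(identity_model(), [], [], obs, ens, rng, horizon=5.0)
        assert len(run.steps) == 1
        np.testing.assert_allclose(
            run.steps[0].analysis_members, run.steps[0].forecast_members
        )

    def test_full_run_is_deterministic_given_seed(self):
        p = BoxParams(52.52, 0.2580)
        obs = ObservationModel(H=[[1.0]], R=[[16.0]])
        times = np.arange(1.0, 11.0)
        zs = 200.0 + np.sin(times)

        def go():
            rng = np.random.default_rng(5)
            init = Ensemble(names=("x",),
                            values=np.random.default_rng(1).normal(200, 14, (30, 1)))
            return run_filter(BoxEvolutionModel(p), times, zs, obs, init, rng)

        r1, r2 = go(), go()
        for s1, s2 in zip(r1.steps, r2.steps):
            np.testing.assert_array_equal(s1.analysis_members, s2.analysis_members)
            np.testing.assert_array_equal(s1.gain, s2.gain)

    def test_augmented_rates_stay_floored(self, rng):
        model = BoxAugmentedModel(rate_floor=1e-6)
        obs = ObservationModel(H=[[1.0, 0.0, 0.0]], R=[[16.0]])
        init = Ensemble(
            names=model.names,
            values=np.column_stack([
                rng.normal(200, 14, 40),
                rng.normal(50, 5, 40),
                rng.normal(0.25, 0.01, 40),
            ]),
        )
        zs = rng.normal(200, 4, size=20)
        run = run_filter(model, np.arange(1.0, 21.0), zs, obs, init, rng,
                         integer_names=("x",),
                         floors={"alpha": 1e-6, "beta": 1e-6})
        assert len(run.steps) == 20


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=40))
def test_log_round_trip_property(values):
    x = np.abs(np.asarray(values)) + 1.5
    logged, clamped = log_transform(x)
    assert clamped == 0
    np.testing.assert_allclose(inverse_log_transform(logged), x, rtol=1e-10)
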