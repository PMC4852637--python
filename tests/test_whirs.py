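"""WHIRS shopper/worker model: rates, batches, event loop, adapter."""

import numpy as np
import pytest
from scipy.stats import lognorm

import abmassim.whirs as wh


@pytest.fixture(scope="module")
def params():
    return wh.WhirsParams()


def small_params(**overrides):
    base = dict(
        n_total=500, n_workers=100, epsilon=5.0, alpha=0.3, beta=0.3,
        gamma_minus=5.0, delta_minus=0.2, gamma_plus=5.0, delta_plus=0.1,
        mu=0.5, sigma=0.4,
    )
    base.update(overrides)
    return wh.WhirsParams(**base)


class TestRates:
    def test_shopper_rate_outside_window_is_zero(self, params):
        s = wh.WhirsState(S=100, I=5, R=0, H=900, W=100, t=3.0)
        s = wh.WhirsState(S=params.n_total - params.n_workers - 5, I=5, R=0,
                          H=params.n_workers, W=0, t=3.0)
        assert wh.shopper_arrival_rate(s, params) == 0.0

    def test_shopper_rate_zero_when_no_susceptibles(self, params):
        n_s = params.n_total - params.n_workers
        s = wh.WhirsState(S=0, I=n_s, R=0, H=params.n_workers, W=0, t=12.0)
        assert wh.shopper_arrival_rate(s, params) == 0.0

    def test_shopper_rate_is_epsilon_with_empty_town(self, params):
        n_s = params.n_total - params.n_workers
        s = wh.WhirsState(S=n_s, I=0, R=0, H=params.n_workers, W=0, t=12.0)
        assert wh.shopper_arrival_rate(s, params) == pytest.approx(params.epsilon)

    def test_shopper_rate_amplified_by_town_occupancy(self, params):
        n_s = params.n_total - params.n_workers
        s = wh.WhirsState(S=n_s - 50, I=40, R=10, H=params.n_workers - 10, W=10,
                          t=12.0)
        expected = params.epsilon + params.alpha * (n_s - 50) * 50 / params.n_total
        assert wh.shopper_arrival_rate(s, params) == pytest.approx(expected)

    def test_worker_rates_gated_by_windows(self):
        p = small_params(gamma_minus=2.0, delta_minus=0.1)
        s = wh.WhirsState(S=400, I=0, R=0, H=90, W=10, t=12.0)
        assert wh.worker_rates(s, p) == (0.0, 0.0)
        s.t = 7.0
        to_work, _ = wh.worker_rates(s, p)
        assert to_work == pytest.approx(2.0 + 0.1 * 10)
        s = wh.WhirsState(S=400, I=0, R=0, H=100, W=0, t=15.0)
        assert wh.worker_rates(s, p)[1] == 0.0


class TestBatchSize:
    def test_degenerate_sigma_gives_rounded_exponential(self, rng):
        for _ in range(20):
            assert wh.draw_batch_size(np.log(3.0), 0.0, 10, rng) == 3

    def test_draws_respect_cap_and_floor(self, rng):
        draws = [wh.draw_batch_size(2.0, 1.0, 7, rng) for _ in range(300)]
        assert min(draws) >= 1 and max(draws) <= 7

    def test_monte_carlo_mean_matches_mass_summation(self, rng):
        mu, sigma = 1.0, 0.5
        draws = [wh.draw_batch_size(mu, sigma, 10**9, rng) for _ in range(100_000)]
        oracle = wh.rounded_lognormal_mean(mu, sigma)
        # cross-check the oracle itself by direct summation here
        k = np.arange(1, 2000)
        pmf = lognorm.cdf(k + 0.5, s=sigma, scale=np.e) - lognorm.cdf(
            k - 0.5, s=sigma, scale=np.e
        )
        pmf[0] = lognorm.cdf(1.5, s=sigma, scale=np.e)
        assert oracle == pytest.approx((k * pmf).sum() / pmf.sum(), rel=1e-4)
        assert np.mean(draws) == pytest.approx(oracle, rel=0.01)

    def test_empty_cap_rejected(self, rng):
        with pytest.raises(ValueError):
            wh.draw_batch_size(1.0, 0.5, 0, rng)


class TestSimulation:
    def test_no_rates_no_events(self, rng):
        p = small_params(epsilon=0.0, alpha=0.0, n_workers=0,
                         gamma_minus=0.0, gamma_plus=0.0)
        res = wh.simulate_whirs(p, wh.initial_state(p), 48.0, rng)
        assert res.n_events == 0
        assert np.all(res.hourly.counts == 0)

    def test_conservation_and_audit_hold_throughout(self, rng):
        p = small_params()
        res = wh.simulate_whirs(p, wh.initial_state(p), 72.0, rng,
                                audit=True, check_invariants=True,
                                record_states=True)
        assert res.n_events > 0
        np.testing.assert_array_equal(res.hourly.counts, res.audit)
        for s in res.states:
            s.validate(p)

    def test_midnight_returns_everyone_to_susceptible(self, rng):
        p = small_params()
        res = wh.simulate_whirs(p, wh.initial_state(p), 48.0, rng,
                                record_states=True)
        # states recorded at integer hours; index 23 is the state at 24:00
        midnight = res.states[23]
        assert midnight.R == 0
        post_day_two = res.states[47]
        assert post_day_two.R == 0

    def test_max_events_stops_early(self, rng):
        p = small_params()
        res = wh.simulate_whirs(p, wh.initial_state(p), 72.0, rng, max_events=50)
        assert res.n_events == 50
        assert res.final_state.t < 72.0

    def test_all_day_window_arrivals_are_poisson(self):
        """With the social term off and unit batches, arrivals are Poisson."""
        eps = 6.0
        p = small_params(
            epsilon=eps, alpha=0.0, beta=0.0, n_total=2000, n_workers=0,
            gamma_minus=0.0, gamma_plus=0.0, mu=0.0, sigma=0.0,
            shopper_window=(0.0, 24.0),
        )
        totals = []
        rng = np.random.default_rng(99)
        for _ in range(500):
            res = wh.simulate_whirs(p, wh.initial_state(p), 24.0, rng)
            totals.append(res.hourly.counts.sum())
        totals = np.asarray(totals, dtype=float)
        expected = 24.0 * eps
        se = totals.std(ddof=1) / np.sqrt(totals.size)
        assert abs(totals.mean() - expected) < 2 * se
        assert 0.9 < totals.var(ddof=1) / totals.mean() < 1.1

    def test_batch_volatility_exceeds_unit_batch_baseline(self):
        """Lognormal batches inflate day-to-day spread beyond Poisson."""
        rng = np.random.default_rng(4)
        batched = small_params(alpha=0.0, beta=0.0, n_workers=0,
                               gamma_minus=0.0, gamma_plus=0.0,
                               epsilon=5.0, mu=1.0, sigma=0.8)
        b_mean = wh.rounded_lognormal_mean(1.0, 0.8)
        unit = small_params(alpha=0.0, beta=0.0, n_workers=0,
                            gamma_minus=0.0, gamma_plus=0.0,
                            epsilon=5.0 * b_mean, mu=0.0, sigma=0.0)
        day = lambda p: wh.simulate_whirs(  # noqa: E731
            p, wh.initial_state(p), 24.0, rng
        ).hourly.counts.sum()
        a = np.array([day(batched) for _ in range(200)], dtype=float)
        b = np.array([day(unit) for _ in range(200)], dtype=float)
        assert abs(a.mean() - b.mean()) / b.mean() < 0.15  # matched means
        # one-sided variance-ratio test at the 5% level
        from scipy.stats import f as f_dist

        ratio = a.var(ddof=1) / b.var(ddof=1)
        assert ratio > f_dist.ppf(0.95, 199, 199)


class TestAdapter:
    def test_pack_unpack_round_trip(self, params):
        state = wh.WhirsState(S=18000, I=500, R=500, H=800, W=200, C=42, t=0.0)
        v = wh.pack_whirs(state, params)
        s2, p2, clamps = wh.unpack_whirs(v, params)
        assert clamps == 0
        assert (s2.S, s2.I, s2.R, s2.H, s2.W, s2.C) == (
            state.S, state.I, state.R, state.H, state.W, state.C
        )
        assert p2 == params

    def test_conservation_reconstruction_clamps_overflow(self, params):
        state = wh.WhirsState(S=18000, I=500, R=500, H=800, W=200, C=0, t=0.0)
        v = wh.pack_whirs(state, params)
        v[0] = 19500.0  # S + I would exceed the shopper pool
        s2, _, clamps = wh.unpack_whirs(v, params)
        assert clamps == 1
        assert s2.S + s2.I + s2.R == params.n_total - params.n_workers
        assert s2.R >= 0

    def test_zero_rate_parameters_freeze_the_state(self, params):
        model = wh.WhirsEvolutionModel(params)
        state = wh.WhirsState(S=18000, I=500, R=500, H=800, W=200, C=9, t=0.0)
        v = wh.pack_whirs(state, params)
        for name, idx in ((n, model.names.index(n)) for n in
                          ("alpha", "beta", "epsilon", "gamma_minus",
                           "gamma_plus", "delta_plus", "delta_minus")):
            v[idx] = 0.0
        out = model.evolve(v, 2.0, 3.0, np.random.default_rng(0))
        assert out[model.names.index("C")] == 0.0
        assert out[model.names.index("S")] == 18000.0

    def test_hourly_count_mean_monotone_in_social_rate(self, params):
        """The rich-get-richer term raises late-morning footfall."""
        means = []
        for alpha in (0.0, 0.15, 0.3):
            rng = np.random.default_rng(11)
            model = wh.WhirsEvolutionModel(params)
            state = wh.WhirsState(S=17000, I=1500, R=500, H=500, W=500,
                                  C=0, t=10.0)
            from dataclasses import replace

            p = replace(params, alpha=alpha)
            v = wh.pack_whirs(state, p)
            cs = [
                model.evolve(v, 10.0, 11.0, r)[model.names.index("C")]
                for r in rng.spawn(60)
            ]
            means.append(np.mean(cs))
        assert means[0] < means[1] < means[2]

    def test_mean_field_profile_tracks_stochastic_mean(self, params):
        mf = wh.mean_field_hourly_counts(params, params.alpha, params.beta)[0]
        rng = np.random.default_rng(2)
        sims = []
        for _ in range(30):
            res = wh.simulate_whirs(params, wh.initial_state(params), 24.0, rng)
            c = np.zeros(24)
            c[res.hourly.hour_starts.astype(int)] = res.hourly.counts
            sims.append(c)
        sim_mean = np.mean(sims, axis=0)
        busy = mf > 100
        np.testing.assert_allclose(mf[busy], sim_mean[busy], rtol=0.15)
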