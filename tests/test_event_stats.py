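import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from qeirq.model_core import ModelParameters, build_geometry
from qeirq import event_stats
from qeirq.event_stats import (
    EventCensus,
    RateModel,
    census,
    estimate_propensities,
    expected_fronts_before_spawn,
    fit_rate_models,
    optimal_width,
    transit_statistics,
)

PRINTED = RateModel(a_fail=-1.82, w_fail=-0.19, a_spawn=1.85e-5, w_spawn=0.53)


class TestCensus:
    def test_counts_and_mean_position(self):
        runs = [None] * 8 + [("fail", 40.0, 100.0), ("spawn", 60.0, 200.0)]
        c = census(runs, width=6, length=300)
        assert (c.n_event, c.n_fail, c.n_spawn) == (2, 1, 1)
        assert c.x_event == pytest.approx(50.0)

    def test_no_events(self):
        c = census([None] * 10, width=6, length=300)
        assert c.n_event == 0
        assert estimate_propensities(c) == (0.0, 0.0, 0.0)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            census([], width=6, length=300)

    def test_propensity_formulas(self):
        c = EventCensus(n_sims=10, n_event=2, n_fail=1, n_spawn=1,
                        x_event=50.0, width=6, length=300)
        lam_tot, lam_fail, lam_spawn = estimate_propensities(c)
        assert lam_tot == pytest.approx(2 / 2500)
        assert lam_fail == pytest.approx(4e-4)
        assert lam_spawn == pytest.approx(4e-4)

    def test_estimator_recovers_known_hazard(self):
        """The censored-exponential hazard estimator is consistent: synthetic
        first-event positions drawn at a known per-layer rate recover it."""
        rng = np.random.default_rng(0)
        lam_true, length, n = 3e-3, 300.0, 10_000
        x = rng.exponential(1 / lam_true, n)
        hit = x < length
        runs = [("fail", float(v), 0.0) if h else None for v, h in zip(x, hit)]
        c = census(runs, width=4, length=length)
        lam_hat, _, _ = estimate_propensities(c)
        se = lam_true / np.sqrt(hit.sum())
        assert abs(lam_hat - lam_true) < 3 * se


class TestRateModelFit:
    def test_noise_free_recovery_machine_precision(self):
        w = np.arange(2, 11, dtype=float)
        table = pd.DataFrame({
            "W": w,
            "lambda_fail": PRINTED.lambda_fail(w),
            "lambda_spawn": PRINTED.lambda_spawn(w),
        })
        m = fit_rate_models(table)
        assert m.a_fail == pytest.approx(PRINTED.a_fail, rel=1e-12)
        assert m.w_fail == pytest.approx(PRINTED.w_fail, rel=1e-9)
        assert m.a_spawn == pytest.approx(PRINTED.a_spawn, rel=1e-12)
        assert m.w_spawn == pytest.approx(PRINTED.w_spawn, rel=1e-9)

    def test_zero_failure_widths_omitted(self):
        w = np.arange(2, 8, dtype=float)
        lf = PRINTED.lambda_fail(w)
        lf[-1] = 0.0
        table = pd.DataFrame({"W": w, "lambda_fail": lf,
                              "lambda_spawn": PRINTED.lambda_spawn(w)})
        m = fit_rate_models(table)
        assert m.a_fail == pytest.approx(PRINTED.a_fail, rel=1e-9)

    def test_single_width_rejected(self):
        table = pd.DataFrame({"W": [4, 4], "lambda_fail": [1e-3, 1e-3],
                              "lambda_spawn": [1e-5, 1e-5]})
        with pytest.raises(ValueError):
            fit_rate_models(table)


class TestOptimalWidth:
    def test_printed_coefficients_give_six(self):
        w_opt, lam_min, rng = optimal_width(PRINTED, range(2, 13))
        assert w_opt == 6
        assert rng == pytest.approx(8.8e3, rel=0.02)

    def test_spawnless_model_is_monotone(self):
        m = RateModel(a_fail=-1.0, w_fail=0.0, a_spawn=0.0, w_spawn=0.0)
        w_opt, _, _ = optimal_width(m, range(2, 13))
        assert w_opt == 12

    @given(
        a_fail=st.floats(-3.0, -0.2),
        w_fail=st.floats(-2.0, 2.0),
        a_spawn=st.floats(1e-6, 1e-3),
        w_spawn=st.floats(-1.0, 2.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force(self, a_fail, w_fail, a_spawn, w_spawn):
        m = RateModel(a_fail=a_fail, w_fail=w_fail, a_spawn=a_spawn, w_spawn=w_spawn)
        ws = list(range(2, 15))
        w_opt, lam_min, _ = optimal_width(m, ws)
        brute = min(ws, key=lambda w: (m.lambda_tot(w), w))
        assert w_opt == brute
        assert lam_min == pytest.approx(float(m.lambda_tot(brute)))

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            optimal_width(PRINTED, [])


class TestExpectedFronts:
    def test_printed_values(self):
        assert expected_fronts_before_spawn(PRINTED, 6, 300) == pytest.approx(33.4, abs=0.2)
        ratio = expected_fronts_before_spawn(PRINTED, 6, 300) / expected_fronts_before_spawn(
            PRINTED, 60, 300
        )
        assert ratio == pytest.approx(9.4, abs=0.2)

    def test_small_rate_limit(self):
        m = RateModel(a_fail=-1.0, w_fail=0.0, a_spawn=1e-9, w_spawn=0.0)
        n = expected_fronts_before_spawn(m, 5, 10)
        assert n == pytest.approx(1.0 / (5e-9 * 10), rel=1e-4)

    def test_no_spawning_is_infinite(self):
        m = RateModel(a_fail=-1.0, w_fail=0.0, a_spawn=0.0, w_spawn=0.0)
        assert np.isinf(expected_fronts_before_spawn(m, 5, 300))


class TestTransitStatistics:
    def test_synthetic_fit_recovery(self):
        """sigma0^2(W) = a/W + b is recovered from Gaussian transit samples
        generated at known coefficients."""
        rng = np.random.default_rng(1)
        a, b, length, v_inv = 6.8, 0.4, 300, 3.5
        data = {}
        for w in range(3, 13):
            sd = np.sqrt((a / w + b) * length)
            data[w] = rng.normal(v_inv * length, sd, 4000)
        ts = transit_statistics(data, length)
        assert ts.a == pytest.approx(a, abs=3 * ts.a_se + 0.05)
        assert ts.b == pytest.approx(b, abs=3 * ts.b_se + 0.02)
        assert np.allclose(ts.per_width["v_inv"], v_inv, atol=0.05)

    def test_nearly_deterministic_model_has_tiny_variance(self, nominal):
        p = ModelParameters(tau_act=0.05, n_e=200, n_i=100, n_r=200)
        geom = build_geometry(3, 40, "periodic")
        tau = event_stats.collect_transits(p, geom, 30, seed=4)
        assert len(tau) == 30
        sigma0_sq = tau.var(ddof=1) / 40
        assert sigma0_sq < 0.1

    def test_too_few_arrivals_rejected(self):
        with pytest.raises(ValueError):
            transit_statistics({3: np.array([100.0])}, 300)


class TestPairAndIntervalScans:
    def test_invalid_arguments(self, nominal):
        geom = build_geometry(4, 30, "periodic")
        with pytest.raises(ValueError):
            event_stats.pair_event_probabilities(nominal, geom, -5.0, 10, seed=0)
        with pytest.raises(ValueError):
            event_stats.pair_event_probabilities(nominal, geom, 100.0, 0, seed=0)
        with pytest.raises(ValueError):
            event_stats.arrival_interval_curve(nominal, geom, [100.0], 5, 1, seed=0)

    def test_distant_pair_mostly_arrives(self, nominal):
        """At ten refractory times apart, the second front behaves like a
        lone front and nearly always crosses a short channel."""
        geom = build_geometry(6, 30, "periodic")
        df = event_stats.pair_event_probabilities(nominal, geom, 10 * 96.6, 40, seed=21)
        arrived = df.set_index("fate").loc["arrived", "probability"]
        assert arrived > 0.85

    def test_tiny_interval_fails_immediately(self, nominal):
        geom = build_geometry(6, 30, "periodic")
        df = event_stats.pair_event_probabilities(nominal, geom, 1.0, 30, seed=33)
        imm = df.set_index("fate").loc["immediate_failure", "probability"]
        assert imm > 0.95

    def test_sparse_initiation_interval_is_transmitted(self, nominal):
        """Fronts initiated far apart arrive at their initiation interval."""
        geom = build_geometry(6, 40, "periodic")
        df, t_min = event_stats.arrival_interval_curve(
            nominal, geom, [300.0, 400.0], n_fronts=12, n_seeds=3, seed=8
        )
        received = df.set_index("interval")["mean_received_interval"]
        assert received[300.0] == pytest.approx(300.0, abs=15.0)
        assert received[400.0] == pytest.approx(400.0, abs=15.0)
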