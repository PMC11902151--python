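import numpy as np
import pytest

from qeirq.model_core import (
    CellState,
    ModelParameters,
    build_geometry,
    single_pair_activation_probability,
)
from qeirq import engine

from conftest import replay_events


class TestSchedules:
    def test_periodic_times(self):
        s = engine.make_schedule("periodic", interval=150.0, n_fronts=5)
        assert s.times == (0.0, 150.0, 300.0, 450.0, 600.0)

    def test_pair_times(self):
        s = engine.make_schedule("pair", interval=61.5)
        assert s.times == (0.0, 61.5)

    def test_slots_bernoulli_reproducible(self):
        a = engine.make_schedule("slots", interval=90.0, n_slots=400, q=0.5, seed=7)
        b = engine.make_schedule("slots", interval=90.0, n_slots=400, q=0.5, seed=7)
        assert a.symbols == b.symbols
        frac = np.mean(a.symbols)
        assert 0.4 < frac < 0.6
        assert a.times == tuple(90.0 * i for i, s in enumerate(a.symbols) if s)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(kind="slots", interval=90.0, n_slots=10, q=1.5),
            dict(kind="periodic", interval=-5.0, n_fronts=3),
            dict(kind="pair", interval=0.0),
            dict(kind="unknown", interval=1.0),
        ],
    )
    def test_invalid_schedules(self, kwargs):
        with pytest.raises(ValueError):
            engine.make_schedule(**kwargs)


class TestSimulation:
    def test_empty_schedule_stays_quiescent(self, nominal):
        geom = build_geometry(3, 10, "periodic")
        rec = engine.run_simulation(
            nominal, geom, engine.InitiationSchedule("single", ()), seed=1, t_max=500.0
        )
        assert rec.n_events == 0
        assert np.all(rec.final_state == 0)
        assert np.all(rec.kymograph.n_ei == 0)

    def test_determinism(self, nominal, small_record):
        geom = small_record.geometry
        again = engine.run_simulation(
            nominal, geom, small_record.schedule, seed=small_record.seed
        )
        assert np.array_equal(small_record.events, again.events)
        assert np.array_equal(small_record.kymograph.n_ei, again.kymograph.n_ei)

    def test_event_log_legality_and_final_state(self, small_record):
        state = replay_events(small_record)
        assert np.array_equal(state, small_record.final_state)

    def test_seed_type_validated(self, nominal):
        geom = build_geometry(3, 10, "periodic")
        with pytest.raises(TypeError):
            engine.run_simulation(nominal, geom, engine.make_schedule("single"), seed=1.5)

    def test_t_max_before_last_initiation_rejected(self, nominal):
        geom = build_geometry(3, 10, "periodic")
        sched = engine.make_schedule("pair", interval=100.0)
        with pytest.raises(ValueError):
            engine.run_simulation(nominal, geom, sched, seed=1, t_max=50.0)

    def test_two_cell_activation_probability(self, nominal):
        """P(second cell ever activates) on an inert 1x2 line is the
        closed-form race probability 0.75."""
        geom = build_geometry(1, 2, "inert")
        codes = CellState(nominal)
        init = np.zeros(2, np.int16)
        init[0] = codes.first_i
        n = 3000
        hits = 0
        for i in range(n):
            rec = engine.run_simulation(
                nominal, geom, engine.InitiationSchedule("single", ()), seed=i,
                t_max=120.0, initial_state=init,
            )
            hits += int(np.any((rec.events["from_code"] == 0)))
        p_hat = hits / n
        p_true = single_pair_activation_probability(nominal)
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert abs(p_hat - p_true) < 3 * se

    def test_line_lattice_absorption_distribution(self):
        """Number of cells activated on a 1x3 inert line matches the exact
        two-step race absorption probabilities (long refractory time keeps
        the chain from re-exciting)."""
        p = ModelParameters(tau_r=1e5)
        codes = CellState(p)
        geom = build_geometry(1, 3, "inert")
        init = np.zeros(3, np.int16)
        init[0] = codes.first_i
        n = 4000
        counts = np.zeros(3)
        for i in range(n):
            rec = engine.run_simulation(
                p, geom, engine.InitiationSchedule("single", ()), seed=i,
                t_max=200.0, initial_state=init,
            )
            k = len(set(rec.events["cell"][rec.events["from_code"] == 0]))
            counts[k] += 1
        pr = single_pair_activation_probability(p)
        expected = np.array([1 - pr, pr * (1 - pr), pr * pr])
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(counts / n - expected) < 3.5 * se)

    def test_wider_channels_are_faster(self, nominal):
        """Mean inverse speed decreases from narrow to wide channels."""
        v = {}
        for w, seed0 in ((2, 100), (8, 500)):
            geom = build_geometry(w, 60, "periodic")
            transits = []
            for i in range(60):
                rec = engine.run_simulation(
                    nominal, geom, engine.make_schedule("single"), seed=seed0 + i,
                    t_max=700.0,
                )
                arr = engine.arrivals_at_end(rec)
                if len(arr):
                    transits.append(arr[0] / 60.0)
            v[w] = np.mean(transits)
        assert v[2] > v[8]


class TestKymograph:
    def test_full_state_partition_conserved(self, small_record):
        km = engine.activity_series(small_record, 1.0, per_state=True)
        total = sum(km.per_state[k] for k in "QEIR")
        assert np.all(total.sum(axis=0) == small_record.geometry.n_cells)
        assert np.array_equal(km.n_ei, km.per_state["E"] + km.per_state["I"])

    def test_replay_matches_kernel_kymograph(self, small_record):
        km = engine.activity_series(small_record, 1.0)
        stored = small_record.kymograph.n_ei
        assert np.array_equal(km.n_ei, stored[:, : km.n_bins])

    def test_hand_built_log_single_cell(self, nominal):
        geom = build_geometry(2, 3, "inert")
        rec = engine.SimulationRecord(
            params=nominal, geometry=geom,
            schedule=engine.InitiationSchedule("single", ()),
            seed=0, t_max=8.0, t_end=8.0,
            kymograph=engine.Kymograph(np.zeros((3, 8), np.int32)),
            final_state=np.zeros(6, np.int16),
            events=np.array(
                [(0.0, 2, 0, 1), (5.0, 2, 1, 2)],
                dtype=[("time", "f8"), ("cell", "i4"), ("from_code", "i2"), ("to_code", "i2")],
            ),
        )
        km = engine.activity_series(rec, 1.0)
        # cell 2 is (row 0, layer 1); it is excited over [0, 8) minutes
        assert list(km.n_ei[1]) == [1] * 8
        assert km.n_ei[[0, 2]].sum() == 0


class TestArrivals:
    def _bump_kymo(self, times, n_layers=5, width=6, t_max=900):
        n_ei = np.zeros((n_layers, t_max), np.int32)
        t = np.arange(t_max)
        for t0 in times:
            tri = np.clip(10 - np.abs(t - t0), 0, None) * width / 10.0
            n_ei[-1] += tri.astype(np.int32)
        return engine.Kymograph(n_ei, 1.0)

    def test_synthetic_bumps_recovered(self):
        km = self._bump_kymo([100, 400, 700])
        arr = engine.arrivals_at_end(km, min_separation=20.0)
        assert len(arr) == 3
        assert np.allclose(arr, [100.5, 400.5, 700.5], atol=1.0)

    def test_close_peaks_merged(self):
        n_ei = np.zeros((3, 200), np.int32)
        n_ei[-1, 95:100] = 3
        n_ei[-1, 105:112] = 5
        arr = engine.arrivals_at_end(engine.Kymograph(n_ei, 1.0), min_separation=20.0)
        assert len(arr) == 1
        assert 104 < arr[0] < 113

    def test_single_front_single_arrival(self, nominal):
        geom = build_geometry(6, 40, "periodic")
        rec = engine.run_simulation(
            nominal, geom, engine.make_schedule("single"), seed=3, t_max=600.0
        )
        arr = engine.arrivals_at_end(rec)
        assert len(arr) == 1
        # within a bin of the last layer's activity midpoint
        last = rec.kymograph.last_layer()
        active = np.nonzero(last)[0]
        assert active[0] <= arr[0] <= active[-1] + 1
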