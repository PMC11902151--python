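"""Exact stochastic simulation of the QEIRQ lattice.

Wraps the kinetic Monte Carlo kernel with front-initiation schedules,
event-log / kymograph containers and end-of-channel arrival detection.
A front is initiated by switching every currently quiescent cell of the
first layer to the first inducing substate; excited, inducing or refractory
cells are left untouched, so initiations into an unrecovered channel entry
produce partial (often immediately failing) fronts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from . import _kernel
from .model_core import (
    Boundary,
    CellState,
    ChannelGeometry,
    ModelParameters,
    deterministic_inverse_speed,
    neighbors,
)

__all__ = [
    "InitiationSchedule",
    "SimulationRecord",
    "Kymograph",
    "make_schedule",
    "run_simulation",
    "activity_series",
    "arrivals_at_end",
    "neighbor_table",
]


@dataclass(frozen=True)
class InitiationSchedule:
    """Times (min) at which fronts are initiated at the channel entry.

    ``kind`` is one of ``single``, ``pair``, ``periodic`` or ``slots``; for
    the binary slot protocol, ``symbols[i]`` says whether a front is
    initiated at slot time ``i * t_slot``.
    """

    kind: str
    times: tuple[float, ...]
    symbols: tuple[int, ...] | None = None
    t_slot: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("initiation times must be strictly increasing")
        if self.symbols is not None and any(s not in (0, 1) for s in self.symbols):
            raise ValueError("symbols must be binary")

    @property
    def last_time(self) -> float:
        return self.times[-1] if self.times else 0.0


def make_schedule(
    kind: str,
    interval: float | None = None,
    n_fronts: int | None = None,
    n_slots: int | None = None,
    q: float = 0.5,
    seed: int | None = None,
) -> InitiationSchedule:
    """Build an initiation schedule.

    - ``single``: one front at t = 0.
    - ``pair``: fronts at t = 0 and t = ``interval``.
    - ``periodic``: ``n_fronts`` fronts spaced ``interval`` apart.
    - ``slots``: ``n_slots`` slots spaced ``interval`` (= T_slot) apart, each
      independently carrying a front with probability ``q`` (Bernoulli draws
      from ``seed``); slot i initiates at ``i * interval`` iff its symbol is 1.
    """
    if kind == "single":
        return InitiationSchedule("single", (0.0,))
    if interval is None or interval <= 0:
        raise ValueError("a positive interval is required")
    if kind == "pair":
        return InitiationSchedule("pair", (0.0, float(interval)))
    if kind == "periodic":
        if not n_fronts or n_fronts < 1:
            raise ValueError("periodic schedule needs n_fronts >= 1")
        return InitiationSchedule("periodic", tuple(i * float(interval) for i in range(n_fronts)))
    if kind == "slots":
        if not n_slots or n_slots < 1:
            raise ValueError("slot schedule needs n_slots >= 1")
        if not 0.0 <= q <= 1.0:
            raise ValueError("q must be in [0, 1]")
        rng = np.random.default_rng(seed)
        symbols = tuple(int(s) for s in (rng.random(n_slots) < q))
        times = tuple(i * float(interval) for i, s in enumerate(symbols) if s)
        return InitiationSchedule("slots", times, symbols=symbols, t_slot=float(interval))
    raise ValueError(f"unknown schedule kind {kind!r}")


@dataclass
class Kymograph:
    """Space-time activity matrix: cells in any E/I substate per layer and bin.

    ``n_ei[x, b]`` is the count in layer ``x`` at the midpoint of time bin
    ``b`` (piecewise-constant interpolation of the event log).  Optional
    per-state matrices hold the full Q/E/I/R partition for audits.
    """

    n_ei: np.ndarray
    binw: float = 1.0
    per_state: dict[str, np.ndarray] | None = None

    @property
    def n_layers(self) -> int:
        return self.n_ei.shape[0]

    @property
    def n_bins(self) -> int:
        return self.n_ei.shape[1]

    def bin_midpoints(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.binw

    def last_layer(self) -> np.ndarray:
        return self.n_ei[-1]


@dataclass
class SimulationRecord:
    """Output of one stochastic simulation."""

    params: ModelParameters
    geometry: ChannelGeometry
    schedule: InitiationSchedule
    seed: int
    t_max: float
    t_end: float
    kymograph: Kymograph
    final_state: np.ndarray
    events: np.ndarray | None = None  # structured: time, cell, from_code, to_code

    @property
    def n_events(self) -> int:
        return 0 if self.events is None else len(self.events)


_EVENT_DTYPE = np.dtype(
    [("time", "f8"), ("cell", "i4"), ("from_code", "i2"), ("to_code", "i2")]
)


def neighbor_table(geom: ChannelGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Flat neighbor index table (n_cells x 6, -1 padded) and counts."""
    n = geom.n_cells
    nbr = np.full((n, 6), -1, np.int32)
    cnt = np.zeros(n, np.int8)
    for row, layer in geom.cells():
        i = geom.index(row, layer)
        for r, c in sorted(neighbors(geom, (row, layer))):
            nbr[i, cnt[i]] = geom.index(r, c)
            cnt[i] += 1
    return nbr, cnt


def default_t_max(p: ModelParameters, geom: ChannelGeometry, sched: InitiationSchedule) -> float:
    """Generous horizon: last initiation + twice the deterministic transit
    plus several refractory times (lets spawned fronts play out)."""
    return sched.last_time + 2.0 * geom.length * deterministic_inverse_speed(p) + 8.0 * p.tau_r


def run_simulation(
    p: ModelParameters,
    geom: ChannelGeometry,
    sched: InitiationSchedule,
    seed: int,
    t_max: float | None = None,
    binw: float = 1.0,
    record_events: bool = True,
    initial_state: np.ndarray | None = None,
) -> SimulationRecord:
    """Run one exact SSA realization.

    The activation propensity of a quiescent cell is (number of inducing
    neighbors) / tau_act; every spontaneous substate exit has rate n_X/tau_X.
    Identical inputs and seed give a bitwise identical record.  With
    ``record_events=False`` only the 1-bin kymograph and final state are
    kept, which is what the batch drivers use.
    """
    if t_max is None:
        t_max = default_t_max(p, geom, sched)
    if sched.times and t_max < sched.last_time:
        raise ValueError("t_max earlier than the last scheduled initiation")
    if not isinstance(seed, (int, np.integer)):
        raise TypeError("seed must be an integer")

    codes = CellState(p)
    state_rates = np.zeros(p.n_states, np.float64)
    for s in range(1, p.n_states):
        state_rates[s] = codes.spontaneous_rate(s)
    nbr, cnt = neighbor_table(geom)
    init_times = np.asarray(sched.times, np.float64)
    n_bins = int(np.ceil(t_max / binw))
    kymo = np.zeros((geom.length, n_bins), np.int32)
    if initial_state is None:
        state = np.zeros(geom.n_cells, np.int16)
    else:
        state = np.asarray(initial_state, np.int16).copy()
        if state.shape != (geom.n_cells,):
            raise ValueError("initial_state has wrong shape")

    if record_events:
        n_cycles = max(1.0, t_max / (p.tau_r + p.tau_e + p.tau_i))
        cap = int(geom.n_cells * p.n_states * min(n_cycles, 50.0)) + 1024
    else:
        cap = 0
    while True:
        state_run = state.copy()
        kymo[:] = 0
        ev_time = np.empty(cap, np.float64)
        ev_cell = np.empty(cap, np.int32)
        ev_from = np.empty(cap, np.int16)
        ev_to = np.empty(cap, np.int16)
        status, n_ev, t_end = _kernel.run_ssa(
            nbr, cnt, geom.width, geom.length,
            codes.first_i, codes.first_r, codes.last_r,
            1.0 / p.tau_act, state_rates, init_times,
            float(t_max), float(binw), int(seed),
            state_run, kymo, ev_time, ev_cell, ev_from, ev_to, record_events,
        )
        if status == _kernel.OK:
            break
        cap *= 2  # event buffer overflow: deterministic rerun with more room

    events = None
    if record_events:
        events = np.empty(n_ev, _EVENT_DTYPE)
        events["time"] = ev_time[:n_ev]
        events["cell"] = ev_cell[:n_ev]
        events["from_code"] = ev_from[:n_ev]
        events["to_code"] = ev_to[:n_ev]

    return SimulationRecord(
        params=p, geometry=geom, schedule=sched, seed=int(seed), t_max=float(t_max),
        t_end=float(t_end), kymograph=Kymograph(kymo, binw), final_state=state_run,
        events=events,
    )


def activity_series(
    rec: SimulationRecord, binw: float = 1.0, per_state: bool = False
) -> Kymograph:
    """Kymograph from a record's event log at arbitrary bin width.

    Replays the log and samples the piecewise-constant lattice state at bin
    midpoints.  With ``per_state=True`` the full Q/E/I/R partition is
    returned as well (every bin then sums to W*L cells).  Records without an
    event log return their stored kymograph when the bin width matches.
    """
    if binw <= 0:
        raise ValueError("bin width must be positive")
    if rec.events is None:
        if binw == rec.kymograph.binw and not per_state:
            return rec.kymograph
        raise ValueError("record has no event log; only the stored kymograph is available")

    p, geom = rec.params, rec.geometry
    codes = CellState(p)
    n_bins = int(np.ceil(rec.t_max / binw))
    classes = {"Q": 0, "E": 1, "I": 2, "R": 3}
    state_class = np.zeros(p.n_states, np.int8)
    for s in range(p.n_states):
        if codes.is_excited(s):
            state_class[s] = classes["E"]
        elif codes.is_inducing(s):
            state_class[s] = classes["I"]
        elif s != 0:
            state_class[s] = classes["R"]

    counts = np.zeros((4, geom.length, n_bins), np.int32)
    state = np.zeros(geom.n_cells, np.int16)
    layers = np.arange(geom.n_cells) // geom.width
    per_layer = np.zeros((4, geom.length), np.int32)
    per_layer[0] = geom.width  # all quiescent initially

    mids = (np.arange(n_bins) + 0.5) * binw
    ev = rec.events
    next_bin = 0
    for k in range(len(ev) + 1):
        t_next = ev["time"][k] if k < len(ev) else np.inf
        while next_bin < n_bins and mids[next_bin] <= t_next:
            counts[:, :, next_bin] = per_layer
            next_bin += 1
        if k == len(ev):
            break
        cell = ev["cell"][k]
        frm, to = ev["from_code"][k], ev["to_code"][k]
        lay = layers[cell]
        per_layer[state_class[frm], lay] -= 1
        per_layer[state_class[to], lay] += 1
        state[cell] = to

    n_ei = counts[1] + counts[2]
    extra = {name: counts[idx] for name, idx in classes.items()} if per_state else None
    return Kymograph(n_ei.astype(np.int32), binw, per_state=extra)


def arrivals_at_end(
    source: SimulationRecord | Kymograph,
    min_separation: float = 20.0,
    min_height: float = 1.0,
) -> np.ndarray:
    """Front arrival times (min) at the last channel layer.

    Local maxima of the last-layer activity along time; peaks closer than
    ``min_separation`` are merged keeping the higher one.  Plateau peaks
    (constant activity over several bins) report their midpoint.
    """
    kymo = source.kymograph if isinstance(source, SimulationRecord) else source
    series = kymo.last_layer().astype(float)
    if not np.any(series >= min_height):
        return np.array([], float)
    distance = max(1, int(round(min_separation / kymo.binw)))
    idx, props = signal.find_peaks(
        series, height=min_height, distance=distance, plateau_size=(1, None)
    )
    mid = (props["left_edges"] + props["right_edges"]) / 2.0
    return (mid + 0.5) * kymo.binw
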