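"""Disruptive-event statistics and rate laws of front propagation.

A single front traveling along the channel is subject to two kinds of
disruptive events: propagation failure (all active cells turn refractory)
and new front spawning (a lingering inducing cell re-activates a recovered
neighbor).  Their propensities per cell layer follow
``lambda_fail(W) = exp(a_fail (W - W_fail))`` and
``lambda_spawn(W) = a_spawn (W - W_spawn)``; their sum is minimized at an
optimal channel width.  This module estimates the propensities from batches
of tracked simulations, fits the rate laws, and computes transit-time and
inter-front statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine, tracking
from .model_core import ChannelGeometry, ModelParameters
from .tracking import TrackingConfig

__all__ = [
    "EventCensus",
    "RateModel",
    "TransitStatistics",
    "first_disruptive_event",
    "census",
    "census_from_simulations",
    "estimate_propensities",
    "fit_rate_models",
    "optimal_width",
    "transit_statistics",
    "transit_survey",
    "collect_transits",
    "pair_event_probabilities",
    "arrival_interval_curve",
    "expected_fronts_before_spawn",
]


@dataclass
class EventCensus:
    """Counts of first disruptive events over a batch of single-front runs."""

    n_sims: int
    n_event: int
    n_fail: int
    n_spawn: int
    x_event: float  # mean layer of the first event (nan if none)
    width: int
    length: int

    def __post_init__(self) -> None:
        if self.n_fail + self.n_spawn != self.n_event or self.n_event > self.n_sims:
            raise ValueError("inconsistent census counts")


@dataclass
class RateModel:
    """Fitted coefficients of the two rate laws."""

    a_fail: float
    w_fail: float
    a_spawn: float
    w_spawn: float
    a_fail_se: float = np.nan
    a_spawn_se: float = np.nan
    cov_fail: np.ndarray | None = None   # covariance of (slope, intercept)
    cov_spawn: np.ndarray | None = None

    def lambda_fail(self, w):
        return np.exp(self.a_fail * (np.asarray(w, float) - self.w_fail))

    def lambda_spawn(self, w):
        return np.maximum(0.0, self.a_spawn * (np.asarray(w, float) - self.w_spawn))

    def lambda_tot(self, w):
        return self.lambda_fail(w) + self.lambda_spawn(w)


def first_disruptive_event(
    tracks: list[tracking.FrontTrack],
    events: list[tracking.SpawnEvent],
    binw: float = 1.0,
) -> tuple[str, float, float] | None:
    """Earliest disruptive event of a single-front run.

    Candidates are propagation failures (terminal sample of a failed track)
    and spawning events (their anchor).  A lone front enters a fully
    recovered channel, so a track dying even within the entry zone is a
    genuine propagation failure here, not an interaction effect; a run with
    no tracks at all means the front collapsed before it was ever detected
    and counts as a failure at the channel entry.  Returns
    ``(kind, layer, time)`` or ``None``.
    """
    if not tracks:
        return "fail", 0.0, 0.0
    candidates: list[tuple[float, float, str]] = []
    for tr in tracks:
        if tr.fate == "propagation_failure":
            candidates.append((tr.end_bin * binw, tr.end_layer, "fail"))
        elif tr.fate == "immediate_failure" and tr.start_bin * binw <= 20.0:
            # the initiated front itself died in the entry zone; later
            # entry-zone flickers are leftovers, not fronts
            candidates.append((tr.end_bin * binw, tr.end_layer, "fail"))
    for ev in events:
        candidates.append((ev.anchor_time, ev.anchor_layer, "spawn"))
    if not candidates:
        return None
    t, x, kind = min(candidates)
    return kind, x, t


def census(
    per_run_events: list[tuple[str, float, float] | None],
    width: int,
    length: int,
) -> EventCensus:
    """Aggregate per-run first events into an :class:`EventCensus`."""
    if not per_run_events:
        raise ValueError("empty batch")
    hits = [e for e in per_run_events if e is not None]
    n_fail = sum(1 for e in hits if e[0] == "fail")
    n_spawn = sum(1 for e in hits if e[0] == "spawn")
    x_event = float(np.mean([e[1] for e in hits])) if hits else float("nan")
    return EventCensus(
        n_sims=len(per_run_events), n_event=len(hits), n_fail=n_fail,
        n_spawn=n_spawn, x_event=x_event, width=width, length=length,
    )


def census_from_simulations(
    p: ModelParameters,
    geom: ChannelGeometry,
    n_runs: int,
    seed: int,
    config: TrackingConfig = TrackingConfig(),
    collect_spawn_events: bool = False,
) -> EventCensus | tuple[EventCensus, list[tracking.SpawnEvent]]:
    """Run ``n_runs`` single-front simulations and census their first events."""
    sched = engine.make_schedule("single")
    # horizon: a full transit plus enough slack for a late spawning event's
    # children to outlive the 50-min discard rule
    t_max = geom.length * engine.deterministic_inverse_speed(p) + 10.0 * p.tau_r
    per_run = []
    first_spawns: list[tracking.SpawnEvent] = []
    for i in range(n_runs):
        rec = engine.run_simulation(p, geom, sched, seed=seed + i, t_max=t_max, record_events=False)
        tracks, events = tracking.track_kymograph(rec.kymograph, geom, config)
        first = first_disruptive_event(tracks, events, rec.kymograph.binw)
        per_run.append(first)
        if collect_spawn_events and first is not None and first[0] == "spawn":
            ev = min(events, key=lambda e: e.anchor_time)
            first_spawns.append(ev)
    c = census(per_run, geom.width, geom.length)
    return (c, first_spawns) if collect_spawn_events else c


def estimate_propensities(c: EventCensus) -> tuple[float, float, float]:
    """Per-layer propensities (lambda_tot, lambda_fail, lambda_spawn).

    ``lambda_tot = n_event / (n_event x_event + (N - n_event) L)``: the
    maximum-likelihood hazard of a constant per-layer event rate observed up
    to the first event or the channel end.
    """
    if c.n_event == 0:
        return 0.0, 0.0, 0.0
    lam_tot = c.n_event / (c.n_event * c.x_event + (c.n_sims - c.n_event) * c.length)
    lam_fail = c.n_fail / c.n_event * lam_tot
    lam_spawn = c.n_spawn / c.n_event * lam_tot
    return lam_tot, lam_fail, lam_spawn


def _polyfit_line(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
    """Straight-line LS fit; covariance only when enough points support it."""
    if len(x) > 3:
        return np.polyfit(x, y, 1, cov=True)
    return np.polyfit(x, y, 1), None


def fit_rate_models(table: pd.DataFrame) -> RateModel:
    """Least-squares fits of the two rate laws to per-width propensities.

    ``table`` needs columns ``W``, ``lambda_fail``, ``lambda_spawn``.  The
    failure law is fitted as ln(lambda_fail) vs W (widths with zero observed
    failures are omitted: no logarithm); the spawning law is a straight line
    through the (W, lambda_spawn) points.
    """
    w = np.asarray(table["W"], float)
    if len(np.unique(w)) < 2:
        raise ValueError("need at least two distinct widths")
    lf = np.asarray(table["lambda_fail"], float)
    ls = np.asarray(table["lambda_spawn"], float)

    pos = lf > 0
    if pos.sum() < 2:
        raise ValueError("need >=2 widths with lambda_fail > 0 for the log-linear fit")
    coef_f, cov_f = _polyfit_line(w[pos], np.log(lf[pos]))
    a_fail, b_f = float(coef_f[0]), float(coef_f[1])
    coef_s, cov_s = _polyfit_line(w, ls)
    a_spawn, b_s = float(coef_s[0]), float(coef_s[1])
    return RateModel(
        a_fail=a_fail,
        w_fail=-b_f / a_fail,
        a_spawn=a_spawn,
        w_spawn=-b_s / a_spawn,
        a_fail_se=float(np.sqrt(cov_f[0, 0])) if isinstance(cov_f, np.ndarray) else np.nan,
        a_spawn_se=float(np.sqrt(cov_s[0, 0])) if isinstance(cov_s, np.ndarray) else np.nan,
        cov_fail=cov_f if isinstance(cov_f, np.ndarray) else None,
        cov_spawn=cov_s if isinstance(cov_s, np.ndarray) else None,
    )


def optimal_width(m: RateModel, w_range=range(2, 13)) -> tuple[int, float, float]:
    """Integer width minimizing lambda_tot; ties go to the smaller width.

    Returns ``(W_opt, lambda_tot_min, expected_range)`` with the expected
    uninterrupted propagation range ``1 / lambda_tot(W_opt)`` in layers.
    """
    ws = np.asarray(sorted(set(int(w) for w in w_range)))
    if ws.size == 0:
        raise ValueError("empty width range")
    lam = m.lambda_tot(ws)
    i = int(np.argmin(lam))  # argmin takes the first minimum: smaller W wins ties
    lam_min = float(lam[i])
    return int(ws[i]), lam_min, (np.inf if lam_min == 0 else 1.0 / lam_min)


@dataclass
class TransitStatistics:
    """Per-width transit-time statistics and the sigma0^2(W) = a/W + b fit.

    ``a_se``/``b_se`` come from the fit residuals; ``a_se_prop`` propagates
    the kurtosis-aware per-point errors of the variance estimates through
    the fit, which is the more honest uncertainty when the transit
    distribution has moderately heavy tails.
    """

    per_width: pd.DataFrame  # W, n, v_inv, v_inv_se, sigma0_sq, sigma0_sq_se
    a: float
    b: float
    a_se: float
    b_se: float
    a_se_prop: float = np.nan

    def sigma0_sq(self, w) -> np.ndarray:
        return self.a / np.asarray(w, float) + self.b


def collect_transits(
    p: ModelParameters,
    geom: ChannelGeometry,
    n_runs: int,
    seed: int,
    min_separation: float = 20.0,
) -> np.ndarray:
    """Transit times (first arrival at the channel end) of arriving fronts."""
    sched = engine.make_schedule("single")
    t_max = geom.length * engine.deterministic_inverse_speed(p) + 5.0 * p.tau_r
    out = []
    for i in range(n_runs):
        rec = engine.run_simulation(p, geom, sched, seed=seed + i, t_max=t_max, record_events=False)
        arr = engine.arrivals_at_end(rec, min_separation=min_separation)
        if len(arr):
            out.append(arr[0])
    return np.asarray(out, float)


def transit_survey(
    p: ModelParameters,
    widths,
    n_runs: int | dict[int, int],
    seed: int,
    length: int = 300,
    boundary: str = "periodic",
    fallback_length: int = 30,
    min_survival: float = 0.5,
    fallback_factor: int = 4,
) -> tuple[dict[int, np.ndarray], dict[int, int]]:
    """Transit times per width, falling back to a short channel when the
    front range is short.

    Conditioning on arrival over a long channel truncates the slow tail of
    the transit distribution once most fronts fail en route, deflating the
    per-length variance; widths where fewer than ``min_survival`` of the
    fronts reach the end are therefore re-measured on a channel of
    ``fallback_length`` layers (with ``fallback_factor`` times the runs —
    short-channel simulations are cheap).  Returns the transit arrays and
    the channel length actually used per width.
    """
    transits: dict[int, np.ndarray] = {}
    lengths: dict[int, int] = {}
    for w in widths:
        n = n_runs[int(w)] if isinstance(n_runs, dict) else n_runs
        # wide stride keeps per-run seed ranges disjoint across widths, so
        # no two simulations anywhere in the survey share an RNG stream
        seed_w = (seed + 2_000_003 * int(w)) % 2**31
        geom = ChannelGeometry(int(w), length, boundary)
        tau = collect_transits(p, geom, n, seed=seed_w)
        if tau.size < min_survival * n:
            geom = ChannelGeometry(int(w), fallback_length, boundary)
            tau = collect_transits(
                p, geom, fallback_factor * n, seed=seed_w + 1_000_000
            )
            lengths[int(w)] = fallback_length
        else:
            lengths[int(w)] = length
        transits[int(w)] = tau
    return transits, lengths


def transit_statistics(
    transits_by_width: dict[int, np.ndarray],
    length: int,
    lengths: dict[int, int] | None = None,
) -> TransitStatistics:
    """Mean inverse speed and per-length transit variance, with the 1/W fit.

    Statistics are conditioned on arrival (only fronts that reached the
    channel end contribute).  ``lengths`` overrides the channel length per
    width (short-channel fallback).  The fit of ``sigma0^2`` against
    ``1/W`` uses ordinary least squares over widths W > 2.
    """
    rows = []
    for w, tau in sorted(transits_by_width.items()):
        tau = np.asarray(tau, float)
        if tau.size < 2:
            raise ValueError(f"width {w}: need >=2 arrivals")
        lw = lengths.get(w, length) if lengths else length
        dev = tau - tau.mean()
        m2 = np.mean(dev**2)
        m4 = np.mean(dev**4)
        rows.append({
            "W": w,
            "n": tau.size,
            "v_inv": tau.mean() / lw,
            "v_inv_se": tau.std(ddof=1) / np.sqrt(tau.size) / lw,
            "sigma0_sq": tau.var(ddof=1) / lw,
            "sigma0_sq_se": np.sqrt(max(m4 - m2**2, 0.0) / tau.size) / lw,
        })
    df = pd.DataFrame(rows)
    sel = df["W"] > 2
    if sel.sum() < 2:
        raise ValueError("need >=2 widths above W=2 for the a/W + b fit")
    x = 1.0 / df.loc[sel, "W"].to_numpy(float)
    y = df.loc[sel, "sigma0_sq"].to_numpy(float)
    y_se = df.loc[sel, "sigma0_sq_se"].to_numpy(float)
    coef, cov = _polyfit_line(x, y)
    if isinstance(cov, np.ndarray):
        a_se, b_se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    else:
        a_se = b_se = np.nan
    factors = (x - x.mean()) / np.sum((x - x.mean()) ** 2)
    a_se_prop = float(np.sqrt(np.sum(factors**2 * y_se**2)))
    return TransitStatistics(
        per_width=df, a=float(coef[0]), b=float(coef[1]),
        a_se=a_se, b_se=b_se, a_se_prop=a_se_prop,
    )


SECOND_FRONT_FATES = (
    "immediate_failure", "propagation_failure", "spawning", "annihilation", "arrived",
)


def _second_front_outcome(
    tracks: list[tracking.FrontTrack],
    events: list[tracking.SpawnEvent],
    t_init: float,
    binw: float,
    zone: int,
    window: tuple[float, float] = (-10.0, 180.0),
) -> str:
    """Fate of the front initiated at ``t_init`` from the tracked picture.

    Candidate tracks start near the channel entry within the time window
    around the initiation (a weak partial front often lingers at the entry
    while the proper front detaches a few layers in, so parentage is
    ignored).  The front counts as an immediate failure when no candidate
    escapes the entry region; the escape threshold adds the spatial
    smoothing scale to the classification zone because tracked positions
    trail the true activity head by about that much.
    """
    # never reach back to the first initiation at t = 0: a track that starts
    # with the run belongs to the first front
    t_lo, t_hi = max(t_init + window[0], binw), t_init + window[1]
    cands = [
        tr for tr in tracks
        if t_lo <= tr.start_bin * binw <= t_hi and tr.start_layer <= zone + 10
    ]
    if not cands:
        return "immediate_failure"
    escape = zone + 2  # tracked peaks trail the activity head by ~sigma_x
    main = max(cands, key=lambda tr: max(tr.layers))
    if max(main.layers) <= escape:
        return "immediate_failure"
    if main.fate == "arrived":
        spawned = any(
            s.parent_id == main.track_id and s.bin * binw >= t_init
            for ev in events
            for s in ev.splits
        )
        return "spawning" if spawned else "arrived"
    if main.fate in ("annihilation", "propagation_failure"):
        return main.fate
    return "propagation_failure"


def pair_event_probabilities(
    p: ModelParameters,
    geom: ChannelGeometry,
    interval: float,
    n_runs: int,
    seed: int,
    config: TrackingConfig = TrackingConfig(),
) -> pd.DataFrame:
    """Fate probabilities of the second of two fronts vs their interval.

    Runs ``n_runs`` two-front simulations and classifies the second front
    through the tracking pipeline.  A run in which no second-front track is
    detected (the entry layer had not recovered enough to carry a front)
    counts as immediate failure.  ``spawning`` means the second front's
    first recorded event is a spawn on its own lineage.  Binomial standard
    errors are attached.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    sched = engine.make_schedule("pair", interval=interval)
    t_max = interval + geom.length * engine.deterministic_inverse_speed(p) + 10.0 * p.tau_r
    zone = tracking.default_immediate_zone(geom.width)
    counts = {f: 0 for f in SECOND_FRONT_FATES}
    for i in range(n_runs):
        rec = engine.run_simulation(p, geom, sched, seed=seed + i, t_max=t_max, record_events=False)
        tracks, events = tracking.track_kymograph(rec.kymograph, geom, config)
        outcome = _second_front_outcome(tracks, events, interval, rec.kymograph.binw, zone)
        counts[outcome] += 1
    rows = []
    for fate, k in counts.items():
        prob = k / n_runs
        rows.append({
            "fate": fate, "n": k, "probability": prob,
            "se": np.sqrt(prob * (1 - prob) / n_runs),
        })
    df = pd.DataFrame(rows)
    df.attrs.update({"interval": interval, "n_runs": n_runs})
    return df


def arrival_interval_curve(
    p: ModelParameters,
    geom: ChannelGeometry,
    intervals,
    n_fronts: int,
    n_seeds: int,
    seed: int,
    min_separation: float = 20.0,
) -> tuple[pd.DataFrame, float]:
    """Mean interval between arriving fronts vs the initiation interval.

    For each initiation interval, ``n_seeds`` simulations of ``n_fronts``
    periodically initiated fronts are run and the mean inter-arrival
    interval at the channel end is recorded.  Returns the scan table and
    ``T_trans_min``, the minimum of the curve.
    """
    intervals = list(intervals)
    if len(intervals) < 2:
        raise ValueError("scan at least two intervals")
    rows = []
    for j, interval in enumerate(intervals):
        gaps = []
        sched = engine.make_schedule("periodic", interval=interval, n_fronts=n_fronts)
        for i in range(n_seeds):
            rec = engine.run_simulation(
                p, geom, sched, seed=seed + j * n_seeds + i, record_events=False
            )
            arr = engine.arrivals_at_end(rec, min_separation=min_separation)
            if len(arr) >= 2:
                gaps.extend(np.diff(arr))
        rows.append({
            "interval": interval,
            "mean_received_interval": float(np.mean(gaps)) if gaps else np.nan,
            "n_gaps": len(gaps),
        })
    df = pd.DataFrame(rows)
    valid = df.dropna(subset=["mean_received_interval"])
    t_trans_min = float(valid["mean_received_interval"].min()) if len(valid) else np.nan
    return df, t_trans_min


def expected_fronts_before_spawn(m: RateModel, width: int, length: int) -> float:
    """Expected number of fronts passing the channel before the first spawn.

    With per-front spawning probability ``1 - exp(-lambda_spawn L)`` the
    count of clean passages is geometric with expectation
    ``1 / (1 - exp(-lambda_spawn L))``.
    """
    lam = float(m.lambda_spawn(width))
    if lam <= 0:
        return np.inf
    return 1.0 / (1.0 - np.exp(-lam * length))
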