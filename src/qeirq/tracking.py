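"""Front tracking in kymographs: peak detection, linking, fates, spawning.

The kymograph is smoothed with a Gaussian kernel along space and a causal
exponential kernel along time, per-bin activity maxima are located, and the
per-bin peaks are linked into tracks by greedy nearest-neighbor matching.
A track that links to two successors records a split; surviving splits are
clustered into spawning events by single linkage under a (20 layer, 150 min)
proximity relation.  Front fates distinguish arrival at the channel end,
annihilation with an opposite-direction front, immediate failure near the
channel entry, and free propagation failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .engine import Kymograph
from .model_core import ChannelGeometry

__all__ = [
    "FrontTrack",
    "SpawnEvent",
    "TrackingConfig",
    "detect_front_positions",
    "link_tracks",
    "classify_fates",
    "group_spawning_events",
    "track_kymograph",
    "default_immediate_zone",
]

FATES = ("arrived", "annihilation", "immediate_failure", "propagation_failure")


@dataclass
class FrontTrack:
    """One tracked front: time-ordered (bin, layer) samples."""

    track_id: int
    bins: list[int] = field(default_factory=list)
    layers: list[float] = field(default_factory=list)
    parent_split: int | None = None  # index into the split list
    fate: str | None = None

    @property
    def start_bin(self) -> int:
        return self.bins[0]

    @property
    def end_bin(self) -> int:
        return self.bins[-1]

    @property
    def start_layer(self) -> float:
        return self.layers[0]

    @property
    def end_layer(self) -> float:
        return self.layers[-1]

    def duration(self, binw: float) -> float:
        return (self.end_bin - self.start_bin) * binw

    @property
    def direction(self) -> int:
        """+1 forward (toward the channel end), -1 backward."""
        return 1 if self.layers[-1] >= self.layers[0] else -1


@dataclass
class Split:
    """A track spawning a child track."""

    parent_id: int
    child_id: int
    bin: int
    layer: float


@dataclass
class SpawnEvent:
    """Group of splits treated as one localized spawning event."""

    anchor_layer: float
    anchor_time: float
    splits: list[Split]
    n_forward: int = 0
    n_backward: int = 0


@dataclass(frozen=True)
class TrackingConfig:
    """Knobs of the tracking pipeline (defaults for 1-min kymograph bins).

    The smoothing widths are not critical as long as the deterministic-limit
    front head (about two layers wide) maps to a single detected peak.
    """

    sigma_x: float = 2.0          # Gaussian smoothing along space (layers)
    tau_t: float = 5.0            # causal exponential time constant (min)
    min_height: float | None = None  # default max(2, 0.25 W) active cells
    min_peak_distance: int = 5    # layers
    max_step: float = 5.0         # max layer displacement per linked bin
    max_gap: int = 30             # bins a track may skip (see link_tracks)
    min_duration: float = 50.0    # min; shorter split-children are discarded
    annihilation_radius: float = 5.0   # layers
    annihilation_window: float = 15.0  # min
    spawn_group_dx: float = 20.0  # layers (single-linkage proximity)
    spawn_group_dt: float = 150.0  # min


def default_immediate_zone(width: int) -> int:
    """Entry zone (layers) for the immediate-failure fate: W/2 clamped to 1..5."""
    return int(np.clip(round(width / 2), 1, 5))


def smooth_kymograph(kymo: Kymograph, sigma_x: float, tau_t: float) -> np.ndarray:
    """Gaussian along the spatial axis, causal exponential along time.

    The spatial kernel is scaled to unit peak, so a smoothed value is a
    weighted count of active cells in nearby layers and height thresholds
    keep their "number of active cells" meaning.
    """
    arr = kymo.n_ei.astype(float)
    if sigma_x > 0:
        half = int(np.ceil(4 * sigma_x))
        imp = np.zeros(2 * half + 1)
        imp[half] = 1.0
        peak = ndimage.gaussian_filter1d(imp, sigma_x).max()
        arr = ndimage.gaussian_filter1d(arr, sigma_x, axis=0, mode="nearest") / peak
    if tau_t > 0:
        alpha = 1.0 - np.exp(-kymo.binw / tau_t)
        arr = signal.lfilter([alpha], [1.0, -(1.0 - alpha)], arr, axis=1)
    return arr


def detect_front_positions(
    kymo: Kymograph,
    sigma_x: float = 2.0,
    tau_t: float = 5.0,
    min_height: float | None = None,
    min_peak_distance: int = 5,
) -> list[np.ndarray]:
    """Per-time-bin front positions: smoothed activity maxima along space.

    Returns one array of peak layer indices per time bin; peaks below
    ``min_height`` or closer than ``min_peak_distance`` (keep higher) are
    suppressed.
    """
    if kymo.n_bins == 0:
        return []
    if min_height is None:
        width = int(kymo.n_ei.max()) if kymo.n_ei.size else 0
        min_height = max(2.0, 0.25 * width)
    arr = smooth_kymograph(kymo, sigma_x, tau_t)
    n_layers, n_bins = arr.shape
    # vectorized local-maximum candidates (boundary layers included: an
    # activity ridge hugging a channel end has no interior maximum)
    cand = np.zeros(arr.shape, bool)
    if n_layers >= 3:
        cand[1:-1] = (arr[1:-1] >= arr[:-2]) & (arr[1:-1] > arr[2:])
    if n_layers >= 2:
        cand[0] = arr[0] > arr[1]
        cand[-1] = arr[-1] > arr[-2]
    else:
        cand[0] = True
    cand &= arr >= min_height
    out: list[np.ndarray] = []
    dist = max(1, min_peak_distance)
    for b in range(n_bins):
        idx = np.nonzero(cand[:, b])[0]
        if idx.size > 1:
            # suppress close peaks, keeping the higher one
            order = idx[np.argsort(arr[idx, b])[::-1]]
            kept: list[int] = []
            for i in order:
                if all(abs(i - j) >= dist for j in kept):
                    kept.append(i)
            idx = np.sort(kept)
        out.append(idx.astype(float))
    return out


def _reach(max_step: float, gap: int) -> float:
    """Linking reach after ``gap`` skipped bins.

    One full step for the first bin, then one layer per further skipped bin:
    a front occluded by a sub-threshold fluctuation keeps advancing at about
    its normal speed, while a genuinely new (spawned) front appears much
    further from any track head than this allows.
    """
    return max_step + max(0, gap - 1)


def link_tracks(
    peaks: list[np.ndarray],
    binw: float = 1.0,
    max_step: float = 5.0,
    max_gap: int = 30,
    min_duration: float = 50.0,
    length: int | None = None,
    origin_zone: float | None = None,
) -> tuple[list[FrontTrack], list[Split]]:
    """Greedy nearest-neighbor linking of per-bin peaks into tracks.

    Each open track is matched to at most one peak per bin within a reach
    that grows slowly over skipped bins (gap closing: brief sub-threshold
    dips do not break a front).  A leftover peak within reach of an
    already-matched track becomes a split child.  When ``origin_zone`` is
    given, any unexplained track born in the channel interior (start layer
    beyond the zone) is treated as a spawned front and attached by a
    synthetic split to the most recent track that passed its birthplace.
    Split children shorter than ``min_duration`` that neither reach the
    channel end nor split themselves are discarded together with their
    creating split.
    """
    tracks: list[FrontTrack] = []
    splits: list[Split] = []
    active: list[int] = []  # track ids still open

    for b, layer_arr in enumerate(peaks):
        layer_list = list(layer_arr)
        # candidate (distance, track, peak slot) pairs
        cands = []
        for tid in active:
            tr = tracks[tid]
            gap = b - tr.end_bin
            if gap > max_gap:
                continue
            reach = _reach(max_step, gap)
            for j, x in enumerate(layer_list):
                d = abs(x - tr.end_layer)
                if d <= reach:
                    cands.append((d, gap, tid, j))
        cands.sort()
        used_tracks: set[int] = set()
        used_peaks: set[int] = set()
        matched_pos: dict[int, float] = {}
        for d, gap, tid, j in cands:
            if tid in used_tracks or j in used_peaks:
                continue
            used_tracks.add(tid)
            used_peaks.add(j)
            matched_pos[tid] = tracks[tid].end_layer
            tracks[tid].bins.append(b)
            tracks[tid].layers.append(layer_list[j])
        # unmatched peaks: split children if within reach of some track's
        # previous head, otherwise fresh tracks
        for j, x in enumerate(layer_list):
            if j in used_peaks:
                continue
            parent = None
            best = np.inf
            for tid in active:
                tr = tracks[tid]
                gap = b - (tr.bins[-2] if tid in used_tracks and len(tr.bins) > 1 else tr.end_bin)
                if gap > max_gap + 1:
                    continue
                ref = matched_pos.get(tid, tr.end_layer)
                d = abs(x - ref)
                if d <= _reach(max_step, max(gap, 1)) and d < best:
                    best, parent = d, tid
            tid_new = len(tracks)
            tr = FrontTrack(tid_new, [b], [x])
            if parent is not None:
                tr.parent_split = len(splits)
                splits.append(Split(parent, tid_new, b, x))
            tracks.append(tr)
            active.append(tid_new)
        # close tracks that exceeded the gap
        active = [tid for tid in active if b - tracks[tid].end_bin <= max_gap]

    if origin_zone is not None:
        _attach_interior_origins(tracks, splits, origin_zone)

    # discard short split-children (root tracks are initiated fronts and
    # are always kept so that immediate failures remain classifiable)
    has_children = {s.parent_id for s in splits}
    keep = np.ones(len(tracks), bool)
    for tr in tracks:
        if tr.parent_split is None:
            continue
        reached_end = length is not None and tr.end_layer >= length - 1
        if tr.duration(binw) < min_duration and not reached_end and tr.track_id not in has_children:
            keep[tr.track_id] = False
    kept_tracks = [tr for tr in tracks if keep[tr.track_id]]
    kept_splits = [s for s in splits if keep[s.child_id]]
    return kept_tracks, kept_splits


def _attach_interior_origins(
    tracks: list[FrontTrack], splits: list[Split], origin_zone: float
) -> None:
    """Mark unexplained interior-born tracks as spawned fronts.

    A front spawned by a lingering inducing cell surfaces in the kymograph
    far behind the parent's current head, long after the parent passed, so
    the per-bin linker sees a parentless track born mid-channel.  Such a
    track is attached by a synthetic split (at its own origin) to the track
    that most recently visited that location, which is the physical parent.
    """
    for tr in tracks:
        if tr.parent_split is not None or tr.start_layer <= origin_zone:
            continue
        parent, best = None, (np.inf, np.inf)
        for other in tracks:
            if other is tr or other.start_bin >= tr.start_bin:
                continue
            ob = np.asarray(other.bins)
            earlier = ob < tr.start_bin
            if not earlier.any():
                continue
            ox = np.asarray(other.layers)[earlier]
            dx = np.abs(ox - tr.start_layer)
            j = int(np.argmin(dx))
            key = (dx[j], tr.start_bin - ob[earlier][j])
            if dx[j] <= 25.0 and key < best:
                best, parent = key, other.track_id
        if parent is not None:
            tr.parent_split = len(splits)
            splits.append(Split(parent, tr.track_id, tr.start_bin, tr.start_layer))


def classify_fates(
    tracks: list[FrontTrack],
    geom: ChannelGeometry,
    binw: float = 1.0,
    immediate_zone: int | None = None,
    annihilation_radius: float = 5.0,
    annihilation_window: float = 15.0,
    arrival_margin: float | None = None,
) -> list[FrontTrack]:
    """Assign one fate per track (in place; returns the list).

    Order of precedence: arrived at the last layer (within
    ``arrival_margin`` layers, since smoothed peak positions trail the
    activity head); annihilation (terminal sample near an
    opposite-direction track in space and time); immediate failure
    (terminal layer within the entry zone); propagation failure.
    """
    if immediate_zone is None:
        immediate_zone = default_immediate_zone(geom.width)
    if arrival_margin is None:
        arrival_margin = min(5.0, max(2.0, 0.02 * geom.length))
    for tr in tracks:
        if tr.end_layer >= geom.length - 1 - arrival_margin:
            tr.fate = "arrived"
            continue
        annihilated = False
        t_end = tr.end_bin * binw
        for other in tracks:
            if other is tr or other.direction == tr.direction:
                continue
            ob = np.asarray(other.bins) * binw
            ox = np.asarray(other.layers)
            near = (np.abs(ox - tr.end_layer) <= annihilation_radius) & (
                np.abs(ob - t_end) <= annihilation_window
            )
            if near.any():
                annihilated = True
                break
        if annihilated:
            tr.fate = "annihilation"
        elif tr.end_layer <= immediate_zone:
            tr.fate = "immediate_failure"
        else:
            tr.fate = "propagation_failure"
    return tracks


def group_spawning_events(
    splits: list[Split],
    tracks: list[FrontTrack],
    binw: float = 1.0,
    max_dx: float = 20.0,
    max_dt: float = 150.0,
) -> list[SpawnEvent]:
    """Single-linkage clustering of splits into spawning events.

    Two splits join the same event when closer than ``max_dx`` layers and
    ``max_dt`` minutes; the relation is applied transitively.  Children are
    counted by their propagation direction.
    """
    if not splits:
        return []
    n = len(splits)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if (
                abs(splits[i].layer - splits[j].layer) <= max_dx
                and abs(splits[i].bin - splits[j].bin) * binw <= max_dt
            ):
                parent[find(i)] = find(j)

    by_track = {tr.track_id: tr for tr in tracks}
    groups: dict[int, list[Split]] = {}
    for i, s in enumerate(splits):
        groups.setdefault(find(i), []).append(s)
    events = []
    for members in groups.values():
        members.sort(key=lambda s: s.bin)
        ev = SpawnEvent(
            anchor_layer=members[0].layer,
            anchor_time=members[0].bin * binw,
            splits=members,
        )
        for s in members:
            child = by_track.get(s.child_id)
            if child is None:
                continue
            if child.direction > 0:
                ev.n_forward += 1
            else:
                ev.n_backward += 1
        events.append(ev)
    events.sort(key=lambda e: e.anchor_time)
    return events


def track_kymograph(
    kymo: Kymograph,
    geom: ChannelGeometry,
    config: TrackingConfig = TrackingConfig(),
    immediate_zone: int | None = None,
) -> tuple[list[FrontTrack], list[SpawnEvent]]:
    """Full pipeline: peaks -> linked tracks -> fates -> spawning events."""
    peaks = detect_front_positions(
        kymo,
        sigma_x=config.sigma_x,
        tau_t=config.tau_t,
        min_height=config.min_height if config.min_height is not None else max(2.0, 0.25 * geom.width),
        min_peak_distance=config.min_peak_distance,
    )
    zone = immediate_zone if immediate_zone is not None else default_immediate_zone(geom.width)
    tracks, splits = link_tracks(
        peaks, binw=kymo.binw, max_step=config.max_step, max_gap=config.max_gap,
        min_duration=config.min_duration, length=geom.length, origin_zone=zone,
    )
    classify_fates(
        tracks, geom, binw=kymo.binw,
        immediate_zone=immediate_zone,
        annihilation_radius=config.annihilation_radius,
        annihilation_window=config.annihilation_window,
    )
    events = group_spawning_events(
        splits, tracks, binw=kymo.binw, max_dx=config.spawn_group_dx, max_dt=config.spawn_group_dt
    )
    return tracks, events
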