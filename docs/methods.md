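# Methods

## Model

Cells are immobile agents on a 2-D triangular lattice forming a channel of
width `W` rows and length `L` layers (axial coordinates; neighbor offsets
(±1, 0), (0, ±1), (+1, −1), (−1, +1); the row index wraps under periodic
boundaries, the layer index never does). Each cell cycles through
quiescent → excited → inducing → refractory → quiescent. Activation
(Q → E₁) is the only induced transition, with propensity
`(number of inducing neighbors) / τ_act`; all other transitions are
first-order substate steps at rate `n_X / τ_X`, so the total residence
times in E, I, R are Erlang(n_X, n_X/τ_X) — mean τ_X, variance τ_X²/n_X.
Increasing the substate counts therefore tunes the model continuously
toward its deterministic limit.

Nominal parameters (all times in minutes): τ_act = 1, τ_E = 4, τ_I = 2,
τ_R = 60, n_E = 4, n_I = 2, n_R = 4. With these values the three rates
1/τ_act and n_I/τ_I (twice) are equal, giving the single-pair activation
probability 1 − (1/2)² · … = 0.75, the deterministic inverse front speed
τ_act/2 + τ_E = 4.5 min/layer, the mean cycle time
T_cycle = τ_act/⟨n_neigh_I⟩ + τ_E + τ_I + τ_R = 66.5 min (with the
flat-front value ⟨n_neigh_I⟩ = 2), the cycle standard deviation
σ_cycle = 30.1 min and the effective refractory time
T_R = T_cycle + σ_cycle ≈ 96.6 min. n_E = 3 also rounds σ_cycle to
30.1 min; both choices are plain constructor arguments and nothing is
hard-coded to either.

`W = 1` with periodic boundaries is rejected (a cell would neighbor
itself twice); single-row channels use the inert boundary, which simply
removes out-of-range neighbors.

## Simulation

Exact direct-method kinetic Monte Carlo in a numba kernel. Per-cell
propensities live in a flat array indexed by a two-level block structure
whose block sums are recomputed exactly on every local update, so sampling
never accumulates floating-point drift; events touch only the firing cell
and (when it enters or leaves the inducing state) its ≤ 6 neighbors.
Identical inputs and seed give bitwise identical trajectories.

Scheduled initiations set the quiescent cells of layer 0 to I₁ and leave
excited/inducing/refractory cells untouched; a front sent into an
unrecovered entry therefore starts as a partial front, which is what makes
the immediate-failure statistics of closely spaced fronts meaningful.

The kernel accumulates the activity kymograph — cells in any E or I
substate per layer, sampled at 1-min bin midpoints — online, so long runs
do not need an event log; small runs keep the full log for audits
(conservation of the Q/E/I/R partition, transition legality, replay
equality with the stored kymograph). Runs end at `t_max` or as soon as
the lattice is fully quiescent with nothing scheduled.

Arrival times at the channel end are local maxima of last-layer activity;
maxima closer than 20 min are merged keeping the higher peak, and plateau
peaks report their midpoints.

## Front tracking

The kymograph is smoothed with a Gaussian along space (σ_x = 2 layers;
kernel scaled to unit peak so thresholds keep their "active cells"
meaning) and a causal exponential along time (τ_t = 5 min). Per time bin,
activity maxima above `max(2, 0.25 W)` cells and at least 5 layers apart
are kept (boundary maxima included — a ridge hugging a channel end has no
interior maximum). Peaks are linked greedily to open tracks; a track may
skip up to 30 bins, with reach `max_step + (gap − 1)` layers
(max_step = 5). The long gap tolerance is deliberate: sub-threshold dips
of up to ~15–20 min are common for narrow fronts, and breaking tracks
there inflates the apparent failure rate several-fold, while a genuine
failure-then-respawn at the same site needs at least the ~96-min
refractory time and therefore cannot be bridged by a 30-min gap.

A leftover peak within reach of an already-matched track is a split child.
Fronts spawned by a lingering inducing cell surface in the kymograph far
behind the parent's current head, long after the parent passed, so a
parentless track born in the channel interior is attached by a synthetic
split to the most recent track that visited its birthplace — the physical
parent. Split children shorter than 50 min that neither reach the channel
end nor split themselves are discarded together with their creating split;
initiated (root) fronts are exempt, otherwise an immediately failing
second front would be invisible.

Fates, in order of precedence: **arrived** (terminal sample within ~5
layers of the last layer at L = 300 — smoothed tracks systematically end a
few layers short of the boundary); **annihilation** (terminal sample
within 5 layers and 15 min of an opposite-direction track);
**immediate failure** (terminal layer within the entry zone,
`clamp(round(W/2), 1, 5)`); otherwise **propagation failure**. Surviving
splits are grouped into spawning events by single linkage under the
(20 layer, 150 min) proximity relation, applied transitively, and children
are counted by direction.

All tracking parameters are exposed in `TrackingConfig`; the defaults
above were validated against event-log ground truth (activation events)
rather than tuned to any target: with them the tracked failure rates over
W = 2..5 reproduce the event-log rates, and first-event type fractions at
W = 6 are spawn-dominated as the rate laws require.

## Event statistics

For single-front censuses the first disruptive event per run is the
earliest of: any track's propagation failure (a lone front enters a fully
recovered channel, so a death even in the entry zone counts — only the
initiated front itself, identified by a start within 20 min of the
initiation; later entry-zone flickers are leftovers), and any spawning
event anchor. The per-layer hazard is the censored-exponential maximum
likelihood estimate `λ_tot = n_event / (n_event·x_event + (N−n_event)·L)`,
split by first-event type into λ_fail and λ_spawn. Rate laws are fitted by
ordinary least squares — ln λ_fail vs W (zero-failure widths omitted) and
λ_spawn vs W — and the optimal width is the integer minimizer of their
sum, ties toward the smaller width. The expected number of fronts passing
a channel before the first spawning event uses the geometric expectation
`1 / (1 − exp(−λ_spawn L))`, which reproduces the ~9.4× ratio between
W = 6 and W = 60 at the published coefficients.

Transit statistics are conditioned on arrival: ⟨v⁻¹⟩ = ⟨τ_transit⟩/L and
σ₀² = Var(τ_transit)/L per width, with an unweighted least-squares fit of
σ₀² against 1/W over W > 2. Conditioning matters: over a long channel a
width that loses most of its fronts to propagation failure keeps only the
fast, clean transits, which truncates the slow tail and deflates the
per-layer variance (at W = 3, L = 300 only ~42% of fronts survive and
σ₀² comes out ~8% below its short-channel value). `transit_survey`
therefore re-measures any width whose survival falls below one half on a
30-layer channel, where failures are rare — the same fallback used when
collecting the underlying arrival statistics in the first place. With it
the per-width values agree with the published a = 6.8, b = 0.4 curve to a
few percent at large run counts, and the fitted a lands at ≈ 6.4–6.8
min² at the campaign sizes used here.

For pair-front scans the second front's fate is decided from the candidate
tracks born near the entry after the second initiation (parentage is
ignored — a weak partial front often lingers at the entry while the proper
front detaches a few layers in): immediate failure iff no candidate
escapes `zone + 2` layers, the +2 compensating the smoothed peak's lag
behind the true activity head. With this rule the measured
immediate-failure probability at a 61.5-min interval (W = 6, L = 300) is
51–53%.

## Information pipeline

The slot protocol sends i.i.d. Bernoulli(q) symbols (default q = ½) every
`T_slot` minutes. Decoding assigns each slot — sent or not — the globally
nearest detected arrival to `t_expected = t_slot + L⟨v⁻¹⟩`, with ⟨v⁻¹⟩
calibrated from separate single-front runs of the same parameters and
width. `H(S | Δt)` is estimated on 1-min bins: a bin with ≥ k = 25 points
uses its own symbol counts; sparser bins are enlarged symmetrically (both
equidistant bins enter together) until k points are gathered; each point
contributes the binary entropy of the gathered counts plus the
Miller–Madow term `1/(2n ln 2)` when both symbols occur. Slots of runs
with no arrivals at all form a separate categorical cell that is never
merged with numeric bins and carries no bias correction, so an arrival-free
channel transmits exactly zero bits. `MI_slot = H(S) − H(S|Δt)` with the
empirical symbol entropy, and `r = MI_slot / T_slot`.

The semi-analytic layer treats the slot channel as a binary asymmetric
channel with erasure probability p. Distant fronts:
`p = 1 − exp(−L(λ_fail + γ λ_spawn n_backward))` with n_backward = 1.285
backward fronts per spawning event and γ the probability that a backward
front meets the next front, γ = 1 in the distant limit. Interacting
fronts replace the propensities with per-interval event probabilities
averaged over the geometric slot-gap distribution
(`Σ q(1−q)^{k−1} p(k T_slot)`, truncated at k_max = 200 with the tail mass
assigned the last value) and
`γ = Σ q(1−q)^{k−1} max(0, 1 − k v T_slot / 2L)`; the combined elimination
probability uses the product form
`p = 1 − (1 − p_fail)(1 − γ p_spawn n_backward)`, first-order equivalent
to the additive one and guaranteed to stay in [0, 1]. The timing
correction takes the transit time Gaussian with variance σ₀²L, computes
`p_accurate = erf(T_slot / (2√2 σ₀ √L))`, inflates the erasure to
`p' = p + (1−p)(1−p_accurate)`, adds the fake-detection probability
`p_fake = q(1−p)(1−p_accurate) − ¼q²(1−p)²(1−p_accurate)²`, and evaluates
the generic matrix MI. All matrices are validated to be joint
distributions with row sums (1−q, q); the general-q MI always goes through
the matrix rather than a transcribed closed form, and reduces to
`1 − ½[(p+1)log₂(p+1) − p log₂ p]` at q = ½ to machine precision.

## Problem sizes and what the tests show

The test-suite and acceptance campaigns run at reduced but statistically
controlled sizes, chosen once: 1200–6000 single-front runs per width for
the transit-variance law (30000 on the short fallback channel at W = 3 —
variance estimates need far more samples than means, and the narrow widths
carry the most 1/W leverage), 350–700 runs per width for the rate-law fit
over the failure-dominated widths W = 2..5, 1500–3000 two-front runs for
the interaction probabilities, and 10 sequences × 200 slots per grid point
for the bitrate scan at L = 30. Every simulation in a campaign gets its
own RNG stream (wide per-width seed strides), since overlapping seed
ranges on different lattices produce subtly correlated draws that a
regression over widths does not average away.
Stochastic comparisons use three combined standard errors (both the run
and the reference value are Monte-Carlo estimates) plus the printed
precision of the reference. Under these conditions the closed forms are
exact; the simulator reproduces the asymptotic speed, the rate-law slope,
the spawn direction statistics, the transit-variance law and the
short-channel bitrate optimum.

All inputs are synthetic by construction — the model is the object of
study, not a fit to data — so the tests demonstrate internal consistency
and agreement with the published analysis of the same model, not anything
about real ERK waves: cell motility, division, heterogeneous per-cell
parameters (extrinsic noise) and continuous-space dynamics are outside the
model.

## Numerical choices

Kymograph bins are 1 min, matching the Δt resolution of the MI estimator.
Event-buffer overflows trigger a deterministic rerun with a doubled
buffer. Seeds derive from a master seed via truncated SHA-256 of the task
coordinates (stable across platforms, always < 2³¹); scan drivers key
completed points by config hash and skip them on resume. Simulation
horizons are one deterministic transit plus 5–10 refractory times beyond
the last initiation — generous enough for late spawns to play out, short
enough to keep batches fast. Series truncation (geometric averages, γ) is
k_max = 200 with an analytic tail bound well below 10⁻⁶ for q = ½.

## Known limitations

- Tracking constants (smoothing widths, thresholds, linker reach, fate
  margins) are validated against event-log ground truth but remain
  operational choices; quantities defined through them (immediate-failure
  probability, event positions) carry a few percentage points of
  definitional uncertainty.
- The greedy linker resolves near-symmetric splits arbitrarily (the parent
  may continue into either branch); direction statistics of freshly
  spawned tracks are unaffected.
- `pair_event_probabilities` classifies the *second* front only; the
  "spawning" and "annihilation" categories blur when the first front's
  tail spawns inside the classification window, exactly as in any
  track-based operationalization.
- The semi-analytic interacting level needs per-length pair-probability
  curves as inputs; it does not correct for forward-spawned fronts.
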