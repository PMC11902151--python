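# qeirq

Stochastic simulation and information-theoretic analysis of traveling
activity fronts in cell-monolayer channels — the kind of excitable
MAPK/ERK wave that relays a signal from a wound edge across many cell
layers by neighbor-to-neighbor activation.

## The model

Each cell on a triangular-lattice channel (width *W* rows, length *L*
layers, periodic or inert side boundaries) is a four-state excitable unit:

```
Q  --activation-->  E_1 … E_nE  -->  I_1 … I_nI  -->  R_1 … R_nR  -->  Q
```

A **q**uiescent cell is activated at rate `n_I_neighbors / τ_act` by
**i**nducing neighbors; the **e**xcited, inducing and **r**efractory
states are chains of exponential substates, so their residence times are
Erlang with means τ_E, τ_I, τ_R and variances τ²/n. Nominal parameters:
τ_act = 1, τ_E = 4, τ_I = 2, τ_R = 60 min with n_E = 4, n_I = 2, n_R = 4.
Dynamics are simulated exactly (direct-method kinetic Monte Carlo, numba
accelerated); fronts are initiated by switching the quiescent cells of the
first layer to I₁.

The analysis stack around the simulator covers:

- **Front tracking** (`qeirq.tracking`): kymograph smoothing, per-bin peak
  detection, greedy linking with gap closing, split/spawn detection, and
  fate classification (arrived / annihilation / immediate failure /
  propagation failure).
- **Disruptive-event rate laws** (`qeirq.event_stats`): per-layer
  propensities of propagation failure and front spawning,
  `λ_fail(W) = exp(a_fail (W − W_fail))` and
  `λ_spawn(W) = a_spawn (W − W_spawn)`, their least-squares fits, the
  optimal channel width minimizing `λ_tot = λ_fail + λ_spawn`, transit-time
  statistics `σ₀²(W) = a/W + b`, and pair-front interaction scans.
- **Information transmission** (`qeirq.info_channel`): binary slot protocol
  (a front is sent or not every `T_slot` minutes), Δt decoding against the
  expected arrival time, a binned nearest-neighbor estimator of
  H(S | Δt) with Miller–Madow bias correction, and bitrate
  `r = MI_slot / T_slot`.
- **Semi-analytic channel theory** (`qeirq.theory`): front-extinction
  probability from the rate laws, the 2×2 confusion-matrix MI
  `MI_slot = 1 − ½[(p+1)log₂(p+1) − p log₂ p]` at q = ½, geometric
  interval averaging, the backward-front collision fraction γ, and the
  transit-time (slot misassignment) correction.

## Worked example

```python
from qeirq import (NOMINAL_PARAMETERS, build_geometry, cycle_statistics,
                   deterministic_inverse_speed, make_schedule, run_simulation,
                   arrivals_at_end)
from qeirq.tracking import track_kymograph

p = NOMINAL_PARAMETERS
cs = cycle_statistics(p)
print(f"deterministic v^-1 : {deterministic_inverse_speed(p):.1f} min/layer")
print(f"T_cycle            : {cs.t_cycle:.1f} min")
print(f"sigma_cycle        : {cs.sigma_cycle:.1f} min")
print(f"T_R (effective)    : {cs.t_refractory:.1f} min")

geom = build_geometry(6, 300, "periodic")
rec = run_simulation(p, geom, make_schedule("single"), seed=42)
arr = arrivals_at_end(rec)
print(f"events             : {rec.n_events}")
print(f"arrival at layer {geom.length - 1}: t = {arr[0]:.0f} min "
      f"(v^-1 = {arr[0]/geom.length:.2f} min/layer)")
tracks, spawns = track_kymograph(rec.kymograph, geom)
print(f"tracks             : {len(tracks)} ({tracks[0].fate}), "
      f"spawning events: {len(spawns)}")
```

prints

```
deterministic v^-1 : 4.5 min/layer
T_cycle            : 66.5 min
sigma_cycle        : 30.1 min
T_R (effective)    : 96.6 min
events             : 19809
arrival at layer 299: t = 1059 min (v^-1 = 3.53 min/layer)
tracks             : 1 (arrived), spawning events: 0
```

The closed-form block gives the model's characteristic times: a
deterministic front advances one layer per 4.5 min, a cell needs
66.5 ± 30.1 min for a full Q→E→I→R→Q cycle, and the effective refractory
time T_R ≈ 96.6 min sets the shortest usable spacing between consecutive
fronts. The stochastic run shows a single front crossing a W = 6, L = 300
channel faster than the deterministic bound (rough front edges see more
than two inducing neighbors), tracked end to end with no disruptive event.

A command-line interface mirrors the library
(`qeirq simulate | track | rates | pairs | info | predict | scan`); e.g.

```bash
qeirq rates --widths 2:8 --nsims 300 --seed 1 --out rates.csv
qeirq info  --tslot 60:150:15 --nseq 10 --nslots 200 --out info.csv
```

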