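# Methods

## Model

The circuit is a one-dimensional, rate-based implementation of Barlow–Levick
nulling inhibition, extended with onset and offset detector stages.  All cells
obey the shunting membrane equation

```
τ ẋ = A(0 − x) + (α − x) I_exc − B(ω + x) I_inh ,
```

whose solution is confined to `[−ω, α]`: at `x = α` the net drive is
non-positive, at `x = −ω` the inhibitory term vanishes and the net drive is
non-negative.  The rectified activity `[x]⁺` stands in for a firing rate.
Simplifications adopted deliberately: no spiking, no conductance delays, no
receptive-field structure beyond nearest-neighbour taps, a single decay rate
shared by all layers, and a purely one-dimensional spatial arrangement.  The
temporal asymmetry that a Barlow–Levick detector needs is supplied entirely by
the slow passive decay of interneuron activity (an activity "trace"), not by
an explicit delay line.

Connectivity, per position `i` and direction `d` (off-grid taps contribute
exactly zero):

| layer | excitation | inhibition |
|---|---|---|
| interneuron | local input `I_i` | opposite-direction interneuron one position ahead |
| directional | local input `I_i` | same source as its interneuron |
| short-range filter (SRF) | `10 · [dir_i]⁺ · [dir_behind]⁺` | — |
| onset | SRF one position ahead | SRF at own position, same direction |
| offset | SRF one position behind | SRF at own position, same direction |

The onset cell's inhibitory tap is a genuinely open design point: a
same-direction veto is the only variant that cancels the null sequence
(constant motion that already swept the cell's own position) and mirrors the
offset cell's wiring, so it is the default; the opposite-direction variant
remains selectable (`onset_inh_opposite` in the readout configuration /
`inh_opposite=` in `onset_rhs`) for sensitivity analysis.  With the opposite
tap, onset cells fire at every position during constant motion and onset
selectivity collapses at low speeds, which contradicts the intended phenomeno-
logy; this is easy to verify with the switch.

## Stimulus and LGN front-end

The input is a binary occupancy indicator: a contrast patch appears at
position 2 at `t = 0`, occupies one position for `1/v` time units (half-open
intervals — the switch instant belongs to the later interval, following the
floor-function definition), and vanishes after leaving position 6.  Boundary
positions 1 and 7 never receive input.  The indicator is scaled by a
speed-dependent gain `J_v`, the modulus of a magnocellular-LGN temporal
transfer function (Benardete–Kaplan form): one contrast-gain high-pass stage
(time constant `τ_S`) times a cascade of `N_L` low-pass stages (time constant
`τ_L`), evaluated at the temporal frequency `ω = 2π f_S v` swept by the patch.

Front-end constants (defaults): `H_S = 1.00`, `τ_L = 1.68 ms`, `N_L = 25.50`,
`C_1/2 = 0.048`, `f_S = 2.181 cyc/°`, contrast `c = 0.1`, and `F = 2.206`, the
normalizer that sets the peak of `J_v` to 1.  `T_0`, the zero-contrast value
of `τ_S`, defaults to `44.96 ms`: numerically inverting the normalization
condition shows `F = 2.206` requires `τ_S(c = 0.1) = 8.419 ms`, i.e. exactly
this `T_0`; a tenfold smaller value sometimes quoted for this constant would
put the peak at 0.133/2.206 and is inconsistent with the stated normalization.
With these defaults `J_v` peaks at ≈ 6.8 °/s and vanishes in both speed
limits (the DC response is zero because `H_S = 1`).

Two unit systems meet here: the network runs in positions per simulation-time
unit (`v_model`), the front-end in degrees per second.  The bridge is
`v_physical = v_model · w` with `w = 10 °/s`, the same constant used by the
reaction-time transform; it is the only printed conversion between the two
systems and is applied consistently in both directions.

A zero-contrast patch is treated as invisible (zero drive), not as a stimulus
with a well-defined transfer modulus: `lgn_gain` remains the pure transfer
function, while `drive_amplitude` gates it by contrast presence.

What the generated stimulus emulates — and what it does not: it reproduces
abrupt motion onset and offset of a single rigid contrast patch at constant
speed on a short line of positions.  It has no spatial extent, no varying
contrast, no acceleration profiles, no two-dimensional trajectories, and no
noise; conclusions from passing tests therefore concern the circuit mechanism,
not the variability or geometry of real stimuli.

## Readouts

Each evidence accumulator obeys the same shunting equation slowed by `C = 10`
(input-on time constant `C·τ/A = 100` time units at defaults), excited by
"correct" and inhibited by "incorrect" rectified cell activities, reading the
network one-way.  Selectivity is the peak accumulator activity over the run;
neural latency is the first crossing of the 0.1 activity threshold, located by
linear interpolation between dense samples, reported relative to motion onset
(`t = 0`) for the onset and direction accumulators and to the input-vanishing
time (`n_swept / v`) for the offset accumulator.  The direction accumulator
has no obvious "event" of its own; motion onset is the only unambiguous
reference, and that choice is fixed here.  A latency is *undefined* (missing
in all outputs, never a sentinel) when the threshold is never reached.
Reaction times are `RT = c/s + r` (`c = 100 ms`, `r = 175 ms`); selectivities
below 1e-6 yield missing RTs rather than astronomically large ones, since
other (undirectional) channels would dominate detection at such speeds.

## Numerics

* **Integration.**  Adaptive Runge–Kutta 4(5) (`scipy.integrate.solve_ivp`,
  RK45), relative tolerance 1e-8, absolute 1e-10.  The drive is piecewise
  constant, so the integrator is restarted at every input switch time `m/v`
  and never steps across a discontinuity; each segment receives its exact
  constant drive vector rather than a time-based lookup, avoiding
  floating-point ambiguity at the boundaries.  Halving the tolerances changes
  peak activities by far less than 1e-5 (tested).
* **Sampling.**  Dense output on a uniform grid of `0.01·τ` plus all switch
  instants; the default horizon is `n_swept/v + 100·τ` so the slow
  accumulators can peak, with a runtime warning if a peak falls on the final
  sample.
* **Accumulator integration.**  Co-integrated with the network by default
  (one combined ODE system); a post-hoc route integrating against linearly
  interpolated tapped activities on the dense grid is provided and agrees
  with co-integration to better than 1e-5 (tested).
* **LGN peak search.**  400 log-spaced speeds over `[1e-2, 1e3] °/s`, then
  bounded scalar minimization in log-speed to 1e-8 tolerance; the gain is
  unimodal in speed at the defaults.
* **State layout.**  The flat state vector is layer-major (interneuron,
  directional, SRF, onset, offset), then position (1…n), then direction
  (leftward before rightward) — fixed for reproducibility.
* **Degenerate inputs.**  Zero-contrast stimuli yield identically zero
  trajectories and empty event summaries; out-of-band speeds yield near-zero
  selectivities and undefined latencies; negative drives, out-of-range
  indices, and malformed state vectors raise immediately.

## Experiment defaults

The default speed sweep covers 60 log-spaced model speeds over
`[1e-2, 1e2]` (physical `0.1–1000 °/s`), comfortably bracketing the
LGN-responsive band.  The parameter sweep perturbs `A`, `B`, and `τ`
multiplicatively over `{0.1, 1, 10}`; the unscaled block is computed once and
shared, so its rows are bitwise identical across parameter blocks.  The test
suite exercises the parameter sweep on coarser grids (5–9 speeds), which
suffices to resolve the qualitative effects it asserts (selectivity loss at
small `B`, band shift toward higher speeds at small `τ`).  Everything is
deterministic; identical configurations reproduce byte-identical tables.

## Known limitations

* With default parameters, onset selectivity exceeds offset selectivity by a
  small margin (≈ 7e-3 at the low-speed band edge, shrinking to ≈ 1e-3 at the
  high edge) throughout the responsive band: offset selectivity is boosted
  *relative* to onset selectivity as speed grows but does not overtake it
  while directional selectivity is still appreciable.  The overtaking would
  require the weakly-directional high-speed regime (interneuron traces too
  brief to null the opposite direction, `v_model ≳ 3`), which the LGN envelope
  silences first under the `w = 10 °/s` unit bridge.
* The reaction-time curve carries ~0.1% ripples near its shallow minimum,
  an artifact of the discrete position sweep beating against the accumulator
  time constant; trend statements about RT vs speed should be read at coarser
  resolution than those ripples.
* The quantitative shape of empirical reaction-time curves is not reproduced,
  only their qualitative orderings; the power-law form is provided for
  overlay, not fitted.
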