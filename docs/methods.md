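# Methods

This note documents the model, the numerical choices, the packaged reduced
study conditions, and what they do and do not demonstrate.

## Membrane model

The cell is a rooted tree of cylindrical compartments, each labeled soma,
main, smooth, or spiny dendrite; the label selects the channel inventory:

| type   | channels |
|--------|----------|
| soma   | Leak, NaF, NaP, CaT, Kh1, Kh2, Kdr, KM, KA |
| main   | Leak, CaP, CaT, Kdr, KM, KA, KC, K2 |
| smooth | Leak, CaP, CaT, KM, KC, K2 |
| spiny  | Leak, CaP, CaT, KM, KC, K2 |

Passive parameters: `c_m` = 1.64 µF/cm², axial resistivity `R` = 250 Ω·cm,
leak reversal −80 mV.  Spiny compartments carry a spine-area compensation
factor (default 5.3) on both `c_m` and the leak conductance density
(0.53 vs 0.1 mS/cm² elsewhere), standing in for the membrane of unmodeled
spines; without it the spiny dendrite is unrealistically excitable and a
single sub-nA pulse triggers a dendritic Ca²⁺ spike.

Axial coupling between adjacent compartments uses the series combination of
half-compartment resistances `R·(L/2)/(πa²)`, which reduces exactly to the
second-difference cable operator on a uniform chain.  Terminals are sealed
(zero flux).

### Units

mV, ms, µm, µF/cm², mS/cm², Ω·cm, nA; current density in µA/cm²; Ca²⁺ in
µM.  All conversions live in `pcseq.units`.

## Channel kinetics

Gate dynamics are first order, `τ_x(v) dx/dt = x_∞(v) − x`.  NaF, NaP, CaP,
CaT and KA define `x_∞` and `τ` through rate functions α(v), β(v); the
remaining channels specify `x_∞(v)` and `τ(v)` directly.  Every rate or
steady-state function is one of five named functional forms (constant,
exponential, sigmoid, Gaussian bell, double exponential) with coefficients
stored in `src/pcseq/data/purkinje_channels.json`, so the kinetics are
auditable and swappable without touching the solver.  Coefficients are
transcribed from the classic Purkinje-cell compartmental model's published
kinetics; where a published form could not be reproduced verbatim (the Kdr
time-constant shape, the KC/K2 calcium terms) a standard form with values in
the published range was substituted and marked in the file's metadata.

Design choices:

* **Ca²⁺ reversal** is a fixed Nernst-style E_Ca = +135 mV, not GHK — a
  documented fidelity knob, configurable per channel.
* **KC/K2 calcium dependence** enters as a multiplicative Hill term
  `ca/(ca + K)` on the activation steady state (K = 3 µM for KC with an
  additional voltage sigmoid; K = 0.2 µM for the purely Ca-gated K2).
* **Calcium pool**: one first-order submembrane shell per compartment,
  depth 0.2 µm, τ_Ca = 20 ms, rest 0.04 µM, fed by the CaP/CaT current
  through the shell/Faraday scale factor; [Ca²⁺] is floored at zero.
* **τ-scaling**: the perturbation factor `f` multiplies only the
  inactivation (h) time constant of CaP or CaT, the two channels whose slow
  inactivation is the candidate memory variable.

## Numerical integration

Two methods share identical Rush–Larsen (exponential) gate and calcium
updates, exact for frozen voltage:

* **explicit** (default, numba-compiled): each compartment's voltage is
  advanced by a local exponential update in which the instantaneous ionic
  conductance acts through the membrane time constant and the axial +
  external current is a frozen source.  The update degenerates smoothly to
  forward Euler as the local conductance vanishes, which preserves exact
  charge conservation for pure diffusion.  This handles the very stiff
  somatic NaF/Kdr densities (local τ ≈ 0.2 µs during a spike) that would
  blow up a plain forward-Euler step at any practical dt.  The axial term
  remains explicit, so the classic diffusion bound
  `dt < c_m A_j / Σ g_ax` (uniform-chain form `c_m R Δx²/a`) is enforced at
  setup with a 0.8 safety factor; violating it is a configuration error,
  not a silent blow-up.  Default dt = 5 µs.
* **implicit_reference**: backward-Euler voltage update via a Hines
  (tree-ordered) elimination, unconditionally stable, default dt = 50 µs.
  It is the numerical oracle: the test suite requires soma traces of the
  two methods to agree within 1 mV on an active fixture, and the measured
  disagreement is ~0.02 mV.

Initialization sets a uniform voltage (default: leak reversal), every gate
at its local steady state, calcium at rest, then integrates a zero-input
settling window (default 200 ms; the packaged experiments use 500 ms).  The
settled model rests near −68 mV at the soma and does not spike
spontaneously (max |dv/dt| < 0.01 mV/ms), which is what makes spiking a
clean response readout.  Experiments reuse one settled state across all
protocol evaluations; the solver itself is deterministic, so identical
configurations produce bit-identical traces.

Verified analytic limits (also recomputed by `scripts/acceptance.py`):
steady-state profile of a sealed passive cable under end current matches the
`cosh((L−x)/λ)/sinh(L/λ)` solution to < 0.01 % at 25 compartments;
sealed-diffusion total charge is conserved to machine precision over
hundreds of steps; a single passive compartment reproduces the RC closed
form to < 1 µV.

## Stimulation

A sequence fires one 1-ms pulse per path compartment at interval `Δ`:
pulse *i* at `onset + i·Δ`.  IN traverses the path distal→proximal, OUT
proximal→distal, with identical compartments, times, and weights — injected
charge is direction-invariant by construction (a tested invariant), so
direction sensitivity can never be an input artifact.  Two pulse shapes are
provided: ideal rectangular (default) and the ramped variant
`w(1 − e^{−(t−t_j)/τ_I})`, τ_I = 50 ms, which the original experiments used
against numerical instability.  Note the ramped pulse delivers only ~2 % of
`w` over its 1-ms window; with the stiff-stable integrator the ideal pulse
needs no such smoothing, so it is the default and the ramped mode is kept
for fidelity comparisons.

Durations are bookkept as `n·Δ` (so 6 pulses × 10 ms = 60 ms and
20 × 200 ms = 4,000 ms, the shortest and longest classically discriminable
sequences) while the physical last-pulse offset `(n−1)Δ + 1 ms` is also
available.

Sweep grids enumerate `n_pulses × interval × weight` with IN/OUT pairs in
deterministic order.  Defaults reproduce the full study dimensions:
n = 2..20 (19 values), interval = 10..200 ms step 10 (20 values), and 20
weights evenly spaced over 0.5–10 nA.  (The narrative range "1–10 nA every
0.5 nA" yields 19 values although 20 strengths are reported, and the quoted
example weights sit on a ×0.99 grid; the 20-value even spacing resolves
this explicitly and the grid is fully config-driven.)

## Response classification

A spike is an upward crossing of 0 mV with ≥ 2 ms separation (the source
experiments report only spiking vs non-spiking; these detector values are
unambiguous for Hodgkin–Huxley somatic spikes and are configurable).  A
sequence "responded" if ≥ 1 spike falls between the first pulse onset and
the last pulse offset plus a 500 ms grace window.  Each (IN, OUT) pair is
classified BOTH / IN_ONLY / OUT_ONLY / NEITHER; the discriminated ratio is
(IN_ONLY + OUT_ONLY)/total, and multi-cube summaries average per-cube
ratios unweighted (cube sizes differ).

## Plasticity

Weight updates run on a dedicated 1-ms plasticity tick, decoupled from the
solver dt: the literal rule adds A₃ every Δt and would diverge as Δt → 0,
so the tick makes the drift's cumulative effect step-size independent while
preserving the rule's intent.  Within a tick, traces first decay and absorb
that tick's events, then `Δw_j = −A₁ y S_j + A₂ x_j S + A₃` is applied with
total clamping to [0, 12.87] nA.  The CF is a trace event only (no
biophysical CF current is injected); it fires 2 ms after the last pulse
offset.  τ_pre = τ_post = 100 ms by default — these are not fixed by the
source model; they are set to the order of the stimulus intervals and are
prominent, mandatory-visible configuration.

Because the weight dynamics depend only on the PF/CF event times, the
learning trial does not need the membrane simulation; it is run (optionally)
only when a trace of the trial itself is wanted.  With a single
presentation and the CF after the last pulse, `y = 0` at every PF event and
the LTD term is inert — only the A₃ drift acts.  This tension is inherent
to the protocol as stated; the package therefore supports
`presentations ≥ 1` per 5,000 ms trial (default 1), and with ≥ 2 the CF of
one presentation depresses the next presentation's pulses in a graded,
order-dependent way.  Results must name the mode used.

The reversal search takes every previously direction-selective sequence,
learns on its responsive direction, re-tests both directions with learning
off and the learned per-compartment weights substituted for the uniform
sweep weight, and reports (class before, class after) plus the strictly
flipped subset (IN_ONLY ↔ OUT_ONLY).

## The reduced synthetic morphology and study conditions

`generate_reduced` builds layered trees (soma → main → smooth → spiny) with
configurable counts, branching, and geometry.  The packaged default is a
39-compartment chain (2 main × 40 µm × r3 µm, 6 smooth × 40 µm × r1.5 µm,
30 spiny × 40 µm × r0.8 µm, soma 30 × r15 µm).  The geometry was chosen
once so that the spiny passive length constant (~400 µm) spans several
compartments — sequential stimulation must be partially, not instantly,
coupled for order to matter — and so that the explicit stability bound
comfortably admits the default dt.

The packaged experiments (`pcseq.presets`) scan a 5-compartment path at the
distal tip over intervals {10, 20, 30, 40, 60} ms and weights
{1.4, 1.5, 1.6, 1.7} nA.  On this tree single pulses below ≈1.8 nA are
subthreshold, so the scan brackets the spiking boundary where temporal
summation — and therefore sequence order — decides.  Observed outcome: 10
of 20 cells spike, 4 respond to exactly one direction (OUT_ONLY; at this
scale the boundary happens to favor OUT), and classes sit exactly at the
spiking/silent border, as in the full-scale cubes.  The τ-scan over
f ∈ {0.1, 1, 3} at the same conditions shows monotone recruitment of
spiking with slower CaT inactivation (f = 3 adds a spiking and a selective
cell) and no increase in selectivity at f = 0.1.  The learning smoke
experiment uses deliberately aggressive constants (A₁ = 2.0,
τ_post = 400 ms, A₃ = 5×10⁻⁴, two presentations) so a single 5,000-ms trial
visibly moves classes: all retested selective sequences change class
(OUT_ONLY → BOTH, dominated by the A₃ drift plus graded LTD); strict
direction reversal at this scale would require repeated trials.

### What the reduced scale does and does not show

It demonstrates the mechanisms end-to-end — boundary-localized direction
selectivity, its dependence on the CaT inactivation clock, and
plasticity-driven class movement — on a tree two orders of magnitude
smaller than the original 1,600-compartment cell.  It does **not**
reproduce the full-scale numbers (per-cube class counts, the ~3 % mean
discriminated ratios, the main-dendrite zero-OUT asymmetry): those depend
on the real morphology's load and branching and on thousands of
multi-second trials.  The pipeline supports the full scale (the `.p` reader
maps the original file's 1/9/105/1,485 type counts; grids and cube anchors
are config inputs), and the structural machinery is exercised on a
generated synthetic tree with exactly those counts.

## Known limitations

* No GHK formalism for Ca²⁺ currents; single Ca shell rather than radial
  diffusion; no stochastic gating or temperature corrections.
* Inputs are current pulses, not conductance-based synapses.
* The model does not fire simple spikes spontaneously (by design — spiking
  is the readout); pause-based coding for spontaneously active models is
  out of scope.
* The kinetics file is a transcription of a 1990s-era model; its direct
  successors add channels and realistic Ca²⁺ handling that this package
  does not attempt.
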