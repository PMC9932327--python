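# pcseq

Compartmental simulation of temporal input-sequence discrimination in a
cerebellar Purkinje cell, with climbing-fiber-gated LTD that can retrain the
cell's direction preference.

## The scientific problem

Cerebellar Purkinje cells (PCs) receive parallel-fiber (PF) input across an
enormous dendritic tree.  If a row of dendritic sites is stimulated
*sequentially* — distal-to-proximal ("IN") or proximal-to-distal ("OUT") —
does the soma's spiking output depend on the order?  In a biophysical PC
model it does: for a narrow band of pulse weights and inter-pulse intervals
the cell fires for exactly one direction, so a single neuron acts as a
sequence discriminator on the hundreds-of-milliseconds timescale relevant to
motor control.  The memory substrate is the slow inactivation of dendritic
Ca²⁺ channels (the T-type channel in particular), not NMDA receptors as in
cortical pyramidal cells.  Pairing a sequence with a delayed climbing-fiber
(CF) teaching signal drives LTD of the PF weights and can move, or even
reverse, the preferred direction.

`pcseq` is a from-scratch implementation of that experiment pipeline for
researchers in dendritic computation: a branched-cable Hodgkin–Huxley solver,
the four-compartment-type PC channel inventory, directional pulse-train
protocols and sweep grids, spike-based response classification, a
Ca²⁺-channel time-constant (τ) perturbation scan, and a trace-based STDP/LTD
rule.

## Model

Each compartment *j* of a labeled tree (soma / main / smooth / spiny
dendrite) obeys the discretized cable equation

```
c_m dv_j/dt = (1/A_j) Σ_n g_ax(j,n) (v_n − v_j) − Σ_k I_k(v_j) + I_ext,j / A_j
```

with Hodgkin–Huxley currents `I_k = g_k m^q h^r (v_j − E_k)`.  Gates evolve
as `τ_x(v) dx/dt = x_∞(v) − x`; five channels (NaF, NaP, CaP, CaT, KA)
define `x_∞ = α/(α+β)`, `τ = 1/(α+β)` from rate functions, the others give
`x_∞` and `τ` directly.  Twelve channel types are distributed by compartment
class (e.g. spiny dendrites: Leak, CaP, CaT, KM, KC, K2); KC and K2 sense a
first-order submembrane Ca²⁺ shell fed by the CaP/CaT currents.  All
kinetics are data, not code: a JSON file of named functional forms and
coefficients (`src/pcseq/data/purkinje_channels.json`).

Stimulation delivers one 1-ms current pulse per path compartment,
`I_ext,j = w_j` for `0 ≤ t − t_j < 1 ms` (a ramped variant
`w_j (1 − e^{−(t−t_j)/τ_I})` is also provided); IN and OUT use identical
compartments, times and weights, so any response difference is pure sequence
order.  Plasticity follows the trace rule

```
x_j(t) = e^{−Δt/τ_pre} x_j(t−Δt) + S_j(t)      (PF trace)
y(t)   = e^{−Δt/τ_post} y(t−Δt) + S(t)         (CF trace)
Δw_j   = −A₁ y S_j + A₂ x_j S + A₃,   w_j ∈ [0, 12.87] nA
```

with A₁ = 0.9, A₂ = 0, A₃ = 0.001 (LTD-dominant; A₃ models slow AMPA
receptor reinsertion).

Two integrators share identical gate updates: a compiled explicit
exponential-Euler scheme (default, dt = 5 µs, stability-checked) and a
backward-Euler tree solve (`implicit_reference`) used as its numerical
oracle.

## Worked example

The packaged reduced morphology (39 compartments: 1 soma, 2 main, 6 smooth,
30 spiny) is scanned over a weight × interval grid at the spiking boundary,
where single pulses are subthreshold and sequence order decides:

```
$ pcseq sweep --config examples/reduced.toml
{"class_counts": {"BOTH": 1, "IN_ONLY": 0, "OUT_ONLY": 3, "NEITHER": 2},
 "discriminated_ratio": 0.5}
```

Three of six (weight, interval) cells spike **only** for the OUT direction —
the cell discriminates the sequence.  Pairing each selective sequence with a
delayed CF stimulus under aggressive LTD and retesting:

```
$ pcseq learn --config examples/reduced.toml
{"before": {"BOTH": 1, "IN_ONLY": 0, "OUT_ONLY": 3, "NEITHER": 2},
 "n_retested": 3, "n_flipped": 0}
```

All three retested sequences change response class after one learning trial
(here OUT_ONLY → BOTH; a strict direction reversal needs repeated trials).
`pcseq tau-scan --config examples/reduced.toml --channel CaT` repeats the
scan with the CaT inactivation time constant scaled by a factor *f*:
shrinking it (f = 0.1) never increases the number of direction-selective
cells, while slowing it (f = 3) recruits additional spiking — the T-type
channel's inactivation clock is the memory that spans the inter-pulse
interval.

Other subcommands: `pcseq simulate` (single protocol → soma trace CSV),
`pcseq make-fixture` (synthetic morphologies in SWC / GENESIS `.p` / JSON),
`pcseq validate` (inventory + solver cross-checks).

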