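"""Trace-based STDP/LTD rule and the CF-pairing learning experiments.

Each stimulated compartment j carries a presynaptic trace
x_j(t) = exp(-dt/tau_pre) x_j(t-dt) + S_j(t), and the climbing-fiber (CF)
teaching signal carries a postsynaptic trace
y(t) = exp(-dt/tau_post) y(t-dt) + S(t).  On every plasticity tick the
parallel-fiber weight updates as

    dw_j = -A1 y S_j + A2 x_j S + A3,

clamped to [0, 12.87] nA.  With the published constants (A1=0.9, A2=0,
A3=0.001) the rule is LTD-dominant: a parallel-fiber pulse arriving while
the CF trace is non-zero is depressed, while A3 models the slow reinsertion
of AMPA receptors (a constant drift toward recovery).

Weight updates run on a dedicated plasticity tick (default 1 ms) decoupled
from the solver dt, so the cumulative A3 drift is step-size independent.
Note that with a single presentation and the CF delivered after the last
pulse, y = 0 at every S_j event and the LTD term is inert; multiple
presentations within the trial let the CF of one presentation depress the
pulses of the next.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .discrimination import (ResponseClass, SpikeDetectorConfig, classify,
                             spiked_in_window)
from .solver import CompiledModel, SolverConfig, run
from .stimulation import Direction, PulseTrainSpec, make_protocol, schedule


class PlasticityConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlasticityParams:
    tau_pre: float = 100.0    # ms (not fixed by the source model; order of
    tau_post: float = 100.0   #     the stimulus intervals)
    a1: float = 0.9
    a2: float = 0.0
    a3: float = 0.001         # per plasticity tick
    w_min: float = 0.0        # nA
    w_max: float = 12.87      # nA
    tick: float = 1.0         # ms, weight-update clock

    def __post_init__(self):
        if min(self.tau_pre, self.tau_post, self.tick) <= 0:
            raise PlasticityConfigError("tau_pre, tau_post, tick must be positive")
        if self.w_min > self.w_max:
            raise PlasticityConfigError("w_min must not exceed w_max")


@dataclass
class TraceState:
    """Per-compartment presynaptic traces, the CF trace, and the weights."""

    x: dict[int, float]   # compartment id -> x_j
    y: float              # CF trace
    w: dict[int, float]   # compartment id -> weight, nA

    @classmethod
    def initial(cls, path, weight: float) -> "TraceState":
        return cls(x={cid: 0.0 for cid in path}, y=0.0,
                   w={cid: float(weight) for cid in path})


def update_trace(x: float, s: int, dt: float, tau: float) -> float:
    """One tick of the exponential trace: x' = exp(-dt/tau) x + S."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return math.exp(-dt / tau) * x + s


def clamp_weight(w: float, p: PlasticityParams) -> float:
    return min(max(w, p.w_min), p.w_max)


def weight_update(ts: TraceState, s_j: dict[int, int], s: int,
                  p: PlasticityParams) -> TraceState:
    """Apply dw_j = -A1 y S_j + A2 x_j S + A3 with total clamping."""
    new_w = {}
    for cid, w in ts.w.items():
        dw = -p.a1 * ts.y * s_j.get(cid, 0) + p.a2 * ts.x[cid] * s + p.a3
        new_w[cid] = clamp_weight(w + dw, p)
    return TraceState(x=dict(ts.x), y=ts.y, w=new_w)


@dataclass(frozen=True)
class LearningProtocol:
    sequence: PulseTrainSpec
    cf_delay: float = 2.0          # ms after the end of stimulation
    trial_duration: float = 5000.0  # ms
    presentations: int = 1
    learning_enabled: bool = True

    def __post_init__(self):
        if self.cf_delay < 0:
            raise PlasticityConfigError("cf_delay must be >= 0")
        if self.presentations < 1:
            raise PlasticityConfigError("presentations must be >= 1")


def _event_times(lp: LearningProtocol) -> tuple[list[tuple[float, int]], list[float]]:
    """PF events [(t, compartment id)] and CF times over the whole trial.

    Presentations are spaced uniformly across the trial; each presentation's
    CF fires cf_delay after its last pulse offset."""
    seq = lp.sequence
    pf, cf = [], []
    period = lp.trial_duration / lp.presentations
    if seq.onset + seq.duration_physical + lp.cf_delay > period:
        raise PlasticityConfigError(
            f"sequence + CF ({seq.onset + seq.duration_physical + lp.cf_delay:.1f} ms) "
            f"does not fit in the per-presentation window ({period:.1f} ms)")
    for rep in range(lp.presentations):
        t0 = rep * period
        for cid, t_on, _ in schedule(seq):
            pf.append((t0 + t_on, cid))
        cf.append(t0 + seq.onset + seq.duration_physical + lp.cf_delay)
    return pf, cf


def learning_trial(model: CompiledModel | None, lp: LearningProtocol,
                   p: PlasticityParams,
                   solver_cfg: SolverConfig | None = None,
                   simulate: bool = False):
    """Run one learning trial and return (final weights, tick-level log).

    The weight dynamics are fully determined by the PF/CF event times, so
    the membrane simulation is optional (``simulate=True`` additionally
    integrates the model for the trial and is only needed when a somatic
    trace of the learning trial itself is wanted).

    Within a tick, traces first decay and absorb this tick's events, then
    the weight update is evaluated - so a CF and a PF pulse in the same tick
    interact (y includes the same-tick S).
    """
    seq = lp.sequence
    ts = TraceState.initial(seq.path, seq.weight)
    log_rows = []
    if lp.learning_enabled:
        pf, cf = _event_times(lp)
        pf_by_tick: dict[int, list[int]] = {}
        for t, cid in pf:
            pf_by_tick.setdefault(int(t // p.tick), []).append(cid)
        cf_ticks = {int(t // p.tick) for t in cf}
        n_ticks = int(math.ceil(lp.trial_duration / p.tick))
        for k in range(n_ticks):
            s = 1 if k in cf_ticks else 0
            cids = pf_by_tick.get(k, ())
            s_j = {cid: 1 for cid in cids}
            ts.y = update_trace(ts.y, s, p.tick, p.tau_post)
            for cid in ts.x:
                ts.x[cid] = update_trace(ts.x[cid], s_j.get(cid, 0), p.tick, p.tau_pre)
            ts = weight_update(ts, s_j, s, p)
            if s or cids:
                log_rows.append({"tick_ms": k * p.tick, "cf": s, "y": ts.y,
                                 "n_pf": len(cids),
                                 "w_mean": float(np.mean(list(ts.w.values())))})
    trace = None
    if simulate and model is not None:
        cfg = solver_cfg or SolverConfig()
        trace = run(model, make_protocol(seq, t_stop=lp.trial_duration), cfg)
    log = pd.DataFrame(log_rows, columns=["tick_ms", "cf", "y", "n_pf", "w_mean"])
    return ts.w, log, trace


def retest_classes(model: CompiledModel, seq_in: PulseTrainSpec,
                   seq_out: PulseTrainSpec, solver_cfg: SolverConfig,
                   det: SpikeDetectorConfig,
                   weights: dict[int, float] | None = None,
                   state=None) -> ResponseClass:
    """Evaluate both directions (learning off) and classify the pair.

    ``state`` optionally supplies a pre-settled initial state (reused,
    never mutated) to avoid re-equilibrating for every evaluation."""
    flags = {}
    for seq in (seq_in, seq_out):
        proto = make_protocol(seq, grace=det.grace, weights=weights)
        tr = run(model, proto, solver_cfg, state=state)
        window = (seq.onset, seq.onset + seq.duration_physical + det.grace)
        flags[seq.direction] = spiked_in_window(tr, window, det)
    return classify(flags[Direction.IN], flags[Direction.OUT])


def reversal_search(model: CompiledModel,
                    before: pd.DataFrame,
                    pairs: list[tuple[PulseTrainSpec, PulseTrainSpec]],
                    p: PlasticityParams,
                    lp_template: LearningProtocol,
                    solver_cfg: SolverConfig,
                    det: SpikeDetectorConfig | None = None,
                    state=None) -> pd.DataFrame:
    """For each previously direction-selective sequence: learn on the
    responsive direction, re-test both directions with the learned
    per-compartment weights, and report (class before, class after).

    ``before`` must align row-wise with ``pairs`` and carry a 'class'
    column.  The flipped subset is the rows whose exclusive direction
    inverted (IN_ONLY -> OUT_ONLY or vice versa).
    """
    det = det or SpikeDetectorConfig()
    rows = []
    for (_, brow), (seq_in, seq_out) in zip(before.iterrows(), pairs):
        cls_before = brow["class"]
        if cls_before not in (ResponseClass.IN_ONLY.value, ResponseClass.OUT_ONLY.value):
            continue
        learn_seq = seq_in if cls_before == ResponseClass.IN_ONLY.value else seq_out
        lp = replace(lp_template, sequence=learn_seq)
        w_learned, _, _ = learning_trial(model, lp, p)
        cls_after = retest_classes(model, seq_in, seq_out, solver_cfg, det,
                                   weights=w_learned, state=state)
        flipped = ({cls_before, cls_after.value}
                   == {ResponseClass.IN_ONLY.value, ResponseClass.OUT_ONLY.value})
        rows.append({
            "n_pulses": seq_in.n_pulses, "interval_ms": seq_in.interval,
            "weight_nA": seq_in.weight, "class_before": cls_before,
            "class_after": cls_after.value, "flipped": flipped,
            "w_learned_mean": float(np.mean(list(w_learned.values()))),
        })
    return pd.DataFrame(rows, columns=["n_pulses", "interval_ms", "weight_nA",
                                       "class_before", "class_after", "flipped",
                                       "w_learned_mean"])
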