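"""Cable-equation integration on branched morphologies.

The membrane equation per compartment j generalizes the 1-D discretized
cable equation to a tree:

    c_m dv_j/dt = (1/A_j) sum_n g_ax(j,n) (v_n - v_j) - sum_k I_k(v_j) + I_ext,j/A_j

with per-pair axial conductances built from half-compartment resistances
(reducing exactly to the second-difference form on a uniform unbranched
chain), sealed ends at terminals, and Hodgkin-Huxley channel currents.

Two integration methods share identical gate and calcium updates:

* ``explicit`` (default, compiled): local exponential update of v with the
  axial/external current frozen over the step.  Conditionally stable; the
  diffusion stability bound is checked at setup.
* ``implicit_reference``: backward-Euler voltage update via a tree-structured
  (Hines) linear solve.  Unconditionally stable; serves as the numerical
  oracle for the explicit scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel
from .channels import (ChannelSet, FORM_CODES, steady_state)
from .morphology import CType, Morphology
from .stimulation import Protocol, PulseMode
from .units import axial_conductance_uS, cylinder_area_cm2, ca_influx_scale

CTYPE_CODES = {CType.SOMA: 0, CType.MAIN: 1, CType.SMOOTH: 2, CType.SPINY: 3}


class ConfigError(ValueError):
    """Invalid solver configuration (including stability violations)."""


class IntegrationError(RuntimeError):
    """Non-finite state encountered during integration."""


@dataclass(frozen=True)
class SolverConfig:
    dt: float = 0.005                 # ms (explicit default; use ~0.05 implicit)
    method: str = "explicit"          # or "implicit_reference"
    settle_time: float = 200.0        # ms of zero-input equilibration
    record_ids: tuple[int, ...] | None = None  # soma always added
    record_stride: int = 10           # record every N steps
    v_init: float | None = None       # mV; default: leak reversal
    stability_safety: float = 0.8

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.settle_time < 0:
            raise ConfigError("settle_time must be >= 0")
        if self.method not in ("explicit", "implicit_reference"):
            raise ConfigError(f"unknown method {self.method!r}")
        if self.record_stride < 1:
            raise ConfigError("record_stride must be >= 1")


@dataclass
class SimulationState:
    """Dynamic state in compiled (topological) compartment order."""

    t: float
    v: np.ndarray          # [n] mV
    gates: np.ndarray      # [n, G]
    ca: np.ndarray         # [n] uM

    def copy(self) -> "SimulationState":
        return SimulationState(self.t, self.v.copy(), self.gates.copy(), self.ca.copy())

    def check_finite(self) -> None:
        if not (np.all(np.isfinite(self.v)) and np.all(np.isfinite(self.gates))
                and np.all(np.isfinite(self.ca))):
            raise IntegrationError(f"non-finite state at t={self.t:.4f} ms")


@dataclass
class RecordedTrace:
    times: np.ndarray              # ms, uniform stride
    v: np.ndarray                  # [n_times, n_recorded] mV
    ids: tuple[int, ...]

    def __getitem__(self, cid: int) -> np.ndarray:
        return self.v[:, self.ids.index(cid)]


class CompiledModel:
    """Morphology + channel set compiled to flat arrays for the kernel.

    Compartments are re-ordered topologically (parent before child); ``ids``
    maps compiled index -> compartment id.
    """

    def __init__(self, m: Morphology, cs: ChannelSet):
        self.morphology = m
        self.channel_set = cs
        ids = m.topological_ids()
        self.ids = list(ids)
        self.index = {cid: i for i, cid in enumerate(ids)}
        n = len(ids)
        self.n = n
        self.parent = np.full(n, -1, dtype=np.int64)
        self.area = np.empty(n)
        self.gax = np.zeros(n)  # uS to parent
        self.ctcode = np.empty(n, dtype=np.int64)
        pas = m.passive
        self.e_leak = float(pas.e_leak)
        self.cm = np.empty(n)
        for i, cid in enumerate(ids):
            c = m[cid]
            self.area[i] = cylinder_area_cm2(c.length, c.radius)
            self.ctcode[i] = CTYPE_CODES[c.ctype]
            # spine-area compensation: spiny membrane carries extra area
            factor = pas.spine_factor if c.ctype is CType.SPINY else 1.0
            self.cm[i] = pas.c_m * factor
            if c.parent_id is not None:
                p = m[c.parent_id]
                self.parent[i] = self.index[c.parent_id]
                self.gax[i] = axial_conductance_uS(pas.r_axial, c.length, c.radius,
                                                   p.length, p.radius)

        # channel tables
        chans = [c for c in cs.channels if any(g > 0 for g in c.g_max.values())]
        self.channels = chans
        K = len(chans)
        self.erev = np.array([c.e_rev for c in chans])
        self.carries = np.array([c.carries_ca for c in chans], dtype=np.bool_)
        self.gdens = np.zeros((4, K))
        for k, c in enumerate(chans):
            for ct, g in c.g_max.items():
                self.gdens[CTYPE_CODES[ct], k] = g
        gate_specs = []
        self.g_start = np.zeros(K, dtype=np.int64)
        self.g_count = np.zeros(K, dtype=np.int64)
        for k, c in enumerate(chans):
            self.g_start[k] = len(gate_specs)
            self.g_count[k] = len(c.gates)
            gate_specs.extend(c.gates)
        self.gate_specs = gate_specs
        G = len(gate_specs)
        self.gkind = np.zeros(G, dtype=np.int64)
        self.gexp = np.zeros(G, dtype=np.int64)
        self.gcahalf = np.full(G, -1.0)
        self.gf = np.ones(G)
        self.f1 = np.zeros(G, dtype=np.int64)
        self.f2 = np.zeros(G, dtype=np.int64)
        self.p1 = np.zeros((G, 4))
        self.p2 = np.zeros((G, 4))
        for gi, gs in enumerate(gate_specs):
            self.gexp[gi] = gs.exponent
            self.gf[gi] = gs.tau_scale
            if gs.is_alpha_beta:
                self.gkind[gi] = 0
                self.f1[gi] = FORM_CODES[gs.alpha.form]
                self.p1[gi, :len(gs.alpha.params)] = gs.alpha.params
                self.f2[gi] = FORM_CODES[gs.beta.form]
                self.p2[gi, :len(gs.beta.params)] = gs.beta.params
            else:
                self.gkind[gi] = 1
                self.f1[gi] = FORM_CODES[gs.xinf.form]
                self.p1[gi, :len(gs.xinf.params)] = gs.xinf.params
                self.f2[gi] = FORM_CODES[gs.tau.form]
                self.p2[gi, :len(gs.tau.params)] = gs.tau.params
                if gs.ca_half is not None:
                    self.gcahalf[gi] = gs.ca_half
        pool = cs.pool
        self.ca_rest = pool.ca_rest
        self.ca_tau = pool.tau_ca
        self.ca_scale = ca_influx_scale(pool.shell_depth)

    # -- stability -------------------------------------------------------
    def explicit_dt_bound(self) -> float:
        """Gershgorin bound on the diffusion-stable explicit dt, ms.

        dt_max = min_j c_m A_j / sum_n g_ax(j,n); on a uniform chain this is
        the classic c_m R dx^2 / a bound of the second-difference operator.
        """
        gsum = np.zeros(self.n)
        for i in range(self.n):
            p = self.parent[i]
            if p >= 0:
                gsum[i] += self.gax[i]
                gsum[p] += self.gax[i]
        with np.errstate(divide="ignore"):
            bounds = self.cm * self.area / (gsum * 1.0e-3)  # uF/uS*1e3 = ms
        return float(np.min(bounds[gsum > 0])) if np.any(gsum > 0) else math.inf

    def check_stability(self, cfg: SolverConfig) -> None:
        if cfg.method != "explicit":
            return
        bound = self.explicit_dt_bound() * cfg.stability_safety
        if cfg.dt > bound:
            raise ConfigError(
                f"explicit dt={cfg.dt} ms violates the diffusion stability bound "
                f"({bound:.4g} ms with safety {cfg.stability_safety}); reduce dt "
                f"or use method='implicit_reference'")

    # -- per-compartment kinetics (numpy path, used by the implicit solver)
    def gate_steady_state(self, v: np.ndarray, ca: np.ndarray) -> np.ndarray:
        G = len(self.gate_specs)
        out = np.empty((self.n, G))
        for gi, gs in enumerate(self.gate_specs):
            ca_arg = ca if gs.ca_dependent else 0.0
            if gs.ca_dependent:
                out[:, gi] = np.clip(gs.xinf(v) * (ca / (ca + gs.ca_half)), 0.0, 1.0)
            else:
                out[:, gi] = steady_state(gs, v, 0.0)
        return out

    def _gate_update_np(self, state: SimulationState, dt: float) -> None:
        v, ca = state.v, state.ca
        for gi, gs in enumerate(self.gate_specs):
            if gs.is_alpha_beta:
                a, b = gs.alpha(v), gs.beta(v)
                xinf = a / (a + b)
                tau = gs.tau_scale / (a + b)
            else:
                xinf = gs.xinf(v)
                if gs.ca_dependent:
                    xinf = xinf * (ca / (ca + gs.ca_half))
                tau = gs.tau_scale * gs.tau(v)
            x = state.gates[:, gi]
            state.gates[:, gi] = np.clip(xinf + (x - xinf) * np.exp(-dt / tau), 0.0, 1.0)

    def _conductances_np(self, state: SimulationState):
        """Per-compartment total open conductance, g*E sum, and Ca current."""
        n = self.n
        gloc = np.zeros(n)
        g_e = np.zeros(n)
        i_ca = np.zeros(n)
        for k, c in enumerate(self.channels):
            gk = self.gdens[self.ctcode, k]
            open_frac = np.ones(n)
            for gi in range(self.g_start[k], self.g_start[k] + self.g_count[k]):
                open_frac *= state.gates[:, gi] ** self.gexp[gi]
            g_open = gk * open_frac
            gloc += g_open
            g_e += g_open * self.erev[k]
            if self.carries[k]:
                i_ca += g_open * (state.v - self.erev[k])
        return gloc, g_e, i_ca


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def compile_model(m: Morphology, cs: ChannelSet) -> CompiledModel:
    return CompiledModel(m, cs)


def axial_term(model: CompiledModel | Morphology, v: np.ndarray,
               cs: ChannelSet | None = None) -> np.ndarray:
    """Axial coupling current density per compartment, uA/cm^2 (positive
    depolarizes).  Antisymmetric in absolute current: what leaves a
    compartment enters its neighbor, so total axial charge flux is zero."""
    if isinstance(model, Morphology):
        if cs is None:
            raise ValueError("pass a ChannelSet when giving a raw Morphology")
        model = CompiledModel(model, cs)
    v = np.asarray(v, dtype=float)
    i_nA = np.zeros(model.n)
    for i in range(model.n):
        p = model.parent[i]
        if p >= 0:
            cur = model.gax[i] * (v[p] - v[i])
            i_nA[i] += cur
            i_nA[p] -= cur
    return i_nA * 1.0e-3 / model.area


def init_state(model: CompiledModel, v_init: float | None = None) -> SimulationState:
    """Initial condition: uniform voltage (default: leak reversal), every
    gate at its steady state there, calcium at rest.  Settling is applied
    separately by `run` / `settle`."""
    v0 = model.e_leak if v_init is None else v_init
    v = np.full(model.n, float(v0))
    ca = np.full(model.n, model.ca_rest)
    gates = model.gate_steady_state(v, ca)
    st = SimulationState(0.0, v, gates, ca)
    st.check_finite()
    return st


_EMPTY_PULSES = (np.zeros(0, dtype=np.int64), np.zeros(0), np.zeros(0))


def _pulse_arrays(model: CompiledModel, protocol: Protocol | None,
                  weights: dict[int, float] | None = None):
    if protocol is None or not protocol.pulses:
        return _EMPTY_PULSES
    comp = np.array([model.index[cid] for cid, _, _ in protocol.pulses], dtype=np.int64)
    t0 = np.array([t for _, t, _ in protocol.pulses])
    w = np.array([w for _, _, w in protocol.pulses])
    return comp, t0, w


def _run_explicit(model: CompiledModel, state: SimulationState, n_steps: int,
                  dt: float, protocol: Protocol | None,
                  stride: int, rec_idx: np.ndarray, rec_buf: np.ndarray,
                  rec_row0: int = 0) -> int:
    comp, t0s, ws = _pulse_arrays(model, protocol)
    ramped = protocol is not None and protocol.mode is PulseMode.RAMPED
    pw_width = protocol.pulse_width if protocol is not None else 1.0
    tau_i = protocol.tau_i if protocol is not None else 50.0
    row = _kernel.integrate(
        state.v, state.gates, state.ca, n_steps, dt, state.t,
        model.parent, model.gax, model.area, model.ctcode, model.cm,
        model.erev, model.carries, model.gdens,
        model.g_start, model.g_count,
        model.gkind, model.gexp, model.gcahalf, model.gf,
        model.f1, model.p1, model.f2, model.p2,
        model.ca_rest, model.ca_scale, model.ca_tau,
        comp, t0s, ws, pw_width, ramped, tau_i,
        stride, rec_idx, rec_buf, rec_row0)
    state.t += n_steps * dt
    state.check_finite()
    return row


def _external_density(model: CompiledModel, protocol: Protocol | None, t: float) -> np.ndarray:
    i_ext = np.zeros(model.n)
    if protocol is None:
        return i_ext
    for cid, t_on, w in protocol.pulses:
        tt = t - t_on
        if 0.0 <= tt < protocol.pulse_width:
            amp = w if protocol.mode is PulseMode.IDEAL else \
                w * (1.0 - math.exp(-tt / protocol.tau_i))
            i_ext[model.index[cid]] += amp
    return i_ext * 1.0e-3 / model.area


def _step_implicit(model: CompiledModel, state: SimulationState, dt: float,
                   protocol: Protocol | None) -> None:
    model._gate_update_np(state, dt)
    gloc, g_e, i_ca = model._conductances_np(state)
    i_ext = _external_density(model, protocol, state.t)
    n = model.n
    cdt = model.cm / dt
    # row-scaled axial conductance densities (mS/cm^2)
    c_child = model.gax * 1.0e-3 / model.area          # row i, neighbor parent
    d = cdt + gloc
    u = np.zeros(n)  # coefficient of v[parent] in row i
    rhs = cdt * state.v + g_e + i_ext
    l_par = np.zeros(n)  # coefficient of v[i] in row parent[i]
    for i in range(n):
        p = model.parent[i]
        if p >= 0:
            d[i] += c_child[i]
            u[i] = -c_child[i]
            cpar = model.gax[i] * 1.0e-3 / model.area[p]
            d[p] += cpar
            l_par[i] = -cpar
    # Hines elimination (children are always after parents in compiled order)
    for i in range(n - 1, 0, -1):
        p = model.parent[i]
        factor = l_par[i] / d[i]
        d[p] -= factor * u[i]
        rhs[p] -= factor * rhs[i]
    vnew = np.empty(n)
    vnew[0] = rhs[0] / d[0]
    for i in range(1, n):
        vnew[i] = (rhs[i] - u[i] * vnew[model.parent[i]]) / d[i]
    state.v = vnew
    # calcium: exponential update toward the instantaneous target
    target = model.ca_rest - model.ca_scale * model.ca_tau * i_ca
    state.ca = np.maximum(target + (state.ca - target) * math.exp(-dt / model.ca_tau), 0.0)
    state.t += dt


def step(model: CompiledModel, state: SimulationState, cfg: SolverConfig,
         protocol: Protocol | None = None,
         ext_currents_nA: np.ndarray | None = None) -> SimulationState:
    """Advance the state by one dt and return the new state.

    ``ext_currents_nA`` injects a constant per-compartment current for this
    step (in addition to any protocol pulses)."""
    model.check_stability(cfg)
    new = state.copy()
    if ext_currents_nA is not None:
        # represent the constant current as a wide pulse covering this step
        extra = tuple((model.ids[i], new.t, float(ext_currents_nA[i]))
                      for i in range(model.n) if ext_currents_nA[i] != 0.0)
        base = protocol.pulses if protocol is not None else ()
        width = max(protocol.pulse_width if protocol else cfg.dt, cfg.dt)
        protocol = Protocol(pulses=base + extra, t_stop=new.t + cfg.dt,
                            pulse_width=width,
                            mode=protocol.mode if protocol else PulseMode.IDEAL,
                            tau_i=protocol.tau_i if protocol else 50.0)
    if cfg.method == "explicit":
        _run_explicit(model, new, 1, cfg.dt, protocol, 0,
                      np.zeros(0, dtype=np.int64), np.zeros((0, 0)))
    else:
        _step_implicit(model, new, cfg.dt, protocol)
        new.check_finite()
    return new


def settle(model: CompiledModel, state: SimulationState, cfg: SolverConfig) -> SimulationState:
    """Zero-input equilibration for cfg.settle_time; time is rewound to the
    pre-stimulus origin afterwards."""
    n_steps = int(round(cfg.settle_time / cfg.dt))
    if n_steps == 0:
        return state.copy()
    new = state.copy()
    new.t = -cfg.settle_time
    if cfg.method == "explicit":
        _run_explicit(model, new, n_steps, cfg.dt, None, 0,
                      np.zeros(0, dtype=np.int64), np.zeros((0, 0)))
    else:
        for _ in range(n_steps):
            _step_implicit(model, new, cfg.dt, None)
        new.check_finite()
    new.t = 0.0
    return new


def run(model: CompiledModel, protocol: Protocol | None, cfg: SolverConfig,
        state: SimulationState | None = None) -> RecordedTrace:
    """Settle, then integrate the protocol window, recording the requested
    compartments (the soma is always included)."""
    model.check_stability(cfg)
    if state is None:
        state = init_state(model, cfg.v_init)
        state = settle(model, state, cfg)
    else:
        state = state.copy()
    t_stop = protocol.t_stop if protocol is not None else 0.0
    n_steps = int(round((t_stop - state.t) / cfg.dt))
    soma_id = model.ids[0]
    rec_ids = tuple(cfg.record_ids or ())
    if soma_id not in rec_ids:
        rec_ids = (soma_id,) + rec_ids
    rec_idx = np.array([model.index[cid] for cid in rec_ids], dtype=np.int64)
    n_rec = n_steps // cfg.record_stride + 1 if n_steps > 0 else 1
    rec_buf = np.empty((n_rec, len(rec_ids)))
    t_start = state.t
    if cfg.method == "explicit":
        rows = _run_explicit(model, state, n_steps, cfg.dt, protocol,
                             cfg.record_stride, rec_idx, rec_buf)
    else:
        rows = 0
        for istep in range(n_steps):
            if istep % cfg.record_stride == 0 and rows < n_rec:
                rec_buf[rows] = state.v[rec_idx]
                rows += 1
            _step_implicit(model, state, cfg.dt, protocol)
        state.check_finite()
    if rows < n_rec:  # final sample at t_stop when the grid allows
        rec_buf[rows] = state.v[rec_idx]
        rows += 1
    times = t_start + np.arange(rows) * cfg.record_stride * cfg.dt
    return RecordedTrace(times=times, v=rec_buf[:rows].copy(), ids=rec_ids)
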