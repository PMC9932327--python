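"""Solver correctness: conservation, analytic limits, cross-method oracle."""

import math

import numpy as np
import pytest

from pcseq.morphology import (Compartment, CType, Morphology, Passive,
                              ReducedSpec, generate_reduced)
from pcseq.solver import (CompiledModel, ConfigError, SolverConfig, axial_term,
                          init_state, run, settle, step)
from pcseq.stimulation import Protocol

from conftest import leak_only_set, uniform_chain


def single_compartment():
    return Morphology([Compartment(1, None, CType.SOMA, 30, 15)], Passive())


# ---------------------------------------------------------------------------
# axial coupling
# ---------------------------------------------------------------------------

def test_axial_term_zero_for_uniform_v():
    model = CompiledModel(uniform_chain(8), leak_only_set())
    out = axial_term(model, np.full(8, -65.0))
    assert np.allclose(out, 0.0, atol=1e-12)


def test_axial_term_second_difference_on_three_chain():
    """On a uniform 3-compartment chain with v=(0,1,0), the middle term is
    -2 g (a/2R dx^2 form) and the sealed ends each get +1 g."""
    m = uniform_chain(3)
    model = CompiledModel(m, leak_only_set())
    out = axial_term(model, np.array([0.0, 1.0, 0.0]))
    c = m[1]
    a_cm, dx_cm = c.radius * 1e-4, c.length * 1e-4
    g_unit = a_cm / (2.0 * m.passive.r_axial) / dx_cm**2 * 1e3  # mS/cm^2 -> uA/cm^2 per mV
    assert out[1] == pytest.approx(-2.0 * g_unit, rel=1e-9)
    assert out[0] == pytest.approx(g_unit, rel=1e-9)
    assert out[2] == pytest.approx(g_unit, rel=1e-9)


def test_axial_flux_antisymmetry_on_random_tree():
    m = generate_reduced(ReducedSpec(n_main=2, n_smooth=4, n_spiny=12, branching=2))
    model = CompiledModel(m, leak_only_set())
    rng = np.random.default_rng(42)
    for _ in range(5):
        v = rng.uniform(-90, 0, model.n)
        density = axial_term(model, v)
        total_nA = np.sum(density * model.area * 1e3)
        assert abs(total_nA) < 1e-9 * np.max(np.abs(density * model.area * 1e3) + 1e-30)


# ---------------------------------------------------------------------------
# initialization and settling
# ---------------------------------------------------------------------------

def test_passive_model_settles_to_leak_reversal():
    model = CompiledModel(uniform_chain(6), leak_only_set(0.1, -80.0))
    cfg = SolverConfig(dt=0.005, settle_time=350.0)  # ~21 membrane tau
    st = settle(model, init_state(model, v_init=-60.0), cfg)
    assert np.allclose(st.v, -80.0, atol=1e-6)


def test_full_channel_set_rests_without_spontaneous_spiking(channel_set):
    """After settling, the full model sits at a stable rest (no spontaneous
    simple spikes): max |dv/dt| below 0.01 mV/ms."""
    m = generate_reduced()
    model = CompiledModel(m, channel_set)
    cfg = SolverConfig(dt=0.005, settle_time=500.0)
    st = settle(model, init_state(model), cfg)
    st2 = settle(model, st, SolverConfig(dt=0.005, settle_time=1.0))
    dvdt = np.abs(st2.v - st.v) / 1.0
    assert np.max(dvdt) < 0.01
    assert -75.0 < st.v[0] < -60.0  # soma rests near -68 mV


def test_settling_is_deterministic(channel_set):
    m = generate_reduced(ReducedSpec(n_main=1, n_smooth=2, n_spiny=5))
    cfg = SolverConfig(dt=0.005, settle_time=100.0)
    states = []
    for _ in range(2):
        model = CompiledModel(m, channel_set)
        states.append(settle(model, init_state(model), cfg))
    assert np.array_equal(states[0].v, states[1].v)
    assert np.array_equal(states[0].gates, states[1].gates)
    assert np.array_equal(states[0].ca, states[1].ca)


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------

def test_stability_bound_enforced_at_setup():
    model = CompiledModel(uniform_chain(10), leak_only_set())
    with pytest.raises(ConfigError, match="stability"):
        run(model, Protocol(pulses=(), t_stop=1.0), SolverConfig(dt=1.0))


def test_pure_diffusion_conserves_total_charge():
    """Sealed cable, no channels: the c_m A - weighted mean of v (total
    charge) is conserved to 1e-9 relative accuracy."""
    model = CompiledModel(uniform_chain(12), leak_only_set(0.0))
    st = init_state(model)
    rng = np.random.default_rng(0)
    st.v = rng.uniform(-80.0, -20.0, model.n)
    weights = model.area * model.cm
    q0 = float(weights @ st.v)
    cfg = SolverConfig(dt=0.005, settle_time=0.0)
    cur = st
    for _ in range(300):
        cur = step(model, cur, cfg)
    assert abs(float(weights @ cur.v) - q0) / abs(q0) < 1e-9
    # and the profile flattens toward the weighted mean
    assert np.ptp(cur.v) < np.ptp(st.v)


def test_rc_response_of_isopotential_compartment():
    """Constant current into one passive compartment relaxes to
    v_rest + I R_in with time constant c_m R_m (closed-form RC)."""
    g_leak, e_leak, i_nA = 0.1, -80.0, 0.05
    model = CompiledModel(single_compartment(), leak_only_set(g_leak, e_leak))
    T = 200.0
    proto = Protocol(pulses=((1, 0.0, i_nA),), t_stop=T, pulse_width=T)
    cfg = SolverConfig(dt=0.005, settle_time=0.0, record_stride=200)
    tr = run(model, proto, cfg)
    dv_inf = i_nA * 1e-3 / model.area[0] / g_leak       # mV
    tau = model.cm[0] / g_leak                           # ms
    analytic = e_leak + dv_inf * (1.0 - np.exp(-tr.times / tau))
    assert np.max(np.abs(tr.v[:, 0] - analytic)) < 1e-6


def test_zero_input_passive_stays_at_rest():
    model = CompiledModel(uniform_chain(5), leak_only_set(0.1, -80.0))
    cfg = SolverConfig(dt=0.005, settle_time=10.0, record_stride=100)
    tr = run(model, Protocol(pulses=(), t_stop=50.0), cfg)
    assert np.allclose(tr.v, -80.0, atol=1e-9)


# ---------------------------------------------------------------------------
# analytic cable limit
# ---------------------------------------------------------------------------

def test_steady_state_matches_cosh_cable_solution():
    """Constant current at the sealed distal end of a 25-compartment passive
    cable: the steady profile matches V(x) = I r_a lambda cosh((L-x)/lambda)
    / sinh(L/lambda) within 1%."""
    N, dx_um, a_um, g_leak = 25, 20.0, 2.0, 0.1
    m = uniform_chain(N, dx_um, a_um)
    model = CompiledModel(m, leak_only_set(g_leak, -80.0))
    i_nA, T = 0.005, 2500.0
    proto = Protocol(pulses=((N, 0.0, i_nA),), t_stop=T, pulse_width=T)
    cfg = SolverConfig(dt=0.005, settle_time=0.0,
                       record_ids=tuple(range(1, N + 1)), record_stride=50000)
    tr = run(model, proto, cfg)
    v = np.array([tr[c][-1] for c in range(1, N + 1)]) + 80.0
    num = v[::-1]  # index 0 = injection end
    r_m = 1.0 / g_leak * 1e3                     # Ohm cm^2
    a_cm, dx_cm = a_um * 1e-4, dx_um * 1e-4
    lam = math.sqrt(r_m * a_cm / (2.0 * m.passive.r_axial))
    L = N * dx_cm
    r_a = m.passive.r_axial / (math.pi * a_cm**2)
    x = (np.arange(N) + 0.5) * dx_cm
    analytic = (i_nA * 1e-9) * r_a * lam * np.cosh((L - x) / lam) / math.sinh(L / lam) * 1e3
    assert np.max(np.abs(num - analytic)) / np.max(analytic) < 0.01


# ---------------------------------------------------------------------------
# explicit vs implicit oracle
# ---------------------------------------------------------------------------

def test_explicit_matches_implicit_reference_on_active_fixture(channel_set):
    """Soma traces of the two methods agree within 1 mV over 500 ms on a
    10-compartment fixture with the full channel inventory."""
    m = generate_reduced(ReducedSpec(n_main=1, n_smooth=2, n_spiny=6))
    model = CompiledModel(m, channel_set)
    pulses = tuple((10 - k, 50.0 + 40.0 * k, 1.0) for k in range(3))
    proto = Protocol(pulses=pulses, t_stop=500.0)
    tr_e = run(model, proto, SolverConfig(dt=0.005, settle_time=300.0, record_stride=10))
    tr_i = run(model, proto, SolverConfig(dt=0.05, method="implicit_reference",
                                          settle_time=300.0, record_stride=1))
    v_e = np.interp(tr_i.times, tr_e.times, tr_e.v[:, 0])
    assert np.max(np.abs(v_e - tr_i.v[:, 0])) < 1.0


def test_explicit_converges_under_dt_refinement(channel_set):
    m = generate_reduced(ReducedSpec(n_main=1, n_smooth=2, n_spiny=4))
    model = CompiledModel(m, channel_set)
    proto = Protocol(pulses=((7, 20.0, 1.0),), t_stop=150.0)
    traces = {}
    for dt in (0.005, 0.0025):
        cfg = SolverConfig(dt=dt, settle_time=100.0, record_stride=int(0.05 / dt))
        traces[dt] = run(model, proto, cfg)
    n = min(len(traces[0.005].times), len(traces[0.0025].times))
    diff = np.max(np.abs(traces[0.005].v[:n, 0] - traces[0.0025].v[:n, 0]))
    assert diff < 0.1  # halving dt barely moves the trace


def test_recorded_trace_is_uniform_and_includes_soma(channel_set):
    m = generate_reduced(ReducedSpec(n_main=1, n_smooth=2, n_spiny=4))
    model = CompiledModel(m, channel_set)
    cfg = SolverConfig(dt=0.005, settle_time=10.0, record_ids=(7,), record_stride=100)
    tr = run(model, Protocol(pulses=(), t_stop=20.0), cfg)
    assert tr.ids[0] == 1  # soma always first
    assert 7 in tr.ids
    dts = np.diff(tr.times)
    assert np.allclose(dts, dts[0])
    assert np.all(dts > 0)
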