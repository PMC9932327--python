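"""Channel kinetics: steady states, time constants, currents, calcium."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pcseq.channels import (ALPHA_BETA_CHANNELS, CalciumPool, ChannelSpec,
                            CType, GateSpec, KineticsError, RateFn,
                            channel_current, load_channel_set, scale_tau,
                            steady_state, step_calcium, step_gate,
                            time_constant, validate_default_set)

# Independent re-statements of the default file's rate expressions for a few
# gates, written directly from the functional definitions (not via RateFn).
INDEPENDENT_RATES = {
    ("CaT", "m"): (lambda v: 2.6 / (1 + math.exp(-(v + 21) / 8)),
                   lambda v: 0.18 / (1 + math.exp((v + 40) / 4))),
    ("CaT", "h"): (lambda v: 0.0025 / (1 + math.exp((v + 40) / 8)),
                   lambda v: 0.19 / (1 + math.exp(-(v + 50) / 10))),
    ("CaP", "m"): (lambda v: 8.5 / (1 + math.exp(-(v - 8) / 12.5)),
                   lambda v: 35.0 / (1 + math.exp((v + 74) / 14.5))),
    ("NaF", "m"): (lambda v: 35.0 * math.exp((v + 5) / 10),
                   lambda v: 7.0 * math.exp(-(v + 65) / 20)),
}


@pytest.fixture(scope="module")
def cs():
    return load_channel_set()


def gate_of(cs, channel, name):
    return next(g for g in cs[channel].gates if g.name == name)


def test_default_inventory_matches_model_tables(cs):
    validate_default_set(cs)
    assert set(cs.inventory(CType.SPINY)) == {"Leak", "CaP", "CaT", "KM", "KC", "K2"}
    soma = set(cs.inventory(CType.SOMA))
    assert "NaF" in soma and "CaP" not in soma


def test_alpha_beta_assignment_is_the_five_channels(cs):
    for c in cs.channels:
        for g in c.gates:
            assert g.is_alpha_beta == (c.name in ALPHA_BETA_CHANNELS)


@pytest.mark.parametrize("channel,gate", list(INDEPENDENT_RATES))
@pytest.mark.parametrize("v", [-60.0, -40.0, -20.0])
def test_steady_state_matches_independent_evaluation(cs, channel, gate, v):
    alpha, beta = INDEPENDENT_RATES[(channel, gate)]
    g = gate_of(cs, channel, gate)
    assert steady_state(g, v) == pytest.approx(alpha(v) / (alpha(v) + beta(v)), rel=1e-12)
    assert time_constant(g, v) == pytest.approx(1.0 / (alpha(v) + beta(v)), rel=1e-12)


def test_steady_state_half_when_alpha_equals_beta():
    g = GateSpec("m", 1, alpha=RateFn("constant", (1.0,)), beta=RateFn("constant", (1.0,)))
    assert steady_state(g, -50.0) == pytest.approx(0.5)
    assert time_constant(g, -50.0) == pytest.approx(0.5)  # 1/(1+1)


def test_steady_state_zero_when_alpha_zero():
    g = GateSpec("m", 1, alpha=RateFn("constant", (0.0,)), beta=RateFn("constant", (2.0,)))
    assert steady_state(g, -50.0) == 0.0


def test_zero_rate_sum_is_kinetics_error():
    g = GateSpec("m", 1, alpha=RateFn("constant", (0.0,)), beta=RateFn("constant", (0.0,)))
    with pytest.raises(KineticsError):
        steady_state(g, -50.0)


def test_time_constant_f_homogeneous(cs):
    g = gate_of(cs, "CaT", "h")
    base = time_constant(g, -55.0)
    for f in (0.1, 0.5, 2.0, 3.0):
        assert time_constant(g, -55.0, f=f) == pytest.approx(f * base, rel=1e-12)


def test_time_constant_rejects_nonpositive_f(cs):
    with pytest.raises(KineticsError):
        time_constant(gate_of(cs, "CaT", "h"), -55.0, f=0.0)


def test_scale_tau_only_h_of_ca_channels(cs):
    cs2 = scale_tau(cs, "CaT", 2.0)
    assert gate_of(cs2, "CaT", "h").tau_scale == 2.0
    assert gate_of(cs2, "CaT", "m").tau_scale == 1.0
    assert gate_of(cs2, "CaP", "h").tau_scale == 1.0
    with pytest.raises(KineticsError):
        scale_tau(cs, "NaF", 2.0)
    with pytest.raises(KineticsError):
        scale_tau(cs, "CaT", -1.0)


def test_channel_current_closed_forms():
    g = GateSpec("m", 2, xinf=RateFn("constant", (1.0,)), tau=RateFn("constant", (1.0,)))
    spec = ChannelSpec("Kdr", e_rev=-85.0, g_max={CType.SOMA: 10.0}, gates=(g,))
    # m=0 -> 0; v=E -> 0; g*m^2*(v-E) arithmetic
    assert channel_current(spec, [0.0], -20.0, CType.SOMA) == 0.0
    assert channel_current(spec, [0.5], -85.0, CType.SOMA) == 0.0
    assert channel_current(spec, [0.5], -65.0, CType.SOMA) == pytest.approx(
        10.0 * 0.25 * 20.0)


def test_leak_current_has_no_gating(cs):
    leak = cs["Leak"]
    assert channel_current(leak, [], -60.0, CType.SOMA) == pytest.approx(
        0.1 * (-60.0 - leak.e_rev))


def test_step_gate_fixed_point_and_closed_form():
    g = GateSpec("m", 1, xinf=RateFn("constant", (0.0,)), tau=RateFn("constant", (3.0,)))
    # dt = tau from x=1 toward xinf=0 -> exp(-1)
    assert step_gate(1.0, g, -50.0, dt=3.0) == pytest.approx(math.exp(-1.0), rel=1e-12)
    g2 = GateSpec("m", 1, xinf=RateFn("constant", (0.4,)), tau=RateFn("constant", (3.0,)))
    assert step_gate(0.4, g2, -50.0, dt=0.1) == pytest.approx(0.4)


@pytest.mark.parametrize("x0", [0.0, 0.3, 1.0])
def test_gate_relaxation_matches_analytic_solution(cs, x0):
    """Iterated exponential updates under fixed v reproduce the analytic
    x(t) = xinf + (x0-xinf) exp(-t/tau) exactly, and converge within 5 tau."""
    g = gate_of(cs, "CaT", "h")
    v = -55.0
    xinf, tau = float(steady_state(g, v)), float(time_constant(g, v))
    x = x0
    dt = 0.37 * tau
    for k in range(1, 30):
        x = float(step_gate(x, g, v, dt=dt))
        analytic = xinf + (x0 - xinf) * math.exp(-k * dt / tau)
        assert x == pytest.approx(analytic, abs=1e-12)
    assert abs(float(step_gate(x0, g, v, dt=5 * tau)) - xinf) < 0.01


@settings(max_examples=200, deadline=None)
@given(v=st.floats(-100, 60), x=st.floats(0, 1),
       dt=st.floats(1e-4, 10.0))
def test_gate_values_stay_in_unit_interval(v, x, dt):
    cs = load_channel_set()
    for c in cs.channels:
        for g in c.gates:
            xn = float(step_gate(x, g, v, ca=0.5, dt=dt))
            assert 0.0 <= xn <= 1.0


def test_ca_dependent_gates_scale_with_hill_term(cs):
    g = gate_of(cs, "K2", "m")
    assert g.ca_dependent
    lo = float(steady_state(g, -60.0, ca=0.04))
    hi = float(steady_state(g, -60.0, ca=2.0))
    assert hi > lo
    assert hi == pytest.approx(2.0 / 2.2, rel=1e-9)


def test_step_calcium_equilibrium_and_decay():
    pool = CalciumPool(ca_rest=0.04, tau_ca=20.0)
    assert step_calcium(0.04, pool, 0.0, 1.0) == pytest.approx(0.04)
    # excess decays to 1/e after tau
    ca = step_calcium(0.08, pool, 0.0, 20.0)
    assert ca - 0.04 == pytest.approx(0.04 * math.exp(-1.0), rel=1e-9)


def test_step_calcium_steady_state_under_constant_influx():
    pool = CalciumPool(ca_rest=0.04, tau_ca=20.0)
    i_ca = -10.0  # inward, uA/cm^2
    target = pool.ca_rest + pool.influx_scale * abs(i_ca) * pool.tau_ca
    ca = 0.04
    for _ in range(400):
        ca = float(step_calcium(ca, pool, i_ca, 1.0))
    assert ca == pytest.approx(target, rel=1e-6)


def test_load_rejects_negative_conductance(tmp_path, cs):
    import json
    from importlib import resources
    payload = json.loads(resources.files("pcseq.data")
                         .joinpath("purkinje_channels.json").read_text())
    payload["channels"]["CaT"]["g_max"]["spiny"] = -1.0
    bad = tmp_path / "bad.json"
    bad.write_text(json.dumps(payload))
    with pytest.raises(KineticsError):
        load_channel_set(bad)


def test_load_rejects_unknown_form(tmp_path):
    import json
    from importlib import resources
    payload = json.loads(resources.files("pcseq.data")
                         .joinpath("purkinje_channels.json").read_text())
    payload["channels"]["KM"]["gates"][0]["tau"]["form"] = "wiggly"
    bad = tmp_path / "bad2.json"
    bad.write_text(json.dumps(payload))
    with pytest.raises(KineticsError):
        load_channel_set(bad)
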