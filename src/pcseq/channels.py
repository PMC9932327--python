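"""Hodgkin-Huxley-type channel kinetics and submembrane calcium dynamics.

Each ionic current follows I_k = g_k * m^q * h^r * (v - E_k).  A gate evolves
as tau_x(v) dx/dt = x_inf(v) - x, where for the five alpha-beta channels
(NaF, NaP, CaP, CaT, KA) x_inf = alpha/(alpha+beta) and tau = 1/(alpha+beta),
and for the remaining channels x_inf and tau are given directly.  Rate
functions are *data*, not code: a small library of named functional forms
(constant / exponential / sigmoid / gaussian bell / double-exponential)
parameterized by coefficients stored in a JSON file, so the kinetics are
auditable and swappable without touching the solver.

The two Ca-dependent K channels (KC, K2) take the submembrane calcium
concentration as a multiplicative Hill term on the activation steady state;
calcium itself follows a first-order shell model driven by the Ca-carrying
currents (CaP, CaT).

The inactivation time constants of CaP and CaT can be scaled by a factor f
(the tau-scan perturbation); f != 1 is only meaningful for those h gates and
`scale_tau` enforces that.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .morphology import CType

V_RANGE = (-100.0, 60.0)  # operating voltage range, mV

CHANNEL_NAMES = ("Leak", "NaF", "NaP", "CaP", "CaT",
                 "Kh1", "Kh2", "Kdr", "KM", "KA", "KC", "K2")
ALPHA_BETA_CHANNELS = frozenset({"NaF", "NaP", "CaP", "CaT", "KA"})


class KineticsError(ValueError):
    """Ill-posed rate function or schema violation in a channel file."""


# ---------------------------------------------------------------------------
# Rate-function library
# ---------------------------------------------------------------------------

#: integer codes shared with the compiled solver kernel
FORM_CODES = {"constant": 0, "exp": 1, "sigmoid": 2, "gauss": 3, "dualexp": 4}


@dataclass(frozen=True)
class RateFn:
    """A named functional form with coefficients.

    constant: a
    exp:      a * exp((v - v0) / s)
    sigmoid:  a / (1 + exp((v - v0) / s))        (s < 0 flips the direction)
    gauss:    a + b * exp(-((v - v0) / s)^2)
    dualexp:  a / (exp((v - v0)/s1) + exp(-(v - v0)/s2))
    """

    form: str
    params: tuple[float, ...]

    def __post_init__(self):
        if self.form not in FORM_CODES:
            raise KineticsError(f"unknown rate functional form {self.form!r}")
        n_expected = {"constant": 1, "exp": 3, "sigmoid": 3, "gauss": 4, "dualexp": 4}
        if len(self.params) != n_expected[self.form]:
            raise KineticsError(
                f"form {self.form!r} takes {n_expected[self.form]} coefficients, "
                f"got {len(self.params)}")

    def __call__(self, v):
        p = self.params
        v = np.asarray(v, dtype=float)
        if self.form == "constant":
            return np.broadcast_to(np.float64(p[0]), v.shape).copy() if v.shape else np.float64(p[0])
        if self.form == "exp":
            return p[0] * np.exp((v - p[1]) / p[2])
        if self.form == "sigmoid":
            return p[0] / (1.0 + np.exp((v - p[1]) / p[2]))
        if self.form == "gauss":
            return p[0] + p[1] * np.exp(-(((v - p[2]) / p[3]) ** 2))
        # dualexp
        return p[0] / (np.exp((v - p[1]) / p[2]) + np.exp(-(v - p[1]) / p[3]))


@dataclass(frozen=True)
class GateSpec:
    """One activation (m) or inactivation (h) gate of a channel."""

    name: str                      # 'm' or 'h'
    exponent: int                  # q for m, r for h
    alpha: RateFn | None = None    # alpha-beta kinetics ...
    beta: RateFn | None = None
    xinf: RateFn | None = None     # ... or direct kinetics
    tau: RateFn | None = None
    ca_half: float | None = None   # uM; Hill term ca/(ca+ca_half) on x_inf
    tau_scale: float = 1.0         # the perturbation factor f

    def __post_init__(self):
        if self.name not in ("m", "h"):
            raise KineticsError(f"gate name must be 'm' or 'h', got {self.name!r}")
        if self.exponent < 0:
            raise KineticsError("gate exponent must be non-negative")
        ab = self.alpha is not None and self.beta is not None
        direct = self.xinf is not None and self.tau is not None
        if ab == direct:
            raise KineticsError("gate needs either alpha+beta or xinf+tau, exclusively")
        if self.tau_scale <= 0:
            raise KineticsError("tau scale factor f must be positive")

    @property
    def is_alpha_beta(self) -> bool:
        return self.alpha is not None

    @property
    def ca_dependent(self) -> bool:
        return self.ca_half is not None


def steady_state(g: GateSpec, v, ca: float = 0.0):
    """x_inf at voltage v (and calcium, for Ca-dependent gates), in [0, 1]."""
    if g.is_alpha_beta:
        a, b = g.alpha(v), g.beta(v)
        denom = a + b
        if np.any(denom <= 0.0):
            raise KineticsError(f"alpha+beta <= 0 at v={v} for gate {g.name}")
        x = a / denom
    else:
        x = g.xinf(v)
        if g.ca_dependent:
            x = x * (ca / (ca + g.ca_half))
    return np.clip(x, 0.0, 1.0)


def time_constant(g: GateSpec, v, ca: float = 0.0, f: float | None = None):
    """tau_x at voltage v, ms, scaled by the perturbation factor f."""
    f = g.tau_scale if f is None else f
    if f <= 0:
        raise KineticsError("tau scale factor f must be positive")
    if g.is_alpha_beta:
        a, b = g.alpha(v), g.beta(v)
        denom = a + b
        if np.any(denom <= 0.0):
            raise KineticsError(f"alpha+beta <= 0 at v={v} for gate {g.name}")
        tau = 1.0 / denom
    else:
        tau = g.tau(v)
        if np.any(np.asarray(tau) <= 0.0):
            raise KineticsError(f"tau <= 0 at v={v} for gate {g.name}")
    return f * tau


def step_gate(x, g: GateSpec, v, ca: float = 0.0, f: float | None = None, dt: float = 0.005):
    """Advance a gate one step with the exponential (Rush-Larsen) update.

    Exact for fixed v: x' = x_inf + (x - x_inf) exp(-dt/tau).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    xinf = steady_state(g, v, ca)
    tau = time_constant(g, v, ca, f)
    return np.clip(xinf + (x - xinf) * np.exp(-dt / tau), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Channels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelSpec:
    name: str
    e_rev: float                       # mV
    g_max: Mapping[CType, float]       # mS/cm^2 per compartment type
    gates: tuple[GateSpec, ...] = ()
    carries_ca: bool = False

    def __post_init__(self):
        if self.name not in CHANNEL_NAMES:
            raise KineticsError(f"unknown channel name {self.name!r}")
        if any(g < 0 for g in self.g_max.values()):
            raise KineticsError(f"{self.name}: conductance density must be >= 0")
        if len(self.gates) > 2:
            raise KineticsError(f"{self.name}: at most two gates (m, h)")


def channel_current(c: ChannelSpec, gate_values: Sequence[float], v, ctype: CType):
    """Ionic current density, uA/cm^2 (positive = outward)."""
    g = c.g_max.get(ctype, 0.0)
    open_frac = 1.0
    for gate, x in zip(c.gates, gate_values):
        open_frac = open_frac * np.asarray(x) ** gate.exponent
    return g * open_frac * (np.asarray(v) - c.e_rev)


@dataclass(frozen=True)
class CalciumPool:
    """First-order submembrane calcium shell.

    d[Ca]/dt = -scale * i_ca - ([Ca] - ca_rest)/tau_ca, with i_ca the
    Ca-carrying current density (inward currents are negative, hence the
    minus sign raises [Ca]); scale follows from shell depth and Faraday's
    constant.  [Ca] is floored at zero.
    """

    ca_rest: float = 0.04      # uM
    shell_depth: float = 0.2   # um
    tau_ca: float = 20.0       # ms

    @property
    def influx_scale(self) -> float:
        from .units import ca_influx_scale
        return ca_influx_scale(self.shell_depth)


def step_calcium(ca: float, pool: CalciumPool, i_ca: float, dt: float):
    """Advance [Ca] one step (exponential update toward the instantaneous
    steady state ca_rest - scale * tau_ca * i_ca)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    target = pool.ca_rest - pool.influx_scale * pool.tau_ca * np.asarray(i_ca)
    ca_new = target + (np.asarray(ca) - target) * math.exp(-dt / pool.tau_ca)
    return np.maximum(ca_new, 0.0)


@dataclass
class ChannelSet:
    """The full channel inventory, per compartment type."""

    channels: list[ChannelSpec]
    pool: CalciumPool = field(default_factory=CalciumPool)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise KineticsError("duplicate channel entries")
        if "Leak" not in names:
            raise KineticsError("every channel set needs a Leak entry")
        leak = self["Leak"]
        for ct in CType:
            if ct not in leak.g_max:
                raise KineticsError(f"Leak density undefined for {ct.value}")

    def __getitem__(self, name: str) -> ChannelSpec:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(name)

    def g_max(self, name: str, ctype: CType) -> float:
        try:
            return self[name].g_max.get(ctype, 0.0)
        except KeyError:
            return 0.0

    def inventory(self, ctype: CType) -> list[str]:
        return [c.name for c in self.channels if c.g_max.get(ctype, 0.0) > 0.0]


def scale_tau(cs: ChannelSet, channel: str, f: float) -> ChannelSet:
    """Return a ChannelSet with the h-gate time constant of CaP or CaT
    multiplied by f (the perturbation of the tau-scan experiments)."""
    if channel not in ("CaP", "CaT"):
        raise KineticsError("tau scaling applies only to CaP or CaT")
    if f <= 0:
        raise KineticsError("tau scale factor f must be positive")
    new_channels = []
    for c in cs.channels:
        if c.name == channel:
            gates = tuple(replace(g, tau_scale=f) if g.name == "h" else g for g in c.gates)
            if not any(g.name == "h" for g in gates):
                raise KineticsError(f"{channel} has no inactivation gate to scale")
            c = replace(c, gates=gates)
        new_channels.append(c)
    return ChannelSet(new_channels, pool=cs.pool, meta=dict(cs.meta))


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _rate_from_dict(d: Mapping) -> RateFn:
    return RateFn(d["form"], tuple(float(x) for x in d["params"]))


def _gate_from_dict(d: Mapping) -> GateSpec:
    kin = d.get("kinetics", "alpha_beta" if "alpha" in d else "direct")
    kwargs = dict(name=d["name"], exponent=int(d["exponent"]),
                  ca_half=float(d["ca_half"]) if d.get("ca_half") is not None else None)
    if kin == "alpha_beta":
        kwargs["alpha"] = _rate_from_dict(d["alpha"])
        kwargs["beta"] = _rate_from_dict(d["beta"])
    elif kin == "direct":
        kwargs["xinf"] = _rate_from_dict(d["xinf"])
        kwargs["tau"] = _rate_from_dict(d["tau"])
    else:
        raise KineticsError(f"unknown kinetics kind {kin!r}")
    return GateSpec(**kwargs)


def load_channel_set(path=None) -> ChannelSet:
    """Load a declarative channel-parameter file (JSON); with no path, the
    packaged default Purkinje inventory is loaded."""
    if path is None:
        text = resources.files("pcseq.data").joinpath("purkinje_channels.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    payload = json.loads(text)
    try:
        channels = []
        for name, cd in payload["channels"].items():
            g_max = {CType(k): float(v) for k, v in cd["g_max"].items()}
            gates = tuple(_gate_from_dict(gd) for gd in cd.get("gates", ()))
            channels.append(ChannelSpec(name=name, e_rev=float(cd["e_rev"]),
                                        g_max=g_max, gates=gates,
                                        carries_ca=bool(cd.get("carries_ca", False))))
        pool = CalciumPool(**payload.get("calcium", {}))
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, KineticsError):
            raise
        raise KineticsError(f"malformed channel file: {exc}") from exc
    return ChannelSet(channels, pool=pool, meta=payload.get("meta", {}))


def validate_default_set(cs: ChannelSet) -> None:
    """Structural checks on the packaged inventory: alpha-beta kinetics for
    exactly the five named channels, and the per-type channel lists of the
    original Purkinje model."""
    for c in cs.channels:
        for g in c.gates:
            if g.is_alpha_beta != (c.name in ALPHA_BETA_CHANNELS):
                raise KineticsError(
                    f"{c.name}: kinetics kind does not match the model convention")
    expected = {
        CType.SOMA: {"Leak", "NaF", "NaP", "CaT", "Kh1", "Kh2", "Kdr", "KM", "KA"},
        CType.MAIN: {"Leak", "CaP", "CaT", "Kdr", "KM", "KA", "KC", "K2"},
        CType.SMOOTH: {"Leak", "CaP", "CaT", "KM", "KC", "K2"},
        CType.SPINY: {"Leak", "CaP", "CaT", "KM", "KC", "K2"},
    }
    for ct, names in expected.items():
        got = set(cs.inventory(ct))
        if got != names:
            raise KineticsError(f"{ct.value} inventory {sorted(got)} != expected {sorted(names)}")
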