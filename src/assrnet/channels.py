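"""Parametric Hodgkin–Huxley channel kinetics and intracellular Ca²⁺ dynamics.

Each voltage-gated channel is described by one or two gating variables with a
sigmoid steady-state curve and an explicit voltage-dependent time constant
(Gaussian-plus-baseline form),

    x_inf(V) = 1 / (1 + exp((V_half − V) / k)),
    τ(V)     = τ_base + τ_amp · exp(−((V − V_peak) / σ)²),

rather than raw α/β rate functions.  This parameterisation exposes exactly the
quantities that ion-channel variants act on — half-activation offset, slope,
time constant and maximal conductance — through a :class:`KineticModifier`
layer, so a variant is a set of (offset shift, slope factor, τ factor, ḡ
factor) deltas per gate.

The channel library covers the eleven conductance classes of the layer-5
pyramidal cell model family this package builds on: transient and persistent
Na⁺, transient/persistent/fast (Kv3-like)/M-type K⁺, the Ca²⁺-dependent K⁺
current SK, the hyperpolarization-activated cation current Ih, high- and
low-voltage-activated Ca²⁺ currents, and leak.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Union

import numpy as np

__all__ = [
    "CHANNEL_NAMES",
    "TauSpec",
    "GateSpec",
    "KineticModifier",
    "IDENTITY_MODIFIER",
    "ChannelSpec",
    "CalciumPool",
    "steady_state",
    "time_constant",
    "channel_current",
    "update_calcium",
    "nernst_ca",
    "load_channel_table",
]

#: The eleven instantiable channel classes.
CHANNEL_NAMES = (
    "NaT",          # transient (fast) Na+
    "NaP",          # persistent Na+
    "K_transient",  # A-type / transient K+
    "K_persistent", # slow persistent K+
    "Kv3",          # Kv3-like fast delayed rectifier
    "SK",           # Ca2+-dependent K+ (voltage independent)
    "M",            # M-type (muscarinic-sensitive) K+
    "Ih",           # HCN hyperpolarization-activated cation current
    "CaHVA",        # high-voltage-activated Ca2+
    "CaLVA",        # low-voltage-activated (T-type) Ca2+
    "leak",
)

#: RT/(zF) for Ca2+ (z = 2) at 37 °C, in mV.
_RT_2F_MV = 13.34
#: Extracellular Ca2+ concentration, mM.
CA_OUT_MM = 2.0


def _require_finite(v, what: str = "voltage"):
    arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite {what}: {v!r}")
    return arr


@dataclass(frozen=True)
class TauSpec:
    """Gaussian-plus-baseline time-constant curve, τ(V) in ms."""

    base: float          # ms, floor of the curve
    amp: float = 0.0     # ms, height of the Gaussian bump
    v_peak: float = 0.0  # mV, center of the bump
    sigma: float = 30.0  # mV, width of the bump

    def __post_init__(self):
        if self.base <= 0:
            raise ValueError(f"tau base must be > 0, got {self.base}")
        if self.amp < 0:
            raise ValueError(f"tau amplitude must be >= 0, got {self.amp}")
        if self.sigma <= 0:
            raise ValueError(f"tau sigma must be > 0, got {self.sigma}")

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        return self.base + self.amp * np.exp(-(((v - self.v_peak) / self.sigma) ** 2))


@dataclass(frozen=True)
class GateSpec:
    """One gating variable: sigmoid steady state plus τ(V) curve.

    ``slope_k`` is signed: positive for activation-like gates (open with
    depolarization), negative for inactivation-like gates.
    """

    name: str
    v_half: float        # mV
    slope_k: float       # mV, signed
    tau: TauSpec
    power: int = 1

    def __post_init__(self):
        if self.slope_k == 0:
            raise ValueError("slope_k must be nonzero")
        if not (isinstance(self.power, (int, np.integer)) and self.power >= 1):
            raise ValueError(f"gate power must be an integer >= 1, got {self.power}")


@dataclass(frozen=True)
class KineticModifier:
    """The handle through which a variant alters a channel.

    ``dv_shift`` translates both the steady-state and the τ curve along the
    voltage axis; ``slope_factor`` multiplies the sigmoid slope;
    ``tau_factor`` multiplies τ(V); ``g_factor`` multiplies the maximal
    conductance.  The identity modifier (0, 1, 1, 1) leaves kinetics
    bit-identical.
    """

    dv_shift: float = 0.0      # mV, additive
    slope_factor: float = 1.0  # dimensionless, > 0
    tau_factor: float = 1.0    # dimensionless, > 0
    g_factor: float = 1.0      # dimensionless, >= 0

    def __post_init__(self):
        if not np.isfinite(self.dv_shift):
            raise ValueError("dv_shift must be finite")
        if self.slope_factor <= 0:
            raise ValueError(f"slope_factor must be > 0, got {self.slope_factor}")
        if self.tau_factor <= 0:
            raise ValueError(f"tau_factor must be > 0, got {self.tau_factor}")
        if self.g_factor < 0:
            raise ValueError(f"g_factor must be >= 0, got {self.g_factor}")

    @property
    def is_identity(self) -> bool:
        return (
            self.dv_shift == 0.0
            and self.slope_factor == 1.0
            and self.tau_factor == 1.0
            and self.g_factor == 1.0
        )

    def compose(self, other: "KineticModifier") -> "KineticModifier":
        """Sequential application: shifts add, factors multiply."""
        return KineticModifier(
            dv_shift=self.dv_shift + other.dv_shift,
            slope_factor=self.slope_factor * other.slope_factor,
            tau_factor=self.tau_factor * other.tau_factor,
            g_factor=self.g_factor * other.g_factor,
        )

    def inverse(self) -> "KineticModifier":
        return KineticModifier(
            dv_shift=-self.dv_shift,
            slope_factor=1.0 / self.slope_factor,
            tau_factor=1.0 / self.tau_factor,
            g_factor=1.0 / self.g_factor if self.g_factor > 0 else np.inf,
        )


IDENTITY_MODIFIER = KineticModifier()


@dataclass(frozen=True)
class ChannelSpec:
    """A channel instance: gates, conductance density and reversal.

    ``reversal`` is either a fixed potential in mV or the string ``"ca"``,
    meaning the reversal is recomputed each step from the local Ca²⁺ pool via
    the Nernst equation.  SK carries no voltage gates; its open fraction is a
    Hill function of [Ca²⁺] with exponent ``ca_hill`` and half-activation
    ``ca_half``.
    """

    name: str
    gates: tuple[GateSpec, ...]
    gbar: float                     # S/cm², conductance density
    reversal: Union[float, str]     # mV or "ca"
    modifier: KineticModifier = IDENTITY_MODIFIER
    gate_modifiers: tuple[tuple[str, KineticModifier], ...] = ()
    ca_half: float = 4.3e-4         # mM, SK half-activation (L5PC family default)
    ca_hill: float = 4.0            # SK Hill exponent

    def __post_init__(self):
        if self.name not in CHANNEL_NAMES:
            raise ValueError(
                f"unknown channel {self.name!r}; must be one of {CHANNEL_NAMES}"
            )
        if self.gbar < 0:
            raise ValueError(f"gbar must be >= 0, got {self.gbar}")
        if isinstance(self.reversal, str) and self.reversal != "ca":
            raise ValueError(f"reversal must be a number or 'ca', got {self.reversal!r}")

    @property
    def is_ca_channel(self) -> bool:
        return self.reversal == "ca"

    @property
    def effective_g_factor(self) -> float:
        """Channel-level ḡ multiplier including any per-gate g factors."""
        g = self.modifier.g_factor
        for _, m in self.gate_modifiers:
            g *= m.g_factor
        return g

    def gate_modifier(self, gate_name: str) -> KineticModifier:
        """Effective kinetic modifier for one gate: channel-wide ∘ per-gate."""
        eff = self.modifier
        for gname, m in self.gate_modifiers:
            if gname == gate_name:
                eff = eff.compose(
                    KineticModifier(m.dv_shift, m.slope_factor, m.tau_factor, 1.0)
                )
        return eff

    def with_modifier(self, modifier: KineticModifier) -> "ChannelSpec":
        """Compose a channel-wide ``modifier`` onto the existing one."""
        return replace(self, modifier=self.modifier.compose(modifier))

    def with_gate_modifiers(self, gate_mods: Mapping[str, KineticModifier]) -> "ChannelSpec":
        """Append per-gate modifiers (they compose with any already present).

        Per-gate ``g_factor`` entries multiply into the channel conductance;
        the other three components act only on the named gate's kinetics.
        """
        known = {g.name for g in self.gates}
        unknown = set(gate_mods) - known
        if unknown and self.name != "SK":
            raise ValueError(
                f"channel {self.name} has no gate(s) {sorted(unknown)}"
            )
        extra = tuple(sorted(gate_mods.items()))
        return replace(self, gate_modifiers=self.gate_modifiers + extra)

    def with_gbar(self, gbar: float) -> "ChannelSpec":
        return replace(self, gbar=gbar)


@dataclass(frozen=True)
class CalciumPool:
    """First-order intracellular Ca²⁺ pool.

    d[Ca]/dt = −influx_scale · i_Ca − ([Ca] − rest)/decay_tau, with i_Ca the
    Ca²⁺ current density in mA/cm² (inward currents are negative, hence the
    minus sign raises [Ca]).  Concentration is clamped at 0.
    """

    concentration: float = 1e-4   # mM
    rest: float = 1e-4            # mM
    decay_tau: float = 80.0       # ms
    influx_scale: float = 5e-3    # mM·cm²/(ms·mA)

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("Ca concentration must be >= 0")
        if self.decay_tau <= 0:
            raise ValueError("Ca decay_tau must be > 0")


def steady_state(gate: GateSpec, modifier: KineticModifier, v):
    """Steady-state open fraction of ``gate`` under ``modifier`` at voltage ``v``.

    Returns 1/(1 + exp((V_half + Δv − v)/(k·s))); strictly monotone in ``v``
    with the direction set by the sign of ``slope_k``.
    """
    v = _require_finite(v)
    k = gate.slope_k * modifier.slope_factor
    return 1.0 / (1.0 + np.exp((gate.v_half + modifier.dv_shift - v) / k))


def time_constant(gate: GateSpec, modifier: KineticModifier, v):
    """τ(V) of ``gate`` under ``modifier``: τ_base(v − Δv) · tau_factor, in ms."""
    v = _require_finite(v)
    return gate.tau(v - modifier.dv_shift) * modifier.tau_factor


def nernst_ca(ca_mm, ca_out: float = CA_OUT_MM):
    """Ca²⁺ Nernst reversal potential (mV) at 37 °C for intracellular [Ca²⁺] in mM."""
    ca = np.maximum(np.asarray(ca_mm, dtype=float), 1e-7)
    return _RT_2F_MV * np.log(ca_out / ca)


def sk_open_fraction(chan: ChannelSpec, ca_mm):
    """Hill-function open fraction of the SK channel given [Ca²⁺] in mM."""
    ca = np.maximum(np.asarray(ca_mm, dtype=float), 0.0)
    cn = ca**chan.ca_hill
    return cn / (cn + chan.ca_half**chan.ca_hill)


def channel_current(chan: ChannelSpec, gate_states, v, ca: CalciumPool | None = None):
    """Ionic current density (mA/cm²) through ``chan``.

    ``gate_states`` is a sequence of open fractions, one per gate, each in
    [0, 1].  Ca²⁺ channels use a Nernst reversal recomputed from ``ca``;
    SK ignores ``gate_states`` and uses the Hill function of ``ca``.
    Sign convention: outward positive.
    """
    v = _require_finite(v)
    g = chan.gbar * chan.effective_g_factor
    if chan.name == "SK":
        if ca is None:
            raise ValueError("SK current requires a CalciumPool")
        open_frac = sk_open_fraction(chan, ca.concentration)
    else:
        states = [np.asarray(s, dtype=float) for s in gate_states]
        if len(states) != len(chan.gates):
            raise ValueError(
                f"channel {chan.name} has {len(chan.gates)} gates, got "
                f"{len(states)} states"
            )
        for s in states:
            if np.any((s < 0) | (s > 1)):
                raise ValueError("gate states must lie in [0, 1]")
        open_frac = 1.0
        for gspec, s in zip(chan.gates, states):
            open_frac = open_frac * s**gspec.power
    if chan.is_ca_channel:
        if ca is None:
            raise ValueError(f"{chan.name} requires a CalciumPool for its reversal")
        e_rev = nernst_ca(ca.concentration)
    else:
        e_rev = chan.reversal
    return g * open_frac * (v - e_rev)


def update_calcium(pool: CalciumPool, i_ca: float, dt: float) -> CalciumPool:
    """Advance the Ca²⁺ pool by ``dt`` ms under Ca current density ``i_ca`` (mA/cm²).

    Uses the exact exponential solution of the linear ODE over the step, so a
    constant current drives [Ca] to rest − influx_scale·i_ca·decay_tau.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    target = pool.rest - pool.influx_scale * i_ca * pool.decay_tau
    f = np.exp(-dt / pool.decay_tau)
    new = target + (pool.concentration - target) * f
    return replace(pool, concentration=float(max(new, 0.0)))


# ---------------------------------------------------------------------------
# Channel parameter tables
# ---------------------------------------------------------------------------

_GATE_PARAMS = {"v_half", "slope_k", "power", "tau_base", "tau_amp", "tau_vpeak", "tau_sigma"}
_CHANNEL_PARAMS = {"reversal", "ca_half", "ca_hill"}


def load_channel_table(path) -> dict[str, ChannelSpec]:
    """Load a channel-kinetics TSV into ``{name: ChannelSpec}`` prototypes.

    The file has columns ``channel  gate  parameter  value`` with one row per
    (channel, gate, parameter); channel-level rows (reversal, SK Ca
    parameters) use ``-`` in the gate column.  Conductance densities are not
    part of this table — they are per-compartment properties of a cell.
    Validation is strict: unknown channels, unknown parameters, missing
    required fields and malformed values are all rejected with the offending
    line number.
    """
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    expected = ["channel", "gate", "parameter", "value"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")

    per_channel: dict[str, dict] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        name = str(row["channel"]).strip()
        if name not in CHANNEL_NAMES:
            raise ValueError(f"{path}:{line}: unknown channel {name!r}")
        gate = str(row["gate"]).strip()
        param = str(row["parameter"]).strip()
        raw = str(row["value"]).strip()
        entry = per_channel.setdefault(name, {"gates": {}, "channel": {}})
        if gate == "-":
            if param not in _CHANNEL_PARAMS:
                raise ValueError(f"{path}:{line}: unknown channel parameter {param!r}")
            if param == "reversal" and raw == "ca":
                entry["channel"][param] = "ca"
            else:
                entry["channel"][param] = float(raw)
        else:
            if param not in _GATE_PARAMS:
                raise ValueError(f"{path}:{line}: unknown gate parameter {param!r}")
            entry["gates"].setdefault(gate, {})[param] = float(raw)

    specs: dict[str, ChannelSpec] = {}
    for name, entry in per_channel.items():
        if "reversal" not in entry["channel"]:
            raise ValueError(f"{path}: channel {name} is missing a reversal row")
        gates = []
        for gname, p in entry["gates"].items():
            missing = {"v_half", "slope_k", "tau_base"} - set(p)
            if missing:
                raise ValueError(
                    f"{path}: gate {name}.{gname} missing parameters {sorted(missing)}"
                )
            gates.append(
                GateSpec(
                    name=gname,
                    v_half=p["v_half"],
                    slope_k=p["slope_k"],
                    power=int(p.get("power", 1)),
                    tau=TauSpec(
                        base=p["tau_base"],
                        amp=p.get("tau_amp", 0.0),
                        v_peak=p.get("tau_vpeak", 0.0),
                        sigma=p.get("tau_sigma", 30.0),
                    ),
                )
            )
        # stable gate order: activation (m-like) before inactivation (h-like)
        gates.sort(key=lambda g: g.name)
        kwargs = {}
        if "ca_half" in entry["channel"]:
            kwargs["ca_half"] = entry["channel"]["ca_half"]
        if "ca_hill" in entry["channel"]:
            kwargs["ca_hill"] = entry["channel"]["ca_hill"]
        specs[name] = ChannelSpec(
            name=name,
            gates=tuple(gates),
            gbar=0.0,
            reversal=entry["channel"]["reversal"],
            **kwargs,
        )
    return specs
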