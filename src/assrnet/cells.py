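"""Reduced-morphology single-cell models and electrophysiological features.

Two cell types are provided: a four-compartment layer-5 pyramidal cell (L5PC:
basal — soma — apical trunk — apical tuft chain, the full eleven-channel
complement at the soma, Ih increasing along the apical dendrite, and an
intracellular Ca²⁺ pool) and a single-compartment fast-spiking PV⁺ basket
cell.  Geometry, densities and kinetics are loaded from versioned parameter
files under ``assrnet/data`` so they are data, not code.

Step-current protocols and the resulting :class:`FeatureVector` (spike
counts, latency, resting potential, input resistance) are used both to
validate the cells and as the acceptance criterion for variant downscaling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .channels import CalciumPool, ChannelSpec, KineticModifier, load_channel_table
from .engine import CompiledCells

__all__ = [
    "CompartmentSpec",
    "CellSpec",
    "FeatureVector",
    "StepProtocol",
    "build_l5pc",
    "build_basket",
    "step_response",
    "step_responses",
    "extract_features",
    "count_spikes",
    "data_path",
]

SPIKE_THRESHOLD_MV = 0.0
SPIKE_MERGE_MS = 2.0


def data_path(name: str) -> Path:
    """Path to a bundled parameter file."""
    return Path(resources.files("assrnet.data") / name)


@dataclass(frozen=True)
class CompartmentSpec:
    name: str
    length_um: float
    diameter_um: float
    axial_resistivity: float       # Ω·cm
    capacitance: float             # µF/cm²
    channels: tuple[ChannelSpec, ...]

    def __post_init__(self):
        if min(self.length_um, self.diameter_um) <= 0:
            raise ValueError(f"compartment {self.name}: geometry must be positive")
        if self.axial_resistivity <= 0 or self.capacitance <= 0:
            raise ValueError(f"compartment {self.name}: Ra and Cm must be positive")


@dataclass(frozen=True)
class CellSpec:
    cell_type: str                      # "L5PC" | "FS_basket"
    compartments: tuple[CompartmentSpec, ...]
    v_init: float
    ca_pool: Optional[CalciumPool] = None

    def __post_init__(self):
        somas = [c for c in self.compartments if c.name == "soma"]
        if len(somas) != 1:
            raise ValueError("cell must contain exactly one soma compartment")
        if self.cell_type == "L5PC" and len(self.compartments) < 2:
            raise ValueError("L5PC requires at least two compartments")
        if self.cell_type == "FS_basket" and len(self.compartments) != 1:
            raise ValueError("FS basket cell is single-compartment")

    @property
    def soma_index(self) -> int:
        return next(i for i, c in enumerate(self.compartments) if c.name == "soma")

    @property
    def channel_names(self) -> set[str]:
        return {ch.name for c in self.compartments for ch in c.channels}

    def with_modifiers(self, modifiers: Mapping[str, KineticModifier]) -> "CellSpec":
        """Compose ``modifiers`` (channel name → modifier) onto every matching channel.

        Raises if a modifier references a channel the cell does not express.
        """
        missing = set(modifiers) - self.channel_names
        if missing:
            raise ValueError(
                f"modifiers reference channels absent from the cell: {sorted(missing)}"
            )
        new_comps = []
        for comp in self.compartments:
            chans = tuple(
                ch.with_modifier(modifiers[ch.name]) if ch.name in modifiers else ch
                for ch in comp.channels
            )
            new_comps.append(replace(comp, channels=chans))
        return replace(self, compartments=tuple(new_comps))


@dataclass(frozen=True)
class FeatureVector:
    """Features of the step-current response used by the downscaling criterion."""

    spike_counts: tuple[int, ...]          # per suprathreshold-protocol amplitude
    first_spike_latency: Optional[float]   # ms from step onset; None if no spikes
    resting_v: float                       # mV
    input_resistance: float                # MΩ

    def __post_init__(self):
        if any(c < 0 for c in self.spike_counts):
            raise ValueError("spike counts must be >= 0")


@dataclass(frozen=True)
class StepProtocol:
    """Somatic step-current protocol for feature extraction.

    Amplitudes are in nA; ``sub_amplitude`` must be subthreshold (it provides
    the input-resistance estimate).  Defaults follow the package's calibrated
    reference amplitude for the L5PC.
    """

    amplitudes: tuple[float, ...] = (0.45, 0.75, 1.05)   # {0.3, 0.5, 0.7} × 1.5 nA
    sub_amplitude: float = -0.05
    delay_ms: float = 200.0
    duration_ms: float = 1000.0
    tail_ms: float = 100.0
    dt_ms: float = 0.025

    def __post_init__(self):
        if self.duration_ms < 500.0:
            raise ValueError("feature protocol steps must last >= 500 ms")
        if self.dt_ms > 0.05:
            raise ValueError("dt must be <= 0.05 ms")
        if len(self.amplitudes) < 2:
            raise ValueError("need >= 2 suprathreshold-protocol amplitudes")


def _build_cell(cell_file, channel_file, modifiers, gbar_overrides=None) -> CellSpec:
    cfg = yaml.safe_load(Path(cell_file).read_text())
    table = load_channel_table(channel_file)
    comps = []
    for c in cfg["compartments"]:
        chans = []
        for name, dens in c["channels"].items():
            if name not in table:
                raise ValueError(
                    f"{cell_file}: compartment {c['name']} references channel "
                    f"{name!r} absent from {channel_file}"
                )
            if gbar_overrides and (c["name"], name) in gbar_overrides:
                dens = gbar_overrides[(c["name"], name)]
            chans.append(table[name].with_gbar(float(dens)))
        comps.append(
            CompartmentSpec(
                name=c["name"],
                length_um=float(c["length_um"]),
                diameter_um=float(c["diameter_um"]),
                axial_resistivity=float(c["axial_resistivity"]),
                capacitance=float(c["capacitance"]),
                channels=tuple(chans),
            )
        )
    ca = None
    if "calcium" in cfg:
        cc = cfg["calcium"]
        ca = CalciumPool(
            concentration=float(cc["rest"]),
            rest=float(cc["rest"]),
            decay_tau=float(cc["decay_tau"]),
            influx_scale=float(cc["influx_scale"]),
        )
    cell = CellSpec(
        cell_type=cfg["cell_type"],
        compartments=tuple(comps),
        v_init=float(cfg["v_init"]),
        ca_pool=ca,
    )
    if modifiers:
        cell = cell.with_modifiers(modifiers)
    return cell


def build_l5pc(
    cell_file=None,
    channel_file=None,
    modifiers: Mapping[str, KineticModifier] | None = None,
) -> CellSpec:
    """Build the reduced layer-5 pyramidal cell from its parameter files."""
    cell_file = cell_file or data_path("cell_l5pc.yaml")
    channel_file = channel_file or data_path("channels_l5pc.tsv")
    return _build_cell(cell_file, channel_file, modifiers)


def build_basket(
    cell_file=None,
    channel_file=None,
    modifiers: Mapping[str, KineticModifier] | None = None,
) -> CellSpec:
    """Build the fast-spiking PV⁺ basket cell from its parameter files."""
    cell_file = cell_file or data_path("cell_fs.yaml")
    channel_file = channel_file or data_path("channels_fs.tsv")
    return _build_cell(cell_file, channel_file, modifiers)


def step_responses(
    cell: CellSpec,
    amplitudes: Sequence[float],
    duration: float = 1000.0,
    dt: float = 0.025,
    delay: float = 200.0,
    tail: float = 100.0,
):
    """Somatic voltage traces for a batch of step amplitudes (one cell each).

    Returns ``(t, V)`` with ``t`` in ms and ``V`` of shape
    ``(len(amplitudes), len(t))``.  Deterministic: no noise enters single-cell
    protocols.
    """
    amplitudes = np.asarray(list(amplitudes), dtype=float)
    pop = CompiledCells(cell, n=len(amplitudes), dt=dt)
    n_steps = int(round((delay + duration + tail) / dt))
    on = int(round(delay / dt))
    off = int(round((delay + duration) / dt))
    inj = np.zeros((len(amplitudes), pop.n_comp))
    t = np.arange(n_steps + 1) * dt
    v = np.empty((len(amplitudes), n_steps + 1))
    v[:, 0] = pop.V[:, pop.soma_index]
    soma = pop.soma_index
    for k in range(n_steps):
        inj[:, soma] = amplitudes if on <= k < off else 0.0
        pop.advance(inj)
        v[:, k + 1] = pop.V[:, soma]
    return t, v


def step_response(cell: CellSpec, amplitude: float, duration: float = 1000.0,
                  dt: float = 0.025, delay: float = 200.0, tail: float = 100.0):
    """Somatic voltage trace for a single step amplitude; ``(t, v)`` arrays."""
    t, v = step_responses(cell, [amplitude], duration=duration, dt=dt,
                          delay=delay, tail=tail)
    return t, v[0]


def count_spikes(t, v, t_start=None, t_stop=None,
                 threshold: float = SPIKE_THRESHOLD_MV,
                 merge_ms: float = SPIKE_MERGE_MS):
    """Spike times from a voltage trace: upward threshold crossings, merged
    within a ``merge_ms`` refractory window."""
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    up = np.flatnonzero((v[1:] >= threshold) & (v[:-1] < threshold))
    times = t[up + 1]
    if t_start is not None:
        times = times[times >= t_start]
    if t_stop is not None:
        times = times[times < t_stop]
    if times.size == 0:
        return times
    kept = [times[0]]
    for x in times[1:]:
        if x - kept[-1] >= merge_ms:
            kept.append(x)
    return np.asarray(kept)


def extract_features(
    cell: CellSpec,
    protocol: StepProtocol = StepProtocol(),
) -> FeatureVector:
    """Run the step protocol on ``cell`` and extract its feature vector.

    The subthreshold step provides the input resistance (steady-state
    deflection / current); the zero-current tail of the subthreshold trace is
    not used — resting potential comes from the pre-stimulus window.
    """
    amps = list(protocol.amplitudes) + [protocol.sub_amplitude]
    t, traces = step_responses(
        cell, amps, duration=protocol.duration_ms, dt=protocol.dt_ms,
        delay=protocol.delay_ms, tail=protocol.tail_ms,
    )
    return features_from_traces(t, traces, protocol)


def features_from_traces(t, traces, protocol: StepProtocol) -> FeatureVector:
    """Feature extraction given already-simulated protocol traces.

    ``traces`` rows follow ``protocol.amplitudes`` order with the subthreshold
    trace last.
    """
    t = np.asarray(t, float)
    traces = np.asarray(traces, float)
    on = protocol.delay_ms
    off = protocol.delay_ms + protocol.duration_ms
    pre = (t >= on - 50.0) & (t < on)
    resting = float(np.mean(traces[-1][pre]))

    counts = []
    latency = None
    for row in traces[:-1]:
        st = count_spikes(t, row, t_start=on, t_stop=off)
        counts.append(len(st))
        if latency is None and len(st):
            latency = float(st[0] - on)

    sub = traces[-1]
    ss = (t >= off - 100.0) & (t < off)
    deflection = float(np.mean(sub[ss])) - resting
    if np.any(count_spikes(t, sub, t_start=on, t_stop=off)):
        raise ValueError("subthreshold protocol step produced spikes")
    input_resistance = deflection / protocol.sub_amplitude  # mV/nA = MΩ
    return FeatureVector(
        spike_counts=tuple(counts),
        first_spike_latency=latency,
        resting_v=resting,
        input_resistance=float(input_resistance),
    )
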