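"""The 256E/64I PING microcircuit: structure, drive, and conditions.

Pyramidal (L5PC) and fast-spiking basket cells are wired with
Erdős–Rényi-per-projection random connectivity; excitatory connections act
through AMPA and NMDA conductances, inhibitory ones through GABA_A.  All
cells receive Poisson background input; the 40 Hz auditory steady-state drive
arrives as bouts of input spikes every 25 ms, optionally jittered per cell,
with a fraction (35 %) of interneurons receiving no drive (preferential
thalamic targeting of pyramidal cells — this subpopulation is what lets
prolonged inhibition express a 20 Hz subharmonic).

Experimental conditions are alternatives applied to a control network:
a scaled ion-channel variant on every pyramidal cell, ``Gmax`` (GABA_A peak
conductance × 0.75) or ``IPSC`` (GABA_A decay 8 → 25 ms).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .cells import CellSpec, build_basket, build_l5pc
from .variants import ScaledVariant, apply_variant

__all__ = [
    "SynapseSpec",
    "DriveSpec",
    "NetworkConfig",
    "Condition",
    "Network",
    "build_network",
    "make_click_train",
    "make_background",
    "apply_condition",
    "synaptic_current",
]

GABA_CONTROL_DECAY_MS = 8.0
GABA_IPSC_DECAY_MS = 25.0
GMAX_REDUCTION_FACTOR = 0.75


@dataclass(frozen=True)
class SynapseSpec:
    """Bi-exponential conductance synapse parameters (per-event peak g_max)."""

    kind: str                 # "AMPA" | "NMDA" | "GABA_A"
    g_max: float              # µS, peak conductance of a unit event
    tau_rise: float           # ms
    tau_decay: float          # ms
    reversal: float           # mV
    mg_block: bool = False    # NMDA voltage-dependent Mg2+ block

    def __post_init__(self):
        if self.kind not in ("AMPA", "NMDA", "GABA_A"):
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("need tau_decay > tau_rise > 0")
        if self.mg_block and self.kind != "NMDA":
            raise ValueError("mg_block applies to NMDA only")


@dataclass(frozen=True)
class DriveSpec:
    """40 Hz click-train drive: bouts of input spikes every 25 ms."""

    inter_bout_interval: float = 25.0   # ms
    spikes_per_bout: int = 1
    weight: float = 8e-3                # µS per bout spike (AMPA peak), pyramidal
    inh_weight_factor: float = 0.3      # interneuron drive relative to pyramidal
    onset: float = 200.0                # ms
    duration: float = 1000.0            # ms of drive
    jitter_ms: float = 0.0              # uniform half-width per (cell, bout)
    inh_no_drive_fraction: float = 0.35

    def __post_init__(self):
        if self.inter_bout_interval <= 0:
            raise ValueError("inter-bout interval must be > 0")
        if self.jitter_ms < 0:
            raise ValueError("jitter half-width must be >= 0")
        if not (0 <= self.inh_no_drive_fraction <= 1):
            raise ValueError("inh_no_drive_fraction must be in [0, 1]")

    @property
    def bout_times(self) -> np.ndarray:
        n = int(np.floor(self.duration / self.inter_bout_interval))
        return self.onset + np.arange(n) * self.inter_bout_interval


@dataclass
class NetworkConfig:
    """Population sizes, connectivity, synapses, background and drive.

    Connection probabilities/weights and background rates are this package's
    calibrated stand-ins (tuned once so the control network entrains to the
    40 Hz drive); only the GABA_A decay of 8 ms is fixed by the modelled
    physiology.  ``scale`` shrinks both populations uniformly (preserving the
    4:1 E:I ratio) for fast test fixtures.
    """

    n_exc: int = 256
    n_inh: int = 64
    # connection probabilities per projection
    p_ee: float = 0.1
    p_ei: float = 0.3
    p_ie: float = 0.3
    p_ii: float = 0.3
    # peak conductances per projection event, µS
    w_ee: float = 5e-4
    w_ei: float = 1e-3
    w_ie: float = 4e-3
    w_ii: float = 2e-3
    nmda_ratio: float = 0.3       # NMDA peak relative to AMPA of same projection
    # synaptic kinetics (defaults conventional; GABA_A decay is physiology-fixed)
    ampa: SynapseSpec = field(default_factory=lambda: SynapseSpec(
        "AMPA", 1.0, 0.5, 2.0, 0.0))
    nmda: SynapseSpec = field(default_factory=lambda: SynapseSpec(
        "NMDA", 1.0, 2.0, 100.0, 0.0, mg_block=True))
    gaba: SynapseSpec = field(default_factory=lambda: SynapseSpec(
        "GABA_A", 1.0, 0.5, GABA_CONTROL_DECAY_MS, -75.0))
    # Poisson background
    bg_rate_exc: float = 600.0    # Hz per pyramidal cell
    bg_rate_inh: float = 600.0    # Hz per basket cell
    bg_weight_exc: float = 8e-4   # µS
    bg_weight_inh: float = 3e-4   # µS
    drive: DriveSpec = field(default_factory=DriveSpec)
    lfp_mode: str = "synaptic"    # synaptic | synaptic_all | membrane
    dt: float = 0.05              # ms
    delay_ms: float = 1.0         # synaptic delay, all projections
    mg_mm: float = 1.0
    scale: float = 1.0

    def __post_init__(self):
        for p in (self.p_ee, self.p_ei, self.p_ie, self.p_ii):
            if not (0 <= p <= 1):
                raise ValueError(f"connection probability {p} outside [0, 1]")
        if self.n_exc <= 0 or self.n_inh <= 0:
            raise ValueError("population sizes must be positive")

    @property
    def n_exc_scaled(self) -> int:
        return max(1, int(round(self.n_exc * self.scale)))

    @property
    def n_inh_scaled(self) -> int:
        return max(1, int(round(self.n_inh * self.scale)))


@dataclass(frozen=True)
class Condition:
    """An experimental condition: control, a variant, Gmax or IPSC.

    Conditions are alternatives — they are applied to a control network and
    do not stack (a Gmax+IPSC composite is not a modelled condition).
    """

    label: str
    variant: Optional[ScaledVariant] = None

    @staticmethod
    def control() -> "Condition":
        return Condition("control")

    @staticmethod
    def from_variant(sv: ScaledVariant) -> "Condition":
        return Condition(f"variant:{sv.id}", variant=sv)

    @staticmethod
    def gmax() -> "Condition":
        return Condition("Gmax")

    @staticmethod
    def ipsc() -> "Condition":
        return Condition("IPSC")

    @property
    def kind(self) -> str:
        return "variant" if self.variant is not None else self.label


class Network:
    """One structural realization (virtual subject) of the microcircuit.

    Holds the cell templates, adjacency matrices and drive-free interneuron
    mask; the integration state is created per trial by the pipeline.
    Deterministic given (config, subject_seed).
    """

    def __init__(self, cfg: NetworkConfig, adj: dict, no_drive_inh: np.ndarray,
                 cell_exc: CellSpec, cell_inh: CellSpec, subject_seed: int,
                 condition: Condition):
        self.cfg = cfg
        self.adj = adj                    # {'ee','ei','ie','ii'}: float32 (n_pre, n_post)
        self.no_drive_inh = no_drive_inh  # bool (n_inh,)
        self.cell_exc = cell_exc
        self.cell_inh = cell_inh
        self.subject_seed = subject_seed
        self.condition = condition

    @property
    def n_exc(self) -> int:
        return self.adj["ee"].shape[0]

    @property
    def n_inh(self) -> int:
        return self.adj["ii"].shape[0]

    def adjacency_checksum(self) -> int:
        """Structure fingerprint used to verify paired-subject reuse."""
        import zlib

        crc = 0
        for key in sorted(self.adj):
            crc = zlib.crc32(np.ascontiguousarray(self.adj[key]).tobytes(), crc)
        crc = zlib.crc32(self.no_drive_inh.tobytes(), crc)
        return crc


def build_network(
    cfg: NetworkConfig,
    subject_seed: int,
    cell_exc: CellSpec | None = None,
    cell_inh: CellSpec | None = None,
) -> Network:
    """Instantiate one virtual subject: cells, connectivity, drive-free mask.

    Connectivity per projection is Bernoulli with the configured probability;
    self-connections are excluded.  round(inh_no_drive_fraction · n_inh)
    interneurons (22 of 64 at defaults, round-half-to-even as in numpy) are
    marked drive-free.  Deterministic given ``subject_seed``.
    """
    ne, ni = cfg.n_exc_scaled, cfg.n_inh_scaled
    rng = np.random.default_rng(np.random.SeedSequence([int(subject_seed), 0xC0FFEE]))
    cell_exc = cell_exc if cell_exc is not None else build_l5pc()
    cell_inh = cell_inh if cell_inh is not None else build_basket()

    def bern(n_pre, n_post, p, no_self=False):
        a = (rng.random((n_pre, n_post)) < p).astype(np.float32)
        if no_self and n_pre == n_post:
            np.fill_diagonal(a, 0.0)
        return a

    adj = {
        "ee": bern(ne, ne, cfg.p_ee, no_self=True),
        "ei": bern(ne, ni, cfg.p_ei),
        "ie": bern(ni, ne, cfg.p_ie),
        "ii": bern(ni, ni, cfg.p_ii, no_self=True),
    }
    n_no_drive = int(round(cfg.drive.inh_no_drive_fraction * ni))
    no_drive = np.zeros(ni, dtype=bool)
    no_drive[rng.choice(ni, size=n_no_drive, replace=False)] = True
    return Network(cfg, adj, no_drive, cell_exc, cell_inh,
                   int(subject_seed), Condition.control())


def apply_condition(network: Network, cond: Condition) -> Network:
    """Return a new network with ``cond`` applied; the input is untouched.

    Conditions only apply to a control network: stacking Gmax with IPSC (or
    any condition onto an already-conditioned network) is rejected, matching
    the modelled experimental design where conditions are alternatives.
    """
    if network.condition.label != "control" and cond.label != "control":
        raise ValueError(
            f"cannot stack condition {cond.label!r} onto "
            f"{network.condition.label!r}: conditions are alternatives"
        )
    cfg = copy.deepcopy(network.cfg)
    cell_exc = network.cell_exc
    if cond.label == "control":
        pass
    elif cond.label == "Gmax":
        cfg.w_ie *= GMAX_REDUCTION_FACTOR
        cfg.w_ii *= GMAX_REDUCTION_FACTOR
    elif cond.label == "IPSC":
        cfg.gaba = replace(cfg.gaba, tau_decay=GABA_IPSC_DECAY_MS)
    elif cond.variant is not None:
        cell_exc = apply_variant(network.cell_exc, cond.variant)
    else:
        raise ValueError(f"unknown condition {cond.label!r}")
    out = Network(cfg, network.adj, network.no_drive_inh, cell_exc,
                  network.cell_inh, network.subject_seed, cond)
    return out


def make_click_train(drive: DriveSpec, n_cells: int, rng=None,
                     drive_mask: np.ndarray | None = None) -> list[np.ndarray]:
    """Per-cell input spike times for the 40 Hz click train.

    Without jitter every cell shares the identical bout times; with jitter
    each (cell, bout) time is offset by an independent uniform draw in
    [−jitter, +jitter].  ``drive_mask`` (True = receives drive) silences the
    drive-free interneuron subpopulation.  Returns a list of time arrays (ms).
    """
    base = np.repeat(drive.bout_times, max(drive.spikes_per_bout, 1))
    if drive.duration < 10 * drive.inter_bout_interval:
        raise ValueError("drive must cover at least 10 bouts")
    schedules = []
    for i in range(n_cells):
        if drive_mask is not None and not drive_mask[i]:
            schedules.append(np.empty(0))
            continue
        if drive.jitter_ms > 0:
            if rng is None:
                raise ValueError("jittered drive requires an rng")
            t = base + rng.uniform(-drive.jitter_ms, drive.jitter_ms, size=base.size)
        else:
            t = base.copy()
        schedules.append(np.sort(t))
    return schedules


def make_background(rate_hz: float, duration: float, rng) -> np.ndarray:
    """Homogeneous Poisson spike times on [0, duration) ms for one cell."""
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    if rate_hz == 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * duration / 1000.0)
    return np.sort(rng.uniform(0.0, duration, size=n))


def synaptic_current(syn: SynapseSpec, spike_times, t, v, mg_mm: float = 1.0):
    """Current (nA) of a bi-exponential synapse at time ``t`` and voltage ``v``.

    Reference implementation of the conductance law used by the integrator:
    the difference of exponentials is normalised so each event of weight
    ``g_max`` peaks at exactly ``g_max`` µS; NMDA is scaled by the sigmoidal
    Mg²⁺-block factor of the postsynaptic voltage.
    """
    from .engine import mg_block

    t = float(t)
    g = 0.0
    tr, td = syn.tau_rise, syn.tau_decay
    tp = (td * tr / (td - tr)) * np.log(td / tr)
    norm = 1.0 / (np.exp(-tp / td) - np.exp(-tp / tr))
    for ts in np.atleast_1d(spike_times):
        dtau = t - ts
        if dtau <= 0:
            continue
        g += syn.g_max * norm * (np.exp(-dtau / td) - np.exp(-dtau / tr))
    if syn.mg_block:
        g *= mg_block(v, mg_mm)
    return g * (v - syn.reversal)
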