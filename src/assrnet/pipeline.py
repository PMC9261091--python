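"""Cohort simulation: virtual subjects × trials per condition, LFP synthesis.

A *virtual subject* is one structural realization of the microcircuit
(connectivity and drive-free mask drawn from a subject-specific seed);
*trials* within a subject differ only in the noise realization (Poisson
background and, if enabled, drive jitter).  The default cohort is 20 subjects
× 10 trials = 200 simulations per condition, with the same 20 subject
structures reused across conditions (paired design against the shared
control).

The model LFP is a standard proxy for this class of network: the sum over
pyramidal cells of the absolute AMPA and GABA_A synaptic currents at the
soma, boxcar-averaged to 1 kHz, in arbitrary units.  A summed-membrane-potential
proxy is selectable via configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .engine import CompiledCells
from .network import (
    Condition,
    Network,
    NetworkConfig,
    apply_condition,
    build_network,
    make_background,
    make_click_train,
)

__all__ = [
    "CohortPlan",
    "TrialResult",
    "CohortResult",
    "run_trial",
    "run_cohort",
    "compute_lfp",
    "trial_schedules",
    "subject_seed_for",
]

LFP_FS_HZ = 1000.0


@dataclass(frozen=True)
class CohortPlan:
    """Simulation grid: conditions × subjects × trials."""

    conditions: tuple[Condition, ...] = (Condition.control(),)
    n_subjects: int = 20
    n_trials: int = 10
    analysis_start: float = 200.0    # ms, drive onset (settling discarded)
    analysis_stop: float = 1200.0    # ms

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("cohort needs >= 1 subject and >= 1 trial")

    @property
    def n_simulations_per_condition(self) -> int:
        return self.n_subjects * self.n_trials


@dataclass
class TrialResult:
    """LFP and spikes of one simulated trial."""

    lfp: np.ndarray                   # a.u., sampled at fs
    fs: float                         # Hz
    spikes_exc: list[np.ndarray]      # per-cell spike times, ms
    spikes_inh: list[np.ndarray]
    metadata: dict
    failed: bool = False

    def __post_init__(self):
        if not self.failed and not np.all(np.isfinite(self.lfp)):
            raise ValueError("LFP contains non-finite samples")
        if self.fs < 1000.0:
            raise ValueError("LFP sampling rate must be >= 1 kHz")


class CohortResult:
    """Complete (condition × subject × trial) grid of trial results."""

    def __init__(self, plan: CohortPlan, cfg: NetworkConfig, base_seed: int):
        self.plan = plan
        self.cfg = cfg
        self.base_seed = base_seed
        self.trials: dict[tuple[str, int, int], TrialResult] = {}
        self.checksums: dict[str, int] = {}

    def add(self, cond: str, subject: int, trial: int, result: TrialResult):
        self.trials[(cond, subject, trial)] = result

    def get(self, cond: str, subject: int, trial: int) -> TrialResult:
        return self.trials[(cond, subject, trial)]

    def lfp_matrix(self, cond: str, subject: int) -> np.ndarray:
        """(n_trials, n_samples) LFP stack for one subject, failed trials excluded."""
        rows = [
            self.trials[(cond, subject, t)].lfp
            for t in range(self.plan.n_trials)
            if not self.trials[(cond, subject, t)].failed
        ]
        if not rows:
            raise ValueError(f"all trials failed for {cond} subject {subject}")
        return np.vstack(rows)

    def n_failed(self) -> int:
        return sum(r.failed for r in self.trials.values())

    def validate_complete(self):
        missing = []
        for cond in self.plan.conditions:
            for s in range(self.plan.n_subjects):
                for t in range(self.plan.n_trials):
                    if (cond.label, s, t) not in self.trials:
                        missing.append((cond.label, s, t))
        if missing:
            raise ValueError(f"incomplete cohort grid, missing {missing[:5]}...")

    # -- persistence --------------------------------------------------
    def save(self, path):
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["base_seed"] = self.base_seed
            f.attrs["n_subjects"] = self.plan.n_subjects
            f.attrs["n_trials"] = self.plan.n_trials
            f.attrs["analysis_start"] = self.plan.analysis_start
            f.attrs["analysis_stop"] = self.plan.analysis_stop
            for (cond, s, t), r in self.trials.items():
                g = f.require_group(f"{cond}/s{s:03d}/t{t:03d}")
                d = g.create_dataset("lfp", data=r.lfp)
                d.attrs["sha256"] = hashlib.sha256(
                    np.ascontiguousarray(r.lfp).tobytes()
                ).hexdigest()
                g.attrs["failed"] = r.failed
                g.attrs["fs"] = r.fs
                meta = {k: v for k, v in r.metadata.items()
                        if not isinstance(v, np.ndarray)}
                g.attrs["metadata"] = json.dumps(meta)

    @staticmethod
    def load(path, plan: CohortPlan, cfg: NetworkConfig) -> "CohortResult":
        import h5py

        with h5py.File(path, "r") as f:
            out = CohortResult(plan, cfg, int(f.attrs["base_seed"]))
            for cond in f:
                for sname in f[cond]:
                    for tname in f[cond][sname]:
                        g = f[cond][sname][tname]
                        lfp = g["lfp"][...]
                        digest = hashlib.sha256(
                            np.ascontiguousarray(lfp).tobytes()
                        ).hexdigest()
                        if digest != g["lfp"].attrs["sha256"]:
                            raise IOError(
                                f"checksum mismatch in {path}: "
                                f"{cond}/{sname}/{tname} is corrupt"
                            )
                        out.add(
                            cond, int(sname[1:]), int(tname[1:]),
                            TrialResult(
                                lfp=lfp, fs=float(g.attrs["fs"]),
                                spikes_exc=[], spikes_inh=[],
                                metadata=json.loads(g.attrs["metadata"]),
                                failed=bool(g.attrs["failed"]),
                            ),
                        )
        return out


def compute_lfp(pop_exc: CompiledCells, mode: str = "synaptic") -> float:
    """Instantaneous model LFP in arbitrary units.  Linear in population size.

    ``synaptic`` (default): Σ over pyramidal cells of |I_AMPA| + |I_GABA_A|
    at the soma, counting recurrent (network) synapses only, so the signal
    reflects circuit activity rather than the stereotyped feed-forward drive.
    ``synaptic_all`` additionally counts the external AMPA (drive +
    background) currents.  ``membrane``: summed somatic membrane potentials
    (selectable so an alternative LFP definition can be swapped in without
    code changes).
    """
    soma = pop_exc.soma_index
    v = pop_exc.V[:, soma]
    if mode == "membrane":
        return float(np.sum(v))
    include_ext = mode in ("ampa_all", "synaptic_all")
    include_gaba = mode in ("synaptic", "synaptic_all")
    i_ampa = np.zeros_like(v)
    i_gaba = np.zeros_like(v)
    for name, syn in pop_exc.synapses.items():
        if name == "ampa_ext" and not include_ext:
            continue
        if name.startswith("gaba") and not include_gaba:
            continue
        g = syn.conductance(v if syn.nmda else None)
        if name.startswith("ampa"):
            i_ampa += g * (v - syn.reversal)
        elif name.startswith("gaba"):
            i_gaba += g * (v - syn.reversal)
    return float(np.sum(np.abs(i_ampa)) + np.sum(np.abs(i_gaba)))


def _bin_events(schedules: Sequence[np.ndarray], weight: float, n_steps: int,
                dt: float, out: np.ndarray):
    """Accumulate weighted spike events into a (n_steps, n_cells) array."""
    for i, times in enumerate(schedules):
        if len(times) == 0:
            continue
        idx = (np.asarray(times) / dt).astype(np.int64)
        idx = idx[(idx >= 0) & (idx < n_steps)]
        np.add.at(out[:, i], idx, weight)


def trial_schedules(network: Network, trial_rng: np.random.Generator,
                    duration: float):
    """Drive and background schedules for one trial of ``network``."""
    cfg = network.cfg
    ne, ni = network.n_exc, network.n_inh
    drive_e = make_click_train(cfg.drive, ne, rng=trial_rng)
    drive_i = make_click_train(cfg.drive, ni, rng=trial_rng,
                               drive_mask=~network.no_drive_inh)
    bg_e = [make_background(cfg.bg_rate_exc, duration, trial_rng) for _ in range(ne)]
    bg_i = [make_background(cfg.bg_rate_inh, duration, trial_rng) for _ in range(ni)]
    return {"drive_exc": drive_e, "drive_inh": drive_i,
            "bg_exc": bg_e, "bg_inh": bg_i}


def run_trial(network: Network, schedules: Mapping, duration: float,
              dt: float | None = None, metadata: dict | None = None,
              record_voltages: bool = False, backend: str = "auto") -> TrialResult:
    """Integrate one trial and synthesize the LFP at 1 kHz.

    Deterministic given the network and schedules.  Integration divergence
    (|V| > 200 mV) marks the trial as failed rather than raising.
    ``backend``: "numba" (jitted kernel), "numpy" (reference python loop) or
    "auto" (numba when available; both implement the same update equations
    and are cross-checked in the test suite).
    """
    cfg = network.cfg
    dt = cfg.dt if dt is None else dt
    if dt > 0.05:
        raise ValueError("dt must be <= 0.05 ms")
    ne, ni = network.n_exc, network.n_inh
    n_steps = int(round(duration / dt))
    steps_per_ms = int(round(1.0 / dt))

    if backend == "auto":
        from .engine_fast import NUMBA_AVAILABLE

        use_fast = (NUMBA_AVAILABLE and not record_voltages
                    and abs(steps_per_ms * dt - 1.0) < 1e-9)
        backend = "numba" if use_fast else "numpy"
    if backend == "numba":
        return _run_trial_fast(network, schedules, duration, dt, metadata)

    pe = CompiledCells(network.cell_exc, ne, dt)
    pi = CompiledCells(network.cell_inh, ni, dt)
    soma_e, soma_i = pe.soma_index, pi.soma_index
    for pop, soma in ((pe, soma_e), (pi, soma_i)):
        pop.add_synapse("ampa_rec", tau_rise=cfg.ampa.tau_rise,
                        tau_decay=cfg.ampa.tau_decay, reversal=cfg.ampa.reversal,
                        comp=soma)
        pop.add_synapse("ampa_ext", tau_rise=cfg.ampa.tau_rise,
                        tau_decay=cfg.ampa.tau_decay, reversal=cfg.ampa.reversal,
                        comp=soma)
        pop.add_synapse("nmda", tau_rise=cfg.nmda.tau_rise,
                        tau_decay=cfg.nmda.tau_decay, reversal=cfg.nmda.reversal,
                        comp=soma, nmda=True, mg_mm=cfg.mg_mm)
        pop.add_synapse("gaba", tau_rise=cfg.gaba.tau_rise,
                        tau_decay=cfg.gaba.tau_decay, reversal=cfg.gaba.reversal,
                        comp=soma)

    ext_e = np.zeros((n_steps, ne), dtype=np.float64)
    ext_i = np.zeros((n_steps, ni), dtype=np.float64)
    _bin_events(schedules["drive_exc"], cfg.drive.weight, n_steps, dt, ext_e)
    _bin_events(schedules["drive_inh"],
                cfg.drive.weight * cfg.drive.inh_weight_factor, n_steps, dt, ext_i)
    _bin_events(schedules["bg_exc"], cfg.bg_weight_exc, n_steps, dt, ext_e)
    _bin_events(schedules["bg_inh"], cfg.bg_weight_inh, n_steps, dt, ext_i)

    delay_steps = max(int(round(cfg.delay_ms / dt)), 1)
    buf_e = [np.zeros(ne) for _ in range(delay_steps)]
    buf_i = [np.zeros(ni) for _ in range(delay_steps)]

    n_samples = n_steps // steps_per_ms
    lfp = np.zeros(n_samples)
    spikes_e: list[list[float]] = [[] for _ in range(ne)]
    spikes_i: list[list[float]] = [[] for _ in range(ni)]
    a_ee, a_ei = network.adj["ee"], network.adj["ei"]
    a_ie, a_ii = network.adj["ie"], network.adj["ii"]
    voltages = [] if record_voltages else None

    failed = False
    try:
        for k in range(n_steps):
            slot = k % delay_steps
            s_e, s_i = buf_e[slot], buf_i[slot]
            exc_on_e = s_e @ a_ee
            exc_on_i = s_e @ a_ei
            pe.synapses["ampa_rec"].add(cfg.w_ee * exc_on_e)
            pe.synapses["nmda"].add(cfg.w_ee * cfg.nmda_ratio * exc_on_e)
            pe.synapses["gaba"].add(cfg.w_ie * (s_i @ a_ie))
            pe.synapses["ampa_ext"].add(ext_e[k])
            pi.synapses["ampa_rec"].add(cfg.w_ei * exc_on_i)
            pi.synapses["nmda"].add(cfg.w_ei * cfg.nmda_ratio * exc_on_i)
            pi.synapses["gaba"].add(cfg.w_ii * (s_i @ a_ii))
            pi.synapses["ampa_ext"].add(ext_i[k])

            spk_e = pe.advance()
            spk_i = pi.advance()
            buf_e[slot] = spk_e.astype(float)
            buf_i[slot] = spk_i.astype(float)
            t_now = (k + 1) * dt
            for idx in np.flatnonzero(spk_e):
                spikes_e[idx].append(t_now)
            for idx in np.flatnonzero(spk_i):
                spikes_i[idx].append(t_now)
            # boxcar-average within each 1 ms window before decimating
            # (anti-aliasing: instantaneous sampling folds volley harmonics
            # near the Nyquist rate back onto the 40 Hz band)
            sidx = k // steps_per_ms
            if sidx < n_samples:
                lfp[sidx] += compute_lfp(pe, cfg.lfp_mode) / steps_per_ms
            if (k + 1) % steps_per_ms == 0 and voltages is not None:
                voltages.append(pe.V[:, soma_e].copy())
    except FloatingPointError:
        failed = True

    meta = dict(metadata or {})
    meta.setdefault("condition", network.condition.label)
    result = TrialResult(
        lfp=lfp, fs=LFP_FS_HZ, spikes_exc=[np.asarray(s) for s in spikes_e],
        spikes_inh=[np.asarray(s) for s in spikes_i], metadata=meta,
        failed=failed,
    )
    if voltages is not None:
        result.metadata["voltages"] = np.asarray(voltages)
    return result


_LFP_MODE_CODES = {"ampa": 0, "ampa_all": 1, "synaptic": 2, "synaptic_all": 3,
                   "membrane": 4}


def _run_trial_fast(network: Network, schedules: Mapping, duration: float,
                    dt: float, metadata: dict | None) -> TrialResult:
    """Numba-kernel twin of the numpy trial loop."""
    from .engine_fast import pack_population, simulate_network

    cfg = network.cfg
    ne, ni = network.n_exc, network.n_inh
    n_steps = int(round(duration / dt))
    steps_per_ms = int(round(1.0 / dt))
    n_samples = n_steps // steps_per_ms

    pe = CompiledCells(network.cell_exc, ne, dt)
    pi = CompiledCells(network.cell_inh, ni, dt)

    ext_e = np.zeros((n_steps, ne))
    ext_i = np.zeros((n_steps, ni))
    _bin_events(schedules["drive_exc"], cfg.drive.weight, n_steps, dt, ext_e)
    _bin_events(schedules["drive_inh"],
                cfg.drive.weight * cfg.drive.inh_weight_factor, n_steps, dt, ext_i)
    _bin_events(schedules["bg_exc"], cfg.bg_weight_exc, n_steps, dt, ext_e)
    _bin_events(schedules["bg_inh"], cfg.bg_weight_inh, n_steps, dt, ext_i)

    def _kin(spec):
        tr, td = spec.tau_rise, spec.tau_decay
        tp = (td * tr / (td - tr)) * np.log(td / tr)
        norm = 1.0 / (np.exp(-tp / td) - np.exp(-tp / tr))
        return np.exp(-dt / tr), np.exp(-dt / td), norm, spec.reversal

    kins = [_kin(cfg.ampa), _kin(cfg.ampa), _kin(cfg.nmda), _kin(cfg.gaba)]
    syn_fr = np.array([k[0] for k in kins])
    syn_fd = np.array([k[1] for k in kins])
    syn_norm = np.array([k[2] for k in kins])
    syn_E = np.array([k[3] for k in kins])
    syn_nmda = np.array([False, False, True, False])

    cap = int(duration / SPIKE_REFRACTORY_FLOOR_MS) + 8
    spk_e = np.zeros((ne, cap))
    spk_i = np.zeros((ni, cap))
    cnt_e = np.zeros(ne, dtype=np.int64)
    cnt_i = np.zeros(ni, dtype=np.int64)
    lfp = np.zeros(n_samples)

    failed = simulate_network(
        *pack_population(pe), *pack_population(pi),
        syn_fr, syn_fd, syn_norm, syn_E, syn_nmda, float(cfg.mg_mm),
        network.adj["ee"].astype(np.float64), network.adj["ei"].astype(np.float64),
        network.adj["ie"].astype(np.float64), network.adj["ii"].astype(np.float64),
        float(cfg.w_ee), float(cfg.w_ee * cfg.nmda_ratio),
        float(cfg.w_ei), float(cfg.w_ei * cfg.nmda_ratio),
        float(cfg.w_ie), float(cfg.w_ii),
        ext_e, ext_i, n_steps, max(int(round(cfg.delay_ms / dt)), 1),
        steps_per_ms, _LFP_MODE_CODES[cfg.lfp_mode],
        lfp, spk_e, cnt_e, spk_i, cnt_i,
    )
    meta = dict(metadata or {})
    meta.setdefault("condition", network.condition.label)
    return TrialResult(
        lfp=lfp if not failed else np.zeros(n_samples), fs=LFP_FS_HZ,
        spikes_exc=[spk_e[i, :cnt_e[i]].copy() for i in range(ne)],
        spikes_inh=[spk_i[i, :cnt_i[i]].copy() for i in range(ni)],
        metadata=meta, failed=bool(failed),
    )


SPIKE_REFRACTORY_FLOOR_MS = 2.0


def subject_seed_for(base_seed: int, subject: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(base_seed), int(subject)])


def trial_rng_for(base_seed: int, subject: int, trial: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(base_seed), int(subject), int(trial)])
    )


def run_cohort(
    plan: CohortPlan,
    cfg: NetworkConfig,
    base_seed: int,
    store_path=None,
    resume: bool = False,
    progress: bool = False,
) -> CohortResult:
    """Run the full (condition × subject × trial) grid.

    The same subject seeds are reused across conditions, so every condition
    sees the same cohort of network structures (paired design).  With
    ``store_path`` the cohort is written to HDF5; with ``resume=True`` an
    existing store is loaded and only missing cells are simulated.
    """
    result = CohortResult(plan, cfg, int(base_seed))
    if resume and store_path is not None:
        import os

        if os.path.exists(store_path):
            prev = CohortResult.load(store_path, plan, cfg)
            result.trials.update(prev.trials)

    duration = plan.analysis_stop
    for subject in range(plan.n_subjects):
        sseed = subject_seed_for(base_seed, subject)
        sseed_int = int(sseed.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
        control_net = build_network(cfg, sseed_int)
        for cond in plan.conditions:
            net = apply_condition(control_net, cond)
            for trial in range(plan.n_trials):
                key = (cond.label, subject, trial)
                if key in result.trials:
                    continue
                rng = trial_rng_for(base_seed, subject, trial)
                sch = trial_schedules(net, rng, duration)
                meta = dict(condition=cond.label, subject=subject, trial=trial,
                            subject_seed=sseed_int,
                            trial_seed=[int(base_seed), subject, trial])
                tr = run_trial(net, sch, duration, metadata=meta)
                result.add(cond.label, subject, trial, tr)
                if progress:
                    print(f"done {key} failed={tr.failed}", flush=True)
    result.validate_complete()
    if store_path is not None:
        result.save(store_path)
    return result
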