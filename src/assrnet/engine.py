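"""Vectorized fixed-step integrator for populations of identical cells.

The simulator advances N copies of one :class:`~assrnet.cells.CellSpec`
simultaneously.  Gating variables use exponential Euler with precomputed
voltage lookup tables (steady state and per-step decay factor on a 0.05 mV
grid); membrane voltages use a backward-Euler-style cable update with channel
and synaptic conductances frozen over the step, solved per cell by the Thomas
algorithm along the compartment chain.  Units: mV, ms, nA, nF, µS, so that
dV/dt = I/C comes out in mV/ms directly.

All cells in a population share kinetics (modifiers included), which is what
lets gate updates collapse to a handful of array operations per step.
"""

from __future__ import annotations

import numpy as np

from .channels import (
    CalciumPool,
    ChannelSpec,
    nernst_ca,
    sk_open_fraction,
    steady_state,
    time_constant,
)

__all__ = ["CompiledCells", "SynapseState", "mg_block"]

_V_MIN, _V_MAX, _V_STEP = -150.0, 100.0, 0.05
#: Ca-gated SK activation time constant (ms); fast relative to the pool.
_SK_TAU_MS = 1.0
#: Spike detection: upward crossing of this threshold, merged within refractory.
SPIKE_THRESHOLD_MV = 0.0
SPIKE_REFRACTORY_MS = 2.0


def mg_block(v, mg_mm: float = 1.0):
    """Sigmoidal Mg²⁺ unblock factor of the NMDA conductance at voltage ``v``."""
    return 1.0 / (1.0 + np.exp(-0.062 * np.asarray(v, dtype=float)) * mg_mm / 3.57)


class SynapseState:
    """Aggregated bi-exponential conductance onto one population.

    Difference-of-exponentials g(t) = norm·(B − A) with per-step decay factors,
    normalised so a unit-weight event produces a unit peak conductance.  Events
    of the same kind onto the same cell superpose linearly, so one (A, B) pair
    per cell suffices for a whole projection.
    """

    def __init__(self, n: int, tau_rise: float, tau_decay: float, reversal: float,
                 dt: float, comp: int = 0, nmda: bool = False, mg_mm: float = 1.0):
        if not (tau_decay > tau_rise > 0):
            raise ValueError(
                f"need tau_decay > tau_rise > 0, got rise={tau_rise}, decay={tau_decay}"
            )
        self.tau_rise = float(tau_rise)
        self.tau_decay = float(tau_decay)
        self.reversal = float(reversal)
        self.comp = int(comp)
        self.nmda = bool(nmda)
        self.mg_mm = float(mg_mm)
        self.fr = np.exp(-dt / tau_rise)
        self.fd = np.exp(-dt / tau_decay)
        tp = (tau_decay * tau_rise / (tau_decay - tau_rise)) * np.log(tau_decay / tau_rise)
        self.norm = 1.0 / (np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise))
        self.A = np.zeros(n)
        self.B = np.zeros(n)

    def add(self, weights):
        """Register synaptic events; ``weights`` is per-cell summed peak conductance (µS)."""
        self.A += weights
        self.B += weights

    def decay(self):
        self.A *= self.fr
        self.B *= self.fd

    def conductance(self, v_comp=None):
        g = self.norm * (self.B - self.A)
        if self.nmda:
            if v_comp is None:
                raise ValueError("NMDA conductance needs the postsynaptic voltage")
            g = g * mg_block(v_comp, self.mg_mm)
        return g


class CompiledCells:
    """N identical cells compiled to flat arrays for fast stepping."""

    def __init__(self, cell, n: int, dt: float):
        from .cells import CellSpec  # local import to avoid cycle

        if not isinstance(cell, CellSpec):
            raise TypeError("cell must be a CellSpec")
        if dt <= 0 or dt > 0.05:
            raise ValueError(f"dt must be in (0, 0.05] ms, got {dt}")
        self.cell = cell
        self.n = int(n)
        self.dt = float(dt)
        comps = cell.compartments
        self.n_comp = len(comps)
        self.soma_index = cell.soma_index

        # --- geometry ---------------------------------------------------
        area = np.array([np.pi * (c.diameter_um * 1e-4) * (c.length_um * 1e-4)
                         for c in comps])               # cm², cylinder side area
        self.area = area
        self.cm_nF = np.array([c.capacitance for c in comps]) * area * 1e3  # µF/cm²·cm² → nF
        # axial coupling between consecutive compartments (chain), in µS
        g_ax = np.empty(max(self.n_comp - 1, 0))
        for i in range(self.n_comp - 1):
            r = 0.0
            for c in (comps[i], comps[i + 1]):
                half_len_cm = c.length_um * 1e-4 / 2.0
                xsec_cm2 = np.pi * (c.diameter_um * 1e-4 / 2.0) ** 2
                r += c.axial_resistivity * half_len_cm / xsec_cm2   # Ω
            g_ax[i] = 1e6 / r                                       # µS
        self.g_ax = g_ax
        ax_diag = np.zeros(self.n_comp)
        if self.n_comp > 1:
            ax_diag[:-1] += g_ax
            ax_diag[1:] += g_ax
        self.ax_diag = ax_diag

        # --- channels, sorted by compartment then name --------------------
        self.vgrid = np.arange(_V_MIN, _V_MAX + _V_STEP / 2, _V_STEP)
        nv = len(self.vgrid)
        self._inv_dv = 1.0 / _V_STEP
        self._nv = nv

        chan_comp, chan_gbar, chan_E, chan_is_ca = [], [], [], []
        gate_comp, gate_pow = [], []
        minf_rows, expf_rows = [], []
        chan_gate_start = []
        sk_rows, sk_chan = [], []
        gate_count = 0
        self._channels: list[ChannelSpec] = []
        for ci, comp in enumerate(comps):
            if not any(ch.name == "leak" for ch in comp.channels):
                raise ValueError(f"compartment {comp.name!r} lacks a leak channel")
            for ch in sorted(comp.channels, key=lambda c: c.name):
                self._channels.append(ch)
                chan_comp.append(ci)
                chan_gbar.append(ch.gbar * ch.effective_g_factor * comp_area_uS(area[ci]))
                chan_is_ca.append(ch.is_ca_channel)
                chan_E.append(np.nan if ch.is_ca_channel else float(ch.reversal))
                chan_gate_start.append(gate_count)
                if ch.name == "SK":
                    # one Ca-driven row; voltage-table update must be a no-op
                    sk_rows.append(gate_count)
                    sk_chan.append(ch)
                    gate_comp.append(ci)
                    gate_pow.append(1.0)
                    minf_rows.append(np.zeros(nv))
                    expf_rows.append(np.ones(nv))
                    gate_count += 1
                elif not ch.gates:  # leak: constant-open dummy row
                    gate_comp.append(ci)
                    gate_pow.append(1.0)
                    minf_rows.append(np.ones(nv))
                    expf_rows.append(np.zeros(nv))
                    gate_count += 1
                else:
                    for g in ch.gates:
                        mod = ch.gate_modifier(g.name)
                        gate_comp.append(ci)
                        gate_pow.append(float(g.power))
                        minf_rows.append(steady_state(g, mod, self.vgrid))
                        tau = np.maximum(time_constant(g, mod, self.vgrid), 1e-6)
                        expf_rows.append(np.exp(-dt / tau))
                        gate_count += 1

        self.chan_comp = np.asarray(chan_comp, dtype=np.intp)
        self.chan_gbar = np.asarray(chan_gbar)
        self.chan_E = np.asarray(chan_E)
        self.ca_rows = np.flatnonzero(np.asarray(chan_is_ca))
        self.gate_comp = np.asarray(gate_comp, dtype=np.intp)
        self.gate_pow = np.asarray(gate_pow)[:, None]
        self._pow_all_one = bool(np.all(self.gate_pow == 1.0))
        self.minf_tab = np.ascontiguousarray(minf_rows)
        self.expf_tab = np.ascontiguousarray(expf_rows)
        self.gate_flat_off = (np.arange(gate_count, dtype=np.intp) * nv)[:, None]
        self.chan_gate_start = np.asarray(chan_gate_start, dtype=np.intp)
        self.sk_rows = np.asarray(sk_rows, dtype=np.intp)
        self._sk_chans = sk_chan
        self._sk_decay = np.exp(-dt / _SK_TAU_MS)
        # compartment group starts in the channel list (sorted by comp, complete)
        self.comp_start = np.searchsorted(self.chan_comp, np.arange(self.n_comp))

        # --- calcium ------------------------------------------------------
        pool = cell.ca_pool if cell.ca_pool is not None else CalciumPool()
        self._pool = pool
        self.has_ca = np.zeros(self.n_comp, dtype=bool)
        self.has_ca[self.chan_comp[self.ca_rows]] = True
        self._ca_decay = np.exp(-dt / pool.decay_tau)
        # nA → mA/cm² conversion per compartment
        self._i_density = 1e-6 / area

        # --- state --------------------------------------------------------
        self.V = np.full((self.n, self.n_comp), cell.v_init, dtype=float)
        vidx = self._v_index(self.V)
        self.X = self.minf_tab.ravel()[self.gate_flat_off + vidx.T[self.gate_comp]].copy()
        self.ca = np.full((self.n_comp, self.n), pool.rest)
        if self.sk_rows.size:
            for r, ch in zip(self.sk_rows, self._sk_chans):
                self.X[r] = sk_open_fraction(ch, self.ca[self.gate_comp[r]])
        self.synapses: dict[str, SynapseState] = {}
        self._refrac_steps = int(round(SPIKE_REFRACTORY_MS / dt))
        self._refrac = np.zeros(self.n, dtype=np.int64)
        self._above = self.V[:, self.soma_index] >= SPIKE_THRESHOLD_MV
        self._cmdt = (self.cm_nF / dt)[:, None]

    # -----------------------------------------------------------------
    def add_synapse(self, name: str, **kwargs) -> SynapseState:
        syn = SynapseState(self.n, dt=self.dt, **kwargs)
        self.synapses[name] = syn
        return syn

    def _v_index(self, v):
        idx = ((v - _V_MIN) * self._inv_dv).astype(np.intp)
        return np.clip(idx, 0, self._nv - 1)

    def advance(self, inj_nA=None):
        """One dt step.  ``inj_nA``: (n, n_comp) injected current or None.

        Returns a boolean array of somatic spikes detected on this step.
        """
        dt = self.dt
        Vt = self.V.T  # (C, N) view

        # gates ---------------------------------------------------------
        vidx = self._v_index(self.V).T          # (C, N)
        gvi = self.gate_flat_off + vidx[self.gate_comp]
        minf = self.minf_tab.ravel()[gvi]
        expf = self.expf_tab.ravel()[gvi]
        self.X = minf + (self.X - minf) * expf
        for r, ch in zip(self.sk_rows, self._sk_chans):
            zinf = sk_open_fraction(ch, self.ca[self.gate_comp[r]])
            self.X[r] = zinf + (self.X[r] - zinf) * self._sk_decay

        # channel conductances -----------------------------------------
        xp = self.X if self._pow_all_one else self.X ** self.gate_pow
        open_frac = np.multiply.reduceat(xp, self.chan_gate_start, axis=0)
        g = self.chan_gbar[:, None] * open_frac          # (K, N) µS
        gE = g * self.chan_E[:, None]
        i_ca_comp = None
        if self.ca_rows.size:
            eca = nernst_ca(self.ca[self.chan_comp[self.ca_rows]])
            gE[self.ca_rows] = g[self.ca_rows] * eca
            i_ca = g[self.ca_rows] * (Vt[self.chan_comp[self.ca_rows]] - eca)  # nA
            i_ca_comp = np.zeros_like(self.ca)
            np.add.at(i_ca_comp, self.chan_comp[self.ca_rows], i_ca)

        gsum = np.add.reduceat(g, self.comp_start, axis=0)    # (C, N)
        gesum = np.add.reduceat(gE, self.comp_start, axis=0)

        # calcium -------------------------------------------------------
        if i_ca_comp is not None:
            pool = self._pool
            dens = i_ca_comp * self._i_density[:, None]        # mA/cm²
            target = pool.rest - pool.influx_scale * dens * pool.decay_tau
            upd = target + (self.ca - target) * self._ca_decay
            np.maximum(upd, 0.0, out=upd)
            self.ca[self.has_ca] = upd[self.has_ca]

        # synapses ------------------------------------------------------
        for syn in self.synapses.values():
            syn.decay()
            gs = syn.conductance(Vt[syn.comp] if syn.nmda else None)
            gsum[syn.comp] += gs
            gesum[syn.comp] += gs * syn.reversal

        # implicit voltage update (Thomas along the chain) --------------
        diag = self._cmdt + self.ax_diag[:, None] + gsum
        rhs = self._cmdt * Vt + gesum
        if inj_nA is not None:
            rhs = rhs + inj_nA.T
        C = self.n_comp
        if C == 1:
            vnew = rhs / diag
        else:
            cprime = np.empty((C - 1, self.n))
            dprime = np.empty((C, self.n))
            dd = diag[0]
            dprime[0] = rhs[0] / dd
            for i in range(1, C):
                cprime[i - 1] = -self.g_ax[i - 1] / dd
                dd = diag[i] + self.g_ax[i - 1] * cprime[i - 1]
                dprime[i] = (rhs[i] + self.g_ax[i - 1] * dprime[i - 1]) / dd
            vnew = np.empty((C, self.n))
            vnew[C - 1] = dprime[C - 1]
            for i in range(C - 2, -1, -1):
                vnew[i] = dprime[i] - cprime[i] * vnew[i + 1]
        self.V = np.ascontiguousarray(vnew.T)

        # spike detection ----------------------------------------------
        soma_v = self.V[:, self.soma_index]
        above = soma_v >= SPIKE_THRESHOLD_MV
        spikes = above & ~self._above & (self._refrac <= 0)
        self._above = above
        self._refrac -= 1
        self._refrac[spikes] = self._refrac_steps
        if not np.all(np.abs(soma_v) <= 200.0):
            raise FloatingPointError(
                "integration diverged: |V| exceeded 200 mV at the soma"
            )
        return spikes


def comp_area_uS(area_cm2: float) -> float:
    """Density (S/cm²) → total conductance (µS) multiplier for one compartment."""
    return area_cm2 * 1e6
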