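"""Numba-accelerated network integration kernel.

Semantically equivalent to stepping two :class:`~assrnet.engine.CompiledCells`
populations with the python loop in :mod:`assrnet.pipeline` (same lookup
tables, same synapse-state recursion, same backward-Euler cable update); the
whole time loop runs inside one jitted function.  The numpy path remains the
reference implementation and the two are cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

_RT_2F_MV = 13.34
_CA_OUT = 2.0


def pack_population(pop) -> tuple:
    """Flatten a CompiledCells instance into the kernel's argument tuple."""
    n_gates = pop.minf_tab.shape[0]
    n_chan = pop.chan_gbar.shape[0]
    gate_count = np.zeros(n_chan, dtype=np.int64)
    for k in range(n_chan):
        stop = pop.chan_gate_start[k + 1] if k + 1 < n_chan else n_gates
        gate_count[k] = stop - pop.chan_gate_start[k]
    is_ca = np.zeros(n_chan, dtype=np.bool_)
    is_ca[pop.ca_rows] = True
    sk_row = int(pop.sk_rows[0]) if pop.sk_rows.size else -1
    if sk_row >= 0:
        ch = pop._sk_chans[0]
        sk_half, sk_hill = float(ch.ca_half), float(ch.ca_hill)
    else:
        sk_half, sk_hill = 1.0, 1.0
    pool = pop._pool
    return (
        pop.V.copy(), pop.X.copy(), pop.ca.copy(),
        np.ascontiguousarray(pop.minf_tab), np.ascontiguousarray(pop.expf_tab),
        pop.gate_comp.astype(np.int64), pop.gate_pow.ravel().astype(np.int64),
        pop.chan_gbar.astype(np.float64),
        np.nan_to_num(pop.chan_E, nan=0.0).astype(np.float64),
        pop.chan_comp.astype(np.int64), pop.chan_gate_start.astype(np.int64),
        gate_count, is_ca, sk_row, sk_half, sk_hill, float(pop._sk_decay),
        float(pool.rest), float(pool.influx_scale), float(pool.decay_tau),
        float(pop._ca_decay), pop._i_density.astype(np.float64),
        (pop.cm_nF / pop.dt).astype(np.float64), pop.ax_diag.astype(np.float64),
        pop.g_ax.astype(np.float64) if pop.g_ax.size else np.zeros(0),
        int(pop.soma_index), float(pop.vgrid[0]),
        float(1.0 / (pop.vgrid[1] - pop.vgrid[0])), int(pop.vgrid.shape[0]),
        int(pop._refrac_steps),
    )


@njit(cache=True)
def _step_pop(V, X, ca, minf, expf, gate_comp, gate_pow,
              chan_gbar, chan_E, chan_comp, chan_gate_start, chan_gate_count,
              chan_is_ca, sk_row, sk_half, sk_hill, sk_decay,
              ca_rest, ca_gamma, ca_tau, ca_decay, i_density,
              cmdt, ax_diag, g_ax, soma, vmin, inv_dv, nv,
              synA, synB, syn_fr, syn_fd, syn_norm, syn_E, syn_nmda, mg_mm,
              incr, refrac, above, refrac_steps, spikes_out):
    n, C = V.shape
    G = X.shape[0]
    K = chan_gbar.shape[0]

    # gate updates from voltage tables (exponential Euler)
    for g in range(G):
        if g == sk_row:
            continue
        comp = gate_comp[g]
        for i in range(n):
            vi = int((V[i, comp] - vmin) * inv_dv)
            if vi < 0:
                vi = 0
            elif vi >= nv:
                vi = nv - 1
            m = minf[g, vi]
            X[g, i] = m + (X[g, i] - m) * expf[g, vi]
    if sk_row >= 0:
        comp = gate_comp[sk_row]
        for i in range(n):
            c = ca[comp, i]
            cn = c**sk_hill
            zinf = cn / (cn + sk_half**sk_hill)
            X[sk_row, i] = zinf + (X[sk_row, i] - zinf) * sk_decay

    gsum = np.zeros((C, n))
    gesum = np.zeros((C, n))
    ica = np.zeros((C, n))
    any_ca = False
    for k in range(K):
        comp = chan_comp[k]
        start = chan_gate_start[k]
        cnt = chan_gate_count[k]
        for i in range(n):
            o = 1.0
            for g in range(start, start + cnt):
                x = X[g, i]
                p = gate_pow[g]
                if p == 1:
                    o *= x
                elif p == 2:
                    o *= x * x
                elif p == 3:
                    o *= x * x * x
                else:
                    o *= x**p
            gk = chan_gbar[k] * o
            if chan_is_ca[k]:
                any_ca = True
                c = ca[comp, i]
                if c < 1e-7:
                    c = 1e-7
                e = _RT_2F_MV * np.log(_CA_OUT / c)
                ica[comp, i] += gk * (V[i, comp] - e)
                gsum[comp, i] += gk
                gesum[comp, i] += gk * e
            else:
                gsum[comp, i] += gk
                gesum[comp, i] += gk * chan_E[k]

    if any_ca:
        for comp in range(C):
            dens_scale = i_density[comp]
            for i in range(n):
                icur = ica[comp, i]
                if icur == 0.0 and ca[comp, i] == ca_rest:
                    continue
                target = ca_rest - ca_gamma * icur * dens_scale * ca_tau
                upd = target + (ca[comp, i] - target) * ca_decay
                ca[comp, i] = upd if upd > 0.0 else 0.0

    # synapses (all at the soma): add increments, then decay, as in the
    # numpy path (event added before the per-step decay is applied)
    S = synA.shape[0]
    for s in range(S):
        fr, fd = syn_fr[s], syn_fd[s]
        for i in range(n):
            a = (synA[s, i] + incr[s, i]) * fr
            b = (synB[s, i] + incr[s, i]) * fd
            synA[s, i] = a
            synB[s, i] = b
            g = syn_norm[s] * (b - a)
            v = V[i, soma]
            if syn_nmda[s]:
                g *= 1.0 / (1.0 + np.exp(-0.062 * v) * mg_mm / 3.57)
            gsum[soma, i] += g
            gesum[soma, i] += g * syn_E[s]

    # implicit voltage update (Thomas along the chain), per cell
    diverged = False
    cprime = np.empty(C)
    dprime = np.empty(C)
    for i in range(n):
        if C == 1:
            V[i, 0] = (cmdt[0] * V[i, 0] + gesum[0, i]) / (
                cmdt[0] + gsum[0, i])
        else:
            dd = cmdt[0] + ax_diag[0] + gsum[0, i]
            dprime[0] = (cmdt[0] * V[i, 0] + gesum[0, i]) / dd
            for c in range(1, C):
                cprime[c - 1] = -g_ax[c - 1] / dd
                dd = cmdt[c] + ax_diag[c] + gsum[c, i] + g_ax[c - 1] * cprime[c - 1]
                dprime[c] = (cmdt[c] * V[i, c] + gesum[c, i]
                             + g_ax[c - 1] * dprime[c - 1]) / dd
            V[i, C - 1] = dprime[C - 1]
            for c in range(C - 2, -1, -1):
                V[i, c] = dprime[c] - cprime[c] * V[i, c + 1]

        sv = V[i, soma]
        if sv > 200.0 or sv < -200.0:
            diverged = True
        is_above = sv >= 0.0
        spk = is_above and (not above[i]) and refrac[i] <= 0
        spikes_out[i] = spk
        above[i] = is_above
        refrac[i] -= 1
        if spk:
            refrac[i] = refrac_steps
    return diverged


@njit(cache=True)
def _lfp_sample(eV, esoma, esynA, esynB, syn_norm, syn_E, syn_nmda, mg_mm,
                lfp_mode):
    ne = eV.shape[0]
    if lfp_mode == 4:
        tot = 0.0
        for i in range(ne):
            tot += eV[i, esoma]
        return tot
    include_ext = lfp_mode == 1 or lfp_mode == 3
    include_gaba = lfp_mode == 2 or lfp_mode == 3
    tot = 0.0
    for i in range(ne):
        v = eV[i, esoma]
        i_ampa = syn_norm[0] * (esynB[0, i] - esynA[0, i]) * (v - syn_E[0])
        if include_ext:
            i_ampa += syn_norm[1] * (esynB[1, i] - esynA[1, i]) * (v - syn_E[1])
        tot += abs(i_ampa)
        if include_gaba:
            tot += abs(syn_norm[3] * (esynB[3, i] - esynA[3, i]) * (v - syn_E[3]))
    return tot


@njit(cache=True)
def simulate_network(
    eV, eX, eca, eminf, eexpf, egate_comp, egate_pow, echan_gbar, echan_E,
    echan_comp, echan_gstart, echan_gcount, echan_isca, esk_row, esk_half,
    esk_hill, esk_decay, eca_rest, eca_gamma, eca_tau, eca_decay, ei_density,
    ecmdt, eax_diag, eg_ax, esoma, evmin, einv_dv, env, erefrac_steps,
    iV, iX, ica_, iminf, iexpf, igate_comp, igate_pow, ichan_gbar, ichan_E,
    ichan_comp, ichan_gstart, ichan_gcount, ichan_isca, isk_row, isk_half,
    isk_hill, isk_decay, ica_rest, ica_gamma, ica_tau, ica_decay, ii_density,
    icmdt, iax_diag, ig_ax, isoma, ivmin, iinv_dv, inv_, irefrac_steps,
    syn_fr, syn_fd, syn_norm, syn_E, syn_nmda, mg_mm,
    a_ee, a_ei, a_ie, a_ii, w_ee, w_nmda_ee, w_ei, w_nmda_ei, w_ie, w_ii,
    ext_e, ext_i,
    n_steps, delay_steps, steps_per_ms, lfp_mode,
    lfp, spk_times_e, spk_count_e, spk_times_i, spk_count_i,
):
    ne = eV.shape[0]
    ni = iV.shape[0]
    dt = 1.0 / steps_per_ms
    esynA = np.zeros((4, ne))
    esynB = np.zeros((4, ne))
    isynA = np.zeros((4, ni))
    isynB = np.zeros((4, ni))
    buf_e = np.zeros((delay_steps, ne), dtype=np.bool_)
    buf_i = np.zeros((delay_steps, ni), dtype=np.bool_)
    erefrac = np.zeros(ne, dtype=np.int64)
    irefrac = np.zeros(ni, dtype=np.int64)
    eabove = np.zeros(ne, dtype=np.bool_)
    iabove = np.zeros(ni, dtype=np.bool_)
    for i in range(ne):
        eabove[i] = eV[i, esoma] >= 0.0
    for i in range(ni):
        iabove[i] = iV[i, isoma] >= 0.0
    spikes_e = np.zeros(ne, dtype=np.bool_)
    spikes_i = np.zeros(ni, dtype=np.bool_)
    incr_e = np.zeros((4, ne))
    incr_i = np.zeros((4, ni))

    for k in range(n_steps):
        slot = k % delay_steps
        incr_e[:] = 0.0
        incr_i[:] = 0.0
        for pre in range(ne):
            if buf_e[slot, pre]:
                for j in range(ne):
                    a = a_ee[pre, j]
                    if a != 0.0:
                        incr_e[0, j] += w_ee * a
                        incr_e[2, j] += w_nmda_ee * a
                for j in range(ni):
                    a = a_ei[pre, j]
                    if a != 0.0:
                        incr_i[0, j] += w_ei * a
                        incr_i[2, j] += w_nmda_ei * a
        for pre in range(ni):
            if buf_i[slot, pre]:
                for j in range(ne):
                    a = a_ie[pre, j]
                    if a != 0.0:
                        incr_e[3, j] += w_ie * a
                for j in range(ni):
                    a = a_ii[pre, j]
                    if a != 0.0:
                        incr_i[3, j] += w_ii * a
        for j in range(ne):
            incr_e[1, j] += ext_e[k, j]
        for j in range(ni):
            incr_i[1, j] += ext_i[k, j]

        d1 = _step_pop(eV, eX, eca, eminf, eexpf, egate_comp, egate_pow,
                       echan_gbar, echan_E, echan_comp, echan_gstart,
                       echan_gcount, echan_isca, esk_row, esk_half, esk_hill,
                       esk_decay, eca_rest, eca_gamma, eca_tau, eca_decay,
                       ei_density, ecmdt, eax_diag, eg_ax, esoma, evmin,
                       einv_dv, env, esynA, esynB, syn_fr, syn_fd, syn_norm,
                       syn_E, syn_nmda, mg_mm, incr_e, erefrac, eabove,
                       erefrac_steps, spikes_e)
        d2 = _step_pop(iV, iX, ica_, iminf, iexpf, igate_comp, igate_pow,
                       ichan_gbar, ichan_E, ichan_comp, ichan_gstart,
                       ichan_gcount, ichan_isca, isk_row, isk_half, isk_hill,
                       isk_decay, ica_rest, ica_gamma, ica_tau, ica_decay,
                       ii_density, icmdt, iax_diag, ig_ax, isoma, ivmin,
                       iinv_dv, inv_, isynA, isynB, syn_fr, syn_fd, syn_norm,
                       syn_E, syn_nmda, mg_mm, incr_i, irefrac, iabove,
                       irefrac_steps, spikes_i)
        if d1 or d2:
            return True

        t_now = (k + 1) * dt
        for i in range(ne):
            buf_e[slot, i] = spikes_e[i]
            if spikes_e[i] and spk_count_e[i] < spk_times_e.shape[1]:
                spk_times_e[i, spk_count_e[i]] = t_now
                spk_count_e[i] += 1
        for i in range(ni):
            buf_i[slot, i] = spikes_i[i]
            if spikes_i[i] and spk_count_i[i] < spk_times_i.shape[1]:
                spk_times_i[i, spk_count_i[i]] = t_now
                spk_count_i[i] += 1

        # boxcar-average each 1 ms window (anti-aliased decimation)
        sidx = k // steps_per_ms
        if sidx < lfp.shape[0]:
            lfp[sidx] += _lfp_sample(eV, esoma, esynA, esynB, syn_norm,
                                     syn_E, syn_nmda, mg_mm,
                                     lfp_mode) / steps_per_ms
    return False
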