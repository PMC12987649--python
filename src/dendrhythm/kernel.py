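"""Numba-jitted branched-cable integrator.

One backward-Euler step of the cable equation per dt: channel gates advance
by exponential Euler on lookup tables, synaptic and ionic conductances are
assembled into a symmetric tree-structured linear system, and the voltage
solve uses the Hines two-sweep elimination (parents precede children).
Intracellular Ca2+ follows a single-pool model per compartment.

All quantities are in the package's standard units (mV, ms, uS, nA, mM);
arrays are laid out per compartment (n) or per synapse.
"""

from __future__ import annotations

import numpy as np
from numba import njit

F_CA_NERNST = 13.27  # RT/2F in mV at ~34.5 C


# fastmath without the no-NaN/no-inf assumptions, so the divergence check
# at the end of each step keeps its meaning
@njit(cache=True, fastmath={"contract", "reassoc", "arcp"},
      error_model="numpy")
def run_sim(parent, g_ax, cm_dt, g_leak, e_leak,
            gbar, na_fac,
            tables, vmin, dvinv,
            gates, zgate, cai,
            kca, ca_rec_fac, min_cai, cao,
            ena, ek, eh,
            v, dt, n_steps, zfac,
            # excitatory synapses
            e_comp, e_gampa, e_gnmda,
            ea_rinf, ea_onfac, ea_offfac, ea_onsteps,
            en_rinf, en_onfac, en_offfac, en_onsteps,
            e_rec1fac, e_rec2fac, e_d1, e_d2,
            ev_e_step, ev_e_syn, ev_e_rel,
            # inhibitory synapses
            i_comp, i_ggaba, i_cls, e_gaba,
            gg_rinf, gg_onfac, gg_offfac, gg_onsteps,
            i_rec1fac, i_rec2fac, i_d1s, i_d2s,
            ev_i_step, ev_i_syn, ev_i_rel,
            # injection
            inj_comp, inj_series,
            # recording
            rec_every, rec_idx, soma_idx,
            out_v, out_gna, out_inmda, out_ica, out_vsoma):
    n = parent.shape[0]
    ne = e_comp.shape[0]
    ni = i_comp.shape[0]
    ntab = tables.shape[2]

    # synapse state
    r_a = np.zeros(ne)
    r_n = np.zeros(ne)
    on_a = np.zeros(ne, dtype=np.int32)
    on_n = np.zeros(ne, dtype=np.int32)
    amp_e = np.ones(ne)
    D1e = np.ones(ne)
    D2e = np.ones(ne)
    r_g = np.zeros(ni)
    on_g = np.zeros(ni, dtype=np.int32)
    amp_i = np.ones(ni)
    D1i = np.ones(ni)
    D2i = np.ones(ni)

    diag = np.empty(n)
    rhs = np.empty(n)
    gca_tot = np.empty(n)
    eca_arr = np.empty(n)
    gnmda_comp = np.zeros(n)

    ptr_e = 0
    ptr_i = 0
    n_ev_e = ev_e_step.shape[0]
    n_ev_i = ev_i_step.shape[0]

    for step in range(n_steps):
        # ---- gates (exponential Euler via tables, using V at t) ----------
        for c in range(n):
            vi = (v[c] - vmin) * dvinv
            if not (vi >= 0.0):   # also catches NaN
                vi = 0.0
            if vi > ntab - 2:
                vi = ntab - 2.0
            i0 = int(vi)
            fr = vi - i0
            for g in range(15):
                inf = tables[g, 0, i0] + (tables[g, 0, i0 + 1]
                                          - tables[g, 0, i0]) * fr
                fac = tables[g, 1, i0] + (tables[g, 1, i0 + 1]
                                          - tables[g, 1, i0]) * fr
                gates[g, c] += (inf - gates[g, c]) * fac
            ci = cai[c]
            if ci < 1e-9:
                ci = 1e-9
            zi = 1.0 / (1.0 + (0.00043 / ci) ** 4.8)
            zgate[c] += (zi - zgate[c]) * zfac

        # ---- membrane conductances --------------------------------------
        for c in range(n):
            gna = gbar[0, c] * gates[0, c] ** 3 * gates[1, c]
            gnap = gbar[1, c] * gates[2, c] ** 3 * gates[3, c]
            gih = gbar[2, c] * gates[4, c]
            gim = gbar[3, c] * gates[5, c]
            gkp = gbar[4, c] * gates[6, c] ** 2 * gates[7, c]
            gkt = gbar[5, c] * gates[8, c] ** 4 * gates[9, c]
            gkv = gbar[6, c] * gates[10, c]
            ghva = gbar[7, c] * gates[11, c] ** 2 * gates[12, c]
            glva = gbar[8, c] * gates[13, c] ** 2 * gates[14, c]
            gsk = gbar[9, c] * zgate[c]
            ci = cai[c]
            if ci < 1e-9:
                ci = 1e-9
            eca = F_CA_NERNST * np.log(cao / ci)
            gk = gim + gkp + gkt + gkv + gsk
            gca = ghva + glva
            gca_tot[c] = gca
            eca_arr[c] = eca
            diag[c] = cm_dt[c] + g_leak[c] + gna + gnap + gih + gk + gca
            rhs[c] = (cm_dt[c] * v[c] + g_leak[c] * e_leak
                      + (gna + gnap) * ena + gih * eh + gk * ek + gca * eca)
            gnmda_comp[c] = 0.0

        # ---- synaptic events at this step -------------------------------
        while ptr_e < n_ev_e and ev_e_step[ptr_e] == step:
            s = ev_e_syn[ptr_e]
            eff = D1e[s] * D2e[s]
            if eff > 1.0:
                eff = 1.0
            D1e[s] *= e_d1
            D2e[s] *= e_d2
            if ev_e_rel[ptr_e] == 1:
                amp_e[s] = eff
                on_a[s] = ea_onsteps
                on_n[s] = en_onsteps
            ptr_e += 1
        while ptr_i < n_ev_i and ev_i_step[ptr_i] == step:
            s = ev_i_syn[ptr_i]
            cls = i_cls[s]
            eff = D1i[s] * D2i[s]
            if eff > 1.0:
                eff = 1.0
            D1i[s] *= i_d1s[cls]
            D2i[s] *= i_d2s[cls]
            if ev_i_rel[ptr_i] == 1:
                amp_i[s] = eff
                on_g[s] = gg_onsteps
            ptr_i += 1

        # ---- synaptic gating + accumulate -------------------------------
        for s in range(ne):
            if on_a[s] > 0:
                r_a[s] = ea_rinf + (r_a[s] - ea_rinf) * ea_onfac
                on_a[s] -= 1
            else:
                r_a[s] *= ea_offfac
            if on_n[s] > 0:
                r_n[s] = en_rinf + (r_n[s] - en_rinf) * en_onfac
                on_n[s] -= 1
            else:
                r_n[s] *= en_offfac
            D1e[s] += (1.0 - D1e[s]) * e_rec1fac
            D2e[s] += (1.0 - D2e[s]) * e_rec2fac
            c = e_comp[s]
            sv = 1.0 / (1.0 + 0.33 * np.exp(-0.06 * v[c]))
            ga = e_gampa[s] * amp_e[s] * r_a[s]
            gn = e_gnmda[s] * amp_e[s] * r_n[s] * sv
            diag[c] += ga + gn      # E_exc = 0: no rhs term
            gnmda_comp[c] += gn
        for s in range(ni):
            cls = i_cls[s]
            if on_g[s] > 0:
                r_g[s] = gg_rinf + (r_g[s] - gg_rinf) * gg_onfac
                on_g[s] -= 1
            else:
                r_g[s] *= gg_offfac
            D1i[s] += (1.0 - D1i[s]) * i_rec1fac[cls]
            D2i[s] += (1.0 - D2i[s]) * i_rec2fac[cls]
            c = i_comp[s]
            gg = i_ggaba[s] * amp_i[s] * r_g[s]
            diag[c] += gg
            rhs[c] += gg * e_gaba

        # ---- axial coupling + injection ---------------------------------
        for c in range(1, n):
            diag[c] += g_ax[c]
            diag[parent[c]] += g_ax[c]
        if inj_comp >= 0:
            rhs[inj_comp] += inj_series[step]

        # ---- Hines solve -------------------------------------------------
        for c in range(n - 1, 0, -1):
            p = parent[c]
            f = g_ax[c] / diag[c]
            diag[p] -= f * g_ax[c]
            rhs[p] += f * rhs[c]
        v[0] = rhs[0] / diag[0]
        for c in range(1, n):
            v[c] = (rhs[c] + g_ax[c] * v[parent[c]]) / diag[c]

        # ---- intracellular Ca2+ -----------------------------------------
        for c in range(n):
            ica = gca_tot[c] * (v[c] - eca_arr[c])
            cai[c] += -kca[c] * ica * dt + (min_cai - cai[c]) * ca_rec_fac[c]
            if cai[c] < 1e-9:
                cai[c] = 1e-9

        # ---- record ------------------------------------------------------
        out_vsoma[step] = v[soma_idx]
        if (step + 1) % rec_every == 0:
            fr = (step + 1) // rec_every - 1
            for j in range(rec_idx.shape[0]):
                c = rec_idx[j]
                out_v[fr, j] = v[c]
                out_gna[fr, j] = na_fac[c] * gates[0, c] ** 3 * gates[1, c]
                out_inmda[fr, j] = gnmda_comp[c] * v[c]
                out_ica[fr, j] = gca_tot[c] * (v[c] - eca_arr[c])
        if not np.isfinite(v[0]):
            return step
    return -1
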