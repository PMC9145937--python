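"""Plain-Python re-derivation of the documented network update rule.

Used as a brute-force oracle for the compiled simulation kernel: the
same leaky-integrator / register / gating semantics written step by
step without numba, compared spike-for-spike on short runs.
"""

import numpy as np


def reference_run(n_steps, rec_from, dt, V, tau_m,
                  pre_e, post_cell_e, post_comp_e, w_a, w_n,
                  pre_i, post_cell_i, post_comp_i, w_g,
                  ext_spk, dec_a, dec_n, dec_g, inc_a, inc_n, inc_g,
                  E_L, E_e, E_i, v_thr, v_reset, refr_steps, g_c,
                  g_leak_dend, theta_eff, theta_ca, relief, conc,
                  ic50_lo, ic50_hi, v_lo, v_hi,
                  ca_chi, ca_tau, ca_high, ca_low, ca_isat, ca_vuln):
    n_cells, n_comp = V.shape
    V = V.copy()
    a_a = np.zeros(len(pre_e))
    a_n = np.zeros(len(pre_e))
    a_g = np.zeros(len(pre_i))
    ca = np.zeros(n_cells)
    blocked = np.zeros(n_cells, bool)
    refr = np.zeros(n_cells, int)
    spiked = np.zeros(n_cells, bool)
    out = []

    def ic50(v):
        if v <= v_lo:
            return ic50_lo
        if v >= v_hi:
            return ic50_hi
        return ic50_lo + (ic50_hi - ic50_lo) * (v - v_lo) / (v_hi - v_lo)

    for t in range(n_steps):
        a_a *= dec_a
        a_n *= dec_n
        a_g *= dec_g
        for i, p in enumerate(pre_e):
            fired = spiked[p] if p < n_cells else ext_spk[p - n_cells, t]
            if fired:
                a_a[i] = min(1.0, a_a[i] + inc_a)
                a_n[i] = min(1.0, a_n[i] + inc_n)
        for i, p in enumerate(pre_i):
            fired = spiked[p] if p < n_cells else ext_spk[p - n_cells, t]
            if fired:
                a_g[i] = min(1.0, a_g[i] + inc_g)

        g_a = np.zeros((n_cells, n_comp))
        g_n = np.zeros((n_cells, n_comp))
        g_g = np.zeros((n_cells, n_comp))
        for i in range(len(pre_e)):
            g_a[post_cell_e[i], post_comp_e[i]] += w_a[i] * a_a[i]
            g_n[post_cell_e[i], post_comp_e[i]] += w_n[i] * a_n[i]
        for i in range(len(pre_i)):
            g_g[post_cell_i[i], post_comp_i[i]] += w_g[i] * a_g[i]

        Vn = np.zeros_like(V)
        for c in range(n_cells):
            i_ca = 0.0
            for k in range(n_comp):
                v = V[c, k]
                gn_eff = 0.0
                if not blocked[c] and v >= theta_eff:
                    if v >= relief or conc == 0.0:
                        blk = 0.0
                    else:
                        blk = conc / (conc + ic50(v))
                    gn_eff = g_n[c, k] * (1.0 - blk)
                i_n = gn_eff * (E_e - v)
                if v >= theta_ca:
                    i_ca += i_n
                i_syn = (g_a[c, k] * (E_e - v) + i_n
                         + g_g[c, k] * (E_i - v))
                cpl = 0.0
                if k > 0:
                    cpl += V[c, k - 1] - v
                if k < n_comp - 1:
                    cpl += V[c, k + 1] - v
                gl = 1.0 if k == 0 else g_leak_dend
                Vn[c, k] = v + dt / tau_m[c] * (gl * (E_L - v) + i_syn
                                                + g_c * cpl)
            influx = ca_vuln[c] * ca_chi * i_ca / (1.0 + i_ca / ca_isat[c])
            ca[c] += dt * (influx - ca[c] / ca_tau)
            if ca_vuln[c] > 0.0:
                if ca[c] >= ca_high:
                    blocked[c] = True
                elif blocked[c] and ca[c] <= ca_low:
                    blocked[c] = False
            sp = False
            if refr[c] > 0:
                refr[c] -= 1
                Vn[c, 0] = v_reset
            elif Vn[c, 0] >= v_thr:
                sp = True
                Vn[c, 0] = v_reset
                refr[c] = refr_steps
                if t >= rec_from:
                    out.append((c, t - rec_from))
            spiked[c] = sp
        V = Vn
    return out
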