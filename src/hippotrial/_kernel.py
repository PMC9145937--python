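"""Numba inner loop of the compartmental network simulation.

Semantics (plain forward-Euler, single thread, bitwise deterministic):

* per-synapse receptor registers decay exponentially and jump
  (clipped at 1) on presynaptic spikes;
* compartment potentials are leaky integrators with conductance-based
  synaptic currents and passive nearest-neighbour coupling;
* the NMDA conductance is gated per compartment: closed below the
  (dose-shifted) opening threshold, otherwise reduced by the
  voltage-dependent memantine Langmuir block, relieved above the
  relief threshold;
* a per-cell calcium load integrates the NMDA current entering above
  the dose-shifted calcium opening threshold; in
  vulnerable cells (pyramidal; granule cells are strongly calcium
  buffered) the NMDA conductance inactivates above ``ca_high``
  (excitotoxic shutdown) until the load recovers below ``ca_low``;
* somatic threshold-reset spiking with an absolute refractory period.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def run_kernel(n_steps, rec_from, dt,
               V,                      # (n_cells, 16) float64, modified
               tau_m,                  # (n_cells,) float64 seconds
               pre_e, post_cell_e, post_comp_e, w_a, w_n,   # excitatory syns
               pre_i, post_cell_i, post_comp_i, w_g,        # inhibitory syns
               ext_spk,                # (n_ext, n_steps) bool
               dec_a, dec_n, dec_g, inc_a, inc_n, inc_g,
               E_L, E_e, E_i, v_thr, v_reset, refr_steps, g_c, g_leak_dend,
               theta_eff, theta_ca, relief, conc,
               ic50_lo, ic50_hi, v_lo, v_hi,
               ca_chi, ca_tau, ca_high, ca_low, ca_isat, ca_vuln,
               spike_cell, spike_step  # preallocated int32 output
               ):
    n_cells = V.shape[0]
    n_comp = V.shape[1]
    ne = pre_e.shape[0]
    ni = pre_i.shape[0]

    a_a = np.zeros(ne)
    a_n = np.zeros(ne)
    a_g = np.zeros(ni)
    g_a = np.zeros((n_cells, n_comp))
    g_n = np.zeros((n_cells, n_comp))
    g_g = np.zeros((n_cells, n_comp))
    Vn = np.zeros((n_cells, n_comp))
    ca = np.zeros(n_cells)
    ca_blocked = np.zeros(n_cells, np.bool_)
    refr = np.zeros(n_cells, np.int64)
    spiked = np.zeros(n_cells, np.bool_)

    ic50_slope = (ic50_hi - ic50_lo) / (v_hi - v_lo)
    n_spikes = 0
    max_spikes = spike_cell.shape[0]

    for t in range(n_steps):
        # --- registers ---
        for i in range(ne):
            a_a[i] *= dec_a
            a_n[i] *= dec_n
            p = pre_e[i]
            sp = spiked[p] if p < n_cells else ext_spk[p - n_cells, t]
            if sp:
                a_a[i] = min(1.0, a_a[i] + inc_a)
                a_n[i] = min(1.0, a_n[i] + inc_n)
        for i in range(ni):
            a_g[i] *= dec_g
            p = pre_i[i]
            sp = spiked[p] if p < n_cells else ext_spk[p - n_cells, t]
            if sp:
                a_g[i] = min(1.0, a_g[i] + inc_g)

        # --- conductances per compartment ---
        for c in range(n_cells):
            for k in range(n_comp):
                g_a[c, k] = 0.0
                g_n[c, k] = 0.0
                g_g[c, k] = 0.0
        for i in range(ne):
            g_a[post_cell_e[i], post_comp_e[i]] += w_a[i] * a_a[i]
            g_n[post_cell_e[i], post_comp_e[i]] += w_n[i] * a_n[i]
        for i in range(ni):
            g_g[post_cell_i[i], post_comp_i[i]] += w_g[i] * a_g[i]

        # --- membrane update ---
        for c in range(n_cells):
            i_nmda_cell = 0.0
            inv_tau = dt / tau_m[c]
            for k in range(n_comp):
                v = V[c, k]
                gn_eff = 0.0
                if (not ca_blocked[c]) and v >= theta_eff:
                    if v >= relief or conc == 0.0:
                        blk = 0.0
                    else:
                        if v <= v_lo:
                            ic50 = ic50_lo
                        elif v >= v_hi:
                            ic50 = ic50_hi
                        else:
                            ic50 = ic50_lo + ic50_slope * (v - v_lo)
                        blk = conc / (conc + ic50)
                    gn_eff = g_n[c, k] * (1.0 - blk)
                i_n = gn_eff * (E_e - v)
                # calcium entry requires the (dose-shifted) Ca opening
                # threshold; this is the excitotoxic load pathway
                if v >= theta_ca:
                    i_nmda_cell += i_n
                i_syn = g_a[c, k] * (E_e - v) + i_n + g_g[c, k] * (E_i - v)
                cpl = 0.0
                if k > 0:
                    cpl += V[c, k - 1] - v
                if k < n_comp - 1:
                    cpl += V[c, k + 1] - v
                gl = 1.0 if k == 0 else g_leak_dend
                Vn[c, k] = v + inv_tau * (gl * (E_L - v) + i_syn + g_c * cpl)

            # calcium load / excitotoxic NMDA shutdown; influx saturates
            # (buffering) so extreme drives load at a common ceiling
            # influx saturates (transporter/buffer capacity), compressing
            # load differences between heavily over-driven states
            influx = (ca_vuln[c] * ca_chi * i_nmda_cell
                      / (1.0 + i_nmda_cell / ca_isat[c]))
            ca[c] += dt * (influx - ca[c] / ca_tau)
            if ca_vuln[c] > 0.0:
                if ca[c] >= ca_high:
                    ca_blocked[c] = True
                elif ca_blocked[c] and ca[c] <= ca_low:
                    ca_blocked[c] = False

            # somatic spiking
            sp = False
            if refr[c] > 0:
                refr[c] -= 1
                Vn[c, 0] = v_reset
            elif Vn[c, 0] >= v_thr:
                sp = True
                Vn[c, 0] = v_reset
                refr[c] = refr_steps
                if t >= rec_from:
                    if n_spikes < max_spikes:
                        spike_cell[n_spikes] = c
                        spike_step[n_spikes] = t - rec_from
                    n_spikes += 1
            spiked[c] = sp
            if not np.isfinite(Vn[c, 0]):
                return -1, c, t

        for c in range(n_cells):
            for k in range(n_comp):
                V[c, k] = Vn[c, k]

    return n_spikes, -1, -1
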