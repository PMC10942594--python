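"""Jit-compiled closed-loop simulation core.

One global clock advances, in lockstep: the septal oscillator ensemble, the
conductance-based neurons of all areas (excitatory block first, inhibitory
block second, each grouped by area), the biexponential synapses, and the
CA1→septum firing-rate feedback X(t).  The feedback computed at step t is
consumed by the oscillators at step t+1 (one-step lag).

Numerics: voltage-gated gates use exponential Euler driven by lookup tables
of x∞(V) and 1−e^{−dt/τ(V)} built from the exact rate expressions; the
calcium-gated CAN gate is updated analytically; the membrane and calcium use
explicit Euler; synaptic (g, h) cascades use the exact linear propagator.
Units: mV, ms, nA, µS, nF, mM.

The kernel integrates a contiguous chunk of steps; the Python wrapper in
:mod:`thetanest.network` supplies per-chunk membrane-noise arrays (drawn
outside the jit code) and carries scalar state between chunks.
"""

from __future__ import annotations

import numpy as np
from numba import njit

SPIKE_THRESHOLD_MV = -20.0
SPIKE_HOLDOFF_MS = 2.0
NOISE_DT_REF_MS = 0.1


@njit(cache=True, fastmath=True, inline="always")
def _table_pos(n, v_min, inv_dv, v):
    """Clamped fractional table index for voltage v."""
    x = (v - v_min) * inv_dv
    if x <= 0.0:
        x = 0.0
    elif x >= n - 1:
        x = float(n - 1) - 1e-9
    i = int(x)
    return i, x - i


@njit(cache=True, fastmath=True)
def run_chunk(
    k0, n_steps_chunk, dt,
    # --- excitatory block ---
    vE, gE_gates, mcan, ca, lastE, areaE,
    # --- inhibitory block ---
    vI, gI_gates, lastI, areaI,
    # --- per-class constants (absolute conductances in µS, C in nF) ---
    constE, constI,
    # gate tables
    tabE_xinf, tabE_efac, tabI_xinf, tabI_efac, v_min, inv_dv,
    # --- synapses: global neuron order = [E block | I block] ---
    ge, he, gi, hi,
    syn_eg_e, syn_eh_e, syn_c_e,
    syn_eg_i, syn_eh_i, syn_c_i,
    rev_e, rev_i,
    indptr, post_idx, w_us,
    # --- external currents for this chunk (nA): ext_e[k_local, area] ---
    ext_e, ext_i,
    # --- pre-scaled membrane noise for this chunk (mV); (1,1) if off ---
    noiseE, noiseI, use_noise,
    # --- septum ---
    theta, omega, sync_ratio, greset, gtheta, peak_phase, phase_offset,
    tau_fr_ms, x0, theta_area, n_ca1e_ref, ca1e_lo, ca1e_hi, reset_on,
    # --- stimulation for this chunk ---
    stim_series, stim_area,
    # --- monitors ---
    mon_idx,
    # --- chunk output views ---
    theta_amp, theta_phase, theta_drive, x_series,
    spike_t, spike_id, spike_count0, ican_mon, im_mon, vm_mon,
):
    nE = vE.shape[0]
    nI = vI.shape[0]
    n_osc = theta.shape[0]
    spike_count = spike_count0
    cap = spike_t.shape[0]
    x_rate = x0
    dt_s = dt * 1e-3
    tau_fr_s = tau_fr_ms * 1e-3
    x_decay = np.exp(-dt / tau_fr_ms)

    (glE, elE, gkE, ekE, gnaE, enaE, gcaE, ecaE, gcanE, ecanE, gmE, emE,
     cE, gammaE, cainfE, taucaE, can_a, can_b) = (
        constE[0], constE[1], constE[2], constE[3], constE[4], constE[5],
        constE[6], constE[7], constE[8], constE[9], constE[10], constE[11],
        constE[12], constE[13], constE[14], constE[15], constE[16], constE[17])
    glI, elI, gkI, ekI, gnaI, enaI, cI = (
        constI[0], constI[1], constI[2], constI[3], constI[4], constI[5],
        constI[6])

    for k in range(n_steps_chunk):
        t = (k0 + k) * dt

        # --- septal oscillators (consume X from previous step) -----------
        sr = 0.0
        cr = 0.0
        for i in range(n_osc):
            sr += np.sin(theta[i])
            cr += np.cos(theta[i])
        sr /= n_osc
        cr /= n_osc
        amp = np.sqrt(sr * sr + cr * cr)
        phi = np.arctan2(sr, cr)
        reset_drive = greset * x_rate if reset_on else 0.0
        coupling = sync_ratio * n_osc * amp   # (k/N)*N*A, mean-field form
        for i in range(n_osc):
            dth = (omega[i] + coupling * np.sin(phi - theta[i])
                   - reset_drive * np.sin(theta[i] - (peak_phase + phase_offset)))
            th = theta[i] + dth * dt_s
            while th > np.pi:
                th -= 2.0 * np.pi
            while th <= -np.pi:
                th += 2.0 * np.pi
            theta[i] = th
        i_theta = gtheta * (amp * np.cos(phi) + 1.0) * 0.5
        theta_amp[k] = amp
        theta_phase[k] = phi
        theta_drive[k] = i_theta

        stim_now = stim_series[k]

        # --- excitatory block --------------------------------------------
        for i in range(nE):
            v = vE[i]
            m = gE_gates[0, i]
            h = gE_gates[1, i]
            nk = gE_gates[2, i]
            mca = gE_gates[3, i]
            hca = gE_gates[4, i]
            p = gE_gates[5, i]
            mc = mcan[i]

            i_l = glE * (v - elE)
            i_k = gkE * nk * nk * nk * nk * (v - ekE)
            i_na = gnaE * m * m * m * h * (v - enaE)
            i_ca = gcaE * mca * mca * hca * (v - ecaE)
            i_can = gcanE * mc * mc * (v - ecanE)
            i_m = gmE * p * (v - emE)
            i_syn = ge[i] * (v - rev_e) + gi[i] * (v - rev_i)

            area = areaE[i]
            i_ext = ext_e[k, area]
            if area == theta_area:
                i_ext += i_theta
            if area == stim_area:
                i_ext += stim_now

            dv = (-(i_l + i_k + i_na + i_ca + i_can + i_m) - i_syn + i_ext) \
                * (dt / cE)
            v_new = v + dv
            if use_noise:
                v_new += noiseE[k, i]
            if not np.isfinite(v_new):
                return spike_count, -(i + 1), t, x_rate

            ti, tf = _table_pos(tabE_xinf.shape[1], v_min, inv_dv, v)
            for row in range(6):
                xi = tabE_xinf[row, ti] * (1.0 - tf) + tabE_xinf[row, ti + 1] * tf
                ef = tabE_efac[row, ti] * (1.0 - tf) + tabE_efac[row, ti + 1] * tf
                g_old = gE_gates[row, i]
                g_new = g_old + (xi - g_old) * ef
                if g_new < 0.0:
                    g_new = 0.0
                elif g_new > 1.0:
                    g_new = 1.0
                gE_gates[row, i] = g_new

            # CAN gate: alpha exponential in calcium, tau = 0.2/(alpha+beta)
            a_can = 0.0002 * np.exp(can_a * ca[i])
            s_can = a_can + can_b
            minf = a_can / s_can
            ef = 1.0 - np.exp(-dt * s_can / 0.2)
            mc_new = mc + (minf - mc) * ef
            if mc_new < 0.0:
                mc_new = 0.0
            elif mc_new > 1.0:
                mc_new = 1.0
            mcan[i] = mc_new

            ca_new = ca[i] + dt * (-i_ca * gammaE + (cainfE - ca[i]) / taucaE)
            ca[i] = ca_new if ca_new > 0.0 else 0.0

            vE[i] = v_new
            if v_new >= SPIKE_THRESHOLD_MV and v < SPIKE_THRESHOLD_MV \
                    and t - lastE[i] >= SPIKE_HOLDOFF_MS:
                lastE[i] = t
                if spike_count < cap:
                    spike_t[spike_count] = t
                    spike_id[spike_count] = i
                    spike_count += 1
                else:
                    return spike_count, -(nE + nI + 1), t, x_rate

            if i == mon_idx:
                ican_mon[k] = i_can
                im_mon[k] = i_m
                vm_mon[k] = v_new

        # --- inhibitory block --------------------------------------------
        for i in range(nI):
            gidx = nE + i
            v = vI[i]
            m = gI_gates[0, i]
            h = gI_gates[1, i]
            nk = gI_gates[2, i]

            i_l = glI * (v - elI)
            i_k = gkI * nk * nk * nk * nk * (v - ekI)
            i_na = gnaI * m * m * m * h * (v - enaI)
            i_syn = ge[gidx] * (v - rev_e) + gi[gidx] * (v - rev_i)

            area = areaI[i]
            i_ext = ext_i[k, area]
            if area == theta_area:
                i_ext += i_theta
            if area == stim_area:
                i_ext += stim_now

            dv = (-(i_l + i_k + i_na) - i_syn + i_ext) * (dt / cI)
            v_new = v + dv
            if use_noise:
                v_new += noiseI[k, i]
            if not np.isfinite(v_new):
                return spike_count, -(nE + i + 1), t, x_rate

            ti, tf = _table_pos(tabI_xinf.shape[1], v_min, inv_dv, v)
            for row in range(3):
                xi = tabI_xinf[row, ti] * (1.0 - tf) + tabI_xinf[row, ti + 1] * tf
                ef = tabI_efac[row, ti] * (1.0 - tf) + tabI_efac[row, ti + 1] * tf
                g_old = gI_gates[row, i]
                g_new = g_old + (xi - g_old) * ef
                if g_new < 0.0:
                    g_new = 0.0
                elif g_new > 1.0:
                    g_new = 1.0
                gI_gates[row, i] = g_new

            vI[i] = v_new
            if v_new >= SPIKE_THRESHOLD_MV and v < SPIKE_THRESHOLD_MV \
                    and t - lastI[i] >= SPIKE_HOLDOFF_MS:
                lastI[i] = t
                if spike_count < cap:
                    spike_t[spike_count] = t
                    spike_id[spike_count] = gidx
                    spike_count += 1
                else:
                    return spike_count, -(nE + nI + 1), t, x_rate

        # --- synapse decay (exact propagator), then spike propagation ----
        n_tot = nE + nI
        for i in range(n_tot):
            ge[i] = syn_eg_e * ge[i] + syn_c_e * he[i]
            he[i] = syn_eh_e * he[i]
            gi[i] = syn_eg_i * gi[i] + syn_c_i * hi[i]
            hi[i] = syn_eh_i * hi[i]

        ca1_spikes = 0
        j = spike_count - 1
        while j >= 0 and spike_t[j] == t:
            j -= 1
        for s in range(j + 1, spike_count):
            pre = spike_id[s]
            if ca1e_lo <= pre < ca1e_hi:
                ca1_spikes += 1
            for e in range(indptr[pre], indptr[pre + 1]):
                tgt = post_idx[e]
                if pre < nE:
                    he[tgt] += w_us[e]
                else:
                    hi[tgt] += w_us[e]

        # --- CA1 -> septum firing-rate feedback --------------------------
        x_rate = x_rate * x_decay + ca1_spikes / (n_ca1e_ref * tau_fr_s)
        x_series[k] = x_rate

    return spike_count, 0, (k0 + n_steps_chunk) * dt, x_rate
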