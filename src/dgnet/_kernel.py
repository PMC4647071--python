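"""Numba integration kernel.

Clock-driven network integration: exponential-Euler membrane update with
tabulated gate kinetics, analytic two-state double-exponential synapse
channels, and per-pathway ring-buffer event queues quantized at dt.

Population blocks are generic over compartment count and synaptic-channel
count; the three slots are used for GC, BC and MC (any can be empty).
Synaptic channel slots:

* GC block: 0 = BC->GC (soma), 1 = MC->GC (inner), 2 = MEC->GC (middle),
  3 = LEC->GC (outer)
* BC block: 0 = GC->BC, 1 = EC->BC (MEC+LEC merged), 2 = MC->BC
* MC block: 0 = GC->MC

Entorhinal spikes and forced mossy-cell volleys enter as pre-sorted
(step, cell) event lists scattered through the same CSR edge lists as
internally generated spikes.
"""

import math

import numpy as np
from numba import njit

from .cells import BK_KD, E_CA, E_K, E_NA, N_V, SK_KD, V_MIN, V_STEP

_INV_VSTEP = 1.0 / V_STEP

# return codes
OK = 0
ERR_NONFINITE = 1
ERR_OVERFLOW = 2


@njit(cache=True)
def _scatter(indptr, post, w, dstep, buf, pre, step):
    """Queue one presynaptic spike's deliveries into a ring buffer."""
    slots = buf.shape[0]
    for k in range(indptr[pre], indptr[pre + 1]):
        buf[(step + dstep[k]) % slots, post[k]] += w[k]


@njit(cache=True)
def _deliver(A, B, ch, norm, buf, step):
    slot = step % buf.shape[0]
    for i in range(A.shape[1]):
        inc = buf[slot, i]
        if inc != 0.0:
            A[ch, i] += inc * norm
            B[ch, i] += inc * norm
            buf[slot, i] = 0.0


@njit(cache=True)
def _decay_channels(A, B, decA, decB):
    for ch in range(A.shape[0]):
        da = decA[ch]
        db = decB[ch]
        for i in range(A.shape[1]):
            A[ch, i] *= da
            B[ch, i] *= db


@njit(cache=True)
def _update_pop(
    pop_code, V, G, CA,
    cm, gl, el, gch, gax, kca, ca_dec, ca0,
    A, B, ch_comp, ch_erev,
    inf_tab, dec_tab, dt,
    inj_cell, inj_comp, inj_amp,
    last_spike, refr, step,
    out_pop, out_cell, out_step, out_n,
):
    """Advance one population block one step; returns 0 or ERR_OVERFLOW."""
    n, ncomp = V.shape
    nch = A.shape[0]
    nbk = inf_tab.shape[0] - 1  # BK voltage-gate row
    for i in range(n):
        v_soma_old = V[i, 0]
        for j in range(ncomp):
            v = V[i, j]
            fvi = (v - V_MIN) * _INV_VSTEP
            vi = int(fvi)
            if vi < 0:
                vi = 0
            elif vi > N_V - 1:
                vi = N_V - 1

            # gating variables (staggered: tables use pre-update V)
            m = inf_tab[0, vi] + (G[i, j, 0] - inf_tab[0, vi]) * dec_tab[0, vi]
            h = inf_tab[1, vi] + (G[i, j, 1] - inf_tab[1, vi]) * dec_tab[1, vi]
            s_ = inf_tab[2, vi] + (G[i, j, 2] - inf_tab[2, vi]) * dec_tab[2, vi]
            nn = inf_tab[3, vi] + (G[i, j, 3] - inf_tab[3, vi]) * dec_tab[3, vi]
            a = inf_tab[4, vi] + (G[i, j, 4] - inf_tab[4, vi]) * dec_tab[4, vi]
            b = inf_tab[5, vi] + (G[i, j, 5] - inf_tab[5, vi]) * dec_tab[5, vi]
            c = inf_tab[6, vi] + (G[i, j, 6] - inf_tab[6, vi]) * dec_tab[6, vi]
            cn = inf_tab[7, vi] + (G[i, j, 7] - inf_tab[7, vi]) * dec_tab[7, vi]
            dn = inf_tab[8, vi] + (G[i, j, 8] - inf_tab[8, vi]) * dec_tab[8, vi]
            e = inf_tab[9, vi] + (G[i, j, 9] - inf_tab[9, vi]) * dec_tab[9, vi]
            f = inf_tab[10, vi] + (G[i, j, 10] - inf_tab[10, vi]) * dec_tab[10, vi]
            G[i, j, 0] = m
            G[i, j, 1] = h
            G[i, j, 2] = s_
            G[i, j, 3] = nn
            G[i, j, 4] = a
            G[i, j, 5] = b
            G[i, j, 6] = c
            G[i, j, 7] = cn
            G[i, j, 8] = dn
            G[i, j, 9] = e
            G[i, j, 10] = f

            ca = CA[i, j]
            g_na = gch[0, j] * m * m * m * h
            g_ks = gch[1, j] * s_ * s_
            g_kf = gch[2, j] * nn * nn * nn * nn
            g_ka = gch[3, j] * a * a * b
            g_cal = gch[4, j] * c * c
            g_can = gch[5, j] * cn * cn * dn
            g_cat = gch[6, j] * e * e * f
            zsk = ca * ca / (ca * ca + SK_KD * SK_KD)
            g_sk = gch[7, j] * zsk
            g_bk = gch[8, j] * (ca / (ca + BK_KD)) * inf_tab[nbk, vi]
            g_k = g_ks + g_kf + g_ka + g_sk + g_bk
            g_ca = g_cal + g_can + g_cat

            g_tot = gl[j] + g_na + g_k + g_ca
            i_sum = gl[j] * el + g_na * E_NA + g_k * E_K + g_ca * E_CA

            for ch in range(nch):
                if ch_comp[ch] == j:
                    gs = A[ch, i] - B[ch, i]
                    if gs > 0.0:
                        g_tot += gs
                        i_sum += gs * ch_erev[ch]
            if j > 0:
                g_tot += gax[j - 1]
                i_sum += gax[j - 1] * V[i, j - 1]
            if j < ncomp - 1:
                g_tot += gax[j]
                i_sum += gax[j] * V[i, j + 1]
            if i == inj_cell and j == inj_comp:
                i_sum += inj_amp

            v_inf = i_sum / g_tot
            V[i, j] = v_inf + (v - v_inf) * math.exp(-dt * g_tot / cm[j])

            # Ca pool: influx from Ca current, first-order decay to ca0
            i_ca = g_ca * (v - E_CA)  # nA; inward (negative) raises Ca
            ca_new = ca0 + (ca - kca[j] * i_ca * dt - ca0) * ca_dec
            if ca_new < 0.0:
                ca_new = 0.0
            CA[i, j] = ca_new

        if V[i, 0] >= 0.0 and v_soma_old < 0.0 and step - last_spike[i] > refr:
            last_spike[i] = step
            k = out_n[0]
            if k >= out_cell.shape[0]:
                return ERR_OVERFLOW
            out_pop[k] = pop_code
            out_cell[k] = i
            out_step[k] = step
            out_n[0] = k + 1
    return OK


@njit(cache=True)
def _check_finite(V):
    n, ncomp = V.shape
    for i in range(n):
        for j in range(ncomp):
            v = V[i, j]
            if not (-150.0 < v < 150.0) or v != v:
                return i
    return -1


@njit(cache=True)
def run_net(
    nsteps, dt, refr_steps,
    inf_tab, dec_tab,
    # GC block
    Vg, Gg, CAg, cm_g, gl_g, el_g, gch_g, gax_g, kca_g, cadec_g, ca0_g,
    Ag, Bg, chcomp_g, cherev_g, decA_g, decB_g, norm_g,
    buf_g0, buf_g1, buf_g2, buf_g3,
    # BC block
    Vb, Gb, CAb, cm_b, gl_b, el_b, gch_b, gax_b, kca_b, cadec_b, ca0_b,
    Ab, Bb, chcomp_b, cherev_b, decA_b, decB_b, norm_b,
    buf_b0, buf_b1, buf_b2,
    # MC block
    Vm, Gm, CAm, cm_m, gl_m, el_m, gch_m, gax_m, kca_m, cadec_m, ca0_m,
    Am, Bm, chcomp_m, cherev_m, decA_m, decB_m, norm_m,
    buf_m0,
    # CSRs: (indptr, post, w, dstep)
    mecgc_i, mecgc_p, mecgc_w, mecgc_d,
    lecgc_i, lecgc_p, lecgc_w, lecgc_d,
    mecbc_i, mecbc_p, mecbc_w, mecbc_d,
    lecbc_i, lecbc_p, lecbc_w, lecbc_d,
    gcbc_i, gcbc_p, gcbc_w, gcbc_d,
    gcmc_i, gcmc_p, gcmc_w, gcmc_d,
    bcgc_i, bcgc_p, bcgc_w, bcgc_d,
    mcgc_i, mcgc_p, mcgc_w, mcgc_d,
    mcbc_i, mcbc_p, mcbc_w, mcbc_d,
    # external events (sorted by step)
    mec_step, mec_cell, lec_step, lec_cell, fmc_step, fmc_cell,
    # injection: population code, cell, compartment, amplitude nA, window
    inj_pop, inj_cell, inj_comp, inj_amp, inj_s0, inj_s1,
    # probes
    probe_pop, probe_cell, probe_comp, vrec,
    # spike output
    out_pop, out_cell, out_step, last_g, last_b, last_m,
):
    """Returns (n_spikes, err_code, err_pop, err_cell, err_step)."""
    out_n = np.zeros(1, dtype=np.int64)
    pm = 0
    pl = 0
    pf = 0
    err_code = OK
    err_pop = -1
    err_cell = -1
    err_step = -1

    for step in range(nsteps):
        # external spikes scatter into ring buffers
        while pm < mec_step.shape[0] and mec_step[pm] == step:
            cell = mec_cell[pm]
            _scatter(mecgc_i, mecgc_p, mecgc_w, mecgc_d, buf_g2, cell, step)
            _scatter(mecbc_i, mecbc_p, mecbc_w, mecbc_d, buf_b1, cell, step)
            pm += 1
        while pl < lec_step.shape[0] and lec_step[pl] == step:
            cell = lec_cell[pl]
            _scatter(lecgc_i, lecgc_p, lecgc_w, lecgc_d, buf_g3, cell, step)
            _scatter(lecbc_i, lecbc_p, lecbc_w, lecbc_d, buf_b1, cell, step)
            pl += 1
        while pf < fmc_step.shape[0] and fmc_step[pf] == step:
            cell = fmc_cell[pf]
            _scatter(mcgc_i, mcgc_p, mcgc_w, mcgc_d, buf_g1, cell, step)
            _scatter(mcbc_i, mcbc_p, mcbc_w, mcbc_d, buf_b2, cell, step)
            pf += 1

        # deliver due events
        if Vg.shape[0] > 0:
            _deliver(Ag, Bg, 0, norm_g[0], buf_g0, step)
            _deliver(Ag, Bg, 1, norm_g[1], buf_g1, step)
            _deliver(Ag, Bg, 2, norm_g[2], buf_g2, step)
            _deliver(Ag, Bg, 3, norm_g[3], buf_g3, step)
        if Vb.shape[0] > 0:
            _deliver(Ab, Bb, 0, norm_b[0], buf_b0, step)
            _deliver(Ab, Bb, 1, norm_b[1], buf_b1, step)
            _deliver(Ab, Bb, 2, norm_b[2], buf_b2, step)
        if Vm.shape[0] > 0:
            _deliver(Am, Bm, 0, norm_m[0], buf_m0, step)

        n0 = out_n[0]
        rc = OK
        if Vg.shape[0] > 0:
            ic = inj_cell if inj_pop == 0 and inj_s0 <= step < inj_s1 else -1
            rc = _update_pop(
                0, Vg, Gg, CAg, cm_g, gl_g, el_g, gch_g, gax_g, kca_g,
                cadec_g, ca0_g, Ag, Bg, chcomp_g, cherev_g,
                inf_tab, dec_tab, dt, ic, inj_comp, inj_amp,
                last_g, refr_steps, step, out_pop, out_cell, out_step, out_n,
            )
        if rc == OK and Vb.shape[0] > 0:
            ic = inj_cell if inj_pop == 1 and inj_s0 <= step < inj_s1 else -1
            rc = _update_pop(
                1, Vb, Gb, CAb, cm_b, gl_b, el_b, gch_b, gax_b, kca_b,
                cadec_b, ca0_b, Ab, Bb, chcomp_b, cherev_b,
                inf_tab, dec_tab, dt, ic, inj_comp, inj_amp,
                last_b, refr_steps, step, out_pop, out_cell, out_step, out_n,
            )
        if rc == OK and Vm.shape[0] > 0:
            ic = inj_cell if inj_pop == 2 and inj_s0 <= step < inj_s1 else -1
            rc = _update_pop(
                2, Vm, Gm, CAm, cm_m, gl_m, el_m, gch_m, gax_m, kca_m,
                cadec_m, ca0_m, Am, Bm, chcomp_m, cherev_m,
                inf_tab, dec_tab, dt, ic, inj_comp, inj_amp,
                last_m, refr_steps, step, out_pop, out_cell, out_step, out_n,
            )
        if rc != OK:
            err_code = rc
            err_step = step
            break

        # scatter newly generated spikes
        for k in range(n0, out_n[0]):
            p = out_pop[k]
            cell = out_cell[k]
            if p == 0:
                _scatter(gcbc_i, gcbc_p, gcbc_w, gcbc_d, buf_b0, cell, step)
                _scatter(gcmc_i, gcmc_p, gcmc_w, gcmc_d, buf_m0, cell, step)
            elif p == 1:
                _scatter(bcgc_i, bcgc_p, bcgc_w, bcgc_d, buf_g0, cell, step)
            else:
                _scatter(mcgc_i, mcgc_p, mcgc_w, mcgc_d, buf_g1, cell, step)
                _scatter(mcbc_i, mcbc_p, mcbc_w, mcbc_d, buf_b2, cell, step)

        # synaptic state decay (event kernels evaluated analytically)
        if Vg.shape[0] > 0:
            _decay_channels(Ag, Bg, decA_g, decB_g)
        if Vb.shape[0] > 0:
            _decay_channels(Ab, Bb, decA_b, decB_b)
        if Vm.shape[0] > 0:
            _decay_channels(Am, Bm, decA_m, decB_m)

        # probes
        for q in range(probe_pop.shape[0]):
            p = probe_pop[q]
            if p == 0:
                vrec[q, step + 1] = Vg[probe_cell[q], probe_comp[q]]
            elif p == 1:
                vrec[q, step + 1] = Vb[probe_cell[q], probe_comp[q]]
            else:
                vrec[q, step + 1] = Vm[probe_cell[q], probe_comp[q]]

        # stability check
        if step % 200 == 199:
            bad = _check_finite(Vg) if Vg.shape[0] > 0 else -1
            if bad >= 0:
                err_code, err_pop, err_cell, err_step = ERR_NONFINITE, 0, bad, step
                break
            bad = _check_finite(Vb) if Vb.shape[0] > 0 else -1
            if bad >= 0:
                err_code, err_pop, err_cell, err_step = ERR_NONFINITE, 1, bad, step
                break
            bad = _check_finite(Vm) if Vm.shape[0] > 0 else -1
            if bad >= 0:
                err_code, err_pop, err_cell, err_step = ERR_NONFINITE, 2, bad, step
                break

    if err_code == ERR_OVERFLOW:
        err_pop = -1
    return out_n[0], err_code, err_pop, err_cell, err_step
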