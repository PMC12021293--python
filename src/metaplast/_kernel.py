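"""Numba kernel for recurrent conductance-based LIF E/I network episodes.

Integration scheme (consistent everywhere, documented in the methods note):

* forward Euler on the membrane equation at ``dt`` (0.1 ms default), using
  start-of-step conductances;
* exact exponential decay of conductances, adaptive thresholds and synaptic
  traces;
* spike-triggered conductance increments and plasticity updates applied at
  the end of the step in which the spike occurs;
* plasticity order within a step: all pre-triggered updates, then all
  post-triggered updates, then trace bumps (+1) of every spiking neuron.

The kernel is RNG-free: external Poisson input arrives as a pre-generated,
step-sorted event list, so episodes are bit-deterministic given their inputs.
"""

import numpy as np
from numba import njit

from ._deltas import (
    BIG, MLP, SMALL, STATIC, TAU_CE, TAU_CI, TAU_LONG, TAU_SHORT, TAU_VAVG,
    big_delta_post, big_delta_pre, mlp_delta_post, mlp_delta_pre,
    small_delta_post, small_delta_pre, trace_at,
)

VOGELS = 0
ZENKE = 1


@njit(cache=True)
def _pre_updates(kind, prm, scale, lo, hi, t, spikers, nspk,
                 ptr, idx, w,
                 trpost_v, trpost_t,
                 xl_pre_v, xl_pre_t, xs_post_v, xs_post_t,
                 vavg, ce, ci, W1, W2):
    """Apply pre-spike-triggered updates of one block; returns False on NaN."""
    ok = True
    for a in range(nspk):
        i = spikers[a]
        for s in range(ptr[i], ptr[i + 1]):
            j = idx[s]
            if kind == SMALL:
                xp = trace_at(trpost_v[j], trpost_t[j], t, prm[5])
                dw = small_delta_pre(prm, xp)
            elif kind == BIG:
                xil = trace_at(xl_pre_v[i], xl_pre_t[i], t, TAU_LONG)
                xjs = trace_at(xs_post_v[j], xs_post_t[j], t, TAU_SHORT)
                dw = big_delta_pre(prm, w[s], vavg[j], ce[j], ci[j], xil, xjs)
            else:
                xil = trace_at(xl_pre_v[i], xl_pre_t[i], t, TAU_LONG)
                xjs = trace_at(xs_post_v[j], xs_post_t[j], t, TAU_SHORT)
                dw = mlp_delta_pre(prm, W1, W2, xil, xjs, w[s],
                                   vavg[j], ce[j], ci[j])
            nw = w[s] + scale * dw
            if not np.isfinite(nw):
                ok = False
            else:
                if nw < lo:
                    nw = lo
                elif nw > hi:
                    nw = hi
                w[s] = nw
    return ok


@njit(cache=True)
def _post_updates(kind, prm, scale, lo, hi, t, spikers, nspk,
                  cptr, cidx, cpre, w,
                  trpre_v, trpre_t,
                  xs_pre_v, xs_pre_t, xl_post_v, xl_post_t,
                  vavg, ce, ci, W1, W2):
    """Apply post-spike-triggered updates of one block (CSC traversal)."""
    ok = True
    for a in range(nspk):
        j = spikers[a]
        for s in range(cptr[j], cptr[j + 1]):
            syn = cidx[s]
            i = cpre[s]
            if kind == SMALL:
                xp = trace_at(trpre_v[i], trpre_t[i], t, prm[4])
                dw = small_delta_post(prm, xp)
            elif kind == BIG:
                xis = trace_at(xs_pre_v[i], xs_pre_t[i], t, TAU_SHORT)
                xjl = trace_at(xl_post_v[j], xl_post_t[j], t, TAU_LONG)
                dw = big_delta_post(prm, w[syn], vavg[j], ce[j], ci[j],
                                    xis, xjl)
            else:
                xis = trace_at(xs_pre_v[i], xs_pre_t[i], t, TAU_SHORT)
                xjl = trace_at(xl_post_v[j], xl_post_t[j], t, TAU_LONG)
                dw = mlp_delta_post(prm, W1, W2, xis, xjl, w[syn],
                                    vavg[j], ce[j], ci[j])
            nw = w[syn] + scale * dw
            if not np.isfinite(nw):
                ok = False
            else:
                if nw < lo:
                    nw = lo
                elif nw > hi:
                    nw = hi
                w[syn] = nw
    return ok


@njit(cache=True)
def _bump(v, tarr, spikers, nspk, t, tau):
    for a in range(nspk):
        i = spikers[a]
        v[i] = v[i] * np.exp(-(t - tarr[i]) / tau) + 1.0
        tarr[i] = t


@njit(cache=True)
def _block_mean(w):
    if w.size == 0:
        return 0.0
    return np.mean(w)


@njit(cache=True)
def run_episode_kernel(
    variant, dt, n_steps,
    # neuron parameters
    tau_m, v_rest, e_exc, e_inh, v_th_base, v_reset, tau_ref,
    tau_ampa, tau_gaba, tau_nmda, a_frac, v_th_spike, tau_th,
    n_e, n_i,
    # external input events, sorted by step
    ext_step, ext_idx,
    # plasticity gating segments (end step exclusive, flag)
    seg_end, seg_plastic,
    # external connectivity (CSR by ext neuron)
    xe_ptr, xe_idx, xe_w, xi_ptr, xi_idx, xi_w,
    # recurrent blocks: CSR + CSC, order ee, ei, ie, ii
    ee_ptr, ee_idx, ee_cptr, ee_cidx, ee_cpre,
    ei_ptr, ei_idx, ei_cptr, ei_cidx, ei_cpre,
    ie_ptr, ie_idx, ie_cptr, ie_cidx, ie_cpre,
    ii_ptr, ii_idx, ii_cptr, ii_cidx, ii_cpre,
    ee_w, ei_w, ie_w, ii_w,
    # plasticity: kind / packed params / scale / bounds per block
    kinds, prms, scales, lo, hi,
    mlp_W1, mlp_W2,
    # recording
    rate_bin_steps, w_sample_steps, max_raster,
):
    ref_steps = int(round(tau_ref / dt))
    dec_ampa = np.exp(-dt / tau_ampa)
    dec_gaba = np.exp(-dt / tau_gaba)
    dec_th = np.exp(-dt / tau_th)

    v_e = np.full(n_e, v_rest)
    v_i = np.full(n_i, v_rest)
    ga_e = np.zeros(n_e)
    gg_e = np.zeros(n_e)
    ga_i = np.zeros(n_i)
    gg_i = np.zeros(n_i)
    gn_e = np.zeros(n_e)
    gn_i = np.zeros(n_i)
    th_e = np.full(n_e, v_th_base)
    th_i = np.full(n_i, v_th_base)
    ref_e = np.zeros(n_e, np.int64)
    ref_i = np.zeros(n_i, np.int64)

    # per-block small-poly traces (pre population, post population)
    ee_pre_v = np.zeros(n_e); ee_pre_t = np.zeros(n_e)
    ee_post_v = np.zeros(n_e); ee_post_t = np.zeros(n_e)
    ei_pre_v = np.zeros(n_e); ei_pre_t = np.zeros(n_e)
    ei_post_v = np.zeros(n_i); ei_post_t = np.zeros(n_i)
    ie_pre_v = np.zeros(n_i); ie_pre_t = np.zeros(n_i)
    ie_post_v = np.zeros(n_e); ie_post_t = np.zeros(n_e)
    ii_pre_v = np.zeros(n_i); ii_pre_t = np.zeros(n_i)
    ii_post_v = np.zeros(n_i); ii_post_t = np.zeros(n_i)

    # global short/long traces + auxiliary variables (big-poly / MLP spaces)
    need_glob = (kinds[0] >= BIG or kinds[1] >= BIG
                 or kinds[2] >= BIG or kinds[3] >= BIG)
    need_aux_e = kinds[0] >= BIG or kinds[2] >= BIG
    need_aux_i = kinds[1] >= BIG or kinds[3] >= BIG
    xs_e_v = np.zeros(n_e); xs_e_t = np.zeros(n_e)
    xl_e_v = np.zeros(n_e); xl_e_t = np.zeros(n_e)
    xs_i_v = np.zeros(n_i); xs_i_t = np.zeros(n_i)
    xl_i_v = np.zeros(n_i); xl_i_t = np.zeros(n_i)
    vavg_e = np.full(n_e, v_rest); ce_e = np.zeros(n_e); ci_e = np.zeros(n_e)
    vavg_i = np.full(n_i, v_rest); ce_i = np.zeros(n_i); ci_i = np.zeros(n_i)

    sp_e = np.empty(n_e, np.int64)
    sp_i = np.empty(n_i, np.int64)

    n_bins = (n_steps + rate_bin_steps - 1) // rate_bin_steps
    e_counts = np.zeros(n_bins, np.int64)
    i_counts = np.zeros(n_bins, np.int64)

    n_samp_max = n_steps // w_sample_steps + 2
    w_times = np.zeros(n_samp_max)
    w_means = np.zeros((n_samp_max, 4))
    n_samp = 0

    re_n = np.empty(max_raster, np.int64)
    re_t = np.empty(max_raster, np.float64)
    ri_n = np.empty(max_raster, np.int64)
    ri_t = np.empty(max_raster, np.float64)
    nre = 0
    nri = 0

    any_plastic = (kinds[0] != STATIC or kinds[1] != STATIC
                   or kinds[2] != STATIC or kinds[3] != STATIC)

    diverged = False
    seg = 0
    ext_p = 0
    n_ext_events = ext_step.size

    for step in range(n_steps):
        while step >= seg_end[seg]:
            seg += 1
        plastic_now = any_plastic and seg_plastic[seg] == 1
        t = step * dt
        rbin = step // rate_bin_steps

        # --- membrane integration + spike detection (start-of-step g) ---
        nspk_e = 0
        for j in range(n_e):
            if variant == VOGELS and ref_e[j] > 0:
                ref_e[j] -= 1
                v_e[j] = v_rest
                continue
            if variant == VOGELS:
                ge = ga_e[j]
            else:
                ge = a_frac * ga_e[j] + (1.0 - a_frac) * gn_e[j]
            gi = gg_e[j]
            v = v_e[j]
            v += (dt / tau_m) * (-(v - v_rest) - ge * (v - e_exc)
                                 - gi * (v - e_inh))
            thr = v_th_base if variant == VOGELS else th_e[j]
            if v >= thr:
                sp_e[nspk_e] = j
                nspk_e += 1
                if variant == VOGELS:
                    v = v_rest
                    ref_e[j] = ref_steps
                else:
                    v = v_reset
                    th_e[j] += v_th_spike
            v_e[j] = v

        nspk_i = 0
        for j in range(n_i):
            if variant == VOGELS and ref_i[j] > 0:
                ref_i[j] -= 1
                v_i[j] = v_rest
                continue
            if variant == VOGELS:
                ge = ga_i[j]
            else:
                ge = a_frac * ga_i[j] + (1.0 - a_frac) * gn_i[j]
            gi = gg_i[j]
            v = v_i[j]
            v += (dt / tau_m) * (-(v - v_rest) - ge * (v - e_exc)
                                 - gi * (v - e_inh))
            thr = v_th_base if variant == VOGELS else th_i[j]
            if v >= thr:
                sp_i[nspk_i] = j
                nspk_i += 1
                if variant == VOGELS:
                    v = v_rest
                    ref_i[j] = ref_steps
                else:
                    v = v_reset
                    th_i[j] += v_th_spike
            v_i[j] = v

        # --- recording ---
        e_counts[rbin] += nspk_e
        i_counts[rbin] += nspk_i
        if max_raster > 0:
            for a in range(nspk_e):
                if nre < max_raster:
                    re_n[nre] = sp_e[a]
                    re_t[nre] = t
                    nre += 1
            for a in range(nspk_i):
                if nri < max_raster:
                    ri_n[nri] = sp_i[a]
                    ri_t[nri] = t
                    nri += 1

        # --- adaptive-threshold relaxation (Zenke) ---
        if variant == ZENKE:
            for j in range(n_e):
                th_e[j] = v_th_base + (th_e[j] - v_th_base) * dec_th
            for j in range(n_i):
                th_i[j] = v_th_base + (th_i[j] - v_th_base) * dec_th

        # --- conductance decay, NMDA low-pass ---
        for j in range(n_e):
            ga_e[j] *= dec_ampa
            gg_e[j] *= dec_gaba
        for j in range(n_i):
            ga_i[j] *= dec_ampa
            gg_i[j] *= dec_gaba
        if variant == ZENKE:
            for j in range(n_e):
                gn_e[j] += (dt / tau_nmda) * (ga_e[j] - gn_e[j])
            for j in range(n_i):
                gn_i[j] += (dt / tau_nmda) * (ga_i[j] - gn_i[j])

        # --- external input increments ---
        while ext_p < n_ext_events and ext_step[ext_p] == step:
            x = ext_idx[ext_p]
            for k in range(xe_ptr[x], xe_ptr[x + 1]):
                ga_e[xe_idx[k]] += xe_w[k]
            for k in range(xi_ptr[x], xi_ptr[x + 1]):
                ga_i[xi_idx[k]] += xi_w[k]
            ext_p += 1

        # --- recurrent spike increments ---
        for a in range(nspk_e):
            i = sp_e[a]
            for s in range(ee_ptr[i], ee_ptr[i + 1]):
                ga_e[ee_idx[s]] += ee_w[s]
            for s in range(ei_ptr[i], ei_ptr[i + 1]):
                ga_i[ei_idx[s]] += ei_w[s]
        for a in range(nspk_i):
            i = sp_i[a]
            for s in range(ie_ptr[i], ie_ptr[i + 1]):
                gg_e[ie_idx[s]] += ie_w[s]
            for s in range(ii_ptr[i], ii_ptr[i + 1]):
                gg_i[ii_idx[s]] += ii_w[s]

        # --- auxiliary low-pass variables (only for big-poly / MLP) ---
        if need_aux_e:
            for j in range(n_e):
                if variant == VOGELS:
                    ge = ga_e[j]
                else:
                    ge = a_frac * ga_e[j] + (1.0 - a_frac) * gn_e[j]
                vavg_e[j] += (dt / TAU_VAVG) * (v_e[j] - vavg_e[j])
                ce_e[j] += (dt / TAU_CE) * (ge * (e_exc - v_e[j]) - ce_e[j])
                ci_e[j] += (dt / TAU_CI) * (gg_e[j] * (e_inh - v_e[j]) - ci_e[j])
        if need_aux_i:
            for j in range(n_i):
                if variant == VOGELS:
                    ge = ga_i[j]
                else:
                    ge = a_frac * ga_i[j] + (1.0 - a_frac) * gn_i[j]
                vavg_i[j] += (dt / TAU_VAVG) * (v_i[j] - vavg_i[j])
                ce_i[j] += (dt / TAU_CE) * (ge * (e_exc - v_i[j]) - ce_i[j])
                ci_i[j] += (dt / TAU_CI) * (gg_i[j] * (e_inh - v_i[j]) - ci_i[j])

        # --- plasticity ---
        if plastic_now and (nspk_e > 0 or nspk_i > 0):
            ok = True
            # pre-triggered updates first (tie-break convention)
            if kinds[0] != STATIC and nspk_e > 0:
                ok &= _pre_updates(kinds[0], prms[0], scales[0], lo[0], hi[0],
                                   t, sp_e, nspk_e, ee_ptr, ee_idx, ee_w,
                                   ee_post_v, ee_post_t,
                                   xl_e_v, xl_e_t, xs_e_v, xs_e_t,
                                   vavg_e, ce_e, ci_e, mlp_W1, mlp_W2)
            if kinds[1] != STATIC and nspk_e > 0:
                ok &= _pre_updates(kinds[1], prms[1], scales[1], lo[1], hi[1],
                                   t, sp_e, nspk_e, ei_ptr, ei_idx, ei_w,
                                   ei_post_v, ei_post_t,
                                   xl_e_v, xl_e_t, xs_i_v, xs_i_t,
                                   vavg_i, ce_i, ci_i, mlp_W1, mlp_W2)
            if kinds[2] != STATIC and nspk_i > 0:
                ok &= _pre_updates(kinds[2], prms[2], scales[2], lo[2], hi[2],
                                   t, sp_i, nspk_i, ie_ptr, ie_idx, ie_w,
                                   ie_post_v, ie_post_t,
                                   xl_i_v, xl_i_t, xs_e_v, xs_e_t,
                                   vavg_e, ce_e, ci_e, mlp_W1, mlp_W2)
            if kinds[3] != STATIC and nspk_i > 0:
                ok &= _pre_updates(kinds[3], prms[3], scales[3], lo[3], hi[3],
                                   t, sp_i, nspk_i, ii_ptr, ii_idx, ii_w,
                                   ii_post_v, ii_post_t,
                                   xl_i_v, xl_i_t, xs_i_v, xs_i_t,
                                   vavg_i, ce_i, ci_i, mlp_W1, mlp_W2)
            # then post-triggered updates
            if kinds[0] != STATIC and nspk_e > 0:
                ok &= _post_updates(kinds[0], prms[0], scales[0], lo[0], hi[0],
                                    t, sp_e, nspk_e, ee_cptr, ee_cidx, ee_cpre,
                                    ee_w, ee_pre_v, ee_pre_t,
                                    xs_e_v, xs_e_t, xl_e_v, xl_e_t,
                                    vavg_e, ce_e, ci_e, mlp_W1, mlp_W2)
            if kinds[1] != STATIC and nspk_i > 0:
                ok &= _post_updates(kinds[1], prms[1], scales[1], lo[1], hi[1],
                                    t, sp_i, nspk_i, ei_cptr, ei_cidx, ei_cpre,
                                    ei_w, ei_pre_v, ei_pre_t,
                                    xs_e_v, xs_e_t, xl_i_v, xl_i_t,
                                    vavg_i, ce_i, ci_i, mlp_W1, mlp_W2)
            if kinds[2] != STATIC and nspk_e > 0:
                ok &= _post_updates(kinds[2], prms[2], scales[2], lo[2], hi[2],
                                    t, sp_e, nspk_e, ie_cptr, ie_cidx, ie_cpre,
                                    ie_w, ie_pre_v, ie_pre_t,
                                    xs_i_v, xs_i_t, xl_e_v, xl_e_t,
                                    vavg_e, ce_e, ci_e, mlp_W1, mlp_W2)
            if kinds[3] != STATIC and nspk_i > 0:
                ok &= _post_updates(kinds[3], prms[3], scales[3], lo[3], hi[3],
                                    t, sp_i, nspk_i, ii_cptr, ii_cidx, ii_cpre,
                                    ii_w, ii_pre_v, ii_pre_t,
                                    xs_i_v, xs_i_t, xl_i_v, xl_i_t,
                                    vavg_i, ce_i, ci_i, mlp_W1, mlp_W2)
            if not ok:
                diverged = True
                break

        # --- trace bumps for this step's spikers (after all updates) ---
        if nspk_e > 0:
            if kinds[0] == SMALL:
                _bump(ee_pre_v, ee_pre_t, sp_e, nspk_e, t, prms[0][4])
                _bump(ee_post_v, ee_post_t, sp_e, nspk_e, t, prms[0][5])
            if kinds[1] == SMALL:
                _bump(ei_pre_v, ei_pre_t, sp_e, nspk_e, t, prms[1][4])
            if kinds[2] == SMALL:
                _bump(ie_post_v, ie_post_t, sp_e, nspk_e, t, prms[2][5])
            if need_glob:
                _bump(xs_e_v, xs_e_t, sp_e, nspk_e, t, TAU_SHORT)
                _bump(xl_e_v, xl_e_t, sp_e, nspk_e, t, TAU_LONG)
        if nspk_i > 0:
            if kinds[1] == SMALL:
                _bump(ei_post_v, ei_post_t, sp_i, nspk_i, t, prms[1][5])
            if kinds[2] == SMALL:
                _bump(ie_pre_v, ie_pre_t, sp_i, nspk_i, t, prms[2][4])
            if kinds[3] == SMALL:
                _bump(ii_pre_v, ii_pre_t, sp_i, nspk_i, t, prms[3][4])
                _bump(ii_post_v, ii_post_t, sp_i, nspk_i, t, prms[3][5])
            if need_glob:
                _bump(xs_i_v, xs_i_t, sp_i, nspk_i, t, TAU_SHORT)
                _bump(xl_i_v, xl_i_t, sp_i, nspk_i, t, TAU_LONG)

        # --- weight sampling ---
        if step % w_sample_steps == 0:
            w_times[n_samp] = t
            w_means[n_samp, 0] = _block_mean(ee_w)
            w_means[n_samp, 1] = _block_mean(ei_w)
            w_means[n_samp, 2] = _block_mean(ie_w)
            w_means[n_samp, 3] = _block_mean(ii_w)
            n_samp += 1

        # --- divergence guard ---
        if step % 500 == 0:
            for j in range(n_e):
                if not np.isfinite(v_e[j]) or abs(v_e[j]) > 1e4:
                    diverged = True
                    break
            if diverged:
                break

    # final weight sample
    w_times[n_samp] = n_steps * dt
    w_means[n_samp, 0] = _block_mean(ee_w)
    w_means[n_samp, 1] = _block_mean(ei_w)
    w_means[n_samp, 2] = _block_mean(ie_w)
    w_means[n_samp, 3] = _block_mean(ii_w)
    n_samp += 1

    return (e_counts, i_counts, w_times[:n_samp], w_means[:n_samp],
            re_n[:nre], re_t[:nre], ri_n[:nri], ri_t[:nri], diverged)
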