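"""Optional numba-accelerated inner loop for the float64 network step.

The kernel fuses, for one hemisphere and one 1 ms tick: conductance decay,
spike-driven conductance jumps (visiting only edges of presynaptic neurons
that fired, in pre-major order), synaptic currents, and the membrane update
with threshold/reset.  It is numerically the same map as the pure-numpy
path in :mod:`cerebsim.network`; only the edge-accumulation order differs
(pre-major here, post-major there), which can move individual conductances
by an ulp when several spikes land on one target.

If numba is not importable the simulator transparently uses the numpy path.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco if not (a and callable(a[0])) else a[0]


@njit(cache=True)
def hemi_step_kernel(
    v_all,          # float64 (n_neurons,) membrane potentials, updated in place
    delta_prev,     # bool (n_neurons,) previous step's impulses
    pop_off,        # int64 (n_pops+1,) population offsets into v_all
    beta_m,         # float64 (n_pops,) membrane decay factors
    c1,             # float64 (n_pops,) (1-beta)*E_L
    a_over_C,       # float64 (n_pops,) dt/C
    vth,            # float64 (n_pops,)
    vr_shift,       # float64 (n_pops,) V_r - V_th
    g_all,          # float64 (sum n_post,) conductances, updated in place
    proj_pre,       # int64 (P,) presynaptic population index
    proj_post,      # int64 (P,) postsynaptic population index
    proj_goff,      # int64 (P+1,) projection offsets into g_all
    proj_beta,      # float64 (P,) conductance decay factors
    proj_E,         # float64 (P,) reversal potentials [mV]
    proj_plastic,   # int8 (P,) 1 for the parallel-fibre class
    indptr_all,     # int64, concatenated per-projection CSC indptr blocks
    proj_iptr_off,  # int64 (P,) start of each projection's indptr block
    edge_post_all,  # int32, concatenated postsynaptic ids (projection-local)
    edge_w_all,     # float64, concatenated edge weights [nS]
    proj_edge_off,  # int64 (P,) start of each projection's edge block
    wT,             # float64 (n_GrC, n_PkC) plastic weights (uS fractions)
    w_scale,        # float64 nS per weight storage unit
    i_acc,          # float64 (n_neurons,) in: external+spontaneous drive [pA]
    fired_out,      # bool (n_neurons,) out: this step's impulses
):
    P = proj_pre.shape[0]
    # conductance decay
    for p in range(P):
        b = proj_beta[p]
        for k in range(proj_goff[p], proj_goff[p + 1]):
            g_all[k] *= b
    # spike-driven jumps from the previous step's impulses
    for p in range(P):
        pre = proj_pre[p]
        s = pop_off[pre]
        npre = pop_off[pre + 1] - s
        gbase = proj_goff[p]
        if proj_plastic[p] == 1:
            nr = wT.shape[1]
            for j in range(npre):
                if delta_prev[s + j]:
                    for m in range(nr):
                        g_all[gbase + m] += wT[j, m] * w_scale
        else:
            io = proj_iptr_off[p]
            eo = proj_edge_off[p]
            for j in range(npre):
                if delta_prev[s + j]:
                    for e in range(indptr_all[io + j], indptr_all[io + j + 1]):
                        g_all[gbase + edge_post_all[eo + e]] += edge_w_all[eo + e]
    # synaptic currents accumulate onto the external drive
    for p in range(P):
        post = proj_post[p]
        s = pop_off[post]
        E = proj_E[p]
        gbase = proj_goff[p]
        npost = proj_goff[p + 1] - gbase
        for m in range(npost):
            i_acc[s + m] -= g_all[gbase + m] * (v_all[s + m] - E)
    # membrane update, threshold, reset
    for q in range(pop_off.shape[0] - 1):
        bm = beta_m[q]
        cc = c1[q]
        aa = a_over_C[q]
        th = vth[q]
        sh = vr_shift[q]
        for j in range(pop_off[q], pop_off[q + 1]):
            vn = v_all[j] * bm + cc + i_acc[j] * aa
            if vn > th:
                fired_out[j] = True
                vn += sh
            else:
                fired_out[j] = False
            v_all[j] = vn


@njit(cache=True)
def plasticity_kernel(wT, q_grc, grc_fired, cf_fired, gamma_ltp, gamma_ltd, decay_q, bump_q):
    """q-trace update plus disjoint LTP/LTD weight updates (no clipping at
    the top; the caller certifies headroom via a running bound)."""
    n_grc, n_pkc = wT.shape
    any_cf = False
    for m in range(n_pkc):
        if cf_fired[m]:
            any_cf = True
    for j in range(n_grc):
        q_grc[j] *= decay_q
        if grc_fired[j]:
            q_grc[j] += bump_q
            if any_cf:
                for m in range(n_pkc):
                    if not cf_fired[m]:
                        wT[j, m] += gamma_ltp
            else:
                for m in range(n_pkc):
                    wT[j, m] += gamma_ltp
    if any_cf:
        for m in range(n_pkc):
            if cf_fired[m]:
                for j in range(n_grc):
                    w = wT[j, m] - gamma_ltd * q_grc[j]
                    wT[j, m] = w if w > 0.0 else 0.0
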