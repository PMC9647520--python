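"""Numba kernel for the lagged-state Kalman filter / disturbance smoother.

The state transition of a stacked-lag model is almost entirely shift rows
(slot (v, l) at time t equals slot (v, l-1) at t-1) plus one sparse equation
row per variable, so the transition is stored in CSR form and every product
with it costs O(nnz * d) instead of O(d^3).  Observations are exact scalar
reads of the current-value slots, handled sequentially; the backward pass is
the disturbance (r/N) smoother, and the smoothed covariance exploits the
fact that the prediction covariance is nonzero only on the "active" slots
whose underlying days are unobserved.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def em_pass(
    values,  # (S, T, V) float64, NaN-free on masked entries not required
    mask,  # (S, T, V) bool
    lengths,  # (S,) int64
    L0,  # conditioning window (int)
    indptr,  # (d+1,) CSR of the transition matrix A
    indices,  # (nnz,)
    data,  # (nnz,)
    Qd,  # (d,) innovation variances on current-value slots
    D,  # (S, d) per-subject intercept shift
    slot_var,  # (d,) variable index of each slot
    slot_lag,  # (d,) lag of each slot
    slot0,  # (V,) slot index of each variable's current value
    do_smooth,  # bool
):
    S, Tmax, V = values.shape
    d = Qd.shape[0]
    ll = np.zeros(V)
    nobs = np.zeros(V, np.int64)
    sum_z = np.zeros((S, d))
    sum_zz = np.zeros((S, d, d))
    counts = np.zeros(S, np.int64)

    mn = np.zeros(d)
    B = np.zeros((d, d))
    Pn = np.zeros((d, d))
    row = np.zeros(d)
    scr1 = np.zeros(d)
    scr2 = np.zeros(d)
    msb = np.zeros(d)
    actb = np.zeros(d, np.int64)
    tmp = np.zeros((d, d))
    PN = np.zeros((d, d))

    for s in range(S):
        Ts = int(lengths[s])
        if Ts <= L0:
            continue
        nst = Ts - L0  # modeled times t = L0 .. Ts-1 (0-based)
        nkeep = nst if do_smooth else 1

        # initial state at time L0-1: observed history where available,
        # unit (stationary) variance for unobserved entries
        m = np.zeros(d)
        P = np.zeros((d, d))
        for i in range(d):
            day = L0 - 1 - slot_lag[i]
            vi = slot_var[i]
            if day >= 0 and mask[s, day, vi]:
                m[i] = values[s, day, vi]
            else:
                P[i, i] = 1.0

        m_p = np.zeros((nkeep, d))
        P_p = np.zeros((nkeep, d, d))
        K_st = np.zeros((nkeep, V, d))
        e_st = np.zeros((nkeep, V))
        s_st = np.zeros((nkeep, V))
        o_st = np.zeros((nkeep, V), np.uint8)

        for st in range(nst):
            t = L0 + st
            # ---- predict: m <- A m + D, P <- A P A' + Q (CSR products)
            for i in range(d):
                acc = D[s, i]
                for kk in range(indptr[i], indptr[i + 1]):
                    acc += data[kk] * m[indices[kk]]
                mn[i] = acc
            for i in range(d):
                for j in range(d):
                    B[i, j] = 0.0
                for kk in range(indptr[i], indptr[i + 1]):
                    a = data[kk]
                    c = indices[kk]
                    for j in range(d):
                        B[i, j] += a * P[c, j]
            for j in range(d):
                for i in range(d):
                    Pn[i, j] = 0.0
                for kk in range(indptr[j], indptr[j + 1]):
                    a = data[kk]
                    c = indices[kk]
                    for i in range(d):
                        Pn[i, j] += a * B[i, c]
            for i in range(d):
                m[i] = mn[i]
                for j in range(i, d):
                    v_ = 0.5 * (Pn[i, j] + Pn[j, i])
                    P[i, j] = v_
                    P[j, i] = v_
                P[i, i] += Qd[i]

            sidx = st if do_smooth else 0
            if do_smooth:
                for i in range(d):
                    m_p[sidx, i] = m[i]
                    for j in range(d):
                        P_p[sidx, i, j] = P[i, j]
                for vi in range(V):
                    o_st[sidx, vi] = 0

            # ---- sequential exact scalar observation updates
            for vi in range(V):
                if mask[s, t, vi]:
                    i0 = slot0[vi]
                    sv = P[i0, i0]
                    if sv < 1e-300:
                        sv = 1e-300
                    ev = values[s, t, vi] - m[i0]
                    ll[vi] += -0.5 * (np.log(2.0 * np.pi * sv) + ev * ev / sv)
                    nobs[vi] += 1
                    for j in range(d):
                        row[j] = P[i0, j]
                    for i in range(d):
                        ki = P[i, i0] / sv
                        K_st[sidx, vi, i] = ki
                        m[i] += ki * ev
                        for j in range(d):
                            P[i, j] -= ki * row[j]
                    if do_smooth:
                        e_st[sidx, vi] = ev
                        s_st[sidx, vi] = sv
                        o_st[sidx, vi] = 1

        if not do_smooth:
            continue

        # ---- backward disturbance smoother
        r = np.zeros(d)
        N = np.zeros((d, d))
        for st in range(nst - 1, -1, -1):
            for vi in range(V - 1, -1, -1):
                if o_st[st, vi] == 1:
                    i0 = slot0[vi]
                    sv = s_st[st, vi]
                    ev = e_st[st, vi]
                    kr = 0.0
                    for i in range(d):
                        kr += K_st[st, vi, i] * r[i]
                    r[i0] += ev / sv - kr
                    for j in range(d):
                        acc = 0.0
                        for i in range(d):
                            acc += K_st[st, vi, i] * N[i, j]
                        scr1[j] = acc  # K'N
                    for i in range(d):
                        acc = 0.0
                        for j in range(d):
                            acc += N[i, j] * K_st[st, vi, j]
                        scr2[i] = acc  # NK
                    knk = 0.0
                    for i in range(d):
                        knk += K_st[st, vi, i] * scr2[i]
                    for j in range(d):
                        N[i0, j] -= scr1[j]
                    for i in range(d):
                        N[i, i0] -= scr2[i]
                    N[i0, i0] += knk + 1.0 / sv

            # smoothed mean/cov; prediction covariance lives on active slots
            na = 0
            for i in range(d):
                msb[i] = m_p[st, i]
                if P_p[st, i, i] > 1e-14:
                    actb[na] = i
                    na += 1
            for aa in range(na):
                i = actb[aa]
                acc = 0.0
                for bb in range(na):
                    j = actb[bb]
                    acc += P_p[st, i, j] * r[j]
                msb[i] += acc
            counts[s] += 1
            for i in range(d):
                zi = msb[i]
                sum_z[s, i] += zi
                for j in range(d):
                    sum_zz[s, i, j] += zi * msb[j]
            if na > 0:
                # PN = P_p[act,act] @ N[act,act]; Ps = P_p - PN @ P_p
                for aa in range(na):
                    i = actb[aa]
                    for bb in range(na):
                        j = actb[bb]
                        acc = 0.0
                        for cc in range(na):
                            kx = actb[cc]
                            acc += P_p[st, i, kx] * N[kx, j]
                        PN[aa, bb] = acc
                for aa in range(na):
                    i = actb[aa]
                    for bb in range(na):
                        j = actb[bb]
                        acc = 0.0
                        for cc in range(na):
                            kx = actb[cc]
                            acc += PN[aa, cc] * P_p[st, kx, j]
                        sum_zz[s, i, j] += P_p[st, i, j] - acc

            # transition to the previous step: r <- A'r, N <- A'NA
            for i in range(d):
                mn[i] = 0.0
            for krow in range(d):
                rk = r[krow]
                if rk != 0.0:
                    for kk in range(indptr[krow], indptr[krow + 1]):
                        mn[indices[kk]] += data[kk] * rk
            for i in range(d):
                r[i] = mn[i]
            for i in range(d):
                for j in range(d):
                    tmp[i, j] = 0.0
            for krow in range(d):
                for kk in range(indptr[krow], indptr[krow + 1]):
                    a = data[kk]
                    c = indices[kk]
                    for j in range(d):
                        tmp[c, j] += a * N[krow, j]
            for i in range(d):
                for j in range(d):
                    N[i, j] = 0.0
            for krow in range(d):
                for kk in range(indptr[krow], indptr[krow + 1]):
                    a = data[kk]
                    c = indices[kk]
                    for i in range(d):
                        N[i, c] += a * tmp[i, krow]

    return ll, nobs, sum_z, sum_zz, counts
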