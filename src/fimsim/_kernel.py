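"""Numba kernel for the whole-cell adhesive-dynamics loop.

All state lives in flat numpy arrays so the time loop compiles to machine
code.  Conventions inside the kernel: lengths nm, forces pN, torques pN*nm,
time s, stresses Pa.  The wall is z = 0, flow along +x.

The pose update is semi-implicit: each step solves

    (R/dt + K) v = F_ext

where ``R`` is the diagonal near-wall resistance matrix and ``K`` the
linearized 6x6 stiffness of the attached tethers (plus the wall repulsion).
This is backward Euler on the linearized elastic force and is stable for
arbitrarily stiff tethers, which explicit stepping at practical dt is not.
Bond and coiling kinetics use exact per-step exponential probabilities with
internal sub-stepping where rates are fast.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .fimbria_mechanics import (
    PM_RISE_A, PM_X0B, PM_X0C, PM_KCOIL, PM_FBUCK, PM_MODE,
    _coil_rates_nb, _stretch_fraction_nb,
    _tension_from_length_nb, _dlength_dtension_nb,
    _tension_partition_nb, _dlength_partition_nb,
)
from .bond_kinetics import (
    PB_K10, PB_K20, PB_K12, PB_K21, PB_KON, PB_CAPTURE,
    _bond_rates_nb,
)

# event codes in the event log
EV_BIND, EV_RUPTURE, EV_ACTIVATE, EV_DEACTIVATE = 1, 2, 3, 4

# tension cap inside the whole-cell kernel: any bond loaded this far past the
# slip regime ruptures within the step, so larger values only destabilize the
# force balance without changing outcomes
_TCAP = 300.0

_FSTAR_CONTACT = 1.7005
_TSTAR_CONTACT = 0.9440


@njit(cache=True)
def seed_kernel_rng(seed: int) -> None:
    np.random.seed(seed)


@njit(cache=True)
def _stress_at(t, prot_t0, prot_s0, prot_rate):
    i = 0
    for j in range(prot_t0.shape[0]):
        if prot_t0[j] <= t + 1e-12:
            i = j
        else:
            break
    return prot_s0[i] + prot_rate[i] * (t - prot_t0[i])


@njit(cache=True)
def _next_switch(t, prot_t0):
    for j in range(prot_t0.shape[0]):
        if prot_t0[j] > t + 1e-12:
            return prot_t0[j]
    return 1e300


@njit(cache=True)
def _tension_capped(ext, nA, nB, nC, pm, F0):
    """Tension of a bound fimbria.  In yielding mode the B/C split is
    taken at its instantaneous equilibrium, solved jointly with the
    tension; other modes use the explicit subunit state."""
    if pm[PM_MODE] == 0.0:
        T = _tension_partition_nb(ext, nA, nB + nC, pm, F0)
    else:
        T = _tension_from_length_nb(ext, nA, nB, nC, pm, F0)
    if T > _TCAP:
        T = _TCAP
    return T


# maximum pose displacement per mechanics sub-step (nm); keeps the
# linearized semi-implicit update inside its domain of validity
_DISP_MAX = 60.0


@njit(cache=True)
def _solve6(A, b, v):
    """In-place Gaussian elimination with partial pivoting for the 6x6
    force balance (A and b are destroyed)."""
    for col in range(6):
        piv = col
        amax = abs(A[col, col])
        for r in range(col + 1, 6):
            if abs(A[r, col]) > amax:
                amax = abs(A[r, col])
                piv = r
        if piv != col:
            for cc in range(6):
                tmp = A[col, cc]
                A[col, cc] = A[piv, cc]
                A[piv, cc] = tmp
            tmp = b[col]
            b[col] = b[piv]
            b[piv] = tmp
        d = A[col, col]
        if abs(d) < 1e-300:
            d = 1e-300
        for r in range(col + 1, 6):
            f = A[r, col] / d
            if f != 0.0:
                for cc in range(col, 6):
                    A[r, cc] -= f * A[col, cc]
                b[r] -= f * b[col]
    for r in range(5, -1, -1):
        acc = b[r]
        for cc in range(r + 1, 6):
            acc -= A[r, cc] * v[cc]
        v[r] = acc / A[r, r]


@njit(cache=True)
def _bond_geometry(c, Rm, u_body, L_nat, attach, status, nA, nB, nC, pm,
                   a_nm, tension, kstiff, nhat, dist, u_w, bound_only):
    """Anchor directions, bond unit vectors, tensions and stiffnesses.

    Warm-starts the tension inversion from the previous values held in
    ``tension``.  With ``bound_only`` the (slowly varying) anchor
    directions of unbound fimbriae are left untouched -- they are only
    needed once per kinetic step, for the binding geometry.  Returns the
    number of bound fimbriae.
    """
    n = u_body.shape[0]
    n_bound = 0
    for i in range(n):
        if status[i] == 0:
            if not bound_only:
                for d in range(3):
                    u_w[i, d] = (Rm[d, 0] * u_body[i, 0]
                                 + Rm[d, 1] * u_body[i, 1]
                                 + Rm[d, 2] * u_body[i, 2])
            tension[i] = 0.0
            continue
        for d in range(3):
            u_w[i, d] = (Rm[d, 0] * u_body[i, 0]
                         + Rm[d, 1] * u_body[i, 1]
                         + Rm[d, 2] * u_body[i, 2])
        n_bound += 1
        dx = attach[i, 0] - (c[0] + a_nm * u_w[i, 0])
        dy = attach[i, 1] - (c[1] + a_nm * u_w[i, 1])
        dz = attach[i, 2] - (c[2] + a_nm * u_w[i, 2])
        di = math.sqrt(dx * dx + dy * dy + dz * dz)
        dist[i] = di
        if di < 1e-9:
            nhat[i, 0] = 0.0
            nhat[i, 1] = 0.0
            nhat[i, 2] = -1.0
            tension[i] = 0.0
            kstiff[i] = 0.0
            continue
        nhat[i, 0] = dx / di
        nhat[i, 1] = dy / di
        nhat[i, 2] = dz / di
        fa = float(nA[i])
        fb = float(nB[i])
        fc = float(nC[i])
        w0 = tension[i] if tension[i] > 1.0 else 1.0
        T = _tension_capped(di, fa, fb, fc, pm, w0)
        tension[i] = T
        if T > 0.0:
            if pm[PM_MODE] == 0.0:
                kstiff[i] = 1.0 / _dlength_partition_nb(T, fa, fb + fc, pm)
            else:
                kstiff[i] = 1.0 / _dlength_dtension_nb(T, fa, fb, fc, pm)
        elif nA[i] > 0:
            # compressed A segment; keeping the spring stiffness through
            # the buckling clamp damps the implicit update (the clamp only
            # flattens the force, it does not soften the contact)
            kstiff[i] = pm[PM_KCOIL] / fa
        else:
            kstiff[i] = 0.0
        if status[i] != 0 and kstiff[i] < 0.02:
            # floor: a near-slack WLC is almost infinitely compliant, which
            # lets linearized hops ping-pong across the taut boundary
            kstiff[i] = 0.02
    return n_bound


@njit(cache=True)
def advance(t_arr, t_end, dt_max, mu,
            prot_t0, prot_s0, prot_rate,
            a_nm, gap_rest, k_wall, grace,
            pm, pb,
            u_body, L_nat, n_sub, nA, nB, nC, status, attach, allow_bind,
            c, Rm, rotacc,
            misc,
            next_out_arr, out_dt,
            out_t, out_sigma, out_pos, out_rot, out_nbound, out_nact,
            out_nunc, out_force, out_status, out_nA,
            k_out_arr,
            ev_t, ev_fim, ev_type, ev_n):
    """Advance the system to ``t_end`` (or detachment).  Returns 1 if the
    cell detached (no bonds for longer than the grace window), -1 on a
    non-finite pose."""
    n = u_body.shape[0]
    mode = pm[PM_MODE]
    ct_coef = 6.0 * math.pi * mu * 1e-6          # a_nm -> pN s/nm
    cr_coef = 8.0 * math.pi * mu * 1e-6          # a_nm^3 -> pN nm s
    fshear_coef = 6.0 * math.pi * mu * 1e-6
    tshear_coef = 4.0 * math.pi * mu * 1e-6

    u_w = np.empty((n, 3))
    tension = np.zeros(n)
    kstiff = np.zeros(n)
    nhat = np.zeros((n, 3))
    dist = np.zeros(n)
    A = np.empty((6, 6))
    bb = np.empty(6)
    v = np.empty(6)
    M3 = np.empty((3, 3))
    Rx = np.zeros((3, 3))

    # zero-force coiling rates for unbound fimbriae (bulk Poisson update)
    kab0, kba0 = _coil_rates_nb(0.0, pm)

    t = t_arr[0]

    while t < t_end - 1e-12:
        sigma = _stress_at(t, prot_t0, prot_s0, prot_rate)
        gdot = sigma / mu

        n_bound = _bond_geometry(c, Rm, u_body, L_nat, attach, status,
                                 nA, nB, nC, pm, a_nm, tension, kstiff,
                                 nhat, dist, u_w, False)

        # fastest kinetics that must be resolved by the step
        max_rate = pb[PB_KON]
        for i in range(n):
            if status[i] == 0:
                continue
            Ft = tension[i] if tension[i] > 0.0 else 0.0
            k10, k20, k12, k21 = _bond_rates_nb(Ft, pb)
            r = k10 if status[i] == 1 else k20
            if r > 2000.0:
                r = 2000.0   # faster ruptures resolve within one step anyway
            if r > max_rate:
                max_rate = r

        dt = dt_max
        if 0.1 / max_rate < dt:
            dt = 0.1 / max_rate
        nb_t = _next_switch(t, prot_t0)
        if nb_t - t < dt:
            dt = nb_t - t
        if t_end - t < dt:
            dt = t_end - t

        # --- record snapshot ---
        if t >= next_out_arr[0] - 1e-12:
            k = k_out_arr[0]
            if k < out_t.shape[0]:
                out_t[k] = t
                out_sigma[k] = sigma
                n_act = 0
                n_unc = 0
                for i in range(n):
                    out_force[k, i] = np.float32(
                        tension[i] if status[i] != 0 else np.nan)
                    out_status[k, i] = np.int8(status[i])
                    out_nA[k, i] = np.int32(nA[i])
                    if status[i] == 2:
                        n_act += 1
                    if (n_sub[i] - nA[i]) > 0.05 * n_sub[i]:
                        n_unc += 1
                for d in range(3):
                    out_pos[k, d] = c[d]
                    out_rot[k, d] = rotacc[d]
                out_nbound[k] = n_bound
                out_nact[k] = n_act
                out_nunc[k] = n_unc
                k_out_arr[0] = k + 1
            next_out_arr[0] += out_dt

        # --- coiling + stretch partition (yielding mode only) ---
        if mode == 0.0:
            for i in range(n):
                if status[i] == 0:
                    # Unbound fimbriae carry no force: recoil dominates by
                    # k0_BA/k0_AB, so partially uncoiled ones re-coil (bulk
                    # Poisson counts) and fully coiled ones stay coiled
                    # (equilibrium edge occupancy ~k0_AB/k0_BA << 1).
                    if nB[i] + nC[i] > 0:
                        up = np.random.poisson(kab0 * dt)
                        dn = np.random.poisson(kba0 * dt)
                        if up > nA[i]:
                            up = nA[i]
                        if dn > nB[i] + nC[i]:
                            dn = nB[i] + nC[i]
                        nA[i] += dn - up
                        rem = dn
                        if nB[i] >= rem:
                            nB[i] -= rem
                        else:
                            rem -= nB[i]
                            nB[i] = 0
                            nC[i] -= rem
                        nB[i] += up
                    continue
                F = tension[i]
                if F < 0.0:
                    F = 0.0
                kab, kba = _coil_rates_nb(F, pm)
                m = int((kab + kba) * dt / 0.1) + 1
                if m > 500:
                    m = 500
                hstep = dt / m
                changed = False
                for _ in range(m):
                    if m > 1 and changed:
                        F = _tension_capped(dist[i], float(nA[i]),
                                            float(nB[i]), float(nC[i]), pm,
                                            F if F > 1.0 else 1.0)
                        if F < 0.0:
                            F = 0.0
                        kab, kba = _coil_rates_nb(F, pm)
                        changed = False
                    if nA[i] > 0 and np.random.random() < -math.expm1(-kab * hstep):
                        nA[i] -= 1
                        nB[i] += 1
                        changed = True
                    if nA[i] < n_sub[i] and (nB[i] + nC[i]) > 0 and \
                            np.random.random() < -math.expm1(-kba * hstep):
                        nA[i] += 1
                        if nB[i] > 0:
                            nB[i] -= 1
                        else:
                            nC[i] -= 1
                        changed = True
                n_unc_i = nB[i] + nC[i]
                if n_unc_i > 0:
                    phi = _stretch_fraction_nb(F, pm)
                    nc_new = int(np.rint(phi * n_unc_i))
                    nC[i] = nc_new
                    nB[i] = n_unc_i - nc_new
                if changed:
                    tension[i] = _tension_capped(
                        dist[i], float(nA[i]), float(nB[i]), float(nC[i]),
                        pm, F if F > 1.0 else 1.0)

        # --- bond state transitions ---
        for i in range(n):
            if status[i] == 0:
                continue
            Ft = tension[i] if tension[i] > 0.0 else 0.0
            k10, k20, k12, k21 = _bond_rates_nb(Ft, pb)
            if status[i] == 1:
                ka = k10
                kb = k12
            else:
                ka = k20
                kb = k21
            ktot = ka + kb
            if ktot <= 0.0:
                continue
            if np.random.random() < -math.expm1(-ktot * dt):
                ev = 0
                if np.random.random() < ka / ktot:
                    status[i] = 0
                    tension[i] = 0.0
                    ev = EV_RUPTURE
                elif status[i] == 1:
                    status[i] = 2
                    ev = EV_ACTIVATE
                else:
                    status[i] = 1
                    ev = EV_DEACTIVATE
                ne = ev_n[0]
                if ne < ev_t.shape[0]:
                    ev_t[ne] = t
                    ev_fim[ne] = i
                    ev_type[ne] = ev
                ev_n[0] = ne + 1

        # --- binding attempts for unbound tips in range ---
        if pb[PB_KON] > 0.0:
            p_on = -math.expm1(-pb[PB_KON] * dt)
            for i in range(n):
                if status[i] != 0 or allow_bind[i] == 0:
                    continue
                tip_z = c[2] + (a_nm + L_nat[i]) * u_w[i, 2]
                if abs(tip_z) > pb[PB_CAPTURE]:
                    continue
                if np.random.random() < p_on:
                    status[i] = 1
                    attach[i, 0] = c[0] + (a_nm + L_nat[i]) * u_w[i, 0]
                    attach[i, 1] = c[1] + (a_nm + L_nat[i]) * u_w[i, 1]
                    attach[i, 2] = 0.0
                    tension[i] = 1.0   # warm start; recomputed below
                    ne = ev_n[0]
                    if ne < ev_t.shape[0]:
                        ev_t[ne] = t
                        ev_fim[ne] = i
                        ev_type[ne] = EV_BIND
                    ev_n[0] = ne + 1

        # --- semi-implicit pose update with displacement-limited
        #     sub-cycling (keeps the linearization valid through ruptures
        #     and protocol switches) ---
        remaining = dt
        for _sub in range(64):
            n_bound = _bond_geometry(c, Rm, u_body, L_nat, attach, status,
                                     nA, nB, nC, pm, a_nm, tension, kstiff,
                                     nhat, dist, u_w, True)
            h = c[2]
            if h < a_nm + 0.5:
                h = a_nm + 0.5
            s = a_nm / h
            dtm = remaining
            for _try in range(8):
                for r in range(6):
                    bb[r] = 0.0
                    for cc in range(6):
                        A[r, cc] = 0.0
                fstar = 1.0 + (_FSTAR_CONTACT - 1.0) * s ** 3
                tstar = 1.0 - (1.0 - _TSTAR_CONTACT) * s ** 3
                bb[0] += fshear_coef * a_nm * h * gdot * fstar
                bb[4] += tshear_coef * a_nm ** 3 * gdot * tstar
                for i in range(n):
                    if status[i] == 0 or dist[i] < 1e-9:
                        continue
                    T = tension[i]
                    rx = a_nm * u_w[i, 0]
                    ry = a_nm * u_w[i, 1]
                    rz = a_nm * u_w[i, 2]
                    fx = T * nhat[i, 0]
                    fy = T * nhat[i, 1]
                    fz = T * nhat[i, 2]
                    bb[0] += fx
                    bb[1] += fy
                    bb[2] += fz
                    bb[3] += ry * fz - rz * fy
                    bb[4] += rz * fx - rx * fz
                    bb[5] += rx * fy - ry * fx
                    kg = (T / dist[i]) if T > 0.0 else 0.0
                    ki = kstiff[i]
                    for p_ in range(3):
                        for q_ in range(3):
                            Mv = (ki - kg) * nhat[i, p_] * nhat[i, q_]
                            if p_ == q_:
                                Mv += kg
                            M3[p_, q_] = Mv
                            A[p_, q_] += Mv
                    Rx[0, 1] = -rz
                    Rx[0, 2] = ry
                    Rx[1, 0] = rz
                    Rx[1, 2] = -rx
                    Rx[2, 0] = -ry
                    Rx[2, 1] = rx
                    for p_ in range(3):
                        for w_ in range(3):
                            acc1 = 0.0
                            acc2 = 0.0
                            for q_ in range(3):
                                acc1 += M3[p_, q_] * Rx[q_, w_]
                                acc2 += Rx[w_, q_] * M3[q_, p_]
                            A[p_, 3 + w_] += -acc1
                            A[3 + w_, p_] += acc2
                    for p_ in range(3):
                        for q_ in range(3):
                            acc = 0.0
                            for w1 in range(3):
                                for w2 in range(3):
                                    acc += Rx[p_, w1] * M3[w1, w2] * Rx[w2, q_]
                            A[3 + p_, 3 + q_] += -acc
                # unbound fimbriae whose rigid rod reaches the wall act
                # as compressible legs: an axial spring capped at the
                # buckling force, pushing up at the contact point.  The
                # lever arm of the contact gives the rolling resistance of
                # the fimbrial bed the cell rests on.
                for i in range(n):
                    if status[i] != 0:
                        continue
                    uz = u_w[i, 2]
                    if uz >= -1e-6:
                        continue
                    az = c[2] + a_nm * uz
                    if az <= 0.0:
                        az = 1e-3
                    s_wall = -az / uz
                    if s_wall >= L_nat[i]:
                        continue
                    delta = L_nat[i] - s_wall
                    k_leg = pm[PM_KCOIL] / n_sub[i]
                    Fz = k_leg * delta
                    if Fz > pm[PM_FBUCK]:
                        Fz = pm[PM_FBUCK]
                    rx = (a_nm + s_wall) * u_w[i, 0]
                    ry = (a_nm + s_wall) * u_w[i, 1]
                    rz = -c[2]
                    bb[2] += Fz
                    bb[3] += ry * Fz
                    bb[4] += -rx * Fz
                    keff = k_leg / (-uz)
                    Rx[0, 1] = -rz
                    Rx[0, 2] = ry
                    Rx[1, 0] = rz
                    Rx[1, 2] = -rx
                    Rx[2, 0] = -ry
                    Rx[2, 1] = rx
                    A[2, 2] += keff
                    for w_ in range(3):
                        A[2, 3 + w_] += -keff * Rx[2, w_]
                        A[3 + w_, 2] += Rx[w_, 2] * keff
                    for p_ in range(3):
                        for q_ in range(3):
                            A[3 + p_, 3 + q_] += -Rx[p_, 2] * keff * Rx[2, q_]

                gap = c[2] - a_nm
                if gap < gap_rest:
                    bb[2] += k_wall * (gap_rest - gap)
                    A[2, 2] += k_wall
                fpar = 1.0 / (1.0 - 0.5625 * s + 0.125 * s ** 3
                              - 0.17578125 * s ** 4 - 0.0625 * s ** 5)
                eps = (h - a_nm) / a_nm
                if eps < 1e-4:
                    eps = 1e-4
                fperp = 1.0 + 1.0 / eps
                frot = 1.0 / (1.0 - 0.3125 * s ** 3)
                ct = ct_coef * a_nm
                cr = cr_coef * a_nm ** 3
                A[0, 0] += ct * fpar / dtm
                A[1, 1] += ct * fpar / dtm
                A[2, 2] += ct * fperp / dtm
                A[3, 3] += cr * frot / dtm
                A[4, 4] += cr * frot / dtm
                A[5, 5] += cr * frot / dtm
                # with A = R/dtm + K the solution of A x = b is the pose
                # DISPLACEMENT over dtm (backward Euler on the linearized
                # elastic force)
                _solve6(A, bb, v)
                if n_bound == 0:
                    break   # free motion: no stiffness, no need to sub-cycle
                vt = math.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
                wr = math.sqrt(v[3] ** 2 + v[4] ** 2 + v[5] ** 2) * a_nm
                disp = vt if vt > wr else wr
                if disp <= 1.5 * _DISP_MAX:
                    break
                if not math.isfinite(disp):
                    t_arr[0] = t
                    return -1
                if _try == 7:
                    # stiff limit: cap the hop, consume proportional time
                    sc = _DISP_MAX / disp
                    for d in range(6):
                        v[d] *= sc
                    dtm *= sc
                    break
                dtm = dtm * _DISP_MAX / disp
                if dtm > remaining:
                    dtm = remaining
                if dtm < 1e-12:
                    dtm = 1e-12
            # advance pose by the solved displacement
            for d in range(3):
                c[d] += v[d]
                rotacc[d] += v[3 + d]
            wx = v[3]
            wy = v[4]
            wz = v[5]
            ang = math.sqrt(wx * wx + wy * wy + wz * wz)
            if ang > 1e-14:
                ux, uy, uz = wx / ang, wy / ang, wz / ang
                ca = math.cos(ang)
                sa = math.sin(ang)
                one = 1.0 - ca
                R00 = ca + ux * ux * one
                R01 = ux * uy * one - uz * sa
                R02 = ux * uz * one + uy * sa
                R10 = uy * ux * one + uz * sa
                R11 = ca + uy * uy * one
                R12 = uy * uz * one - ux * sa
                R20 = uz * ux * one - uy * sa
                R21 = uz * uy * one + ux * sa
                R22 = ca + uz * uz * one
                for cc in range(3):
                    m0 = Rm[0, cc]
                    m1 = Rm[1, cc]
                    m2 = Rm[2, cc]
                    Rm[0, cc] = R00 * m0 + R01 * m1 + R02 * m2
                    Rm[1, cc] = R10 * m0 + R11 * m1 + R12 * m2
                    Rm[2, cc] = R20 * m0 + R21 * m1 + R22 * m2
            remaining -= dtm
            misc[3] += 1.0
            if remaining <= 1e-15:
                break

        misc[2] += 1.0
        if int(misc[2]) % 256 == 0:
            nrm = math.sqrt(Rm[0, 0] ** 2 + Rm[1, 0] ** 2 + Rm[2, 0] ** 2)
            for d in range(3):
                Rm[d, 0] /= nrm
            dot = Rm[0, 0] * Rm[0, 1] + Rm[1, 0] * Rm[1, 1] + Rm[2, 0] * Rm[2, 1]
            for d in range(3):
                Rm[d, 1] -= dot * Rm[d, 0]
            nrm = math.sqrt(Rm[0, 1] ** 2 + Rm[1, 1] ** 2 + Rm[2, 1] ** 2)
            for d in range(3):
                Rm[d, 1] /= nrm
            Rm[0, 2] = Rm[1, 0] * Rm[2, 1] - Rm[2, 0] * Rm[1, 1]
            Rm[1, 2] = Rm[2, 0] * Rm[0, 1] - Rm[0, 0] * Rm[2, 1]
            Rm[2, 2] = Rm[0, 0] * Rm[1, 1] - Rm[1, 0] * Rm[0, 1]

        if not (math.isfinite(c[0]) and math.isfinite(c[1])
                and math.isfinite(c[2])):
            t_arr[0] = t
            return -1

        nb2 = 0
        for i in range(n):
            if status[i] != 0:
                nb2 += 1
        if nb2 == 0:
            misc[0] += dt
            if misc[0] >= grace:
                misc[1] = t + dt - misc[0]   # when the last bond was lost
                t_arr[0] = t
                return 1
        else:
            misc[0] = 0.0

        t += dt

    t_arr[0] = t
    return 0
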