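"""Numba kernels for the Langevin/Berendsen integrator.

These are the hot loops.  Neighbors are kept in a two-level Verlet buffer:
an outer "super" list with a generous skin is rebuilt by an O(N^2) scan only
when beads have drifted far, and the inner force list is refreshed cheaply
by filtering the super list.  Both refreshes follow the standard Verlet
criterion (rebuild when any bead moved more than half the respective skin
since the last build, with a small safety margin for barostat rescaling).
The integrator is the BAOAB splitting of the Langevin equation with one
force evaluation per step; Berendsen pressure coupling isotropically
rescales box and coordinates each step.

Everything operates on plain arrays so whole stages run inside compiled
code; the Python-facing wrappers live in :mod:`flexgel.engine`.

Status codes returned by ``run_stage_kernel`` (OR-able bit flags):
0 = ok, 1 = stability failure (per-step displacement exceeded skin/2),
2 = bead overlap, 4 = neighbor-list capacity overflow.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_STABILITY = 1
STATUS_OVERLAP = 2
STATUS_PAIR_OVERFLOW = 4

#: extra buffer (sigma) of the outer list beyond cutoff + skin
SUPER_SKIN = 1.8


# ---------------------------------------------------------------------------
# thermal noise: counter-style splitmix64 + 128-layer ziggurat
#
# Exact standard-normal sampling with explicit uint64 state, no allocation
# and no library call inside the integrator.  Tables follow the classic
# 128-layer construction (tail cut at r = 3.442619855899, layer area
# v = 9.91256303526217e-3), scaled for 31-bit integer magnitudes.
# ---------------------------------------------------------------------------

def _make_ziggurat_tables():
    import math

    m1 = 2147483648.0
    dn = tn = 3.442619855899
    vn = 9.91256303526217e-3
    kn = np.zeros(128, dtype=np.int64)
    wn = np.zeros(128)
    fn = np.zeros(128)
    q = vn / math.exp(-0.5 * dn * dn)
    kn[0] = int((dn / q) * m1)
    kn[1] = 0
    wn[0] = q / m1
    wn[127] = dn / m1
    fn[0] = 1.0
    fn[127] = math.exp(-0.5 * dn * dn)
    for i in range(126, 0, -1):
        dn = math.sqrt(-2.0 * math.log(vn / dn + math.exp(-0.5 * dn * dn)))
        kn[i + 1] = int((dn / tn) * m1)
        tn = dn
        fn[i] = math.exp(-0.5 * dn * dn)
        wn[i] = dn / m1
    return kn, wn, fn


ZIG_KN, ZIG_WN, ZIG_FN = _make_ziggurat_tables()
_ZIG_R = 3.442619855899
_SM64_GOLD = np.uint64(0x9E3779B97F4A7C15)
_U53 = 1.0 / 9007199254740992.0


@njit(cache=True)
def _sm64_next(state):
    """splitmix64: advance the counter and return (mixed value, new state)."""
    state = state + _SM64_GOLD
    z = state
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    return z, state


@njit(cache=True, fastmath=True)
def _zig_normal(state):
    """One standard-normal draw by the ziggurat method; returns (x, state)."""
    while True:
        z, state = _sm64_next(state)
        # signed 32-bit integer from the top bits
        hz = np.int64(np.int32(z >> np.uint64(32)))
        iz = hz & 127
        if hz < 0:
            ahz = -hz
        else:
            ahz = hz
        if ahz < ZIG_KN[iz]:
            return hz * ZIG_WN[iz], state
        # slow path: tail or wedge
        if iz == 0:
            while True:
                z, state = _sm64_next(state)
                u1 = (np.float64(z >> np.uint64(11)) + 0.5) * _U53
                z, state = _sm64_next(state)
                u2 = (np.float64(z >> np.uint64(11)) + 0.5) * _U53
                x = -np.log(u1) * 0.29047645161474317  # 1/r
                y = -np.log(u2)
                if y + y >= x * x:
                    if hz > 0:
                        return _ZIG_R + x, state
                    return -_ZIG_R - x, state
        x = hz * ZIG_WN[iz]
        z, state = _sm64_next(state)
        u = (np.float64(z >> np.uint64(11)) + 0.5) * _U53
        if ZIG_FN[iz] + u * (ZIG_FN[iz - 1] - ZIG_FN[iz]) < np.exp(-0.5 * x * x):
            return x, state
        # otherwise loop with a fresh integer


_OVERLAP_D2 = 1e-12


@njit(cache=True)
def _in_sorted(arr, key):
    lo = 0
    hi = arr.shape[0]
    while lo < hi:
        mid = (lo + hi) // 2
        v = arr[mid]
        if v == key:
            return True
        elif v < key:
            lo = mid + 1
        else:
            hi = mid
    return False


@njit(cache=True, fastmath=True)
def build_pairs(pos, L, rlist2, excl, pair_i, pair_j):
    """O(N^2) scan filling pair_i/pair_j with non-excluded pairs within
    sqrt(rlist2).  Returns the pair count, or -1 on capacity overflow."""
    n = pos.shape[0]
    half = 0.5 * L
    cap = pair_i.shape[0]
    cnt = 0
    for i in range(n - 1):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for j in range(i + 1, n):
            dx = xi - pos[j, 0]
            if dx > half:
                dx -= L
            elif dx < -half:
                dx += L
            dx2 = dx * dx
            if dx2 >= rlist2:
                continue
            dy = yi - pos[j, 1]
            if dy > half:
                dy -= L
            elif dy < -half:
                dy += L
            dz = zi - pos[j, 2]
            if dz > half:
                dz -= L
            elif dz < -half:
                dz += L
            if dx2 + dy * dy + dz * dz < rlist2:
                if not _in_sorted(excl, i * n + j):
                    if cnt >= cap:
                        return -1
                    pair_i[cnt] = i
                    pair_j[cnt] = j
                    cnt += 1
    return cnt


@njit(cache=True, fastmath=True)
def _filter_pairs(pos, L, rlist2, src_i, src_j, n_src, dst_i, dst_j):
    """Refresh the fine list from the super list; -1 on overflow."""
    half = 0.5 * L
    cap = dst_i.shape[0]
    cnt = 0
    for k in range(n_src):
        i = src_i[k]
        j = src_j[k]
        dx = pos[i, 0] - pos[j, 0]
        if dx > half:
            dx -= L
        elif dx < -half:
            dx += L
        dy = pos[i, 1] - pos[j, 1]
        if dy > half:
            dy -= L
        elif dy < -half:
            dy += L
        dz = pos[i, 2] - pos[j, 2]
        if dz > half:
            dz -= L
        elif dz < -half:
            dz += L
        if dx * dx + dy * dy + dz * dz < rlist2:
            if cnt >= cap:
                return -1
            dst_i[cnt] = i
            dst_j[cnt] = j
            cnt += 1
    return cnt


@njit(cache=True, fastmath=True)
def compute_forces_kernel(pos, L, pair_i, pair_j, n_pairs, bonded, angles,
                          K_bond, r0, K_theta, cos0, flexible,
                          eps, sigma2, dcut2, rep_shift, F):
    """Accumulate forces into F; return (status, epot, e_angle, virial)."""
    n = pos.shape[0]
    half = 0.5 * L
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
    epot = 0.0
    e_angle = 0.0
    virial = 0.0

    # repulsive pairs
    for k in range(n_pairs):
        i = pair_i[k]
        j = pair_j[k]
        dx = pos[i, 0] - pos[j, 0]
        if dx > half:
            dx -= L
        elif dx < -half:
            dx += L
        dy = pos[i, 1] - pos[j, 1]
        if dy > half:
            dy -= L
        elif dy < -half:
            dy += L
        dz = pos[i, 2] - pos[j, 2]
        if dz > half:
            dz -= L
        elif dz < -half:
            dz += L
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < dcut2:
            if r2 < _OVERLAP_D2:
                return STATUS_OVERLAP, 0.0, 0.0, 0.0
            inv2 = sigma2 / r2
            inv6 = inv2 * inv2 * inv2
            inv12 = inv6 * inv6
            epot += 4.0 * eps * inv12 + rep_shift
            fod = 48.0 * eps * inv12 / r2
            F[i, 0] += fod * dx
            F[i, 1] += fod * dy
            F[i, 2] += fod * dz
            F[j, 0] -= fod * dx
            F[j, 1] -= fod * dy
            F[j, 2] -= fod * dz
            virial += fod * r2

    # bonds and crosslinks (harmonic, rest length r0)
    for k in range(bonded.shape[0]):
        i = bonded[k, 0]
        j = bonded[k, 1]
        dx = pos[i, 0] - pos[j, 0]
        if dx > half:
            dx -= L
        elif dx < -half:
            dx += L
        dy = pos[i, 1] - pos[j, 1]
        if dy > half:
            dy -= L
        elif dy < -half:
            dy += L
        dz = pos[i, 2] - pos[j, 2]
        if dz > half:
            dz -= L
        elif dz < -half:
            dz += L
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < _OVERLAP_D2:
            return STATUS_OVERLAP, 0.0, 0.0, 0.0
        d = np.sqrt(r2)
        x = d - r0
        epot += 0.5 * K_bond * x * x
        fod = -K_bond * x / d
        F[i, 0] += fod * dx
        F[i, 1] += fod * dy
        F[i, 2] += fod * dz
        F[j, 0] -= fod * dx
        F[j, 1] -= fod * dy
        F[j, 2] -= fod * dz
        virial += fod * r2

    # bending triads
    if (not flexible) and K_theta > 0.0:
        for k in range(angles.shape[0]):
            ia = angles[k, 0]
            jv = angles[k, 1]
            ka = angles[k, 2]
            ax = pos[ia, 0] - pos[jv, 0]
            if ax > half:
                ax -= L
            elif ax < -half:
                ax += L
            ay = pos[ia, 1] - pos[jv, 1]
            if ay > half:
                ay -= L
            elif ay < -half:
                ay += L
            az = pos[ia, 2] - pos[jv, 2]
            if az > half:
                az -= L
            elif az < -half:
                az += L
            bx = pos[ka, 0] - pos[jv, 0]
            if bx > half:
                bx -= L
            elif bx < -half:
                bx += L
            by = pos[ka, 1] - pos[jv, 1]
            if by > half:
                by -= L
            elif by < -half:
                by += L
            bz = pos[ka, 2] - pos[jv, 2]
            if bz > half:
                bz -= L
            elif bz < -half:
                bz += L
            la2 = ax * ax + ay * ay + az * az
            lb2 = bx * bx + by * by + bz * bz
            la = np.sqrt(la2)
            lb = np.sqrt(lb2)
            inv_lalb = 1.0 / (la * lb)
            c = (ax * bx + ay * by + az * bz) * inv_lalb
            if c > 1.0:
                c = 1.0
            elif c < -1.0:
                c = -1.0
            dc = c - cos0
            e_angle += 0.5 * K_theta * dc * dc
            dVdc = K_theta * dc
            gax = bx * inv_lalb - c * ax / la2
            gay = by * inv_lalb - c * ay / la2
            gaz = bz * inv_lalb - c * az / la2
            gbx = ax * inv_lalb - c * bx / lb2
            gby = ay * inv_lalb - c * by / lb2
            gbz = az * inv_lalb - c * bz / lb2
            fix = -dVdc * gax
            fiy = -dVdc * gay
            fiz = -dVdc * gaz
            fkx = -dVdc * gbx
            fky = -dVdc * gby
            fkz = -dVdc * gbz
            F[ia, 0] += fix
            F[ia, 1] += fiy
            F[ia, 2] += fiz
            F[ka, 0] += fkx
            F[ka, 1] += fky
            F[ka, 2] += fkz
            F[jv, 0] -= fix + fkx
            F[jv, 1] -= fiy + fky
            F[jv, 2] -= fiz + fkz
            virial += fix * ax + fiy * ay + fiz * az
            virial += fkx * bx + fky * by + fkz * bz
    epot += e_angle
    return STATUS_OK, epot, e_angle, virial


# ---------------------------------------------------------------------------
# stage driver
#
# The per-step work lives in separately compiled helpers that the driver
# receives as *function-valued arguments*, and the driver's loop body is a
# straight line of four opaque calls with no branches: error conditions are
# returned as OR-able status bits and accumulated.  Both properties matter:
# when the whole step is inlined into one function, or when early exits are
# interleaved with the calls, the JIT's code quality for the hot loop
# collapses by ~4x.  After a failure the stage keeps stepping (cheaply, on
# garbage data) and the caller discards the result based on the status.
# Mutable state crosses helper boundaries through two small arrays:
#   fstate: [L, cum_f, cum_s, epot, e_angle, virial, L0, max_step2,
#            max_f2, max_s2]
#   istate: [n_super, n_pairs, n_rec, n_snap, n_clamped]
# ---------------------------------------------------------------------------

FS_L = 0
FS_CUMF = 1
FS_CUMS = 2
FS_EPOT = 3
FS_EANG = 4
FS_VIRIAL = 5
FS_L0 = 6
FS_MAXSTEP2 = 7
FS_MAXF2 = 8
FS_MAXS2 = 9

IS_NSUPER = 0
IS_NPAIRS = 1
IS_NREC = 2
IS_NSNAP = 3
IS_NCLAMP = 4


@njit(cache=True, fastmath=True)
def _integrate_step(pos, vel, F, acc, acc_s, fstate, rng_state,
                    half_dt, half_dt_over_m, c1, c2, trig_f2):
    """One fused B(h/2) A(h/2) O(h) A(h/2) sweep over all beads.

    Thermal noise comes from the inline splitmix64/ziggurat sampler; the
    advanced state is returned.  Stores the squared maxima of the per-step
    displacement and of the displacements accumulated since the last
    fine/super list builds into fstate; returns STATUS_STABILITY if a single
    step moved a bead farther than the neighbor-list trigger.
    """
    n = pos.shape[0]
    L = fstate[FS_L]
    max_step2 = 0.0
    max_f2 = 0.0
    max_s2 = 0.0
    for i in range(n):
        d2 = 0.0
        f2 = 0.0
        s2 = 0.0
        for d in range(3):
            v = vel[i, d] + half_dt_over_m * F[i, d]
            dx1 = half_dt * v
            g, rng_state = _zig_normal(rng_state)
            v = c1 * v + c2 * g
            vel[i, d] = v
            dd = dx1 + half_dt * v
            x = pos[i, d] + dd
            if x >= L or x < 0.0:
                x -= L * np.floor(x / L)
            pos[i, d] = x
            d2 += dd * dd
            a = acc[i, d] + dd
            acc[i, d] = a
            f2 += a * a
            a = acc_s[i, d] + dd
            acc_s[i, d] = a
            s2 += a * a
        if d2 > max_step2:
            max_step2 = d2
        if f2 > max_f2:
            max_f2 = f2
        if s2 > max_s2:
            max_s2 = s2
    fstate[FS_MAXSTEP2] = max_step2
    fstate[FS_MAXF2] = max_f2
    fstate[FS_MAXS2] = max_s2
    if max_step2 > trig_f2:
        return STATUS_STABILITY, rng_state
    return STATUS_OK, rng_state


@njit(cache=True, fastmath=True)
def _scale_positions(pos, s):
    n = pos.shape[0]
    for i in range(n):
        pos[i, 0] *= s
        pos[i, 1] *= s
        pos[i, 2] *= s


@njit(cache=True, fastmath=True)
def _kick(vel, F, half_dt_over_m):
    n = vel.shape[0]
    for i in range(n):
        vel[i, 0] += half_dt_over_m * F[i, 0]
        vel[i, 1] += half_dt_over_m * F[i, 1]
        vel[i, 2] += half_dt_over_m * F[i, 2]


@njit(cache=True, fastmath=True)
def _maintain_lists(pos, excl, super_i, super_j, pair_i, pair_j,
                    acc, acc_s, fstate, istate,
                    trig_f2, trig_s2, rlist_f, rlist_s,
                    schedule_on, target_edge, schedule_steps, step):
    """Box-schedule interpolation and two-level neighbor-list refresh."""
    n = pos.shape[0]
    L = fstate[FS_L]
    if schedule_on and step <= schedule_steps:
        if step == schedule_steps:
            L_new = target_edge
        else:
            L0 = fstate[FS_L0]
            L_new = L0 + (target_edge - L0) * step / schedule_steps
        scale = L_new / L
        _scale_positions(pos, scale)
        L = L_new
        fstate[FS_L] = L
        fstate[FS_CUMF] *= scale
        fstate[FS_CUMS] *= scale

    cum_f = fstate[FS_CUMF]
    cum_s = fstate[FS_CUMS]
    refresh_super = (fstate[FS_MAXS2] > trig_s2
                     or cum_s > 1.01 or cum_s < 0.99)
    refresh_fine = refresh_super or (
        fstate[FS_MAXF2] > trig_f2 or cum_f > 1.01 or cum_f < 0.99
    )
    if refresh_super:
        n_super = build_pairs(pos, L, rlist_s * rlist_s, excl,
                              super_i, super_j)
        if n_super < 0:
            return STATUS_PAIR_OVERFLOW
        istate[IS_NSUPER] = n_super
        for i in range(n):
            acc_s[i, 0] = 0.0
            acc_s[i, 1] = 0.0
            acc_s[i, 2] = 0.0
        fstate[FS_CUMS] = 1.0
    if refresh_fine:
        n_pairs = _filter_pairs(pos, L, rlist_f * rlist_f, super_i, super_j,
                                istate[IS_NSUPER], pair_i, pair_j)
        if n_pairs < 0:
            return STATUS_PAIR_OVERFLOW
        istate[IS_NPAIRS] = n_pairs
        for i in range(n):
            acc[i, 0] = 0.0
            acc[i, 1] = 0.0
            acc[i, 2] = 0.0
        fstate[FS_CUMF] = 1.0
    return STATUS_OK


@njit(cache=True, fastmath=True)
def _forces_and_kick(pos, vel, F, pair_i, pair_j, bonded, angles,
                     fstate, istate,
                     K_bond, r0, K_theta, cos0, flexible,
                     eps, sigma2, dcut2, rep_shift, half_dt_over_m):
    """Force evaluation at the new positions plus the trailing half-kick."""
    st, epot, eang, virial = compute_forces_kernel(
        pos, fstate[FS_L], pair_i, pair_j, istate[IS_NPAIRS], bonded, angles,
        K_bond, r0, K_theta, cos0, flexible, eps, sigma2, dcut2,
        rep_shift, F)
    if st != STATUS_OK:
        return st
    fstate[FS_EPOT] = epot
    fstate[FS_EANG] = eang
    fstate[FS_VIRIAL] = virial
    _kick(vel, F, half_dt_over_m)
    return STATUS_OK


@njit(cache=True, fastmath=True)
def _post_step(pos, vel, fstate, istate,
               rec_step, rec_vol, rec_pres, rec_epot, rec_eang,
               snaps_pos, snaps_vel, snaps_L,
               kBT, barostat_on, p_target, tau_p, kappa, dt,
               mu_min, mu_max, record_every, snap_every, step):
    """Berendsen weak coupling followed by trace/snapshot bookkeeping."""
    n = pos.shape[0]
    L = fstate[FS_L]
    vol = L * L * L
    pres = (n * kBT + fstate[FS_VIRIAL] / 3.0) / vol
    if barostat_on:
        mu3 = 1.0 - kappa * (dt / tau_p) * (p_target - pres)
        if mu3 <= 0.0:
            mu = mu_min
            istate[IS_NCLAMP] += 1
        else:
            mu = mu3 ** (1.0 / 3.0)
            if mu < mu_min:
                mu = mu_min
                istate[IS_NCLAMP] += 1
            elif mu > mu_max:
                mu = mu_max
                istate[IS_NCLAMP] += 1
        if mu != 1.0:
            _scale_positions(pos, mu)
            L *= mu
            fstate[FS_L] = L
            fstate[FS_CUMF] *= mu
            fstate[FS_CUMS] *= mu
            vol = L * L * L
    if step % record_every == 0:
        k = istate[IS_NREC]
        rec_step[k] = step
        rec_vol[k] = vol
        rec_pres[k] = pres
        rec_epot[k] = fstate[FS_EPOT]
        rec_eang[k] = fstate[FS_EANG]
        istate[IS_NREC] = k + 1
    if snap_every > 0 and step % snap_every == 0:
        k = istate[IS_NSNAP]
        for i in range(n):
            for d in range(3):
                snaps_pos[k, i, d] = pos[i, d]
                snaps_vel[k, i, d] = vel[i, d]
        snaps_L[k] = L
        istate[IS_NSNAP] = k + 1
    return STATUS_OK


@njit(cache=True, fastmath=True)
def _init_stage(pos, excl, super_i, super_j, pair_i, pair_j,
                bonded, angles, F, fstate, istate,
                rec_step, rec_vol, rec_pres, rec_epot, rec_eang,
                rlist_f, rlist_s, K_bond, r0, K_theta, cos0, flexible,
                eps, sigma2, dcut2, rep_shift, kBT):
    """Initial list builds, force evaluation and the step-0 trace entry."""
    n = pos.shape[0]
    L = fstate[FS_L]
    n_super = build_pairs(pos, L, rlist_s * rlist_s, excl, super_i, super_j)
    if n_super < 0:
        return STATUS_PAIR_OVERFLOW
    istate[IS_NSUPER] = n_super
    n_pairs = _filter_pairs(pos, L, rlist_f * rlist_f, super_i, super_j,
                            n_super, pair_i, pair_j)
    if n_pairs < 0:
        return STATUS_PAIR_OVERFLOW
    istate[IS_NPAIRS] = n_pairs
    st, epot, eang, virial = compute_forces_kernel(
        pos, L, pair_i, pair_j, n_pairs, bonded, angles,
        K_bond, r0, K_theta, cos0, flexible, eps, sigma2, dcut2,
        rep_shift, F)
    if st != STATUS_OK:
        return st
    fstate[FS_EPOT] = epot
    fstate[FS_EANG] = eang
    fstate[FS_VIRIAL] = virial
    rec_step[0] = 0
    rec_vol[0] = L * L * L
    rec_pres[0] = (n * kBT + virial / 3.0) / (L * L * L)
    rec_epot[0] = epot
    rec_eang[0] = eang
    istate[IS_NREC] = 1
    return STATUS_OK


# no cache=True here: the function-typed arguments cannot be serialized
# into numba's on-disk cache index
@njit(fastmath=True)
def run_stage_kernel(fn_integrate, fn_init, fn_maintain,
                     fn_forces_kick, fn_post,
                     pos, vel, L, bonded, angles, excl,
                     n_steps, dt, gamma, m, kBT,
                     K_bond, r0, K_theta, cos0, flexible,
                     eps, sigma, d_cutoff, rep_shift, skin,
                     barostat_on, p_target, tau_p, kappa, mu_min, mu_max,
                     schedule_on, target_edge, schedule_steps,
                     record_every, snap_every, seed,
                     rec_step, rec_vol, rec_pres, rec_epot, rec_eang,
                     snaps_pos, snaps_vel, snaps_L,
                     pair_i, pair_j, super_i, super_j):
    """Advance n_steps of BAOAB Langevin dynamics; see module docstring."""
    # scramble the seed through the splitmix finalizer so nearby seeds start
    # at far-apart points of the counter sequence (the raw counter would give
    # merely shifted noise streams for adjacent seeds)
    z = np.uint64(seed) * _SM64_GOLD + _SM64_GOLD
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    rng_state = z ^ (z >> np.uint64(31))
    n = pos.shape[0]
    half_dt = 0.5 * dt
    half_dt_over_m = 0.5 * dt / m
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kBT / m * (1.0 - c1 * c1))
    rlist_f = d_cutoff + skin
    rlist_s = rlist_f + SUPER_SKIN
    # triggers carry a margin for the <=1% affine drift allowed between builds
    trig_f = 0.5 * skin - 0.011 * rlist_f
    if trig_f < 0.25 * skin:
        trig_f = 0.25 * skin
    trig_s = 0.5 * SUPER_SKIN - 0.011 * rlist_s
    trig_f2 = trig_f * trig_f
    trig_s2 = trig_s * trig_s
    sigma2 = sigma * sigma
    dcut2 = d_cutoff * d_cutoff

    acc = np.zeros((n, 3))        # displacement since last fine build
    acc_s = np.zeros((n, 3))      # displacement since last super build
    F = np.zeros((n, 3))
    fstate = np.zeros(10)
    fstate[FS_L] = L
    fstate[FS_CUMF] = 1.0
    fstate[FS_CUMS] = 1.0
    fstate[FS_L0] = L
    istate = np.zeros(5, dtype=np.int64)

    status = fn_init(pos, excl, super_i, super_j, pair_i, pair_j,
                     bonded, angles, F, fstate, istate,
                     rec_step, rec_vol, rec_pres, rec_epot, rec_eang,
                     rlist_f, rlist_s, K_bond, r0, K_theta, cos0, flexible,
                     eps, sigma2, dcut2, rep_shift, kBT)

    n_run = n_steps * (1 - min(status, 1))
    for step in range(1, n_run + 1):
        st, rng_state = fn_integrate(pos, vel, F, acc, acc_s, fstate,
                                     rng_state, half_dt, half_dt_over_m,
                                     c1, c2, trig_f2)
        st |= fn_maintain(pos, excl, super_i, super_j, pair_i, pair_j,
                          acc, acc_s, fstate, istate,
                          trig_f2, trig_s2, rlist_f, rlist_s,
                          schedule_on, target_edge, schedule_steps, step)
        st |= fn_forces_kick(pos, vel, F, pair_i, pair_j, bonded, angles,
                             fstate, istate,
                             K_bond, r0, K_theta, cos0, flexible,
                             eps, sigma2, dcut2, rep_shift, half_dt_over_m)
        st |= fn_post(pos, vel, fstate, istate,
                      rec_step, rec_vol, rec_pres, rec_epot, rec_eang,
                      snaps_pos, snaps_vel, snaps_L,
                      kBT, barostat_on, p_target, tau_p, kappa, dt,
                      mu_min, mu_max, record_every, snap_every, step)
        status |= st

    return (status, fstate[FS_L], istate[IS_NREC],
            istate[IS_NSNAP], istate[IS_NCLAMP])


#: helper bundle passed to run_stage_kernel as opaque function values
STEP_FUNCS = (_integrate_step, _init_stage, _maintain_lists,
              _forces_and_kick, _post_step)
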