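"""Numba-compiled core of the Monte Carlo dynamics.

The elementary-move physics lives here exactly once, inside three substep
functions that each run a batch of attempts of one move type:

* ``substep_separation`` -- shifts of the local membrane separation,
* ``substep_protein``    -- single-protein hops to nearest-neighbour patches,
* ``substep_pair``       -- hops of apposing partner pairs.

Called with ``forced=False`` they draw proposals from numba's internal RNG
(the fast trajectory path, one call per substep); with ``forced=True`` and
``n_attempts=1`` they evaluate one externally supplied proposal (the
Python-level move API, driven by a ``numpy.random.Generator``). Both paths
execute the identical physics code. The outcome of a forced attempt is
reported through the ``out_i``/``out_f`` scratch arrays.

State layout (all arrays owned by the Python wrapper in ``engine``):

``l``            (nx, ny) float64   separation field in nm
``occ1``         (nx, ny) int8      membrane-1 occupancy (0 empty, 1 TCR, 2 LFA-1)
``occ2``         (nx, ny) int8      membrane-2 occupancy (0 empty, 1 self-pMHC,
                                    2 foreign-pMHC, 3 ICAM-1)
``bond_start``   (nx, ny) int64     formation step of the bond at a patch, -1 if none
``nbond``        (3,)     int64     current bond count per complex kind
``pm, pi, pj``   (N,)               protein registry: membrane, row, col
``prot_at1/2``   (nx, ny) int32     patch -> protein-registry index, -1 if empty
``pairs_i/j``    (nx*ny,) int32     registry of apposing cognate pairs
``pair_at``      (nx, ny) int32     patch -> pair-registry index, -1 if none
``counts``       (1,)     int64     [number of apposing pairs M]

Complex kinds: 0 = TCR/self-pMHC, 1 = TCR/foreign-pMHC, 2 = LFA-1/ICAM-1.
Dwell times are recorded on the fly for bonds that form and rupture inside
the measurement window [dlo, dhi].
"""

from __future__ import annotations

import numpy as np
from numba import njit

# species codes, membrane 1
M1_EMPTY, M1_TCR, M1_LFA = 0, 1, 2
# species codes, membrane 2
M2_EMPTY, M2_SMHC, M2_FMHC, M2_ICAM = 0, 1, 2, 3

# complex kinds
KIND_TCR_SELF, KIND_TCR_FOREIGN, KIND_LFA_ICAM = 0, 1, 2

# move status codes
ST_REJECT_STRUCT = 0  # target occupied / separation would go negative
ST_REJECT_METRO = 1
ST_ACCEPT = 2
ST_EXCLUDED = 3  # bound protein would hop directly into a new complex

# bond-event codes
EV_NONE = 0
EV_FORMED = 1
EV_BROKEN = 2
EV_MOVED = 3  # bond persisted through a pair move

# stats layout: [sep att, sep acc, -, prot att, prot acc, prot excl, pair att, pair acc, -]
# out_i layout: [status, event, kind, i, j, ni, nj]; out_f: [dE]


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def pair_kind(s1, s2):
    """Complex kind formed by apposed species s1 (membrane 1) / s2 (membrane 2), -1 if none."""
    if s1 == M1_TCR:
        if s2 == M2_SMHC:
            return KIND_TCR_SELF
        if s2 == M2_FMHC:
            return KIND_TCR_FOREIGN
    elif s1 == M1_LFA and s2 == M2_ICAM:
        return KIND_LFA_ICAM
    return -1


@njit(cache=True, inline="always")
def in_window(lv, kind, rest, halfw):
    """Whether separation lv lies in the closed binding window of the given kind."""
    return rest[kind] - halfw[kind] <= lv <= rest[kind] + halfw[kind]


@njit(cache=True, inline="always")
def laplacian(l, i, j):
    """Discretized Laplacian l_i1+l_i2+l_i3+l_i4-4*l_i with periodic neighbours."""
    nx, ny = l.shape
    ip = i + 1 if i + 1 < nx else 0
    im = i - 1 if i > 0 else nx - 1
    jp = j + 1 if j + 1 < ny else 0
    jm = j - 1 if j > 0 else ny - 1
    return l[ip, j] + l[im, j] + l[i, jp] + l[i, jm] - 4.0 * l[i, j]


@njit(cache=True)
def bending_energy(l, kappa, a):
    """Total discretized bending energy (kappa/2a^2) * sum of squared Laplacians, in kBT."""
    nx, ny = l.shape
    s = 0.0
    for i in range(nx):
        for j in range(ny):
            d = laplacian(l, i, j)
            s += d * d
    return kappa / (2.0 * a * a) * s


@njit(cache=True, inline="always")
def delta_bending(l, i, j, dl, kappa, a):
    """Exact change of the total bending energy for shifting l[i,j] by dl.

    Only the Laplacians of the patch and its four neighbours change: the
    centre Laplacian by -4*dl and each neighbour Laplacian by +dl, so

        dE = (kappa/2a^2) * (20*dl^2 - 8*dl*Lap_c + 2*dl*S)

    where Lap_c is the centre Laplacian and S the sum of the four neighbour
    Laplacians -- a 13-patch read footprint.
    """
    nx, ny = l.shape
    ip = i + 1 if i + 1 < nx else 0
    im = i - 1 if i > 0 else nx - 1
    jp = j + 1 if j + 1 < ny else 0
    jm = j - 1 if j > 0 else ny - 1
    ip2 = ip + 1 if ip + 1 < nx else 0
    im2 = im - 1 if im > 0 else nx - 1
    jp2 = jp + 1 if jp + 1 < ny else 0
    jm2 = jm - 1 if jm > 0 else ny - 1
    lc = l[i, j]
    n4 = l[ip, j] + l[im, j] + l[i, jp] + l[i, jm]
    lap_c = n4 - 4.0 * lc
    diag = l[ip, jp] + l[ip, jm] + l[im, jp] + l[im, jm]
    far = l[ip2, j] + l[im2, j] + l[i, jp2] + l[i, jm2]
    lap_sum = far + 4.0 * lc + 2.0 * diag - 4.0 * n4
    return kappa / (2.0 * a * a) * (20.0 * dl * dl - 8.0 * dl * lap_c + 2.0 * dl * lap_sum)


@njit(cache=True, inline="always")
def _metropolis(dE, u):
    if dE <= 0.0:
        return True
    return u < np.exp(-dE)


@njit(cache=True, inline="always")
def _form_bond(bond_start, nbond, bind_counts, i, j, kind, step, dlo, dhi):
    bond_start[i, j] = step
    nbond[kind] += 1
    if dlo <= step <= dhi:
        bind_counts[kind] += 1


@njit(cache=True, inline="always")
def _break_bond(
    bond_start, nbond, unbind_counts, dwell_kind, dwell_time, dwell_form, dwell_meta,
    i, j, kind, step, dlo, dhi,
):
    born = bond_start[i, j]
    bond_start[i, j] = -1
    nbond[kind] -= 1
    if dlo <= step <= dhi:
        unbind_counts[kind] += 1
        # a dwell time is recorded only if the bond also formed inside the
        # measurement window (bonds older than the window are left-censored)
        if born >= dlo:
            n = dwell_meta[0]
            if n < dwell_time.shape[0]:
                dwell_kind[n] = kind
                dwell_time[n] = step - born
                dwell_form[n] = born
                dwell_meta[0] = n + 1
            else:
                dwell_meta[1] = 1  # overflow flag; runner prevents this by chunking


@njit(cache=True, inline="always")
def _update_pair_registry(occ1, occ2, pairs_i, pairs_j, pair_at, counts, i, j):
    """Reconcile the apposing-pair registry with the occupancy at patch (i, j)."""
    k = pair_kind(occ1[i, j], occ2[i, j])
    idx = pair_at[i, j]
    if k >= 0 and idx < 0:
        n = counts[0]
        pairs_i[n] = i
        pairs_j[n] = j
        pair_at[i, j] = n
        counts[0] = n + 1
    elif k < 0 and idx >= 0:
        n = counts[0] - 1
        if idx != n:
            li = pairs_i[n]
            lj = pairs_j[n]
            pairs_i[idx] = li
            pairs_j[idx] = lj
            pair_at[li, lj] = idx
        pair_at[i, j] = -1
        counts[0] = n


@njit(cache=True)
def substep_separation(
    l, occ1, occ2, bond_start, nbond, bind_counts, unbind_counts,
    dwell_kind, dwell_time, dwell_form, dwell_meta,
    n_attempts, forced, fi, fj, fdl, fu,
    step, kappa, a, w, rest, halfw, ub, dlo, dhi, stats, out_i, out_f,
):
    """Run ``n_attempts`` separation-shift attempts (move type 1).

    A patch pair is chosen uniformly and its separation shifted by
    dl ~ U(-w, w); dE combines the local bending change and any bond formed
    or broken at that patch. Proposals taking the separation negative are
    rejected outright (hard impenetrability of the membranes).
    """
    nx, ny = l.shape
    w2 = 2.0 * w
    for _ in range(n_attempts):
        if forced:
            i = fi
            j = fj
            dl = fdl
            u = fu
        else:
            site = np.random.randint(0, nx * ny)
            i = site // ny
            j = site - i * ny
            dl = (np.random.random() - 0.5) * w2
            u = np.random.random()
        stats[0] += 1
        status = ST_REJECT_STRUCT
        event = EV_NONE
        kind = -1
        dE = 0.0
        l1 = l[i, j] + dl
        if l1 >= 0.0:
            dE = delta_bending(l, i, j, dl, kappa, a)
            k = pair_kind(occ1[i, j], occ2[i, j])
            bound_before = False
            bound_after = False
            if k >= 0:
                bound_before = bond_start[i, j] >= 0
                bound_after = in_window(l1, k, rest, halfw)
                if bound_after and not bound_before:
                    dE -= ub[k]
                elif bound_before and not bound_after:
                    dE += ub[k]
            if not _metropolis(dE, u):
                status = ST_REJECT_METRO
            else:
                status = ST_ACCEPT
                stats[1] += 1
                l[i, j] = l1
                if k >= 0:
                    if bound_after and not bound_before:
                        _form_bond(bond_start, nbond, bind_counts, i, j, k, step, dlo, dhi)
                        event = EV_FORMED
                        kind = k
                    elif bound_before and not bound_after:
                        _break_bond(
                            bond_start, nbond, unbind_counts,
                            dwell_kind, dwell_time, dwell_form, dwell_meta,
                            i, j, k, step, dlo, dhi,
                        )
                        event = EV_BROKEN
                        kind = k
        if forced:
            out_i[0] = status
            out_i[1] = event
            out_i[2] = kind
            out_i[3] = i
            out_i[4] = j
            out_i[5] = i
            out_i[6] = j
            out_f[0] = dE


@njit(cache=True)
def substep_protein(
    l, occ1, occ2, bond_start, nbond, bind_counts, unbind_counts,
    dwell_kind, dwell_time, dwell_form, dwell_meta,
    pm, pi, pj, prot_at1, prot_at2,
    pairs_i, pairs_j, pair_at, counts,
    n_attempts, forced, fp, fd, fu,
    step, rest, halfw, ub, dlo, dhi, stats, out_i, out_f,
):
    """Run ``n_attempts`` single-protein hop attempts (move type 2).

    A protein and one of the four directions are chosen uniformly; the move
    is rejected if the target patch is occupied, and *excluded* (counted as
    a rejected attempt, not re-drawn) if a bound protein would directly hop
    into a new complex at the target.
    """
    nx, ny = l.shape
    n_prot = pm.shape[0]
    for _ in range(n_attempts):
        if forced:
            p = fp
            d = fd
            u = fu
        else:
            p = np.random.randint(0, n_prot)
            d = np.random.randint(0, 4)
            u = np.random.random()
        stats[3] += 1
        i = pi[p]
        j = pj[p]
        if d == 0:
            ni = i - 1 if i > 0 else nx - 1
            nj = j
        elif d == 1:
            ni = i + 1 if i + 1 < nx else 0
            nj = j
        elif d == 2:
            ni = i
            nj = j - 1 if j > 0 else ny - 1
        else:
            ni = i
            nj = j + 1 if j + 1 < ny else 0
        status = ST_REJECT_STRUCT
        event = EV_NONE
        kind = -1
        dE = 0.0
        mem = pm[p]
        target_free = (occ1[ni, nj] == M1_EMPTY) if mem == 1 else (occ2[ni, nj] == M2_EMPTY)
        if target_free:
            if mem == 1:
                species = occ1[i, j]
                k_dst = pair_kind(species, occ2[ni, nj])
            else:
                species = occ2[i, j]
                k_dst = pair_kind(occ1[ni, nj], species)
            bound_src = bond_start[i, j] >= 0
            k_src = pair_kind(occ1[i, j], occ2[i, j])
            would_bind = k_dst >= 0 and in_window(l[ni, nj], k_dst, rest, halfw)
            if bound_src and would_bind:
                status = ST_EXCLUDED
                stats[5] += 1
            else:
                if bound_src:
                    dE += ub[k_src]
                if would_bind:
                    dE -= ub[k_dst]
                if not _metropolis(dE, u):
                    status = ST_REJECT_METRO
                else:
                    status = ST_ACCEPT
                    stats[4] += 1
                    if bound_src:
                        _break_bond(
                            bond_start, nbond, unbind_counts,
                            dwell_kind, dwell_time, dwell_form, dwell_meta,
                            i, j, k_src, step, dlo, dhi,
                        )
                        event = EV_BROKEN
                        kind = k_src
                    if mem == 1:
                        occ1[i, j] = M1_EMPTY
                        occ1[ni, nj] = species
                        prot_at1[i, j] = -1
                        prot_at1[ni, nj] = p
                    else:
                        occ2[i, j] = M2_EMPTY
                        occ2[ni, nj] = species
                        prot_at2[i, j] = -1
                        prot_at2[ni, nj] = p
                    pi[p] = ni
                    pj[p] = nj
                    _update_pair_registry(occ1, occ2, pairs_i, pairs_j, pair_at, counts, i, j)
                    _update_pair_registry(occ1, occ2, pairs_i, pairs_j, pair_at, counts, ni, nj)
                    if would_bind:
                        _form_bond(bond_start, nbond, bind_counts, ni, nj, k_dst, step, dlo, dhi)
                        event = EV_FORMED
                        kind = k_dst
        if forced:
            out_i[0] = status
            out_i[1] = event
            out_i[2] = kind
            out_i[3] = i
            out_i[4] = j
            out_i[5] = ni
            out_i[6] = nj
            out_f[0] = dE


@njit(cache=True)
def substep_pair(
    l, occ1, occ2, bond_start, nbond, bind_counts, unbind_counts,
    dwell_kind, dwell_time, dwell_form, dwell_meta,
    pm, pi, pj, prot_at1, prot_at2,
    pairs_i, pairs_j, pair_at, counts,
    n_attempts, forced, fq, fd, fu,
    step, rest, halfw, ub, dlo, dhi, stats, out_i, out_f,
):
    """Run ``n_attempts`` pair-hop attempts (move type 3).

    An apposing cognate pair (bound or not) is chosen uniformly from the
    live registry; both target patches must be unoccupied. A bond whose
    source and target separations are both inside the window diffuses
    intact, keeping its formation step. The substep ends early if no pair
    is left.
    """
    nx, ny = l.shape
    for _ in range(n_attempts):
        if counts[0] == 0:
            break
        if forced:
            q = fq
            d = fd
            u = fu
        else:
            q = np.random.randint(0, counts[0])
            d = np.random.randint(0, 4)
            u = np.random.random()
        stats[6] += 1
        i = pairs_i[q]
        j = pairs_j[q]
        if d == 0:
            ni = i - 1 if i > 0 else nx - 1
            nj = j
        elif d == 1:
            ni = i + 1 if i + 1 < nx else 0
            nj = j
        elif d == 2:
            ni = i
            nj = j - 1 if j > 0 else ny - 1
        else:
            ni = i
            nj = j + 1 if j + 1 < ny else 0
        status = ST_REJECT_STRUCT
        event = EV_NONE
        kind = -1
        dE = 0.0
        if occ1[ni, nj] == M1_EMPTY and occ2[ni, nj] == M2_EMPTY:
            k = pair_kind(occ1[i, j], occ2[i, j])
            bound_src = bond_start[i, j] >= 0
            bound_dst = in_window(l[ni, nj], k, rest, halfw)
            if bound_src and not bound_dst:
                dE += ub[k]
            elif bound_dst and not bound_src:
                dE -= ub[k]
            if not _metropolis(dE, u):
                status = ST_REJECT_METRO
            else:
                status = ST_ACCEPT
                stats[7] += 1
                if bound_src and bound_dst:
                    bond_start[ni, nj] = bond_start[i, j]
                    bond_start[i, j] = -1
                    event = EV_MOVED
                elif bound_src:
                    _break_bond(
                        bond_start, nbond, unbind_counts,
                        dwell_kind, dwell_time, dwell_form, dwell_meta,
                        i, j, k, step, dlo, dhi,
                    )
                    event = EV_BROKEN
                    kind = k
                s1 = occ1[i, j]
                s2 = occ2[i, j]
                p1 = prot_at1[i, j]
                p2 = prot_at2[i, j]
                occ1[i, j] = M1_EMPTY
                occ2[i, j] = M2_EMPTY
                occ1[ni, nj] = s1
                occ2[ni, nj] = s2
                prot_at1[i, j] = -1
                prot_at2[i, j] = -1
                prot_at1[ni, nj] = p1
                prot_at2[ni, nj] = p2
                pi[p1] = ni
                pj[p1] = nj
                pi[p2] = ni
                pj[p2] = nj
                _update_pair_registry(occ1, occ2, pairs_i, pairs_j, pair_at, counts, i, j)
                _update_pair_registry(occ1, occ2, pairs_i, pairs_j, pair_at, counts, ni, nj)
                if bound_dst and not bound_src:
                    _form_bond(bond_start, nbond, bind_counts, ni, nj, k, step, dlo, dhi)
                    event = EV_FORMED
                    kind = k
        if forced:
            out_i[0] = status
            out_i[1] = event
            out_i[2] = kind
            out_i[3] = i
            out_i[4] = j
            out_i[5] = ni
            out_i[6] = nj
            out_f[0] = dE


@njit(cache=True)
def run_steps(
    l, occ1, occ2, bond_start, nbond, bind_counts, unbind_counts,
    dwell_kind, dwell_time, dwell_form, dwell_meta,
    pm, pi, pj, prot_at1, prot_at2,
    pairs_i, pairs_j, pair_at, counts,
    kappa, a, w, contact_threshold, rest, halfw, ub,
    step0, n_steps, dlo, dhi,
    sample_interval,
    samp_step, samp_nb, samp_ncontact, samp_nwindow, samp_minl, samp_ebend, samp_meta,
    stats,
    stop_if_no_pairs,
    out_i, out_f,
):
    """Run up to ``n_steps`` Monte Carlo steps starting from step counter ``step0``.

    One step = nx*ny separation attempts, N protein-hop attempts (N = total
    proteins), and M pair-hop attempts with the attempt count M frozen at
    substep start. Returns the number of steps actually executed; the loop
    exits early when the dwell buffer is close to full (the caller harvests
    and resumes) or, if ``stop_if_no_pairs``, when no apposing partner pair
    is left.

    ``stats`` accumulates attempt/acceptance/exclusion counters (see layout
    at the top of this module).
    """
    nx, ny = l.shape
    n_prot = pm.shape[0]
    margin = nx * ny + 2 * n_prot + 8  # upper bound on dwell events per step
    tcr_lo = rest[0] - halfw[0]
    tcr_hi = rest[0] + halfw[0]
    for s in range(n_steps):
        if dwell_meta[0] + margin > dwell_time.shape[0]:
            return s
        step = step0 + s
        substep_separation(
            l, occ1, occ2, bond_start, nbond, bind_counts, unbind_counts,
            dwell_kind, dwell_time, dwell_form, dwell_meta,
            nx * ny, False, 0, 0, 0.0, 0.0,
            step, kappa, a, w, rest, halfw, ub, dlo, dhi, stats, out_i, out_f,
        )
        substep_protein(
            l, occ1, occ2, bond_start, nbond, bind_counts, unbind_counts,
            dwell_kind, dwell_time, dwell_form, dwell_meta,
            pm, pi, pj, prot_at1, prot_at2,
            pairs_i, pairs_j, pair_at, counts,
            n_prot, False, 0, 0, 0.0,
            step, rest, halfw, ub, dlo, dhi, stats, out_i, out_f,
        )
        m_frozen = counts[0]
        substep_pair(
            l, occ1, occ2, bond_start, nbond, bind_counts, unbind_counts,
            dwell_kind, dwell_time, dwell_form, dwell_meta,
            pm, pi, pj, prot_at1, prot_at2,
            pairs_i, pairs_j, pair_at, counts,
            m_frozen, False, 0, 0, 0.0,
            step, rest, halfw, ub, dlo, dhi, stats, out_i, out_f,
        )
        new_step = step + 1
        if sample_interval > 0 and new_step % sample_interval == 0:
            row = samp_meta[0]
            samp_step[row] = new_step
            samp_nb[row, 0] = nbond[0]
            samp_nb[row, 1] = nbond[1]
            samp_nb[row, 2] = nbond[2]
            ncontact = 0
            nwindow = 0
            minl = l[0, 0]
            for i in range(nx):
                for j in range(ny):
                    lv = l[i, j]
                    if lv < contact_threshold:
                        ncontact += 1
                    if tcr_lo <= lv <= tcr_hi:
                        nwindow += 1
                    if lv < minl:
                        minl = lv
            samp_ncontact[row] = ncontact
            samp_nwindow[row] = nwindow
            samp_minl[row] = minl
            samp_ebend[row] = bending_energy(l, kappa, a)
            samp_meta[0] = row + 1
        if stop_if_no_pairs and counts[0] == 0:
            return s + 1
    return n_steps
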