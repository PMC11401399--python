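"""Numba kernels for the hourly agent update.

Flat-array state layout shared with :class:`gridabm.dynamics.SimulationState`:
agents live in parallel arrays indexed by slot; ``occ[y, x]`` holds slot+1 or 0.
``meta`` (int64) carries counters:

    0 free-stack top, 1 deferred-free count,
    2 C_apoptosis, 3 C_effector, 4 C_Tx, 5 C_mitosis, 6 kill-location count,
    7 cancer-list length, 8 effector-list length.

``c_list``/``e_list`` hold the slots of live cancer and effector agents (the
two targetable classes) with O(1) swap-remove via ``slot_pos``; nearest-target
queries brute-force these lists when targets are sparse and fall back to an
expanding ring search over the occupancy grid when they are abundant.

Slots freed during a step go to ``dead_buf`` and are merged back into the free
stack only after hit resolution, so a daughter cell can never reuse the slot of
an agent that is still waiting its turn in the shuffled order.

All randomness uses numba's global np.random stream; seed via :func:`seed`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

EMPTY = 0
CANCER = 1
EFFECTOR = 2
REGULATORY = 3

NO_DEATH = 1.0e30


@njit(cache=True)
def seed(seed_value):
    np.random.seed(seed_value)


@njit(cache=True)
def _sample_cycle_length(mean, sd, lo, hi):
    # truncated normal by rejection; bounds are a few SD wide so this is cheap
    for _ in range(10000):
        v = mean + sd * np.random.standard_normal()
        if lo <= v <= hi:
            return v
    return mean


@njit(cache=True)
def _vacant_moore(occ, x, y, vx, vy):
    H, W = occ.shape
    n = 0
    for dy in range(-1, 2):
        ny = y + dy
        if ny < 0 or ny >= H:
            continue
        for dx in range(-1, 2):
            if dx == 0 and dy == 0:
                continue
            nx = x + dx
            if nx < 0 or nx >= W:
                continue
            if occ[ny, nx] == 0:
                vx[n] = nx
                vy[n] = ny
                n += 1
    return n


@njit(cache=True)
def _list_add(idx, tlist, slot_pos, meta, slot):
    tlist[meta[slot]] = idx
    slot_pos[idx] = meta[slot]
    meta[slot] += 1


@njit(cache=True)
def _list_remove(idx, tlist, slot_pos, meta, slot):
    j = slot_pos[idx]
    meta[slot] -= 1
    last = tlist[meta[slot]]
    tlist[j] = last
    slot_pos[last] = j


@njit(cache=True)
def _remove_agent(idx, kind, xs, ys, occ, dead_buf, meta, c_list, e_list, slot_pos):
    k = kind[idx]
    if k == CANCER:
        _list_remove(idx, c_list, slot_pos, meta, 7)
    elif k == EFFECTOR:
        _list_remove(idx, e_list, slot_pos, meta, 8)
    occ[ys[idx], xs[idx]] = 0
    kind[idx] = EMPTY
    dead_buf[meta[1]] = idx
    meta[1] += 1


@njit(cache=True)
def step_cancer(idx, kind, xs, ys, div_len, cyc_pos, doomed, death_h, quiesc,
                hits_del, hits_recv, occ, free_stack, dead_buf, meta,
                c_list, e_list, slot_pos, hour,
                p_a, p_m, cancer_submoves, div_mean, div_sd, div_lo, div_hi):
    # (1) delayed radiation death
    if doomed[idx] and hour >= death_h[idx]:
        _remove_agent(idx, kind, xs, ys, occ, dead_buf, meta, c_list, e_list, slot_pos)
        meta[4] += 1
        return
    # (2) spontaneous apoptosis; node freed immediately
    if np.random.random() < p_a:
        _remove_agent(idx, kind, xs, ys, occ, dead_buf, meta, c_list, e_list, slot_pos)
        meta[2] += 1
        return
    x = xs[idx]
    y = ys[idx]
    vx = np.empty(8, np.int64)
    vy = np.empty(8, np.int64)
    nv = _vacant_moore(occ, x, y, vx, vy)
    # (3) cycle progression requires free space; otherwise quiescent this step
    if nv > 0:
        cyc_pos[idx] += 1.0
        quiesc[idx] = False
    else:
        quiesc[idx] = True
    # (4) mitosis into a uniformly random vacant Moore node
    if (not doomed[idx]) and nv > 0 and cyc_pos[idx] >= div_len[idx]:
        j = np.random.randint(nv)
        meta[0] -= 1
        d = free_stack[meta[0]]
        kind[d] = CANCER
        xs[d] = vx[j]
        ys[d] = vy[j]
        occ[vy[j], vx[j]] = d + 1
        div_len[d] = _sample_cycle_length(div_mean, div_sd, div_lo, div_hi)
        cyc_pos[d] = 0.0
        doomed[d] = False
        death_h[d] = NO_DEATH
        quiesc[d] = False
        hits_del[d] = 0
        hits_recv[d] = 0
        _list_add(d, c_list, slot_pos, meta, 7)
        cyc_pos[idx] = 0.0
        meta[5] += 1
    # (5) random walk: one Bernoulli(p_m) draw gates the whole sub-move budget
    if np.random.random() < p_m:
        for _ in range(cancer_submoves):
            nv = _vacant_moore(occ, x, y, vx, vy)
            if nv == 0:
                break
            j = np.random.randint(nv)
            occ[y, x] = 0
            x = vx[j]
            y = vy[j]
            occ[y, x] = idx + 1
        xs[idx] = x
        ys[idx] = y


@njit(cache=True)
def _ring_min_d2(occ, kind, x, y, target_kind, k, r2, best):
    H, W = occ.shape
    for dx in range(-k, k + 1):
        nx = x + dx
        if nx < 0 or nx >= W:
            continue
        ny = y - k
        if ny >= 0:
            v = occ[ny, nx]
            if v > 0 and kind[v - 1] == target_kind:
                d2 = dx * dx + k * k
                if d2 <= r2 and d2 < best:
                    best = d2
        ny = y + k
        if ny < H:
            v = occ[ny, nx]
            if v > 0 and kind[v - 1] == target_kind:
                d2 = dx * dx + k * k
                if d2 <= r2 and d2 < best:
                    best = d2
    for dy in range(-k + 1, k):
        ny = y + dy
        if ny < 0 or ny >= H:
            continue
        nx = x - k
        if nx >= 0:
            v = occ[ny, nx]
            if v > 0 and kind[v - 1] == target_kind:
                d2 = k * k + dy * dy
                if d2 <= r2 and d2 < best:
                    best = d2
        nx = x + k
        if nx < W:
            v = occ[ny, nx]
            if v > 0 and kind[v - 1] == target_kind:
                d2 = k * k + dy * dy
                if d2 <= r2 and d2 < best:
                    best = d2
    return best


@njit(cache=True)
def _pick_nearest_target(occ, kind, x, y, target_kind, r):
    """Uniform pick among the tied nearest targets within Euclid radius r.

    Expanding Chebyshev ring search; a ring at distance k cannot contain a
    node closer than k, so the scan stops once k*k exceeds the best distance.
    Returns (found, qx, qy).
    """
    H, W = occ.shape
    r2 = r * r
    best = np.int64(1) << np.int64(62)
    kmax = int(r) + 1
    span = W if W > H else H
    if kmax > span:
        kmax = span
    k = 1
    while k <= kmax and k * k <= best:
        best = _ring_min_d2(occ, kind, x, y, target_kind, k, r2, best)
        k += 1
    if best > r2 or best >= (np.int64(1) << np.int64(62)):
        return False, 0, 0
    kb = int(np.sqrt(float(best))) + 1
    cnt = 0
    for dy in range(-kb, kb + 1):
        ny = y + dy
        if ny < 0 or ny >= H:
            continue
        for dx in range(-kb, kb + 1):
            nx = x + dx
            if nx < 0 or nx >= W:
                continue
            v = occ[ny, nx]
            if v > 0 and kind[v - 1] == target_kind and dx * dx + dy * dy == best:
                cnt += 1
    pick = np.random.randint(cnt)
    i = 0
    for dy in range(-kb, kb + 1):
        ny = y + dy
        if ny < 0 or ny >= H:
            continue
        for dx in range(-kb, kb + 1):
            nx = x + dx
            if nx < 0 or nx >= W:
                continue
            v = occ[ny, nx]
            if v > 0 and kind[v - 1] == target_kind and dx * dx + dy * dy == best:
                if i == pick:
                    return True, nx, ny
                i += 1
    return False, 0, 0


@njit(cache=True)
def _pick_nearest_from_list(xs, ys, x, y, r, tlist, n_t):
    """Uniform pick among tied nearest targets, brute-forced over the
    target-class slot list (exact; preferred when targets are sparse)."""
    r2 = r * r
    best = np.int64(1) << np.int64(62)
    for ii in range(n_t):
        t = tlist[ii]
        dx = xs[t] - x
        dy = ys[t] - y
        d2 = dx * dx + dy * dy
        if d2 <= r2 and d2 < best:
            best = d2
    if best >= (np.int64(1) << np.int64(62)):
        return False, 0, 0
    cnt = 0
    for ii in range(n_t):
        t = tlist[ii]
        dx = xs[t] - x
        dy = ys[t] - y
        if dx * dx + dy * dy == best:
            cnt += 1
    pick = np.random.randint(cnt)
    i = 0
    for ii in range(n_t):
        t = tlist[ii]
        dx = xs[t] - x
        dy = ys[t] - y
        if dx * dx + dy * dy == best:
            if i == pick:
                return True, xs[t], ys[t]
            i += 1
    return False, 0, 0


SPARSE_TARGET_LIMIT = 256


@njit(cache=True)
def _nearest_target(occ, kind, xs, ys, x, y, target_kind, r, tlist, n_t):
    if n_t == 0:
        return False, 0, 0
    if n_t <= SPARSE_TARGET_LIMIT:
        return _pick_nearest_from_list(xs, ys, x, y, r, tlist, n_t)
    return _pick_nearest_target(occ, kind, x, y, target_kind, r)


@njit(cache=True)
def step_immune(idx, kind, xs, ys, div_len, cyc_pos, doomed, death_h, quiesc,
                hits_del, hits_recv, occ, free_stack, dead_buf, meta,
                c_list, e_list, slot_pos, hour,
                eta_directed, search_radius, immune_submoves):
    # delayed radiation removal (no ledger count: C_* track cancer deaths)
    if death_h[idx] <= hour:
        _remove_agent(idx, kind, xs, ys, occ, dead_buf, meta, c_list, e_list, slot_pos)
        return
    if kind[idx] == EFFECTOR:
        target_kind = CANCER
        tlist = c_list
        t_slot = 7
    else:
        target_kind = EFFECTOR
        tlist = e_list
        t_slot = 8
    x = xs[idx]
    y = ys[idx]
    vx = np.empty(8, np.int64)
    vy = np.empty(8, np.int64)
    cosv = np.empty(8, np.float64)
    for _ in range(immune_submoves):
        found, qx, qy = _nearest_target(occ, kind, xs, ys, x, y, target_kind,
                                        search_radius, tlist, meta[t_slot])
        nv = _vacant_moore(occ, x, y, vx, vy)
        if nv == 0:
            continue
        if not found:
            j = np.random.randint(nv)
        else:
            dx = float(qx - x)
            dy = float(qy - y)
            nrm = np.sqrt(dx * dx + dy * dy)
            ux = dx / nrm
            uy = dy / nrm
            ang = np.random.random() * 2.0 * np.pi
            wx = (1.0 - eta_directed) * np.cos(ang) + eta_directed * ux
            wy = (1.0 - eta_directed) * np.sin(ang) + eta_directed * uy
            best = -2.0
            for i in range(nv):
                ddx = float(vx[i] - x)
                ddy = float(vy[i] - y)
                cosv[i] = (ddx * wx + ddy * wy) / np.sqrt(ddx * ddx + ddy * ddy)
                if cosv[i] > best:
                    best = cosv[i]
            nties = 0
            for i in range(nv):
                if cosv[i] == best:
                    nties += 1
            pick = np.random.randint(nties)
            j = 0
            t = 0
            for i in range(nv):
                if cosv[i] == best:
                    if t == pick:
                        j = i
                        break
                    t += 1
        occ[y, x] = 0
        x = vx[j]
        y = vy[j]
        occ[y, x] = idx + 1
    xs[idx] = x
    ys[idx] = y
    # after all sub-moves: at most one hit on a uniformly chosen Moore target
    H, W = occ.shape
    ntg = 0
    for dy in range(-1, 2):
        ny = y + dy
        if ny < 0 or ny >= H:
            continue
        for dx in range(-1, 2):
            if dx == 0 and dy == 0:
                continue
            nx = x + dx
            if nx < 0 or nx >= W:
                continue
            v = occ[ny, nx]
            if v > 0 and kind[v - 1] == target_kind:
                vx[ntg] = v - 1
                ntg += 1
    if ntg > 0:
        tgt = vx[np.random.randint(ntg)]
        hits_recv[tgt] += 1
        hits_del[idx] += 1
        if hits_del[idx] >= 10:
            _remove_agent(idx, kind, xs, ys, occ, dead_buf, meta, c_list, e_list, slot_pos)


@njit(cache=True)
def resolve_hits(kind, xs, ys, hits_recv, occ, dead_buf, meta, kill_x, kill_y,
                 c_list, e_list, slot_pos):
    """Three same-step hits kill; fewer repair fully. Cancer kills are ledgered
    with their location for post-code recruit placement."""
    cap = kind.shape[0]
    for i in range(cap):
        k = kind[i]
        if k == CANCER and hits_recv[i] >= 3:
            kill_x[meta[6]] = xs[i]
            kill_y[meta[6]] = ys[i]
            meta[6] += 1
            meta[3] += 1
            _remove_agent(i, kind, xs, ys, occ, dead_buf, meta, c_list, e_list, slot_pos)
        elif k == EFFECTOR and hits_recv[i] >= 3:
            _remove_agent(i, kind, xs, ys, occ, dead_buf, meta, c_list, e_list, slot_pos)
        hits_recv[i] = 0


@njit(cache=True)
def merge_freed(free_stack, dead_buf, meta):
    for t in range(meta[1]):
        free_stack[meta[0]] = dead_buf[t]
        meta[0] += 1
    meta[1] = 0


@njit(cache=True)
def step_all(kind, xs, ys, div_len, cyc_pos, doomed, death_h, quiesc,
             hits_del, hits_recv, occ, free_stack, dead_buf, meta,
             c_list, e_list, slot_pos, kill_x, kill_y, hour,
             p_a, p_m, cancer_submoves, div_mean, div_sd, div_lo, div_hi,
             eta_directed, search_radius, immune_submoves):
    """One shuffled pass over all live agents, then hit resolution."""
    cap = kind.shape[0]
    order = np.empty(cap, np.int64)
    n = 0
    for i in range(cap):
        if kind[i] != EMPTY:
            order[n] = i
            n += 1
    for i in range(n - 1, 0, -1):
        j = np.random.randint(i + 1)
        t = order[i]
        order[i] = order[j]
        order[j] = t
    for s in range(n):
        i = order[s]
        if kind[i] == EMPTY:  # self-removed earlier this step
            continue
        if kind[i] == CANCER:
            step_cancer(i, kind, xs, ys, div_len, cyc_pos, doomed, death_h,
                        quiesc, hits_del, hits_recv, occ, free_stack, dead_buf,
                        meta, c_list, e_list, slot_pos, hour, p_a, p_m,
                        cancer_submoves, div_mean, div_sd, div_lo, div_hi)
        else:
            step_immune(i, kind, xs, ys, div_len, cyc_pos, doomed, death_h,
                        quiesc, hits_del, hits_recv, occ, free_stack, dead_buf,
                        meta, c_list, e_list, slot_pos, hour, eta_directed,
                        search_radius, immune_submoves)
    resolve_hits(kind, xs, ys, hits_recv, occ, dead_buf, meta, kill_x, kill_y,
                 c_list, e_list, slot_pos)
    merge_freed(free_stack, dead_buf, meta)
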