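"""Numba event loops for the lattice stochastic simulator.

Two statistically exact samplers of the same jump process:

``direct_engine``
    Textbook direct-method SSA.  Every diffusive hop is an explicit event;
    per-rule pairwise propensity totals are recomputed whenever a position or
    species changes.  Efficient when hops are rare relative to the pairwise
    proposal bound (slow diffusion, small worlds) and required for
    trajectory-level position output.

``uniformized_engine``
    Exploits the fact that free hopping is autonomous: each molecule's
    position is advanced lazily by sampling the free-propagator displacement
    (difference of two Poisson counts per axis) only when the molecule is
    observed.  Pairwise reactions fire as candidate events at the constant
    per-rule bound ``n_a * n_b * max_rate`` and are accepted by thinning with
    the true kernel rate at the candidate time.  Reflecting boundaries are
    realized by cell-centered image folding of the free walk, which
    reproduces exactly the suppressed-outward-hop convention (the preimages
    of an edge voxel are ``0`` and ``-1`` modulo ``2n``, so the folded walk
    at the edge stays put with probability 1/2 — identical, by Poisson
    thinning, to removing the outward channel).

Both engines share the state layout: ``species[i]`` (-1 = removed),
``pos[i, ax]`` voxel coordinates, per-species member lists for O(1) species
lookup, and piecewise-constant count accumulators for exact time averages.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes
OK = 0
STALLED = 1
REACTED = 2


@njit(cache=True, inline="always")
def _fold(x, n, periodic):
    if periodic:
        return x % n
    m = x % (2 * n)
    if m < n:
        return m
    return 2 * n - 1 - m


@njit(cache=True, inline="always")
def _axis_offset(a, b, n, periodic):
    d = a - b
    if d < 0:
        d = -d
    if periodic and d > n - d:
        d = n - d
    return d


@njit(cache=True, inline="always")
def _pair_rate(kind, amp, eps_vox2, table, pi, pj, dim, n, periodic):
    """Rate for a molecule pair at voxel positions pi, pj (folded coords)."""
    if kind == 1:  # indicator at voxel-center distance
        d2 = 0.0
        for ax in range(dim):
            d = _axis_offset(pi[ax], pj[ax], n, periodic)
            d2 += d * d
        if d2 <= eps_vox2:
            return amp
        return 0.0
    rate = amp
    for ax in range(dim):
        rate *= table[_axis_offset(pi[ax], pj[ax], n, periodic)]
        if rate == 0.0:
            return 0.0
    return rate


@njit(cache=True)
def _remove_member(members, mcount, slot, sp, mol):
    s = slot[mol]
    last = mcount[sp] - 1
    moved = members[sp, last]
    members[sp, s] = moved
    slot[moved] = s
    mcount[sp] = last


@njit(cache=True)
def _add_member(members, mcount, slot, sp, mol):
    members[sp, mcount[sp]] = mol
    slot[mol] = mcount[sp]
    mcount[sp] += 1


@njit(cache=True)
def _rule_total(k, species, pos, members, mcount, pair_ra, pair_rb, pair_kind,
                pair_amp, pair_eps2, tables, dim, n, periodic):
    ra = pair_ra[k]
    rb = pair_rb[k]
    tot = 0.0
    for ii in range(mcount[ra]):
        i = members[ra, ii]
        for jj in range(mcount[rb]):
            j = members[rb, jj]
            tot += _pair_rate(pair_kind[k], pair_amp[k], pair_eps2[k], tables[k],
                              pos[i], pos[j], dim, n, periodic)
    return tot


@njit(cache=True)
def _molecule_rule_sum(k, pos_m, partner_sp, pos, members, mcount,
                       pair_kind, pair_amp, pair_eps2, tables, dim, n, periodic):
    """Sum of rule-k rates over all pairs of a molecule at pos_m with partners."""
    tot = 0.0
    for jj in range(mcount[partner_sp]):
        j = members[partner_sp, jj]
        tot += _pair_rate(pair_kind[k], pair_amp[k], pair_eps2[k], tables[k],
                          pos_m, pos[j], dim, n, periodic)
    return tot


@njit(cache=True)
def direct_engine(
    seed,
    dim, n, periodic,
    hop_dir,                       # per-species hop rate per direction
    species, pos,                  # mutated in place
    uni_r, uni_p, uni_rate,
    pair_ra, pair_rb, pair_pa, pair_pb, pair_kind, pair_amp, pair_eps2, tables,
    t_end, sample_times, avg_start,
    stop_on_pair, record_pos,
    counts_out, pos_out, occ_int, uni_events, pair_events,
):
    np.random.seed(seed)
    nmol = species.shape[0]
    nspecies = hop_dir.shape[0]
    nuni = uni_r.shape[0]
    npair = pair_ra.shape[0]
    nsamp = sample_times.shape[0]

    members = np.empty((nspecies, nmol), np.int64)
    mcount = np.zeros(nspecies, np.int64)
    slot = np.empty(nmol, np.int64)
    for i in range(nmol):
        if species[i] >= 0:
            _add_member(members, mcount, slot, species[i], i)

    pair_tot = np.empty(npair, np.float64)
    for k in range(npair):
        pair_tot[k] = _rule_total(k, species, pos, members, mcount, pair_ra, pair_rb,
                                  pair_kind, pair_amp, pair_eps2, tables, dim, n, periodic)

    t = 0.0
    isamp = 0
    status = OK
    reaction_time = -1.0
    two_dim = 2 * dim
    hops_since_resync = 0

    while True:
        total_hop = 0.0
        for s in range(nspecies):
            total_hop += mcount[s] * two_dim * hop_dir[s]
        total_uni = 0.0
        for k in range(nuni):
            total_uni += mcount[uni_r[k]] * uni_rate[k]
        total_pair = 0.0
        for k in range(npair):
            total_pair += pair_tot[k]
        total = total_hop + total_uni + total_pair

        if total <= 0.0:
            t_next = t_end
            stalled = t < t_end
        else:
            t_next = t + (-np.log(np.random.random())) / total
            stalled = False

        # record sample crossings and accumulate window integrals with the
        # pre-event (piecewise-constant) state
        t_stop = t_next if t_next < t_end else t_end
        while isamp < nsamp and sample_times[isamp] <= t_stop:
            for s in range(nspecies):
                counts_out[isamp, s] = mcount[s]
            if record_pos:
                for i in range(nmol):
                    for ax in range(dim):
                        pos_out[isamp, i, ax] = pos[i, ax]
            isamp += 1
        lo = t if t > avg_start else avg_start
        hi = t_stop
        if hi > lo:
            for s in range(nspecies):
                occ_int[s] += mcount[s] * (hi - lo)

        if stalled:
            status = STALLED
            t = t_end
            break
        if t_next >= t_end:
            t = t_end
            break
        t = t_next

        u = np.random.random() * total
        if u < total_hop:
            # hop: pick species block, then molecule, then direction
            for s in range(nspecies):
                block = mcount[s] * two_dim * hop_dir[s]
                if u < block:
                    idx = np.int64(u / (two_dim * hop_dir[s]))
                    if idx >= mcount[s]:
                        idx = mcount[s] - 1
                    m = members[s, idx]
                    d = np.random.randint(0, two_dim)
                    ax = d >> 1
                    step = (d & 1) * 2 - 1
                    v = pos[m, ax] + step
                    if periodic:
                        if v < 0:
                            v += n
                        elif v >= n:
                            v -= n
                    else:
                        if not 0 <= v < n:
                            break  # null event at reflecting wall
                    sp = species[m]
                    # incremental update: remove old-position contributions,
                    # move, add new-position contributions
                    for k in range(npair):
                        partner = -1
                        if pair_ra[k] == sp:
                            partner = pair_rb[k]
                        elif pair_rb[k] == sp:
                            partner = pair_ra[k]
                        if partner >= 0:
                            pair_tot[k] -= _molecule_rule_sum(
                                k, pos[m], partner, pos, members, mcount,
                                pair_kind, pair_amp, pair_eps2, tables, dim, n, periodic)
                    pos[m, ax] = v
                    for k in range(npair):
                        partner = -1
                        if pair_ra[k] == sp:
                            partner = pair_rb[k]
                        elif pair_rb[k] == sp:
                            partner = pair_ra[k]
                        if partner >= 0:
                            delta = _molecule_rule_sum(
                                k, pos[m], partner, pos, members, mcount,
                                pair_kind, pair_amp, pair_eps2, tables, dim, n, periodic)
                            pair_tot[k] += delta
                            if pair_tot[k] < 0.0:
                                pair_tot[k] = 0.0
                    hops_since_resync += 1
                    if hops_since_resync >= 65536:
                        # guard against floating-point drift of the running sums
                        hops_since_resync = 0
                        for k in range(npair):
                            pair_tot[k] = _rule_total(k, species, pos, members, mcount,
                                                      pair_ra, pair_rb, pair_kind, pair_amp,
                                                      pair_eps2, tables, dim, n, periodic)
                    break
                u -= block
            continue
        u -= total_hop

        if u < total_uni:
            for k in range(nuni):
                block = mcount[uni_r[k]] * uni_rate[k]
                if u < block:
                    m = members[uni_r[k], np.random.randint(0, mcount[uni_r[k]])]
                    old = species[m]
                    _remove_member(members, mcount, slot, old, m)
                    newsp = uni_p[k]
                    if newsp >= 0:
                        species[m] = newsp
                        _add_member(members, mcount, slot, newsp, m)
                    else:
                        species[m] = -1
                    uni_events[k] += 1
                    for kk in range(npair):
                        if (pair_ra[kk] == old or pair_rb[kk] == old
                                or pair_ra[kk] == newsp or pair_rb[kk] == newsp):
                            pair_tot[kk] = _rule_total(kk, species, pos, members, mcount,
                                                       pair_ra, pair_rb, pair_kind, pair_amp,
                                                       pair_eps2, tables, dim, n, periodic)
                    break
                u -= block
            continue
        u -= total_uni

        for k in range(npair):
            if u < pair_tot[k] or k == npair - 1:
                ra = pair_ra[k]
                rb = pair_rb[k]
                # select the pair proportionally to its rate
                acc = 0.0
                mi = -1
                mj = -1
                target = u if u < pair_tot[k] else pair_tot[k] * 0.9999999
                done = False
                for ii in range(mcount[ra]):
                    i = members[ra, ii]
                    for jj in range(mcount[rb]):
                        j = members[rb, jj]
                        acc += _pair_rate(pair_kind[k], pair_amp[k], pair_eps2[k], tables[k],
                                          pos[i], pos[j], dim, n, periodic)
                        if acc > target:
                            mi = i
                            mj = j
                            done = True
                            break
                    if done:
                        break
                if mi < 0:
                    break
                touched0 = species[mi]
                touched1 = species[mj]
                _remove_member(members, mcount, slot, touched0, mi)
                _remove_member(members, mcount, slot, touched1, mj)
                pa = pair_pa[k]
                pb = pair_pb[k]
                if pa >= 0:
                    species[mi] = pa
                    _add_member(members, mcount, slot, pa, mi)
                else:
                    species[mi] = -1
                if pb >= 0:
                    species[mj] = pb
                    _add_member(members, mcount, slot, pb, mj)
                else:
                    species[mj] = -1
                pair_events[k] += 1
                for kk in range(npair):
                    pair_tot[kk] = _rule_total(kk, species, pos, members, mcount,
                                               pair_ra, pair_rb, pair_kind, pair_amp,
                                               pair_eps2, tables, dim, n, periodic)
                if stop_on_pair:
                    status = REACTED
                    reaction_time = t
                break
            u -= pair_tot[k]
        if status == REACTED:
            break

    return t, status, reaction_time


@njit(cache=True, inline="always")
def _advance(m, t_now, upos, tlast, species, hop_dir, dim):
    """Lazily advance molecule m's free walk to t_now (unwrapped coords)."""
    sp = species[m]
    if sp >= 0:
        mu = hop_dir[sp] * (t_now - tlast[m])
        if mu > 0.0:
            for ax in range(dim):
                upos[m, ax] += np.random.poisson(mu) - np.random.poisson(mu)
    tlast[m] = t_now


@njit(cache=True)
def uniformized_engine(
    seed,
    dim, n, periodic,
    hop_dir,
    species, pos,
    uni_r, uni_p, uni_rate,
    pair_ra, pair_rb, pair_pa, pair_pb, pair_kind, pair_amp, pair_eps2, tables,
    pair_rmax,
    t_end, sample_times, avg_start,
    stop_on_pair, record_pos,
    counts_out, pos_out, occ_int, uni_events, pair_events,
):
    np.random.seed(seed)
    nmol = species.shape[0]
    nspecies = hop_dir.shape[0]
    nuni = uni_r.shape[0]
    npair = pair_ra.shape[0]
    nsamp = sample_times.shape[0]

    members = np.empty((nspecies, nmol), np.int64)
    mcount = np.zeros(nspecies, np.int64)
    slot = np.empty(nmol, np.int64)
    for i in range(nmol):
        if species[i] >= 0:
            _add_member(members, mcount, slot, species[i], i)

    # unwrapped coordinates; folded on observation
    upos = pos.copy()
    tlast = np.zeros(nmol, np.float64)
    pi = np.empty(dim, np.int64)
    pj = np.empty(dim, np.int64)

    t = 0.0
    isamp = 0
    status = OK
    reaction_time = -1.0

    while True:
        total_uni = 0.0
        for k in range(nuni):
            total_uni += mcount[uni_r[k]] * uni_rate[k]
        total_bound = 0.0
        for k in range(npair):
            total_bound += mcount[pair_ra[k]] * mcount[pair_rb[k]] * pair_rmax[k]
        total = total_uni + total_bound

        if total <= 0.0:
            t_next = t_end
            stalled = False  # nothing left to react; diffusion continues freely
        else:
            t_next = t + (-np.log(np.random.random())) / total
            stalled = False

        t_stop = t_next if t_next < t_end else t_end
        while isamp < nsamp and sample_times[isamp] <= t_stop:
            ts = sample_times[isamp]
            for s in range(nspecies):
                counts_out[isamp, s] = mcount[s]
            if record_pos:
                for i in range(nmol):
                    _advance(i, ts, upos, tlast, species, hop_dir, dim)
                    for ax in range(dim):
                        pos_out[isamp, i, ax] = _fold(upos[i, ax], n, periodic)
            isamp += 1
        lo = t if t > avg_start else avg_start
        if t_stop > lo:
            for s in range(nspecies):
                occ_int[s] += mcount[s] * (t_stop - lo)

        if t_next >= t_end:
            t = t_end
            break
        t = t_next

        u = np.random.random() * total
        if u < total_uni:
            for k in range(nuni):
                block = mcount[uni_r[k]] * uni_rate[k]
                if u < block:
                    m = members[uni_r[k], np.random.randint(0, mcount[uni_r[k]])]
                    _advance(m, t, upos, tlast, species, hop_dir, dim)
                    old = species[m]
                    _remove_member(members, mcount, slot, old, m)
                    if uni_p[k] >= 0:
                        species[m] = uni_p[k]
                        _add_member(members, mcount, slot, uni_p[k], m)
                    else:
                        species[m] = -1
                    uni_events[k] += 1
                    break
                u -= block
            continue
        u -= total_uni

        for k in range(npair):
            block = mcount[pair_ra[k]] * mcount[pair_rb[k]] * pair_rmax[k]
            if u < block or k == npair - 1:
                if mcount[pair_ra[k]] == 0 or mcount[pair_rb[k]] == 0:
                    break
                mi = members[pair_ra[k], np.random.randint(0, mcount[pair_ra[k]])]
                mj = members[pair_rb[k], np.random.randint(0, mcount[pair_rb[k]])]
                _advance(mi, t, upos, tlast, species, hop_dir, dim)
                _advance(mj, t, upos, tlast, species, hop_dir, dim)
                for ax in range(dim):
                    pi[ax] = _fold(upos[mi, ax], n, periodic)
                    pj[ax] = _fold(upos[mj, ax], n, periodic)
                rate = _pair_rate(pair_kind[k], pair_amp[k], pair_eps2[k], tables[k],
                                  pi, pj, dim, n, periodic)
                if np.random.random() * pair_rmax[k] < rate:
                    a_old = species[mi]
                    b_old = species[mj]
                    _remove_member(members, mcount, slot, a_old, mi)
                    _remove_member(members, mcount, slot, b_old, mj)
                    if pair_pa[k] >= 0:
                        species[mi] = pair_pa[k]
                        _add_member(members, mcount, slot, pair_pa[k], mi)
                    else:
                        species[mi] = -1
                    if pair_pb[k] >= 0:
                        species[mj] = pair_pb[k]
                        _add_member(members, mcount, slot, pair_pb[k], mj)
                    else:
                        species[mj] = -1
                    pair_events[k] += 1
                    if stop_on_pair:
                        status = REACTED
                        reaction_time = t
                break
            u -= block
        if status == REACTED:
            break

    # materialize final folded positions
    for i in range(nmol):
        _advance(i, t, upos, tlast, species, hop_dir, dim)
        for ax in range(dim):
            pos[i, ax] = _fold(upos[i, ax], n, periodic)
    return t, status, reaction_time
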