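"""Hudson-style coalescent-with-recombination simulator (numba hot path).

A compact ms-style structured-coalescent engine used by the rejection-ABC
loops, where millions of small two-population simulations make per-call
overhead the binding cost.  It implements the same model as
:mod:`milletpop.coalescent` (which delegates to msprime and serves as the
reference engine): two populations, piecewise-constant sizes with the
founder-bottleneck epoch, a mass merge at the split time, symmetric-rate
island migration while both populations exist, uniform recombination and
infinite-sites mutation.  The two engines are cross-validated against each
other distributionally in the test suite.

Algorithm: each ancestral lineage carries a sorted list of genomic
segments on [0, 1); every segment stores the bitmask of sampled sequences
descending from it and the time it was created.  Rates follow the ms
conventions (time in units of 4*N_a generations; pair coalescence rate
2/x_i in a population of relative size x_i; per-lineage recombination rate
rho * breakable span; per-lineage backward migration rate = the 4Nm-scaled
rate).  When a segment dies (its lineage coalesces, or the segment reaches
its sample-wide MRCA) the mutations on its branch are drawn as
Poisson(theta * length * lifetime) and recorded as (position, carrier
bitmask) pairs — which is exactly infinite-sites mutation on the ancestral
recombination graph, with genotype columns read directly off the bitmasks.

Sample-size limit: n_wild + n_cult <= 128 (two 64-bit mask words).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sim_locus", "sim_locus_matrix"]

_INF = np.inf


@njit(cache=True, inline="always")
def _seg_alloc(fstack, ftop):
    ftop -= 1
    return fstack[ftop], ftop


@njit(cache=True)
def _lineage_span(head, sl, sr, snx):
    """(leftmost start, rightmost end) over a lineage's segment list."""
    lo = sl[head]
    hi = sr[head]
    s = head
    while s != -1:
        hi = sr[s]
        s = snx[s]
    return lo, hi


@njit(cache=True)
def _emit_muts_range(left, right, birth, mask_lo, mask_hi, t, theta,
                     mpos, mlo, mhi, mcount):
    """Draw mutations for a branch piece [left, right) alive on [birth, t);
    return the new mutation count (or -1 on buffer overflow)."""
    lam = theta * (right - left) * (t - birth)
    if lam <= 0.0:
        return mcount
    k = np.random.poisson(lam)
    if mcount + k > mpos.shape[0]:
        return -1
    for _ in range(k):
        mpos[mcount] = left + (right - left) * np.random.random()
        mlo[mcount] = mask_lo
        mhi[mcount] = mask_hi
        mcount += 1
    return mcount


@njit(cache=True)
def _sim_core(n1, n2, x2p, x2b, tau1, tau2, mig_c2w, mig_w2c,
              theta, rho, seed,
              mpos, mlo, mhi):
    """Run one locus; fills the mutation buffers, returns the mutation
    count, or -1 if a buffer/pool capacity was exceeded."""
    np.random.seed(seed)
    ntot = n1 + n2
    full_lo = np.int64(-1) if ntot >= 64 else np.int64((np.int64(1) << ntot) - 1)
    full_hi = np.int64(0) if ntot <= 64 else \
        np.int64(-1) if ntot >= 128 else np.int64((np.int64(1) << (ntot - 64)) - 1)

    seg_cap = 64 * ntot + 16 * int(rho) + 2048
    sl = np.empty(seg_cap, np.float64)
    sr = np.empty(seg_cap, np.float64)
    smlo = np.empty(seg_cap, np.int64)
    smhi = np.empty(seg_cap, np.int64)
    sbirth = np.empty(seg_cap, np.float64)
    snx = np.empty(seg_cap, np.int32)
    fstack = np.empty(seg_cap, np.int32)
    for i in range(seg_cap):
        fstack[i] = seg_cap - 1 - i
    ftop = seg_cap

    lin_cap = 2 * ntot + int(rho) + 256
    lhead = np.empty(lin_cap, np.int32)
    lpop = np.empty(lin_cap, np.int8)
    live = np.empty(lin_cap, np.int32)  # compact list of live lineage slots
    lspan = np.zeros(lin_cap, np.float64)  # breakable span per lineage
    plist = np.empty((2, lin_cap), np.int32)  # per-population live lists
    pidx = np.empty(lin_cap, np.int32)  # position of a slot in its pop list
    gidx = np.empty(lin_cap, np.int32)  # position of a slot in `live`
    lfree = np.empty(lin_cap, np.int32)
    for i in range(lin_cap):
        lfree[i] = lin_cap - 1 - i
    lftop = lin_cap

    nlive = 0
    k1 = 0
    k2 = 0
    for i in range(ntot):
        s, ftop = _seg_alloc(fstack, ftop)
        sl[s] = 0.0
        sr[s] = 1.0
        if i < 64:
            smlo[s] = np.int64(1) << i
            smhi[s] = 0
        else:
            smlo[s] = 0
            smhi[s] = np.int64(1) << (i - 64)
        sbirth[s] = 0.0
        snx[s] = -1
        lftop -= 1
        slot = lfree[lftop]
        lhead[slot] = s
        pp = 0 if i < n1 else 1
        lpop[slot] = pp
        lspan[slot] = 1.0
        gidx[slot] = nlive
        live[nlive] = slot
        nlive += 1
        if pp == 0:
            plist[0, k1] = slot
            pidx[slot] = k1
            k1 += 1
        else:
            plist[1, k2] = slot
            pidx[slot] = k2
            k2 += 1

    mcount = 0
    t = 0.0
    span_tot = float(ntot)  # maintained incrementally
    nseg_total = ntot  # live segments (for termination)

    while nseg_total > 0:
        # population 1 (cultivated) relative size in the current epoch
        if t < tau1:
            x2 = x2p
        else:
            x2 = x2b
        migration_on = t < tau2

        rate_c1 = k1 * (k1 - 1) * 1.0  # pair rate 2 / x1, x1 = 1
        rate_c2 = (k2 * (k2 - 1) / x2) if k2 > 1 else 0.0
        rate_r = rho * span_tot
        rate_m = (k1 * mig_w2c + k2 * mig_c2w) if migration_on else 0.0
        total = rate_c1 + rate_c2 + rate_r + rate_m

        # next deterministic demographic event
        if t < tau1:
            t_next = tau1
        elif t < tau2:
            t_next = tau2
        else:
            t_next = _INF

        if total <= 0.0:
            if t_next == _INF:
                return -1  # stuck: should be impossible
            t = t_next
            if t == tau2:
                for ii in range(k2):
                    slot = plist[1, ii]
                    lpop[slot] = 0
                    plist[0, k1] = slot
                    pidx[slot] = k1
                    k1 += 1
                k2 = 0
            continue
        dt = np.random.exponential(1.0 / total)
        if t + dt >= t_next:
            t = t_next
            if t == tau2:
                for ii in range(k2):
                    slot = plist[1, ii]
                    lpop[slot] = 0
                    plist[0, k1] = slot
                    pidx[slot] = k1
                    k1 += 1
                k2 = 0
            continue
        t += dt
        u = np.random.random() * total

        if u < rate_c1 + rate_c2:
            # ---- coalescence in pop 0 or pop 1
            pop = 0 if u < rate_c1 else 1
            kpop = k1 if pop == 0 else k2
            a_idx = int(np.random.random() * kpop)
            b_idx = int(np.random.random() * (kpop - 1))
            if b_idx >= a_idx:
                b_idx += 1
            la = plist[pop, a_idx]
            lb = plist[pop, b_idx]
            # sweep-merge the two sorted segment lists.  Pieces covered by
            # only one parent pass through the unary node unchanged (same
            # storage, mask and birth time: their marginal branch simply
            # continues).  Only genuinely overlapping pieces coalesce here:
            # each dying sub-piece draws the mutations of its branch and a
            # merged segment is born at time t with the OR of the masks
            # (dropped if it reaches the sample-wide MRCA).
            pa = lhead[la]
            pb = lhead[lb]
            out_head = np.int32(-1)
            out_tail = np.int32(-1)
            new_count = 0
            while pa != -1 or pb != -1:
                if pb == -1 or (pa != -1 and sr[pa] <= sl[pb]):
                    nxt = snx[pa]
                    snx[pa] = -1
                    if out_tail == -1:
                        out_head = pa
                    else:
                        snx[out_tail] = pa
                    out_tail = pa
                    new_count += 1
                    pa = nxt
                elif pa == -1 or sr[pb] <= sl[pa]:
                    nxt = snx[pb]
                    snx[pb] = -1
                    if out_tail == -1:
                        out_head = pb
                    else:
                        snx[out_tail] = pb
                    out_tail = pb
                    new_count += 1
                    pb = nxt
                elif sl[pa] < sl[pb]:
                    # left overhang of pa: slice it off, keeping birth & mask
                    if ftop == 0:
                        return -1
                    s, ftop = _seg_alloc(fstack, ftop)
                    sl[s] = sl[pa]
                    sr[s] = sl[pb]
                    smlo[s] = smlo[pa]
                    smhi[s] = smhi[pa]
                    sbirth[s] = sbirth[pa]
                    snx[s] = -1
                    nseg_total += 1
                    if out_tail == -1:
                        out_head = s
                    else:
                        snx[out_tail] = s
                    out_tail = s
                    new_count += 1
                    sl[pa] = sl[pb]
                elif sl[pb] < sl[pa]:
                    if ftop == 0:
                        return -1
                    s, ftop = _seg_alloc(fstack, ftop)
                    sl[s] = sl[pb]
                    sr[s] = sl[pa]
                    smlo[s] = smlo[pb]
                    smhi[s] = smhi[pb]
                    sbirth[s] = sbirth[pb]
                    snx[s] = -1
                    nseg_total += 1
                    if out_tail == -1:
                        out_head = s
                    else:
                        snx[out_tail] = s
                    out_tail = s
                    new_count += 1
                    sl[pb] = sl[pa]
                else:
                    ov_r = min(sr[pa], sr[pb])
                    mcount = _emit_muts_range(sl[pa], ov_r, sbirth[pa],
                                              smlo[pa], smhi[pa], t, theta,
                                              mpos, mlo, mhi, mcount)
                    if mcount < 0:
                        return -1
                    mcount = _emit_muts_range(sl[pb], ov_r, sbirth[pb],
                                              smlo[pb], smhi[pb], t, theta,
                                              mpos, mlo, mhi, mcount)
                    if mcount < 0:
                        return -1
                    or_lo = smlo[pa] | smlo[pb]
                    or_hi = smhi[pa] | smhi[pb]
                    if or_lo != full_lo or or_hi != full_hi:
                        if ftop == 0:
                            return -1
                        s, ftop = _seg_alloc(fstack, ftop)
                        sl[s] = sl[pa]
                        sr[s] = ov_r
                        smlo[s] = or_lo
                        smhi[s] = or_hi
                        sbirth[s] = t
                        snx[s] = -1
                        nseg_total += 1
                        if out_tail == -1:
                            out_head = s
                        else:
                            snx[out_tail] = s
                        out_tail = s
                        new_count += 1
                    if sr[pa] > ov_r:
                        sl[pa] = ov_r
                    else:
                        nxt = snx[pa]
                        fstack[ftop] = pa
                        ftop += 1
                        nseg_total -= 1
                        pa = nxt
                    if sr[pb] > ov_r:
                        sl[pb] = ov_r
                    else:
                        nxt = snx[pb]
                        fstack[ftop] = pb
                        ftop += 1
                        nseg_total -= 1
                        pb = nxt
            # remove lb everywhere; la becomes the merged lineage or dies
            kpop = k1 if pop == 0 else k2
            moved = plist[pop, kpop - 1]
            plist[pop, pidx[lb]] = moved
            pidx[moved] = pidx[lb]
            kpop -= 1
            moved = live[nlive - 1]
            live[gidx[lb]] = moved
            gidx[moved] = gidx[lb]
            nlive -= 1
            lfree[lftop] = lb
            lftop += 1
            span_tot -= lspan[la] + lspan[lb]
            lspan[lb] = 0.0
            if new_count == 0:
                lspan[la] = 0.0
                moved = plist[pop, kpop - 1]
                plist[pop, pidx[la]] = moved
                pidx[moved] = pidx[la]
                kpop -= 1
                moved = live[nlive - 1]
                live[gidx[la]] = moved
                gidx[moved] = gidx[la]
                nlive -= 1
                lfree[lftop] = la
                lftop += 1
            else:
                lhead[la] = out_head
                lo, hi = _lineage_span(out_head, sl, sr, snx)
                lspan[la] = hi - lo
                span_tot += lspan[la]
            if pop == 0:
                k1 = kpop
            else:
                k2 = kpop

        elif u < rate_c1 + rate_c2 + rate_r:
            # ---- recombination: pick lineage weighted by breakable span
            # span-weighted lineage pick by rejection (spans are <= 1)
            slot = live[int(np.random.random() * nlive)]
            while np.random.random() >= lspan[slot]:
                slot = live[int(np.random.random() * nlive)]
            lo, hi = _lineage_span(lhead[slot], sl, sr, snx)
            brk = lo + (hi - lo) * np.random.random()
            # walk to the first segment ending beyond brk
            p = lhead[slot]
            prev = np.int32(-1)
            while sr[p] <= brk:
                prev = p
                p = snx[p]
            if sl[p] < brk:
                # straddling segment: split it in two (same mask & birth)
                if ftop == 0:
                    return -1
                s2, ftop = _seg_alloc(fstack, ftop)
                sl[s2] = brk
                sr[s2] = sr[p]
                smlo[s2] = smlo[p]
                smhi[s2] = smhi[p]
                sbirth[s2] = sbirth[p]
                snx[s2] = snx[p]
                sr[p] = brk
                snx[p] = -1
                prev = p
                p = s2
                nseg_total += 1
            else:
                if prev == -1:
                    continue  # brk left of all material: no-op
                snx[prev] = -1
            if lftop == 0:
                return -1
            lftop -= 1
            slot2 = lfree[lftop]
            lhead[slot2] = p
            pp = lpop[slot]
            lpop[slot2] = pp
            span_tot -= lspan[slot]
            lo, hi = _lineage_span(lhead[slot], sl, sr, snx)
            lspan[slot] = hi - lo
            lo, hi = _lineage_span(p, sl, sr, snx)
            lspan[slot2] = hi - lo
            span_tot += lspan[slot] + lspan[slot2]
            gidx[slot2] = nlive
            live[nlive] = slot2
            nlive += 1
            if pp == 0:
                plist[0, k1] = slot2
                pidx[slot2] = k1
                k1 += 1
            else:
                plist[1, k2] = slot2
                pidx[slot2] = k2
                k2 += 1

        else:
            # ---- migration
            v = u - rate_c1 - rate_c2 - rate_r
            from_pop = 0 if v < k1 * mig_w2c else 1
            to_pop = 1 - from_pop
            kpop = k1 if from_pop == 0 else k2
            pick = int(np.random.random() * kpop)
            slot = plist[from_pop, pick]
            moved = plist[from_pop, kpop - 1]
            plist[from_pop, pick] = moved
            pidx[moved] = pick
            lpop[slot] = to_pop
            if from_pop == 0:
                k1 -= 1
                plist[1, k2] = slot
                pidx[slot] = k2
                k2 += 1
            else:
                k2 -= 1
                plist[0, k1] = slot
                pidx[slot] = k1
                k1 += 1

    return mcount


def sim_locus(n_wild: int, n_cult: int, theta_locus: float, rho_locus: float,
              seed: int, *, x2_present: float = 1.0, x2_bottleneck: float = 1.0,
              tau1: float = np.inf, tau2: float = np.inf,
              m12: float = 0.0, m21: float = 0.0):
    """Simulate one locus; returns (positions in [0,1), mask_lo, mask_hi).

    Times are in 4*N_a units; sizes relative to N_a; m12 (wild->cultivar,
    forward) and m21 are 4Nm-scaled.  The standard single-population model
    is the default (n_cult=0, no events).
    """
    ntot = n_wild + n_cult
    if ntot < 2 or ntot > 128:
        raise ValueError("need 2 <= n_wild + n_cult <= 128")
    cap = max(256, int(8 * theta_locus * (np.log(ntot) + 2) + 64))
    while True:
        mpos = np.empty(cap, np.float64)
        mlo = np.empty(cap, np.int64)
        mhi = np.empty(cap, np.int64)
        k = _sim_core(n_wild, n_cult, x2_present, x2_bottleneck,
                      tau1, tau2, m12, m21,
                      float(theta_locus), float(rho_locus), int(seed) & 0x7FFFFFFF,
                      mpos, mlo, mhi)
        if k >= 0:
            order = np.argsort(mpos[:k], kind="stable")
            return mpos[order], mlo[order], mhi[order]
        cap *= 4
        if cap > 1 << 22:
            raise RuntimeError("mutation buffer overflow")


def _masks_to_matrix(mask_lo: np.ndarray, mask_hi: np.ndarray, n: int
                     ) -> np.ndarray:
    """(S,) mask words -> (n, S) 0/1 genotype matrix."""
    lo = mask_lo.view(np.uint64)
    shifts = np.arange(min(n, 64), dtype=np.uint64)[:, None]
    G_lo = ((lo[None, :] >> shifts) & np.uint64(1)).astype(np.int8)
    if n <= 64:
        return G_lo
    hi = mask_hi.view(np.uint64)
    shifts = np.arange(n - 64, dtype=np.uint64)[:, None]
    G_hi = ((hi[None, :] >> shifts) & np.uint64(1)).astype(np.int8)
    return np.vstack([G_lo, G_hi])


def sim_locus_matrix(n_wild: int, n_cult: int, theta_locus: float,
                     rho_locus: float, seed: int, L: float = 1.0, **kw):
    """As :func:`sim_locus` but returning (genotypes (n,S), positions*L)."""
    pos, mlo, mhi = sim_locus(n_wild, n_cult, theta_locus, rho_locus, seed,
                              **kw)
    return _masks_to_matrix(mlo, mhi, n_wild + n_cult), pos * L
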