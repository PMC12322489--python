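"""Exact feasibility machinery for the dip statistic.

For a trial tube half-width Delta (in ECDF counts), a unimodal CDF exists
within the tube iff for some mode placement a convex nondecreasing chain fits
the box constraints left of the mode, a concave one fits them on the right,
and the two can be joined across the mode.  When the mode sits in a gap
between data values, the join is constrained by the chains' end slopes: the
convex branch leaves its last point no flatter than its final internal slope,
and the concave branch must enter its first point no flatter than its first
internal slope, while staying inside the tube over the gap.

The sweep propagates, point by point, the convex region of achievable
(incoming slope s, value g) states of a convex chain.  Its lower boundary
lo(s) is convex piecewise-linear and the upper boundary hi(s) concave; each
step closes the region upward in s (slopes may only grow), shears values by
s * gap, and clips to the next box.  The concave side reuses the same sweep
on the reflected data.  Mode-in-gap feasibility reduces to: there exist a
prefix lower-frontier vertex (s1, g1), a reflected-suffix vertex (s2, g2) and
a junction offset t in [0, gap] with

    g1 + s1 t <= cap           (tube on the flat)
    g1 + s1 t <= n - g2 - s2 (gap - t)   (monotone join, both slope rules)

which is a pair of linear conditions in t per vertex pair.  A mode at a data
value carries an atom that absorbs the jump, decoupling the slopes; there the
join only compares achievable end values.

Polylines are stored as parallel breakpoint arrays so the whole sweep can be
jit-compiled.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover

    def njit(*a, **k):
        def deco(f):
            return f

        return deco if not (a and callable(a[0])) else a[0]

BIG = 1e30
MAXV = 64  # frontier vertices kept per prefix (thinned if ever exceeded)


@njit(cache=False)
def _upclose(xs, vs, m, smax, convex):
    """Running min (convex lower bound) or running max (concave upper bound)
    over slopes <= s, extending the domain to smax."""
    if convex:
        arg = 0
        for i in range(1, m):
            if vs[i] < vs[arg]:
                arg = i
    else:
        arg = 0
        for i in range(1, m):
            if vs[i] > vs[arg]:
                arg = i
    k = arg + 1
    if xs[arg] < smax:
        xs[k] = smax
        vs[k] = vs[arg]
        k += 1
    return k


@njit(cache=False)
def _shear(xs, vs, m, h):
    for i in range(m):
        vs[i] += xs[i] * h


@njit(cache=False)
def _clip_const(xs, vs, m, bound, take_max, oxs, ovs):
    """max (or min) of a polyline with a constant; writes to output arrays."""
    k = 0
    for i in range(m):
        if i > 0:
            a, b = vs[i - 1] - bound, vs[i] - bound
            if (a > 0) != (b > 0) and a != b:
                t = a / (a - b)
                oxs[k] = xs[i - 1] + t * (xs[i] - xs[i - 1])
                ovs[k] = bound
                k += 1
        v = vs[i]
        if take_max:
            ovs[k] = v if v > bound else bound
        else:
            ovs[k] = v if v < bound else bound
        oxs[k] = xs[i]
        k += 1
    return k


@njit(cache=False)
def _eval(xs, vs, m, s):
    if s <= xs[0]:
        return vs[0]
    for i in range(1, m):
        if s <= xs[i]:
            if xs[i] == xs[i - 1]:
                return vs[i]
            t = (s - xs[i - 1]) / (xs[i] - xs[i - 1])
            return vs[i - 1] + t * (vs[i] - vs[i - 1])
    return vs[m - 1]


@njit(cache=False)
def _domain(lxs, lvs, lm, hxs, hvs, hm):
    """Interval of s where lo(s) <= hi(s); returns (sa, sb) or (1, 0)."""
    sa = BIG
    sb = -BIG
    prev_s = min(lxs[0], hxs[0])
    prev_d = _eval(hxs, hvs, hm, prev_s) - _eval(lxs, lvs, lm, prev_s)
    if prev_d >= 0:
        sa = prev_s
        sb = prev_s
    i = 0
    j = 0
    while i < lm or j < hm:
        if j >= hm or (i < lm and lxs[i] <= hxs[j]):
            s = lxs[i]
            i += 1
        else:
            s = hxs[j]
            j += 1
        if s <= prev_s:
            continue
        d = _eval(hxs, hvs, hm, s) - _eval(lxs, lvs, lm, s)
        if (prev_d > 0) != (d > 0) and prev_d != d:
            t = prev_d / (prev_d - d)
            cross = prev_s + t * (s - prev_s)
            if d >= 0:
                sa = min(sa, cross)
                sb = max(sb, s)
            else:
                sa = min(sa, prev_s)
                sb = max(sb, cross)
        elif d >= 0:
            sa = min(sa, prev_s if prev_d >= 0 else s)
            sb = max(sb, s)
        prev_s = s
        prev_d = d
    return sa, sb


@njit(cache=False)
def _trim(xs, vs, m, sa, sb, oxs, ovs):
    """Restrict a polyline to [sa, sb]."""
    k = 0
    va = _eval(xs, vs, m, sa)
    oxs[k] = sa
    ovs[k] = va
    k += 1
    for i in range(m):
        if sa < xs[i] < sb:
            oxs[k] = xs[i]
            ovs[k] = vs[i]
            k += 1
    if sb > sa:
        oxs[k] = sb
        ovs[k] = _eval(xs, vs, m, sb)
        k += 1
    return k


@njit(cache=False)
def _store_frontier(lxs, lvs, lm, out_s, out_g, j):
    """Keep prefix j's lower frontier; thin nearly-collinear vertices when it
    would overflow the fixed-size store."""
    m = lm
    while m > MAXV:
        # drop the interior vertex with the smallest deviation from the
        # chord of its neighbours (changes the frontier negligibly)
        best_i = 1
        best_dev = BIG
        for i in range(1, m - 1):
            t = (lxs[i] - lxs[i - 1]) / (lxs[i + 1] - lxs[i - 1])
            chord = lvs[i - 1] + t * (lvs[i + 1] - lvs[i - 1])
            dev = abs(lvs[i] - chord)
            if dev < best_dev:
                best_dev = dev
                best_i = i
        for i in range(best_i, m - 1):
            lxs[i] = lxs[i + 1]
            lvs[i] = lvs[i + 1]
        m -= 1
    for i in range(m):
        out_s[j, i] = lxs[i]
        out_g[j, i] = lvs[i]
    return m


@njit(cache=False)
def _min_on(xs, vs, m):
    best = vs[0]
    for i in range(1, m):
        if vs[i] < best:
            best = vs[i]
    return best


@njit(cache=False)
def _prefix_sweep(xi, p, c, n, delta, feas, mend, feas_at, mend_at, fr_s, fr_g, fr_m):
    """Forward pass over prefixes 0..j.

    Records per prefix: feasibility and minimal end value with the normal box
    at j (plus the atom-box variants), and the lower frontier of achievable
    (end slope, end value) states for the mode-in-gap join.
    """
    U = xi.size
    cap = 4 * U + 16
    lxs = np.empty(cap)
    lvs = np.empty(cap)
    hxs = np.empty(cap)
    hvs = np.empty(cap)
    wx = np.empty(cap)
    wv = np.empty(cap)
    wx2 = np.empty(cap)
    wv2 = np.empty(cap)
    wx3 = np.empty(cap)
    wv3 = np.empty(cap)
    hmin = BIG
    for j in range(1, U):
        g = xi[j] - xi[j - 1]
        if g < hmin:
            hmin = g
    smax = (2.0 * n + 4.0 * delta) / hmin if hmin < BIG else 1.0

    alive = True
    lm = hm = 0
    for j in range(U):
        lb = c[j] - delta
        ub = p[j] + delta
        lb_at = p[j] - delta
        ub_at = p[j] + delta
        if lb < 0.0:
            lb = 0.0
        if ub > n:
            ub = n
        if lb_at < 0.0:
            lb_at = 0.0
        if ub_at > n:
            ub_at = n
        if j > 0 and not alive:
            feas[j] = False
            mend[j] = BIG
            feas_at[j] = False
            mend_at[j] = BIG
            fr_m[j] = 0
            continue
        if j == 0:
            lxs[0] = 0.0
            lxs[1] = smax
            lvs[0] = lvs[1] = lb
            hxs[0] = 0.0
            hxs[1] = smax
            hvs[0] = hvs[1] = ub
            lm = hm = 2
            alive = lb <= ub
            feas[0] = alive
            mend[0] = lb if alive else BIG
            feas_at[0] = lb_at <= ub_at
            mend_at[0] = lb_at if feas_at[0] else BIG
            fr_m[0] = _store_frontier(lxs, lvs, lm, fr_s, fr_g, 0) if alive else 0
            continue
        h = xi[j] - xi[j - 1]
        lm = _upclose(lxs, lvs, lm, smax, True)
        hm = _upclose(hxs, hvs, hm, smax, False)
        _shear(lxs, lvs, lm, h)
        _shear(hxs, hvs, hm, h)
        # atom variant at j (does not advance the running state)
        m1 = _clip_const(lxs, lvs, lm, lb_at, True, wx, wv)
        m2 = _clip_const(hxs, hvs, hm, ub_at, False, wx2, wv2)
        sa, sb = _domain(wx, wv, m1, wx2, wv2, m2)
        if sa > sb:
            feas_at[j] = False
            mend_at[j] = BIG
        else:
            feas_at[j] = True
            best = _eval(wx, wv, m1, sa)
            e2 = _eval(wx, wv, m1, sb)
            if e2 < best:
                best = e2
            for i in range(m1):
                if sa <= wx[i] <= sb and wv[i] < best:
                    best = wv[i]
            mend_at[j] = best
        # normal box at j
        m1 = _clip_const(lxs, lvs, lm, lb, True, wx, wv)
        m2 = _clip_const(hxs, hvs, hm, ub, False, wx2, wv2)
        sa, sb = _domain(wx, wv, m1, wx2, wv2, m2)
        if sa > sb:
            alive = False
            feas[j] = False
            mend[j] = BIG
            fr_m[j] = 0
            continue
        lm = _trim(wx, wv, m1, sa, sb, wx3, wv3)
        for i in range(lm):
            lxs[i] = wx3[i]
            lvs[i] = wv3[i]
        hm = _trim(wx2, wv2, m2, sa, sb, wx3, wv3)
        for i in range(hm):
            hxs[i] = wx3[i]
            hvs[i] = wv3[i]
        feas[j] = True
        mend[j] = _min_on(lxs, lvs, lm)
        fr_m[j] = _store_frontier(lxs, lvs, lm, fr_s, fr_g, j)


@njit(cache=False)
def _gap_join_ok(ps, pg, pm, ss, sg, sm, h, cap, n):
    """Mode-in-gap join between a prefix frontier and a reflected-suffix
    frontier: exists t in [0, h] and vertices with
    g1 + s1 t <= cap and g1 + s1 t + g2 + s2 (h - t) <= n."""
    for i in range(pm):
        s1 = ps[i]
        g1 = pg[i]
        if g1 > cap:
            continue
        # t-range for the cap condition
        if s1 > 0.0:
            tA = (cap - g1) / s1
            if tA > h:
                tA = h
        else:
            tA = h
        for j in range(sm):
            s2 = ss[j]
            g2 = sg[j]
            # g1 + g2 + s2 h + t (s1 - s2) <= n on t in [0, tA]
            base = g1 + g2 + s2 * h - n
            coef = s1 - s2
            if base <= 0.0:
                return True  # t = 0 works (cap holds there trivially)
            if coef < 0.0 and base + coef * tA <= 0.0:
                return True
    return False


@njit(cache=False)
def tube_feasible(xi, p, c, n, delta):
    """Is there a unimodal CDF within +-delta (counts) of the ECDF?"""
    U = xi.size
    feas = np.empty(U, np.bool_)
    mend = np.empty(U)
    feas_at = np.empty(U, np.bool_)
    mend_at = np.empty(U)
    fr_s = np.empty((U, MAXV))
    fr_g = np.empty((U, MAXV))
    fr_m = np.empty(U, np.int64)
    _prefix_sweep(xi, p, c, n, delta, feas, mend, feas_at, mend_at, fr_s, fr_g, fr_m)
    xr = np.empty(U)
    pr = np.empty(U)
    cr = np.empty(U)
    for i in range(U):
        xr[i] = -xi[U - 1 - i]
        pr[i] = n - c[U - 1 - i]
        cr[i] = n - p[U - 1 - i]
    feas_r = np.empty(U, np.bool_)
    mend_r = np.empty(U)
    feas_r_at = np.empty(U, np.bool_)
    mend_r_at = np.empty(U)
    fr_s_r = np.empty((U, MAXV))
    fr_g_r = np.empty((U, MAXV))
    fr_m_r = np.empty(U, np.int64)
    _prefix_sweep(
        xr, pr, cr, n, delta, feas_r, mend_r, feas_r_at, mend_r_at, fr_s_r, fr_g_r, fr_m_r
    )

    if feas_r[U - 1] or feas[U - 1]:  # mode beyond all data on one side
        return True
    for a in range(1, U):  # mode in the gap left of xi[a]
        jp = a - 1
        jr = U - 1 - a
        if not (feas[jp] and feas_r[jr]):
            continue
        h = xi[a] - xi[a - 1]
        cap = c[a - 1] + delta
        if cap > n:
            cap = n
        if _gap_join_ok(
            fr_s[jp], fr_g[jp], fr_m[jp], fr_s_r[jr], fr_g_r[jr], fr_m_r[jr], h, cap, n
        ):
            return True
    for j in range(U):  # mode at xi[j]: the atom decouples the slopes
        if feas_at[j] and feas_r_at[U - 1 - j]:
            if mend_at[j] <= n - mend_r_at[U - 1 - j]:
                return True
    return False
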