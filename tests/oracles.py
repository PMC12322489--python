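"""Brute-force reference implementations used only to validate the package.

These oracles are deliberately slow and definition-direct; they share no code
with the implementations they check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def dip_bruteforce(values) -> float:
    """Dip via linear programming over piecewise-linear unimodal CDFs.

    Enumerates every mode placement: beyond the data on either side, at a
    data value (with an atom there absorbing the ECDF jump), or inside a gap
    immediately right of a data value (the mode with its jump sits at one end
    of the gap; an interior mode position is never needed, because a binding
    tube cap inside the gap forces the join value onto the cap, which
    propagates to a degenerate configuration).  Each placement is a small LP
    minimising the tube half-width d subject to the sup-norm tube constraints
    at the data points, monotonicity, and convex-below / concave-above shape
    constraints including the slope conditions joining the two branches
    across the mode's gap.  The dip is the smallest optimum.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    xi, counts = np.unique(x, return_counts=True)
    U = xi.size
    if U == 1:
        return 0.0
    c = np.cumsum(counts) / n  # ECDF value at xi[j]
    p = c - counts / n  # left limit at xi[j]

    best = np.inf
    for spec in _mode_placements(U):
        val = _solve_placement(xi, p, c, spec)
        if val is not None and val < best:
            best = val
    return best


def _mode_placements(U):
    yield ("all_convex",)
    yield ("all_concave",)
    for j in range(U):
        yield ("atom", j)
    for m in range(U - 1):  # mode in the gap (xi[m], xi[m+1])
        yield ("gap0", m)  # join at the left end of the gap
        yield ("gap1", m)  # join at the right end of the gap
    # the m = -1 / m = U-1 "gap" cases coincide with all_concave/all_convex


def _solve_placement(xi, p, c, spec):
    U = xi.size
    kind = spec[0]
    atom = spec[1] if kind == "atom" else None
    nb = U + (1 if atom is not None else 0) + 1  # g's, optional b, d
    id_b = U
    id_d = nb - 1
    A, rhs = [], []

    def row(pairs, ub):
        r = np.zeros(nb)
        for k, v in pairs:
            r[k] += v
        A.append(r)
        rhs.append(ub)

    def right_val(j):
        return id_b if (atom is not None and j == atom) else j

    # --- tube constraints at the data points
    for j in range(U):
        if atom is not None and j == atom:
            row([(j, 1.0), (id_d, -1.0)], p[j])  # left limit <= p_j + d
            row([(j, -1.0), (id_d, -1.0)], -p[j])  # left limit >= p_j - d
            row([(id_b, 1.0), (id_d, -1.0)], c[j])  # value <= c_j + d
            row([(id_b, -1.0), (id_d, -1.0)], -c[j])  # value >= c_j - d
            row([(j, 1.0), (id_b, -1.0)], 0.0)  # a <= b
        else:
            row([(j, 1.0), (id_d, -1.0)], p[j])  # G(xi_j) <= p_j + d
            row([(j, -1.0), (id_d, -1.0)], -c[j])  # G(xi_j) >= c_j - d
    # --- monotonicity between consecutive points
    for j in range(U - 1):
        row([(right_val(j), 1.0), (j + 1, -1.0)], 0.0)

    # --- shape constraints
    if kind == "all_convex":
        conv_end, conc_start = U - 1, U  # everything convex
    elif kind == "all_concave":
        conv_end, conc_start = -1, 0
    elif kind == "atom":
        conv_end, conc_start = atom, atom
    else:  # gap0 / gap1 around the gap right of xi[m]
        m = spec[1]
        conv_end, conc_start = m, m + 1
    # slopes non-decreasing among segments fully on the convex side
    for j in range(1, conv_end):
        dx0 = xi[j] - xi[j - 1]
        dx1 = xi[j + 1] - xi[j]
        lo = right_val(j - 1)
        row([(j, dx1 + dx0), (lo, -dx1), (j + 1, -dx0)], 0.0)
    # slopes non-increasing on the concave side
    for j in range(conc_start + 1, U - 1):
        dx0 = xi[j] - xi[j - 1]
        dx1 = xi[j + 1] - xi[j]
        lo = right_val(j - 1)
        row([(j, -(dx1 + dx0)), (lo, dx1), (j + 1, dx0)], 0.0)

    # --- join conditions across the mode's gap
    if kind == "gap0" and spec[1] + 2 < U:
        # mode at the left end: the concave extension over the whole gap must
        # be at least as steep as the suffix's first internal slope s2:
        # g_m + s2 h <= g_{m+1}
        m = spec[1]
        h = xi[m + 1] - xi[m]
        dxn = xi[m + 2] - xi[m + 1]
        row([(m, dxn), (m + 2, h), (m + 1, -h), (m + 1, -dxn)], 0.0)
    if kind == "gap1" and spec[1] >= 1:
        # mode at the right end: the convex extension at slope >= s1 spans
        # the gap and must stay under the tube cap and below g_{m+1}:
        # g_m + s1 h <= min(c_m + d, g_{m+1})
        m = spec[1]
        h = xi[m + 1] - xi[m]
        dxp = xi[m] - xi[m - 1]
        row([(m, dxp + h), (m - 1, -h), (id_d, -dxp)], c[m] * dxp)
        row([(m, dxp + h), (m - 1, -h), (m + 1, -dxp)], 0.0)

    bounds = [(0.0, 1.0)] * U + ([(0.0, 1.0)] if atom is not None else []) + [(0.0, 0.5)]
    cost = np.zeros(nb)
    cost[id_d] = 1.0
    res = linprog(cost, A_ub=np.array(A), b_ub=np.array(rhs), bounds=bounds, method="highs")
    if not res.success:
        return None
    return float(res.x[id_d])


def weighted_mean_bruteforce(props, weights):
    """Pooled-count identity for the trip-weighted outside proportion."""
    props = np.asarray(props, dtype=float)
    weights = np.asarray(weights, dtype=float)
    return float(np.sum(props * weights) / np.sum(weights))


def logistic_regression_map(X, y, prior_sd):
    """Newton-Raphson MAP fit of a logistic regression with N(0, sd) priors.

    Oracle for the Bernoulli mixed model in the zero random-effect-variance
    limit.  Returns the posterior mode and the Laplace covariance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    prior_prec = 1.0 / np.asarray(prior_sd, dtype=float) ** 2
    beta = np.zeros(X.shape[1])
    for _ in range(200):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - prior_prec * beta
        hess = X.T @ (X * w[:, None]) + np.diag(prior_prec)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    cov = np.linalg.inv(hess)
    return beta, cov
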