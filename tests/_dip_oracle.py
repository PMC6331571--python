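"""Brute-force oracle for Hartigan's dip statistic.

Solves the defining minimax problem directly with linear programming:
dip = min over unimodal cdfs G of sup |F_n - G|, where G is convex up to
some mode m and concave after it (an atom is allowed at the mode).  The
mode either falls strictly between two order statistics (handled by a
"split" with a free connector segment whose minimal rise is bounded by
the smaller adjacent slope) or sits exactly on one (handled with an
explicit left-limit variable and an upward jump).  Every candidate mode
placement yields one or two small LPs; the oracle returns the global
minimum.  Only distinct-valued samples are supported.

Intended for cross-validating the fast implementation at small n; cost
grows as ~3n LPs of size n.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def _solve(n, rows, rhs):
    # variables: g_1..g_n, (optional gm appended by caller via n_extra), d
    c = np.zeros(rows.shape[1])
    c[-1] = 1.0
    bounds = [(0.0, 1.0)] * (rows.shape[1] - 1) + [(0.0, None)]
    res = linprog(c, A_ub=rows, b_ub=rhs, bounds=bounds, method="highs")
    return res.fun if res.success else np.inf


def dip_lp(values) -> float:
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n == 1:
        return 0.0
    if len(np.unique(x)) != n:
        raise ValueError("oracle requires distinct values")

    def band_rows(n_var, relax_u=None):
        """|g_i - F| <= d constraints; relax_u relaxes the upper bound at
        one index (mode with an atom)."""
        rows, rhs = [], []
        for i in range(n):  # 0-based; F(x_i) = (i+1)/n, left value i/n
            r = np.zeros(n_var)
            r[i], r[-1] = 1.0, -1.0  # g_i - d <= u_i
            u = (i + 1) / n if relax_u == i else i / n
            rows.append(r)
            rhs.append(u)
            r = np.zeros(n_var)
            r[i], r[-1] = -1.0, -1.0  # -g_i - d <= -(i+1)/n
            rows.append(r)
            rhs.append(-(i + 1) / n)
        return rows, rhs

    def mono_rows(n_var, order):
        rows = []
        for a, b in zip(order[:-1], order[1:]):
            r = np.zeros(n_var)
            r[a], r[b] = 1.0, -1.0  # g_a <= g_b
            rows.append(r)
        return rows

    def shape_rows(n_var, idx, xs, convex):
        """slope monotonicity over consecutive triples of (idx, xs)."""
        rows = []
        for i in range(1, len(idx) - 1):
            dx1 = xs[i] - xs[i - 1]
            dx2 = xs[i + 1] - xs[i]
            r = np.zeros(n_var)
            # convex: (g_i - g_{i-1}) dx2 <= (g_{i+1} - g_i) dx1
            r[idx[i - 1]] = -dx2
            r[idx[i]] = dx2 + dx1
            r[idx[i + 1]] = -dx1
            if not convex:
                r = -r
            rows.append(r)
        return rows

    best = np.inf
    n_var = n + 1  # g's + d

    # mode strictly between x_{a-1} and x_a (0-based gap a = 0..n)
    for a in range(n + 1):
        left = list(range(a))
        right = list(range(a, n))
        base_rows, base_rhs = band_rows(n_var)
        base_rows += mono_rows(n_var, list(range(n)))
        base_rhs += [0.0] * (n - 1)
        base_rows += shape_rows(n_var, left, x[left], convex=True)
        base_rows += shape_rows(n_var, right, x[right], convex=False)
        base_rhs += [0.0] * (max(len(left) - 2, 0) + max(len(right) - 2, 0))

        couplings: list = [None]
        if len(left) >= 2 and len(right) >= 2:
            # connector rise >= gap_width * min(adjacent slopes):
            # disjunction -> try each branch
            couplings = ["left", "right"]
        for branch in couplings:
            rows = [r.copy() for r in base_rows]
            rhs = list(base_rhs)
            if branch is not None:
                i0, i1 = left[-2], left[-1]
                j0, j1 = right[0], right[1]
                T = x[j0] - x[i1]
                r = np.zeros(n_var)
                if branch == "left":
                    s_dx = x[i1] - x[i0]
                    # (g_j0 - g_i1) * s_dx >= T * (g_i1 - g_i0)
                    r[j0], r[i1], r[i0] = -s_dx, s_dx + T, -T
                else:
                    s_dx = x[j1] - x[j0]
                    r[j0], r[i1] = -s_dx - T, s_dx
                    r[j1] = T
                rows.append(r)
                rhs.append(0.0)
            best = min(best, _solve(n, np.array(rows), np.array(rhs)))

    # mode exactly at x_k with an atom: left limit gm, jump up to g_k
    n_var_j = n + 2  # g's + gm + d
    gm = n  # index of the left-limit variable
    for k in range(n):
        rows, rhs = band_rows(n_var_j, relax_u=k)
        rows += mono_rows(n_var_j, list(range(n)))
        rhs += [0.0] * (n - 1)
        # gm between g_{k-1} and g_k, below the left band limit
        r = np.zeros(n_var_j)
        r[gm], r[-1] = 1.0, -1.0
        rows.append(r)
        rhs.append(k / n)  # gm - d <= k/n  (F left value at x_k)
        r = np.zeros(n_var_j)
        r[gm], r[k] = 1.0, -1.0
        rows.append(r)
        rhs.append(0.0)  # gm <= g_k
        if k >= 1:
            r = np.zeros(n_var_j)
            r[k - 1], r[gm] = 1.0, -1.0
            rows.append(r)
            rhs.append(0.0)  # g_{k-1} <= gm
        left_idx = list(range(k)) + [gm]
        left_x = np.concatenate([x[:k], [x[k]]])
        right_idx = list(range(k, n))
        rows += shape_rows(n_var_j, left_idx, left_x, convex=True)
        rows += shape_rows(n_var_j, right_idx, x[right_idx], convex=False)
        rhs += [0.0] * (max(len(left_idx) - 2, 0) + max(len(right_idx) - 2, 0))
        best = min(best, _solve(n, np.array(rows), np.array(rhs)))

    return float(best)
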