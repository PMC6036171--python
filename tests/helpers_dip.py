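"""Brute-force oracle for the Hartigan dip statistic.

The dip of a sample is the minimum over unimodal CDFs G of the sup-norm
distance to the empirical CDF. For small n this is solved exactly as a
family of linear programs: one per candidate mode location, with G convex
left of the mode, concave right of it, monotone in [0, 1], and allowed an
atom at the mode (a unimodal distribution function can jump only there).
"""

import numpy as np
from scipy.optimize import linprog


def dip_lp(x):
    x = np.sort(np.asarray(x, float))
    n = len(x)
    u, counts = np.unique(x, return_counts=True)
    K = len(u)
    if K == 1:
        return 0.0
    hi = np.cumsum(counts) / n          # ECDF at each unique value
    lo = hi - counts / n                # ECDF just below
    best = np.inf
    for ms in range(K):
        # variables: g_0..g_{K-1} (G at the unique values), ell (left limit
        # of G at the mode), t (the sup distance)
        nv = K + 2
        iell, it = K, K + 1
        A, b = [], []

        def row(pairs, rhs):
            r = np.zeros(nv)
            for i, c in pairs:
                r[i] += c
            A.append(r)
            b.append(rhs)

        for k in range(K):
            if k == ms:
                row([(iell, 1), (it, -1)], lo[k])     # |ell - F(mode-)| <= t
                row([(iell, -1), (it, -1)], -lo[k])
                row([(k, 1), (it, -1)], hi[k])        # |g - F(mode)| <= t
                row([(k, -1), (it, -1)], -hi[k])
            else:
                row([(k, 1), (it, -1)], lo[k])        # g <= F(x-) + t
                row([(k, -1), (it, -1)], -hi[k])      # g >= F(x) - t
        for k in range(K - 1):
            nxt = iell if k + 1 == ms else k + 1
            row([(k, 1), (nxt, -1)], 0.0)             # monotone
        row([(iell, 1), (ms, -1)], 0.0)               # ell <= g at the mode
        left = [(u[k], k) for k in range(ms)] + [(u[ms], iell)]
        for j in range(1, len(left) - 1):
            (x0, i0), (x1, i1), (x2, i2) = left[j - 1], left[j], left[j + 1]
            # convexity: slope(i0,i1) <= slope(i1,i2), cross-multiplied
            row([(i1, x2 - x1), (i0, -(x2 - x1)),
                 (i1, x1 - x0), (i2, -(x1 - x0))], 0.0)
        right = [(u[ms], ms)] + [(u[k], k) for k in range(ms + 1, K)]
        for j in range(1, len(right) - 1):
            (x0, i0), (x1, i1), (x2, i2) = right[j - 1], right[j], right[j + 1]
            row([(i1, -(x2 - x1)), (i0, (x2 - x1)),
                 (i1, -(x1 - x0)), (i2, (x1 - x0))], 0.0)
        c = np.zeros(nv)
        c[it] = 1.0
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                      bounds=[(0, 1)] * (K + 1) + [(0, None)],
                      method="highs")
        assert res.success, res.message
        best = min(best, res.fun)
    return best
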