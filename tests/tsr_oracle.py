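"""Exhaustive brute-force oracle for trapezoidal segmented regression.

Enumerates every breakpoint placement, parity, and level assignment over the
same finite search space the package's dynamic program is pinned to
(breakpoints at sample indices; breakpoint values from the unique sample
values plus the sample mean; flats force equal values at their two ends).
Independent of the DP implementation: it evaluates fitted signals directly.
Only feasible for small N and T.
"""

import itertools

import numpy as np


def brute_force_tsr_sse(x: np.ndarray, T: int) -> float:
    x = np.asarray(x, dtype=float)
    n = x.size
    levels = np.unique(np.concatenate([x, [x.mean()]]))
    grid = np.arange(n)
    best = np.inf
    for flat_first in (True, False):
        kinds = ["flat" if ((j % 2 == 1) == flat_first) else "sloped" for j in range(1, T + 1)]
        for interior in itertools.combinations(range(1, n - 1), T - 1):
            bps = np.array((0,) + interior + (n - 1,))
            # group breakpoint-value indices tied together by flat segments
            group = list(range(T + 1))
            for j, kind in enumerate(kinds, start=1):
                if kind == "flat":
                    keep, drop = group[j - 1], group[j]
                    group = [keep if g == drop else g for g in group]
            uniq = sorted(set(group))
            col_of = [uniq.index(g) for g in group]
            # weight matrix: fitted = U @ W with U the free level values
            w = np.zeros((len(uniq), n))
            for j in range(T + 1):
                basis = np.zeros(T + 1)
                basis[j] = 1.0
                w[col_of[j]] += np.interp(grid, bps, basis)
            combos = np.array(list(itertools.product(levels, repeat=len(uniq))))
            fitted = combos @ w
            sse = ((fitted - x[None, :]) ** 2).sum(axis=1)
            m = sse.min()
            if m < best:
                best = m
    return float(best)
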