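"""Brute-force reference minimizer for tiny decomposition problems.

:func:`grid_search_minimum` minimizes the balanced cross-entropy + L1
objective by exhaustively evaluating it on a regular grid over
``[lo, hi]^d``.  It shares no code path with the proximal-gradient solver,
so it serves as an independent check that the solver reaches the global
minimum of the convex objective on problems small enough to enumerate.

The evaluation exploits that ``D`` is binary: rows are grouped by their 0/1
pattern (at most ``2^d`` groups), and within a group the linear score
``(D x)_t`` is a sum of grid coordinates, which on a regular grid takes only
``d * (m - 1) + 1`` distinct values — so cross-entropy is computed once per
distinct sum and broadcast, instead of once per grid point and row.
"""

from __future__ import annotations

import numpy as np

from .decomposition import DecompositionProblem

_LN2 = float(np.log(2.0))


def grid_search_minimum(
    problem: DecompositionProblem,
    lo: float = -3.0,
    hi: float = 3.0,
    step: float = 0.05,
) -> tuple[np.ndarray, float]:
    """Exhaustive grid minimization of the decomposition objective.

    Returns ``(x_grid, f_grid)``: the best grid point and its objective
    value.  ``f_grid`` upper-bounds the true minimum by at most the local
    curvature times the squared grid spacing.  Memory and time grow as
    ``m^d`` with ``m`` grid points per axis; intended for d <= 4.
    """
    D = np.asarray(problem.D)
    c = problem.c
    w = problem.weights
    lam = problem.lam
    d = D.shape[1]
    m = int(round((hi - lo) / step)) + 1
    grid = lo + step * np.arange(m)

    # accumulate per-pattern class weights
    w1: dict[tuple, float] = {}
    w0: dict[tuple, float] = {}
    for t in range(D.shape[0]):
        key = tuple(int(v) for v in D[t])
        if c[t] == 1:
            w1[key] = w1.get(key, 0.0) + w[t]
        else:
            w0[key] = w0.get(key, 0.0) + w[t]

    obj = np.zeros((m,) * d, dtype=np.float32)
    for axis in range(d):
        shape = [1] * d
        shape[axis] = m
        obj += (lam * np.abs(grid)).astype(np.float32).reshape(shape)

    for key in sorted(set(w1) | set(w0)):
        a1 = w1.get(key, 0.0)
        a0 = w0.get(key, 0.0)
        support = [i for i, bit in enumerate(key) if bit]
        s = len(support)
        if s == 0:  # score is 0 for every x: a constant ln 2 per unit weight
            obj += np.float32((a1 + a0) * _LN2)
            continue
        # distinct score values: sums of s grid coordinates
        z = lo * s + step * np.arange(s * (m - 1) + 1)
        table = (a1 * np.logaddexp(0.0, -z) + a0 * np.logaddexp(0.0, z)).astype(
            np.float32
        )
        idx = np.zeros((1,) * d, dtype=np.int32)
        for axis in support:
            shape = [1] * d
            shape[axis] = m
            idx = idx + np.arange(m, dtype=np.int32).reshape(shape)
        obj += table[idx]

    flat = int(np.argmin(obj))
    best = np.unravel_index(flat, obj.shape)
    x = np.array([grid[i] for i in best])
    # re-evaluate the winning point in float64 against the package objective
    from .decomposition import objective

    return x, objective(x, problem)
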