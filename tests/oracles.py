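"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: a brute-force explicit
finite-difference PDE solver, textbook sum-formula Pearson correlation, an
exhaustive regression-window search, and a clique-based compact-letter
construction.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def pde_cumulative(model, C_donor, t_eval, n_nodes=400):
    """Explicit forward-Euler finite-difference solution of the one-membrane
    diffusion problem; returns cumulative amount exited per area at t_eval.

    Boundary conditions: c(0) = K·C_donor (vehicle side), c(h) = 0 (sink);
    zero initial concentration.  Exit flux via a second-order one-sided
    derivative, integrated with the trapezoid rule at every (tiny,
    stability-limited) step.
    """
    D, h, K = model.D, model.h, model.K
    c0 = K * C_donor
    dx = h / n_nodes
    dt = 0.4 * dx * dx / D
    t_end = float(np.max(t_eval))
    nsteps = int(np.ceil(t_end / dt))
    dt = t_end / nsteps
    r = D * dt / (dx * dx)

    c = np.zeros(n_nodes + 1)
    c[0] = c0
    qacc = 0.0
    tcur = 0.0
    fprev = -D * (3 * c[-1] - 4 * c[-2] + c[-3]) / (2 * dx)
    qtimes = [0.0]
    qvals = [0.0]
    for _ in range(nsteps):
        c[1:-1] += r * (c[2:] - 2 * c[1:-1] + c[:-2])
        tcur += dt
        f = -D * (3 * c[-1] - 4 * c[-2] + c[-3]) / (2 * dx)
        qacc += 0.5 * (f + fprev) * dt
        fprev = f
        qtimes.append(tcur)
        qvals.append(qacc)
    return np.interp(np.asarray(t_eval, float), qtimes, qvals)


def pde_cumulative_richardson(model, C_donor, t_eval, n_nodes=200):
    """Richardson extrapolation over grids (n, 2n) to cancel the O(dx²) term."""
    q_coarse = pde_cumulative(model, C_donor, t_eval, n_nodes=n_nodes)
    q_fine = pde_cumulative(model, C_donor, t_eval, n_nodes=2 * n_nodes)
    return (4.0 * q_fine - q_coarse) / 3.0


def pearson_r_sums(x, y):
    """Pearson r from the raw textbook sum formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    num = n * sxy - sx * sy
    den = np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


def ols_slope_intercept_r2(t, q):
    """OLS via normal equations (no scipy)."""
    t = np.asarray(t, float)
    q = np.asarray(q, float)
    n = len(t)
    tbar, qbar = t.mean(), q.mean()
    sxx = ((t - tbar) ** 2).sum()
    sxy = ((t - tbar) * (q - qbar)).sum()
    slope = sxy / sxx
    intercept = qbar - slope * tbar
    ss_res = ((q - (slope * t + intercept)) ** 2).sum()
    ss_tot = ((q - qbar) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return slope, intercept, r2


def brute_force_best_window(t, q, min_points=4):
    """Exhaustive window search with naive loops: max r², positive slope,
    ties to longer window then earlier start.  Returns ((i, j), slope)."""
    n = len(t)
    best = None
    for i in range(n):
        for j in range(i + min_points, n + 1):
            slope, _, r2 = ols_slope_intercept_r2(t[i:j], q[i:j])
            if slope <= 0:
                continue
            cand = (r2, j - i, -i, (i, j), slope)
            if best is None or cand[:3] > best[:3]:
                best = cand
    if best is None:
        return None
    return best[3], best[4]


def cld_by_maximal_cliques(groups, means, reject):
    """Compact letters as the maximal cliques of the non-significance graph
    (independent of the insert-and-absorb implementation)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(groups)
    for a, b in combinations(groups, 2):
        if not reject.get((a, b), reject.get((b, a), False)):
            g.add_edge(a, b)
    cliques = [frozenset(c) for c in nx.find_cliques(g)]
    order = sorted(groups, key=lambda x: means[x])
    rank = {x: i for i, x in enumerate(order)}
    cliques.sort(key=lambda c: min(rank[x] for x in c))
    letters = {x: [] for x in groups}
    for i, c in enumerate(cliques):
        for x in c:
            letters[x].append(chr(ord("a") + i))
    return {x: "".join(sorted(v)) for x, v in letters.items()}


def share_letter(letters, a, b):
    return bool(set(letters[a]) & set(letters[b]))
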