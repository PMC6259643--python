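"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive every quantity from first principles (double
loops over atom pairs, Floyd-Warshall distances, normal equations) and share
no code with the implementation they check.
"""

import numpy as np


def _fw_distances(n, bonds):
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i, j, _ in bonds:
        D[i, j] = D[j, i] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def moran_brute(g, w, lag):
    n = g.n_atoms
    D = _fw_distances(n, g.bonds)
    wbar = sum(w) / n
    var = sum((wi - wbar) ** 2 for wi in w) / n
    if var == 0:
        return 0.0
    num, count = 0.0, 0
    for i in range(n):
        for j in range(n):
            if i != j and D[i, j] == lag:
                num += (w[i] - wbar) * (w[j] - wbar)
                count += 1
    if count == 0:
        return 0.0
    return (num / count) / var


def geary_brute(g, w, lag):
    n = g.n_atoms
    if n < 2:
        return 0.0
    D = _fw_distances(n, g.bonds)
    wbar = sum(w) / n
    var = sum((wi - wbar) ** 2 for wi in w) / (n - 1)
    if var == 0:
        return 0.0
    num, count = 0.0, 0
    for i in range(n):
        for j in range(n):
            if i != j and D[i, j] == lag:
                num += (w[i] - w[j]) ** 2
                count += 1
    if count == 0:
        return 0.0
    return (num / (2 * count)) / var


def ats_brute(g, w, lag):
    n = g.n_atoms
    D = _fw_distances(n, g.bonds)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] == lag:
                total += w[i] * w[j]
    return total


def ols_normal_equations(X, y):
    """(intercept, coefficients) via the normal equations (X'X)^-1 X'y."""
    M = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(M.T @ M, M.T @ y)
    return beta[0], beta[1:]


def kennard_stone_maximin_holds(dist, selected_order):
    """Check each selection (after the seed pair) attains the maximal minimum
    distance to the previously selected points."""
    sel = list(selected_order)
    n = dist.shape[0]
    for step in range(2, len(sel)):
        chosen = sel[step]
        prev = sel[:step]
        rest = [k for k in range(n) if k not in prev]
        best = max(min(dist[k, p] for p in prev) for k in rest)
        got = min(dist[chosen, p] for p in prev)
        if not np.isclose(got, best):
            return False
    return True
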