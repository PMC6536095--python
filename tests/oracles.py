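"""Independent brute-force oracles used to validate the LP solver.

The radial expansion factor is recomputed by exhaustive search over the
peer-weight simplex on an integer grid, refined locally over several
zoom rounds.  The objective phi(lambda) = min_r (lambda . Y_r) / y0_r is
concave over the convex feasible set, so zooming around the incumbent
converges; the grid never touches the LP code path.
"""

from itertools import combinations

import numpy as np


def _compositions(total: int, parts: int) -> np.ndarray:
    """All nonnegative integer vectors of length ``parts`` summing to
    ``total`` (stars and bars)."""
    if parts == 1:
        return np.array([[total]])
    rows = []
    for bars in combinations(range(total + parts - 1), parts - 1):
        prev = -1
        comp = []
        for b in bars:
            comp.append(b - prev - 1)
            prev = b
        comp.append(total + parts - 2 - prev)
        rows.append(comp)
    return np.asarray(rows, dtype=np.int64)


def _phi_values(L: np.ndarray, X: np.ndarray, Y: np.ndarray,
                x0: np.ndarray, y0: np.ndarray) -> np.ndarray:
    feasible = np.all(L @ X <= x0 * (1.0 + 1e-9) + 1e-12, axis=1)
    mask = y0 > 0
    ratios = (L @ Y)[:, mask] / y0[mask]
    phi = ratios.min(axis=1)
    phi[~feasible] = -np.inf
    return phi


def grid_phi(target: int, X: np.ndarray, Y: np.ndarray,
             coarse: int = 20, zoom: int = 6, rounds: int = 4) -> float:
    """Exhaustive-grid radial expansion factor for DMU ``target``.

    Final grid resolution is ``1 / (coarse * zoom**rounds)`` per weight
    (about 4e-5 with the defaults), giving phi to well under 1e-3 on
    unit-scale instances.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    x0, y0 = X[target], Y[target]
    if not np.any(y0 > 0):
        raise ValueError("degenerate target: all services zero")

    A = _compositions(coarse, n)
    D = coarse
    phi = _phi_values(A / D, X, Y, x0, y0)
    k = int(np.argmax(phi))
    best_phi, a = float(phi[k]), A[k]

    span = np.arange(-2 * zoom, 2 * zoom + 1)
    for _ in range(rounds):
        a = a * zoom
        D = D * zoom
        if n == 1:
            break
        grids = np.meshgrid(*([span] * (n - 1)), indexing="ij")
        d = np.stack([g.ravel() for g in grids], axis=1)
        d = np.column_stack([d, -d.sum(axis=1)])
        cand = a + d
        cand = cand[np.all(cand >= 0, axis=1)]
        phi = _phi_values(cand / D, X, Y, x0, y0)
        if phi.size and float(np.max(phi)) > best_phi:
            k = int(np.argmax(phi))
            best_phi, a = float(phi[k]), cand[k]
    return best_phi


def ols_closed_form(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Simple-regression normal equations, written out longhand."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    sxy = float(((x - xbar) * (y - ybar)).sum())
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    sst = float(((y - ybar) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sst if sst > 0 else float("nan")
    return slope, intercept, r2


def mean_sd_pairwise(values) -> tuple[float, float]:
    """Mean and sample SD via an independent pairwise-difference identity:
    SD^2 = sum_{i<j} (v_i - v_j)^2 / (n * (n - 1))."""
    v = np.asarray(list(values), dtype=float)
    n = v.size
    mean = float(v.sum() / n)
    acc = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            acc += (v[i] - v[j]) ** 2
    sd = (acc / (n * (n - 1))) ** 0.5 if n > 1 else 0.0
    return mean, sd
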