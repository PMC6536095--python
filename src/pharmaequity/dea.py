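"""Output-oriented, variable-returns-to-scale DEA envelopment solver.

For a target unit with needs ``x0`` and services ``y0``, the radial
expansion factor solves

    max  phi
    s.t. sum_j lambda_j x_j <= x0          (peer needs no greater)
         sum_j lambda_j y_j >= phi * y0    (peer services expanded)
         sum_j lambda_j = 1,  lambda >= 0  (variable returns to scale)

The equity index is EI = 1/phi: 1 on the frontier, below 1 a relative
coverage deficit.  A second phase fixes phi at its optimum and maximises
total slack, yielding the projected ("optimal") service vector
``phi * y0 + output_slacks`` the unit would receive on the frontier.

LPs are solved with HiGHS via :func:`scipy.optimize.linprog`; feasibility
is guaranteed because the target can always reference itself (phi = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .dataset import Dataset, ValidationError

_FRONTIER_TOL = 1e-6


class SolverError(RuntimeError):
    """The LP backend failed on a well-posed instance."""


@dataclass
class EfficiencyResult:
    """One DEA solve for one target DMU.

    Attributes
    ----------
    phi : float
        Radial service-expansion factor, >= 1.
    ei : float
        Equity index 1/phi in (0, 1]; 0 for a degenerate all-zero-services
        target, where no radial expansion is defined.
    lambdas : dict
        Convex peer weights (sum to 1).  Alternative optimal supports are
        possible; only phi, ei and the projected vector are contractual.
    output_slacks, input_slacks : ndarray
        Residual shortfall/excess after radial expansion (phase 2).
    projected : ndarray
        Frontier service target, ``phi * y0 + output_slacks``.
    """

    dmu_id: str
    phi: float
    ei: float
    lambdas: dict[str, float]
    output_slacks: np.ndarray
    input_slacks: np.ndarray
    projected: np.ndarray
    needs_subset: tuple[str, ...]
    services_subset: tuple[str, ...]
    degenerate: bool = False
    on_frontier: bool = field(init=False)

    def __post_init__(self) -> None:
        self.on_frontier = (
            not self.degenerate
            and self.phi <= 1.0 + _FRONTIER_TOL
            and float(np.max(self.output_slacks, initial=0.0)) <= _FRONTIER_TOL
            and float(np.max(self.input_slacks, initial=0.0)) <= _FRONTIER_TOL
        )


def equity_index(phi: float) -> float:
    """EI = 1/phi; requires phi >= 1 (up to solver tolerance)."""
    if phi < 1.0 - 1e-9:
        raise ValidationError(f"expansion factor must be >= 1, got {phi}")
    return 1.0 / max(phi, 1.0)


def _subset_indices(names: Sequence[str], subset) -> tuple[list[int], tuple[str, ...]]:
    if subset is None:
        subset = names
    subset = tuple(subset)
    if not subset:
        raise ValidationError("variable subset must be non-empty")
    idx = []
    for nm in subset:
        if nm not in names:
            raise ValidationError(f"unknown variable {nm!r}")
        idx.append(list(names).index(nm))
    return idx, subset


def solve_output_vrs(
    target: str,
    dataset: Dataset,
    needs_subset: Sequence[str] | None = None,
    services_subset: Sequence[str] | None = None,
    two_phase: bool = True,
) -> EfficiencyResult:
    """Solve the output-oriented VRS model for one target DMU.

    ``needs_subset`` / ``services_subset`` restrict the variable set (used
    by the MDEA ensemble); ``None`` means the full model.  With
    ``two_phase=False`` only phi/EI are computed and slacks are reported as
    zero — sufficient for ensemble EI distributions, roughly halving cost.
    """
    n_idx, n_names = _subset_indices(dataset.needs_names, needs_subset)
    s_idx, s_names = _subset_indices(dataset.services_names, services_subset)
    k = dataset.index_of(target)
    X = dataset.needs_matrix[:, n_idx]  # (n, m)
    Y = dataset.services_matrix[:, s_idx]  # (n, s)
    x0, y0 = X[k], Y[k]
    n, m = X.shape
    s = Y.shape[1]

    bad = [nm for j, nm in zip(n_idx, n_names) if dataset.needs_matrix[k, j] <= 0]
    if bad:
        raise ValidationError(
            f"non-positive need(s) {bad} for dmu {target!r}: DEA inputs must be > 0"
        )

    if np.all(y0 == 0.0):
        # no radial expansion of a zero service vector; flagged, EI := 0
        lam = {target: 1.0}
        return EfficiencyResult(
            target, np.inf, 0.0, lam,
            np.zeros(s), np.zeros(m), np.zeros(s),
            n_names, s_names, degenerate=True,
        )

    # ---- phase 1: maximise phi --------------------------------------------
    # variables: [phi, lambda_1..n]
    c = np.zeros(n + 1)
    c[0] = -1.0
    A_ub = np.zeros((m + s, n + 1))
    b_ub = np.zeros(m + s)
    A_ub[:m, 1:] = X.T
    b_ub[:m] = x0
    A_ub[m:, 0] = y0
    A_ub[m:, 1:] = -Y.T
    A_eq = np.zeros((1, n + 1))
    A_eq[0, 1:] = 1.0
    bounds = [(1.0, None)] + [(0.0, None)] * n
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0],
                  bounds=bounds, method="highs")
    if not res.success:
        raise SolverError(f"phase-1 LP failed for {target!r}: {res.message}")
    phi = float(res.x[0])
    lam = np.asarray(res.x[1:], dtype=float)

    if not two_phase:
        lam_map = {dataset.dmu_ids[j]: float(lam[j]) for j in range(n) if lam[j] > 1e-10}
        return EfficiencyResult(
            target, phi, equity_index(phi), lam_map,
            np.zeros(s), np.zeros(m), lam @ Y,
            n_names, s_names,
        )

    # ---- phase 2: maximise total slack at fixed phi -----------------------
    # variables: [lambda_1..n, s_in_1..m, s_out_1..s]
    nv = n + m + s
    c2 = np.zeros(nv)
    c2[n:] = -1.0
    A_eq2 = np.zeros((m + s + 1, nv))
    b_eq2 = np.zeros(m + s + 1)
    A_eq2[:m, :n] = X.T
    A_eq2[:m, n:n + m] = np.eye(m)
    b_eq2[:m] = x0
    A_eq2[m:m + s, :n] = Y.T
    A_eq2[m:m + s, n + m:] = -np.eye(s)
    b_eq2[m:m + s] = phi * y0
    A_eq2[-1, :n] = 1.0
    b_eq2[-1] = 1.0
    res2 = linprog(c2, A_eq=A_eq2, b_eq=b_eq2,
                   bounds=[(0.0, None)] * nv, method="highs")
    if not res2.success:
        # phi* on the boundary can be marginally infeasible in phase 2;
        # back off by one part in 1e9
        b_eq2[m:m + s] = phi * (1.0 - 1e-9) * y0
        res2 = linprog(c2, A_eq=A_eq2, b_eq=b_eq2,
                       bounds=[(0.0, None)] * nv, method="highs")
    if not res2.success:
        raise SolverError(f"phase-2 LP failed for {target!r}: {res2.message}")
    lam = np.asarray(res2.x[:n], dtype=float)
    s_in = np.maximum(res2.x[n:n + m], 0.0)
    s_out = np.maximum(res2.x[n + m:], 0.0)
    lam_map = {dataset.dmu_ids[j]: float(lam[j]) for j in range(n) if lam[j] > 1e-10}
    return EfficiencyResult(
        target, phi, equity_index(phi), lam_map,
        np.asarray(s_out), np.asarray(s_in), lam @ Y,
        n_names, s_names,
    )


def peer_target(result: EfficiencyResult, dataset: Dataset) -> np.ndarray:
    """Projected services for the target: the peer combination's outputs.

    Equals ``phi * y0 + output_slacks`` at the phase-2 optimum, and is
    componentwise >= the observed services.
    """
    if result.degenerate:
        return np.zeros(len(result.services_subset))
    s_idx = [list(dataset.services_names).index(nm) for nm in result.services_subset]
    Y = dataset.services_matrix[:, s_idx]
    out = np.zeros(Y.shape[1])
    for dmu_id, w in result.lambdas.items():
        out += w * Y[dataset.index_of(dmu_id)]
    return out


class DEAModel:
    """Full-variable DEA equity model over a dataset (statsmodels-style).

    ``DEAModel(dataset).fit()`` solves the two-phase output-oriented VRS
    program once per DMU and returns a :class:`DEAResults`.
    """

    def __init__(self, dataset: Dataset):
        if len(dataset) < 2:
            raise ValidationError("frontier computation needs >= 2 DMUs")
        self.dataset = dataset

    @classmethod
    def from_dataframe(cls, df, needs_names=None, services_names=None):
        from .dataset import DEFAULT_NEEDS, DEFAULT_SERVICES
        return cls(Dataset.from_frame(
            df, needs_names or DEFAULT_NEEDS, services_names or DEFAULT_SERVICES
        ))

    def fit(self) -> "DEAResults":
        results = [
            solve_output_vrs(r.dmu_id, self.dataset) for r in self.dataset
        ]
        return DEAResults(self, results)


class DEAResults:
    """Per-DMU efficiency results of a fitted :class:`DEAModel`."""

    def __init__(self, model: DEAModel, results: list[EfficiencyResult]):
        self.model = model
        self.results = results
        self._by_id = {r.dmu_id: r for r in results}

    def __getitem__(self, dmu_id: str) -> EfficiencyResult:
        return self._by_id[dmu_id]

    @property
    def ei(self) -> dict[str, float]:
        return {r.dmu_id: r.ei for r in self.results}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "dmu_id": [r.dmu_id for r in self.results],
                "phi": [r.phi for r in self.results],
                "ei": [r.ei for r in self.results],
                "on_frontier": [r.on_frontier for r in self.results],
            }
        )

    def projection_table(self):
        from .reallocation import build_projection_table

        return build_projection_table(self.model.dataset, self.results)

    def summary(self) -> str:
        df = self.to_frame()
        lines = ["Output-oriented VRS DEA (full variable set)",
                 f"DMUs: {len(df)}   on frontier: {int(df.on_frontier.sum())}",
                 ""]
        lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)
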