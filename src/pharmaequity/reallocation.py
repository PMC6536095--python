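"""Frontier projections, capture shares and budget-constrained reallocation.

Three layers of "how much should each state receive":

* **Projection** (no budget constraint): the frontier service target for
  every DMU, from the full-model DEA peer combination.
* **Capture / required increase**: how far observed transfers fall short of
  the projected ones, per state (``100 * effective / projected``) and in
  aggregate (``100 * (projected - effective) / projected``).
* **Reallocation** (budget constrained): redistribute the *existing* budget
  in proportion to projected values.  Under the *complementary* hypothesis
  each programme keeps its own budget; under the *substitution* hypothesis
  the programmes are treated as mutually exclusive and their budgets are
  pooled.  Both schemes conserve the relevant total exactly.

The proportional rule — coefficient = projected / (sum of projected over
the redistribution pool), allocation = coefficient * (pooled effective
budget) — was reverse-engineered from the published 2013 state-level
allocation tables and reproduces their printed cells to print rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataset import Dataset, ValidationError
from .dea import EfficiencyResult, peer_target

HYPOTHESES = ("complementary", "substitution")


@dataclass
class ProjectionTable:
    """Long-format effective vs projected (frontier) values.

    ``frame`` columns: dmu_id, program, effective, projected — values in
    millions of currency.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"dmu_id", "program", "effective", "projected"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"projection table missing columns {sorted(missing)}")

    @property
    def programs(self) -> list[str]:
        return list(dict.fromkeys(self.frame["program"]))

    def totals(self) -> pd.DataFrame:
        """Effective and projected totals per program."""
        return self.frame.groupby("program", sort=False)[
            ["effective", "projected"]
        ].sum()

    def wide(self) -> pd.DataFrame:
        """One row per DMU with effective_/projected_ columns per program."""
        w = self.frame.pivot(index="dmu_id", columns="program",
                             values=["effective", "projected"])
        w.columns = [f"{a}_{b}" for a, b in w.columns]
        return w.reset_index()


@dataclass
class ReallocationResult:
    """Budget-constrained allocation under one hypothesis.

    ``frame`` columns: dmu_id, program, coefficient, allocated.  Full
    precision is kept; :meth:`to_frame` applies the reporting rounding
    (half-even, 3 decimals for coefficients, 2 for values).
    """

    hypothesis: str
    frame: pd.DataFrame

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        df = self.frame.copy()
        if rounded:
            df["coefficient"] = df["coefficient"].round(3)
            df["allocated"] = df["allocated"].round(2)
        return df


def build_projection_table(
    dataset: Dataset, dea_results: Sequence[EfficiencyResult]
) -> ProjectionTable:
    """Frontier projections from full-model DEA solves.

    Effective values are the observed services; projected values are the
    peer targets (radial expansion plus output slacks).  Degenerate
    all-zero-services DMUs project to zero.
    """
    rows = []
    for res in dea_results:
        if tuple(res.services_subset) != tuple(dataset.services_names):
            raise ValidationError(
                f"projection requires full-model results (dmu {res.dmu_id})"
            )
        eff = dataset.services_matrix[dataset.index_of(res.dmu_id)]
        proj = peer_target(res, dataset)
        for p, program in enumerate(dataset.services_names):
            rows.append(
                {
                    "dmu_id": res.dmu_id,
                    "program": program,
                    "effective": float(eff[p]),
                    "projected": float(proj[p]),
                }
            )
    return ProjectionTable(pd.DataFrame(rows))


def capture_percentage(effective: float, projected: float,
                       decimals: int | None = 1) -> float:
    """Share of the frontier-optimal value actually received, in percent.

    ``100 * effective / projected``, reported to one decimal by default;
    NaN (flagged missing) when the projected value is zero.
    """
    if projected == 0:
        return float("nan")
    pct = 100.0 * effective / projected
    return float(np.round(pct, decimals)) if decimals is not None else pct


def required_increase(effective_total: float, projected_total: float,
                      decimals: int | None = 2) -> float:
    """Aggregate increase needed to put every DMU on the frontier, percent.

    ``100 * (projected - effective) / projected`` — the shortfall as a share
    of the frontier-optimal total.
    """
    if not projected_total >= effective_total > 0:
        raise ValidationError(
            "need projected_total >= effective_total > 0, got "
            f"({effective_total}, {projected_total})"
        )
    pct = 100.0 * (projected_total - effective_total) / projected_total
    return float(np.round(pct, decimals)) if decimals is not None else pct


def reallocate(projection: ProjectionTable, hypothesis: str) -> ReallocationResult:
    """Redistribute existing budgets in proportion to projected values.

    complementary
        Per program p: ``coef_i = projected_i / sum_j projected_j`` within p,
        ``allocated_i = coef_i * sum_j effective_j`` within p.  Each
        programme's budget is conserved.
    substitution
        Programmes pooled: coefficients normalise over every DMU x program
        cell and the pooled effective total is redistributed.  The grand
        budget is conserved.
    """
    if hypothesis not in HYPOTHESES:
        raise ValidationError(f"hypothesis must be one of {HYPOTHESES}")
    df = projection.frame.copy()
    if hypothesis == "complementary":
        grp = df.groupby("program", sort=False)
        proj_tot = grp["projected"].transform("sum")
        eff_tot = grp["effective"].transform("sum")
    else:
        proj_tot = df["projected"].sum()
        eff_tot = df["effective"].sum()
    if np.any(np.asarray(proj_tot) == 0.0):
        raise ValidationError("zero projected total: coefficients undefined")
    df["coefficient"] = df["projected"] / proj_tot
    df["allocated"] = df["coefficient"] * eff_tot
    return ReallocationResult(
        hypothesis, df[["dmu_id", "program", "coefficient", "allocated"]]
    )


def deficit_regression(
    mean_eis: Mapping[str, float], pharmacy_ratio: Mapping[str, float]
) -> tuple[float, float, float]:
    """OLS of the coverage deficit (1 - mean EI) on the accredited-pharmacy
    ratio; returns (slope, intercept, r_squared)."""
    ids = list(mean_eis)
    if len(ids) < 3:
        raise ValidationError("deficit_regression requires >= 3 DMUs")
    y = np.array([1.0 - mean_eis[i] for i in ids])
    x = np.array([pharmacy_ratio[i] for i in ids])
    if np.ptp(x) == 0.0:
        raise ValidationError("pharmacy ratio has zero variance")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.params[1]), float(fit.params[0]), float(fit.rsquared)
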