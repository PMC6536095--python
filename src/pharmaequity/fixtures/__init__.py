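"""Bundled reference tables: the published 2013 state-level results.

The underlying study's per-state raw needs (survey and administrative
sources) were never published, so its headline equity indices cannot be
recomputed from scratch.  What *was* published — per-state equity indices
with SEs and CIs, effective and projected transfer values, and the
budget-constrained allocations — is bundled verbatim as small CSVs and
drives both the arithmetic-reproduction test-suite and the
``reproduce`` command.

Known quirks of the printed tables, preserved as printed unless noted:

* The grand effective total is printed as 2,850.00 although the 27 state
  rows sum to 2,850.34; recomputation here always uses exact sums.
* The Minas Gerais substitution-BPPP coefficient is garbled in the source;
  the bundled value 0.070 is reconstructed from the (unambiguous) printed
  allocation 200.16 and the projected totals.
* One descriptive row reports hypertension prevalence as "1.2 thousand"
  while the narrative says over one million diagnoses; the unit for that
  row is likely millions.  Stored verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

_PKG = "pharmaequity.fixtures"


def _read(name: str) -> pd.DataFrame:
    with resources.files(_PKG).joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class FixtureTable2Row:
    """Equity index summary for one state (or a regional average row)."""

    dmu_id: str
    name: str
    region: str
    is_region: bool
    ei_mean: float
    se: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class FixtureTable3Row:
    """Effective and projected transfer values for one state, in millions."""

    dmu_id: str
    name: str
    region: str
    is_region: bool
    effective_bppp: float
    effective_bcpa: float
    effective_total: float
    projected_bppp: float
    projected_bcpa: float
    projected_total: float


def load_fixture_table1() -> pd.DataFrame:
    """Published descriptive statistics (mean, SD) of the variable set."""
    return _read("table1_descriptives.csv")


def load_fixture_table2(include_regions: bool = False) -> list[FixtureTable2Row]:
    """Per-state equity index, SE and 95% CI (27 states; optionally the 5
    regional average rows)."""
    df = _read("table2_equity_index.csv")
    rows = [
        FixtureTable2Row(
            r.dmu_id, r.name, r.region, bool(r.is_region),
            float(r.ei_mean), float(r.se), float(r.ci_low), float(r.ci_high),
        )
        for r in df.itertuples()
    ]
    if not include_regions:
        rows = [r for r in rows if not r.is_region]
    return rows


def load_fixture_table3(include_regions: bool = False) -> list[FixtureTable3Row]:
    """Per-state effective vs projected values (27 states; optionally the
    regional subtotal and grand-total rows)."""
    df = _read("table3_projections.csv")
    rows = [
        FixtureTable3Row(
            r.dmu_id, r.name, r.region, bool(r.is_region),
            float(r.effective_bppp), float(r.effective_bcpa),
            float(r.effective_total),
            float(r.projected_bppp), float(r.projected_bcpa),
            float(r.projected_total),
        )
        for r in df.itertuples()
    ]
    if not include_regions:
        rows = [r for r in rows if not r.is_region]
    return rows


def load_fixture_table4(include_regions: bool = False) -> pd.DataFrame:
    """Published budget-constrained coefficients and allocations under both
    hypotheses (wide frame: comp_/sub_ columns)."""
    df = _read("table4_reallocation.csv")
    if not include_regions:
        df = df[df["is_region"] == 0].reset_index(drop=True)
    return df


def fixture_projection_table():
    """The bundled effective/projected values as a :class:`ProjectionTable`
    ready for :func:`pharmaequity.reallocation.reallocate`."""
    from ..reallocation import ProjectionTable

    rows = []
    for r in load_fixture_table3():
        for prog, eff, proj in (
            ("bppp", r.effective_bppp, r.projected_bppp),
            ("bcpa", r.effective_bcpa, r.projected_bcpa),
        ):
            rows.append(
                {"dmu_id": r.dmu_id, "program": prog,
                 "effective": eff, "projected": proj}
            )
    return ProjectionTable(pd.DataFrame(rows))
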