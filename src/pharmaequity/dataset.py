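"""State-level needs/services datasets for equity frontier analysis.

A dataset holds one row per decision-making unit (DMU) — in the motivating
application, the 26 Brazilian states plus the Federal District — with a
*needs* vector (disease prevalence counts, elderly population, a negative
income index) and a *services* vector (pharmaceutical-assistance transfer
values, in millions of reais).  DEA requires strictly positive inputs, so
raw income must be converted to a positive, income-decreasing "negative
income" index before loading (see :func:`negative_income_index`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

REGIONS = ("North", "Northeast", "Southeast", "South", "Midwest")

#: canonical needs columns, in thousands of persons except the income index
DEFAULT_NEEDS = (
    "hypertension_thousands",
    "diabetics_thousands",
    "asthmatics_thousands",
    "elderly_thousands",
    "negative_income_index",
)
#: canonical services columns, in millions of currency
DEFAULT_SERVICES = ("bppp_value_millions", "bcpa_value_millions")


class SchemaError(ValueError):
    """A required column is missing or unresolvable."""


class ValidationError(ValueError):
    """A value violates a dataset invariant; names the offending DMU/field."""


@dataclass(frozen=True)
class DMURecord:
    """One decision-making unit: id, display name, region, needs, services."""

    dmu_id: str
    name: str
    region: str
    needs: Mapping[str, float]
    services: Mapping[str, float]

    @property
    def degenerate(self) -> bool:
        """True when every service is zero (no radial expansion defined)."""
        return all(v == 0.0 for v in self.services.values())


@dataclass
class Dataset:
    """Ordered collection of DMU records sharing one variable layout.

    Provides dense numpy views (``needs_matrix``, ``services_matrix``) used
    by the DEA solvers; row order is preserved and meaningful only for
    reproducibility, never for results.
    """

    records: list[DMURecord]
    needs_names: tuple[str, ...] = DEFAULT_NEEDS
    services_names: tuple[str, ...] = DEFAULT_SERVICES
    _needs: np.ndarray = field(init=False, repr=False)
    _services: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.needs_names = tuple(self.needs_names)
        self.services_names = tuple(self.services_names)
        ids = [r.dmu_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate dmu_id(s): {dup}")
        for r in self.records:
            for nm in self.needs_names:
                v = float(r.needs[nm])
                if not np.isfinite(v) or v < 0:
                    raise ValidationError(
                        f"negative or non-finite need {nm}={v} for dmu {r.dmu_id}"
                    )
            for nm in self.services_names:
                v = float(r.services[nm])
                if not np.isfinite(v) or v < 0:
                    raise ValidationError(
                        f"negative or non-finite service {nm}={v} for dmu {r.dmu_id}"
                    )
        self._needs = np.array(
            [[float(r.needs[nm]) for nm in self.needs_names] for r in self.records],
            dtype=float,
        )
        self._services = np.array(
            [[float(r.services[nm]) for nm in self.services_names] for r in self.records],
            dtype=float,
        )

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def dmu_ids(self) -> list[str]:
        return [r.dmu_id for r in self.records]

    def index_of(self, dmu_id: str) -> int:
        for i, r in enumerate(self.records):
            if r.dmu_id == dmu_id:
                return i
        raise KeyError(f"unknown dmu_id {dmu_id!r}")

    @property
    def needs_matrix(self) -> np.ndarray:
        """(n_dmus, n_needs) float array, row order as loaded."""
        return self._needs

    @property
    def services_matrix(self) -> np.ndarray:
        """(n_dmus, n_services) float array, row order as loaded."""
        return self._services

    @property
    def region_map(self) -> dict[str, str]:
        return {r.dmu_id: r.region for r in self.records}

    # -- frame conversion ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"dmu_id": r.dmu_id, "name": r.name, "region": r.region}
            row.update({nm: r.needs[nm] for nm in self.needs_names})
            row.update({nm: r.services[nm] for nm in self.services_names})
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        needs_names: Sequence[str] = DEFAULT_NEEDS,
        services_names: Sequence[str] = DEFAULT_SERVICES,
    ) -> "Dataset":
        required = ["dmu_id", *needs_names, *services_names]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {missing}")
        records = []
        for _, row in df.iterrows():
            records.append(
                DMURecord(
                    dmu_id=str(row["dmu_id"]),
                    name=str(row.get("name", row["dmu_id"])),
                    region=str(row.get("region", "")),
                    needs={nm: float(row[nm]) for nm in needs_names},
                    services={nm: float(row[nm]) for nm in services_names},
                )
            )
        return cls(records, tuple(needs_names), tuple(services_names))


@dataclass(frozen=True)
class ColumnMap:
    """Maps canonical column names to the CSV's header names.

    ``columns`` maps canonical -> actual header; canonical names absent from
    the mapping are looked up verbatim.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    needs_names: tuple[str, ...] = DEFAULT_NEEDS
    services_names: tuple[str, ...] = DEFAULT_SERVICES

    def resolve(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


def load_dataset(path, config: ColumnMap | None = None) -> Dataset:
    """Read a DMU table from CSV (UTF-8, comma separated, dot decimal).

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` for negative needs/services, naming the
    offending column or DMU.  Row order is preserved.
    """
    config = config or ColumnMap()
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    canonical = ["dmu_id", *config.needs_names, *config.services_names]
    rename = {}
    for canon in canonical + ["name", "region"]:
        actual = config.resolve(canon)
        if actual in df.columns:
            rename[actual] = canon
        elif canon in ("name", "region"):
            continue
        else:
            raise SchemaError(f"missing column: {actual!r} (for {canon!r})")
    df = df.rename(columns=rename)
    return Dataset.from_frame(df, config.needs_names, config.services_names)


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset to CSV; 17 significant digits round-trip exactly."""
    df = dataset.to_frame()
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.17g")
    text = buf.getvalue()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(text)


def descriptive_stats(dataset: Dataset) -> pd.DataFrame:
    """Unweighted mean and sample SD (ddof=1) per needs/services column."""
    if len(dataset) < 2:
        raise ValidationError("descriptive_stats requires at least 2 records")
    df = dataset.to_frame()
    cols = list(dataset.needs_names) + list(dataset.services_names)
    out = pd.DataFrame(
        {"mean": df[cols].mean(), "sd": df[cols].std(ddof=1)}
    )
    out.index.name = "variable"
    return out


def negative_income_index(
    income: Sequence[float], eps: float = 0.01
) -> np.ndarray:
    """Strictly positive, income-decreasing need index.

    ``(max(income) - income) / sd(income) + eps``: poorer units get a larger
    index, encoding a greater claim on subsidised drug provision.  Any
    strictly positive decreasing transform serves; this one is unit-free up
    to the additive floor ``eps`` that keeps the richest unit's index
    positive (DEA inputs must be > 0).
    """
    inc = np.asarray(income, dtype=float)
    if inc.size < 2:
        raise ValidationError("negative_income_index requires >= 2 values")
    sd = float(np.std(inc, ddof=1))
    if sd == 0.0:
        return np.full(inc.shape, eps)
    return (inc.max() - inc) / sd + eps
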