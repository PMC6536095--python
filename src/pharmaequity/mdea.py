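"""Multiple-DEA (MDEA): subset-model ensemble equity indices.

With few DMUs and many variables, plain DEA pushes most units onto the
frontier and loses discriminatory power.  MDEA runs the DEA for *every*
non-empty subset pair of needs and services — (2^m - 1)(2^s - 1) submodels,
93 for the 5-need/2-service layout — and summarises each DMU's EI
distribution by its mean, standard error and a normal 95% confidence
interval.  The ensemble is exhaustive and deterministic: no sampling, no
randomness, bit-reproducible across runs.

By dimension monotonicity (adding variables can only enlarge the feasible
peer set of each submodel's frontier) the full model attains the ensemble
maximum, so mean EI <= full-model EI for every DMU.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import Dataset, ValidationError
from .dea import DEAModel, DEAResults, solve_output_vrs

Z_95 = 1.96  # fixed normal quantile for the 95% interval


@dataclass(frozen=True)
class SubmodelSpec:
    """One needs-subset x services-subset combination."""

    needs_subset: tuple[str, ...]
    services_subset: tuple[str, ...]


@dataclass
class MDEAResult:
    """Ensemble EI distribution for one DMU, with mean/SE/CI."""

    dmu_id: str
    ei_values: np.ndarray
    mean_ei: float
    se: float
    ci_low: float
    ci_high: float
    n_models: int
    full_model_ei: float
    n_degenerate: int = 0


def enumerate_submodels(
    needs_names: Sequence[str], services_names: Sequence[str]
) -> list[SubmodelSpec]:
    """All non-empty subset pairs, ordered lexicographically by bitmask.

    Bit ``i`` of a mask selects variable ``i`` in the dataset's declared
    order; needs masks vary slowest.  The last element is always the full
    model.
    """
    if not needs_names or not services_names:
        raise ValidationError("needs and services label sets must be non-empty")
    needs_names = tuple(needs_names)
    services_names = tuple(services_names)
    specs = []
    for nmask in range(1, 1 << len(needs_names)):
        nsub = tuple(nm for i, nm in enumerate(needs_names) if nmask >> i & 1)
        for smask in range(1, 1 << len(services_names)):
            ssub = tuple(nm for i, nm in enumerate(services_names) if smask >> i & 1)
            specs.append(SubmodelSpec(nsub, ssub))
    return specs


def summarize(
    ei_values: Iterable[float], se_mode: str = "sd_over_sqrt_n", z: float = Z_95
) -> tuple[float, float, float, float]:
    """Mean, SE and symmetric normal CI of an EI ensemble.

    ``se_mode='sd_over_sqrt_n'`` (default) treats the ensemble as a sample
    of size n; ``'sd'`` reports the raw ensemble spread.  The CI is
    ``mean -/+ z*se`` and is deliberately *not* truncated at 1: an upper
    bound above 1 simply reflects ensemble spread around a near-frontier
    unit.
    """
    vals = np.asarray(list(ei_values), dtype=float)
    if vals.size == 0:
        raise ValidationError("summarize requires at least one EI value")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    if se_mode == "sd_over_sqrt_n":
        se = sd / np.sqrt(vals.size)
    elif se_mode == "sd":
        se = sd
    else:
        raise ValidationError(f"unknown se_mode {se_mode!r}")
    return mean, se, mean - z * se, mean + z * se


def run_mdea(
    dataset: Dataset, se_mode: str = "sd_over_sqrt_n"
) -> list[MDEAResult]:
    """Run the exhaustive submodel ensemble for every DMU."""
    return MDEAModel(dataset, se_mode=se_mode).fit().results


def regional_average(
    mean_eis: Mapping[str, float], region_map: Mapping[str, str]
) -> dict[str, float]:
    """Unweighted mean of member-DMU mean EIs per region."""
    sums: dict[str, list[float]] = {}
    for dmu_id, ei in mean_eis.items():
        if dmu_id not in region_map:
            raise ValidationError(f"dmu {dmu_id!r} has no region mapping")
        sums.setdefault(region_map[dmu_id], []).append(ei)
    return {reg: float(np.mean(v)) for reg, v in sums.items()}


class MDEAModel:
    """Subset-ensemble equity model (statsmodels-style Model object).

    Parameters
    ----------
    dataset : Dataset
        Validated DMU table; needs strictly positive.
    se_mode : {'sd_over_sqrt_n', 'sd'}
        How the printed "standard error" is computed from the ensemble.
    z : float
        Normal quantile for the confidence interval (default 1.96).
    """

    def __init__(self, dataset: Dataset, se_mode: str = "sd_over_sqrt_n",
                 z: float = Z_95):
        if len(dataset) < 2:
            raise ValidationError("MDEA needs >= 2 DMUs")
        if se_mode not in ("sd_over_sqrt_n", "sd"):
            raise ValidationError(f"unknown se_mode {se_mode!r}")
        self.dataset = dataset
        self.se_mode = se_mode
        self.z = z
        self.submodels = enumerate_submodels(
            dataset.needs_names, dataset.services_names
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, needs_names=None,
                       services_names=None, **kwargs) -> "MDEAModel":
        from .dataset import DEFAULT_NEEDS, DEFAULT_SERVICES
        ds = Dataset.from_frame(
            df, needs_names or DEFAULT_NEEDS, services_names or DEFAULT_SERVICES
        )
        return cls(ds, **kwargs)

    def fit(self) -> "MDEAResults":
        """Solve every submodel LP for every DMU and aggregate.

        Only phase 1 (the radial factor) is needed for the ensemble; the
        full model is additionally solved in two phases so projections and
        slacks are available from the same fit.
        """
        full = DEAModel(self.dataset).fit()
        results = []
        for rec in self.dataset:
            eis = np.empty(len(self.submodels))
            n_degenerate = 0
            for i, spec in enumerate(self.submodels):
                r = solve_output_vrs(
                    rec.dmu_id, self.dataset,
                    spec.needs_subset, spec.services_subset,
                    two_phase=False,
                )
                eis[i] = r.ei
                n_degenerate += int(r.degenerate)
            mean, se, lo, hi = summarize(eis, self.se_mode, self.z)
            results.append(
                MDEAResult(
                    rec.dmu_id, eis, mean, se, lo, hi,
                    len(self.submodels), full[rec.dmu_id].ei, n_degenerate,
                )
            )
        return MDEAResults(self, results, full)


class MDEAResults:
    """Fitted MDEA ensemble: per-DMU EI distributions and summaries."""

    def __init__(self, model: MDEAModel, results: list[MDEAResult],
                 full_model: DEAResults):
        self.model = model
        self.results = results
        self.full_model = full_model
        self._by_id = {r.dmu_id: r for r in results}

    def __getitem__(self, dmu_id: str) -> MDEAResult:
        return self._by_id[dmu_id]

    @property
    def mean_ei(self) -> dict[str, float]:
        return {r.dmu_id: r.mean_ei for r in self.results}

    def regional_averages(self) -> dict[str, float]:
        return regional_average(self.mean_ei, self.model.dataset.region_map)

    def to_frame(self) -> pd.DataFrame:
        region = self.model.dataset.region_map
        return pd.DataFrame(
            {
                "dmu_id": [r.dmu_id for r in self.results],
                "region": [region[r.dmu_id] for r in self.results],
                "ei_mean": [r.mean_ei for r in self.results],
                "se": [r.se for r in self.results],
                "ci_low": [r.ci_low for r in self.results],
                "ci_high": [r.ci_high for r in self.results],
                "n_models": [r.n_models for r in self.results],
                "n_degenerate": [r.n_degenerate for r in self.results],
            }
        )

    def summary(self) -> str:
        df = self.to_frame().drop(columns="n_degenerate")
        regional = self.regional_averages()
        lines = [
            "Multiple-DEA equity indices (output-oriented, VRS)",
            f"DMUs: {len(df)}   submodels per DMU: {len(self.model.submodels)}"
            f"   se_mode: {self.model.se_mode}",
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            "",
            "Regional averages:",
        ]
        for reg, val in regional.items():
            lines.append(f"  {reg:<12s} {val:.4f}")
        return "\n".join(lines)
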