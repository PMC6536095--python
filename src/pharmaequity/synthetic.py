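"""Synthetic state-level data with a planted efficiency frontier.

The raw per-state needs behind the published equity indices were never
released, so end-to-end testing relies on generated data whose ground truth
is known by construction.  The generator emulates the published variable
layout — five needs (three chronic-disease prevalence counts and an elderly
count in thousands, a dimensionless negative-income index) and two service
transfers in millions — at the published orders of magnitude, with heavy
right skew across units (log-normal draws).

Planted structure: ``n_frontier`` units sit exactly on a concave increasing
service frontier ``y = a * z^0.7`` (or linear) of an aggregate need ``z``;
every other unit copies a frontier unit's needs (jittered upward by at most
1%) and receives its services scaled by a known multiplier ``u`` in (0, 1].
Because the anchor unit then weakly dominates the copy, the copy's true
radial inefficiency is ``1/u`` and its full-model equity index recovers
``u`` up to the jitter (within about 0.7% for 1% jitter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import (
    DEFAULT_NEEDS,
    DEFAULT_SERVICES,
    Dataset,
    DMURecord,
    REGIONS,
    ValidationError,
)

#: per-variable (median, log-sd) of the log-normal needs draws, matched in
#: order of magnitude to the published 2013 descriptives
DEFAULT_NEEDS_SCALE = (
    (1200.0, 0.8),   # hypertension, thousands
    (340.0, 0.8),    # diabetics, thousands
    (240.0, 0.8),    # asthmatics, thousands
    (980.0, 0.6),    # elderly, thousands
    (0.54, 0.5),     # negative income index
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults mirror the 27-unit federative layout."""

    n_dmus: int = 27
    n_frontier: int = 5
    inefficiency_range: tuple[float, float] = (0.6, 1.0)
    needs_scale: tuple[tuple[float, float], ...] = DEFAULT_NEEDS_SCALE
    seed: int = 0
    frontier_shape: str = "concave_power"  # or "linear"
    jitter: float = 0.01

    def __post_init__(self) -> None:
        lo, hi = self.inefficiency_range
        if not (self.n_dmus >= 3 and 2 <= self.n_frontier <= self.n_dmus):
            raise ValidationError("need n_dmus >= 3 and 2 <= n_frontier <= n_dmus")
        if not (0 < lo <= hi <= 1):
            raise ValidationError("inefficiency_range must be within (0, 1]")
        if self.frontier_shape not in ("linear", "concave_power"):
            raise ValidationError(f"unknown frontier_shape {self.frontier_shape!r}")
        if len(self.needs_scale) != len(DEFAULT_NEEDS):
            raise ValidationError("needs_scale must give (median, sigma) per need")


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-DMU radial inefficiency multiplier."""

    true_u: dict[str, float]
    is_frontier: dict[str, bool]
    anchor: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.true_u)
        return pd.DataFrame(
            {
                "dmu_id": ids,
                "true_u": [self.true_u[i] for i in ids],
                "is_frontier": [self.is_frontier[i] for i in ids],
                "anchor": [self.anchor.get(i, "") for i in ids],
            }
        )


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    # one counter-based root, spawned sub-streams: draws are independent of
    # the order other variables are drawn in
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate(config: SyntheticConfig) -> tuple[Dataset, SyntheticTruth]:
    """Generate (dataset, truth); bit-reproducible for a given seed."""
    m = len(DEFAULT_NEEDS)
    rng_needs, rng_assign, rng_u, rng_jit = _streams(config.seed, 4)

    nf = config.n_frontier
    needs_f = np.empty((nf, m))
    for j, (median, sigma) in enumerate(config.needs_scale):
        needs_f[:, j] = median * np.exp(rng_needs.normal(0.0, sigma, size=nf))

    # concave increasing service frontier of the weighted aggregate need;
    # weights 1/median make each variable contribute ~1 at the median
    w = 1.0 / np.array([s[0] for s in config.needs_scale])
    z_f = needs_f @ w
    expo = 0.7 if config.frontier_shape == "concave_power" else 1.0
    # scale services to published magnitude: ~68 / ~38 million at z = m
    a1 = 67.6 / m**expo
    a2 = 38.0 / m**expo
    services_f = np.column_stack([a1 * z_f**expo, a2 * z_f**expo])

    ids = [f"S{i + 1:02d}" for i in range(config.n_dmus)]
    lo, hi = config.inefficiency_range
    anchors = rng_assign.integers(0, nf, size=config.n_dmus - nf)
    u_all = rng_u.uniform(lo, hi, size=config.n_dmus - nf)

    records, true_u, is_front, anchor_map = [], {}, {}, {}
    for i in range(config.n_dmus):
        if i < nf:
            needs, services, u = needs_f[i], services_f[i], 1.0
        else:
            k = int(anchors[i - nf])
            # upward-only jitter keeps the anchor feasible as a peer; the
            # copy's services sit at fraction u of the frontier value for
            # its *own* (jittered) needs, so u = 1 copies are exactly
            # efficient and u < 1 is recoverable up to the jitter
            jit = 1.0 + rng_jit.uniform(0.0, config.jitter, size=m)
            needs = needs_f[k] * jit
            u = float(u_all[i - nf])
            z = needs @ w
            services = u * np.array([a1 * z**expo, a2 * z**expo])
            anchor_map[ids[i]] = ids[k]
        true_u[ids[i]] = u
        is_front[ids[i]] = i < nf
        records.append(
            DMURecord(
                dmu_id=ids[i],
                name=f"Synthetic state {i + 1}",
                region=REGIONS[i % len(REGIONS)],
                needs=dict(zip(DEFAULT_NEEDS, needs)),
                services=dict(zip(DEFAULT_SERVICES, services)),
            )
        )
    return Dataset(records), SyntheticTruth(true_u, is_front, anchor_map)


def generate_pharmacy_ratio(
    truth: SyntheticTruth, slope: float, noise_sd: float, seed: int
) -> dict[str, float]:
    """Accredited-pharmacy share covariate linked to the planted deficit.

    ``ratio_i = clip(a + slope * (1 - u_i) + noise, 0, 1)`` with the
    intercept ``a`` chosen so the ratios centre at 0.4 (the published
    national accreditation share is in that vicinity).
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ids = list(truth.true_u)
    deficit = np.array([1.0 - truth.true_u[i] for i in ids])
    a = 0.4 - slope * float(deficit.mean())
    raw = a + slope * deficit + rng.normal(0.0, noise_sd, size=len(ids))
    return dict(zip(ids, np.clip(raw, 0.0, 1.0)))
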