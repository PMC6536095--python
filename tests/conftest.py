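import numpy as np
import pandas as pd
import pytest

from pharmaequity import Dataset, SyntheticConfig, generate


@pytest.fixture
def toy_dataset() -> Dataset:
    """1 need / 1 service: A and B efficient, C half-covered (phi = 2)."""
    df = pd.DataFrame(
        {
            "dmu_id": ["A", "B", "C"],
            "region": ["North", "North", "South"],
            "x": [1.0, 2.0, 2.0],
            "y": [1.0, 4.0, 2.0],
        }
    )
    return Dataset.from_frame(df, ["x"], ["y"])


@pytest.fixture(scope="session")
def planted_dataset():
    """12-unit synthetic dataset with 4 frontier units, seed 7."""
    cfg = SyntheticConfig(
        n_dmus=12, n_frontier=4, inefficiency_range=(0.4, 0.9), seed=7
    )
    return generate(cfg)


def random_instance(seed: int, n: int | None = None, m: int = 2, s: int = 2):
    """Small random DEA instance on unit scale, for oracle comparisons."""
    rng = np.random.default_rng(seed)
    n = n or int(rng.integers(2, 6))
    X = rng.uniform(0.5, 3.0, size=(n, m))
    Y = rng.uniform(0.5, 3.0, size=(n, s))
    df = pd.DataFrame({"dmu_id": [f"D{i}" for i in range(n)]})
    for j in range(m):
        df[f"x{j}"] = X[:, j]
    for r in range(s):
        df[f"y{r}"] = Y[:, r]
    ds = Dataset.from_frame(df, [f"x{j}" for j in range(m)], [f"y{r}" for r in range(s)])
    return ds, X, Y
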