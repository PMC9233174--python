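import numpy as np
import pandas as pd
import pytest

from dictypatch import SimulationConfig, SporePool, generate_spore_table


@pytest.fixture(scope="session")
def spore_table() -> pd.DataFrame:
    """The default synthetic plate-level table (fixed generator seed).

    Plays the role of the archived empirical table: one fixed dataset that
    the simulator resamples from.
    """
    return generate_spore_table()


@pytest.fixture(scope="session")
def pool(spore_table) -> SporePool:
    return SporePool(spore_table)


@pytest.fixture(scope="session")
def scaled_config() -> SimulationConfig:
    """Reduced-scale study conditions used throughout the suite."""
    return SimulationConfig(n_patches=100, n_rounds=50, n_replicates=20)


def point_mass_pool(
    values: dict[tuple[str, str], float], n: int = 4
) -> SporePool:
    """A pool whose cells are point masses — handy for exact arithmetic checks."""
    rows = []
    for (phenotype, context), value in values.items():
        for i in range(n):
            rows.append((phenotype, context, f"{phenotype[:3]}{i}", "batch1", value, 0.0))
    frame = pd.DataFrame(
        rows,
        columns=[
            "phenotype",
            "food_context",
            "clone_id",
            "date_id",
            "spores_per_plate",
            "symbiont_od",
        ],
    )
    return SporePool(frame)


def lag1_autocorr(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.corrcoef(x[:-1], x[1:])[0, 1])
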