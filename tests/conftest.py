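import numpy as np
import pandas as pd
import pytest

from fibromics import AbundanceTable, CohortDesign, PlantedSignal


@pytest.fixture(scope="session")
def screen_design():
    return CohortDesign.screen_design(seed=11)


@pytest.fixture(scope="session")
def default_signal():
    return PlantedSignal()


def make_table(values: np.ndarray, breeds, diets, levels=None) -> AbundanceTable:
    """Hand-rolled AbundanceTable from a raw matrix and group labels."""
    n = values.shape[1]
    assert len(breeds) == len(diets) == n
    if levels is None:
        levels = [0.0 if d == "CON" else 10.5 for d in diets]
    ids = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {"breed": breeds, "diet": diets, "level": levels}, index=ids
    )
    mat = pd.DataFrame(
        values, index=[f"f{i}" for i in range(values.shape[0])], columns=ids
    )
    return AbundanceTable(mat, meta)


@pytest.fixture
def four_group_table():
    """Small deterministic 4-group table: 3 features × (4 groups × 3)."""
    rng = np.random.default_rng(42)
    vals = rng.lognormal(0, 0.3, size=(3, 12))
    breeds = ["MS"] * 6 + ["LW"] * 6
    diets = (["CON"] * 3 + ["WB-10.5"] * 3) * 2
    return make_table(vals, breeds, diets)
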