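import numpy as np
import pandas as pd
import pytest

from poolscreen.datagen import PlantedTruth, PoolDesign, generate_pool
from poolscreen.normalize import regroup_tags


@pytest.fixture(scope="session")
def small_pool():
    """200-strain pool, one generation, 10 planted strains at -2 log2 (5 g)."""
    design = PoolDesign(n_strains=200, generations=(5,), seed=42)
    planted = tuple(
        PlantedTruth(f"strain{i:05d}", {d: 0.4 for d in design.dose_levels})
        for i in range(10)
    )
    intensity, chips, truth = generate_pool(design, planted)
    return design, planted, intensity, chips, truth


@pytest.fixture(scope="session")
def chip_level(small_pool):
    _, _, intensity, chips, _ = small_pool
    return regroup_tags(intensity), chips


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_design():
    """2 control + 2 treated chips at one dose, generation 5."""
    return pd.DataFrame(
        {
            "compound": ["control", "control", "HQ", "HQ"],
            "dose": ["control", "control", "25", "25"],
            "generation": [5, 5, 5, 5],
            "replicate": [1, 2, 1, 2],
        },
        index=pd.Index(["c1", "c2", "t1", "t2"], name="chip"),
    )
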