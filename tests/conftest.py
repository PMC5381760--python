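import numpy as np
import pytest

from phenoniche import synth
from phenoniche.raster import EnvStack, GridSpec


# Published biome x phenotype counts (columns: non-melanistic, melanistic)
# used as a fixed input table throughout the association tests.
BIOME_COUNTS = [
    ("desert_xeric_shrublands", 69, 0),
    ("mediterranean_forests", 13, 0),
    ("tundra", 2, 0),
    ("montane_grasslands", 47, 3),
    ("temperate_broadleaf_mixed", 108, 3),
    ("temperate_coniferous", 5, 0),
    ("temperate_grasslands", 2, 0),
    ("tropical_coniferous", 5, 0),
    ("tropical_dry_broadleaf", 38, 2),
    ("tropical_grasslands_savannas", 126, 0),
    ("tropical_moist_broadleaf", 137, 59),
]


@pytest.fixture(scope="session")
def biome_counts():
    import numpy as np

    names = [b for b, _, _ in BIOME_COUNTS]
    counts = np.array([[nm, m] for _, nm, m in BIOME_COUNTS], dtype=float)
    return names, counts


@pytest.fixture(scope="session")
def flat_truth():
    """Synthetic bundle with uniform suitability (no niche signal)."""
    cfg = synth.SyntheticConfig(
        grid_shape=(50, 50),
        n_layers=3,
        n_records=400,
        melanism_freq_by_biome=(0.30, 0.10, 0.02, 0.0),
        seed=11,
    )
    return synth.generate_truth(cfg)


@pytest.fixture(scope="session")
def niche_truth():
    """Synthetic bundle where melanism loads positively on env_0."""
    cfg = synth.SyntheticConfig(
        grid_shape=(50, 50),
        n_layers=3,
        n_records=500,
        melanism_freq_by_biome=(0.15, 0.15, 0.15, 0.15),
        niche_coeffs={
            "melanistic": {"env_0": (3.0, 0.0)},
            "non_melanistic": {"env_0": (-1.0, 0.0)},
        },
        seed=21,
    )
    return synth.generate_truth(cfg)


@pytest.fixture()
def unit_env():
    """Single uniform layer spanning [0, 1] on a 100x100 grid."""
    rng = np.random.default_rng(5)
    grid = GridSpec(100, 100, 0.0, 0.0, 0.01)
    return EnvStack(grid, {"x": rng.uniform(0.0, 1.0, (100, 100))})
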