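import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("deterministic")

DAY_GRID = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def day_grid():
    return np.asarray(DAY_GRID)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 3-treatment synthetic study on disk, shared across pipeline tests."""
    from chromakin.synthetic import DatasetConfig, default_cohort, generate_dataset

    cohort = default_cohort()
    cfg = DatasetConfig(
        treatments={k: cohort[k] for k in ("control", "basil-spray", "greentea-dip6")},
        frame=(80, 80),
        radius=30,
        seed=7,
    )
    out = tmp_path_factory.mktemp("smallstudy")
    manifest = generate_dataset(cfg, out, force=True)
    return {"config": cfg, "manifest": manifest, "dir": out}
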