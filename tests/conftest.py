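import pandas as pd
import pytest

from aucscreen.pipeline import write_synthetic_screen
from aucscreen.synth import ScreenConfig, generate_screen, plant_effects


@pytest.fixture(scope="session")
def small_config() -> ScreenConfig:
    """A 30-compound screen, small enough to run dozens of times."""
    return ScreenConfig(n_compounds=30, noise_cv=0.05, seed=3)


@pytest.fixture(scope="session")
def small_screen(small_config):
    effects = plant_effects(small_config, n_inhibitors=3, n_enhancers=2)
    return generate_screen(small_config, effects)


@pytest.fixture()
def small_screen_dir(small_screen, tmp_path):
    write_synthetic_screen(small_screen, tmp_path / "data")
    return tmp_path / "data"


def viability_frame(rows) -> pd.DataFrame:
    """Build a long viability table from (compound_id, replicate,
    concentration_um, viability) tuples."""
    return pd.DataFrame(
        rows, columns=["compound_id", "replicate", "concentration_um", "viability"]
    )
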