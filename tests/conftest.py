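import warnings

import numpy as np
import pytest

from qwa import synthetic
from qwa.io import _default_droughts


@pytest.fixture(scope="session")
def small_config():
    """Reduced-size configuration for fast end-to-end unit tests."""
    return synthetic.SyntheticConfig(
        seed=42,
        n_years=40,
        start_year=1970,
        trees_per_group=4,
        cells_per_ring=60,
        drought_spec=(
            synthetic.DroughtEvent(1980, (4, 5, 6)),
            synthetic.DroughtEvent(1995, (5, 6, 7)),
        ),
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synthetic.generate_dataset(small_config)


@pytest.fixture(scope="session")
def study_dataset():
    """Study-scale dataset with planted droughts and a pure-group
    post-drought anatomical density elevation."""
    cfg = synthetic.SyntheticConfig(
        seed=7,
        drought_spec=_default_droughts(),
        effect_spec=synthetic.EffectSpec(after={"pure": 1.15, "mixed": 1.0}),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cfg, synthetic.generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
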