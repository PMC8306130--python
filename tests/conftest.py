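import numpy as np
import pytest

from gnas_imprint import MethylationModel, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20210715)


@pytest.fixture
def small_cohort_config():
    """A small but threshold-derivable cohort (enough gsp-positive tumors)."""
    return SimulationConfig(n_tumors=60, n_normals=6, seed=42)


@pytest.fixture
def printed_reference_config():
    """Generator pinned to the published reference-group parameters:
    19 gsp-positive tumors with methylation N(42.4, 5.7) and GNAS
    expression with mean + SD = 517."""
    return SimulationConfig(
        n_tumors=19,
        n_normals=6,
        p_gsp=1.0,
        seed=7,
        methylation=MethylationModel(gsp_pos_mean=42.4, gsp_pos_sd=5.7),
    )
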