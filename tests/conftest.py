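import warnings

import numpy as np
import pytest

from dfirscreen.core import build_axis
from dfirscreen.synth import BandModel, SpotConfig

# QC warnings (skipped scatter rule on DF_9, empty cells) are expected in
# several pipeline-level tests; keep the output clean.
warnings.filterwarnings("ignore", message=".*scatter rule skipped.*")


@pytest.fixture(scope="session")
def full_axis():
    return build_axis("FULL_199")


@pytest.fixture(scope="session")
def df14_axis():
    return build_axis("DF_14")


@pytest.fixture(scope="session")
def df9_axis():
    return build_axis("DF_9")


@pytest.fixture
def rng():
    return np.random.default_rng(20160204)


@pytest.fixture
def quiet_spot_config():
    """Noise- and artefact-free spot: deterministic forward model."""
    return SpotConfig(noise_sd=0.0, baseline_offset_range=(0.0, 0.0),
                      baseline_slope_range=(0.0, 0.0), thickness_scale_sd=0.0)


@pytest.fixture
def single_band():
    return BandModel(1651.0, 1.0, 45.0, "gaussian", name="amide_I")
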