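import numpy as np
import pytest

import rardose as rd
from rardose import reference
from rardose.synthetic import MarkerSpec


@pytest.fixture(scope="session")
def reference_curves() -> dict[str, rd.CalibrationModel]:
    """The 11 reference markers' generating curves as evaluable models."""
    curves = {}
    for m in reference.RAR_MARKERS:
        entry = reference.CALIBRATION_CONSTANTS[m]
        curves[m] = MarkerSpec(m, entry["family"], dict(entry["constants"])).curve()
    return curves


@pytest.fixture(scope="session")
def noiseless_study():
    """A CV=0 synthetic study: every reading equals its curve value."""
    config = rd.SyntheticConfig(markers=rd.default_markers(cv=0.0), seed=1)
    readings, truth = rd.generate_study(config)
    return config, readings, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
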