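import numpy as np
import pytest

from cssr.params import calibrate
from cssr.synthetic import make_calibration_set, make_hairpin, make_pseudoknot


@pytest.fixture(scope="session")
def ideal_wc_params():
    """Parameters calibrated on noise-free Watson-Crick-only duplexes:
    every sigma sits at the floor, scores of ideal geometry are exactly 1."""
    structures, refs = make_calibration_set(
        n_helices=20, length=15, sigma=0.0, seed=11, wobble_frac=0.0)
    return calibrate(structures, refs)


@pytest.fixture(scope="session")
def ideal_mixed_params():
    """Noise-free calibration including G:U wobble steps (both classes)."""
    structures, refs = make_calibration_set(
        n_helices=20, length=15, sigma=0.0, seed=11, wobble_frac=0.15)
    return calibrate(structures, refs)


@pytest.fixture(scope="session")
def noisy_params():
    """Parameters calibrated under 0.5 Å coordinate noise (the packaged
    default conditions)."""
    structures, refs = make_calibration_set(
        n_helices=40, length=20, sigma=0.5, seed=12345, wobble_frac=0.1)
    return calibrate(structures, refs)


@pytest.fixture()
def hairpin():
    return make_hairpin(5, 4, rng=3)


@pytest.fixture()
def pseudoknot():
    return make_pseudoknot(3, 3, rng=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
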