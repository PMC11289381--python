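import numpy as np
import pytest

from ssvep_bci import CortexModel, plan_bands
from ssvep_bci.fixtures import digit_template


@pytest.fixture
def noiseless_model():
    """Deterministic cortex model: flat first order, default chi2, no noise."""
    return CortexModel().noiseless()


@pytest.fixture
def default_model():
    return CortexModel()


@pytest.fixture
def flat_chi2_model():
    """Noise-free model with a frequency-independent second-order response."""
    return CortexModel(chi2_scale=1.0, chi2_decay=np.inf).noiseless()


@pytest.fixture
def pnn_plan():
    """The 64+64-line, 0.5 Hz band plan of the digit-classification network."""
    return plan_bands(64, 64, 15.0, 20.0, 0.5)


@pytest.fixture
def digit_images():
    return {c: digit_template(c, 8) for c in (0, 1, 7)}


def random_two_band_combs(rng, max_lines=8):
    """A random pair of narrowband combs with a valid product-band plan.

    Line spacings and start frequencies are multiples of 1/8 Hz so that all
    comb lines (and their pairwise sums) fall on exact DFT bins of a
    one-period record.
    """
    from ssvep_bci.cortex import band_plan_from_combs
    from ssvep_bci.fdm import FrequencyComb

    while True:
        d = 0.125
        nx = int(rng.integers(2, max_lines + 1))
        na = int(rng.integers(2, max_lines + 1))
        f_a = d * int(rng.integers(96, 128))  # 12-16 Hz
        f_b = d * int(rng.integers(152, 200))  # 19-25 Hz
        X = FrequencyComb(f_a, d, rng.uniform(0.2, 1.0, nx))
        A = FrequencyComb(f_b, d, rng.uniform(0.2, 1.0, na))
        try:
            band_plan_from_combs(X, A)
        except ValueError:
            continue
        return X, A
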