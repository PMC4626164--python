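import numpy as np
import pytest
from scipy.signal import lfilter

from periqeeg import Recording, SimulationConfig

AR_COEFFS = (1.885708, -0.9025)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def ar2_series(rng, n, coeffs=AR_COEFFS, burn=2048):
    """Stationary AR(2) noise matching the synthetic background process."""
    e = rng.normal(size=n + burn)
    return lfilter([1.0], [1.0, -coeffs[0], -coeffs[1]], e)[burn:]


@pytest.fixture
def small_config():
    """Small, fast simulation scenario used across tests."""
    return SimulationConfig(
        n_channels=8,
        pre_s=60.0,
        ictal_s=20.0,
        post_s=30.0,
        generator_channels=(0, 1),
        rbt_channels=(0, 1, 2),
        soz_channels=(0, 1),
        reference_lead_s=50.0,
        seed=42,
    )


@pytest.fixture
def noise_recording(rng):
    """Plain white-noise recording with a nominal seizure annotation."""
    fs = 512.0
    sig = rng.normal(size=(6, int(30 * fs)))
    return Recording(
        signals=sig,
        sampling_rate=fs,
        onset_sample=int(10 * fs),
        termination_sample=int(20 * fs),
    )
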