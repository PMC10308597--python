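import numpy as np
import pytest

from beadpulse import (
    AcquisitionConfig,
    BeadModel,
    TrialSpec,
    default_aperture,
)

#: The six default carriers (Hz), used throughout.
FREQS = np.array([45e3, 150e3, 380e3, 2e6, 11e6, 35e6])


@pytest.fixture(scope="session")
def aperture():
    return default_aperture()


@pytest.fixture()
def acq():
    return AcquisitionConfig(seed=0)


@pytest.fixture()
def quiet_acq():
    """Noise-free, drift-free acquisition for oracle comparisons."""
    return AcquisitionConfig(
        noise_sd_mag=0.0, noise_sd_phase=0.0, drift_amp=0.0, seed=0
    )


@pytest.fixture()
def working_bead(aperture):
    """The nonmetallized 8.2 um working bead."""
    return BeadModel.nonmetallized(8.2e-6, aperture)


def make_trial(conc_nm: float, seed: int, **kwargs) -> TrialSpec:
    return TrialSpec(probe_concentration=conc_nm, seed=seed, **kwargs)
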