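import numpy as np
import pytest

from octgan import spectra as sp
from octgan.phantoms import AcquisitionConfig, make_bead_phantom, make_pair


@pytest.fixture(scope="session")
def axis():
    return sp.SpectralAxis.uniform(400.0, 710.0, 1024)


@pytest.fixture(scope="session")
def broadband(axis):
    return sp.make_broadband_spectrum(axis)


@pytest.fixture(scope="session")
def gapped_window(axis):
    return sp.make_gapped_window(axis)


@pytest.fixture(scope="session")
def gapped(broadband, gapped_window):
    return sp.apply_window(broadband, gapped_window)


@pytest.fixture(scope="session")
def bead_pair():
    """A deterministic noiseless synthetic-gap bead pair."""
    phantom = make_bead_phantom(6, seed=42, min_separation_um=12.0)
    acq = AcquisitionConfig(seed=7, noise_sigma=0.0)
    return phantom, acq, make_pair(phantom, acq, phantom_id="beads-t0")


@pytest.fixture(scope="session")
def noisy_bead_pair():
    phantom = make_bead_phantom(6, seed=11, min_separation_um=12.0)
    acq = AcquisitionConfig(seed=3)
    return phantom, acq, make_pair(phantom, acq, phantom_id="beads-t1")
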