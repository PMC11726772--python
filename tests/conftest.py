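import numpy as np
import pytest

import radrelax as rr


@pytest.fixture(scope="session")
def heart16():
    return rr.build_heart_phantom(matrix=16)


@pytest.fixture(scope="session")
def t1rho_protocol16():
    return rr.t1rho_protocol(matrix=16, spokes_per_frame=1024)


@pytest.fixture(scope="session")
def t1rho_sim16(heart16, t1rho_protocol16):
    """Noiseless fully-sampled spin-lock acquisition of the 16^3 heart."""
    spokes = rr.make_t1rho_spokes(t1rho_protocol16)
    series = rr.frame_images(heart16, t1rho_protocol16, spokes.frame_times)
    ks = rr.sample_kspace(series, spokes, noise_sigma=0.0, seed=1)
    return series, ks


@pytest.fixture(scope="session")
def t1_reference16(heart16):
    vals = np.where(heart16.mask, heart16.maps["t1"], np.nan)
    return rr.RelaxationMap(vals, "s", mask=heart16.mask, name="T1")
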