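"""Shared fixtures: small, fast synthetic configurations."""

import numpy as np
import pytest

from digitsel.synthetic import ContrastProfile, SyntheticConfig


@pytest.fixture
def small_config():
    """Two-contrast config on a small grid, fast enough for unit tests."""
    return SyntheticConfig(
        grid_shape=(32, 24, 24),
        digit_centers_mm=(12.0, 16.0, 20.0),
        tuning_sigma_mm=3.0,
        neural_overlap=0.3,
        seed=7,
    )


@pytest.fixture
def separated_noiseless_config():
    """Zero-PSF, high-CNR, well-separated centers: exact-recovery regime."""
    return SyntheticConfig(
        grid_shape=(48, 24, 24),
        digit_centers_mm=(10.0, 24.0, 38.0),
        tuning_sigma_mm=2.0,
        neural_overlap=0.0,
        contrasts={"ideal": ContrastProfile(psf_fwhm_mm=0.0, amplitude=8.0)},
        noise_sd=0.0,
        seed=1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
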