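import numpy as np
import pytest

import chemocal as cc


@pytest.fixture(scope="session")
def grid():
    return cc.WavelengthGrid.default()


@pytest.fixture(scope="session")
def design():
    """Default 25-run design, odd/even split (13 calibration, 12 validation)."""
    return cc.split_design(cc.generate_design())


@pytest.fixture(scope="session")
def cal_val_indices(design):
    cal = [i for i, r in enumerate(design.role) if r == "calibration"]
    val = [i for i, r in enumerate(design.role) if r == "validation"]
    return cal, val


@pytest.fixture(scope="session")
def clean_spectra(design, grid):
    """Noise-free Beer-Lambert mixture spectra of the default components."""
    noise = cc.NoiseModel(seed=0, noise_sd=0.0)
    return cc.simulate_mixtures(design, cc.DEFAULT_COMPONENTS, noise, grid)


@pytest.fixture(scope="session")
def noisy_spectra(design, grid):
    """Seeded spectra at the default instrument noise level (0.002 AU)."""
    noise = cc.NoiseModel(seed=42, noise_sd=0.002)
    return cc.simulate_mixtures(design, cc.DEFAULT_COMPONENTS, noise, grid)


@pytest.fixture(scope="session")
def calibration_blocks(design, cal_val_indices, clean_spectra):
    cal, _ = cal_val_indices
    return design.conc[cal], clean_spectra.absorbance[cal]


@pytest.fixture(scope="session")
def noisy_blocks(design, cal_val_indices, noisy_spectra):
    cal, val = cal_val_indices
    return (
        design.conc[cal], noisy_spectra.absorbance[cal],
        design.conc[val], noisy_spectra.absorbance[val],
    )
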