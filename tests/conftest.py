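import numpy as np
import pytest

from albind.spectra import AxisKind, Spectrum, TitrationSeries
from albind.synthetic import HSA_AMIDE_I_CENTERS, AmideIGroundTruth, generate_amide_i


@pytest.fixture
def emission_grid():
    return np.arange(300.0, 500.0 + 1e-9, 1.0)


@pytest.fixture
def simple_series(emission_grid):
    """Three-member titration with a fixed Gaussian band, no quenching."""
    band = 100.0 * np.exp(-((emission_grid - 337.0) ** 2) / (2 * 25.0**2))
    conc = np.array([0.0, 5e-7, 1e-6])
    spectra = [
        Spectrum(AxisKind.wavelength_nm, emission_grid, band, label=f"{c}")
        for c in conc
    ]
    return TitrationSeries(
        temperature_K=310.0,
        ligand_concentrations_M=conc,
        spectra=spectra,
        protein_concentration_M=5e-7,
    )


#: seven-band amide-I layout (centers from a published ligand-free serum
#: albumin deconvolution; widths/areas synthetic) used by recovery tests
AMIDE_AREAS = (0.9, 0.8, 0.7, 0.6, 1.2, 0.8, 0.5)
AMIDE_SIGMA = 4.5


def amide_ground_truth(noise_sd_rel=0.0, seed=0):
    bands = [(c, AMIDE_SIGMA, a) for c, a in zip(HSA_AMIDE_I_CENTERS, AMIDE_AREAS)]
    return AmideIGroundTruth(bands, noise_sd_rel=noise_sd_rel, seed=seed)


def amide_class_truth():
    from albind.secondary_structure import STRUCTURE_CLASSES, assign_band

    total = sum(AMIDE_AREAS)
    truth = {k: 0.0 for k in STRUCTURE_CLASSES}
    for c, a in zip(HSA_AMIDE_I_CENTERS, AMIDE_AREAS):
        truth[assign_band(c)] += a / total
    return truth


@pytest.fixture
def amide_spectrum():
    grid = np.arange(1580.0, 1721.0, 1.0)
    return generate_amide_i(amide_ground_truth(), grid)
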