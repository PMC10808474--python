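"""Shared fixtures: the printed reference design and synthetic datasets."""

import numpy as np
import pytest

from quatcal import design as dg
from quatcal import spectra as sp

# The 25 published calibration mixtures (µg/mL), transcribed independently
# of the design generator: analyte order CAF, COD, PAR, PAP.
PRINTED_CALIBRATION = np.array([
    [3.6, 8, 12, 4.5],
    [3.6, 2, 4, 7.5],
    [1.2, 2, 20, 3],
    [1.2, 14, 8, 7.5],
    [6, 5, 20, 4.5],
    [2.4, 14, 12, 3],
    [6, 8, 8, 3],
    [3.6, 5, 8, 6],
    [2.4, 5, 16, 7.5],
    [2.4, 11, 20, 6],
    [4.8, 14, 16, 4.5],
    [6, 11, 12, 7.5],
    [4.8, 8, 20, 7.5],
    [3.6, 14, 20, 1.5],
    [6, 14, 4, 6],
    [6, 2, 16, 1.5],
    [1.2, 11, 4, 4.5],
    [4.8, 2, 12, 6],
    [1.2, 8, 16, 6],
    [3.6, 11, 16, 3],
    [4.8, 11, 8, 1.5],
    [4.8, 5, 4, 3],
    [2.4, 2, 8, 4.5],
    [1.2, 5, 12, 1.5],
    [2.4, 8, 4, 1.5],
])

# The six published validation mixtures (rows 26-31).
PRINTED_VALIDATION = np.array([
    [1.2, 2, 20, 2],
    [3.6, 8, 12, 4.5],
    [4, 4, 4, 4],
    [6, 2, 16, 1.5],
    [1.2, 14, 4, 7.5],
    [6, 14, 4, 1.5],
])


@pytest.fixture(scope="session")
def default_design():
    return dg.build_design()


@pytest.fixture(scope="session")
def full_grid():
    return sp.make_grid(*sp.FULL_SCAN, "inclusive")


@pytest.fixture(scope="session")
def library(full_grid):
    return sp.default_library(full_grid)


@pytest.fixture(scope="session")
def noiseless_calibration(default_design, library):
    """Noiseless 25-mixture dataset on the full scan grid."""
    return sp.simulate_mixtures(default_design.concentrations, library,
                                noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def noiseless_validation(library):
    return sp.simulate_mixtures(dg.validation_set(), library,
                                noise_sd=0.0, seed=0,
                                sample_ids=dg.validation_mixture_ids())


@pytest.fixture(scope="session")
def cal_window(noiseless_calibration):
    """Noiseless calibration restricted to the 210-300 nm window."""
    return sp.restrict(noiseless_calibration, (210.0, 300.0))
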