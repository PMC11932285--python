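import numpy as np
import pytest

from urinmr import (
    DcvConfig,
    SimulationConfig,
    build_matrix,
    default_library,
    double_cross_validate,
    paper_effects,
    simulate_cohort_spectra,
    simulate_concentrations,
)


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def cohort():
    """One noiseless synthetic cohort: spectra, labels, ground truth."""
    cfg = SimulationConfig(seed=17, effects=paper_effects())
    spectra, groups, truth = simulate_cohort_spectra(cfg)
    return spectra, groups, truth


@pytest.fixture(scope="session")
def quantified(cohort, library):
    spectra, groups, _ = cohort
    return build_matrix(spectra, list(groups), library)


@pytest.fixture(scope="session")
def effect_matrix():
    """Concentration table with the study's direction-of-change pattern."""
    return simulate_concentrations(SimulationConfig(seed=5, effects=paper_effects()))


@pytest.fixture(scope="session")
def effect_dcv(effect_matrix):
    return double_cross_validate(effect_matrix.values,
                                 effect_matrix.class_codes(),
                                 DcvConfig(seed=5))
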