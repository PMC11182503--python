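import warnings

import numpy as np
import pytest

from microftir.bands import default_library
from microftir.core import WavenumberGrid
from microftir.simulate import CohortConfig, generate_cohort, regular_taxonomy


@pytest.fixture(scope="session")
def grid():
    return WavenumberGrid.default()


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def media_cohort():
    """Default two-media cohort at 18 °C (the media-study conditions)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(CohortConfig.media_study(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A compact regular-taxonomy cohort for fast structural tests."""
    cfg = CohortConfig.media_study(
        seed=5, taxonomy=regular_taxonomy(2, 2, 2)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise- and artifact-free cohort: measured spectra equal clean ones."""
    cfg = CohortConfig.media_study(
        seed=5,
        taxonomy=regular_taxonomy(2, 2, 2),
        sigma_bio=0.0,
        sigma_tech=0.0,
        baseline_sd=0.0,
        slope_sd=0.0,
        curvature_sd=0.0,
        multiplicative_log_sd=0.0,
        noise_sd=0.0,
    )
    return generate_cohort(cfg)
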