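import warnings

import numpy as np
import pytest

from strokeseg import SyntheticConfig, generate_case, generate_cohort, preprocess_case


@pytest.fixture(scope="session")
def default_case():
    """One synthetic case under the default study condition."""
    return generate_case(SyntheticConfig(seed=11), 0)


@pytest.fixture(scope="session")
def clean_case():
    """Noiseless, perfectly grid-aligned case (exact mirror symmetry
    outside the lesion)."""
    cfg = SyntheticConfig(seed=3, noise_sd_frac=0.0, asymmetry_sd_mm=0.0)
    return generate_case(cfg, 0)


SMALL_COHORT_CFG = SyntheticConfig(
    seed=21,
    n_patients=5,
    grid_shape=(24, 24, 14),
    brain_semiaxes_mm=(20.0, 21.0, 12.0),
    lesion_volume_ml_range=(1.5, 3.0),
)


@pytest.fixture(scope="session")
def small_cohort():
    """Five small cases for fast cross-validation tests."""
    return generate_cohort(SMALL_COHORT_CFG)


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {c.patient_id: preprocess_case(c) for c in small_cohort}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
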