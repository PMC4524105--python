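"""Shared fixtures: small synthetic cohorts generated at test time."""

import pytest

from mpradiomics import PhantomConfig, generate_cohort, generate_study
from mpradiomics.pipeline import cohort_feature_matrices, derive_modalities


@pytest.fixture(scope="session")
def noiseless_config():
    """Degenerate parameter ranges so closed-form values are exact."""
    return PhantomConfig(
        n_patients=3,
        grid_shape=(32, 32, 8),
        noise_sigma=0.0,
        D_healthy=(1.8e-3, 1.8e-3),
        D_tumour=(6.0e-4, 6.0e-4),
        S0_range=(1000.0, 1000.0),
        bias_field_amplitude=0.0,
        lesion_count_probs=(0.0, 1.0, 0.0),
        seed=42,
    )


@pytest.fixture(scope="session")
def noiseless_study(noiseless_config):
    return generate_study(noiseless_config, 0)


@pytest.fixture(scope="session")
def small_cohort():
    """Six mildly noisy patients with derived modalities attached."""
    config = PhantomConfig(n_patients=6, grid_shape=(32, 32, 8), seed=5)
    return [derive_modalities(s) for s in generate_cohort(config)]


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """Per-modality cohort feature matrices for T2w and ADC."""
    return cohort_feature_matrices(small_cohort, ["T2w", "ADC"])
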