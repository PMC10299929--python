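import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import archssm as a
from archssm import shape_model as sm
from archssm.synthetic import attenuated_contrast

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_arch():
    """One noise-free coarctation-like arch with known parameters."""
    params = a.coa_like_params()
    params.noise_sd = 0.0
    return params, a.generate_arch(params, seed=11)


@pytest.fixture(scope="session")
def cohort():
    """Default-contrast synthetic cohort (n=80), shared across tests."""
    spec = a.SyntheticCohortSpec(n_cases=80, prevalence=0.4, seed=42)
    return a.generate_cohort(spec)


@pytest.fixture(scope="session")
def aligned_cohort(cohort):
    return [a.align(arch) for arch in cohort.arches]


@pytest.fixture(scope="session")
def features(aligned_cohort):
    return sm.assemble_features(aligned_cohort)


@pytest.fixture(scope="session")
def model(features, cohort):
    return sm.fit_pca(features, case_ids=cohort.case_ids)


@pytest.fixture(scope="session")
def soft_cohort():
    """Attenuated-contrast cohort where classification does not saturate."""
    p0, p1 = attenuated_contrast(0.35)
    spec = a.SyntheticCohortSpec(n_cases=90, prevalence=0.4,
                                 class0_means=p0, class1_means=p1, seed=7)
    return a.generate_cohort(spec)


@pytest.fixture(scope="session")
def cylinder_mesh():
    """Straight tube of radius 3 mm along +Z, 60 mm long."""
    from archssm.synthetic import _sweep_tube

    n = 61
    pts = np.column_stack([np.zeros(n), np.zeros(n), np.linspace(0.0, 60.0, n)])
    line = a.Centerline(pts, np.full(n, 3.0))
    return _sweep_tube(line, 24)
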