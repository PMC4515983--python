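import numpy as np
import pytest

from mtlshape.synthetic import (
    CohortParams,
    EffectParams,
    generate_cohort,
    generate_markers,
    icosphere,
)


@pytest.fixture(scope="session")
def sphere():
    """42-vertex icosphere, radius 10 mm."""
    return icosphere(1, radius=10.0)


@pytest.fixture(scope="session")
def small_cohort():
    """30 subjects (20/5/5) with repeated scans."""
    params = CohortParams(n_control=20, n_preclinical=5, n_symptomatic=5,
                          scans_per_subject_mean=(3.0, 3.0, 3.0))
    return generate_cohort(params, seed=11)


@pytest.fixture(scope="session")
def small_markers(small_cohort):
    eff = EffectParams(n_vertices=6, affected_vertex_fraction=0.5, beta=0.0,
                       sigma2=0.01, rho=0.5)
    return generate_markers(small_cohort, eff, seed=12)


@pytest.fixture(scope="session")
def cs_cohort():
    """Single-scan two-group cohort for cross-sectional designs."""
    params = CohortParams(n_control=25, n_preclinical=0, n_symptomatic=25,
                          entry_age_mean=(60.0, 60.0, 60.0),
                          scans_per_subject_mean=(1.0, 1.0, 1.0))
    return generate_cohort(params, seed=21).first_scans()


def perturbed_mesh(mesh, scale=0.05, seed=0):
    """Template plus a smooth random low-frequency displacement."""
    rng = np.random.default_rng(seed)
    v = mesh.vertices
    disp = np.zeros_like(v)
    for _ in range(3):
        center = v[rng.integers(len(v))]
        amp = rng.normal(scale=scale, size=3)
        w = np.exp(-np.sum((v - center) ** 2, axis=1) / (2 * 25.0))
        disp += w[:, None] * amp
    return mesh.with_vertices(v * (1.0 + scale * 0.1) + disp)
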