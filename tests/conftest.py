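import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rsncausal import synthetic as syn

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_grid() -> syn.VoxelGrid:
    return syn.VoxelGrid(dims=(12, 12, 8))


@pytest.fixture(scope="session")
def small_templates(small_grid) -> syn.TemplateSet:
    return syn.make_templates(small_grid, n_networks=4, blobs_per_network=2,
                              blob_radius_vox=2.0, seed=11)


@pytest.fixture(scope="session")
def small_cohort_cfg(small_grid, small_templates) -> syn.CohortConfig:
    """Desk-size cohort: full statistical structure, reduced grid/duration."""
    return syn.CohortConfig(
        n_high=4, n_low=4, n_volumes_raw=80, n_discard=5,
        grid=small_grid, templates=small_templates, master_seed=101,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cohort_cfg):
    return syn.simulate_cohort(small_cohort_cfg)


def planted_mixture(grid, templates, n_steps=500, snr=2.0, seed=0):
    """Independent source time courses mixed through template-bounded maps."""
    rng = np.random.default_rng(seed)
    k = len(templates.names)
    V = grid.n_voxels
    S = rng.standard_normal((n_steps, k))
    M = np.zeros((k, V))
    for i in range(k):
        m = templates.masks[i]
        M[i, m] = rng.uniform(0.5, 1.0, int(m.sum()))
    X = S @ M
    if np.isfinite(snr):
        noise_sd = np.sqrt(X[:, templates.union_mask].var(axis=0).mean() / snr)
        X = X + rng.normal(scale=noise_sd, size=X.shape)
    return X, S, M
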