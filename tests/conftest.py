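import numpy as np
import pytest

from insulanet import CohortSpec, simulate_clinical, simulate_connectivity


def small_spec(seed: int = 0, **kw) -> CohortSpec:
    """A desk-scale cohort: 24+16 subjects, 40 parcels with 6 'insular'
    seeds, short series.  Keeps generator-dependent tests fast while
    exercising the same code paths as the full-size default."""
    base = dict(n_control=24, n_concussed=16, n_parcels=40,
                insula_indices=tuple(range(18, 24)), n_timepoints=80,
                volume_shape=(14, 14, 14), seed=seed,
                dti_effect=dict(n_fa_clusters=1, n_md_clusters=2))
    base.update(kw)
    return CohortSpec(**base)


@pytest.fixture(scope="session")
def small_cohort():
    spec = small_spec(seed=3)
    clinical = simulate_clinical(spec)
    tensor, truth = simulate_connectivity(spec, clinical)
    return spec, clinical, tensor, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
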