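import warnings

import numpy as np
import pytest

from ifmkit import synthetic_data as sd

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def disk_cohort():
    """Dense single-specimen disk-geometry cohort for geometry oracles."""
    spec = sd.CohortSimSpec(
        n_specimens=1, cells_per_specimen=20_000, geometry="disk",
        tissue_size_um=(5000.0, 5000.0), tumor_fraction=0.5, seed=3,
    )
    return spec, sd.simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-specimen cohort with a planted protective CD3 effect."""
    spec = sd.CohortSimSpec(
        n_specimens=6, cells_per_specimen=1500, geometry="disk",
        infiltration_effect={"CD3": -1.6}, seed=5,
    )
    return spec, sd.simulate_cohort(spec)


@pytest.fixture(scope="session")
def planted_corpus():
    """10 disjoint-support topics, 5000 documents, 60 tokens each."""
    rng = np.random.default_rng(42)
    K_true, V, n_docs, tokens = 10, 30, 5000, 60
    phi = np.zeros((K_true, V))
    for k, block in enumerate(np.array_split(np.arange(V), K_true)):
        phi[k, block] = rng.dirichlet(np.full(len(block), 0.3))
    theta = rng.dirichlet(np.full(K_true, 0.08), size=n_docs)
    z = (rng.random((n_docs, tokens))[:, :, None]
         < np.cumsum(theta, 1)[:, None, :]).argmax(2)
    counts = np.zeros((n_docs, V), dtype=np.int64)
    for d in range(n_docs):
        for zz in z[d]:
            counts[d, rng.choice(V, p=phi[zz])] += 1
    return counts, phi
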