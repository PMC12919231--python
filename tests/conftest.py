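import numpy as np
import pytest

from hyperfc import (
    IncidenceMatrix,
    SimulationConfig,
    TimeSeriesPanel,
    simulate_panels,
)

#: Planted study conditions used across structure/weighting/stats tests:
#: four disjoint hyperedges over 20 regions, strong coupling, light noise.
PLANTED = [[0, 1, 2, 3, 4], [5, 6, 7, 8], [9, 10, 11, 12], [13, 14, 15]]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_incidence():
    """4 regions, 2 hyperedges (centroids 0 and 3) sharing regions 1, 2."""
    entries = np.array(
        [
            [1, 0],
            [1, 1],
            [1, 1],
            [0, 1],
        ]
    )
    return IncidenceMatrix(entries=entries, centroids=[0, 3])


def random_incidence(rng, n_regions=8, n_hyperedges=4):
    """Random valid incidence matrix for property tests."""
    entries = np.zeros((n_regions, n_hyperedges), dtype=np.int8)
    centroids = rng.choice(n_regions, size=n_hyperedges, replace=False)
    for j, c in enumerate(centroids):
        k = rng.integers(3, n_regions + 1)
        members = rng.choice(n_regions, size=k, replace=False)
        entries[members, j] = 1
        entries[c, j] = 1
        if entries[:, j].sum() < 3:
            extra = rng.choice(np.flatnonzero(entries[:, j] == 0), size=3, replace=False)
            entries[extra, j] = 1
    return IncidenceMatrix(entries=entries, centroids=[int(c) for c in centroids])


@pytest.fixture
def random_panel(rng):
    data = rng.standard_normal((6, 40))
    return TimeSeriesPanel(subject_id="rand", data=data).zscore()


@pytest.fixture(scope="session")
def planted_study():
    """30 backbone subjects with the planted four-hyperedge structure."""
    cfg = SimulationConfig(
        n_regions=20,
        n_timepoints=192,
        n_subjects_per_group={"HC": 30},
        planted_hyperedges=PLANTED,
        coupling=0.8,
        noise_sd=0.2,
        seed=42,
    )
    panels, groups, truth = simulate_panels(cfg)
    return cfg, panels, truth
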