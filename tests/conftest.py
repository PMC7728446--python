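import numpy as np
import pytest

from gastrukit import synthetic as syn


@pytest.fixture(scope="session")
def small_colony():
    """Four-ring colony with 50 cells per marker, fixed seed."""
    spec = syn.ColonySpec(
        seed=11, cells_per_marker={m: 50 for m in syn.DEFAULT_RING_LAYOUT}
    )
    return syn.generate_colony_image(spec)


@pytest.fixture(scope="session")
def clustered_counts():
    """Three planted clusters, 40 cells each, strong markers."""
    spec = syn.CountSimSpec(
        n_cells_per_cluster={f"C{i}": 40 for i in range(3)},
        n_genes=400,
        markers_per_cluster={
            f"C{i}": [f"MK{i}_{j}" for j in range(6)] for i in range(3)
        },
        marker_fold_change=20.0,
        seed=12,
    )
    cm, truth = syn.generate_counts(spec)
    return cm, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
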