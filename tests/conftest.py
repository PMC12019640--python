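import numpy as np
import pytest

from clusterfold import Dataset, SharedFeatureSpace, SimConfig, simulate_paired_datasets


def make_space(*datasets: Dataset) -> SharedFeatureSpace:
    """Shared feature space over one or more datasets (no 2-dataset minimum)."""
    shared = set(datasets[0].feature_ids)
    for ds in datasets[1:]:
        shared &= set(ds.feature_ids)
    space = SharedFeatureSpace(feature_ids=sorted(shared))
    for ds in datasets:
        pos = {f: i for i, f in enumerate(ds.feature_ids)}
        space.row_index[ds.name] = np.array([pos[f] for f in space.feature_ids])
    return space


@pytest.fixture
def tiny_dataset() -> Dataset:
    """4 features × 6 cells, two groups of three."""
    rng = np.random.default_rng(0)
    counts = rng.poisson(5.0, size=(4, 6)).astype(float)
    cells = [f"c{i}" for i in range(6)]
    return Dataset(
        name="tiny",
        counts=counts,
        feature_ids=["fA", "fB", "fC", "fD"],
        cell_ids=cells,
        group_of={c: ("A" if i < 3 else "B") for i, c in enumerate(cells)},
    )


@pytest.fixture(scope="session")
def small_pair():
    """Two small paired datasets with strong planted markers, plus truth."""
    cfg = SimConfig(
        n_datasets=2,
        n_groups=4,
        cells_per_group=60,
        n_features=300,
        n_markers_per_group=8,
        marker_log2fc=3.0,
        seed=42,
    )
    datasets, truth = simulate_paired_datasets(cfg)
    return cfg, datasets, truth
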