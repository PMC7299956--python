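import numpy as np
import pandas as pd
import pytest

from retatlas.preprocess import NormalizedMatrix, normalize_log
from retatlas.simulate import SimConfig, generate_atlas


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Scaled-down atlas: 6 classes / 13 types, 1,600 human cells, 800 genes."""
    return SimConfig(
        n_cells_fovea=800,
        n_cells_periphery=800,
        n_cells_species_b=1000,
        n_genes=800,
        types_per_class=(2, 2, 3, 2, 2, 2),
        n_markers_per_type=12,
        region_de_genes_per_type=8,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_atlas(small_config):
    return generate_atlas(small_config)


@pytest.fixture(scope="session")
def small_norm(small_atlas) -> NormalizedMatrix:
    return normalize_log(small_atlas.counts)


@pytest.fixture(scope="session")
def singlet_mask(small_atlas) -> np.ndarray:
    t = small_atlas.truth
    return ((~t.is_doublet) & (~t.is_low_quality)).to_numpy()


def make_norm(values: np.ndarray, scale: float = 1.0) -> NormalizedMatrix:
    """Wrap a dense array as a NormalizedMatrix with generated ids."""
    g, c = values.shape
    return NormalizedMatrix(
        np.asarray(values, dtype=float),
        np.array([f"g{i}" for i in range(g)], dtype=object),
        np.array([f"c{j}" for j in range(c)], dtype=object),
        scale,
    )
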