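import numpy as np
import pytest

from voxtype.data_model_io import CellTypePanel, DensityField, ExpressionAtlas
from voxtype.synthetic_atlas import (
    SyntheticConfig,
    compose_atlas,
    generate_density_field,
    generate_panel,
    plant_clique,
)


@pytest.fixture
def tiny_cfg() -> SyntheticConfig:
    """Noise-free 4x4x4 world with 3 types and a 12-gene pool (enumerable)."""
    return SyntheticConfig(
        grid_dims=(4, 4, 4),
        n_types=3,
        n_genes=12,
        markers_per_type=4,
        noise_sd=0.0,
        seed=7,
    )


@pytest.fixture
def tiny_world(tiny_cfg):
    panel = generate_panel(tiny_cfg)
    field, masks = generate_density_field(tiny_cfg)
    atlas = compose_atlas(field, panel, tiny_cfg)
    clique = plant_clique(panel, target_type=0, k=3, seed=11)
    return {
        "cfg": tiny_cfg,
        "panel": panel,
        "field": field,
        "masks": masks,
        "atlas": atlas,
        "clique": clique,
    }


@pytest.fixture
def small_atlas() -> ExpressionAtlas:
    values = np.array([[1.0, 0.0, 2.0], [0.0, 3.0, 0.0]])
    return ExpressionAtlas(
        values=values,
        gene_ids=("Ga", "Gb", "Gc"),
        voxel_coords=np.array([[0, 0, 0], [1, 0, 0]]),
        grid_dims=(2, 1, 1),
    )


@pytest.fixture
def small_panel() -> CellTypePanel:
    return CellTypePanel(
        values=np.array([[1.0, 2.0, 0.5], [0.0, 1.0, 4.0]]),
        type_labels=("alpha", "beta"),
        gene_ids=("Ga", "Gb", "Gc"),
    )


def make_field(values) -> DensityField:
    values = np.asarray(values, dtype=float)
    return DensityField(
        values=values,
        type_labels=tuple(f"t{i}" for i in range(values.shape[1])),
    )
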