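"""Synthetic atlases with known ground truth.

Generates a marker-structured cell-type panel, localized spatial densities
on a small 3D grid, region masks, a composed expression atlas (linear model
plus additive Gaussian noise truncated at zero), and planted gene cliques
enriched in a chosen cell type. Every downstream stage of the pipeline is
testable against these known quantities without any external data.

All randomness flows through explicit seeds; substreams are derived from
the config seed with fixed tags so stages are independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from voxtype.data_model_io import (
    CellTypePanel,
    DensityField,
    ExpressionAtlas,
    GeneClique,
    RegionMask,
    grid_coordinates,
)

logger = logging.getLogger(__name__)

# substream tags for seed derivation
_TAG_FIELD = 1
_TAG_NOISE = 2


@dataclass(frozen=True)
class SyntheticConfig:
    grid_dims: tuple[int, int, int] = (8, 8, 8)
    n_types: int = 6
    n_genes: int = 300
    markers_per_type: int = 20
    marker_strength: float = 10.0
    baseline_expression: float = 1.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid_dims) < 1:
            raise ValueError("grid_dims must be positive")
        if self.n_types < 1 or self.n_genes < 1 or self.markers_per_type < 1:
            raise ValueError("counts must be positive")
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ValueError("marker blocks exceed the number of genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.baseline_expression <= 0 or self.marker_strength <= 0:
            raise ValueError("baseline_expression and marker_strength must be > 0")

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.grid_dims
        return nx * ny * nz


def _gene_ids(n_genes: int) -> tuple[str, ...]:
    return tuple(f"g{j:04d}" for j in range(n_genes))


def _type_labels(n_types: int) -> tuple[str, ...]:
    return tuple(f"type{t:02d}" for t in range(n_types))


def generate_panel(config: SyntheticConfig) -> CellTypePanel:
    """Panel with disjoint marker blocks.

    Type ``t`` expresses genes ``[t*m, (t+1)*m)`` at
    ``baseline * marker_strength`` and every other gene at ``baseline``.
    Deterministic (no randomness involved).
    """
    if config.marker_strength == 1.0:
        logger.warning("marker_strength=1 yields a degenerate panel (identical rows)")
    m = config.markers_per_type
    values = np.full(
        (config.n_types, config.n_genes), config.baseline_expression, dtype=float
    )
    for t in range(config.n_types):
        values[t, t * m : (t + 1) * m] = (
            config.baseline_expression * config.marker_strength
        )
    return CellTypePanel(
        values=values,
        type_labels=_type_labels(config.n_types),
        gene_ids=_gene_ids(config.n_genes),
    )


def generate_density_field(
    config: SyntheticConfig,
) -> tuple[DensityField, list[RegionMask]]:
    """Localized densities: one axis-aligned slab territory per type.

    The grid is partitioned into ``n_types`` contiguous slabs along the x
    axis, so all territories (in particular the first two) are pairwise
    disjoint. Density magnitudes are drawn uniform on [0.5, 1.5] inside
    each territory and are exactly zero outside.
    """
    nx, ny, nz = config.grid_dims
    if nx < config.n_types:
        raise ValueError(
            f"grid x-extent {nx} too small to place {config.n_types} territories"
        )
    rng = np.random.default_rng([config.seed, _TAG_FIELD])
    coords = grid_coordinates(config.grid_dims)
    n_voxels = coords.shape[0]
    values = np.zeros((n_voxels, config.n_types), dtype=float)
    masks: list[RegionMask] = []
    slabs = np.array_split(np.arange(nx), config.n_types)
    labels = _type_labels(config.n_types)
    for t, slab in enumerate(slabs):
        inside = np.isin(coords[:, 0], slab)
        idx = np.flatnonzero(inside)
        values[idx, t] = rng.uniform(0.5, 1.5, size=idx.size)
        masks.append(
            RegionMask(name=f"territory_{labels[t]}", voxel_indices=frozenset(idx))
        )
    return DensityField(values=values, type_labels=labels), masks


def compose_atlas(
    field: DensityField, panel: CellTypePanel, config: SyntheticConfig
) -> ExpressionAtlas:
    """Compose expression energies as densities x transcriptomes + noise.

    ``E = rho @ C`` plus i.i.d. Gaussian noise of standard deviation
    ``noise_sd``, truncated at zero so atlas invariants hold. With
    ``noise_sd=0`` the result is the exact matrix product.
    """
    if field.n_types != panel.n_types:
        raise ValueError(
            f"field has {field.n_types} types but panel has {panel.n_types}"
        )
    if field.n_voxels != config.n_voxels:
        raise ValueError("field voxel count does not match config grid")
    values = field.values @ panel.values
    if config.noise_sd > 0:
        rng = np.random.default_rng([config.seed, _TAG_NOISE])
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
        np.maximum(values, 0.0, out=values)
    return ExpressionAtlas(
        values=values,
        gene_ids=panel.gene_ids,
        voxel_coords=grid_coordinates(config.grid_dims),
        grid_dims=config.grid_dims,
    )


def marker_genes(panel: CellTypePanel, target_type: int) -> tuple[str, ...]:
    """Genes strictly above the target type's baseline (its marker block)."""
    row = panel.values[target_type]
    return tuple(
        panel.gene_ids[j] for j in np.flatnonzero(row > row.min())
    )


def plant_clique(
    panel: CellTypePanel, target_type: int, k: int, seed: int
) -> GeneClique:
    """Sample a clique of ``k`` genes from the target type's marker block."""
    if not 0 <= target_type < panel.n_types:
        raise ValueError(f"target_type {target_type} out of range")
    markers = marker_genes(panel, target_type)
    if k > len(markers):
        raise ValueError(
            f"clique size {k} exceeds the {len(markers)}-gene marker block "
            f"of type {target_type}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(markers), size=k, replace=False)
    return GeneClique(
        name=f"planted_t{target_type}_k{k}",
        gene_ids=tuple(markers[j] for j in chosen),
    )
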