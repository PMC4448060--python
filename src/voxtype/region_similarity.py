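"""Cosine similarity between density profiles and anatomical region masks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from voxtype.data_model_io import DensityField, RegionMask


@dataclass
class RegionIndicator:
    """Unit-norm vector uniform on a region's voxels and zero elsewhere."""

    values: np.ndarray
    mask_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("indicator must be nonnegative")
        norm = float(np.linalg.norm(self.values))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("indicator must have unit L2 norm")


def region_indicator(mask: RegionMask, n_voxels: int) -> RegionIndicator:
    """Indicator with value 1/sqrt(|mask|) on mask voxels, 0 elsewhere."""
    mask.validate_against(n_voxels)
    values = np.zeros(n_voxels, dtype=float)
    idx = np.fromiter(mask.voxel_indices, dtype=int)
    values[idx] = 1.0 / np.sqrt(len(mask.voxel_indices))
    return RegionIndicator(values=values, mask_name=mask.name)


def region_cosine(density: np.ndarray, indicator: RegionIndicator) -> float:
    """Cosine of a density profile to the region indicator; 0 for zero density."""
    density = np.asarray(density, dtype=float)
    if density.shape != indicator.values.shape:
        raise ValueError("density and indicator lengths differ")
    if np.any(density < 0):
        raise ValueError("density must be nonnegative")
    norm = float(np.linalg.norm(density))
    if norm == 0.0:
        return 0.0
    return float(min(1.0, float(density @ indicator.values) / norm))


def rank_types_by_region(
    field: DensityField, mask: RegionMask
) -> list[tuple[int, float]]:
    """All (type index, phi) pairs by descending phi, ties by type index."""
    chi = region_indicator(mask, field.n_voxels)
    phi = np.array(
        [region_cosine(field.values[:, t], chi) for t in range(field.n_types)]
    )
    order = sorted(range(field.n_types), key=lambda t: (-phi[t], t))
    return [(t, float(phi[t])) for t in order]
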