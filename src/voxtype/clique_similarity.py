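"""Clique expression profiles, cosine scoring, and the threshold sweep.

A clique's brain-wide profile is the elementwise sum of its member genes'
expression columns (optionally L2-normalizing each column first, which
damps gene-to-gene multiplicative effects). Profiles are scored against
density columns with the cosine similarity, which lies in [0, 1] because
both vectors are nonnegative. The threshold sweep L2-normalizes the
profile, zeroes entries at or below a threshold tau running from 0 to
the profile maximum, and records the similarity curve per cell type; a
high peak at a positive tau indicates that the cell type's territory is
highlighted by the clique's strongly expressing voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from voxtype.data_model_io import DensityField, ExpressionAtlas, GeneClique

logger = logging.getLogger(__name__)


@dataclass
class CliqueProfile:
    """Summed expression profile of a gene clique over all voxels."""

    values: np.ndarray  # (n_voxels,), nonnegative
    clique_name: str
    n_genes: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile must be 1-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile must be finite")
        if np.any(self.values < 0):
            raise ValueError("profile must be nonnegative")


@dataclass
class ThresholdSweep:
    thresholds: np.ndarray  # ascending, from 0 to max of normalized profile
    similarities: np.ndarray  # (n_thresholds, n_types), entries in [0, 1]
    peak_thresholds: np.ndarray  # (n_types,)
    peak_values: np.ndarray  # (n_types,)


def sum_expression(
    atlas: ExpressionAtlas, clique: GeneClique, per_gene_normalize: bool = False
) -> CliqueProfile:
    """Sum the clique's gene columns into one voxel profile.

    With ``per_gene_normalize`` each column is divided by its L2 norm
    before summing; all-zero columns are skipped with a warning.
    """
    total = np.zeros(atlas.n_voxels, dtype=float)
    for g in clique.gene_ids:
        col = atlas.gene_column(g)  # raises KeyError naming the gene
        if per_gene_normalize:
            norm = float(np.linalg.norm(col))
            if norm == 0.0:
                logger.warning("gene %s has an all-zero column; skipped", g)
                continue
            col = col / norm
        total += col
    return CliqueProfile(values=total, clique_name=clique.name, n_genes=len(clique))


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine of two nonnegative voxel vectors; in [0, 1].

    Returns 0 by convention when either vector has zero norm (this is the
    limit reached at the top of the threshold sweep).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-dimensional and of equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("cosine similarity requires nonnegative vectors")
    nx = float(np.linalg.norm(x))
    ny = float(np.linalg.norm(y))
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(min(1.0, float(x @ y) / (nx * ny)))


def threshold_profile(profile: CliqueProfile, tau: float) -> CliqueProfile:
    """Zero all entries at or below ``tau``.

    At tau=0 only exact zeros are affected, so the profile is preserved;
    at tau equal to the maximum entry the result is all-zero, giving the
    zero-similarity limit at the top of the sweep.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    values = np.where(profile.values <= tau, 0.0, profile.values)
    return CliqueProfile(
        values=values, clique_name=profile.clique_name, n_genes=profile.n_genes
    )


def threshold_sweep(
    profile: CliqueProfile, field: DensityField, n_steps: int = 101
) -> ThresholdSweep:
    """Similarity of the thresholded, L2-normalized profile to every type.

    Thresholds form a uniform grid from 0 to the maximum entry of the
    normalized profile (inclusive); the per-type peak is the argmax over
    the grid, ties resolved to the smallest threshold.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be at least 2")
    norm = float(np.linalg.norm(profile.values))
    if norm == 0.0:
        raise ValueError("cannot sweep an all-zero profile")
    normalized = CliqueProfile(
        values=profile.values / norm,
        clique_name=profile.clique_name,
        n_genes=profile.n_genes,
    )
    thresholds = np.linspace(0.0, float(normalized.values.max()), n_steps)
    sims = np.empty((n_steps, field.n_types), dtype=float)
    for i, tau in enumerate(thresholds):
        cut = threshold_profile(normalized, float(tau))
        for t in range(field.n_types):
            sims[i, t] = cosine_similarity(cut.values, field.values[:, t])
    peak_idx = np.argmax(sims, axis=0)  # first occurrence = smallest tau
    return ThresholdSweep(
        thresholds=thresholds,
        similarities=sims,
        peak_thresholds=thresholds[peak_idx],
        peak_values=sims[peak_idx, np.arange(field.n_types)],
    )


def rank_by_similarity(
    profile: CliqueProfile, field: DensityField
) -> list[tuple[int, float]]:
    """All (type index, psi) pairs sorted by descending psi, ties by index."""
    psi = np.array(
        [
            cosine_similarity(profile.values, field.values[:, t])
            for t in range(field.n_types)
        ]
    )
    order = sorted(range(field.n_types), key=lambda t: (-psi[t], t))
    return [(t, float(psi[t])) for t in order]


def similarity_vector(profile: CliqueProfile, field: DensityField) -> np.ndarray:
    """psi for every type, in type order."""
    return np.array(
        [
            cosine_similarity(profile.values, field.values[:, t])
            for t in range(field.n_types)
        ]
    )
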