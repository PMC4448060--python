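"""Monte Carlo null for clique-to-cell-type similarity.

The null distribution of the cosine similarity between the summed profile
of a random gene set of size k and a cell type's density column is
simulated by drawing R random sets uniformly without replacement from the
full gene pool. One shared draw sequence is reused across all cell types
(per-type values remain marginally correct; they are positively coupled
across types). R is sized with Hoeffding's inequality: the probability of
the empirical proportion missing the truth by more than ``tolerance`` is
at most 2*exp(-2*R*tolerance^2).

Significance of an observed similarity is the fraction of null samples
strictly below it ("ties count as not-lower"); cell types are ranked by
descending significance, ties by descending observed similarity, then by
ascending type index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from voxtype.data_model_io import DensityField, ExpressionAtlas, GeneClique

_BATCH = 4096


@dataclass(frozen=True)
class MonteCarloConfig:
    n_draws: int = 27000
    seed: int = 0
    tolerance: float = 0.01
    delta: float = 0.01

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be at least 1")
        if not 0 < self.tolerance < 1 or not 0 < self.delta < 1:
            raise ValueError("tolerance and delta must lie in (0, 1)")


@dataclass
class NullDistribution:
    """Per-type sorted similarity samples for random cliques of a fixed size."""

    clique_size: int
    samples: np.ndarray  # (R, n_types), each column sorted ascending
    seed: int

    @property
    def n_draws(self) -> int:
        return self.samples.shape[0]

    @property
    def n_types(self) -> int:
        return self.samples.shape[1]


@dataclass
class SignificanceTable:
    observed: np.ndarray  # psi per type
    p_values: np.ndarray  # P_R per type, in [0, 1]
    ranks: np.ndarray  # permutation of 1..n_types, rank 1 = most significant
    type_labels: tuple[str, ...] | None = None

    def order(self) -> np.ndarray:
        """Type indices sorted from rank 1 to rank n."""
        return np.argsort(self.ranks)


def hoeffding_bound(n_draws: int, tolerance: float) -> float:
    """Value of the two-sided Hoeffding bound 2*exp(-2*R*tolerance^2)."""
    return 2.0 * math.exp(-2.0 * n_draws * tolerance**2)


def hoeffding_sample_size(tolerance: float, delta: float) -> int:
    """Smallest R with 2*exp(-2*R*tolerance^2) <= delta."""
    if not 0 < tolerance < 1 or not 0 < delta < 1:
        raise ValueError("tolerance and delta must lie in (0, 1)")
    r = math.ceil(math.log(2.0 / delta) / (2.0 * tolerance**2))
    while r > 1 and hoeffding_bound(r - 1, tolerance) <= delta:
        r -= 1
    while hoeffding_bound(r, tolerance) > delta:
        r += 1
    return r


def _draw_index_matrix(
    rng: np.random.Generator, pool_size: int, k: int, n_draws: int
) -> np.ndarray:
    """(n_draws, k) indices, each row a uniform k-subset of the pool."""
    if k > pool_size:
        raise ValueError(f"cannot draw {k} genes from a pool of {pool_size}")
    # argsort of iid uniforms yields a uniform random permutation per row
    return np.argsort(
        rng.random((n_draws, pool_size)), axis=1, kind="stable"
    )[:, :k]


def draw_random_cliques(
    gene_pool: tuple[str, ...] | list[str], k: int, n_draws: int, seed: int
) -> list[GeneClique]:
    """R independent uniform k-subsets of the gene pool, reproducible by seed."""
    pool = tuple(gene_pool)
    rng = np.random.default_rng(seed)
    idx = _draw_index_matrix(rng, len(pool), k, n_draws)
    return [
        GeneClique(
            name=f"random_{r:06d}", gene_ids=tuple(pool[j] for j in idx[r])
        )
        for r in range(n_draws)
    ]


def random_profiles(
    atlas: ExpressionAtlas, k: int, n_draws: int, seed: int
):
    """Yield (start, profiles) batches; profiles has shape (n_voxels, batch).

    Uses the identical draw sequence as :func:`draw_random_cliques` with
    the same seed, so profile-level and clique-level APIs agree.
    """
    rng = np.random.default_rng(seed)
    idx = _draw_index_matrix(rng, atlas.n_genes, k, n_draws)
    for start in range(0, n_draws, _BATCH):
        block = idx[start : start + _BATCH]  # (B, k)
        yield start, atlas.values[:, block].sum(axis=2)


def simulate_null(
    atlas: ExpressionAtlas,
    field: DensityField,
    k: int,
    config: MonteCarloConfig,
) -> NullDistribution:
    """Simulate similarity samples for all types from one shared draw sequence."""
    if field.n_voxels != atlas.n_voxels:
        raise ValueError("atlas and field voxel counts differ")
    col_norms = np.linalg.norm(field.values, axis=0)
    safe_norms = np.where(col_norms == 0.0, 1.0, col_norms)
    samples = np.empty((config.n_draws, field.n_types), dtype=float)
    for start, profiles in random_profiles(atlas, k, config.n_draws, config.seed):
        pnorm = np.linalg.norm(profiles, axis=0)
        safe_p = np.where(pnorm == 0.0, 1.0, pnorm)
        sims = (profiles.T @ field.values) / (safe_p[:, None] * safe_norms[None, :])
        sims[pnorm == 0.0, :] = 0.0
        sims[:, col_norms == 0.0] = 0.0
        samples[start : start + profiles.shape[1]] = np.minimum(sims, 1.0)
    samples.sort(axis=0)
    return NullDistribution(clique_size=k, samples=samples, seed=config.seed)


def significance(
    observed: np.ndarray,
    null: NullDistribution,
    type_labels: tuple[str, ...] | None = None,
) -> SignificanceTable:
    """P_R per type: fraction of null samples strictly below the observed psi."""
    observed = np.asarray(observed, dtype=float)
    if observed.shape != (null.n_types,):
        raise ValueError(
            f"observed has shape {observed.shape}, expected ({null.n_types},)"
        )
    if type_labels is not None and len(type_labels) != null.n_types:
        raise ValueError("type_labels length must match the null distribution")
    R = null.n_draws
    p = np.array(
        [
            np.searchsorted(null.samples[:, t], observed[t], side="left") / R
            for t in range(null.n_types)
        ]
    )
    order = sorted(
        range(null.n_types), key=lambda t: (-p[t], -observed[t], t)
    )
    ranks = np.empty(null.n_types, dtype=int)
    for r, t in enumerate(order, start=1):
        ranks[t] = r
    return SignificanceTable(
        observed=observed, p_values=p, ranks=ranks, type_labels=type_labels
    )
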