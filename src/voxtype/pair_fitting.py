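"""Optimal nonnegative two-type fits of a clique profile.

For a pair of density columns (rho1, rho2) the best nonnegative
combination minimizing ||E - a1*rho1 - a2*rho2||^2 is found in closed form:
solve the unconstrained 2x2 normal equations; if a coefficient is
negative, fall back to the two single-column boundary problems and keep
the lower objective. The pair similarity psi_pair is the cosine between
the fitted vector and the profile, which always dominates both single-type
similarities because single-type fits are feasible points.

"Better pairs" are those whose psi_pair strictly exceeds the best
single-type psi; their significance reuses the Monte Carlo draw sequence
of the single-type null, re-solving the pair fit for every random profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from voxtype.clique_similarity import CliqueProfile, cosine_similarity
from voxtype.data_model_io import DensityField, ExpressionAtlas
from voxtype.monte_carlo import MonteCarloConfig, random_profiles


@dataclass
class PairFitResult:
    t1: int
    t2: int
    alpha: np.ndarray  # optimal nonnegative coefficients (a1, a2)
    fitted: np.ndarray  # a1*rho1 + a2*rho2
    psi_pair: float
    in_better_set: bool | None = None
    p_value: float | None = None


def _as_values(profile: CliqueProfile | np.ndarray) -> np.ndarray:
    if isinstance(profile, CliqueProfile):
        return profile.values
    return np.asarray(profile, dtype=float)


def _solve_two_column(
    e: np.ndarray, rho1: np.ndarray, rho2: np.ndarray
) -> np.ndarray:
    """Argmin over alpha >= 0 of ||e - a1*rho1 - a2*rho2||^2."""
    g11 = float(rho1 @ rho1)
    g22 = float(rho2 @ rho2)
    g12 = float(rho1 @ rho2)
    h1 = float(e @ rho1)
    h2 = float(e @ rho2)

    def objective(a1: float, a2: float) -> float:
        return (
            -2.0 * (a1 * h1 + a2 * h2)
            + a1 * a1 * g11
            + 2.0 * a1 * a2 * g12
            + a2 * a2 * g22
        )

    candidates: list[tuple[float, float]] = []
    det = g11 * g22 - g12 * g12
    if det > 1e-14 * max(g11 * g22, 1e-300):
        a1 = (h1 * g22 - h2 * g12) / det
        a2 = (h2 * g11 - h1 * g12) / det
        if a1 >= 0.0 and a2 >= 0.0:
            candidates.append((a1, a2))
    # boundary problems (also cover the collinear case)
    b1 = max(0.0, h1 / g11) if g11 > 0 else 0.0
    b2 = max(0.0, h2 / g22) if g22 > 0 else 0.0
    candidates.append((b1, 0.0))
    candidates.append((0.0, b2))
    best = min(candidates, key=lambda a: objective(*a))
    return np.array(best, dtype=float)


def fit_pair(
    profile: CliqueProfile | np.ndarray,
    rho1: np.ndarray,
    rho2: np.ndarray,
    t1: int = 0,
    t2: int = 1,
) -> PairFitResult:
    """Best nonnegative combination of two density columns for one profile."""
    e = _as_values(profile)
    rho1 = np.asarray(rho1, dtype=float)
    rho2 = np.asarray(rho2, dtype=float)
    if e.shape != rho1.shape or e.shape != rho2.shape:
        raise ValueError("profile and density vectors must have equal length")
    if np.any(e < 0) or np.any(rho1 < 0) or np.any(rho2 < 0):
        raise ValueError("inputs must be nonnegative")
    if not np.any(e):
        raise ValueError("cannot fit an all-zero profile")
    if not np.any(rho1) and not np.any(rho2):
        raise ValueError("density vectors must not both be zero")
    alpha = _solve_two_column(e, rho1, rho2)
    fitted = alpha[0] * rho1 + alpha[1] * rho2
    psi = cosine_similarity(fitted, e)
    return PairFitResult(t1=t1, t2=t2, alpha=alpha, fitted=fitted, psi_pair=psi)


def pair_similarity_matrix(
    profile: CliqueProfile | np.ndarray, field: DensityField
) -> np.ndarray:
    """Symmetric (n_types, n_types) matrix of psi_pair; diagonal = single psi."""
    if field.n_types < 2:
        raise ValueError("need at least two cell types")
    e = _as_values(profile)
    T = field.n_types
    M = np.empty((T, T), dtype=float)
    for t in range(T):
        M[t, t] = cosine_similarity(e, field.values[:, t])
    for t1 in range(T):
        for t2 in range(t1 + 1, T):
            res = fit_pair(e, field.values[:, t1], field.values[:, t2], t1, t2)
            M[t1, t2] = M[t2, t1] = res.psi_pair
    return M


def better_pairs(
    pair_matrix: np.ndarray, single_psi: np.ndarray
) -> set[tuple[int, int]]:
    """Unordered pairs whose psi_pair strictly beats every single-type psi."""
    single_psi = np.asarray(single_psi, dtype=float)
    T = pair_matrix.shape[0]
    if pair_matrix.shape != (T, T) or single_psi.shape != (T,):
        raise ValueError("inconsistent dimensions")
    best_single = float(single_psi.max())
    return {
        (t1, t2)
        for t1 in range(T)
        for t2 in range(t1 + 1, T)
        if pair_matrix[t1, t2] > best_single
    }


def pair_psi_batch(
    profiles: np.ndarray, rho1: np.ndarray, rho2: np.ndarray
) -> np.ndarray:
    """psi_pair of many profiles (columns of ``profiles``) to one pair.

    Vectorized over draws via the candidate enumeration of the 2x2 KKT
    system; agrees with :func:`fit_pair` applied column by column.
    """
    g11 = float(rho1 @ rho1)
    g22 = float(rho2 @ rho2)
    g12 = float(rho1 @ rho2)
    h1 = profiles.T @ rho1  # (R,)
    h2 = profiles.T @ rho2
    det = g11 * g22 - g12 * g12

    def objective(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
        return (
            -2.0 * (a1 * h1 + a2 * h2)
            + a1 * a1 * g11
            + 2.0 * a1 * a2 * g12
            + a2 * a2 * g22
        )

    cand_a1 = []
    cand_a2 = []
    cand_obj = []
    zeros = np.zeros_like(h1)
    if det > 1e-14 * max(g11 * g22, 1e-300):
        a1 = (h1 * g22 - h2 * g12) / det
        a2 = (h2 * g11 - h1 * g12) / det
        feasible = (a1 >= 0.0) & (a2 >= 0.0)
        obj = np.where(feasible, objective(a1, a2), np.inf)
        cand_a1.append(np.where(feasible, a1, 0.0))
        cand_a2.append(np.where(feasible, a2, 0.0))
        cand_obj.append(obj)
    b1 = np.maximum(0.0, h1 / g11) if g11 > 0 else zeros
    cand_a1.append(b1)
    cand_a2.append(zeros)
    cand_obj.append(objective(b1, zeros))
    b2 = np.maximum(0.0, h2 / g22) if g22 > 0 else zeros
    cand_a1.append(zeros)
    cand_a2.append(b2)
    cand_obj.append(objective(zeros, b2))

    obj = np.stack(cand_obj)  # (n_cand, R)
    pick = np.argmin(obj, axis=0)
    a1 = np.choose(pick, cand_a1)
    a2 = np.choose(pick, cand_a2)
    # at the constrained optimum, <fitted, e> = ||fitted||^2
    dot = a1 * h1 + a2 * h2
    fit_norm = np.sqrt(np.maximum(dot, 0.0))
    p_norm = np.linalg.norm(profiles, axis=0)
    denom = fit_norm * p_norm
    psi = np.zeros_like(dot)
    ok = denom > 0
    psi[ok] = np.minimum(1.0, dot[ok] / denom[ok])
    return psi


def pair_significance(
    atlas: ExpressionAtlas,
    field: DensityField,
    profile: CliqueProfile,
    pairs: set[tuple[int, int]] | list[tuple[int, int]],
    k: int,
    config: MonteCarloConfig,
) -> dict[tuple[int, int], float]:
    """P_R per pair: fraction of random-clique pair fits strictly below observed.

    Reuses the same draw sequence (same seed) as the single-type null.
    """
    pairs = sorted({(min(a, b), max(a, b)) for a, b in pairs})
    observed = {
        p: fit_pair(
            profile, field.values[:, p[0]], field.values[:, p[1]], *p
        ).psi_pair
        for p in pairs
    }
    below = {p: 0 for p in pairs}
    total = 0
    for _start, profiles in random_profiles(atlas, k, config.n_draws, config.seed):
        total += profiles.shape[1]
        for p in pairs:
            psi = pair_psi_batch(
                profiles, field.values[:, p[0]], field.values[:, p[1]]
            )
            below[p] += int(np.count_nonzero(psi < observed[p]))
    return {p: below[p] / total for p in pairs}


def pair_occurrence_histogram(
    pairs: set[tuple[int, int]] | list[tuple[int, int]], n_types: int
) -> np.ndarray:
    """Count, per type, of qualifying pairs containing it (mass = 2x pairs)."""
    counts = np.zeros(n_types, dtype=int)
    for t1, t2 in pairs:
        counts[t1] += 1
        counts[t2] += 1
    return counts
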