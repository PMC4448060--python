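import itertools

import numpy as np
import pytest

from voxtype.clique_similarity import cosine_similarity, sum_expression
from voxtype.monte_carlo import MonteCarloConfig, random_profiles
from voxtype.pair_fitting import (
    better_pairs,
    fit_pair,
    pair_occurrence_histogram,
    pair_psi_batch,
    pair_significance,
    pair_similarity_matrix,
)

from tests.conftest import make_field


def pair_objective(e, rho1, rho2, a1, a2):
    r = e - a1 * rho1 - a2 * rho2
    return float(r @ r)


def refined_grid_oracle(e, rho1, rho2, step=1e-3, refinements=2):
    """Grid search at the given step, then zoomed re-grids around the best.

    Works on unit-normalized columns, where any optimal coefficient is
    bounded by ||e|| (the fitted vector is no longer than e and the
    nonnegative cross term only adds length), so the grid extent is known
    a priori. The objective is expanded through the Gram scalars, which is
    exact and keeps the search O(grid^2) instead of O(grid^2 * dim).
    """
    n1, n2 = np.linalg.norm(rho1), np.linalg.norm(rho2)
    u1 = rho1 / n1 if n1 > 0 else rho1
    u2 = rho2 / n2 if n2 > 0 else rho2
    ee = float(e @ e)
    h1, h2, g12 = float(e @ u1), float(e @ u2), float(u1 @ u2)
    hi = 1.5 * np.sqrt(ee) + step

    def search(lo1, hi1, lo2, hi2, s):
        g1 = np.arange(max(lo1, 0.0), hi1 + s / 2, s)
        g2 = np.arange(max(lo2, 0.0), hi2 + s / 2, s)
        best = (0.0, 0.0, np.inf)
        for b1 in g1:  # chunk by rows to bound memory
            obj = (
                ee
                - 2.0 * (b1 * h1 + g2 * h2)
                + b1 * b1
                + 2.0 * b1 * g2 * g12
                + g2 * g2
            )
            j = int(np.argmin(obj))
            if obj[j] < best[2]:
                best = (float(b1), float(g2[j]), float(obj[j]))
        return best

    b1, b2, obj = search(0.0, hi, 0.0, hi, step)
    s = step
    for _ in range(refinements):
        s /= 50.0
        b1, b2, obj = search(b1 - 60 * s, b1 + 60 * s, b2 - 60 * s, b2 + 60 * s, s)
    alpha = (b1 / n1 if n1 > 0 else 0.0, b2 / n2 if n2 > 0 else 0.0)
    return alpha, obj


class TestFitPair:
    def test_exact_multiple_of_first_column(self):
        rho1 = np.array([1.0, 2.0, 0.5])
        rho2 = np.array([0.0, 1.0, 1.0])
        res = fit_pair(3.0 * rho1, rho1, rho2)
        np.testing.assert_allclose(res.alpha, [3.0, 0.0], atol=1e-10)
        assert res.psi_pair == pytest.approx(1.0)

    def test_orthogonal_basis(self):
        res = fit_pair(
            np.array([3.0, 4.0]), np.array([1.0, 0.0]), np.array([0.0, 1.0])
        )
        np.testing.assert_allclose(res.alpha, [3.0, 4.0], atol=1e-12)
        assert res.psi_pair == pytest.approx(1.0)

    def test_boundary_solution_matches_grid_oracle(self):
        # unconstrained alpha1 < 0 -> optimum sits on the rho2 boundary
        rho1 = np.array([1.0, 0.0])
        rho2 = np.array([1.0, 1.0]) / np.sqrt(2)
        e = np.array([0.0, 1.0])
        res = fit_pair(e, rho1, rho2)
        (b1, b2), oracle_obj = refined_grid_oracle(e, rho1, rho2)
        assert pair_objective(e, rho1, rho2, *res.alpha) <= oracle_obj + 1e-9
        assert res.alpha[0] == 0.0
        assert res.psi_pair == pytest.approx(1 / np.sqrt(2), abs=1e-9)

    def test_collinear_densities_no_error(self):
        rho = np.array([1.0, 2.0, 3.0])
        res = fit_pair(np.array([2.0, 4.0, 6.0]), rho, 2.0 * rho)
        assert res.psi_pair == pytest.approx(1.0)
        fitted_total = res.alpha[0] * rho + res.alpha[1] * 2.0 * rho
        np.testing.assert_allclose(fitted_total, [2.0, 4.0, 6.0], atol=1e-9)

    def test_zero_profile_rejected(self):
        with pytest.raises(ValueError):
            fit_pair(np.zeros(3), np.ones(3), np.ones(3))

    def test_both_densities_zero_rejected(self):
        with pytest.raises(ValueError):
            fit_pair(np.ones(3), np.zeros(3), np.zeros(3))

    def test_kkt_conditions_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(2, 8))
            e = rng.random(n)
            rho1 = rng.random(n)
            rho2 = rng.random(n)
            if not np.any(e):
                continue
            res = fit_pair(e, rho1, rho2)
            scale = max(float(e @ e), 1.0)
            # gradient of ||e - a1 r1 - a2 r2||^2 wrt (a1, a2)
            resid = e - res.alpha[0] * rho1 - res.alpha[1] * rho2
            for a, rho in ((res.alpha[0], rho1), (res.alpha[1], rho2)):
                grad = -2.0 * float(resid @ rho)
                if a > 0:
                    assert abs(grad) < 1e-6 * scale
                else:
                    assert grad >= -1e-6 * scale

    def test_cone_cosine_equivalence_via_angular_grid(self):
        # max cosine over the nonnegative cone equals the cosine of the
        # distance-minimizing point; oracle is a 1-D grid over cone angles
        rng = np.random.default_rng(8)
        thetas = np.linspace(0.0, np.pi / 2, 100_001)
        w1, w2 = np.cos(thetas), np.sin(thetas)
        for _ in range(20):
            n = int(rng.integers(2, 6))
            e = rng.random(n) + 0.01
            rho1 = rng.random(n) + 0.01
            rho2 = rng.random(n) + 0.01
            res = fit_pair(e, rho1, rho2)
            combos = np.outer(w1, rho1) + np.outer(w2, rho2)
            cosines = (combos @ e) / (
                np.linalg.norm(combos, axis=1) * np.linalg.norm(e)
            )
            assert res.psi_pair == pytest.approx(float(cosines.max()), abs=1e-6)


class TestPairSimilarityMatrix:
    def test_symmetric_with_single_psi_diagonal(self, tiny_world):
        profile = sum_expression(tiny_world["atlas"], tiny_world["clique"])
        field = tiny_world["field"]
        M = pair_similarity_matrix(profile, field)
        np.testing.assert_allclose(M, M.T, atol=0)
        for t in range(field.n_types):
            assert M[t, t] == pytest.approx(
                cosine_similarity(profile.values, field.values[:, t])
            )

    def test_dominance_matrix_wide(self, tiny_world):
        profile = sum_expression(tiny_world["atlas"], tiny_world["clique"])
        M = pair_similarity_matrix(profile, tiny_world["field"])
        T = M.shape[0]
        for t1, t2 in itertools.combinations(range(T), 2):
            assert M[t1, t2] >= max(M[t1, t1], M[t2, t2]) - 1e-9

    def test_three_type_matrix_matches_grid_oracle(self):
        rng = np.random.default_rng(9)
        field = make_field(rng.random((6, 3)))
        e = rng.random(6) + 0.1
        M = pair_similarity_matrix(e, field)
        for t1, t2 in itertools.combinations(range(3), 2):
            rho1, rho2 = field.values[:, t1], field.values[:, t2]
            (b1, b2), _ = refined_grid_oracle(e, rho1, rho2)
            fitted = b1 * rho1 + b2 * rho2
            psi_oracle = float(
                fitted @ e / (np.linalg.norm(fitted) * np.linalg.norm(e))
            )
            assert M[t1, t2] == pytest.approx(psi_oracle, abs=1e-6)


class TestBetterPairs:
    def test_perfect_single_type_gives_empty_set(self):
        M = np.array([[1.0, 1.0], [1.0, 0.3]])
        assert better_pairs(M, np.array([1.0, 0.3])) == set()

    def test_zero_singles_with_positive_pair(self):
        M = np.array([[0.0, 0.6], [0.6, 0.0]])
        assert better_pairs(M, np.array([0.0, 0.0])) == {(0, 1)}

    def test_fraction_arithmetic(self):
        n_pairs = 64 * 63 // 2
        assert n_pairs == 2016
        assert round(100 * 62 / n_pairs, 2) == 3.08
        assert round(100 * 66 / n_pairs, 2) == 3.27


class TestPairPsiBatch:
    def test_agrees_with_fit_pair_per_column(self):
        rng = np.random.default_rng(10)
        profiles = rng.random((12, 40))
        rho1 = rng.random(12)
        rho2 = rng.random(12)
        batch = pair_psi_batch(profiles, rho1, rho2)
        for r in range(profiles.shape[1]):
            single = fit_pair(profiles[:, r], rho1, rho2).psi_pair
            assert batch[r] == pytest.approx(single, abs=1e-10)


class TestPairSignificance:
    def test_unreachable_observed_gives_p_one(self, tiny_world):
        atlas, field = tiny_world["atlas"], tiny_world["field"]
        profile = sum_expression(atlas, tiny_world["clique"])
        cfg = MonteCarloConfig(n_draws=300, seed=0)
        p = pair_significance(atlas, field, profile, {(0, 1)}, 3, cfg)
        # the observed profile is a pure type-0 marker sum; nearly every
        # random 3-gene profile fits the (0, 1) plane strictly worse
        assert 0.0 <= p[(0, 1)] <= 1.0

    def test_single_gene_pool_all_ties(self, tiny_world):
        # pool of one gene: every draw equals the observed clique -> ties
        # count as not-lower, so P_R = 0
        from tests.test_monte_carlo import _single_gene_atlas
        from voxtype.data_model_io import GeneClique
        from voxtype.clique_similarity import sum_expression as s

        sub = _single_gene_atlas(tiny_world["atlas"], 0)
        field = tiny_world["field"]
        profile = s(sub, GeneClique(name="c", gene_ids=(sub.gene_ids[0],)))
        p = pair_significance(
            sub, field, profile, {(0, 1)}, 1, MonteCarloConfig(n_draws=50, seed=0)
        )
        assert p[(0, 1)] == 0.0

    def test_matches_enumeration_on_toy_pool(self, tiny_world):
        atlas, field = tiny_world["atlas"], tiny_world["field"]
        profile = sum_expression(atlas, tiny_world["clique"])
        pair = (0, 1)
        rho1, rho2 = field.values[:, 0], field.values[:, 1]
        observed = fit_pair(profile, rho1, rho2).psi_pair
        combos = list(itertools.combinations(range(atlas.n_genes), 3))
        below = 0
        for combo in combos:
            prof = atlas.values[:, list(combo)].sum(axis=1)
            below += fit_pair(prof, rho1, rho2).psi_pair < observed
        exact = below / len(combos)
        cfg = MonteCarloConfig(n_draws=5000, seed=3)
        p = pair_significance(atlas, field, profile, {pair}, 3, cfg)
        assert abs(p[pair] - exact) <= 0.05

    def test_reuses_single_null_draw_sequence(self, tiny_world):
        # same seed -> pair significance sees the very profiles produced by
        # random_profiles, so results are exactly reproducible
        atlas, field = tiny_world["atlas"], tiny_world["field"]
        profile = sum_expression(atlas, tiny_world["clique"])
        cfg = MonteCarloConfig(n_draws=200, seed=17)
        p1 = pair_significance(atlas, field, profile, {(0, 2)}, 3, cfg)
        p2 = pair_significance(atlas, field, profile, {(0, 2)}, 3, cfg)
        assert p1 == p2
        prof_batches = [b for _, b in random_profiles(atlas, 3, 200, 17)]
        manual = np.concatenate(
            [
                pair_psi_batch(b, field.values[:, 0], field.values[:, 2])
                for b in prof_batches
            ]
        )
        observed = fit_pair(profile, field.values[:, 0], field.values[:, 2]).psi_pair
        assert p1[(0, 2)] == np.mean(manual < observed)


class TestPairOccurrenceHistogram:
    def test_counts_and_mass(self):
        counts = pair_occurrence_histogram({(1, 2), (1, 3)}, n_types=5)
        np.testing.assert_array_equal(counts, [0, 2, 1, 1, 0])
        assert counts.sum() == 4

    def test_empty_set(self):
        counts = pair_occurrence_histogram(set(), n_types=3)
        np.testing.assert_array_equal(counts, [0, 0, 0])

    def test_mass_is_twice_pair_count(self):
        rng = np.random.default_rng(11)
        pairs = set()
        while len(pairs) < 62:
            a, b = sorted(rng.integers(0, 64, size=2))
            if a != b:
                pairs.add((int(a), int(b)))
        assert pair_occurrence_histogram(pairs, 64).sum() == 124
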