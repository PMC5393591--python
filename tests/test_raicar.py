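"""RAICAR: cross-correlation bookkeeping, alignment, reproducibility."""

import itertools

import numpy as np
import pytest

from miprest import (
    align_components,
    cross_correlation_matrices,
    raicar_decompose,
    reproducibility,
)
from miprest.ica import ICARealization
from miprest.raicar import ReproducibleICA, _signed_cross_correlations


def realization_from_sources(S):
    S = np.asarray(S, dtype=float)
    return ICARealization(
        S_hat=S,
        A_hat=np.zeros((S.shape[0], S.shape[0])),
        converged_flags=np.ones(S.shape[0], dtype=bool),
        n_requested=S.shape[0],
    )


class TestCrossCorrelations:
    def test_pair_count(self, rng):
        reals = [
            realization_from_sources(rng.standard_normal((2, 200)))
            for _ in range(4)
        ]
        crcm = cross_correlation_matrices(reals)
        assert len(crcm) == 4 * 3 // 2

    def test_identical_realizations_give_permutation_of_ones(self, rng):
        S = rng.standard_normal((3, 500))
        crcm = cross_correlation_matrices(
            [realization_from_sources(S), realization_from_sources(S[::-1])]
        )
        M = crcm[(0, 1)]
        assert np.all((M >= 0) & (M <= 1 + 1e-12))
        np.testing.assert_allclose(np.sort(M.max(axis=1)), 1.0, atol=1e-12)

    def test_mismatched_sample_counts_error(self, rng):
        a = realization_from_sources(rng.standard_normal((2, 100)))
        b = realization_from_sources(rng.standard_normal((2, 101)))
        with pytest.raises(ValueError):
            cross_correlation_matrices([a, b])


def exhaustive_alignment(crcm, K, n_comp):
    """Oracle: exhaustively search per-realization permutations maximizing the
    total within-group mean |corr| (feasible only for tiny K and n_comp)."""
    best_score, best_groups = -1.0, None
    perms = list(itertools.permutations(range(n_comp)))
    for assign in itertools.product(perms, repeat=K - 1):
        # group g contains component g of realization 0 and perm[g] of others
        groups = []
        for g in range(n_comp):
            grp = [(0, g, 1.0)]
            for k, perm in enumerate(assign, start=1):
                grp.append((k, perm[g], 1.0))
            groups.append(grp)
        score = sum(reproducibility(g, crcm) for g in groups)
        if score > best_score:
            best_score, best_groups = score, groups
    return best_groups, best_score


class TestAlignment:
    def test_identical_realizations_full_groups(self, rng):
        S = rng.standard_normal((3, 400))
        reals = [realization_from_sources(S) for _ in range(4)]
        crcm = _signed_cross_correlations(reals)
        groups = align_components(crcm, 4, 3)
        full = [g for g in groups if len(g) == 4]
        assert len(full) == 3
        for g in full:
            assert len({k for k, _, _ in g}) == 4  # one member per realization
            assert reproducibility(g, crcm) == pytest.approx(1.0, abs=1e-12)

    def test_missing_component_gives_short_group(self, rng):
        S = rng.standard_normal((3, 400))
        reals = [realization_from_sources(S) for _ in range(3)]
        reals[1] = realization_from_sources(S[:2])  # one dropped component
        crcm = _signed_cross_correlations(reals)
        groups = align_components(crcm, 3, 3)
        sizes = sorted(len(g) for g in groups)
        assert sizes == [2, 3, 3]

    def test_greedy_matches_exhaustive_oracle(self, rng):
        """On a small sparse-plus-noise instance the greedy alignment attains
        the exhaustive-search grouping."""
        n, K = 3, 3
        sparse = rng.laplace(size=(2, 3000))
        reals = []
        for k in range(K):
            noise = rng.standard_normal((1, 3000))
            S = np.vstack([sparse + 0.05 * rng.standard_normal((2, 3000)), noise])
            perm = rng.permutation(n)
            reals.append(realization_from_sources(S[perm]))
        crcm = _signed_cross_correlations(reals)
        greedy = align_components(crcm, K, n)
        oracle, oracle_score = exhaustive_alignment(crcm, K, n)
        greedy_score = sum(reproducibility(g, crcm) for g in greedy)
        assert greedy_score == pytest.approx(oracle_score, abs=1e-9)


class TestReproducibility:
    def test_identical_components_r_one(self, rng):
        S = rng.standard_normal((2, 300))
        reals = [realization_from_sources(S) for _ in range(3)]
        crcm = _signed_cross_correlations(reals)
        group = [(0, 0, 1.0), (1, 0, 1.0), (2, 0, 1.0)]
        assert reproducibility(group, crcm) == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_near_zero(self, rng):
        """Monte-Carlo null: |corr| between independent vectors at p=1e4."""
        reals = [
            realization_from_sources(rng.standard_normal((1, 10_000)))
            for _ in range(5)
        ]
        crcm = _signed_cross_correlations(reals)
        group = [(k, 0, 1.0) for k in range(5)]
        assert reproducibility(group, crcm) < 0.05

    def test_singleton_and_empty_zero(self):
        assert reproducibility([], {}) == 0.0
        assert reproducibility([(0, 0, 1.0)], {}) == 0.0


class TestRaicarDecompose:
    def test_replicated_sparse_source(self, rng):
        s = rng.laplace(size=4000)
        X = np.vstack([s, s, s]) + 1e-6 * rng.standard_normal((3, 4000))
        res = raicar_decompose(X, n_components=1, n_runs=4, seed=0)
        assert res.R[0] == pytest.approx(1.0, abs=1e-3)

    def test_r_sorted_and_bounded(self, small_overextraction):
        res = raicar_decompose(
            small_overextraction.X, n_components=10, n_runs=4, seed=1
        )
        assert np.all(np.diff(res.R) <= 1e-12)
        assert np.all((res.R >= 0) & (res.R <= 1 + 1e-12))
        assert len(res.R) == 10

    def test_missing_groups_have_zero_rows(self, small_overextraction):
        res = raicar_decompose(
            small_overextraction.X, n_components=10, n_runs=4, seed=1
        )
        empty = [i for i, g in enumerate(res.groups) if not g]
        assert empty, "overextraction should leave unfilled groups"
        for i in empty:
            assert res.R[i] == 0.0
            np.testing.assert_array_equal(res.S_avg[i], 0.0)

    def test_deterministic_under_seed(self, two_laplace_mixture):
        a = raicar_decompose(two_laplace_mixture.X, 2, n_runs=3, seed=9)
        b = raicar_decompose(two_laplace_mixture.X, 2, n_runs=3, seed=9)
        np.testing.assert_array_equal(a.R, b.R)
        np.testing.assert_array_equal(a.S_avg, b.S_avg)
        np.testing.assert_array_equal(a.A_avg, b.A_avg)

    def test_averaged_sources_unit_variance_and_no_intra_realization_mixing(
        self, two_laplace_mixture
    ):
        res = raicar_decompose(two_laplace_mixture.X, 2, n_runs=4, seed=2)
        np.testing.assert_allclose(res.S_avg.std(axis=1, ddof=1), 1.0, atol=1e-10)
        for grp in res.groups:
            reals = [k for k, _, _ in grp]
            assert len(reals) == len(set(reals))

    def test_sign_flip_invariance_of_r(self, rng):
        """R is unchanged when a realization's components are sign-flipped
        and permuted."""
        S = rng.laplace(size=(2, 2000))
        reals = [realization_from_sources(S) for _ in range(3)]
        flipped = [
            realization_from_sources(S),
            realization_from_sources(-S[::-1]),
            realization_from_sources(S),
        ]
        r1 = [
            reproducibility(g, _signed_cross_correlations(reals))
            for g in align_components(_signed_cross_correlations(reals), 3, 2)
        ]
        r2 = [
            reproducibility(g, _signed_cross_correlations(flipped))
            for g in align_components(_signed_cross_correlations(flipped), 3, 2)
        ]
        np.testing.assert_allclose(sorted(r1), sorted(r2), atol=1e-9)

    def test_estimator_api(self, two_laplace_mixture):
        from sklearn.base import clone

        est = ReproducibleICA(n_components=2, n_runs=3, random_state=0)
        est2 = clone(est)
        est2.fit(two_laplace_mixture.X.T)
        assert est2.sources_.shape == (two_laplace_mixture.X.shape[1], 2)
        assert est2.mixing_.shape == (2, 2)
        # transform approximately recovers the fitted sources
        T = est2.transform(two_laplace_mixture.X.T)
        c = np.abs(np.corrcoef(T.T, est2.sources_.T)[:2, 2:])
        assert np.all(c.max(axis=1) > 0.99)

    def test_serialization_roundtrip(self, tmp_path, two_laplace_mixture):
        res = raicar_decompose(two_laplace_mixture.X, 2, n_runs=3, seed=0)
        res.save(tmp_path)
        R = np.loadtxt(tmp_path / "reproducibility.tsv")
        np.testing.assert_allclose(R, res.R)
        assert (tmp_path / "groups.json").exists()
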