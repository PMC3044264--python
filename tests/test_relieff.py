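"""ReliefF core: distances, first-K neighbour rule, weights, SURF."""

import numpy as np
import pytest

from epifilter import (
    GenotypeDataset,
    distance_matrix,
    find_neighbors,
    permute_samples,
    relieff_weights,
    surf_weights,
)
from epifilter.relieff import (
    genotype_diff,
    relieff_scan,
    sample_distance,
    surf_neighbors,
    surf_threshold,
)

from conftest import random_dataset


def brute_force_relieff(dataset, K):
    """Independent oracle: plain-loop ReliefF with first-K tie breaking.

    Neighbours chosen by an exhaustive sort over (distance, position);
    weights accumulated in floats, one (sample, k) update at a time.
    """
    X = dataset.genotypes
    y = dataset.labels
    m, n = X.shape
    w = np.zeros(n)
    for i in range(m):
        dist = [(int((X[i] != X[j]).sum()), j) for j in range(m) if j != i]
        hits = sorted((d, j) for d, j in dist if y[j] == y[i])[:K]
        misses = sorted((d, j) for d, j in dist if y[j] != y[i])[:K]
        for _, h in hits:
            for g in range(n):
                w[g] -= (X[i, g] != X[h, g]) / (m * K)
        for _, mm in misses:
            for g in range(n):
                w[g] += (X[i, g] != X[mm, g]) / (m * K)
    return w


def _search_dataset(seed: int, want_ties: bool) -> GenotypeDataset:
    """First random small dataset whose K=1 scan has (no) neighbour ties."""
    rng = np.random.default_rng(seed)
    for _ in range(500):
        ds = random_dataset(rng, m=8, n=6, min_per_class=3)
        _, ties = relieff_scan(ds, K=1)
        if bool(ties.any()) == want_ties:
            return ds
    raise AssertionError("no suitable fixture found")


class TestDistances:
    def test_genotype_diff_is_equality_test(self):
        a = np.array([0, 0, 0, 2])
        b = np.array([0, 1, 2, 2])
        assert [genotype_diff(g, a, b) for g in range(4)] == [0, 1, 1, 0]
        assert all(
            genotype_diff(g, a, b) == genotype_diff(g, b, a) for g in range(4)
        )

    def test_sample_distance_counts_mismatches(self):
        a = np.array([0, 1, 2, 0, 1])
        b = np.array([0, 2, 1, 0, 0])
        assert sample_distance(a, b) == 3
        assert sample_distance(a, a) == 0
        assert sample_distance(a, b, snp_subset=[0, 3]) == 0

    def test_sample_distance_rejects_empty_subset(self):
        with pytest.raises(ValueError, match="non-empty"):
            sample_distance(np.array([0]), np.array([1]), snp_subset=[])

    def test_distance_matrix_matches_pairwise_loop(self):
        rng = np.random.default_rng(3)
        ds = random_dataset(rng, m=5, n=4)
        d = distance_matrix(ds)
        assert np.array_equal(d, d.T) and (np.diag(d) == 0).all()
        for i in range(5):
            for j in range(5):
                assert d[i, j] == sample_distance(
                    ds.genotypes[i], ds.genotypes[j]
                )

    def test_distance_matrix_on_subset_equals_reduced_dataset(self):
        rng = np.random.default_rng(4)
        ds = random_dataset(rng, m=6, n=4)
        subset = [0, 2]
        assert np.array_equal(
            distance_matrix(ds, subset),
            distance_matrix(ds.select_snps(subset)),
        )


class TestFindNeighbors:
    def test_basic_hit_and_miss_selection(self):
        # distances from s0: s1=1 (hit side); s2=1, s3=2 (miss side)
        dist = np.array([0, 1, 1, 2])
        labels = np.array([1, 1, 0, 0])
        ns = find_neighbors(dist, labels, target=0, K=1)
        assert ns.hits == (1,) and ns.misses == (2,)
        assert not ns.tie_flag

    def test_tied_candidates_resolved_by_position(self):
        # three same-class candidates all at distance 2, K=2
        labels = np.array([0, 0, 0, 0, 1, 1])
        dist = np.array([0, 2, 2, 2, 1, 3])
        ns = find_neighbors(dist, labels, target=0, K=2)
        assert ns.hits == (1, 2)  # earliest positions win
        assert ns.tie_flag
        # moving candidate 3 forward changes the chosen set
        order = [0, 3, 1, 2, 4, 5]
        ns2 = find_neighbors(dist[order], labels[order], target=0, K=2)
        assert ns2.hits == (1, 2)  # positions 1,2 now hold old samples 3,1

    def test_exhaustion_without_ties(self):
        labels = np.array([0, 0, 0, 1, 1])
        dist = np.array([0, 1, 2, 1, 2])
        ns = find_neighbors(dist, labels, target=0, K=2)
        assert ns.hits == (1, 2) and ns.misses == (3, 4)
        assert not ns.tie_flag

    def test_small_class_raises(self):
        labels = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError, match="K=2"):
            find_neighbors(np.array([0, 1, 1, 2]), labels, 0, K=2)


class TestRelieffWeights:
    def test_hand_computed_toy(self, toy_dataset):
        w = relieff_weights(toy_dataset, K=1)
        assert w.weights.tolist() == [1.0, -1.0]

    def test_constant_snp_scores_zero(self):
        ds = GenotypeDataset(
            genotypes=np.array([[1, 0], [1, 1], [1, 2], [1, 0]]),
            labels=np.array([0, 0, 1, 1]),
            snp_names=("const", "var"),
        )
        w = relieff_weights(ds, K=1)
        assert w.weights[0] == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            m = int(rng.integers(6, 9))
            n = int(rng.integers(1, 5))
            ds = random_dataset(rng, m=m, n=n, min_per_class=3)
            k = int(rng.integers(1, 3))
            got = relieff_weights(ds, K=k).weights
            expected = brute_force_relieff(ds, k)
            assert np.allclose(got, expected, atol=1e-12)

    def test_weights_bounded_on_random_datasets(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            ds = random_dataset(rng, m=int(rng.integers(8, 14)),
                                n=int(rng.integers(1, 5)), min_per_class=4)
            w = relieff_weights(ds, K=int(rng.integers(1, 4))).weights
            assert np.abs(w).max() <= 1.0 + 1e-15

    def test_order_invariant_when_tie_free(self):
        ds = _search_dataset(seed=21, want_ties=False)
        base = relieff_weights(ds, K=1).weights
        for seed in range(5):
            permuted = permute_samples(ds, seed)
            w = relieff_weights(permuted, K=1).weights
            assert np.array_equal(w, base)

    def test_ties_break_order_invariance(self):
        ds = _search_dataset(seed=22, want_ties=True)
        weights = {
            tuple(relieff_weights(permute_samples(ds, s), K=1).weights)
            for s in range(20)
        }
        assert len(weights) > 1

    def test_random_target_selection_reproducible(self, sim_small):
        a = relieff_weights(sim_small, K=3, n_samples=20, seed=9)
        b = relieff_weights(sim_small, K=3, n_samples=20, seed=9)
        assert np.array_equal(a.weights, b.weights)
        with pytest.raises(ValueError, match="seed"):
            relieff_weights(sim_small, K=3, n_samples=20)


class TestDiscrimination:
    def test_epistatic_pair_outranks_noise_median(self):
        """ReliefF pulls a purely epistatic pair above the noise median.

        At high heritability the interacting pair should, on average,
        rank clearly better than the median noise SNP even though
        neither locus has any marginal effect.
        """
        from epifilter import (
            SimulationConfig,
            make_penetrance_model,
            simulate_dataset,
            weights_to_ranking,
        )

        cfg = SimulationConfig(n_snps=100, n_cases=100, n_controls=100,
                               h2=0.3)
        model = make_penetrance_model(cfg.h2, cfg.maf, cfg.prevalence, seed=2)
        pair_ranks = []
        for i in range(20):
            ds = simulate_dataset(cfg, model, seed=600 + i)
            rk = weights_to_ranking(relieff_weights(ds, K=10))
            pair_ranks.append((rk.rank_of("X0") + rk.rank_of("X1")) / 2)
        assert np.mean(pair_ranks) < 50  # median noise rank ~ N/2


class TestSurf:
    def test_threshold_bounds_neighbor_sets(self):
        rng = np.random.default_rng(11)
        ds = random_dataset(rng, m=8, n=4, min_per_class=3)
        d = distance_matrix(ds)
        offdiag = d[~np.eye(8, dtype=bool)]
        below = surf_neighbors(d, ds.labels, 0, threshold=0.5)
        assert below.hits == () and below.misses == ()
        above = surf_neighbors(d, ds.labels, 0, float(offdiag.max()) + 1)
        assert len(above.hits) + len(above.misses) == 7

    def test_default_threshold_is_mean_pairwise(self):
        d = np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]])
        assert surf_threshold(d) == pytest.approx(4.0)

    def test_toy_matches_relieff_at_equivalent_threshold(self, toy_dataset):
        # threshold 1.5 admits exactly the K=1 neighbour sets of the toy
        w = surf_weights(toy_dataset, threshold=1.5)
        assert w.weights.tolist() == [1.0, -1.0]

    def test_weights_exactly_order_invariant(self, sim_small):
        base = surf_weights(sim_small).weights
        for seed in (1, 2, 3):
            permuted = permute_samples(sim_small, seed)
            assert np.array_equal(surf_weights(permuted).weights, base)

    def test_constant_snp_scores_zero(self):
        ds = GenotypeDataset(
            genotypes=np.array([[1, 0], [1, 1], [1, 2], [1, 0]]),
            labels=np.array([0, 0, 1, 1]),
            snp_names=("const", "var"),
        )
        assert surf_weights(ds).weights[0] == 0.0
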