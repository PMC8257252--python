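import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from asymparc import (
    ConnectivityProfile,
    Parcellation,
    SimilarityMatrix,
    block_similarity,
    group_similarity,
    match_labels,
    scan_k,
    seed_similarity,
    spectral_parcellate,
)
from oracles import brute_match_overlap


def norm_profile(matrix):
    return ConnectivityProfile(
        matrix=np.asarray(matrix, dtype=float), normalized=True
    )


class TestSeedSimilarity:
    def test_identical_and_anticorrelated_rows(self):
        sim = seed_similarity(
            norm_profile([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        )
        m = sim.matrix
        assert m[0, 1] == pytest.approx(1.0)
        assert m[0, 2] == pytest.approx(-1.0)
        assert np.all(np.diag(m) == 1.0)

    def test_constant_row_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="constant seed row"):
            sim = seed_similarity(
                norm_profile([[0.5, 0.5, 0.5], [0.1, 0.5, 0.9], [0.9, 0.4, 0.2]])
            )
        assert np.all(sim.matrix[0, 1:] == 0.0)
        assert sim.matrix[0, 0] == 1.0

    def test_single_seed_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            seed_similarity(norm_profile([[1.0, 2.0]]))

    def test_unnormalized_profile_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            seed_similarity(ConnectivityProfile(matrix=np.ones((3, 3))))


class TestGroupSimilarity:
    def test_mean_of_entries_and_closure(self):
        a = np.array([[1.0, 0.2], [0.2, 1.0]])
        b = np.array([[1.0, 0.6], [0.6, 1.0]])
        out = group_similarity(
            [SimilarityMatrix(a), SimilarityMatrix(b)]
        )
        assert out.level == "group"
        assert out.matrix[0, 1] == pytest.approx(0.4)
        assert np.array_equal(out.matrix, out.matrix.T)

    def test_single_matrix_is_identity_operation(self):
        a = SimilarityMatrix(np.array([[1.0, -0.3], [-0.3, 1.0]]))
        assert np.allclose(group_similarity([a]).matrix, a.matrix)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mixed shapes"):
            group_similarity(
                [SimilarityMatrix(np.eye(2)), SimilarityMatrix(np.eye(3))]
            )


class TestSpectralParcellate:
    def two_block_sim(self):
        m = np.full((10, 10), -0.2)
        m[:5, :5] = 1.0
        m[5:, 5:] = 1.0
        np.fill_diagonal(m, 1.0)
        return SimilarityMatrix(m, level="group")

    def test_recovers_well_separated_blocks(self):
        parc = spectral_parcellate(self.two_block_sim(), k=2, seed=0)
        assert parc.labels.tolist() == [1] * 5 + [2] * 5

    def test_stable_across_kmeans_seeds_on_separated_case(self):
        a = spectral_parcellate(self.two_block_sim(), k=2, seed=0)
        b = spectral_parcellate(self.two_block_sim(), k=2, seed=99)
        assert np.array_equal(a.labels, b.labels)

    def test_k_equals_m_gives_singletons(self):
        sim, _ = block_similarity(6, k=2, noise_sd=0.05, seed=3)
        parc = spectral_parcellate(sim, k=6, seed=0)
        assert sorted(parc.labels.tolist()) == [1, 2, 3, 4, 5, 6]

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            spectral_parcellate(self.two_block_sim(), k=1)
        with pytest.raises(ValueError, match="out of range"):
            spectral_parcellate(self.two_block_sim(), k=11)

    def test_canonical_labels_invariant_under_seed_permutation(self):
        sim, truth = block_similarity(40, k=3, noise_sd=0.05, seed=5)
        perm = np.random.default_rng(1).permutation(40)
        permuted = SimilarityMatrix(sim.matrix[np.ix_(perm, perm)], level="group")
        a = spectral_parcellate(sim, k=3, seed=0)
        b = spectral_parcellate(permuted, k=3, seed=0)
        # the partitions coincide up to relabeling after undoing the permutation
        assert adjusted_rand_score(a.labels[perm], b.labels) == pytest.approx(1.0)

    def test_fingerprints_are_cluster_means(self):
        profile = norm_profile(np.vstack([np.zeros((5, 3)), np.ones((5, 3))]))
        parc = spectral_parcellate(self.two_block_sim(), k=2, seed=0, profile=profile)
        assert np.allclose(parc.fingerprints, [[0, 0, 0], [1, 1, 1]])


class TestMatchLabels:
    def parc(self, labels):
        labels = np.asarray(labels)
        return Parcellation(labels=labels, k=int(labels.max()))

    def test_permuted_labels_recovered_with_full_overlap(self):
        a = self.parc([1, 1, 2, 2, 3, 3])
        b = self.parc([2, 2, 3, 3, 1, 1])
        m = match_labels(a, b)
        assert m.mapping == {1: 2, 2: 3, 3: 1}
        assert m.overlap == 1.0
        assert all(v == 1.0 for v in m.pair_dice.values())

    def test_identity_on_self(self):
        a = self.parc([1, 2, 1, 2])
        m = match_labels(a, a)
        assert m.mapping == {1: 1, 2: 2}
        assert m.overlap == 1.0

    def test_four_seed_toy_brute_force(self):
        a = self.parc([1, 1, 2, 2])
        b = self.parc([2, 2, 1, 1])
        m = match_labels(a, b)
        assert m.mapping == {1: 2, 2: 1}
        assert m.overlap == 1.0

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_overlap_equals_bruteforce_maximum(self, k, rng):
        a_labels = rng.integers(1, k + 1, size=40)
        b_labels = rng.integers(1, k + 1, size=40)
        # ensure every label occurs
        a_labels[:k] = np.arange(1, k + 1)
        b_labels[:k] = np.arange(1, k + 1)
        m = match_labels(self.parc(a_labels), self.parc(b_labels))
        assert m.overlap == pytest.approx(
            brute_match_overlap(a_labels, b_labels, k)
        )

    def test_unequal_k_rejected(self):
        with pytest.raises(ValueError, match="different k"):
            match_labels(self.parc([1, 2, 2]), self.parc([1, 2, 3]))


class TestScanK:
    def test_identical_groups_score_one_at_planted_k(self):
        sim, _ = block_similarity(80, k=4, noise_sd=0.02, seed=2)
        res = scan_k({"a": sim, "b": sim}, k_range=range(2, 7), tau=0.8, seed=0)
        assert res.scores[4] == pytest.approx(1.0)
        assert res.ari_scores[4] == pytest.approx(1.0)

    def test_planted_k_selected_across_noisy_groups(self):
        groups = {
            f"g{i}": block_similarity(120, k=4, noise_sd=0.1, seed=10 + i)[0]
            for i in range(3)
        }
        res = scan_k(groups, k_range=range(2, 9), tau=0.8, seed=0)
        assert res.chosen_k == 4
        assert res.reached_tau

    def test_noise_group_depresses_consistency(self):
        clean = {
            f"g{i}": block_similarity(60, k=3, noise_sd=0.05, seed=i)[0]
            for i in range(2)
        }
        noise_only = block_similarity(60, k=1, r_within=0.0, r_between=0.0,
                                      noise_sd=0.3, seed=99)[0]
        res_clean = scan_k(clean, k_range=range(2, 6), tau=0.8, seed=0)
        res_noisy = scan_k(
            {**clean, "noise": noise_only}, k_range=range(2, 6), tau=0.8, seed=0
        )
        assert all(
            res_noisy.scores[k] <= res_clean.scores[k] for k in res_clean.scores
        )

    def test_no_k_reaching_tau_is_flagged(self):
        groups = {
            f"g{i}": block_similarity(40, k=1, r_within=0.0, r_between=0.0,
                                      noise_sd=0.3, seed=50 + i)[0]
            for i in range(2)
        }
        res = scan_k(groups, k_range=range(2, 5), tau=0.99, seed=0)
        assert not res.reached_tau
        assert res.chosen_k in res.scores

    def test_single_group_rejected(self):
        sim, _ = block_similarity(20, k=2, seed=0)
        with pytest.raises(ValueError, match=">= 2 groups"):
            scan_k({"only": sim})
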