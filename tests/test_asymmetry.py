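import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from asymparc import (
    asymmetry_index,
    bh_fdr,
    bonferroni_adjust,
    generate_dataset,
    paired_signed_rank,
    region_values,
    run_asymmetry_battery,
    vertexwise_test,
)
from asymparc.parcellation import Parcellation
from conftest import small_spec
from oracles import bh_stepup, brute_wilcoxon_p, exhaustive_signflip_p


class TestAsymmetryIndex:
    def test_hand_examples(self):
        assert asymmetry_index(5.0, 5.0) == 0.0
        assert asymmetry_index(3.0, 1.0) == pytest.approx(-1.0)  # leftward
        assert np.isnan(asymmetry_index(0.0, 0.0))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            asymmetry_index(-1.0, 2.0)

    @settings(deadline=None, max_examples=200)
    @given(
        st.floats(0, 1e9, allow_nan=False),
        st.floats(0, 1e9, allow_nan=False),
    )
    def test_antisymmetry_and_range(self, left, right):
        ai = asymmetry_index(left, right)
        if left + right == 0:
            assert np.isnan(ai)
        else:
            assert -2.0 <= ai <= 2.0
            assert ai == pytest.approx(-asymmetry_index(right, left), abs=1e-12)

    def test_vectorized_matches_scalar(self, rng):
        left = rng.gamma(2.0, 1.0, size=20)
        right = rng.gamma(2.0, 1.0, size=20)
        vec = asymmetry_index(left, right)
        assert np.allclose(
            vec, [asymmetry_index(l, r) for l, r in zip(left, right)]
        )


class TestVertexwiseTest:
    def test_exhaustive_p_matches_enumeration_oracle(self, rng):
        for n in range(3, 9):
            x = rng.normal(0.2, 1.0, size=(n, 3))
            res = vertexwise_test(x, n_perm=2**n, seed=0)
            for j in range(3):
                assert res["p"][j] == pytest.approx(
                    exhaustive_signflip_p(x[:, j]), abs=1e-12
                )

    def test_constant_positive_vertex_has_minimal_exhaustive_p(self):
        # n=10 identical AIs: only the two all-same-sign flips attain |t|max
        x = np.full((10, 1), 0.3)
        res = vertexwise_test(x, n_perm=1024, seed=0)
        assert res["p"][0] == pytest.approx(2 / 1024)

    def test_all_zero_vertex_saturates_null(self):
        res = vertexwise_test(np.zeros((8, 1)), n_perm=256, seed=0)
        assert res["p"][0] == 1.0
        assert res["d"][0] == 0.0
        assert not res["significant"][0]

    def test_cohens_d_hand_arithmetic(self):
        # AIs {1, 3}: d = mean/sd = 2/sqrt(2)
        res = vertexwise_test(np.array([[1.0], [3.0]]), n_perm=4, seed=0)
        assert res["d"][0] == pytest.approx(np.sqrt(2.0))

    def test_monte_carlo_close_to_exhaustive(self, rng):
        x = rng.normal(0.5, 1.0, size=(12, 4))
        exact = vertexwise_test(x, n_perm=4096, seed=0)["p"]
        mc = vertexwise_test(x, n_perm=4000, seed=1)["p"]  # 2^12 > 4000 -> MC
        assert np.all(mc >= 1.0 / 4001.0)
        assert np.allclose(mc, exact, atol=0.02)

    def test_missing_values_dropped_pairwise(self):
        x = np.array([[0.5, 0.5], [0.7, np.nan], [0.6, 0.4], [np.nan, 0.2]])
        res = vertexwise_test(x, n_perm=64, seed=0)
        assert res["n"].tolist() == [3, 3]
        assert np.all(np.isfinite(res["p"]))

    def test_mask_restricts_units_and_fdr_family(self, rng):
        x = rng.normal(0.0, 1.0, size=(10, 6))
        res = vertexwise_test(x, mask=[1, 4], n_perm=512, seed=0)
        assert res["unit"].tolist() == [1, 4]


class TestRegionValues:
    def test_single_index_returns_entry(self):
        L = np.array([[0.1, 0.9]])
        R = np.array([[0.3, 0.7]])
        lv, rv = region_values(L, R, [1])
        assert lv[0] == 0.9 and rv[0] == 0.7

    def test_mean_over_region(self):
        L = np.array([[0.2, 0.4, 1.0]])
        lv, _ = region_values(L, L, [0, 1])
        assert lv[0] == pytest.approx(0.3)

    def test_constant_map_gives_constant(self):
        L = np.full((3, 5), 0.8)
        lv, rv = region_values(L, L, np.arange(5))
        assert np.allclose(lv, 0.8) and np.allclose(rv, 0.8)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            region_values(np.ones((2, 3)), np.ones((2, 3)), [])


class TestPairedSignedRank:
    def test_equal_hemispheres_degenerate(self):
        with pytest.warns(UserWarning, match="all paired differences"):
            res = paired_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0
        assert res.statistic == 0.0

    def test_all_positive_distinct_differences_exact_p(self):
        res = paired_signed_rank(np.zeros(5), [1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 32)

    def test_swapping_hemispheres_preserves_two_sided_p(self, rng):
        left = rng.gamma(2.0, 1.0, size=9)
        right = rng.gamma(2.0, 1.0, size=9)
        a = paired_signed_rank(left, right)
        b = paired_signed_rank(right, left)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    @pytest.mark.parametrize("n", [4, 7, 10, 12])
    def test_exact_p_matches_bruteforce_enumeration(self, n, rng):
        for _ in range(10):
            diffs = rng.normal(0.3, 1.0, size=n)
            # occasionally force rank ties
            if rng.random() < 0.5:
                diffs[1] = -diffs[0]
            res = paired_signed_rank(np.zeros(n), diffs)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(brute_wilcoxon_p(diffs), abs=1e-12)

    def test_exact_agrees_with_scipy_on_tie_free_data(self, rng):
        diffs = rng.normal(0.5, 1.0, size=10)
        res = paired_signed_rank(np.zeros(10), diffs)
        ref = stats.wilcoxon(diffs, method="exact", alternative="two-sided")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_n_uses_normal_approximation(self, rng):
        diffs = rng.normal(0.2, 1.0, size=30)
        res = paired_signed_rank(np.zeros(30), diffs)
        ref = stats.wilcoxon(diffs, correction=True, method="approx")
        assert res.method == "approx"
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_zeros_discarded_and_counted(self):
        res = paired_signed_rank([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 5.0, 6.0])
        assert res.n_zeros == 2
        assert res.n_used == 2


class TestCorrections:
    def test_bonferroni_examples(self):
        assert bonferroni_adjust([0.01], m=5)[0] == pytest.approx(0.05)
        assert bonferroni_adjust([0.5], m=44)[0] == 1.0
        assert np.array_equal(bonferroni_adjust([0.3, 0.7]), [0.6, 1.0])

    def test_bonferroni_rejects_bad_inputs(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bonferroni_adjust([1.5])
        with pytest.raises(ValueError, match="family size"):
            bonferroni_adjust([0.1, 0.2], m=1)

    def test_bh_stepup_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_bh_single_and_constant_lists(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(bh_fdr([0.3, 0.3, 0.3]), 0.3)
        assert bh_fdr([]).size == 0

    def test_bh_matches_independent_stepup_and_bounds(self, rng):
        p = rng.uniform(0, 1, size=25)
        q = bh_fdr(p)
        assert np.allclose(q, bh_stepup(p), atol=1e-12)
        assert np.all(q >= p - 1e-12)  # q never below raw p
        assert np.all(bonferroni_adjust(p) >= q - 1e-12)


class TestBattery:
    def dataset_and_parcellation(self, **overrides):
        fields = dict(n_subjects=10, noise_sd=0.1, volume_noise_sd=0.05)
        fields.update(overrides)
        spec = small_spec(**fields)
        ds = generate_dataset(spec, seed=5)
        parc = Parcellation(labels=spec.block_assignment, k=spec.k_true)
        return ds, parc

    def test_tidy_table_has_all_levels(self):
        ds, parc = self.dataset_and_parcellation()
        table = run_asymmetry_battery(
            ds, parc, roi_sets={"ROI1": [0, 1]}, tract_sets={"TR1": [2, 3]},
            n_perm=200, seed=0, pop_threshold=0.0,
        )
        assert set(table["level"]) == {"volumetric", "vertex", "roi", "tract"}
        assert {"ai_mean", "p", "p_corr", "d", "significant"} <= set(table.columns)
        assert np.all(table["p_corr"] >= table["p"] - 1e-12)

    def test_empty_roi_sets_skips_roi_block(self):
        ds, parc = self.dataset_and_parcellation()
        table = run_asymmetry_battery(
            ds, parc, roi_sets=None, tract_sets={"TR1": [0]},
            n_perm=100, seed=0, pop_threshold=0.0,
        )
        assert "roi" not in set(table["level"])
        assert {"volumetric", "vertex", "tract"} <= set(table["level"])

    def test_missing_hemisphere_raises(self):
        ds, parc = self.dataset_and_parcellation()
        del ds.profiles[(ds.subject_ids[0], "R")]
        with pytest.raises(ValueError, match="missing hemisphere"):
            run_asymmetry_battery(ds, parc, n_perm=50, seed=0)

    def test_planted_volumetric_signs_recovered(self):
        ds, parc = self.dataset_and_parcellation(
            n_subjects=40, volume_ai=np.array([-0.2, 0.0, 0.2])
        )
        table = run_asymmetry_battery(ds, parc, n_perm=100, seed=0,
                                      pop_threshold=0.0)
        vol = table[table["level"] == "volumetric"].set_index("subregion")
        assert vol.loc["C1", "ai_mean"] < 0 < vol.loc["C3", "ai_mean"]
        assert vol.loc["C1", "significant"] and vol.loc["C3", "significant"]
        assert not vol.loc["C2", "significant"]
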