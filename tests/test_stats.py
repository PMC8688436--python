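"""Nonparametric contrasts: Mann-Whitney Z, Kruskal-Wallis/Dunn, voxelwise
chi-square, BH-FDR."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from _oracles import brute_force_bh, exact_mannwhitney_p
from disconnectome import stats as dstats
from disconnectome.core import DisconnectivityMatrix, Tractogram, VolumeGrid


class TestMannWhitney:
    def test_identical_multisets_give_zero(self):
        u, z, p = dstats.mannwhitney_z([1, 2, 2, 5], [1, 2, 2, 5])
        assert z == 0.0 and p == 1.0

    def test_complete_separation_u_and_exact_p(self):
        u, z, p = dstats.mannwhitney_z([1, 2, 3], [4, 5, 6])
        assert u == 0.0 and z < 0
        assert exact_mannwhitney_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.10)

    def test_all_tied_convention(self):
        u, z, p = dstats.mannwhitney_z([3, 3], [3, 3, 3])
        assert (u, z, p) == (3.0, 0.0, 1.0)

    def test_sign_convention_first_group_higher_is_positive(self):
        _, z, _ = dstats.mannwhitney_z([10, 11, 12], [1, 2, 3])
        assert z > 0

    def test_matches_scipy_asymptotic_no_continuity(self, rng):
        for _ in range(50):
            x = rng.poisson(3, rng.integers(3, 12)).astype(float)
            y = rng.poisson(4, rng.integers(3, 12)).astype(float)
            u, z, p = dstats.mannwhitney_z(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic", use_continuity=False)
            assert u == pytest.approx(ref.statistic)
            if p < 1.0:
                assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_tail_decisions_track_exact_permutation(self, rng):
        """Where it matters for reporting (the |Z| > 1.96 calls), the normal
        approximation and the exact permutation test point the same way."""
        for _ in range(60):
            n1, n2 = rng.integers(4, 9, 2)
            x = np.where(rng.random(n1) < 0.5, 0, rng.poisson(3, n1)).astype(float)
            y = np.where(rng.random(n2) < 0.5, 0, rng.poisson(3, n2)).astype(float)
            _, z, p = dstats.mannwhitney_z(x, y)
            pe = exact_mannwhitney_p(x, y)
            if abs(z) > 2.6:
                assert pe < 0.05
            if pe > 0.5:
                assert abs(z) < dstats.Z_CRIT_DEFAULT

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            dstats.mannwhitney_z([], [1.0])


class TestKruskalDunn:
    def test_hand_computed_h(self):
        h, p = dstats.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)
        assert p == pytest.approx(sps.chi2.sf(7.2, 2))

    def test_identical_groups(self):
        assert dstats.kruskal_wallis([[2, 2], [2, 2, 2]]) == (0.0, 1.0)

    def test_h_invariant_under_monotone_transform(self, rng):
        groups = [rng.poisson(3, 5).astype(float) for _ in range(3)]
        h1, _ = dstats.kruskal_wallis(groups)
        h2, _ = dstats.kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2)

    def test_dunn_worked_example(self):
        # groups [1,2,3],[4,5,6],[7,8,9]: mean ranks 2, 5, 8;
        # pair (0,2): z = 6/sqrt(5), bonferroni x3
        table = dstats.dunn_posthoc([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        row = table[(table.group_a == "group0") & (table.group_b == "group2")].iloc[0]
        assert row["z"] == pytest.approx(-6 / np.sqrt(5))
        assert row["p_unadjusted"] == pytest.approx(0.00729, abs=2e-5)
        assert row["p_adjusted"] == pytest.approx(0.02188, abs=5e-5)

    def test_dunn_identical_groups_all_one(self):
        table = dstats.dunn_posthoc([[1, 1], [1, 1], [1, 1]])
        assert (table["p_adjusted"] == 1.0).all()

    def test_adjusted_never_below_unadjusted(self, rng):
        groups = [rng.poisson(3, 6).astype(float) for _ in range(4)]
        for method in ("bonferroni", "sidak"):
            table = dstats.dunn_posthoc(groups, adjust=method)
            assert (table["p_adjusted"] >= table["p_unadjusted"] - 1e-12).all()


def _mat(counts, ids=(1, 2, 3), site_id=None):
    return DisconnectivityMatrix(np.asarray(counts), tuple(ids), site_id=site_id)


def _pair_matrix(value, i=0, j=1, p=3):
    c = np.zeros((p, p), dtype=int)
    c[i, j] = c[j, i] = value
    return c


class TestMatrixwise:
    def test_identical_groups_all_zero_z(self):
        g = [_mat(_pair_matrix(5), site_id=f"a{i}") for i in range(3)]
        res = dstats.matrixwise_compare(g, [_mat(_pair_matrix(5)) for _ in range(3)])
        assert not res.Z.any()
        assert (res.p == 1.0).all()

    def test_programmed_cell_attains_max_abs_z(self):
        ga = [_mat(_pair_matrix(10)) for _ in range(4)]
        gb = [_mat(_pair_matrix(0)) for _ in range(4)]
        res = dstats.matrixwise_compare(ga, gb, ("A", "B"))
        assert abs(res.Z[0, 1]) == np.abs(res.Z).max() > 0
        assert res.Z[0, 1] > 0  # first group ranks higher

    def test_group_swap_negates_z(self, rng):
        ga = [_mat(_pair_matrix(int(v))) for v in rng.integers(0, 9, 5)]
        gb = [_mat(_pair_matrix(int(v))) for v in rng.integers(0, 9, 6)]
        r1 = dstats.matrixwise_compare(ga, gb)
        r2 = dstats.matrixwise_compare(gb, ga)
        np.testing.assert_allclose(r1.Z, -r2.Z, atol=1e-12)

    def test_needs_two_sites_per_group(self):
        with pytest.raises(ValueError, match="at least 2"):
            dstats.matrixwise_compare([_mat(_pair_matrix(1))], [_mat(_pair_matrix(1))] * 2)

    def test_threshold_pairs_sorted_and_monotone_in_zcrit(self):
        ga = [_mat(_pair_matrix(10))] * 4 + [_mat(_pair_matrix(9))]
        gb = [_mat(_pair_matrix(0))] * 5
        res = dstats.matrixwise_compare(ga, gb)
        pairs = dstats.threshold_pairs(res)
        assert list(pairs["Z"].abs()) == sorted(pairs["Z"].abs(), reverse=True)
        more = dstats.threshold_pairs(res, z_crit=1.0)
        kept = set(map(tuple, pairs[["parcel_a", "parcel_b"]].to_numpy()))
        larger = set(map(tuple, more[["parcel_a", "parcel_b"]].to_numpy()))
        assert kept <= larger

    def test_all_zero_resultless_threshold(self):
        g = [_mat(_pair_matrix(0)) for _ in range(3)]
        res = dstats.matrixwise_compare(g, g)
        assert len(dstats.threshold_pairs(res)) == 0


class TestVoxelwise:
    def test_binarize_straight_streamline_marks_its_corridor(self):
        grid = VolumeGrid((20, 5, 5), np.eye(4))
        sl = np.linspace((2.0, 2.0, 2.0), (17.0, 2.0, 2.0), 16)
        vol = dstats.binarize_tractogram(Tractogram([sl]), grid)
        assert vol.sum() == 16
        assert vol[2:18, 2, 2].all()

    def test_binarize_empty(self):
        grid = VolumeGrid((5, 5, 5), np.eye(4))
        assert not dstats.binarize_tractogram(Tractogram([]), grid).any()

    def test_binarize_union_property(self, toy_bundles, toy_parcellation, rng):
        grid = toy_parcellation.grid
        sls = toy_bundles.tractogram.streamlines
        for _ in range(5):
            pick = rng.permutation(len(sls))[:20]
            a, b = pick[:10], pick[10:]
            m_a = dstats.binarize_tractogram(Tractogram([sls[i] for i in a]), grid)
            m_b = dstats.binarize_tractogram(Tractogram([sls[i] for i in b]), grid)
            m_ab = dstats.binarize_tractogram(Tractogram([sls[i] for i in pick]), grid)
            np.testing.assert_array_equal(m_ab, m_a | m_b)

    def test_chisq_worked_example(self):
        # 4/4 traversed vs 0/16: chi2 = 20*64^2/(4*16*4*16) = 20
        shape = (2, 2, 1)
        ones = np.ones(shape, np.uint8)
        zeros = np.zeros(shape, np.uint8)
        vm = dstats.voxelwise_chisq([ones] * 4, [zeros] * 16)
        np.testing.assert_allclose(vm.chi2, 20.0)
        np.testing.assert_allclose(vm.p, sps.chi2.sf(20.0, 1))
        assert vm.fdr_mask.all()

    def test_chisq_matches_scipy_contingency(self):
        maps_a = [np.array([[[1]]]), np.array([[[1]]]), np.array([[[0]]]),
                  np.array([[[1]]])]
        maps_b = [np.array([[[0]]]), np.array([[[1]]]), np.array([[[0]]]),
                  np.array([[[0]]]), np.array([[[0]]])]
        vm = dstats.voxelwise_chisq(maps_a, maps_b)
        table = np.array([[3, 1], [1, 4]])
        ref = sps.chi2_contingency(table, correction=False)
        assert vm.chi2[0, 0, 0] == pytest.approx(ref.statistic)
        assert vm.p[0, 0, 0] == pytest.approx(ref.pvalue)

    def test_equal_proportions_give_zero(self):
        m = np.ones((3, 3, 3), np.uint8)
        vm = dstats.voxelwise_chisq([m, m], [m, m, m])
        assert not vm.chi2.any() and (vm.p == 1.0).all()

    def test_untested_voxels_excluded_from_fdr_family(self):
        a = np.zeros((4, 1, 1), np.uint8)
        a[0] = 1
        b = np.zeros((4, 1, 1), np.uint8)
        vm = dstats.voxelwise_chisq([a, a, a], [b, b, b])
        assert vm.tested.sum() == 1
        assert not vm.fdr_mask[~vm.tested].any()


class TestBHFDR:
    def test_step_up_worked_example(self):
        mask = dstats.bh_fdr([0.01, 0.02, 0.03, 0.5], q=0.05)
        assert mask.tolist() == [True, True, True, False]

    def test_all_ones_reject_nothing(self):
        assert not dstats.bh_fdr([1.0] * 10).any()

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60),
           st.sampled_from([0.01, 0.05, 0.1, 0.25]))
    def test_identical_to_brute_force_step_up(self, ps, q):
        np.testing.assert_array_equal(dstats.bh_fdr(ps, q), brute_force_bh(ps, q))

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            dstats.bh_fdr([0.5, 1.2])
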