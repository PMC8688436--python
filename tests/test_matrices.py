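"""VOI filtering, endpoint embedding, disconnectivity matrices, chord tables."""
import numpy as np
import pandas as pd
import pytest

from _oracles import dense_segment_sphere
from disconnectome import matrices as dmat
from disconnectome import synthetic as dsyn
from disconnectome.core import SphericalVOI, StimulationSite, Tractogram


def test_voi_volume_closed_form():
    site = StimulationSite("s", "p", (0, 0, 0), "Ph-A")
    voi = dmat.make_voi(site)
    assert voi.radius_mm == 2.5  # probe-resolution default
    assert voi.volume_mm3 == pytest.approx(65.44984695, abs=1e-6)
    r = [dmat.make_voi(site, r).radius_mm for r in dmat.DEFAULT_RADII_MM]
    assert r == sorted(r) == [2.5, 3.0, 3.5]


class TestSegmentSphere:
    def test_endpoint_at_center(self):
        voi = SphericalVOI((0, 0, 0), 2.5)
        assert dmat.segment_sphere_intersects((0, 0, 0), (10, 0, 0), voi)

    def test_midspan_graze(self):
        # segment passes 2.4 mm from the center while both endpoints are
        # 10 mm away
        voi = SphericalVOI((0, 0, 2.4), 2.5)
        far = np.sqrt(100.0 - 2.4**2)
        assert dmat.segment_sphere_intersects((-far, 0, 0), (far, 0, 0), voi)

    def test_fully_outside(self):
        voi = SphericalVOI((0, 0, 10.0), 2.5)
        assert not dmat.segment_sphere_intersects((-5, 0, 0), (5, 0, 0), voi)

    def test_agrees_with_dense_sampling_oracle(self, rng):
        voi = SphericalVOI((0, 0, 0), 2.5)
        for _ in range(500):
            p0 = rng.uniform(-6, 6, 3)
            p1 = rng.uniform(-6, 6, 3)
            assert dmat.segment_sphere_intersects(p0, p1, voi) == dense_segment_sphere(
                p0, p1, voi.center, voi.radius_mm
            )


class TestFilterByVoi:
    def test_voi_on_corridor_keeps_exactly_that_bundle(self, toy_bundles):
        mid = toy_bundles.centerlines["ILF-toy"]
        voi = SphericalVOI(mid[len(mid) // 2], 2.5)
        kept = dmat.filter_by_voi(toy_bundles.tractogram, voi)
        assert len(kept) > 0
        assert set(kept.tags) == {"ILF-toy"}

    def test_empty_tractogram(self):
        assert len(dmat.filter_by_voi(Tractogram([]), SphericalVOI((0, 0, 0), 2.5))) == 0

    def test_radius_nesting_monotonicity(self, toy_bundles, rng):
        t = toy_bundles.tractogram
        for _ in range(20):
            center = rng.uniform(5, 35, 3)
            counts = [len(dmat.filter_by_voi(t, SphericalVOI(center, r)))
                      for r in (2.5, 3.0, 3.5)]
            assert counts[0] <= counts[1] <= counts[2]

    def test_locality_far_voi_keeps_nothing(self, toy_bundles):
        assert len(dmat.filter_by_voi(toy_bundles.tractogram,
                                      SphericalVOI((39.0, 39.0, 39.0), 2.5))) == 0


class TestEndpointLabel:
    def test_inside_parcel(self, toy_parcellation):
        assert dmat.endpoint_label((5.0, 30.0, 20.0), toy_parcellation, 0) == 1

    def test_one_voxel_outside_with_fallback(self, toy_parcellation):
        # parcel 1 box starts at x=2; x=1 is background
        point = (1.0, 30.0, 20.0)
        assert dmat.endpoint_label(point, toy_parcellation, 0) == 0
        assert dmat.endpoint_label(point, toy_parcellation, 1) == 1

    def test_deep_background_and_outside_grid(self, toy_parcellation):
        assert dmat.endpoint_label((39.0, 39.0, 39.0), toy_parcellation, 1) == 0
        assert dmat.endpoint_label((-10.0, 0.0, 0.0), toy_parcellation, 1) == 0

    def test_tie_broken_by_smallest_parcel_id(self):
        parc = dsyn.make_toy_parcellation(
            (9, 5, 5),
            [dsyn.ParcelSpec(4, "right", "L", ((5, 8), (1, 4), (1, 4))),
             dsyn.ParcelSpec(2, "left", "L", ((1, 4), (1, 4), (1, 4)))],
        )
        # voxel (4, 2, 2) is background, flanked symmetrically by ids 4 and 2
        assert dmat.endpoint_label((4.0, 2.0, 2.0), parc, 1) == 2


class TestBuildMatrix:
    def test_three_streamlines_one_pair(self, toy_parcellation):
        sl = np.array([[5.0, 30.0, 20.0], [6.0, 20.0, 15.0], [7.0, 5.0, 7.0]])
        t = Tractogram([sl, sl, sl])
        m = dmat.build_matrix(t, toy_parcellation)
        i, j = m.parcel_ids.index(1), m.parcel_ids.index(3)
        assert m.counts[i, j] == m.counts[j, i] == 3
        assert m.counts.sum() == 6 and m.qc_excluded == 0

    def test_unlabeled_endpoint_goes_to_qc(self, toy_parcellation):
        sl = np.array([[5.0, 30.0, 20.0], [20.0, 20.0, 20.0]])  # ends in background
        m = dmat.build_matrix(Tractogram([sl]), toy_parcellation)
        assert m.counts.sum() == 0 and m.qc_excluded == 1

    def test_same_parcel_pair_excluded(self, toy_parcellation):
        sl = np.array([[4.0, 30.0, 20.0], [6.0, 31.0, 21.0]])  # both in parcel 1
        m = dmat.build_matrix(Tractogram([sl]), toy_parcellation)
        assert m.counts.sum() == 0 and m.qc_excluded == 1

    def test_conservation_on_random_voi_filtered_sets(self, toy_parcellation, toy_bundles, rng):
        t = toy_bundles.tractogram
        for _ in range(10):
            voi = SphericalVOI(rng.uniform(5, 35, 3), 3.5)
            kept = dmat.filter_by_voi(t, voi)
            m = dmat.build_matrix(kept, toy_parcellation)
            assert m.upper_triangle_total() + m.qc_excluded == len(kept)


class TestGroupSums:
    def test_doubling_and_symmetry(self, toy_parcellation, toy_bundles):
        voi = SphericalVOI(toy_bundles.centerlines["pAF-toy"][10], 2.5)
        m = dmat.build_matrix(dmat.filter_by_voi(toy_bundles.tractogram, voi),
                              toy_parcellation, site_id="a")
        m2 = dmat.DisconnectivityMatrix(m.counts.copy(), m.parcel_ids, site_id="b")
        sums = dmat.sum_by_group([m, m2], {"a": "Ph-A", "b": "Ph-A"})
        np.testing.assert_array_equal(sums["Ph-A"].counts, 2 * m.counts)

    def test_empty_group_warns_and_zeroes(self, toy_parcellation):
        m = dmat.DisconnectivityMatrix(
            np.zeros((8, 8), dtype=int), toy_parcellation.parcel_ids, site_id="a"
        )
        with pytest.warns(UserWarning, match="no sites"):
            sums = dmat.sum_by_group([m], {"a": "Ph-A", "ghost": "Pu-A"})
        assert not sums["Pu-A"].counts.any()

    def test_mixed_orderings_rejected(self, toy_parcellation):
        m1 = dmat.DisconnectivityMatrix(np.zeros((8, 8), int), toy_parcellation.parcel_ids, "a")
        m2 = dmat.DisconnectivityMatrix(np.zeros((8, 8), int),
                                        tuple(reversed(toy_parcellation.parcel_ids)), "b")
        with pytest.raises(ValueError, match="orderings"):
            dmat.sum_by_group([m1, m2], {"a": "Ph-A", "b": "Ph-A"})


class TestChordTable:
    def test_single_cell_carries_full_lobe_share(self, toy_parcellation):
        counts = np.zeros((8, 8), dtype=int)
        counts[0, 2] = counts[2, 0] = 7  # parcels 1 (Frontal) and 3 (Temporal)
        m = dmat.DisconnectivityMatrix(counts, toy_parcellation.parcel_ids,
                                       params={"n_sites": 4})
        df = dmat.export_chord_table(m, toy_parcellation.table)
        assert len(df) == 1
        row = df.iloc[0]
        assert row["count"] == 7 and row["mean_count_per_site"] == pytest.approx(7 / 4)
        assert row["share_of_lobe_a_pct"] == 100.0 and row["share_of_lobe_b_pct"] == 100.0

    def test_lobe_shares_sum_to_hundred(self, toy_parcellation, toy_bundles):
        sites = dsyn.make_cohort(dsyn.alexia_cohort_spec(seed=2), toy_bundles)
        mats = []
        for s in sites:
            kept = dmat.filter_by_voi(toy_bundles.tractogram, dmat.make_voi(s))
            mats.append(dmat.build_matrix(kept, toy_parcellation, site_id=s.site_id))
        sums = dmat.sum_by_group(mats, {s.site_id: s.label for s in sites})
        df = dmat.export_chord_table(sums["Ls-A"], toy_parcellation.table)
        assert len(df) >= 2
        for lobe in set(df["lobe_a"]) | set(df["lobe_b"]):
            sub = df[(df["lobe_a"] == lobe) | (df["lobe_b"] == lobe)]
            shares = np.where(sub["lobe_a"] == lobe,
                              sub["share_of_lobe_a_pct"], sub["share_of_lobe_b_pct"])
            assert shares.sum() == pytest.approx(100.0)

    def test_zero_matrix_gives_empty_table(self, toy_parcellation):
        m = dmat.DisconnectivityMatrix(np.zeros((8, 8), int), toy_parcellation.parcel_ids)
        assert len(dmat.export_chord_table(m, toy_parcellation.table)) == 0
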