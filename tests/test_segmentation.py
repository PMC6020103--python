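"""Two-stage individual tree detection: density clustering, allometric
splitting and crown cleaning."""

import numpy as np
import pytest

import urbancanopy as uc
from urbancanopy import synthetic as syn
from urbancanopy.pointcloud import PointCloud
from urbancanopy.segmentation import Cluster, CrownSet

from oracle_density import density_cluster_oracle


def cloud_from_xyz(xyz):
    xyz = np.asarray(xyz, dtype=float)
    return PointCloud(xyz[:, 0], xyz[:, 1], xyz[:, 2],
                      np.full(len(xyz), 2), normalized=True)


def label_sets(labels):
    return {frozenset(np.flatnonzero(labels == lab))
            for lab in np.unique(labels) if lab != -1}


class TestDensityStage:
    def test_two_separated_blobs_form_two_clusters(self):
        rng = np.random.default_rng(0)
        a = rng.normal([0, 0, 10], 0.5, size=(100, 3))
        b = rng.normal([10, 0, 10], 0.5, size=(100, 3))
        clusters, noise = uc.cluster_density(cloud_from_xyz(np.vstack([a, b])),
                                             eps=3.5, min_samples=20)
        assert len(clusters) == 2 and len(noise) == 0
        # oracle agreement on the same points
        oracle = density_cluster_oracle(np.vstack([a, b]), 3.5, 20)
        assert label_sets(oracle) == {frozenset(range(100)),
                                      frozenset(range(100, 200))}

    def test_below_minimum_membership_is_noise(self):
        xyz = np.tile([5.0, 5.0, 10.0], (19, 1))
        clusters, noise = uc.cluster_density(cloud_from_xyz(xyz),
                                             eps=3.5, min_samples=20)
        assert clusters == [] and len(noise) == 19

    def test_single_blob_keeps_all_members(self):
        rng = np.random.default_rng(1)
        xyz = rng.normal([0, 0, 10], 1.0, size=(500, 3))
        clusters, noise = uc.cluster_density(cloud_from_xyz(xyz),
                                             eps=3.5, min_samples=20)
        assert len(clusters) == 1
        assert clusters[0].n_points == 500 and len(noise) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_density_connectivity(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 300))
        xyz = rng.uniform(0, 40, size=(n, 3))
        eps = float(rng.uniform(1.5, 4.0))
        ms = int(rng.integers(3, 12))
        clusters, noise = uc.cluster_density(cloud_from_xyz(xyz), eps, ms)
        got = {frozenset(map(tuple, c.points)) for c in clusters}
        oracle = density_cluster_oracle(xyz, eps, ms)
        want = {frozenset(map(tuple, xyz[list(idx)]))
                for idx in label_sets(oracle)}
        assert got == want

    def test_empty_cloud(self):
        clusters, noise = uc.cluster_density(cloud_from_xyz(np.empty((0, 3))))
        assert clusters == [] and len(noise) == 0


class TestSplitCriterion:
    model = uc.ThresholdModel(alpha=0.5, beta=1.0, kind="split_95pi")

    def cluster_with(self, H, r):
        # circle of radius r at height H (plus a low point to pin H)
        theta = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta),
                               np.full(60, H)])
        c = Cluster(pts)
        assert c.H == H
        return c

    def test_inside_bound_is_kept(self):
        c = self.cluster_with(10.0, 5.9)
        c.r = 5.9  # exact radius, bypassing hull discretisation
        assert not uc.needs_split(c, self.model)

    def test_outside_bound_is_split(self):
        c = self.cluster_with(10.0, 6.1)
        c.r = 6.1
        assert uc.needs_split(c, self.model)

    def test_boundary_is_strict(self):
        c = self.cluster_with(10.0, 6.0)
        c.r = 6.0  # exactly beta + alpha*H
        assert not uc.needs_split(c, self.model)


class TestCanopySplitting:
    def test_no_split_needed_returns_cluster_unchanged(self, seg_params):
        rng = np.random.default_rng(2)
        pts = rng.normal([0, 0, 12], [1.0, 1.0, 1.0], size=(80, 3))
        c = Cluster(pts)
        if uc.needs_split(c, seg_params.split_model):
            pytest.skip("construction unexpectedly wide")
        out, dropped = uc.split_canopy(c, seg_params.bt_model,
                                       seg_params.split_model, seg_params)
        assert out == [c] and len(dropped) == 0

    def test_merged_pair_splits_at_true_stem_positions(self, seg_params):
        cloud, truth = syn.merged_pair_scene(seed=3)
        crowns = uc.segment_trees(cloud, seg_params)
        assert len(crowns) == 2
        got = sorted(c.centroid for c in crowns)
        want = sorted(zip(truth.trees.x, truth.trees.y))
        for (gx, gy), (wx, wy) in zip(got, want):
            assert np.hypot(gx - wx, gy - wy) < 2.0

    def test_row_of_three_touching_crowns(self, seg_params):
        H, r = 15.0, 1.0 + 0.15 * 15.0
        trees = [syn.TreeSpec(id=i, x=30.0 + i * 8.0, y=30.0, H=H,
                              crown_radius=r, crown_base=4.0, V_true=5.0)
                 for i in range(3)]
        cloud, truth = syn.render_scene(
            syn.SceneSpec(extent=(90, 60), trees=trees, seed=11))
        crowns = uc.segment_trees(cloud, seg_params)
        assert len(crowns) == 3
        for c in crowns:
            assert (not uc.needs_split(c, seg_params.split_model)
                    or c.non_convergent)

    def test_disjoint_subsets_of_input(self, seg_params):
        cloud, _ = syn.merged_pair_scene(seed=4)
        veg = uc.filter_low_points(uc.filter_single_return_points(cloud))
        clusters, _ = uc.cluster_density(veg, seg_params.eps,
                                         seg_params.min_samples)
        big = max(clusters, key=lambda c: c.n_points)
        subs, dropped = uc.split_canopy(big, seg_params.bt_model,
                                        seg_params.split_model, seg_params)
        seen = set()
        for sub in subs:
            keys = set(map(tuple, sub.points))
            assert not (keys & seen)
            seen |= keys
        all_in = set(map(tuple, big.points))
        assert seen <= all_in
        assert len(seen) + len(dropped) == big.n_points


class TestCleanCrowns:
    def params(self, **kw):
        tm = uc.ThresholdModel(alpha=0.15, beta=2.0)
        defaults = dict(split_model=tm, bt_model=tm)
        defaults.update(kw)
        return uc.SegmentationParams(**defaults)

    @staticmethod
    def square_crown(side, H, x0=0.0, y0=0.0, n=50):
        rng = np.random.default_rng(9)
        pts = np.column_stack([x0 + rng.uniform(0, side, n),
                               y0 + rng.uniform(0, side, n),
                               rng.uniform(H - 1, H, n)])
        # pin the corners so hull area is exactly side^2
        corners = np.array([[x0, y0], [x0 + side, y0],
                            [x0 + side, y0 + side], [x0, y0 + side]])
        pts[:4, :2] = corners
        return Cluster(pts)

    def test_small_polygons_removed(self):
        crowns = CrownSet([self.square_crown(3.0, 10),      # 9 m^2
                           self.square_crown(np.sqrt(15), 10)])
        out = uc.clean_crowns(crowns, self.params())
        assert len(out) == 1
        assert out.crowns[0].Ar == pytest.approx(15.0)

    def test_vertically_offset_duplicates_collapse(self):
        a = self.square_crown(5.0, 12, n=80)
        b = self.square_crown(5.0, 9, x0=0.3, n=40)
        out = uc.clean_crowns(CrownSet([a, b]), self.params())
        assert len(out) == 1
        assert out.crowns[0].n_points == 80  # more points wins

    def test_overheight_crowns_removed(self):
        tall = self.square_crown(5.0, 80.0)
        ok = self.square_crown(5.0, 20.0, x0=50.0)
        out = uc.clean_crowns(CrownSet([tall, ok]),
                              self.params(max_crown_height=50.0))
        assert [c.H for c in out] == [pytest.approx(20.0, abs=1.1)]

    def test_raising_min_area_never_adds_crowns(self, benchmark_scene,
                                                seg_params):
        cloud, _ = benchmark_scene
        counts = []
        for area in (0.0, 10.0, 30.0, 60.0):
            p = self.params(split_model=seg_params.split_model,
                            bt_model=seg_params.bt_model,
                            min_polygon_area=area)
            counts.append(len(uc.segment_trees(cloud, p)))
        assert counts == sorted(counts, reverse=True)


class TestEndToEnd:
    def test_empty_cloud_gives_empty_crownset(self, seg_params):
        empty = cloud_from_xyz(np.empty((0, 3)))
        assert len(uc.segment_trees(empty, seg_params)) == 0

    def test_recovers_well_separated_trees(self, benchmark_scene, seg_params):
        cloud, truth = benchmark_scene
        crowns = uc.segment_trees(cloud, seg_params)
        m = syn.match_crowns(truth, crowns, max_dist=2.0)
        assert m["precision"] >= 0.9 and m["recall"] >= 0.9

    def test_building_is_rejected_by_return_filter(self, seg_params):
        tree = syn.TreeSpec(id=0, x=20, y=20, H=15.0, crown_radius=3.2,
                            crown_base=4.0, V_true=5.0)
        spec = syn.SceneSpec(extent=(60, 60), trees=[tree],
                             buildings=[syn.Building(35, 35, 55, 55, 12.0)],
                             seed=21)
        cloud, truth = syn.render_scene(spec)
        crowns = uc.segment_trees(cloud, seg_params)
        assert len(crowns) == 1
        m = syn.match_crowns(truth, crowns)
        assert m["n_matched"] == 1

    def test_partition_and_bookkeeping(self, seg_params):
        cloud, _ = syn.well_separated_scene(n_trees=16, seed=5)
        crowns = uc.segment_trees(cloud, seg_params)
        prov = crowns.provenance
        # crown points are pairwise disjoint
        seen = set()
        for c in crowns:
            keys = set(map(tuple, c.points))
            assert not (keys & seen)
            seen |= keys
        # crown + noise + filtered + dropped points account for the input
        # (cleaning may discard whole crowns, so <=)
        accounted = (len(seen) + prov["n_noise_points"]
                     + prov["n_filtered_out"]
                     + prov["n_dropped_subcluster_points"])
        assert accounted <= prov["n_input_points"]
        veg_points = prov["n_input_points"] - prov["n_filtered_out"]
        assert len(seen) <= veg_points

    def test_determinism(self, seg_params):
        cloud, _ = syn.well_separated_scene(n_trees=16, seed=6)
        a = uc.segment_trees(cloud, seg_params)
        b = uc.segment_trees(cloud, seg_params)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.points, cb.points)

    def test_geojson_export_round_trip(self, seg_params, tmp_path):
        cloud, _ = syn.well_separated_scene(n_trees=9, seed=8)
        crowns = uc.segment_trees(cloud, seg_params)
        path = tmp_path / "crowns.geojson"
        fc = uc.crowns_to_geojson(crowns, path)
        assert path.exists()
        assert len(fc["features"]) == len(crowns)
        props = fc["features"][0]["properties"]
        assert {"id", "H_m", "Ar_m2", "r_m", "n_points"} <= set(props)


def test_segmentation_params_from_flat_config(tmp_path, thresholds):
    split, bt = thresholds
    cfg = tmp_path / "seg.cfg"
    cfg.write_text("eps = 3.0\nmin_samples = 15  # points\n"
                   "min_polygon_area = 12.5\nmax_iterations = 10\n")
    params = uc.SegmentationParams.from_file(cfg, split, bt)
    assert params.eps == 3.0 and params.min_samples == 15
    assert params.min_polygon_area == 12.5 and params.max_iterations == 10
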