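import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from roottrace import (
    BaseNode,
    HelixCurve,
    Polyline,
    RSATree,
    SingleRootTraits,
    average_growth_angle,
    compute_rsa_traits,
    export_traits_csv,
    rdi,
    resample_at_voxel_resolution,
    root_growth_angle,
    root_length,
    total_root_length,
)

from conftest import random_polyline


class TestGrowthAngle:
    def test_unit_rise_over_unit_run_is_45_degrees(self):
        assert root_growth_angle(Polyline([(0, 0, 0), (1, 0, 1)])) == pytest.approx(
            math.pi / 4
        )

    def test_vertical_root_returns_right_angle(self):
        assert root_growth_angle(Polyline([(0, 0, 0), (0, 0, 5)])) == math.pi / 2

    def test_345_chord_cross_checked_by_dot_product(self):
        poly = Polyline([(0, 0, 0), (3, 4, 5)])
        theta = root_growth_angle(poly)
        assert theta == pytest.approx(math.pi / 4)
        # independent vector-geometry check: angle between the chord and
        # its horizontal projection
        chord = np.array([3.0, 4.0, 5.0])
        horiz = np.array([3.0, 4.0, 0.0])
        expected = math.acos(
            chord @ horiz / (np.linalg.norm(chord) * np.linalg.norm(horiz))
        )
        assert theta == pytest.approx(expected, rel=1e-12)

    def test_only_end_vertices_matter(self):
        wiggly = Polyline([(0, 0, 0), (9, -3, 2), (-4, 6, 1), (1, 0, 1)])
        assert root_growth_angle(wiggly) == pytest.approx(math.pi / 4)

    def test_angle_bounds_and_horizontal_invariances(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            poly = random_polyline(rng)
            theta = root_growth_angle(poly)
            assert 0 <= theta <= math.pi / 2
            # rotation about the vertical axis and horizontal translation
            rot = Rotation.from_euler("z", rng.uniform(0, 360), degrees=True)
            moved = rot.apply(np.array(poly.points)) + [rng.uniform(-9, 9), rng.uniform(-9, 9), 0]
            assert root_growth_angle(Polyline(moved)) == pytest.approx(theta, abs=1e-9)


class TestRootLength:
    def test_345_segment_at_point3_mm_per_voxel(self):
        poly = Polyline([(0, 0, 0), (3, 4, 0)])
        assert root_length(poly, 0.3) == pytest.approx(0.15)

    def test_dense_helix_matches_analytic_arc_length(self):
        helix = HelixCurve(center_xy=(0, 0), radius=20.0, z_start=0.0,
                           z_end=100.0, turns=3.0)
        t = np.linspace(0, 1, 1000)
        poly = Polyline(helix.point(t))
        expected = 0.3 / 10 * helix.arc_length()
        assert root_length(poly, 0.3) == pytest.approx(expected, rel=1e-3)

    def test_length_is_rotation_invariant(self):
        rng = np.random.default_rng(11)
        poly = random_polyline(rng, n_min=5)
        rot = Rotation.random(random_state=11)
        assert root_length(Polyline(rot.apply(np.array(poly.points))), 0.5) == pytest.approx(
            root_length(poly, 0.5), rel=1e-12
        )

    def test_refinement_on_segment_keeps_length_off_segment_grows_it(self):
        poly = Polyline([(0, 0, 0), (10, 0, 0)])
        on_segment = Polyline([(0, 0, 0), (4, 0, 0), (10, 0, 0)])
        off_segment = Polyline([(0, 0, 0), (4, 2, 0), (10, 0, 0)])
        base = root_length(poly, 1.0)
        assert root_length(on_segment, 1.0) == pytest.approx(base)
        assert root_length(off_segment, 1.0) > base


class TestAggregates:
    def test_mean_angle_of_30_and_60_degrees_is_45(self):
        roots = [
            SingleRootTraits(0, math.pi / 6, 1.0),
            SingleRootTraits(1, math.pi / 3, 2.0),
        ]
        assert average_growth_angle(roots) == pytest.approx(math.pi / 4)
        assert total_root_length(roots) == pytest.approx(3.0)

    def test_aggregates_match_independent_summation(self):
        rng = np.random.default_rng(5)
        roots = [
            SingleRootTraits(i, float(rng.uniform(0, math.pi / 2)),
                             float(rng.uniform(0, 50)))
            for i in range(100)
        ]
        mean = sum(r.theta for r in roots) / len(roots)
        total = sum(r.length_cm for r in roots)
        assert average_growth_angle(roots) == pytest.approx(mean, rel=1e-12)
        assert total_root_length(roots) == pytest.approx(total, rel=1e-12)

    def test_empty_root_list_rejected(self):
        with pytest.raises(ValueError, match="no roots"):
            average_growth_angle([])
        with pytest.raises(ValueError, match="no roots"):
            total_root_length([])

    def test_total_length_additivity(self):
        rng = np.random.default_rng(13)
        roots = [
            SingleRootTraits(i, 0.5, float(rng.uniform(1, 9))) for i in range(6)
        ]
        removed = roots[2]
        assert total_root_length(roots) - total_root_length(
            [r for r in roots if r is not removed]
        ) == pytest.approx(removed.length_cm)


class TestResample:
    def test_ten_voxel_segment_gains_integer_spaced_vertices(self):
        poly = resample_at_voxel_resolution(Polyline([(0, 0, 0), (0, 0, 10)]))
        assert len(poly) == 11
        assert np.allclose(poly.points[:, 2], np.arange(11))

    def test_already_dense_polyline_unchanged(self):
        pts = np.column_stack([np.zeros(20), np.zeros(20), np.linspace(0, 9.5, 20)])
        poly = Polyline(pts)
        assert resample_at_voxel_resolution(poly) == poly

    def test_original_vertices_retained_and_length_preserved(self):
        rng = np.random.default_rng(17)
        poly = random_polyline(rng, n_min=4)
        resampled = resample_at_voxel_resolution(poly)
        for vertex in poly.points:
            assert np.any(np.all(resampled.points == vertex, axis=1))
        assert resampled.length_voxels() == pytest.approx(
            poly.length_voxels(), rel=1e-9
        )
        spacing = np.linalg.norm(np.diff(resampled.points, axis=0), axis=1)
        assert spacing.max() <= 1.0 + 1e-9


class TestRdi:
    def test_uniform_vertical_root_centroid(self):
        poly = resample_at_voxel_resolution(Polyline([(0, 0, 0), (0, 0, 10)]))
        assert rdi([poly], base_z=0.0, resolution_mm=0.3) == pytest.approx(0.15)

    def test_horizontal_roots_at_base_depth_give_zero(self):
        polys = [
            Polyline([(0, 0, 5), (9, 0, 5)]),
            Polyline([(0, 0, 5), (0, 9, 5)]),
        ]
        polys = [resample_at_voxel_resolution(p) for p in polys]
        assert rdi(polys, base_z=5.0, resolution_mm=0.3) == pytest.approx(0.0)

    def test_matches_explicit_double_loop(self):
        rng = np.random.default_rng(19)
        polys = [
            resample_at_voxel_resolution(random_polyline(rng)) for _ in range(3)
        ]
        base_z, r = 2.0, 0.4
        acc = 0.0
        for p in polys:
            inner = 0.0
            for vertex in p.points:
                inner += vertex[2]
            acc += inner / len(p.points)
        expected = r / 10 * (acc / len(polys) - base_z)
        assert rdi(polys, base_z, r) == pytest.approx(expected, rel=1e-12)

    def test_bounds_follow_vertex_depths(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            polys = [
                resample_at_voxel_resolution(random_polyline(rng)) for _ in range(3)
            ]
            depths = np.concatenate([p.points[:, 2] for p in polys])
            base_z = float(depths.min())  # base at or above every vertex
            value = rdi(polys, base_z, 0.3)
            assert value >= 0.0
            assert value <= 0.3 / 10 * (depths.max() - base_z)

    def test_no_roots_rejected(self):
        with pytest.raises(ValueError, match="no roots"):
            rdi([], 0.0, 0.3)


class TestExport:
    def _vectorized_tree(self):
        tree = RSATree(BaseNode((0.0, 0.0, 0.0)), resolution_mm=0.3)
        for k in range(3):
            rid = tree.add_root([(3.0 + k, 4.0, 5.0 + k)])
            root = tree.get_root(rid)
            root.polyline = Polyline([(0, 0, 0), (3.0 + k, 4.0, 5.0 + k)])
            root.interpolation = "straight"
        return tree

    def test_single_root_tree_has_one_data_row(self, tmp_path):
        tree = self._vectorized_tree()
        while tree.n_roots > 1:
            tree.remove_root(tree.roots[-1].id)
        per_root_path, _ = export_traits_csv(tree, tmp_path)
        assert len(pd.read_csv(per_root_path)) == 1

    def test_summary_total_equals_parsed_back_per_root_sum(self, tmp_path):
        per_root_path, summary_path = export_traits_csv(
            self._vectorized_tree(), tmp_path
        )
        per_root = pd.read_csv(per_root_path)
        summary = pd.read_csv(summary_path)
        assert summary.loc[0, "total_length_cm"] == pytest.approx(
            per_root["length_cm"].sum(), rel=1e-5
        )
        assert summary.loc[0, "n_roots"] == 3

    def test_summary_matches_computed_traits(self, tmp_path):
        tree = self._vectorized_tree()
        _, summary_path = export_traits_csv(tree, tmp_path)
        summary = pd.read_csv(summary_path)
        rsa = compute_rsa_traits(tree)
        assert summary.loc[0, "mean_theta_deg"] == pytest.approx(
            math.degrees(rsa.mean_theta), rel=1e-5
        )
        assert summary.loc[0, "rdi_cm"] == pytest.approx(rsa.rdi_cm, rel=1e-5)

    def test_empty_tree_yields_zero_root_summary(self, tmp_path):
        tree = RSATree(BaseNode((0.0, 0.0, 0.0)), resolution_mm=0.3)
        per_root_path, summary_path = export_traits_csv(tree, tmp_path)
        assert len(pd.read_csv(per_root_path)) == 0
        summary = pd.read_csv(summary_path)
        assert summary.loc[0, "n_roots"] == 0
        assert summary["mean_theta_deg"].isna().all()

    def test_unvectorized_root_blocks_export(self, tmp_path):
        tree = RSATree(BaseNode((0.0, 0.0, 0.0)), resolution_mm=0.3)
        tree.add_root([(1.0, 2.0, 3.0)])
        with pytest.raises(ValueError, match="vectorize before export: root 0"):
            export_traits_csv(tree, tmp_path)
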