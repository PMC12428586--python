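"""Skeleton data model, I/O, grading, radius processing and trimming."""

import json

import numpy as np
import pytest

import airwaykit as ak
from airwaykit.skeleton import SkeletonError


def make_branch(radii, zs=None, bid="b0", parent=None):
    if zs is None:
        zs = np.linspace(0.0, 10.0 * (len(radii) - 1), len(radii))
    pts = [ak.SkeletonPoint(np.array([0.0, 0.0, z]), r) for z, r in zip(zs, radii)]
    return ak.Branch(bid, parent, pts)


class TestDataModel:
    def test_nonpositive_radius_rejected(self):
        with pytest.raises(SkeletonError, match="radius"):
            ak.SkeletonPoint(np.zeros(3), 0.0)

    def test_single_point_branch_rejected(self):
        with pytest.raises(SkeletonError, match="points"):
            ak.Branch("b", None, [ak.SkeletonPoint(np.zeros(3), 1.0)])

    def test_arclens_nondecreasing(self, small_tree):
        for b in small_tree.branches:
            assert np.all(np.diff(b.arclens()) >= 0)

    def test_two_roots_rejected(self):
        b0 = make_branch([2, 2], bid="b0")
        b1 = make_branch([2, 2], bid="b1")
        with pytest.raises(SkeletonError, match="root"):
            ak.Skeleton([b0, b1])

    def test_cycle_rejected(self):
        b0 = make_branch([2, 2], bid="b0", parent="b1")
        b1 = make_branch([2, 2], bid="b1", parent="b0")
        with pytest.raises(SkeletonError):
            ak.Skeleton([b0, b1])

    def test_detached_child_rejected(self):
        b0 = make_branch([2, 2], bid="b0")
        pts = [ak.SkeletonPoint(np.array([50.0, 0, 0]), 2.0),
               ak.SkeletonPoint(np.array([60.0, 0, 0]), 2.0)]
        b1 = ak.Branch("b1", "b0", pts)
        with pytest.raises(SkeletonError, match="parent"):
            ak.Skeleton([b0, b1])


class TestIO:
    def test_minimal_json(self, tmp_path):
        doc = {"schema": "skeleton-v1", "units": "mm", "branches": [
            {"id": "b0", "parent_id": None, "generation": 0,
             "points": [{"xyz": [0, 0, 0], "radius": 5.0},
                        {"xyz": [0, 0, 10], "radius": 5.0}]}]}
        p = tmp_path / "s.json"
        p.write_text(json.dumps(doc))
        s = ak.read_skeleton(p)
        assert len(s.branches) == 1 and s.root.generation == 0

    def test_invalid_radius_in_file(self, tmp_path):
        doc = {"branches": [{"id": "b0", "parent_id": None, "points": [
            {"xyz": [0, 0, 0], "radius": -1.0}, {"xyz": [0, 0, 1], "radius": 1.0}]}]}
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(SkeletonError, match="radius"):
            ak.read_skeleton(p)

    def test_malformed_json(self, tmp_path):
        p = tmp_path / "garbage.json"
        p.write_text("{not json")
        with pytest.raises(SkeletonError, match="malformed"):
            ak.read_skeleton(p)

    @pytest.mark.parametrize("fmt", ["json", "csv"])
    def test_roundtrip_three_generation_tree(self, tmp_path, fmt):
        tree = ak.make_bifurcating_tree(ak.TreeSpec(generations=3, seed=1, jitter=0.1))
        p = tmp_path / f"tree.{fmt}"
        ak.write_skeleton(tree, p, fmt)
        back = ak.read_skeleton(p)
        assert len(back.branches) == len(tree.branches)
        for a, b in zip(tree.branches, back.branches):
            assert a.id == b.id and a.parent_id == b.parent_id
            np.testing.assert_allclose(a.positions(), b.positions(), atol=1e-9)
            # repr() serialization keeps radii bit-identical
            assert np.array_equal(a.radii(), b.radii())

    def test_csv_missing_columns(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(SkeletonError, match="columns"):
            ak.read_skeleton(p)


class TestGrading:
    def test_root_children_generations(self):
        b0 = make_branch([5, 5], bid="b0")
        tip = b0.points[-1].position
        kids = []
        for k in range(2):
            pts = [ak.SkeletonPoint(tip, 4.0),
                   ak.SkeletonPoint(tip + np.array([5.0 * (k + 1), 0, 5.0]), 4.0)]
            kids.append(ak.Branch(f"c{k}", "b0", pts, generation=99))
        graded = ak.grade_generations(ak.Skeleton([b0] + kids))
        assert graded.root.generation == 0
        assert all(b.generation == 1 for b in graded.children("b0"))

    def test_four_level_tree_max_generation(self):
        tree = ak.make_bifurcating_tree(ak.TreeSpec(generations=4, seed=0))
        graded = ak.grade_generations(tree)
        assert max(b.generation for b in graded.branches) == 3

    def test_idempotent_and_order_independent(self, small_tree):
        g1 = ak.grade_generations(small_tree)
        g2 = ak.grade_generations(g1)
        assert [b.generation for b in g1.branches] == [b.generation for b in g2.branches]
        shuffled = ak.Skeleton(list(reversed(small_tree.copy().branches)))
        g3 = ak.grade_generations(shuffled)
        gens = {b.id: b.generation for b in g3.branches}
        assert gens == {b.id: b.generation for b in g1.branches}


class TestEquivalentRadius:
    def test_formula(self):
        assert ak.area_to_radius(np.pi) == pytest.approx(1.0)
        assert ak.area_to_radius(9 * np.pi) == pytest.approx(3.0)

    def test_cylinder_within_one_percent(self):
        mesh = ak.make_cylinder_mesh(5.0, 40.0, n_circ=128, n_axial=8).to_trimesh()
        r = ak.equivalent_radius(mesh, np.array([0.0, 0, 0]), np.array([0.0, 0, 1]))
        assert abs(r - 5.0) / 5.0 < 0.01

    def test_plane_missing_mesh(self):
        mesh = ak.make_cylinder_mesh(5.0, 40.0).to_trimesh()
        with pytest.raises(SkeletonError):
            ak.equivalent_radius(mesh, np.array([0.0, 0, 100.0]), np.array([0.0, 0, 1]))


class TestSmoothNodeRadii:
    def _junction(self, rp, rc):
        b0 = make_branch([rp] * 8, bid="b0")
        tip = b0.points[-1].position
        pts = [ak.SkeletonPoint(tip + np.array([0, 0, 10.0 * k]), rc)
               for k in range(8)]
        return ak.Skeleton([b0, ak.Branch("c0", "b0", pts)])

    def test_below_threshold_unchanged(self):
        s = self._junction(2.0, 2.1)  # 4.8 % difference
        out = ak.smooth_node_radii(s)
        for a, b in zip(s.branches, out.branches):
            np.testing.assert_array_equal(a.radii(), b.radii())

    def test_above_threshold_monotone_ramp(self):
        s = self._junction(2.0, 3.0)  # 33 % difference
        out = ak.smooth_node_radii(s, window=3)
        seq = np.concatenate([out.branch("b0").radii()[-4:],
                              out.branch("c0").radii()[:4]])
        assert np.all(np.diff(seq) >= -1e-12)
        assert seq.min() >= 2.0 - 1e-12 and seq.max() <= 3.0 + 1e-12
        # ramp is linear in the across-junction arc length (the parent end
        # and child start coincide at s = 0)
        svals = np.concatenate([np.arange(-3, 1), np.arange(0, 4)]) * 10.0
        ramp = np.interp(svals, [svals[0], svals[-1]], [seq[0], seq[-1]])
        np.testing.assert_allclose(seq, ramp, atol=1e-9)

    def test_zero_threshold_ramps_every_junction(self, small_tree):
        out = ak.smooth_node_radii(small_tree, threshold=0.0)
        # child heads no longer equal their original constant radius
        child = next(b for b in out.branches if b.parent_id == small_tree.root.id)
        orig = next(b for b in small_tree.branches if b.id == child.id)
        assert not np.allclose(child.radii()[:3], orig.radii()[:3])

    def test_radii_stay_within_flank_bounds(self):
        s = self._junction(2.0, 4.0)
        out = ak.smooth_node_radii(s)
        allr = np.concatenate([b.radii() for b in out.branches])
        assert allr.min() >= 2.0 - 1e-12 and allr.max() <= 4.0 + 1e-12


class TestCenterline:
    def test_collinear_stays_collinear(self):
        pts = np.outer(np.linspace(0, 1, 8), np.array([1.0, 2.0, 3.0]))
        out, _ = ak.fit_centerline(pts, smoothing=0.0, n_out=20)
        d = out - out[0]
        axis = d[-1] / np.linalg.norm(d[-1])
        offsets = d - np.outer(d @ axis, axis)
        assert np.abs(offsets).max() < 1e-9

    def test_interpolates_at_zero_smoothing(self):
        # equal chord steps, so the n_out = n_in uniform parameter samples
        # coincide with the input parameters and must recover the inputs
        theta = np.linspace(0, np.pi, 9)
        pts = np.stack([np.cos(theta), np.sin(theta), 0.1 * theta], axis=1) * 20.0
        out, _ = ak.fit_centerline(pts, smoothing=0.0, n_out=len(pts))
        np.testing.assert_allclose(out, pts, atol=1e-6)

    def test_smoothing_reduces_curvature_of_noisy_helix(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0, 4 * np.pi, 60)
        helix = np.stack([np.cos(t), np.sin(t), 0.2 * t], axis=1) * 10.0
        noisy = helix + rng.normal(0, 0.3, helix.shape)

        def curvature(p):
            d1 = np.gradient(p, axis=0)
            d2 = np.gradient(d1, axis=0)
            num = np.linalg.norm(np.cross(d1, d2), axis=1)
            return num / np.linalg.norm(d1, axis=1) ** 3

        out, _ = ak.fit_centerline(noisy, smoothing=50.0, n_out=60)
        assert np.median(curvature(out)) < np.median(curvature(noisy))

    def test_endpoints_pinned_with_smoothing(self):
        rng = np.random.default_rng(11)
        pts = np.cumsum(rng.normal(1, 0.3, (12, 3)), axis=0)
        out, _ = ak.fit_centerline(pts, smoothing=5.0, n_out=30)
        np.testing.assert_allclose(out[0], pts[0], atol=1e-12)
        np.testing.assert_allclose(out[-1], pts[-1], atol=1e-12)

    def test_tangents_unit_norm(self):
        pts = np.outer(np.linspace(0, 1, 6), np.array([1.0, 0, 0]))
        _, tan = ak.fit_centerline(pts, n_out=10)
        np.testing.assert_allclose(np.linalg.norm(tan, axis=1), 1.0, atol=1e-12)


class TestResampleRadii:
    def test_constant_profile(self, straight_branch):
        new = np.array([[0, 0, 3.3], [0, 0, 11.7]])
        out = ak.resample_radii(straight_branch, new)
        np.testing.assert_allclose(out.radii(), 2.0)

    def test_linear_midpoint(self):
        pts = [ak.SkeletonPoint(np.array([0.0, 0, 0]), 2.0),
               ak.SkeletonPoint(np.array([0.0, 0, 10]), 4.0)]
        b = ak.Branch("b", None, pts)
        out = ak.resample_radii(b, np.array([[0, 0, 5.0]] * 2))
        assert out.points[0].radius == pytest.approx(3.0)

    def test_identity_at_original_samples(self):
        rng = np.random.default_rng(3)
        zs = np.linspace(0, 30, 12)
        radii = rng.uniform(1, 5, 12)
        pts = [ak.SkeletonPoint(np.array([0.0, 0, z]), r) for z, r in zip(zs, radii)]
        b = ak.Branch("b", None, pts)
        out = ak.resample_radii(b, b.positions())
        np.testing.assert_allclose(out.radii(), radii, atol=1e-12)


class TestTrimDistal:
    def test_trims_to_requested_length(self, small_tree):
        out = ak.trim_distal(small_tree, 10.0)
        for b in out.terminal_branches():
            assert b.length == pytest.approx(10.0, abs=1e-9)

    def test_short_branch_unchanged(self, small_tree):
        long_out = ak.trim_distal(small_tree, 1e6)
        assert long_out.total_length() == pytest.approx(small_tree.total_length())

    def test_idempotent(self, small_tree):
        once = ak.trim_distal(small_tree, 10.0)
        twice = ak.trim_distal(once, 10.0)
        assert twice.total_length() == pytest.approx(once.total_length(), abs=1e-9)

    def test_never_grows_tree(self, small_tree):
        out = ak.trim_distal(small_tree, 5.0)
        assert out.total_length() <= small_tree.total_length()

    def test_rejects_nonpositive_length(self, small_tree):
        with pytest.raises(ValueError):
            ak.trim_distal(small_tree, 0.0)
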