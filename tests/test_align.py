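"""Anatomical frame, cropping, slice extraction and centroid-size scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from torsoshape import align, pipeline, synth
from torsoshape.align import (SliceProfile, build_frame, centroid_size,
                              crop_torso, extract_slices, joint_centroid_size,
                              scale_slices, transform_to_frame)
from conftest import ring_cloud

UP = np.array([0.0, 0.0, 1.0])


def finite_coords():
    return st.floats(-500.0, 500.0, allow_nan=False)


class TestBuildFrame:
    def test_canonical_example(self):
        f = build_frame(np.array([1.0, 0, 0]), np.array([-1.0, 0, 0]), UP)
        assert np.allclose(f.origin, 0.0)
        assert np.allclose(f.X, [-1.0, 0.0, 0.0], atol=1e-12)
        assert np.allclose(f.Z, [0.0, 0.0, 1.0], atol=1e-12)
        assert np.allclose(f.Y, [0.0, 1.0, 0.0], atol=1e-12)

    def test_coincident_landmarks_raise(self):
        p = np.array([3.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            build_frame(p, p, UP)

    def test_vertical_axis_raises(self):
        with pytest.raises(ValueError):
            build_frame(np.zeros(3), np.array([0.0, 0.0, 100.0]), UP)

    @settings(max_examples=60, deadline=None)
    @given(st.tuples(*[finite_coords()] * 6))
    def test_orthonormality(self, coords):
        L1 = np.array(coords[:3])
        L2 = np.array(coords[3:])
        d = L2 - L1
        if np.linalg.norm(d) <= 1.0:
            return
        horiz = np.linalg.norm(d[:2])
        if horiz < 1e-3 * np.linalg.norm(d):
            return
        f = build_frame(L1, L2, UP)
        for a, b in ((f.X, f.Y), (f.X, f.Z), (f.Y, f.Z)):
            assert abs(a @ b) <= 1e-9
        assert f.Z @ UP > 0


class TestTransformToFrame:
    def test_identity_frame_is_noop(self):
        f = align.AnatomicalFrame(origin=np.zeros(3), X=np.array([1.0, 0, 0]),
                                  Y=np.array([0, 1.0, 0]),
                                  Z=np.array([0, 0, 1.0]))
        cloud = ring_cloud()
        assert np.allclose(transform_to_frame(cloud, f), cloud)

    def test_landmarks_map_to_half_distance_poles(self):
        L1 = np.array([120.0, 30.0, 5.0])
        L2 = np.array([-140.0, -10.0, 5.0])
        f = build_frame(L1, L2, UP)
        d = np.linalg.norm(L2 - L1)
        got = transform_to_frame(np.vstack([L1, L2]), f)
        assert np.allclose(got[0], [-d / 2.0, 0.0, 0.0], atol=1e-9)
        assert np.allclose(got[1], [+d / 2.0, 0.0, 0.0], atol=1e-9)

    def test_distances_preserved(self):
        rng = np.random.default_rng(0)
        cloud = rng.normal(size=(50, 3)) * 100.0
        f = build_frame(np.array([100.0, 20.0, 0.0]),
                        np.array([-90.0, -15.0, 2.0]), UP)
        out = transform_to_frame(cloud, f)
        din = np.linalg.norm(cloud[:1] - cloud, axis=1)
        dout = np.linalg.norm(out[:1] - out, axis=1)
        assert np.allclose(din, dout, rtol=1e-9)

    def test_rigid_motion_invariance_with_moved_landmarks(self):
        rng = np.random.default_rng(1)
        cloud = rng.normal(size=(200, 3)) * 80.0
        L1 = np.array([130.0, 5.0, 10.0])
        L2 = np.array([-120.0, -8.0, 10.0])
        base = transform_to_frame(cloud, build_frame(L1, L2, UP))
        ang = 1.1
        c, s = np.cos(ang), np.sin(ang)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        t = np.array([55.0, -20.0, 140.0])
        moved = transform_to_frame(cloud @ R.T + t,
                                   build_frame(R @ L1 + t, R @ L2 + t, UP))
        assert np.allclose(base, moved, atol=1e-6)


class TestCropTorso:
    def test_matches_brute_force(self):
        cloud = ring_cloud(z_levels=np.arange(0.0, 40.0, 2.0))
        kept = crop_torso(cloud, 5.0, 21.0)
        brute = cloud[(cloud[:, 2] >= 5.0) & (cloud[:, 2] <= 21.0)]
        assert len(kept) == len(brute)

    def test_full_range_is_identity(self):
        cloud = ring_cloud()
        out = crop_torso(cloud, cloud[:, 2].min(), cloud[:, 2].max())
        assert np.array_equal(out, cloud)

    def test_inverted_bounds_raise(self):
        with pytest.raises(ValueError):
            crop_torso(ring_cloud(), 10.0, 5.0)

    def test_empty_crop_raises(self):
        with pytest.raises(ValueError):
            crop_torso(ring_cloud(z_levels=[0.0]), 100.0, 200.0)


class TestExtractSlices:
    def test_default_yields_25_flattened_profiles(self):
        cloud = ring_cloud(z_levels=np.arange(0.0, 100.0, 1.0))
        slices = extract_slices(cloud, 0.0, 99.0)
        assert len(slices.profiles) == 25
        for p in slices.profiles:
            assert len(p.points) >= 10

    def test_uniform_cylinder_slices_congruent(self):
        cloud = ring_cloud(radius=120.0, z_levels=np.arange(0.0, 100.0, 1.0))
        slices = extract_slices(cloud, 0.0, 99.0)
        for p in slices.profiles:
            assert np.allclose(np.hypot(*p.points.T), 120.0, atol=1e-9)

    def test_occluded_band_raises(self):
        z = np.concatenate([np.arange(0.0, 40.0, 1.0),
                            np.arange(44.0, 100.0, 1.0)])
        cloud = ring_cloud(z_levels=z)
        with pytest.raises(ValueError, match="occlusion"):
            extract_slices(cloud, 0.0, 99.0)

    def test_short_segment_raises(self):
        cloud = ring_cloud(z_levels=np.arange(0.0, 30.0, 1.0))
        with pytest.raises(ValueError):
            extract_slices(cloud, 0.0, 29.0)

    def test_profile_ordering_convention(self):
        cloud = ring_cloud(z_levels=np.arange(0.0, 100.0, 1.0))
        slices = extract_slices(cloud, 0.0, 99.0)
        p = slices.profiles[0].points
        c = p.mean(axis=0)
        ang = np.mod(np.arctan2(p[:, 1] - c[1], p[:, 0] - c[0]), 2 * np.pi)
        assert np.all(np.diff(ang) >= -1e-9)


class TestCentroidSize:
    def test_square_hand_computation(self):
        square = np.array([[0.0, 0], [2, 0], [2, 2], [0, 2]])
        assert centroid_size(square) == pytest.approx(np.sqrt(8.0), abs=1e-12)

    def test_coincident_points_zero(self):
        assert centroid_size(np.ones((5, 2))) == 0.0

    def test_single_point_raises(self):
        with pytest.raises(ValueError):
            centroid_size(np.array([[1.0, 2.0]]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(finite_coords(), finite_coords()),
                    min_size=2, max_size=40),
           st.floats(0.01, 100.0))
    def test_homogeneity(self, pts, k):
        X = np.array(pts)
        assert centroid_size(k * X) == pytest.approx(
            k * centroid_size(X), rel=1e-12, abs=1e-9)


class TestScaleSlices:
    def _slices(self, scale=1.0):
        cloud = ring_cloud(radius=140.0 * scale,
                           z_levels=np.arange(0.0, 100.0, 1.0) * scale)
        return extract_slices(cloud, 0.0, 99.0 * scale)

    def test_joint_size_equals_reference(self):
        scaled = scale_slices(self._slices())
        assert scaled.joint_centroid_size == pytest.approx(1.0, abs=1e-9)

    def test_scale_removed_between_participants(self):
        base = self._slices()
        tripled = align.TorsoSlices(
            profiles=tuple(
                align.SliceProfile(slice_index=p.slice_index,
                                   z_level=3.0 * p.z_level,
                                   points=3.0 * p.points)
                for p in base.profiles),
            joint_centroid_size=3.0 * base.joint_centroid_size)
        a = scale_slices(base)
        b = scale_slices(tripled)
        for pa, pb in zip(a.profiles, b.profiles):
            assert np.allclose(pa.points, pb.points, atol=1e-9)

    def test_idempotent(self):
        once = scale_slices(self._slices())
        twice = scale_slices(once)
        for pa, pb in zip(once.profiles, twice.profiles):
            assert np.allclose(pa.points, pb.points, atol=1e-12)

    def test_degenerate_configuration_raises(self):
        prof = tuple(SliceProfile(slice_index=i, z_level=float(i),
                                  points=np.ones((12, 2)))
                     for i in range(25))
        degenerate = align.TorsoSlices(profiles=prof, joint_centroid_size=0.0)
        with pytest.raises(ValueError):
            scale_slices(degenerate)


class TestFullPipelineInvariance:
    def test_rigid_motion_and_scale(self, clean_spec):
        """End-to-end: landmark detection through descriptors commutes with
        rotation about the vertical, translation and uniform scale."""
        cfg = pipeline.PipelineConfig(cohort=clean_spec)
        lat = synth.LatentShape(1.2, 0.6, 0.03, 1.0, 0.8)
        s = synth.generate_torso_cloud(lat, 1, clean_spec, seed=21)
        fv0, _, _ = pipeline.process_cloud(s.cloud, s.buttock_height,
                                           s.neck_height, cfg)
        rng = np.random.default_rng(7)
        for _ in range(5):
            pose = synth.PoseTransform(
                rotation_deg=rng.uniform(-180, 180),
                translation_mm=tuple(rng.uniform(-200, 200, 3)),
                scale=rng.uniform(0.95, 1.05))
            fv, _, _ = pipeline.process_cloud(
                pose.apply(s.cloud),
                pose.scale * s.buttock_height + pose.translation_mm[2],
                pose.scale * s.neck_height + pose.translation_mm[2], cfg)
            rel = np.linalg.norm(fv - fv0) / np.linalg.norm(fv0)
            assert rel <= 1e-3
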