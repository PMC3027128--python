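"""Phantom construction, point location, ray tracing and the printed anatomy constraints."""

import numpy as np
import pytest

from scatterdose.geometry import WORLD_EXIT, Sphere
from scatterdose.phantom import (
    DEFAULT_PHANTOM_CONFIG,
    axial_slice_mask,
    build_phantom,
    config_hash,
    load_phantom_config,
    mc_region_volume,
    save_phantom_config,
)
from scatterdose.synthetic_data import water_sphere_phantom

EXPECTED_REGIONS = {
    "left_breast", "right_breast", "left_lung", "right_lung",
    "heart", "chest_wall", "spleen", "body", "world_air",
}


class TestBuild:
    def test_region_set(self, phantom):
        assert {r.id for r in phantom.geometry.ordered_regions} == EXPECTED_REGIONS

    def test_bounding_dimensions_match_reported_phantom(self, phantom):
        lo, hi = np.asarray(phantom.bounding_box[0]), np.asarray(phantom.bounding_box[1])
        width, height, length = hi - lo
        assert width == pytest.approx(26.0, rel=0.05)
        assert height == pytest.approx(12.0, rel=0.05)
        assert length == pytest.approx(70.0, rel=0.05)

    def test_breast_volume_is_520cc(self, phantom):
        vol = mc_region_volume(phantom, "left_breast", n=600_000,
                               rng=np.random.default_rng(42))
        assert vol == pytest.approx(520.0, rel=0.02)

    def test_spleen_tally_is_150cc(self, phantom):
        assert phantom.tally("spleen").volume_cc == pytest.approx(150.0, rel=1e-6)

    def test_spleen_tally_5cm_inferior_to_field_edge(self, phantom):
        # field spans z in [5, 25]; the spleen tally centre sits at z = 0
        assert phantom.tally("spleen").center[2] == pytest.approx(5.0 - 5.0)

    def test_tally_volumes_in_quoted_range(self, phantom):
        for tid in ("left_breast", "right_breast", "heart_lad", "ipsilateral_lung"):
            assert 0.5 <= phantom.tally(tid).volume_cc <= 0.8

    def test_duplicate_priorities_rejected(self, materials):
        cfg = {"spleen": {"center": [6.5, 0.0, 0.0], "radius": 3.7}}
        ph = build_phantom(cfg, materials)
        regions = list(ph.geometry.regions)
        regions[0].priority = regions[1].priority
        from scatterdose.geometry import Geometry
        with pytest.raises(ValueError, match="priorities"):
            Geometry(regions)

    def test_config_round_trip_and_hash(self, tmp_path):
        path = tmp_path / "phantom.yaml"
        save_phantom_config(DEFAULT_PHANTOM_CONFIG, path)
        cfg = load_phantom_config(path)
        assert config_hash(cfg) == config_hash(DEFAULT_PHANTOM_CONFIG)
        assert build_phantom(cfg).tally("spleen").volume_cc == pytest.approx(150.0)


class TestPointLocation:
    def test_tally_centres_sit_in_their_organs(self, phantom):
        expected = {
            "left_breast": "left_breast",
            "right_breast": "right_breast",
            "heart_lad": "heart",
            "ipsilateral_lung": "left_lung",
            "spleen": "spleen",
        }
        for tid, region in expected.items():
            assert phantom.region_at(phantom.tally(tid).center) == region

    def test_outside_world_gives_exit_sentinel(self, phantom):
        assert phantom.region_at((500.0, 0.0, 0.0)) == WORLD_EXIT

    def test_every_interior_point_claimed_by_exactly_one_region(self, phantom):
        rng = np.random.default_rng(7)
        lo, hi = np.asarray(phantom.bounding_box[0]), np.asarray(phantom.bounding_box[1])
        pts = rng.uniform(lo, hi, size=(100_000, 3))
        idx = phantom.geometry.region_index(pts)
        assert np.all(idx >= 0)

    def test_agrees_with_brute_force_membership(self, phantom):
        rng = np.random.default_rng(11)
        lo, hi = np.asarray(phantom.bounding_box[0]), np.asarray(phantom.bounding_box[1])
        pts = rng.uniform(lo * 1.2, hi * 1.2, size=(20_000, 3))
        idx = phantom.geometry.region_index(pts)
        # independent oracle: evaluate every region's membership predicate
        regions = phantom.geometry.ordered_regions
        claims = np.stack([r.shape.contains(pts) for r in regions])
        expect = np.where(claims.any(axis=0), claims.argmax(axis=0), -1)
        np.testing.assert_array_equal(idx, expect)

    def test_tally_spheres_entirely_inside_their_regions(self, phantom):
        rng = np.random.default_rng(3)
        expected = {
            "left_breast": "left_breast",
            "right_breast": "right_breast",
            "heart_lad": "heart",
            "ipsilateral_lung": "left_lung",
            "spleen": "spleen",
        }
        for tid, region in expected.items():
            t = phantom.tally(tid)
            u = rng.normal(size=(500, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            surface = np.asarray(t.center) + 0.999 * t.radius * u
            idx = phantom.geometry.region_index(surface)
            names = [phantom.geometry.ordered_regions[i].id for i in idx]
            assert set(names) == {region}, f"{tid} pokes out of {region}"


class TestRayTracing:
    def test_distance_from_sphere_centre_is_radius(self):
        ph = water_sphere_phantom(radius_cm=10.0)
        d, nxt = ph.distance_to_boundary((0, 0, 0), (0, 0, 1.0))
        assert d == pytest.approx(10.0, abs=1e-9)
        assert nxt == "world"

    def test_tangent_ray_does_not_enter_sphere(self):
        s = Sphere((0.0, 0.0, 0.0), 2.0)
        ts = s.ray_ts(np.array([[-10.0, 2.0, 0.0]]), np.array([[1.0, 0.0, 0.0]]))
        assert np.all(np.isinf(ts))

    def test_non_unit_direction_rejected(self, phantom):
        with pytest.raises(ValueError, match="unit-norm"):
            phantom.distance_to_boundary((0, 0, 0), (0, 0, 2.0))

    def test_traversal_matches_dense_sampling(self, phantom):
        rng = np.random.default_rng(5)
        for _ in range(15):
            origin = rng.uniform((-20, -10, -40), (20, 10, 40))
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            # walk via boundary queries
            seq = [phantom.region_at(origin)]
            pos = np.asarray(origin, dtype=float)
            travelled = 0.0
            while travelled < 60.0 and seq[-1] != WORLD_EXIT:
                dist, nxt = phantom.distance_to_boundary(pos, d)
                if not np.isfinite(dist):
                    break
                pos = pos + (dist + 1e-6) * d
                travelled += dist
                seq.append(nxt)
            # dense-sampling oracle at 0.1 mm
            ts = np.arange(0.0, min(travelled, 60.0), 0.01)
            dense = [phantom.region_at(origin + t * d) for t in ts]
            dense_seq = [dense[0]] + [b for a, b in zip(dense, dense[1:]) if a != b]
            assert seq[: len(dense_seq)] == dense_seq

    def test_forward_backward_sequences_mirror(self, phantom):
        origin = np.array([-20.0, 2.0, 15.0])
        d = np.array([1.0, 0.0, 0.0])
        def walk(p0, direction, span):
            seq = [phantom.region_at(p0)]
            pos = np.asarray(p0, dtype=float)
            total = 0.0
            while total < span:
                dist, nxt = phantom.distance_to_boundary(pos, direction)
                if not np.isfinite(dist) or total + dist > span:
                    break
                pos = pos + (dist + 1e-6) * direction
                total += dist
                seq.append(nxt)
            return seq
        fwd = walk(origin, d, 40.0)
        back = walk(origin + 40.0 * d, -d, 40.0)
        assert fwd == back[::-1]


def test_axial_slice_mask_shape_and_export(phantom, tmp_path):
    from scatterdose.phantom import export_axial_slice

    xs, ys, mask = axial_slice_mask(phantom, z=15.0, resolution=1.0)
    assert mask.shape == (len(ys), len(xs))
    assert mask.min() >= 0  # inside the anatomy bbox everything is claimed
    out = tmp_path / "slice.csv"
    export_axial_slice(phantom, 15.0, out, resolution=1.0)
    assert out.exists() and out.stat().st_size > 100
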