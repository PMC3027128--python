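"""Technique configurations, brachytherapy plans, emitters and beam modifiers."""

import numpy as np
import pytest

from scatterdose.physics import default_materials
from scatterdose.protocols import (
    DEFAULT_TARGET_CENTER,
    IsotropicPointsEmitter,
    TangentialBeamEmitter,
    balloon_doses,
    dwell_dose_rate,
    make_dwell_plan,
    make_emitter,
    make_protocol,
    make_seed_plan,
    seeds_total_activity,
    sphere_volume,
    wedge_regions,
)
from scatterdose.physics import ir192_spectrum, monoenergetic


class TestMakeProtocol:
    @pytest.mark.parametrize(
        "name,gy,fx,field",
        [
            ("wedge", 50.0, 25, (16.0, 20.0)),
            ("imrt", 50.0, 25, (16.0, 20.0)),
            ("3dcrt_pbi", 38.5, 10, (8.0, 20.0)),
            ("hdr_catheter", 34.0, 10, None),
            ("pbsi", 90.0, 1, None),
        ],
    )
    def test_prescriptions_and_fields(self, name, gy, fx, field):
        p = make_protocol(name)
        assert p.prescription_gy == gy
        assert p.fractions == fx
        assert p.field_cm == field

    def test_wedge_modifier_is_30deg_steel(self):
        p = make_protocol("wedge")
        assert p.modifier == {"kind": "wedge", "angle_deg": 30.0, "material": "steel"}

    def test_imrt_field_in_field_weights(self):
        p = make_protocol("imrt")
        assert p.modifier["segment_weight"] == pytest.approx(0.2)
        assert p.modifier["open_weight"] == pytest.approx(0.8)

    def test_unknown_name_raises(self):
        with pytest.raises(ValueError, match="unknown protocol"):
            make_protocol("cyberknife")

    def test_overrides(self):
        p = make_protocol("wedge", prescription_gy=40.0)
        assert p.prescription_gy == 40.0


class TestPlanArithmetic:
    def test_sphere_volume_113cc(self):
        assert round(sphere_volume(3.0)) == 113

    def test_sphere_volume_edge_cases(self):
        assert sphere_volume(0.0) == 0.0
        assert sphere_volume(1.0) == pytest.approx(4.18879, abs=1e-5)
        with pytest.raises(ValueError):
            sphere_volume(-1.0)

    def test_total_activity_printed_value(self):
        assert seeds_total_activity(100, 2.7, 1.293) == pytest.approx(0.2088, abs=5e-5)

    def test_total_activity_linearity(self):
        assert seeds_total_activity(1, 2.7, 1.293) == pytest.approx(0.002088, abs=5e-7)
        assert seeds_total_activity(100, 1.293, 1.293) == pytest.approx(0.1)

    def test_total_activity_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            seeds_total_activity(0, 2.7, 1.293)


class TestSeedPlan:
    def test_all_seeds_inside_target(self, rng):
        plan = make_seed_plan(3.0, 100, rng)
        r = np.linalg.norm(plan.positions - np.asarray(DEFAULT_TARGET_CENTER), axis=1)
        assert np.all(r <= 3.0)
        assert len(plan.positions) == 100

    def test_single_seed_at_centre(self, rng):
        plan = make_seed_plan(3.0, 1, rng)
        np.testing.assert_allclose(plan.positions[0], DEFAULT_TARGET_CENTER)

    def test_nearest_neighbour_spacing_near_lattice_pitch(self, rng):
        # (113 cc / 100)^(1/3) ~ 1.04 cm pitch
        plan = make_seed_plan(3.0, 100, rng)
        p = plan.positions
        d = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        assert np.median(nn) == pytest.approx(1.04, abs=0.3)

    def test_plan_activity(self, rng):
        plan = make_seed_plan(3.0, 100, rng)
        assert plan.total_activity_ci == pytest.approx(0.2088, abs=5e-5)
        assert plan.half_life_days == pytest.approx(16.99)


class TestDwellPlan:
    def test_positions_on_1cm_grid_inside_target(self):
        plan = make_dwell_plan()
        rel = plan.positions - np.asarray(DEFAULT_TARGET_CENTER)
        np.testing.assert_allclose(rel, np.round(rel), atol=1e-9)
        assert np.all(np.linalg.norm(rel, axis=1) <= 3.0 + 1e-9)
        assert len(plan.positions) == 123  # lattice points in a radius-3 ball

    def test_doubling_activity_halves_time(self):
        t1 = make_dwell_plan(source_activity_ci=10.0).total_time_s
        t2 = make_dwell_plan(source_activity_ci=20.0).total_time_s
        assert t2 == pytest.approx(t1 / 2, rel=1e-9)

    def test_total_time_matches_independent_quadrature(self):
        plan = make_dwell_plan()
        # independent oracle: Monte Carlo surface integration of the same
        # point-source model
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(120_000, 3))
        pts = np.asarray(DEFAULT_TARGET_CENTER) + 3.0 * pts / np.linalg.norm(
            pts, axis=1, keepdims=True
        )
        rate = np.median(dwell_dose_rate(plan.positions, pts, 10.0))
        t_fx_h = (34.0 / 10) * len(plan.positions) / rate
        assert plan.total_time_s == pytest.approx(t_fx_h * 3600 * 10, rel=0.01)

    def test_realistic_fraction_duration(self):
        # a 10 Ci source treating 3.4 Gy/fraction should dwell minutes, not hours
        plan = make_dwell_plan()
        assert 60 < plan.total_time_s / plan.fractions < 1800


class TestBalloonDoses:
    def test_printed_worked_example(self):
        catheter = {
            "heart": (3.6, "Gy"),
            "spleen": (1171.0, "mSv"),
            "ipsilateral_lung": (2471.0, "mSv"),
        }
        out = balloon_doses(catheter)
        assert out["heart"] == (5.2, "Gy")
        assert out["spleen"] == (1686, "mSv")
        assert out["ipsilateral_lung"] == (3558, "mSv")

    def test_zero_maps_to_zero(self):
        assert balloon_doses({"spleen": (0.0, "mSv")})["spleen"] == (0, "mSv")


class TestEmitters:
    def test_beam_rays_pass_through_aperture(self, rng):
        p = make_protocol("wedge")
        em = TangentialBeamEmitter(p.beam, monoenergetic(2.0))
        pos, dirs, e, w = em.sample(5_000, rng)
        iso = np.asarray(p.beam.isocenter)
        lateral, _, e_u, e_v = p.beam.axes
        # intersect each ray with the isocentre plane of its beam
        for src in p.beam.sources:
            from_src = np.all(np.isclose(pos, src), axis=1)
            if not from_src.any():
                continue
            axis = (iso - src) / np.linalg.norm(iso - src)
            t = ((iso - pos[from_src]) @ axis) / (dirs[from_src] @ axis)
            hit = pos[from_src] + t[:, None] * dirs[from_src]
            u = (hit - iso) @ e_u
            v = (hit - iso) @ e_v
            (u_lo, u_hi), (v_lo, v_hi) = p.beam.aperture_u, p.beam.aperture_v
            assert np.all((u > u_lo - 1e-6) & (u < u_hi + 1e-6))
            assert np.all((v > v_lo - 1e-6) & (v < v_hi + 1e-6))

    def test_effective_aperture_is_half_beam(self):
        beam = make_protocol("wedge").beam
        (u_lo, u_hi) = beam.aperture_u
        assert u_hi - u_lo <= beam.field_cm[0] / 2.0 + 1e-9

    def test_isotropic_emitter_covers_4pi(self, rng):
        em = IsotropicPointsEmitter(np.zeros((1, 3)), ir192_spectrum())
        _, dirs, _, _ = em.sample(50_000, rng)
        np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0, rtol=1e-9)
        assert np.all(np.abs(dirs.mean(axis=0)) < 0.02)

    def test_field_in_field_uses_two_segments(self, rng):
        em, extra = make_emitter(make_protocol("imrt"))
        assert len(em.segments) == 2
        assert extra == []

    def test_pbsi_emitter_samples_seed_positions(self, rng):
        em, extra = make_emitter(make_protocol("pbsi"), plan_rng=rng)
        assert extra == []
        pos, _, e, _ = em.sample(2_000, rng)
        r = np.linalg.norm(pos - np.asarray(DEFAULT_TARGET_CENTER), axis=1)
        assert np.all(r <= 3.0)
        assert e.mean() < 0.05  # Pd-103 x-rays


class TestWedge:
    def test_wedge_regions_are_steel_prisms(self):
        beam = make_protocol("wedge").beam
        regions = wedge_regions(beam, default_materials())
        assert [r.id for r in regions] == ["wedge_lateral", "wedge_medial"]
        assert all(r.material.name == "steel" for r in regions)
        assert all(r.material.density == pytest.approx(7.81) for r in regions)

    def test_thickness_grows_across_gradient(self):
        # chord length of beam-parallel rays through the wedge grows with u
        beam = make_protocol("wedge").beam
        region = wedge_regions(beam, default_materials())[0]
        iso = np.asarray(beam.isocenter)
        src = beam.sources[0]
        axis = (iso - src) / np.linalg.norm(iso - src)
        _, _, e_u, _ = beam.axes
        (u_lo, u_hi) = beam.aperture_u
        chords = []
        for u in np.linspace(u_lo + 0.3, u_hi - 0.3, 8):
            target = iso + u * e_u
            d = (target - src) / np.linalg.norm(target - src)
            ts = region.shape.ray_ts(src.reshape(1, 3), d.reshape(1, 3))[0]
            ts = ts[np.isfinite(ts)]
            chords.append(ts.max() - ts.min() if len(ts) >= 2 else 0.0)
        assert all(b >= a - 1e-9 for a, b in zip(chords, chords[1:]))
        assert chords[-1] > chords[0] > 0
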