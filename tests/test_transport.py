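"""Random-walk engine: conservation, attenuation, batch statistics, determinism."""

import numpy as np
import pytest

from scatterdose.geometry import Box, Geometry, Region
from scatterdose.physics import default_materials, monoenergetic
from scatterdose.protocols import IsotropicPointsEmitter
from scatterdose.synthetic_data import (
    absorber_slab_phantom,
    inverse_square_phantom,
    water_sphere_phantom,
)
from scatterdose.transport import (
    PhotonState,
    TransportSettings,
    relative_error,
    run_simulation,
    track,
)


class _PencilEmitter:
    def __init__(self, origin, direction, energy):
        self.origin = np.asarray(origin, dtype=float)
        self.direction = np.asarray(direction, dtype=float)
        self.energy = energy

    def sample(self, n, rng):
        return (
            np.tile(self.origin, (n, 1)),
            np.tile(self.direction, (n, 1)),
            np.full(n, self.energy),
            np.ones(n),
        )


class TestRelativeError:
    def test_constant_batches_give_zero(self):
        assert relative_error([5.0, 5.0, 5.0, 5.0]) == 0.0

    def test_hand_computed_example(self):
        # s = 1, S_xbar = 1/sqrt(3), mean = 10 -> R ~ 0.0577
        assert relative_error([9.0, 10.0, 11.0]) == pytest.approx(1 / np.sqrt(3) / 10)

    def test_single_batch_raises(self):
        with pytest.raises(ValueError):
            relative_error([1.0])

    def test_zero_mean_gives_inf(self):
        assert relative_error([0.0, 0.0]) == float("inf")

    def test_reliability_flag_threshold(self):
        from scatterdose.transport import TallyResult
        steady = TallyResult("t", np.array([1.0, 1.001, 0.999, 1.0]), 4)
        noisy = TallyResult("t", np.array([0.1, 2.0, 0.5, 3.0]), 4)
        assert steady.reliable and steady.relative_error < 0.05
        assert not noisy.reliable and noisy.relative_error >= 0.05


class TestPhotonState:
    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError, match="unit-norm"):
            PhotonState((0, 0, 0), (0, 0, 2.0), 1.0)

    def test_invalid_energy_weight_rejected(self):
        with pytest.raises(ValueError):
            PhotonState((0, 0, 0), (0, 0, 1.0), -1.0)
        with pytest.raises(ValueError):
            PhotonState((0, 0, 0), (0, 0, 1.0), 1.0, weight=0.0)


class TestTrack:
    def test_vacuum_world_full_escape(self, rng):
        mats = default_materials()
        geom = Geometry([Region("world", Box((-10,) * 3, (10,) * 3), mats["vacuum"], 0)])
        out = track(geom, PhotonState((0, 0, 0), (1.0, 0, 0), 2.0), rng)
        assert out.deposits == []
        assert out.deposited_total == 0.0
        assert out.escaped == pytest.approx(2.0)

    def test_energy_ledger_balances_exactly(self, rng):
        ph = water_sphere_phantom()
        for energy in (0.03, 0.367, 2.0, 5.5):
            out = track(ph, PhotonState((0, 0, 0), (0, 0, 1.0), energy), rng)
            assert out.deposited_total + out.escaped == pytest.approx(energy, rel=1e-9)


class TestRunSimulation:
    def test_deterministic_given_seed(self):
        ph = water_sphere_phantom()
        em = IsotropicPointsEmitter(np.zeros((1, 3)), monoenergetic(1.0))
        a = run_simulation(ph.geometry, em, ph.tallies, 20_000, 4, seed=9)
        b = run_simulation(ph.geometry, em, ph.tallies, 20_000, 4, seed=9)
        np.testing.assert_array_equal(
            a["center"].batch_values, b["center"].batch_values
        )

    def test_validation_errors(self):
        ph = water_sphere_phantom()
        em = IsotropicPointsEmitter(np.zeros((1, 3)), monoenergetic(1.0))
        with pytest.raises(ValueError):
            run_simulation(ph.geometry, em, ph.tallies, 0, 2, seed=1)
        with pytest.raises(ValueError):
            run_simulation(ph.geometry, em, ph.tallies, 1000, 1, seed=1)
        with pytest.raises(ValueError):
            run_simulation(ph.geometry, em, ph.tallies, 1001, 4, seed=1)

    def test_pure_absorber_transmission(self):
        # closed-form oracle: transmitted fraction = exp(-mu t) = 1/e
        ph = absorber_slab_phantom(mu_per_cm=0.5, thickness_cm=2.0)
        em = _PencilEmitter((-5, 0, 0), (1.0, 0, 0), 1.0)
        res = run_simulation(ph.geometry, em, [], 100_000, 10, seed=3)
        p = np.exp(-1.0)
        sigma = np.sqrt(p * (1 - p) / res.n_histories)
        assert res.escaped_energy / res.emitted_energy == pytest.approx(p, abs=3 * sigma)

    def test_per_history_energy_conservation(self):
        ph = water_sphere_phantom()
        em = IsotropicPointsEmitter(np.zeros((1, 3)), monoenergetic(5.0))
        res = run_simulation(
            ph.geometry, em, ph.tallies, 2_000, 2, seed=4, track_energy=True
        )
        total = res.per_history_deposited + res.per_history_escaped
        np.testing.assert_allclose(total, res.per_history_emitted, rtol=1e-9)

    def test_inverse_square_dose_ratio(self):
        ph = inverse_square_phantom()
        em = IsotropicPointsEmitter(np.zeros((1, 3)), monoenergetic(1.0))
        res = run_simulation(ph.geometry, em, ph.tallies, 600_000, 10, seed=5)
        mu = ph.config["mu_per_cm"]
        # quadrature oracle: expected collisions ~ integral of attenuated
        # inverse-square fluence over each tally sphere
        def expected(center_r):
            rng_ = np.random.default_rng(0)
            t = ph.tally("near") if center_r == 5 else ph.tally("far")
            pts = rng_.normal(size=(200_000, 3))
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            radii = t.radius * rng_.random(200_000) ** (1 / 3)
            pts = np.asarray(t.center) + pts * radii[:, None]
            s = np.linalg.norm(pts, axis=1)
            return np.mean(np.exp(-mu * s) / (4 * np.pi * s**2)) * t.volume_cc * mu
        ratio = res["near"].mean / res["far"].mean
        expected_ratio = expected(5) / expected(10)
        r_comb = res["near"].relative_error + res["far"].relative_error
        assert ratio == pytest.approx(expected_ratio, rel=3 * r_comb)

    def test_relative_error_scales_inverse_sqrt(self):
        ph = inverse_square_phantom()
        em = IsotropicPointsEmitter(np.zeros((1, 3)), monoenergetic(1.0))
        r1 = run_simulation(ph.geometry, em, ph.tallies, 100_000, 10, seed=6)
        r4 = run_simulation(ph.geometry, em, ph.tallies, 400_000, 10, seed=6)
        ratio = r4["near"].relative_error / r1["near"].relative_error
        assert 0.3 < ratio < 0.75  # ~0.5 expected

    def test_russian_roulette_noop_at_unit_weight(self):
        # roulette only acts below its weight threshold; unit-weight photons
        # must give bit-identical results with the option on or off
        ph = water_sphere_phantom()
        em = IsotropicPointsEmitter(np.zeros((1, 3)), monoenergetic(0.5))
        on = run_simulation(ph.geometry, em, ph.tallies, 20_000, 4, seed=8,
                            settings=TransportSettings(russian_roulette=True))
        off = run_simulation(ph.geometry, em, ph.tallies, 20_000, 4, seed=8)
        np.testing.assert_array_equal(on["center"].batch_values,
                                      off["center"].batch_values)
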