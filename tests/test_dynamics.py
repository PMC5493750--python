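import math

import numpy as np
import pytest

from lanesim import (
    ModelParams,
    ParticleState,
    drive_torque,
    euler_step,
    init_random,
    neighbor_pairs,
    pair_torque,
    simulate,
)
from lanesim.errors import DegeneratePairError
from lanesim.state import wrap_angle

from conftest import scalar_reference_step


class TestPairTorque:
    def test_zero_when_pointing_away(self, small_params):
        # particle i already points along r_i - r_j: angular equilibrium
        r_i, r_j = np.array([10.0, 10.0]), np.array([9.0, 10.0])
        assert pair_torque(0.0, r_i, r_j, 1.0, 1.0, small_params) == 0.0

    def test_zero_beyond_range(self, small_params):
        r_i, r_j = np.array([10.0, 10.0]), np.array([7.0, 10.0])
        for theta in (0.0, 1.0, 2.5):
            assert pair_torque(theta, r_i, r_j, 1.0, 1.0, small_params) == 0.0

    def test_half_range_perpendicular_value(self):
        # B=5, a_i=a_j=1, r=1 (half range), theta - phi = pi/2:
        # kernel 5*(1-1/2) = 2.5, torque -2.5*sin(pi/2) = -2.5
        p = ModelParams(B=5.0, Lx=40.0, Ly=20.0)
        r_i, r_j = np.array([10.0, 10.0]), np.array([9.0, 10.0])
        got = pair_torque(np.pi / 2, r_i, r_j, 1.0, 1.0, p)
        assert got == pytest.approx(-2.5)

    def test_matches_energy_derivative(self, small_params):
        # oracle: T = -dU/dtheta for U = -B(r) cos(theta - phi),
        # by central differences of the energy
        rng = np.random.default_rng(0)
        for _ in range(50):
            r_i = rng.uniform(5, 15, 2)
            r_j = r_i + rng.uniform(-1.5, 1.5, 2)
            theta = rng.uniform(-4, 4)
            d = r_i - r_j
            r = np.hypot(*d)
            if r < 1e-3:
                continue

            def energy(th):
                rng_ij = 2.0
                if r >= rng_ij:
                    return 0.0
                kern = small_params.B * (1 - r / rng_ij)
                return -kern * math.cos(th - math.atan2(d[1], d[0]))

            h = 1e-6
            expected = -(energy(theta + h) - energy(theta - h)) / (2 * h)
            got = pair_torque(theta, r_i, r_j, 1.0, 1.0, small_params)
            assert got == pytest.approx(expected, abs=1e-8)

    def test_restoring_toward_away_direction(self, small_params):
        # small deviation from pointing away decays back: torque sign
        # opposes the deviation, magnitude bounded by the kernel
        r_i, r_j = np.array([10.0, 10.0]), np.array([9.0, 10.0])
        for dev in (0.3, -0.3, 2.0, -2.0):
            t = pair_torque(dev, r_i, r_j, 1.0, 1.0, small_params)
            assert np.sign(t) == -np.sign(dev)
            assert abs(t) <= small_params.B * (1 - 1.0 / 2.0) + 1e-12

    def test_coincident_pair_raises(self, small_params):
        r = np.array([10.0, 10.0])
        with pytest.raises(DegeneratePairError):
            pair_torque(0.3, r, r.copy(), 1.0, 1.0, small_params)


class TestDriveTorque:
    def test_zero_at_preferred_direction(self, small_params):
        assert drive_torque(0.0, 1, small_params) == 0.0
        assert drive_torque(math.pi, -1, small_params) == pytest.approx(0.0)

    def test_right_mover_perpendicular(self):
        p = ModelParams(B=2.0, H=1.0, Lx=40.0, Ly=20.0)
        assert drive_torque(math.pi / 2, 1, p) == pytest.approx(-1.0)

    def test_restoring_sign(self, small_params):
        for species, theta0 in ((1, 0.0), (-1, math.pi)):
            for dev in (0.5, -0.5, 1.2):
                t = drive_torque(theta0 + dev, species, small_params)
                assert np.sign(t) == -np.sign(dev)


class TestNeighborPairs:
    def test_far_apart_empty(self, small_params):
        s = ParticleState(
            np.array([1.0, 6.0]), np.array([5.0, 5.0]), np.zeros(2),
            np.array([1, -1], dtype=np.int8), np.array([1.0, 1.4]),
        )
        assert len(neighbor_pairs(s, small_params)) == 0

    def test_periodic_wraparound_pair(self, small_params):
        s = ParticleState(
            np.array([0.1, small_params.Lx - 0.1]), np.array([5.0, 5.0]),
            np.zeros(2), np.array([1, -1], dtype=np.int8),
            np.array([1.0, 1.4]),
        )
        pairs = neighbor_pairs(s, small_params)
        assert pairs.tolist() == [[0, 1]]

    @pytest.mark.parametrize("seed", range(8))
    def test_sweep_and_prune_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 300)) * 2
        ly = rng.uniform(8.0, 30.0)
        p = ModelParams(B=2.0, Lx=2 * ly, Ly=ly)
        s = init_random(n, p, seed=seed + 1000)
        sap = neighbor_pairs(s, p, method="sap")
        brute = neighbor_pairs(s, p, method="brute")
        assert np.array_equal(sap, brute)


class TestEulerStep:
    def test_single_right_mover_ballistic(self):
        p = ModelParams(B=2.0, Lx=40.0, Ly=20.0)
        s = ParticleState(
            np.array([5.0, 30.0]), np.array([5.0, 15.0]),
            np.array([0.0, math.pi]), np.array([1, -1], dtype=np.int8),
            np.ones(2),
        )
        out = euler_step(s, p)
        assert out.x[0] == pytest.approx(5.0 + p.v0 * p.dt)
        assert out.y[0] == pytest.approx(5.0)
        assert out.theta[0] == 0.0
        # the far-away left mover advances along its own orientation
        assert out.x[1] == pytest.approx(30.0 - p.v0 * p.dt)

    def test_matches_scalar_reference(self, small_params):
        s = init_random(24, small_params, seed=5)
        got = euler_step(s, small_params)
        want = scalar_reference_step(s, small_params)
        np.testing.assert_allclose(got.x, want.x, atol=1e-12)
        np.testing.assert_allclose(got.y, want.y, atol=1e-12)
        np.testing.assert_allclose(got.theta, want.theta, atol=1e-12)

    def test_multi_step_matches_scalar_reference(self, small_params):
        s = init_random(16, small_params, seed=6)
        got = simulate(s, small_params, 25, sample_every=25).state
        want = s
        for _ in range(25):
            want = scalar_reference_step(want, small_params)
        np.testing.assert_allclose(got.theta, want.theta, atol=1e-9)
        np.testing.assert_allclose(got.x, want.x, atol=1e-9)

    def test_degenerate_pair_raises_with_indices(self, small_params):
        s = ParticleState(
            np.array([5.0, 5.0, 9.0, 12.0]), np.array([5.0, 5.0, 5.0, 5.0]),
            np.zeros(4), np.array([1, -1, 1, -1], dtype=np.int8), np.ones(4),
        )
        with pytest.raises(DegeneratePairError) as exc:
            euler_step(s, small_params)
        assert exc.value.indices == (0, 1)


class TestTrajectoryInvariants:
    def test_species_conserved_and_positions_in_box(self, small_params):
        s = init_random(64, small_params, seed=2)
        res = simulate(s, small_params, 500, sample_every=100)
        out = res.state
        assert np.array_equal(np.sort(out.species), np.sort(s.species))
        assert ((out.x >= 0) & (out.x < small_params.Lx)).all()
        assert ((out.y >= 0) & (out.y < small_params.Ly)).all()

    def test_speed_exactly_v0(self, small_params):
        # positions advance by exactly v0*dt along the orientation:
        # torques act on angles only
        s = init_random(32, small_params, seed=3)
        out = euler_step(s, small_params)
        dx = out.x - s.x
        dx -= small_params.Lx * np.round(dx / small_params.Lx)
        dy = out.y - s.y
        dy -= small_params.Ly * np.round(dy / small_params.Ly)
        np.testing.assert_allclose(
            np.hypot(dx, dy), small_params.v0 * small_params.dt, rtol=1e-12
        )

    def test_mirror_symmetry_commutes_with_dynamics(self, small_params):
        # relabelling species with theta -> pi - theta, x -> -x is a
        # symmetry of the model: transforming then evolving equals
        # evolving then transforming
        def transform(st):
            out = st.copy()
            out.x = (small_params.Lx - st.x) % small_params.Lx
            out.theta = math.pi - st.theta
            out.species = -st.species
            return out

        s = init_random(40, small_params, seed=8)
        a = transform(simulate(s, small_params, 100, sample_every=100).state)
        b = simulate(transform(s), small_params, 100, sample_every=100).state
        np.testing.assert_allclose(
            np.cos(a.theta), np.cos(b.theta), atol=1e-9
        )
        np.testing.assert_allclose(a.x, b.x, atol=1e-9)
        np.testing.assert_allclose(a.y, b.y, atol=1e-9)

    def test_no_repulsion_converges_to_preferred_directions(self):
        p = ModelParams(B=0.0, Lx=40.0, Ly=20.0)
        s = init_random(32, p, seed=4)
        dev = np.abs(wrap_angle(s.theta - s.preferred_angle))
        state = s
        for _ in range(5):
            state = simulate(state, p, 200, sample_every=200).state
            new_dev = np.abs(wrap_angle(state.theta - state.preferred_angle))
            # monotone decay everywhere (away from the unstable point)
            mask = dev > 1e-12
            assert (new_dev[mask] <= dev[mask] + 1e-12).all()
            dev = new_dev
        assert dev.max() < 0.05
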