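"""MD engine: pair potentials, forces, neighbor-search equivalence,
velocity-Verlet integration and its conservation properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from janusmpc.config import RC_FACTOR
from janusmpc.driver import _spawn_streams, make_fixture_scenario
from janusmpc.geometry import build_motor
from janusmpc.md import (OverlapError, PairPotentialTable,
                         SystemState, compute_forces,
                         compute_forces_bruteforce, init_force_cache,
                         make_state, md_interval, spring_force,
                         velocity_verlet_step, wca_potential_and_force)


# ----------------------------------------------------------------------
# WCA potential
# ----------------------------------------------------------------------
class TestWca:
    def test_zero_at_cutoff_minimum(self):
        v, f = wca_potential_and_force(RC_FACTOR * 0.3, 5.0, 0.3)
        assert v == 0.0 and f == 0.0

    def test_value_at_sigma(self):
        v, f = wca_potential_and_force(0.3, 5.0, 0.3)
        assert v == pytest.approx(4 * 5.0 * 0.25, rel=1e-12)
        assert f == pytest.approx(24 * 5.0 * (2 - 1) / 0.3, rel=1e-12)

    def test_zero_beyond_cutoff(self):
        v, f = wca_potential_and_force(0.6, 5.0, 0.3)
        assert v == 0.0 and f == 0.0

    def test_continuous_at_cutoff(self):
        rc = RC_FACTOR * 0.3
        v, f = wca_potential_and_force(rc * (1 - 1e-8), 5.0, 0.3)
        assert abs(v) < 1e-10 and abs(f) < 1e-4

    def test_overlap_error(self):
        with pytest.raises(OverlapError):
            wca_potential_and_force(0.0, 1.0, 0.3)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(r=st.floats(0.05, 1.0), eps=st.floats(0.01, 10.0))
    def test_purely_repulsive(self, r, eps):
        v, f = wca_potential_and_force(r, eps, 0.3)
        assert v >= 0.0 and f >= 0.0


# ----------------------------------------------------------------------
# springs
# ----------------------------------------------------------------------
class TestSpring:
    def test_equilibrium_zero_force(self):
        fi, fj = spring_force([0, 0, 0], [0, 0, 1.0], 60.0, 1.0)
        np.testing.assert_allclose(fi, 0.0)
        np.testing.assert_allclose(fj, 0.0)

    def test_magnitude_and_direction(self):
        fi, fj = spring_force([0, 0, 0], [0, 0, 1.1], 60.0, 1.0)
        assert np.linalg.norm(fi) == pytest.approx(6.0, rel=1e-12)
        assert fi[2] > 0  # stretched spring pulls i toward j
        np.testing.assert_allclose(fi + fj, 0.0, atol=0)

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(OverlapError):
            spring_force([1, 1, 1], [1, 1, 1], 60.0, 0.5)


# ----------------------------------------------------------------------
# force assembly
# ----------------------------------------------------------------------
def _bare_state(spos, sspecies, cfg=None, motor=None):
    cfg = cfg or make_fixture_scenario("micro", phi=0.5)
    motor = motor or build_motor(cfg)
    center = cfg.box / 2
    n = len(spos)
    return SystemState(
        mpos=motor.positions + center, mvel=np.zeros_like(motor.positions),
        mmass=motor.masses.copy(), mspecies=motor.species.copy(),
        msigma=motor.sigmas.copy(), spring_i=motor.spring_i,
        spring_j=motor.spring_j, spring_r0=motor.spring_r0,
        spos=np.asarray(spos, dtype=float),
        svel=np.zeros((n, 3)),
        sspecies=np.asarray(sspecies, dtype=np.int8),
        ms=cfg.ms, ks=cfg.ks, box=cfg.box.astype(float))


class TestComputeForces:
    def test_far_solvent_feels_nothing(self):
        st_ = _bare_state([[0.5, 0.5, 0.5]], [0])
        f = compute_forces(st_, PairPotentialTable.from_config(
            make_fixture_scenario("micro", phi=0.5)))
        np.testing.assert_allclose(f.full_solvent_forces(1), 0.0)
        # springs are at rest, so motor forces vanish too
        np.testing.assert_allclose(f.f_motor, 0.0, atol=1e-10)
        assert f.potential == pytest.approx(0.0, abs=1e-12)

    def test_single_pair_analytic_force(self):
        """One fuel particle at r = sigma1 from one catalytic bead."""
        cfg = make_fixture_scenario("micro", phi=0.0)
        motor = build_motor(cfg)
        table = PairPotentialTable.from_config(cfg)
        # place the solvent particle radially outward from an E1 bead
        st_ = _bare_state([[0.0, 0.0, 0.0]], [0], cfg, motor)
        bead = np.flatnonzero(st_.mspecies == 2)[0]
        bp = st_.mpos[bead]
        direction = bp - cfg.box / 2
        direction /= np.linalg.norm(direction)
        st_.spos[0] = bp + direction * cfg.sigma1
        f = compute_forces(st_, table)
        expected = 24 * 0.2 * (2 - 1) / cfg.sigma1
        got = f.full_solvent_forces(1)[0]
        assert np.linalg.norm(got) == pytest.approx(expected, rel=1e-6)
        np.testing.assert_allclose(got + f.f_motor[bead], 0.0, atol=1e-12)

    def test_net_force_vanishes_on_random_state(self):
        cfg = make_fixture_scenario("micro", phi=0.7, seed=5)
        motor = build_motor(cfg)
        rng = np.random.default_rng(5)
        spos = rng.uniform(0, 10.0, size=(400, 3))
        st_ = _bare_state(spos, rng.integers(0, 3, 400), cfg, motor)
        f = compute_forces(st_, PairPotentialTable.from_config(cfg))
        total = f.full_solvent_forces(400).sum(axis=0) + f.f_motor.sum(axis=0)
        scale = np.abs(f.f_motor).sum() + 1.0
        assert np.all(np.abs(total) < 1e-9 * scale)

    def test_cell_list_matches_bruteforce(self):
        """Oracle equivalence of the grid search on a <= 500-particle state."""
        cfg = make_fixture_scenario("micro", phi=0.6, seed=9)
        motor = build_motor(cfg)
        rng = np.random.default_rng(9)
        # concentrate particles near the motor so many pairs interact
        n = 500
        spos = cfg.box / 2 + rng.normal(0, 2.5, size=(n, 3))
        spos = np.mod(spos, cfg.box)
        st_ = _bare_state(spos, rng.integers(0, 3, n), cfg, motor)
        table = PairPotentialTable.from_config(cfg)
        fast = compute_forces(st_, table)
        slow = compute_forces_bruteforce(st_, table)
        np.testing.assert_allclose(fast.full_solvent_forces(n),
                                   slow.full_solvent_forces(n),
                                   rtol=1e-12, atol=1e-12)
        np.testing.assert_allclose(fast.f_motor, slow.f_motor,
                                   rtol=1e-12, atol=1e-12)
        assert fast.potential == pytest.approx(slow.potential, rel=1e-12)
        full = np.zeros(n, dtype=np.uint8)
        full[fast.candidates] = fast.zone1
        np.testing.assert_array_equal(full, slow.zone1)

    def test_fused_interval_matches_single_steps(self):
        """The fused multi-substep kernel reproduces the reference
        one-substep-at-a-time integration of the same equations."""
        cfg = make_fixture_scenario("micro", phi=0.5, seed=3,
                                    md_inner_substeps=1)
        motor = build_motor(cfg)
        rngs = _spawn_streams(3)
        table = PairPotentialTable.from_config(cfg)
        s1 = make_state(cfg, motor, rngs["init"])
        import copy
        s2 = copy.deepcopy(s1)
        cache = init_force_cache(s1, table)
        for _ in range(20):
            md_interval(s1, table, cache, cfg.t_md, 1)
        forces = compute_forces(s2, table)
        for _ in range(20):
            forces = velocity_verlet_step(s2, table, forces, cfg.t_md)
        np.testing.assert_allclose(s1.spos, s2.spos, rtol=0, atol=1e-11)
        np.testing.assert_allclose(s1.mpos, s2.mpos, rtol=0, atol=1e-11)
        np.testing.assert_allclose(s1.svel, s2.svel, rtol=0, atol=1e-9)


# ----------------------------------------------------------------------
# velocity Verlet
# ----------------------------------------------------------------------
class TestVelocityVerlet:
    def test_free_particle_drifts(self):
        cfg = make_fixture_scenario("micro", phi=0.0)
        motor = build_motor(cfg)
        st_ = _bare_state([[1.0, 1.0, 1.0]], [0], cfg, motor)
        st_.svel[0] = [0.3, -0.2, 0.1]
        table = PairPotentialTable.from_config(cfg)
        f = compute_forces(st_, table)
        velocity_verlet_step(st_, table, f, 0.005)
        np.testing.assert_allclose(
            st_.spos[0], [1.0015, 0.999, 1.0005], rtol=1e-12)
        np.testing.assert_allclose(st_.svel[0], [0.3, -0.2, 0.1])

    def test_two_mass_spring_matches_discrete_closed_form(self):
        """The integrator's trajectory equals the exact solution of the
        velocity-Verlet difference equations for a harmonic pair, whose
        discrete frequency is 2/dt * asin(omega dt / 2)."""
        ks, m, r0, dt = 60.0, 0.44, 1.0, 0.005
        x0 = 0.08  # initial stretch
        st_ = SystemState(
            mpos=np.array([[5.0, 5.0, 5.0 - (r0 + x0) / 2],
                           [5.0, 5.0, 5.0 + (r0 + x0) / 2]]),
            mvel=np.zeros((2, 3)),
            mmass=np.array([m, m]), mspecies=np.array([1, 2], dtype=np.int8),
            msigma=np.array([0.3, 0.3]),
            spring_i=np.array([0]), spring_j=np.array([1]),
            spring_r0=np.array([r0]),
            spos=np.zeros((0, 3)), svel=np.zeros((0, 3)),
            sspecies=np.zeros(0, dtype=np.int8),
            ms=1.0, ks=ks, box=np.array([10.0, 10.0, 10.0]))
        table = PairPotentialTable.from_config(make_fixture_scenario("micro"))
        f = compute_forces(st_, table)
        mu = m / 2.0
        omega = math.sqrt(ks / mu)
        omega_d = 2.0 / dt * math.asin(omega * dt / 2.0)
        energies, stretches = [], []
        for n in range(400):
            stretch = st_.mpos[1, 2] - st_.mpos[0, 2] - r0
            stretches.append(stretch)
            energies.append(st_.kinetic_energy() + f.potential)
            f = velocity_verlet_step(st_, table, f, dt)
        # discrete-time trajectory: x_n = x0 cos(omega_d t_n)
        t = np.arange(400) * dt
        np.testing.assert_allclose(stretches, x0 * np.cos(omega_d * t),
                                   atol=1e-9)
        # energy series from the same closed form: VV velocities are the
        # central differences of the discrete positions
        e = np.array(energies)
        x_n = x0 * np.cos(omega_d * t)
        v_n = (x0 * np.cos(omega_d * (t + dt))
               - x0 * np.cos(omega_d * (t - dt))) / (2 * dt)
        e_oracle = 0.5 * ks * x_n ** 2 + 0.5 * mu * v_n ** 2
        np.testing.assert_allclose(e, e_oracle, atol=1e-6)

    def test_momentum_exact_conservation(self):
        cfg = make_fixture_scenario("micro", phi=0.5, seed=4)
        motor = build_motor(cfg)
        rngs = _spawn_streams(4)
        st_ = make_state(cfg, motor, rngs["init"])
        table = PairPotentialTable.from_config(cfg)
        p0 = st_.total_momentum()
        f = compute_forces(st_, table)
        for _ in range(50):
            f = velocity_verlet_step(st_, table, f, cfg.t_md)
        p1 = st_.total_momentum()
        scale = st_.ms * np.abs(st_.svel).sum()
        assert np.all(np.abs(p1 - p0) < 1e-11 * scale)

    def test_motor_rigidity(self):
        """Bead radial positions fluctuate by less than 5% of the bead
        size (RMS) while the motor moves through solvent: the spring
        network holds the body nearly rigid."""
        cfg = make_fixture_scenario("tiny", phi=0.5, seed=6)
        motor = build_motor(cfg)
        rngs = _spawn_streams(6)
        state = make_state(cfg, motor, rngs["init"])
        table = PairPotentialTable.from_config(cfg)
        cache = init_force_cache(state, table)
        inner = (state.mspecies == 1) | (state.mspecies == 2)
        radii = []
        for cycle in range(16):
            for _ in range(50):
                md_interval(state, table, cache, cfg.t_md,
                            cfg.md_inner_substeps)
            center = state.mpos[inner].mean(axis=0)
            radii.append(np.linalg.norm(state.mpos[inner] - center, axis=1))
        radii = np.array(radii[6:])  # discard the elastic settling transient
        per_bead_std = radii.std(axis=0)
        rms = float(np.sqrt(np.mean(per_bead_std ** 2)))
        assert rms < 0.05 * cfg.sigma1
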