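"""Trajectory measurements: velocity statistics, concentration and flow
fields, and the coverage power-law fits."""

import math

import numpy as np
import pytest

from janusmpc.observables import (Frame, InsufficientDataError,
                                  ObservableSeries, angular_concentration_profile,
                                  axial_velocity_stats, blocked_standard_error,
                                  fit_amplitude_vs_R2, fit_power_law,
                                  flow_field_map, make_synthetic_sweep,
                                  radial_concentration_profile)

BOX = np.array([20.0, 20.0, 20.0])
CENTER = BOX / 2
U = np.array([0.0, 0.0, 1.0])


def _frame(positions, species=None, velocities=None, motor_velocity=None,
           t=0.0):
    positions = np.asarray(positions, float)
    n = len(positions)
    return Frame(
        time=t, positions=positions,
        velocities=(np.zeros((n, 3)) if velocities is None
                    else np.asarray(velocities, float)),
        species=(np.zeros(n, dtype=np.int8) if species is None
                 else np.asarray(species, dtype=np.int8)),
        center=CENTER.copy(), axis=U.copy(),
        motor_velocity=(np.zeros(3) if motor_velocity is None
                        else np.asarray(motor_velocity, float)),
        box=BOX.copy())


# ----------------------------------------------------------------------
# axial velocity series
# ----------------------------------------------------------------------
class TestSeries:
    def test_projection_identities(self):
        t = np.arange(10.0) + 1
        u = np.tile([0.0, 0.0, 1.0], (10, 1))
        c = 0.37
        s = ObservableSeries(t, np.tile([0.0, 0.0, c], (10, 1)), u)
        stats = axial_velocity_stats(s, burn_in_frac=0.2)
        assert stats.mean == pytest.approx(c, abs=1e-15)
        s_perp = ObservableSeries(t, np.tile([c, 0.0, 0.0], (10, 1)), u)
        assert axial_velocity_stats(s_perp, 0.2).mean == 0.0

    def test_rest_distribution_is_delta(self):
        t = np.arange(20.0) + 1
        u = np.tile([0.0, 0.0, 1.0], (20, 1))
        s = ObservableSeries(t, np.zeros((20, 3)), u)
        stats = axial_velocity_stats(s, 0.2)
        assert stats.mean == 0.0
        assert stats.hist_density.sum() > 0  # single occupied bin
        w = np.diff(stats.hist_edges)
        assert float((stats.hist_density * w).sum()) == pytest.approx(1.0)

    def test_histogram_normalized(self):
        rng = np.random.default_rng(0)
        t = np.arange(500.0) + 1
        u = np.tile([0.0, 0.0, 1.0], (500, 1))
        v = np.column_stack([rng.normal(size=500)] * 3)
        stats = axial_velocity_stats(ObservableSeries(t, v, u), 0.2)
        w = np.diff(stats.hist_edges)
        assert float((stats.hist_density * w).sum()) == pytest.approx(1.0)

    def test_monotone_time_required(self):
        with pytest.raises(ValueError):
            ObservableSeries(np.array([1.0, 1.0]), np.zeros((2, 3)),
                             np.tile([0, 0, 1.0], (2, 1)))

    def test_unit_axis_required(self):
        with pytest.raises(ValueError):
            ObservableSeries(np.array([1.0, 2.0]), np.zeros((2, 3)),
                             np.tile([0, 0, 2.0], (2, 1)))

    def test_empty_window_rejected(self):
        t = np.array([1.0, 2.0])
        s = ObservableSeries(t, np.zeros((2, 3)), np.tile([0, 0, 1.0], (2, 1)))
        with pytest.raises(InsufficientDataError):
            axial_velocity_stats(s, burn_in_frac=1.5)

    def test_blocked_se_uncorrelated_matches_naive(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=4000)
        se = blocked_standard_error(x, 10)
        assert se == pytest.approx(x.std() / math.sqrt(len(x)), rel=0.6)


# ----------------------------------------------------------------------
# radial profiles
# ----------------------------------------------------------------------
class TestRadialProfile:
    def test_hand_built_densities(self):
        """Eight particles at known radii: densities equal counts over
        shell-sector volumes computed by hand."""
        radii = [3.1, 3.1, 3.3, 3.45, 3.45, 3.45, 3.8, 3.9]
        pos = [CENTER + np.array([0.0, 0.0, -r]) for r in radii]  # theta=0
        frames = [_frame(pos)]
        edges = np.array([3.0, 3.5, 4.0])
        grid = radial_concentration_profile(frames, "A", edges, "catalytic")
        vol1 = 0.5 * 4 * math.pi / 3 * (3.5 ** 3 - 3.0 ** 3)
        vol2 = 0.5 * 4 * math.pi / 3 * (4.0 ** 3 - 3.5 ** 3)
        np.testing.assert_allclose(grid.table["density"],
                                   [6 / vol1, 2 / vol2], rtol=1e-12)

    def test_sector_restriction(self):
        # theta = 0 lies on the -u side (catalytic); +u side is inert
        pos = [CENTER + [0, 0, -3.2], CENTER + [0, 0, 3.2]]
        frames = [_frame(pos)]
        edges = np.array([3.0, 3.5])
        cat = radial_concentration_profile(frames, "A", edges, "catalytic")
        inert = radial_concentration_profile(frames, "A", edges, "inert")
        full = radial_concentration_profile(frames, "A", edges, "full")
        assert cat.table["counts"].sum() == 1
        assert inert.table["counts"].sum() == 1
        assert full.table["counts"].sum() == 2

    def test_uniform_gas_recovers_bulk_density(self):
        rng = np.random.default_rng(2)
        ns = 12.0
        n = rng.poisson(ns * BOX.prod())
        frames = [_frame(rng.uniform(0, BOX[0], size=(n, 3)))]
        edges = np.linspace(4.0, 8.0, 5)
        grid = radial_concentration_profile(frames, "A", edges, "full")
        for counts, dens in zip(grid.table["counts"], grid.table["density"]):
            se = ns / math.sqrt(max(counts, 1.0))
            assert abs(dens - ns) < 3 * se

    def test_absent_species_zero_profile(self):
        frames = [_frame([CENTER + [0, 0, -3.2]], species=[0])]
        grid = radial_concentration_profile(frames, "B",
                                            np.array([3.0, 3.5]), "full")
        assert (grid.table["density"] == 0).all()


# ----------------------------------------------------------------------
# angular profiles
# ----------------------------------------------------------------------
class TestAngularProfile:
    def test_particle_on_minus_u_axis_lands_at_theta_zero(self):
        frames = [_frame([CENTER + [0, 0, -3.35]])]
        grid = angular_concentration_profile(frames, "A", 3.2, 3.5, n_bins=18)
        t = grid.table.sort_values("theta_mid").reset_index(drop=True)
        assert t.loc[0, "counts"] == 1
        assert t["counts"].sum() == 1

    def test_hand_built_counts(self):
        thetas = [0.1, 0.1, 1.2, 2.2, 3.0]
        pos = [CENTER + 3.35 * np.array(
            [math.sin(th), 0.0, -math.cos(th)]) for th in thetas]
        frames = [_frame(pos)]
        grid = angular_concentration_profile(frames, "A", 3.2, 3.5, n_bins=4)
        # equal-cos bins: edges at cos(theta) = -1, -0.5, 0, 0.5, 1
        t = grid.table.sort_values("theta_mid").reset_index(drop=True)
        np.testing.assert_array_equal(t["counts"], [2, 1, 0, 2])

    def test_uniform_gas_flat(self):
        rng = np.random.default_rng(3)
        n = 200000
        frames = [_frame(rng.uniform(0, BOX[0], size=(n, 3)))]
        grid = angular_concentration_profile(frames, "A", 3.0, 4.5, n_bins=6)
        dens = grid.table["density"].to_numpy()
        assert dens.std() / dens.mean() < 0.1

    def test_empty_shell_rejected(self):
        frames = [_frame([CENTER + [0, 0, -9.0]])]
        with pytest.raises(InsufficientDataError):
            angular_concentration_profile(frames, "A", 3.2, 3.5)


# ----------------------------------------------------------------------
# flow field
# ----------------------------------------------------------------------
class TestFlowField:
    r_edges = np.array([3.0, 4.0, 5.0])
    th_edges = np.array([0.0, math.pi / 2, math.pi])

    def test_comoving_solvent_gives_zero_field(self):
        rng = np.random.default_rng(4)
        pos = CENTER + rng.normal(0, 1.5, size=(300, 3))
        w = np.array([0.1, -0.2, 0.05])
        frames = [_frame(pos, velocities=np.tile(w, (300, 1)),
                         motor_velocity=w)]
        grid = flow_field_map(frames, self.r_edges, self.th_edges)
        sampled = grid.table[grid.table["n_samples"] > 0]
        np.testing.assert_allclose(sampled["v_axial"], 0.0, atol=1e-14)
        np.testing.assert_allclose(sampled["v_radial"], 0.0, atol=1e-14)

    def test_axial_drift_projects_onto_axis(self):
        rng = np.random.default_rng(5)
        pos = CENTER + rng.normal(0, 1.5, size=(400, 3))
        w = 0.3 * U
        frames = [_frame(pos, velocities=np.tile(w, (400, 1)))]
        grid = flow_field_map(frames, self.r_edges, self.th_edges)
        sampled = grid.table[grid.table["n_samples"] > 0]
        np.testing.assert_allclose(sampled["v_axial"], 0.3, atol=1e-12)
        np.testing.assert_allclose(sampled["v_radial"], 0.0, atol=1e-12)

    def test_two_frame_hand_average(self):
        p = CENTER + np.array([0.0, 0.0, -3.5])  # theta=0 cell, r in [3,4)
        f1 = _frame([p], velocities=[[0.0, 0.0, 0.4]])
        f2 = _frame([p], velocities=[[0.0, 0.0, -0.1]])
        grid = flow_field_map([f1, f2], self.r_edges, self.th_edges)
        cell = grid.table[(grid.table["n_samples"] > 0)]
        assert len(cell) == 1
        assert cell["v_axial"].iloc[0] == pytest.approx(0.15, abs=1e-14)
        assert cell["n_samples"].iloc[0] == 2

    def test_empty_cells_are_missing_not_zero(self):
        frames = [_frame([CENTER + [0, 0, -3.5]])]
        grid = flow_field_map(frames, self.r_edges, self.th_edges)
        empty = grid.table[grid.table["n_samples"] == 0]
        assert empty["v_axial"].isna().all()


# ----------------------------------------------------------------------
# power-law fits
# ----------------------------------------------------------------------
class TestPowerLawFit:
    phis = np.linspace(0.0, 1.0, 11)

    def test_noiseless_recovery(self):
        vu = make_synthetic_sweep(self.phis, 0.01, 0.0029)
        fit = fit_power_law(self.phis, vu)
        assert fit.amplitude == pytest.approx(0.01, abs=1e-10)
        assert fit.baseline == pytest.approx(0.0029, abs=1e-10)
        assert fit.exponent == pytest.approx(4.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_exponent_recovery_under_noise(self):
        """Monte-Carlo: with 5% multiplicative noise on 11 coverage
        points the mean free exponent stays within 4 +/- 0.3."""
        rng = np.random.default_rng(42)
        exps = []
        for _ in range(100):
            vu = make_synthetic_sweep(self.phis, 0.01, 0.0029,
                                      noise_frac=0.05, rng=rng)
            exps.append(fit_power_law(self.phis, vu).exponent)
        exps = np.array(exps)
        assert np.isfinite(exps).all()
        assert abs(exps.mean() - 4.0) < 0.3

    def test_constant_data(self):
        vu = np.full(11, 0.0042)
        fit = fit_power_law(self.phis, vu)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-15)
        assert fit.baseline == pytest.approx(0.0042, abs=1e-15)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law(np.full(6, 0.5), np.ones(6))

    def test_summary_mentions_estimates(self):
        vu = make_synthetic_sweep(self.phis, 0.01, 0.0029)
        text = fit_power_law(self.phis, vu).summary()
        assert "A" in text and "Vu0" in text


class TestAmplitudeLine:
    def test_reference_line_recovery(self):
        """Exact line A = a - b R2 at the three studied outer radii."""
        a, b = 5.05e-2, 0.98e-2
        r2 = np.array([3.95, 4.2, 4.35])
        fit = fit_amplitude_vs_R2(r2, a - b * r2)
        assert fit.a == pytest.approx(a, abs=1e-12)
        assert fit.b == pytest.approx(b, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_points_interpolate(self):
        fit = fit_amplitude_vs_R2([1.0, 3.0], [0.5, 0.1])
        assert fit.a == pytest.approx(0.7)
        assert fit.b == pytest.approx(0.2)

    def test_flat_line(self):
        fit = fit_amplitude_vs_R2([1.0, 2.0, 3.0], [0.4, 0.4, 0.4])
        assert fit.b == pytest.approx(0.0, abs=1e-15)

    def test_single_radius_rejected(self):
        with pytest.raises(ValueError):
            fit_amplitude_vs_R2([2.0, 2.0], [0.1, 0.2])
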