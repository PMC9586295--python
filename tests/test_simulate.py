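"""Langevin simulator: stepping, boundaries, variants, ensembles."""

import numpy as np
import pytest

from gyrowall import (SimConfig, WallFields, total_omega, euler_maruyama_step,
                      apply_boundaries, run_ensemble, run_unbounded,
                      measure_drift_diffusivity)
from gyrowall.simulate import GriddedField2D, VARIANTS
from gyrowall.fields import make_grid, estimate_drift_diffusion, accumulate


def const_fields(V=100.0, w=0.3, D=0.025):
    return WallFields(
        V_s=lambda y, phi: np.broadcast_to(V, np.shape(y)),
        omega_w=lambda y, phi: np.broadcast_to(w, np.shape(y)),
        D_r=lambda y, phi: np.broadcast_to(D, np.shape(y)),
    )


class TestTotalOmega:
    def test_variant_iii_gyro_only(self):
        cfg = SimConfig(variant="III", B=5.0)
        w = total_omega(500.0, 0.0, const_fields(w=0.3), cfg)
        assert w == pytest.approx(-0.1)

    def test_variant_i_wall_only(self):
        cfg = SimConfig(variant="I")
        assert total_omega(500.0, 1.0, const_fields(w=0.3), cfg) == \
            pytest.approx(0.3)

    def test_variant_iv_sum(self):
        cfg = SimConfig(variant="IV", B=5.0)
        assert total_omega(500.0, 0.0, const_fields(w=0.3), cfg) == \
            pytest.approx(0.2)

    def test_gyro_variant_requires_B(self):
        with pytest.raises(ValueError, match="requires B"):
            SimConfig(variant="III")

    def test_variant_table_flags(self):
        assert VARIANTS["I"] == (True, True, False, False)
        assert VARIANTS["V"] == (True, True, True, True)


class TestStep:
    def test_deterministic_position_update(self):
        # dt = dtau*W/V_sb = 1e-4 * 1000 / 100 ... choose dtau for dt=0.01
        cfg = SimConfig(variant="I", W=1000.0, V_sb=100.0, dtau=1e-3)
        assert cfg.dt == pytest.approx(0.01)
        f = const_fields(V=100.0, w=0.0, D=0.0)
        y, phi = euler_maruyama_step(np.array([500.0]), np.array([-np.pi / 2]),
                                     f, cfg, np.zeros(1))
        assert y[0] == pytest.approx(501.0)   # -sin(-pi/2) = +1

    def test_deterministic_heading_update(self):
        cfg = SimConfig(variant="I", W=1000.0, V_sb=100.0, dtau=1e-3)
        f = const_fields(V=0.0, w=0.5, D=0.0)
        _, phi = euler_maruyama_step(np.array([500.0]), np.array([0.2]),
                                     f, cfg, np.zeros(1))
        assert phi[0] == pytest.approx(0.205)

    def test_heading_variance_growth(self, rng):
        """With V=0, omega=0, D_r=0.025: heading variance grows as 2*D_r*t
        (Brownian closed form, within 3 SE across replicates)."""
        cfg = SimConfig(variant="I", W=1000.0, V_sb=100.0, dtau=1e-3,
                        D_rb=0.025)
        f = const_fields(V=0.0, w=0.0, D=0.025)
        n, steps = 1000, 10_000
        phi = np.zeros(n)
        y = np.full(n, 500.0)
        for _ in range(steps):
            noise = rng.standard_normal(n)
            y, phi_new = euler_maruyama_step(y, phi, f, cfg, noise)
            # track the unwrapped angle for the variance comparison
            phi = phi + (phi_new - phi + np.pi) % (2 * np.pi) - np.pi
        t = steps * cfg.dt
        target = 2 * 0.025 * t
        se = target * np.sqrt(2 / n)
        assert abs(phi.var() - target) < 3 * se

    def test_rejects_non_finite(self):
        cfg = SimConfig(variant="I")
        with pytest.raises(ValueError):
            euler_maruyama_step(np.array([np.nan]), np.array([0.0]),
                                const_fields(), cfg, np.zeros(1))


class TestBoundaries:
    @pytest.mark.parametrize("y,phi,exp_y,exp_phi", [
        (-0.3, np.pi / 4, 0.3, -np.pi / 4),
        (500.0, 0.7, 500.0, 0.7),
        (1002.0, -np.pi / 3, 998.0, np.pi / 3),
        (0.0, 0.5, 0.0, 0.5),
    ])
    def test_reflection_rules(self, y, phi, exp_y, exp_phi):
        ry, rphi = apply_boundaries(np.array([y]), np.array([phi]), 1000.0)
        assert ry[0] == pytest.approx(exp_y)
        assert rphi[0] == pytest.approx(exp_phi)

    def test_overshoot_rejected(self):
        with pytest.raises(RuntimeError):
            apply_boundaries(np.array([-1500.0]), np.array([0.0]), 1000.0)

    def test_zero_noise_ray_tracing_oracle(self):
        """Zero-noise zero-torque trajectories are straight with specular
        bounces; compare against event-driven ray tracing."""
        W, V, phi0, y0 = 1000.0, 100.0, 1.1, 300.0
        cfg = SimConfig(variant="I", W=W, V_sb=V, dtau=1e-4)
        f = const_fields(V=V, w=0.0, D=0.0)
        y = np.array([y0])
        phi = np.array([phi0])
        n_steps = 40_000
        for _ in range(n_steps):
            y, phi = euler_maruyama_step(y, phi, f, cfg, np.zeros(1))
            y, phi = apply_boundaries(y, phi, W)
        # ray-tracing oracle: fold the free-flight position into [0, 2W]
        t = n_steps * cfg.dt
        free = y0 - V * np.sin(phi0) * t
        folded = np.abs((free % (2 * W)))
        expected = folded if folded <= W else 2 * W - folded
        assert y[0] == pytest.approx(expected, abs=1e-6)


class TestEnsemble:
    def test_walkers_stay_inside_and_P_normalized(self):
        cfg = SimConfig(variant="I", n_traj=500, tau_end=2.0, burn_in_tau=0.5,
                        dtau=1e-3, seed=3)
        res = run_ensemble(cfg)
        assert np.all((res.final_y >= 0) & (res.final_y <= cfg.W))
        assert res.P.sum() * res.grid.bin_area() == pytest.approx(1.0)

    def test_seed_determinism_bit_identical(self):
        cfg = SimConfig(variant="I", n_traj=300, tau_end=1.0, dtau=1e-3,
                        burn_in_tau=0.2, seed=11)
        r1 = run_ensemble(cfg)
        r2 = run_ensemble(cfg)
        np.testing.assert_array_equal(r1.final_y, r2.final_y)
        np.testing.assert_array_equal(r1.grid.count, r2.grid.count)

    def test_track_dump_closes_loop_with_analysis(self):
        cfg = SimConfig(variant="I", n_traj=50, tau_end=2.0, dtau=5e-4,
                        burn_in_tau=0.5, seed=4)
        res = run_ensemble(cfg, dump_tracks=5)
        assert len(res.tracks) == 5
        from gyrowall import compute_kinematics
        k = compute_kinematics(res.tracks[0])
        assert np.isfinite(k.speed).all()

    def test_gridded_fields_drive_simulation(self):
        """A simulator driven by a BinnedField via bilinear interpolation
        reproduces the constant-field run."""
        g = make_grid(1000.0, min_count=1)
        g.mean_speed = np.full(g.shape, 80.0)
        g.omega = np.zeros(g.shape)
        g.D_r = np.full(g.shape, 0.025)
        wf = WallFields.from_binned(g)
        assert wf.V_s(np.array([500.0]), np.array([0.3]))[0] == pytest.approx(80.0)
        cfg = SimConfig(variant="II", n_traj=200, tau_end=1.0, dtau=1e-3,
                        burn_in_tau=0.2, seed=5)
        res = run_ensemble(cfg, fields=wf)
        assert np.all((res.final_y >= 0) & (res.final_y <= 1000.0))


class TestGriddedField2D:
    def test_periodic_heading_interpolation(self):
        g = make_grid(1000.0, n_orientation_bins=8, min_count=1)
        vals = np.tile(np.sin(g.orientation_centers), (51, 1))
        f = GriddedField2D(g.position_centers, g.orientation_centers, vals)
        # query on the periodic seam between the last and first bin centers
        seam = f(np.array([500.0]), np.array([np.pi]))
        expected = 0.5 * (np.sin(g.orientation_centers[-1])
                          + np.sin(g.orientation_centers[0]))
        assert seam[0] == pytest.approx(expected)

    def test_nan_bins_filled_from_nearest(self):
        vals = np.ones((51, 8))
        vals[10, 3] = np.nan
        g = make_grid(1000.0, n_orientation_bins=8, min_count=1)
        f = GriddedField2D(g.position_centers, g.orientation_centers, vals)
        assert f.n_filled == 1
        assert np.isfinite(f.vals).all()


class TestStepSizeRobustness:
    def test_halving_dt_preserves_bulk_sigma(self):
        """Halving the Euler step changes the fitted bulk concentration
        slope by < 2%.  The two resolutions consume the same Brownian path
        (the coarse step sums the fine noise pairs), so the comparison
        isolates the discretization effect from sampling noise."""
        from gyrowall import fit_exponential_profile
        from gyrowall.fields import make_grid, estimate_pdf_and_concentration
        rng = np.random.default_rng(77)
        W, V, B, Dr = 6000.0, 100.0, 10.0, 0.1
        n, dt = 3000, 0.06
        steps = 20_000                      # 1200 s
        burn = 8_000
        yc = rng.uniform(0, W, n)
        pc = rng.uniform(-np.pi, np.pi, n)
        yf, pf = yc.copy(), pc.copy()
        gc = make_grid(W)
        gf = make_grid(W)

        def advance(y, phi, dt_, noise):
            y = y - V * np.sin(phi) * dt_
            phi = phi + (-np.cos(phi) / (2 * B)) * dt_ \
                + np.sqrt(2 * Dr * dt_) * noise
            return apply_boundaries(y, (phi + np.pi) % (2 * np.pi) - np.pi, W)

        for step in range(steps):
            n1 = rng.standard_normal(n)
            n2 = rng.standard_normal(n)
            yf, pf = advance(yf, pf, dt / 2, n1)
            yf, pf = advance(yf, pf, dt / 2, n2)
            yc, pc = advance(yc, pc, dt, (n1 + n2) / np.sqrt(2))
            if step >= burn and step % 10 == 0:
                for g, yy, pp in ((gc, yc, pc), (gf, yf, pf)):
                    accumulate(g, yy, pp, np.full(n, V), np.zeros(n))
        sigmas = []
        for g in (gc, gf):
            _, conc = estimate_pdf_and_concentration(g)
            _, s = fit_exponential_profile(conc, W)
            sigmas.append(s)
        assert abs(sigmas[0] - sigmas[1]) / abs(sigmas[1]) < 0.02


class TestUnboundedControl:
    def test_drift_diffusivity_measurement(self):
        """V_z and D_T from mean/variance growth match the weak-bias closed
        forms V_z ~ V kappa/2 and D_T ~ V^2/(2 D_r) within a few percent."""
        from scipy.special import i0, i1
        cfg = SimConfig(variant="III", V_sb=100.0, D_rb=0.1, B=60.0,
                        W=20000.0, n_traj=8000, tau_end=5.0, dtau=2.5e-4,
                        seed=6, reflect=False)
        times, zs, thetas = run_unbounded(cfg, record_every=200)
        Vz, DT = measure_drift_diffusivity(times, zs, discard=60.0)
        kappa = 1 / (2 * cfg.B * cfg.D_rb)
        Vz_pred = cfg.V_sb * i1(kappa) / i0(kappa)
        assert Vz == pytest.approx(Vz_pred, rel=0.15)
        assert DT == pytest.approx(cfg.V_sb ** 2 / (2 * cfg.D_rb), rel=0.15)
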