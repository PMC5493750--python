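import numpy as np
import pytest
from scipy.linalg import solve_continuous_lyapunov

from lanesim import ModelParams
from lanesim.errors import ClosureValidityError, StabilityError
from lanesim.hydro import (
    HydroParams,
    SpectralGrid,
    axis_limits,
    fit_decay_exponent,
    kinetic_coefficients,
    lyapunov_matrix,
    random_stable_params,
    realspace_correlations,
    spde_integrate,
    structure_factor,
)
from lanesim.observables import scaling_collapse

BASE = HydroParams(v=1.0, c=0.4, Dx=0.5, Dy=0.5, Dtx=0.3, Dty=0.3, T=1.0)


class TestStructureFactor:
    @pytest.mark.parametrize(
        "params",
        [
            BASE,
            HydroParams(v=0.8, c=0.2, Dx=0.6, Dy=0.4, Dtx=0.2, Dty=0.25,
                        Tx=1.3, Ty=0.7),
        ],
    )
    def test_matches_lyapunov_oracle(self, params):
        # independent route: solve the stationary covariance equation
        # A C + C A^H + N = 0 per mode with scipy
        g = SpectralGrid(6, 6, 14.0, 14.0)
        sf = structure_factor(params, g)
        QX, QY = g.meshes()
        tx, ty = params.noise_xy
        for i in range(6):
            for j in range(6):
                if QX[i, j] == 0 and QY[i, j] == 0:
                    continue
                A = lyapunov_matrix(params, QX[i, j], QY[i, j])
                nq = 2.0 * (tx * QX[i, j] ** 2 + ty * QY[i, j] ** 2)
                C = solve_continuous_lyapunov(A, -nq * np.eye(2))
                assert sf.S_auto[i, j] == pytest.approx(C[0, 0].real, rel=1e-9)
                assert sf.S_cross[i, j] == pytest.approx(C[0, 1], rel=1e-9)

    def test_even_in_q_and_nonnegative(self):
        g = SpectralGrid(16, 12, 30.0, 24.0)
        sf = structure_factor(BASE, g)
        assert (sf.S_auto >= 0).all()
        flipped = sf.S_auto[
            (-np.arange(16)) % 16][:, (-np.arange(12)) % 12]
        np.testing.assert_allclose(sf.S_auto, flipped, rtol=1e-12)
        assert sf.S_auto[0, 0] == 0.0  # q = 0 pinned

    def test_zero_coupling_isotropic_diffusion_is_analytic(self):
        p = HydroParams(v=1.0, c=0.0, Dx=0.5, Dy=0.5, Dtx=0.0, Dty=0.0)
        a, b = axis_limits(p)
        assert a == pytest.approx(b)
        g = SpectralGrid(32, 32, 40.0, 40.0)
        sf = structure_factor(p, g)
        vals = sf.S_auto[sf.S_auto > 0]
        assert np.ptp(vals) < 1e-9 * vals.mean()  # direction independent

    def test_coupling_opens_axis_gap(self):
        a, b = axis_limits(BASE)
        assert abs(a - b) > 0.1
        # the closed-form grid limits approach the analytic constants
        g = SpectralGrid(256, 256, 2000.0, 2000.0)
        sf = structure_factor(BASE, g)
        assert sf.S_auto[1, 0] == pytest.approx(a, rel=1e-3)
        assert sf.S_auto[0, 1] == pytest.approx(b, rel=1e-3)

    def test_unstable_parameters_rejected_naming_modes(self):
        bad = HydroParams(v=1.0, c=0.2, Dx=0.3, Dy=0.3, Dtx=0.5, Dty=0.5)
        with pytest.raises(StabilityError) as exc:
            structure_factor(bad, SpectralGrid(16, 16, 20.0, 20.0))
        assert exc.value.modes


class TestRealSpaceCorrelations:
    def test_longitudinal_decay_exponent(self):
        g = SpectralGrid(2048, 512, 716.8, 179.2)
        rs = realspace_correlations(structure_factor(BASE, g))
        x, c = rs.longitudinal_cut()
        slope = fit_decay_exponent(x, c, 15, 120)
        assert slope == pytest.approx(-1.5, abs=0.15)

    def test_no_algebraic_tail_without_coupling(self):
        p = HydroParams(v=1.0, c=0.0, Dx=0.5, Dy=0.5, Dtx=0.0, Dty=0.0)
        g = SpectralGrid(2048, 512, 716.8, 179.2)
        rs = realspace_correlations(structure_factor(p, g))
        x, c = rs.longitudinal_cut()
        coupled = realspace_correlations(structure_factor(BASE, g))
        xc, cc = coupled.longitudinal_cut()
        i = np.argmin(np.abs(x - 30.0))
        # only the spectral-taper ringing floor remains without coupling
        assert abs(c[i]) < 0.1 * abs(cc[i])

    def test_slices_collapse_with_halfpower_scaling(self):
        g = SpectralGrid(2048, 512, 716.8, 179.2)
        rs = realspace_correlations(structure_factor(BASE, g))
        grid = rs.to_grid()
        good = scaling_collapse(grid, x_slices=[12, 20, 32, 50], eta_max=2.0)
        null = scaling_collapse(
            grid, x_slices=[12, 20, 32, 50],
            x_exponent=1.0, y_exponent=1.0, eta_max=2.0,
        )
        assert good.spread < 0.15
        assert null.spread > 3 * good.spread

    def test_anisotropic_noise_keeps_the_exponent(self):
        # conserved-noise anisotropy changes amplitudes, not the power
        # law; the scale-free ray-limit part of the spectrum (which the
        # anisotropy feeds) is subtracted so the jump-induced tail is
        # visible at numerically accessible distances
        g = SpectralGrid(4096, 1024, 1433.6, 358.4)
        slopes, amps = [], []
        for tx, ty in [(1.0, 1.0), (1.6, 0.6)]:
            p = HydroParams(v=1.0, c=0.4, Dx=0.5, Dy=0.5, Dtx=0.3, Dty=0.3,
                            Tx=tx, Ty=ty)
            rs = realspace_correlations(
                structure_factor(p, g), subtract_ray_limit=True
            )
            x, c = rs.longitudinal_cut()
            slopes.append(fit_decay_exponent(x, c, 20, 200))
            amps.append(abs(c[np.argmin(np.abs(x - 30.0))]))
        assert slopes[0] == pytest.approx(-1.5, abs=0.15)
        assert slopes[1] == pytest.approx(-1.5, abs=0.15)
        assert amps[1] != pytest.approx(amps[0], rel=0.05)  # amplitudes move


class TestKineticCoefficients:
    MICRO = ModelParams(B=5.0, Lx=168.0, Ly=84.0)

    def test_zero_density_free_limit(self):
        hp = kinetic_coefficients(self.MICRO, 0.0, 0.0)
        assert hp.meta["lambda"] == 0.0
        assert hp.c == 0.0
        assert hp.Dtx == 0.0
        assert hp.v == pytest.approx(self.MICRO.v0)

    def test_collision_rate_linear_in_partner_density(self):
        h1 = kinetic_coefficients(self.MICRO, 0.07, 0.07)
        h2 = kinetic_coefficients(self.MICRO, 0.14, 0.14)
        assert h2.meta["lambda"] == pytest.approx(2 * h1.meta["lambda"])
        # collision-induced rotational diffusion doubles with density
        assert h2.Dtx == pytest.approx(2 * h1.Dtx)

    def test_three_force_contributions(self):
        # drive alignment, pressure coupling, collision-induced
        # rotational diffusion: each responds to its own knob
        h = kinetic_coefficients(self.MICRO, 0.07, 0.07)
        stronger_drive = kinetic_coefficients(
            self.MICRO.with_(H=2.0), 0.07, 0.07
        )
        assert stronger_drive.meta["sigma2"] < h.meta["sigma2"]
        assert stronger_drive.v > h.v
        assert h.c > 0          # denser partners slow the drift
        assert h.Dtx > 0        # pressure coupling present
        assert h.v < self.MICRO.v0  # collisions suppress the mean drift

    def test_closure_rejected_when_alignment_dominates(self):
        with pytest.raises(ClosureValidityError):
            kinetic_coefficients(self.MICRO.with_(B=0.8), 0.07, 0.07)

    def test_estimates_are_stable_on_long_wavelength_grid(self):
        hp = kinetic_coefficients(self.MICRO, 0.07, 0.07)
        g = SpectralGrid(64, 64, 160.0, 160.0)  # q up to ~1.2
        sf = structure_factor(hp, g)
        assert (sf.S_auto >= 0).all()


class TestSpde:
    GRID = SpectralGrid(16, 16, 12.0, 12.0)

    def test_zero_noise_decays(self):
        p = HydroParams(v=1.0, c=0.4, Dx=0.5, Dy=0.5, Dtx=0.3, Dty=0.3, T=0.0)
        res = spde_integrate(p, self.GRID, steps=400, dt=0.5, seed=0,
                             burn_in=0)
        assert res.S_auto.max() == 0.0

    def test_mass_mode_strictly_conserved(self):
        res = spde_integrate(BASE, self.GRID, steps=500, dt=0.5, seed=1)
        assert np.abs(res.mass_right).max() == 0.0

    def test_decoupled_species_matches_closed_form(self):
        # single anisotropic-diffusion species with conserved noise:
        # S(q) = n_q / (2 D_q), checked against the sampled spectrum
        p = HydroParams(v=1.0, c=0.0, Dx=0.7, Dy=0.4, Dtx=0.0, Dty=0.0)
        res = spde_integrate(p, self.GRID, steps=20_000, dt=0.5, seed=2)
        QX, QY = self.GRID.meshes()
        Dq = p.Dx * QX**2 + p.Dy * QY**2
        nq = 2.0 * (QX**2 + QY**2)
        m = (QX != 0) | (QY != 0)
        S = np.zeros_like(Dq)
        S[m] = nq[m] / (2 * Dq[m])
        z = (res.S_auto[m] - S[m]) / res.S_auto_se[m]
        assert np.mean(np.abs(z) < 3) > 0.97
        assert np.abs(z).max() < 6.0
        assert np.mean(res.S_auto[m] / S[m]) == pytest.approx(1.0, abs=0.02)

    def test_coupled_spectra_match_structure_factor(self):
        res = spde_integrate(BASE, self.GRID, steps=20_000, dt=0.5, seed=3)
        sf = structure_factor(BASE, self.GRID)
        m = sf.S_auto > 0
        z = (res.S_auto[m] - sf.S_auto[m]) / res.S_auto_se[m]
        # calibrated statistical bounds: ~0.5% of modes are expected
        # beyond 3 s.e. for a correct integrator
        assert np.mean(np.abs(z) < 3) > 0.97
        assert np.abs(z).max() < 6.0
        assert np.mean(res.S_auto[m] / sf.S_auto[m]) == pytest.approx(
            1.0, abs=0.03
        )
        # cross-spectrum also agrees in the median
        rel = np.abs(res.S_cross[m] - sf.S_cross[m]) / sf.S_auto[m]
        assert np.median(rel) < 0.1

    def test_semi_implicit_variant_is_stable_and_close(self):
        res = spde_integrate(BASE, self.GRID, steps=10_000, dt=0.05, seed=4,
                             method="semi-implicit")
        sf = structure_factor(BASE, self.GRID)
        m = sf.S_auto > 0
        ratio = res.S_auto[m] / sf.S_auto[m]
        assert 0.7 < np.mean(ratio) < 1.1  # O(dt)-biased but consistent

    def test_exponent_robust_over_random_parameter_draws(self):
        rng = np.random.default_rng(42)
        g = SpectralGrid(2048, 512, 716.8, 179.2)
        for _ in range(5):
            p = random_stable_params(rng)
            rs = realspace_correlations(structure_factor(p, g))
            x, c = rs.longitudinal_cut()
            assert fit_decay_exponent(x, c, 15, 120) == pytest.approx(
                -1.5, abs=0.15
            )
            col = scaling_collapse(
                rs.to_grid(), x_slices=[12, 20, 32, 50], eta_max=2.0
            )
            assert col.spread < 0.2
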