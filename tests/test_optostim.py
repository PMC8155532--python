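"""Light transport (KM closed form, Monte Carlo) and excitability thresholds."""

import numpy as np
import pytest
from scipy.linalg import expm

from magsim.optostim import (LightSource, OpticalTissue, VoxelGrid,
                             chronaxie_from_curve, irradiance_threshold,
                             km_irradiance, km_scatter_attenuation,
                             km_transmittance, mc_irradiance)


class TestKubelkaMunk:
    def test_origin_limit(self):
        # sinh 0 = 0, cosh 0 = 1 -> M = 1, and the on-axis source profile is 1
        assert np.isclose(float(km_scatter_attenuation(0.0, OpticalTissue())), 1.0)
        assert np.isclose(float(km_transmittance(0.0, 0.0)), 1.0)

    def test_lossless_limit(self):
        # mu_a = 0 -> a = 1, b = 0, no scattering attenuation beyond geometry
        t = OpticalTissue(mu_a=0.0)
        x = np.array([0.0, 0.1, 1.0, 5.0])
        assert np.allclose(km_scatter_attenuation(x, t), 1.0)

    def test_two_flux_ode_oracle(self):
        """M(x) equals the transmitted flux of the two-flux system with
        I+(0) = 1 and no returning flux at the far face."""
        mu_s, mu_a, x = 10.0, 0.1, 0.5
        tissue = OpticalTissue(mu_s=mu_s, mu_a=mu_a)
        # d/dx [I+, I-] = A [I+, I-]
        a_mat = np.array([[-(mu_s + mu_a), mu_s],
                          [-mu_s, (mu_s + mu_a)]])
        prop = expm(a_mat * x)
        # solve I-(0) from I-(x) = 0
        i_minus_0 = -prop[1, 0] / prop[1, 1]
        t_numeric = prop[0, 0] + prop[0, 1] * i_minus_0
        t_formula = float(km_scatter_attenuation(x, tissue))
        assert abs(t_numeric - t_formula) < 1e-6

    def test_monotone_in_r_and_depth(self):
        r = np.linspace(0, 400, 60)
        t_r = km_transmittance(r, np.full_like(r, 150.0))
        assert np.all(np.diff(t_r) <= 1e-12)
        z = np.linspace(1.0, 600, 80)
        t_z = km_transmittance(np.zeros_like(z), z)
        assert np.all(np.diff(t_z) <= 1e-12)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            km_transmittance(0.0, -1.0)

    def test_points_behind_fiber_get_zero(self):
        src = LightSource(irradiance=1.0, position=(0, 0, 0), direction=(0, 0, -1))
        irr = km_irradiance([[0.0, 0.0, 50.0]], source=src)
        assert irr[0] == 0.0


class TestMonteCarlo:
    def test_energy_accounting_is_exact(self):
        f = mc_irradiance(n_photons=20_000, seed=3)
        a = f.accounting
        total = a["deposited"] + a["escaped"] + a["residual"] + a["roulette_net"]
        assert abs(total - a["launched"]) / a["launched"] < 1e-6

    def test_minimum_photon_count_enforced(self):
        with pytest.raises(ValueError):
            mc_irradiance(n_photons=100)

    def test_isotropic_point_source_beer_lambert_oracle(self):
        """Fluence in a purely absorbing medium follows e^(-mu_a d)/(4 pi d^2)."""
        mu_a = 2.0
        tissue = OpticalTissue(mu_s=1e-6, mu_a=mu_a, g=0.0)
        grid = VoxelGrid(origin=(-1000.0, -1000.0, -1000.0), shape=(40, 40, 40),
                         spacing=50.0)
        src = LightSource(position=(0.0, 0.0, 0.0))
        reps = [mc_irradiance(src, tissue, n_photons=60_000, seed=s, grid=grid,
                              geometry="isotropic") for s in range(4)]
        centers = [grid.centers(i) for i in range(3)]
        xx, yy, zz = np.meshgrid(*centers, indexing="ij")
        d = np.sqrt(xx ** 2 + yy ** 2 + zz ** 2) * 1e-3            # mm
        for d_lo, d_hi in ((0.25, 0.35), (0.45, 0.55), (0.7, 0.8)):
            shell = (d >= d_lo) & (d < d_hi)
            vals = np.array([r.fluence[shell].mean() for r in reps])
            # voxel-wise expectation (the kernel is convex over the shell)
            expected = (np.exp(-mu_a * d[shell]) / (4 * np.pi * d[shell] ** 2)).mean()
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - expected) < 3 * se + 0.03 * expected

    def test_ballistic_limit_geometric_spread(self):
        """Scatter-free tissue: near-axis fluence follows the geometric
        1/R(z)^2 spread of the emission cone (times Beer-Lambert)."""
        tissue = OpticalTissue(mu_s=1e-6, mu_a=0.2, g=0.0)
        grid = VoxelGrid(origin=(-500.0, -500.0, -2100.0), shape=(10, 10, 21),
                         spacing=100.0)
        src = LightSource(irradiance=1.0, position=(0.0, 0.0, 0.0),
                          direction=(0, 0, -1))
        f = mc_irradiance(src, tissue, n_photons=400_000, seed=2, grid=grid)
        near_axis = f.fluence[4:6, 4:6, :].mean(axis=(0, 1))
        zc = -grid.centers(2)                                     # depth, μm
        theta = src.divergence(tissue.n)
        r0 = src.diameter / 2.0
        pick = (zc > 500) & (zc < 1800)
        expected = (np.exp(-tissue.mu_a * zc * 1e-3)
                    * (r0 / (r0 + zc * np.tan(theta))) ** 2)
        ratio = near_axis[pick] / expected[pick]
        assert ratio.std() / ratio.mean() < 0.25

    def test_sqrt_n_convergence(self):
        """Doubling the photon count shrinks the voxel standard error ~ sqrt(2)."""
        grid = VoxelGrid(origin=(-400, -400, 600), shape=(20, 20, 20), spacing=40.0)
        src = LightSource(position=(0.0, 0.0, 1500.0), direction=(0, 0, -1))

        def mean_se(n):
            reps = np.stack([mc_irradiance(src, OpticalTissue(), n_photons=n,
                                           seed=100 + s, grid=grid).absorbed
                             for s in range(6)])
            return reps.std(axis=0, ddof=1).mean()

        ratio = mean_se(20_000) / mean_se(40_000)
        assert 1.1 < ratio < 1.8


class TestThresholds:
    def test_lapicque_chronaxie_recovered_exactly(self):
        rheo, c = 10.0, 2.0
        d = np.array([0.3, 0.5, 1.0, c, 3.0, 5.0, 10.0, np.inf])
        th = rheo * (1.0 + c / d)
        assert np.isclose(chronaxie_from_curve(d, th), c, rtol=1e-12)

    def test_lapicque_chronaxie_off_grid_interpolation(self):
        rheo, c = 5.0, 1.7
        d = np.array([0.3, 0.6, 1.2, 2.4, 4.8, 9.6, 1e6])
        th = rheo * (1.0 + c / d)
        assert np.isclose(chronaxie_from_curve(d, th), c, rtol=0.05)

    def test_long_pulse_threshold_not_above_short(self, gbc_template):
        t_short = irradiance_threshold(gbc_template, "calyx", 1.0)
        t_long = irradiance_threshold(gbc_template, "calyx", 10.0)
        assert t_long <= t_short

    def test_node_illumination_cannot_trigger(self, gbc_template):
        thr = irradiance_threshold(gbc_template, "axon_nodes", 3.0)
        assert np.isinf(thr)
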