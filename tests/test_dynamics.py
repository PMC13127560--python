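"""Trajectory statistics against closed-form and constructed oracles."""

import numpy as np
import pytest
from scipy import special

from epidyn import dynamics as dyn
from epidyn.synthetic import SyntheticParams, gen_trajectories

from conftest import make_table


class TestTMSD:
    def test_static_zero(self, static_tracks):
        m = dyn.tmsd(static_tracks, np.arange(1, 10))
        assert np.allclose(m.values, 0.0)

    def test_translation_and_rotation_invariance(self, brownian_tracks):
        lags = np.array([2, 7, 20])
        base = dyn.tmsd(brownian_tracks, lags).values
        _, _, pos = brownian_tracks.position_array()
        c, s = np.cos(0.7), np.sin(0.7)
        rot = pos @ np.array([[c, -s], [s, c]]) + 50.0
        assert np.allclose(dyn.tmsd(make_table(rot), lags).values, base)

    def test_lag_beyond_record_dropped_with_warning(self, static_tracks):
        with pytest.warns(UserWarning, match="dropped"):
            m = dyn.tmsd(static_tracks, np.array([5, 10_000]))
        assert len(m.dt_min) == 1


class TestCageRelativeTMSD:
    def test_rigid_translation_removed(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 100, (60, 2))
        drift = np.cumsum(rng.normal(0, 0.5, (40, 2)), axis=0)
        pos = base[None] + drift[:, None, :]
        m = dyn.cage_relative_tmsd(make_table(pos), np.array([1, 5, 10]),
                                   neighbor_cutoff=20.0)
        assert np.all(m.values < 1e-20)

    def test_independent_brownian_slightly_above_plain(self, brownian_tracks):
        lags = np.array([5, 10])
        plain = dyn.tmsd(brownian_tracks, lags)
        cage = dyn.cage_relative_tmsd(brownian_tracks, lags,
                                      neighbor_cutoff=16.0, origin_stride=7)
        # subtracting the mean of n̄ independent neighbors adds variance
        # 1/n̄: expect cage/plain ≈ 1 + 1/n̄ with n̄ ≈ ρπr² − 1
        ratio = cage.values / plain.values
        assert np.all(ratio > 1.0)
        assert np.all(ratio < 1.6)

    def test_rigid_rotation_not_removed(self):
        ang = np.linspace(0, 0.3, 30)
        rng = np.random.default_rng(1)
        base = rng.uniform(-50, 50, (80, 2))
        pos = np.einsum("tab,nb->tna",
                        np.array([[[np.cos(a), -np.sin(a)],
                                   [np.sin(a), np.cos(a)]] for a in ang]),
                        base)
        m = dyn.cage_relative_tmsd(make_table(pos), np.array([5, 10]),
                                   neighbor_cutoff=25.0)
        assert np.all(m.values > 1e-3)


class TestRotationalMSD:
    def test_constant_theta_zero(self):
        pos = np.zeros((20, 10, 2)) + np.arange(10)[None, :, None]
        t = make_table(pos, theta=np.full((20, 10), 0.3))
        m = dyn.rotational_msd(t, np.arange(1, 5))
        assert np.allclose(m.values, 0.0)

    def test_angular_brownian_motion(self):
        rng = np.random.default_rng(5)
        D_theta = 5e-4
        T, N = 200, 400
        th = np.cumsum(rng.normal(0, np.sqrt(2 * D_theta * 5.0), (T, N)),
                       axis=0)
        pos = np.zeros((T, N, 2)) + np.arange(N)[None, :, None]
        t = make_table(pos, theta=th)
        m = dyn.rotational_msd(t, np.array([2, 5, 10, 20]))
        assert np.allclose(m.values, 2 * D_theta * m.dt_min, rtol=0.1)

    def test_alternating_step_is_bounded(self):
        T, N = 40, 3
        th = 0.8 + 0.1 * (np.arange(T) % 2)[:, None] * np.ones((T, N))
        pos = np.zeros((T, N, 2)) + np.arange(N)[None, :, None]
        m = dyn.rotational_msd(make_table(pos, theta=th), np.arange(1, 6))
        # odd lags see the ±δ flip, even lags none
        assert np.allclose(m.values, [0.01, 0, 0.01, 0, 0.01], atol=1e-12)


class TestDiffusionCoefficient:
    def test_exact_line_inversion(self):
        msd = dyn.MSDCurve(dt_min=np.arange(10, 500, 10.0),
                           values=4 * 0.025 * np.arange(10, 500, 10.0),
                           counts=np.ones(49), variant="translational")
        assert np.isclose(dyn.diffusion_coefficient(msd), 0.025)

    def test_anisotropic_ratio_recovered(self):
        p = SyntheticParams(n_cells=1500, field_width=500, field_height=500,
                            n_frames=100, model="anisotropic", D=0.03,
                            anisotropy_ratio=2.0, rng_seed=8)
        t = gen_trajectories(p)
        out = dyn.directional_diffusion(
            t, angles=np.array([0.0, np.pi / 2]),
            lags=np.arange(10, 90, 10), fit_window=(50.0, 400.0))
        ratio = out.D.iloc[0] / out.D.iloc[1]
        assert abs(ratio - 2.0) < 0.2

    def test_isotropic_flat_in_angle(self, brownian_tracks):
        out = dyn.directional_diffusion(
            brownian_tracks, angles=np.linspace(0, np.pi, 7)[:-1],
            lags=np.arange(5, 60, 5), fit_window=(25.0, 300.0))
        assert out.D.std() / out.D.mean() < 0.05

    def test_too_few_points_in_window(self):
        msd = dyn.MSDCurve(dt_min=np.array([5.0]), values=np.array([1.0]),
                           counts=np.array([1]), variant="translational")
        with pytest.raises(ValueError):
            dyn.diffusion_coefficient(msd)


class TestScattering:
    def test_static_is_unity(self, static_tracks):
        fs = dyn.self_intermediate_scattering(static_tracks,
                                              lags=np.arange(1, 6))
        assert np.allclose(fs.Fs, 1.0)

    def test_brownian_gaussian_characteristic_function(self, brownian_tracks):
        fs = dyn.self_intermediate_scattering(
            brownian_tracks, q=np.array([0.05, 0.1, 0.2]),
            lags=np.arange(5, 60, 10), origin_stride=4)
        expected = np.exp(-0.025 * fs.q[:, None] ** 2 * fs.dt_min[None, :])
        assert np.max(np.abs(fs.Fs - expected)) < 0.01

    def test_fixed_length_random_direction_is_bessel(self):
        rng = np.random.default_rng(2)
        N, L = 4000, 7.0
        ang = rng.uniform(0, 2 * np.pi, N)
        pos = np.zeros((2, N, 2))
        pos[1] = L * np.column_stack([np.cos(ang), np.sin(ang)])
        pos += 100.0
        fs = dyn.self_intermediate_scattering(
            make_table(pos), q=np.array([0.1, 0.3, 0.6]), lags=np.array([1]),
            n_directions=24)
        assert np.allclose(fs.Fs[:, 0], special.j0(fs.q * L), atol=0.02)

    def test_stretched_fit_exact_recovery(self):
        t = np.geomspace(5, 2000, 40)
        q = np.array([0.05, 0.1])
        tau0 = np.array([400.0, 150.0])
        Fs = np.exp(-(t[None, :] / tau0[:, None]))
        ss = dyn.ScatteringSet(q=q, dt_min=t, Fs=Fs)
        ss = dyn.fit_stretched_exponential(ss)
        assert np.allclose(ss.fits["tau"], tau0, rtol=1e-4)
        assert np.allclose(ss.fits["beta"], 1.0, atol=1e-4)

    def test_brownian_tau_scales_as_q_minus_two(self, brownian_tracks):
        fs = dyn.self_intermediate_scattering(
            brownian_tracks, q=np.geomspace(0.15, 0.6, 8),
            lags=np.unique(np.geomspace(1, 110, 25).astype(int)),
            origin_stride=4)
        fs = dyn.fit_stretched_exponential(fs)
        ok = fs.fits["converged"]
        assert np.allclose(fs.fits.loc[ok, "beta"], 1.0, atol=0.1)
        assert abs(fs.tau_exponent - 2.0) < 0.1


class TestVanHove:
    def test_gaussian_alpha2_zero_and_normal_shape(self, brownian_tracks):
        vh = dyn.van_hove(brownian_tracks, lags=np.array([10, 30]))
        assert np.all(np.abs(vh.alpha2) < 0.05)
        x = vh.centers
        ref = np.exp(-x ** 2 / 2) / np.sqrt(2 * np.pi)
        assert np.max(np.abs(vh.pdfs[0] - ref)) < 0.02
        # each PDF integrates to one
        dx = np.diff(vh.bins)
        assert np.allclose((vh.pdfs * dx).sum(axis=1), 1.0, atol=0.01)

    def test_two_point_distribution_alpha2(self):
        # all displacements of identical magnitude ±L: α₂ = 1/3 − 1 = −2/3
        T, N, L = 2, 500, 3.0
        pos = np.zeros((T, N, 2))
        signs = np.where(np.arange(N) % 2 == 0, L, -L)
        pos[1, :, 0] = signs
        pos[1, :, 1] = -signs
        pos += 10.0
        vh = dyn.van_hove(make_table(pos), lags=np.array([1]))
        assert np.isclose(vh.alpha2[0], -2.0 / 3.0, atol=1e-12)

    def test_alpha2_consistent_with_binned_moments(self, trap_tracks):
        vh = dyn.van_hove(trap_tracks, lags=np.array([20]), bins=201,
                          extent=8.0)
        x = vh.centers
        dx = np.diff(vh.bins)
        m2 = (vh.pdfs[0] * x ** 2 * dx).sum()
        m4 = (vh.pdfs[0] * x ** 4 * dx).sum()
        alpha2_binned = m4 / (3 * m2 ** 2) - 1
        assert abs(alpha2_binned - vh.alpha2[0]) < 0.05


class TestGumbel:
    def test_normalization_constant(self):
        # A(1) = 1/(2(1−e⁻¹)) ≈ 0.791, and the density integrates to 1
        x = np.linspace(-40, 40, 40001)
        f = dyn.gumbel_displacement_pdf(x, 1.0)
        assert np.isclose(np.trapezoid(f, x), 1.0, atol=1e-6)
        assert np.isclose(dyn.gumbel_displacement_pdf(np.array([0.0]), 1.0)
                          / np.exp(-1.0), 1 / (2 * (1 - np.exp(-1))),
                          rtol=1e-12)

    def test_parameter_recovery_from_samples(self):
        rng = np.random.default_rng(9)
        # rejection-sample the ζ = 1 displacement Gumbel law
        prop = rng.laplace(0, 1.5, 400_000)
        envelope = (1.2 / 3.0) * np.exp(-np.abs(prop) / 1.5)
        accept = (rng.uniform(0, 1, prop.size)
                  < dyn.gumbel_displacement_pdf(prop, 1.0) / envelope)
        samp = prop[accept]
        hist, edges = np.histogram(samp, bins=81, range=(-6, 6),
                                   density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        out = dyn.fit_gumbel(centers, hist)
        assert abs(out["zeta"] - 1.0) < 0.05
        assert out["log_rms_residual"] < 0.1

    def test_gaussian_flagged_as_poor_fit(self):
        x = np.linspace(-5, 5, 101)
        gauss = np.exp(-x ** 2 / 2) / np.sqrt(2 * np.pi)
        out = dyn.fit_gumbel(x, gauss)
        assert out["log_rms_residual"] > 0.15


class TestAutocovariance:
    def test_straight_line_motion(self):
        T, N = 30, 8
        vel = np.array([0.3, 0.1])
        pos = np.arange(T)[:, None, None] * vel[None, None, :] \
            + np.arange(N)[None, :, None] * 10.0
        ac = dyn.displacement_autocovariance(make_table(pos), 5.0)
        assert np.allclose(ac.values, 1.0)

    def test_brownian_is_memoryless(self, brownian_tracks):
        ac = dyn.displacement_autocovariance(
            brownian_tracks, 5.0, lags=np.array([5.0, 25.0, 100.0]))
        se = 1.0 / np.sqrt(ac.counts.min())
        assert np.all(np.abs(ac.values) < 4 * se)

    def test_zero_steps_excluded_and_counted(self, static_tracks):
        ac = dyn.displacement_autocovariance(static_tracks, 5.0,
                                             lags=np.array([5.0]))
        assert ac.n_zero_steps > 0
        assert np.isnan(ac.values).all()


class TestConditionalSteps:
    def test_perfect_reversal_slope(self):
        # second step = −first step: ⟨d12∥⟩ = −d01, ⟨d12⊥⟩ = 0
        rng = np.random.default_rng(3)
        N, T = 2000, 3
        step = rng.normal(0, 1.5, (N, 2))
        pos = np.zeros((T, N, 2))
        pos[1] = step
        pos[2] = 0.0
        pos += 50.0
        ms = dyn.conditional_step_stats(make_table(pos), dt_step=5.0)
        # skip the lowest bins where the within-bin d01 density (∝ r)
        # shifts the conditional mean off the bin centre
        ok = (ms.counts > 20) & (ms.d01_centers > 1.0)
        assert np.allclose(ms.mean_par[ok], -ms.d01_centers[ok], rtol=0.05)
        assert np.all(np.abs(ms.mean_perp[ok]) < 0.05)
        assert ms.memory_slope() < -0.9

    def test_independent_steps_have_no_memory(self, brownian_tracks):
        ms = dyn.conditional_step_stats(brownian_tracks, dt_step=10.0)
        ok = ms.counts > 500
        sigma = np.sqrt(2 * 0.025 * 10.0)
        assert np.all(np.abs(ms.mean_par[ok]) < 0.1 * sigma)
        # FWHM of the Gaussian conditional equals 2√(2 ln 2)·σ per column
        expected = 2 * np.sqrt(2 * np.log(2)) * sigma
        assert np.allclose(ms.fwhm_par[ok], expected, rtol=0.1)
        assert np.allclose(ms.fwhm_perp[ok], expected, rtol=0.1)

    def test_trap_model_shows_anticorrelated_memory(self, trap_tracks):
        # for the creep generator the intracage (anticorrelated) component
        # dominates the step variance at bin times approaching τ_r; the
        # OU prediction for the slope at τ = 100 min is ≈ −0.08
        ms = dyn.conditional_step_stats(trap_tracks, dt_step=100.0)
        assert ms.memory_slope() < -0.04


class TestSelfOverlap:
    def test_static_cell_is_one(self, static_tracks):
        ov = dyn.self_overlap(static_tracks, a=1.2, dt_lag=50.0,
                              window=(0.0, 250.0))
        assert np.allclose(ov.Q, 1.0)

    def test_displacement_equal_to_a(self):
        # |Δr| = a every interval -> Q = e^(−1/2)
        T, N, a = 40, 6, 1.2
        drift = a / 10 * np.arange(T)  # moves a per 10 frames
        pos = np.zeros((T, N, 2))
        pos[:, :, 0] = drift[:, None] + np.arange(N)[None, :] * 5
        ov = dyn.self_overlap(make_table(pos), a=a, dt_lag=50.0,
                              window=(0.0, 150.0))
        assert np.allclose(ov.Q, np.exp(-0.5))

    def test_monotone_under_displacement_scaling(self, trap_tracks):
        _, _, pos = trap_tracks.position_array()
        base = pos[0]
        for lam in (1.0, 1.5, 3.0):
            scaled = base[None] + lam * (pos - base[None])
            ov = dyn.self_overlap(make_table(scaled), a=1.2, dt_lag=200.0,
                                  window=(105.0, 1400.0))
            if lam == 1.0:
                prev = ov.Q
            else:
                assert np.all(ov.Q <= prev + 1e-12)
                prev = ov.Q

    def test_window_shorter_than_lag_rejected(self, static_tracks):
        with pytest.raises(ValueError):
            dyn.self_overlap(static_tracks, a=1.2, dt_lag=100.0,
                             window=(0.0, 50.0))
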