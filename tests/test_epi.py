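import numpy as np
import pytest

from cvpgrad import GradientChainModel, ParameterError, apply_chain
from cvpgrad.constants import K_PER_MTM_US
from cvpgrad.epi import (circular_mask, design_epi, ghost_intensity,
                         integrate_trajectory, make_phantom, navigator_correct,
                         optimize_delay, reconstruct, simulate_epi_raw)
from cvpgrad.errors import TimingError
from cvpgrad.waveforms import Waveform, make_trapezoid

ROI1 = (1, 24, 5, 16)


@pytest.fixture(scope="module")
def geo():
    return design_epi(64, 200.0, 5.0, 100.0)


@pytest.fixture(scope="module")
def phantom():
    return make_phantom(64)


@pytest.fixture(scope="module")
def resonant_setup(geo, phantom):
    """Chain with resonance near the readout frequency + delay + asymmetry."""
    model = GradientChainModel(delay=3.0, lowpass_bandwidth=30.0,
                               resonance_terms=((0.004, 1.0, 3.0),),
                               sign_asymmetry=0.002)
    actual = apply_chain(geo.readout, model, tail_us=1000.0)
    traj_true = integrate_trajectory(actual, geo.adc_times, k_pe=geo.k_pe,
                                     nominal=geo.readout)
    ref_traj = integrate_trajectory(actual, geo.adc_times[:3],
                                    k_pe=np.zeros(3), nominal=geo.readout)
    raw = simulate_epi_raw(phantom, traj_true, 200.0, ref_traj=ref_traj,
                           dwell_adc=5.0)
    return model, actual, traj_true, raw


class TestTrajectory:
    def test_constant_gradient_gives_linear_k(self):
        g = 10.0
        wf = Waveform(np.full(501, g), dwell=1.0)
        adc = np.linspace(100.0, 400.0, 31)[None, :]
        traj = integrate_trajectory(wf, adc)
        slopes = np.diff(traj.k_ro[0]) / np.diff(adc[0])
        np.testing.assert_allclose(slopes, K_PER_MTM_US * g, rtol=1e-9)

    def test_nominal_train_has_centered_echoes(self, geo):
        traj = integrate_trajectory(geo.readout, geo.adc_times, k_pe=geo.k_pe)
        np.testing.assert_allclose(traj.echo_center_k, 0.0, atol=1e-6)

    def test_resonant_chain_alternating_center_shifts(self, geo, resonant_setup):
        _, _, traj_true, _ = resonant_setup
        centers = traj_true.echo_center_k[:10]
        # odd/even echo centers shifted against each other, oscillating
        assert np.all(np.sign(np.diff(centers)) == np.tile([1, -1], 5)[:9])

    def test_delay_equals_shifted_waveform_integration(self, geo):
        tau = 3.7
        t1 = integrate_trajectory(geo.readout, geo.adc_times, delay=tau,
                                  nominal=geo.readout)
        t2 = integrate_trajectory(geo.readout.shifted(tau), geo.adc_times,
                                  nominal=geo.readout)
        np.testing.assert_allclose(t2.k_ro, t1.k_ro, atol=1e-9)

    def test_adc_outside_support_rejected(self, geo):
        with pytest.raises(TimingError):
            integrate_trajectory(geo.readout, geo.adc_times,
                                 delay=geo.readout.duration)


class TestNavigator:
    def test_identical_references_give_zero_correction(self, geo, phantom):
        traj = integrate_trajectory(geo.readout, geo.adc_times, k_pe=geo.k_pe)
        refs = integrate_trajectory(geo.readout, geo.adc_times[:3],
                                    k_pe=np.zeros(3), nominal=geo.readout)
        raw = simulate_epi_raw(phantom, traj, 200.0, ref_traj=refs)
        out = navigator_correct(raw)
        assert abs(out.navigator_phase) < 1e-9
        np.testing.assert_allclose(out.echoes, raw.echoes)

    def test_injected_phase_recovered(self, geo, phantom):
        traj = integrate_trajectory(geo.readout, geo.adc_times, k_pe=geo.k_pe)
        refs = integrate_trajectory(geo.readout, geo.adc_times[:3],
                                    k_pe=np.zeros(3), nominal=geo.readout)
        raw = simulate_epi_raw(phantom, traj, 200.0, ref_traj=refs)
        phi0 = 0.4
        refs_mod = raw.reference_echoes.copy()
        refs_mod[1] *= np.exp(1j * phi0)
        from dataclasses import replace
        raw_mod = replace(raw, reference_echoes=refs_mod)
        out = navigator_correct(raw_mod)
        assert out.navigator_phase == pytest.approx(phi0, abs=1e-6)

    def test_idempotence(self, geo, phantom, resonant_setup):
        _, _, _, raw = resonant_setup
        once = navigator_correct(raw)
        # re-estimating on corrected references: apply the same correction to refs
        refs = once.reference_echoes.copy()
        refs[1] *= np.exp(-1j * once.navigator_phase)
        from dataclasses import replace
        twice = navigator_correct(replace(once, reference_echoes=refs))
        assert abs(twice.navigator_phase) < 1e-6

    def test_pure_noise_references_flagged(self, geo, phantom):
        traj = integrate_trajectory(geo.readout, geo.adc_times, k_pe=geo.k_pe)
        raw = simulate_epi_raw(phantom, traj, 200.0)
        rng = np.random.default_rng(0)
        from dataclasses import replace
        raw = replace(raw, reference_echoes=rng.standard_normal((3, 64, 1))
                      + 1j * rng.standard_normal((3, 64, 1)))
        out = navigator_correct(raw)
        assert not out.navigator_confident

    def test_zero_references_fail(self, geo, phantom):
        traj = integrate_trajectory(geo.readout, geo.adc_times, k_pe=geo.k_pe)
        raw = simulate_epi_raw(phantom, traj, 200.0)
        from dataclasses import replace
        raw = replace(raw, reference_echoes=np.zeros((3, 64, 1), dtype=complex))
        with pytest.raises(ParameterError):
            navigator_correct(raw)


class TestReconstruct:
    def test_dc_impulse_gives_flat_image(self, geo):
        traj = integrate_trajectory(geo.readout, geo.adc_times, k_pe=geo.k_pe)
        echoes = np.zeros((64, 64, 1), dtype=complex)
        # single unit sample on the central (k_pe = 0) line: |image| is flat
        echoes[32, 31, 0] = 1.0
        from cvpgrad.epi import EPIRawData
        raw = EPIRawData(echoes=echoes, reference_echoes=None, fov_mm=200.0,
                         matrix_size=64, dwell_adc=5.0, k_pe_nominal=geo.k_pe)
        img = reconstruct(raw, traj)
        assert img.std() / img.mean() < 0.05

    def test_exact_trajectory_recovers_phantom(self, geo, phantom):
        traj = integrate_trajectory(geo.readout, geo.adc_times, k_pe=geo.k_pe)
        raw = simulate_epi_raw(phantom, traj, 200.0)
        img = reconstruct(raw, traj)
        nrmse = (np.linalg.norm(img / img.max() - phantom / phantom.max())
                 / np.linalg.norm(phantom / phantom.max()))
        assert nrmse < 0.05

    def test_lsq_mode_at_least_as_accurate_as_adjoint(self, geo, phantom,
                                                      resonant_setup):
        _, _, traj_true, raw = resonant_setup
        ref = phantom / phantom.max()
        errs = {}
        for mode in ("adjoint", "lsq"):
            img = reconstruct(raw, traj_true, mode=mode)
            errs[mode] = np.linalg.norm(img / img.max() - ref)
        assert errs["lsq"] <= errs["adjoint"] * 1.05

    def test_ghost_appears_with_nominal_but_not_true_trajectory(
            self, geo, resonant_setup):
        _, _, traj_true, raw = resonant_setup
        traj_nom = integrate_trajectory(geo.readout, geo.adc_times,
                                        k_pe=geo.k_pe)
        g_nom = ghost_intensity(reconstruct(navigator_correct(raw), traj_nom),
                                ROI1).gamma
        with pytest.warns(UserWarning):
            g_true = ghost_intensity(reconstruct(raw, traj_true), ROI1).gamma
        assert g_true < g_nom

    def test_multicoil_root_sum_of_squares(self, geo, phantom):
        traj = integrate_trajectory(geo.readout, geo.adc_times, k_pe=geo.k_pe)
        n = 64
        yy = np.linspace(-1, 1, n)[:, None] * np.ones((1, n))
        sens = np.stack([1.0 + 0.5 * yy, 1.0 - 0.5 * yy])
        raw = simulate_epi_raw(phantom, traj, 200.0, coil_sens=sens)
        img = reconstruct(raw, traj)
        expected = phantom * np.sqrt(sens[0] ** 2 + sens[1] ** 2)
        nrmse = (np.linalg.norm(img / img.max() - expected / expected.max())
                 / np.linalg.norm(expected / expected.max()))
        assert nrmse < 0.05


class TestGhostIntensity:
    def test_zero_outside_object_gives_zero(self):
        img = np.zeros((64, 64))
        img[28:36, 28:36] = 1.0
        assert ghost_intensity(img, ROI1).gamma == 0.0

    def test_scaled_replica_at_half_fov(self):
        img = np.zeros((64, 64))
        img[30:36, 24:40] = 1.0  # object rows overlap ROI1 rows + 32
        alpha = 0.17
        img[ROI1[0]:ROI1[0] + ROI1[2], ROI1[1]:ROI1[1] + ROI1[3]] = alpha
        rep = ghost_intensity(img, ROI1)
        assert rep.gamma == pytest.approx(100.0 * alpha)
        assert rep.roi2[0] == ROI1[0] + 32

    def test_out_of_bounds_roi_rejected(self):
        with pytest.raises(ParameterError):
            ghost_intensity(np.ones((64, 64)), (60, 0, 10, 10))


class TestOptimizeDelay:
    def test_quartic_on_five_points_interpolates(self, geo, phantom):
        # degenerate scan: 5 points exactly determine the quartic
        traj = integrate_trajectory(geo.readout, geo.adc_times, k_pe=geo.k_pe)
        raw = simulate_epi_raw(phantom, traj, 200.0)
        rep = optimize_delay(raw, geo.readout, geo.adc_times,
                             delay_grid=np.linspace(-1.0, 1.0, 5),
                             nominal=geo.readout)
        resid = (np.polyval(rep.polynomial_coeffs, rep.delay_scan[:, 0])
                 - rep.delay_scan[:, 1])
        assert np.abs(resid).max() < 1e-9 * np.abs(rep.delay_scan[:, 1]).max()

    def test_injected_delay_recovered(self, geo, phantom):
        tau = 2.3
        actual = apply_chain(geo.readout, GradientChainModel(delay=tau),
                             tail_us=500.0)
        traj = integrate_trajectory(actual, geo.adc_times, k_pe=geo.k_pe,
                                    nominal=geo.readout)
        raw = simulate_epi_raw(phantom, traj, 200.0)
        rep = optimize_delay(raw, geo.readout, geo.adc_times,
                             delay_grid=np.arange(-2.0, 7.0, 0.5),
                             nominal=geo.readout, fit_window=9)
        assert rep.optimal_delay == pytest.approx(tau, abs=0.1)

    def test_optimum_stable_to_grid_point_removal(self, geo, phantom):
        tau = 1.4
        actual = apply_chain(geo.readout, GradientChainModel(delay=tau),
                             tail_us=500.0)
        traj = integrate_trajectory(actual, geo.adc_times, k_pe=geo.k_pe,
                                    nominal=geo.readout)
        raw = simulate_epi_raw(phantom, traj, 200.0)
        grid = np.arange(-1.0, 4.0, 0.5)
        base = optimize_delay(raw, geo.readout, geo.adc_times, delay_grid=grid,
                              nominal=geo.readout).optimal_delay
        for drop in (0, grid.size - 1):
            trimmed = np.delete(grid, drop)
            alt = optimize_delay(raw, geo.readout, geo.adc_times,
                                 delay_grid=trimmed,
                                 nominal=geo.readout).optimal_delay
            assert abs(alt - base) < 0.05
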