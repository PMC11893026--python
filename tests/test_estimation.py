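import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvpgrad import (GradientChainModel, ParameterError, SliceSet,
                     estimate_waveform, extract_frequency, median_filter_time,
                     simulate_fid, solve_weighted_ls)
from cvpgrad.constants import HZ_PER_MTM_MM
from cvpgrad.errors import StructureError
from cvpgrad.estimation import FrequencySeries, assemble_design
from cvpgrad.simulate import simulated_test_gradient


def _series(values, weights=None, dwell=5.0, method="vp", steps=(1, 2)):
    values = np.asarray(values, dtype=float)
    weights = (np.ones_like(values) if weights is None
               else np.asarray(weights, dtype=float))
    times = dwell * np.arange(values.shape[-1])
    return FrequencySeries(values=values, weights=weights, dwell=dwell,
                           times=times, scheme_method=method, steps=steps)


class TestExtractFrequency:
    def test_pure_tone_recovered(self, cvp_data_ideal):
        from dataclasses import replace

        f0, dwell = 100.0, 5.0
        t = dwell * 1e-6 * np.arange(400)
        tone = np.exp(2j * np.pi * f0 * t)
        data = replace(cvp_data_ideal,
                       signal=np.broadcast_to(
                           tone, (*cvp_data_ideal.signal.shape[:3], 400)).copy(),
                       dwell=dwell)
        freq = extract_frequency(data)
        np.testing.assert_allclose(freq.values[..., 1:-1], f0, atol=1e-6)
        np.testing.assert_allclose(freq.weights, 1.0)

    def test_conjugate_negates_frequency(self, cvp_data_ideal):
        from dataclasses import replace

        f = extract_frequency(cvp_data_ideal)
        f_conj = extract_frequency(replace(cvp_data_ideal,
                                           signal=np.conj(cvp_data_ideal.signal)))
        np.testing.assert_allclose(f_conj.values, -f.values, atol=1e-9)

    def test_constant_gradient_forward_oracle(self):
        # simulated FID at slice r under a constant plateau: f = 42.577*G*r
        from tests_helpers import constant_plateau_dataset

        data, g_plateau, r = constant_plateau_dataset()
        freq = extract_frequency(data)
        t = data.times - data.scheme.readout_start
        sel = (t > 150.0) & (t < 350.0)
        np.testing.assert_allclose(freq.values[0, 0, 0, sel],
                                   HZ_PER_MTM_MM * g_plateau * r, rtol=2e-3)


class TestMedianFilter:
    def test_length_one_is_identity(self):
        f = _series(np.random.default_rng(0).normal(size=(1, 2, 1, 30)))
        out = median_filter_time(f, 1)
        np.testing.assert_array_equal(out.values, f.values)

    def test_spike_removed_with_shrinking_edges(self):
        f = _series(np.array([1.0, 100.0, 1.0, 1.0])[None, None, None, :])
        out = median_filter_time(f, 3)
        np.testing.assert_array_equal(out.values.ravel(), [1.0, 1.0, 1.0, 1.0])

    def test_monotone_interior_unchanged(self):
        x = np.linspace(0.0, 1.0, 20)[None, None, None, :]
        out = median_filter_time(_series(x), 3)
        np.testing.assert_array_equal(out.values[..., 1:-1], x[..., 1:-1])

    def test_even_length_rejected(self):
        with pytest.raises(ParameterError):
            median_filter_time(_series(np.zeros((1, 2, 1, 5))), 4)


class TestDesignMatrices:
    def test_vp_block_structure_and_shape(self):
        slices = SliceSet(np.array([-10.0, 10.0]), 3.0)
        dm = assemble_design("vp", "vp", slices, n_pre=2)
        assert dm.A.shape == (8, 4)  # N*2 steps*M rows; [d(2), qI(2)] cols
        # step-2 rows carry no P block
        np.testing.assert_array_equal(dm.A[4:, :2], 0.0)
        np.testing.assert_array_equal(dm.A[:4, 1],
                                      HZ_PER_MTM_MM * np.array([-10, 10, -10, 10]))

    def test_cvp_unknown_count(self):
        slices = SliceSet(np.array([-10.0, 10.0]), 3.0)
        dm = assemble_design("cvp", "cvp", slices, n_pre=1)
        assert dm.A.shape == (8, 8)  # [d(2), d_vp1(2), qI(2), qII(2)]
        assert np.linalg.matrix_rank(dm.A) == 8

    def test_fcvp_full_column_rank(self):
        slices = SliceSet(np.array([-10.0, 0.0, 10.0]), 3.0)
        dm = assemble_design("fcvp", "fcvp", slices, n_pre=2)
        assert dm.A.shape == (4 * 2 * 3, 2 + 4 + 2 * 3 + 2 * 3)
        assert np.linalg.matrix_rank(dm.A) == dm.A.shape[1]

    def test_equal_slice_positions_rank_deficient(self):
        slices = SliceSet.__new__(SliceSet)  # bypass distinctness guard
        slices.positions = np.array([10.0, 10.0])
        slices.thickness = 3.0
        dm = assemble_design("vp", "vp", slices, n_pre=2)
        assert np.linalg.matrix_rank(dm.A) < dm.A.shape[1]
        b, cond = solve_weighted_ls(dm.A, np.zeros(8), np.ones(8))
        assert cond == np.inf

    def test_method_scheme_mismatch_rejected(self):
        slices = SliceSet(np.array([-10.0, 10.0]), 3.0)
        with pytest.raises(StructureError):
            assemble_design("vp", "cvp", slices, n_pre=2)
        with pytest.raises(StructureError):
            assemble_design("cvp", "fcvp", slices, n_pre=2)


class TestWeightedLeastSquares:
    def test_identity_design_returns_observations(self):
        f = np.array([1.0, -2.0, 3.0])
        b, _ = solve_weighted_ls(np.eye(3), f, np.array([0.5, 2.0, 1.0]))
        np.testing.assert_allclose(b, f, atol=1e-12)

    def test_zero_weight_row_is_inert(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(4, 2))
        f = rng.normal(size=4)
        a_dup = np.vstack([a, a[-1]])
        f_dup = np.append(f, 999.0)
        w = np.array([1.0, 2.0, 0.7, 1.5])
        w_dup = np.append(w, 0.0)
        b1, _ = solve_weighted_ls(a, f, w)
        b2, _ = solve_weighted_ls(a_dup, f_dup, w_dup)
        np.testing.assert_allclose(b2, b1, atol=1e-12)

    def test_all_zero_weights_yield_nan(self):
        b, cond = solve_weighted_ls(np.eye(3), np.ones(3), np.zeros(3))
        assert np.isnan(b).all() and cond == np.inf

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_explicit_normal_equation_formula(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.integers(6, 13)
        cols = rng.integers(2, min(rows, 6))
        a = rng.normal(size=(rows, cols))
        f = rng.normal(size=rows)
        w = rng.uniform(0.1, 3.0, size=rows)
        b, _ = solve_weighted_ls(a, f, w)
        sigma_inv = np.diag(w ** 2)
        expected = np.linalg.solve(a.T @ sigma_inv @ a, a.T @ sigma_inv @ f)
        np.testing.assert_allclose(b, expected, rtol=1e-10, atol=1e-12)


class TestEstimateWaveform:
    def test_all_methods_recover_chain_output(self, cvp_data_ideal, cvp_scheme,
                                              ideal_model, trapezoid_test,
                                              slice_select, slices9):
        from cvpgrad import build_scheme, simulate_fid

        truth = simulated_test_gradient(cvp_scheme, ideal_model, dwell=2.0)
        peak = np.abs(truth).max()
        for method in ("vp", "cvp"):
            fc = estimate_waveform(cvp_data_ideal, method)
            err = np.nanmax(np.abs(fc.g[2:-2] - truth[2:-2]))
            assert err < 1e-3 * peak, method
        ss, exc = slice_select
        schf = build_scheme("fcvp", trapezoid_test,
                            cvp_scheme.prephaser_amplitudes, ss, exc,
                            readout_duration=1500.0)
        dataf = simulate_fid(schf, ideal_model, slices9, dwell=2.0)
        fc = estimate_waveform(dataf, "fcvp")
        assert np.nanmax(np.abs(fc.g[2:-2] - truth[2:-2])) < 1e-3 * peak

    def test_invalid_time_points_reported_as_nan(self, cvp_data_ideal):
        from dataclasses import replace

        sig = cvp_data_ideal.signal.copy()
        sig[..., 7] = 0.0
        data = replace(cvp_data_ideal, signal=sig)
        fc = estimate_waveform(data, "cvp", filter_length=1)
        assert not fc.valid[7] and np.isnan(fc.g[7])
        assert fc.valid[8] and np.isfinite(fc.g[8])
        # opt-in gap filling is explicit, linear, and keeps the mask
        from cvpgrad.estimation import interpolate_invalid

        filled = interpolate_invalid(fc)
        assert np.isfinite(filled.g[7])
        assert filled.g[7] == pytest.approx((fc.g[6] + fc.g[8]) / 2.0)
        assert not filled.valid[7]

    def test_noise_scaling_of_estimator_std(self, cvp_scheme, ideal_model):
        # std(G_hat) at a fixed t scales linearly with noise_sigma
        slices = SliceSet(np.array([-20.0, -10.0, 10.0, 20.0]), 3.0)
        stds = []
        for sigma in (0.005, 0.01):
            g_t = []
            for rep in range(24):
                data = simulate_fid(cvp_scheme, ideal_model, slices, dwell=20.0,
                                    noise_sigma=sigma, seed=1000 + rep,
                                    intra_slice_points=8)
                g_t.append(estimate_waveform(data, "vp", filter_length=1).g[30])
            stds.append(np.std(g_t))
        ratio = stds[1] / stds[0]
        assert 1.4 < ratio < 2.8  # 2.0 within Monte-Carlo error
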