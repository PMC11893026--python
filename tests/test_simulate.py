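import numpy as np
import pytest

from cvpgrad import (GradientChainModel, ParameterError, SliceSet,
                     build_scheme, choose_prephasers, make_slice_select,
                     make_trapezoid, simulate_fid)
from cvpgrad.constants import HZ_PER_MTM_MM


def small_scheme(method="vp", n_pre=2, readout=600.0, test_amp=10.0):
    test = make_trapezoid(test_amp, 100.0, 300.0, 1.0)
    ss, exc = make_slice_select(6.0, 100.0, 300.0, 1.0)
    amps = choose_prephasers(test, n_pre)
    return build_scheme(method, test, amps, ss, exc, readout_duration=readout)


class TestNullAndClosedFormPhysics:
    def test_null_physics_gives_unit_signal_zero_phase(self):
        test = make_trapezoid(0.0, 100.0, 300.0, 1.0)
        ss, _ = make_slice_select(0.0, 100.0, 300.0, 1.0)
        sch = build_scheme("vp", test, [0.0, 0.0], ss, 250.0,
                           readout_duration=400.0)
        data = simulate_fid(sch, GradientChainModel(),
                            SliceSet(np.array([0.0, 10.0]), 3.0), dwell=2.0)
        np.testing.assert_allclose(data.signal, 1.0 + 0j, atol=1e-12)

    def test_constant_gradient_fid_frequency_closed_form(self):
        # thin slice at r=10mm, constant-ish plateau: frequency = 42.577*G*r Hz
        sch = small_scheme("vp", 2, readout=380.0)
        slices = SliceSet(np.array([10.0, -10.0]), 0.01)  # near-zero thickness
        data = simulate_fid(sch, GradientChainModel(), slices, dwell=1.0,
                            intra_slice_points=1)
        t = data.times - sch.readout_start
        plateau = (t > 120.0) & (t < 360.0)
        phase = np.unwrap(np.angle(data.signal[0, 0, 0]))
        freq = np.gradient(phase, 1e-6) / (2 * np.pi)
        expected = HZ_PER_MTM_MM * 10.0 * 10.0
        np.testing.assert_allclose(freq[plateau], expected, rtol=1e-3)

    def test_rephasing_maximum_at_moment_cancellation(self):
        sch = small_scheme("vp", 4)
        slices = SliceSet(np.array([30.0, 40.0]), 5.0)
        data = simulate_fid(sch, GradientChainModel(), slices, dwell=1.0)
        t = data.times - sch.readout_start
        cum = np.interp(t, sch.test_waveform.times - sch.test_waveform.t0,
                        sch.test_waveform.cumulative_moment())
        for n in (1, 2):  # interior prephasers rephase mid-waveform
            pre_moment = (sch.prephaser_amplitudes[n]
                          * sch.prephaser_shape.moment())
            t_expected = t[np.argmin(np.abs(cum + pre_moment))]
            t_max = t[np.argmax(np.abs(data.signal[n, 0, 0]))]
            assert abs(t_max - t_expected) <= 2 * data.dwell


class TestSymmetries:
    def test_oddness_negated_gradients_negate_phases(self):
        sch = small_scheme("cvp", 2)
        neg = small_scheme("cvp", 2, test_amp=-10.0)
        neg.prephaser_amplitudes = -sch.prephaser_amplitudes
        # also negate the slice-select event
        neg.slice_select_waveform = neg.slice_select_waveform.scaled(-1.0)
        slices = SliceSet(np.array([-15.0, 20.0]), 3.0)
        model = GradientChainModel(delay=2.0, lowpass_bandwidth=20.0,
                                   resonance_terms=((0.01, 1.0, 2.0),))
        a = simulate_fid(sch, model, slices, dwell=2.0)
        b = simulate_fid(neg, model, slices, dwell=2.0)
        np.testing.assert_array_equal(b.signal, np.conj(a.signal))

    def test_concomitant_phase_invariant_under_sign_inversion(self):
        slices = SliceSet(np.array([-15.0, 20.0]), 3.0)
        base = dict(delay=0.0, lowpass_bandwidth=20.0)
        m_conc = GradientChainModel(**base, kappa0=0.1, kappa1=50.0)
        m_lin = GradientChainModel(**base)
        sch = small_scheme("cvp", 2)
        neg = small_scheme("cvp", 2, test_amp=-10.0)
        neg.prephaser_amplitudes = -sch.prephaser_amplitudes
        neg.slice_select_waveform = neg.slice_select_waveform.scaled(-1.0)
        # c-contribution = phase(model with kappa) - phase(linear model),
        # formed wrap-free as the angle of the signal ratio
        c_pos = np.angle(simulate_fid(sch, m_conc, slices, dwell=2.0).signal
                         * np.conj(simulate_fid(sch, m_lin, slices,
                                                dwell=2.0).signal))
        c_neg = np.angle(simulate_fid(neg, m_conc, slices, dwell=2.0).signal
                         * np.conj(simulate_fid(neg, m_lin, slices,
                                                dwell=2.0).signal))
        np.testing.assert_allclose(c_neg, c_pos, atol=1e-9)

    def test_magnitude_argmax_monotone_in_prephaser_amplitude(self):
        sch = small_scheme("vp", 5)
        slices = SliceSet(np.array([30.0, 40.0]), 5.0)
        data = simulate_fid(sch, GradientChainModel(), slices, dwell=1.0)
        argmaxes = [int(np.argmax(np.abs(data.signal[n, 0, 0])))
                    for n in range(5)]
        assert all(a <= b for a, b in zip(argmaxes, argmaxes[1:]))


class TestReproducibility:
    def test_identical_seeds_bit_identical(self):
        sch = small_scheme("vp", 2)
        slices = SliceSet(np.array([10.0, 20.0]), 3.0)
        kw = dict(dwell=2.0, noise_sigma=0.01, seed=123)
        a = simulate_fid(sch, GradientChainModel(), slices, **kw)
        b = simulate_fid(sch, GradientChainModel(), slices, **kw)
        np.testing.assert_array_equal(a.signal, b.signal)

    def test_noise_without_seed_rejected(self):
        sch = small_scheme("vp", 2)
        slices = SliceSet(np.array([10.0, 20.0]), 3.0)
        with pytest.raises(ParameterError):
            simulate_fid(sch, GradientChainModel(), slices, dwell=2.0,
                         noise_sigma=0.01)
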