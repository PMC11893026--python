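import numpy as np
import pytest

from cvpgrad import (GradientChainModel, ParameterError, Waveform, apply_chain,
                     estimate_gstf, make_triangle_set, make_trapezoid,
                     predict_waveform)


@pytest.fixture(scope="module")
def triangles():
    return make_triangle_set(12, 20.0, 5.0, 80.0, 300.0)


@pytest.fixture(scope="module")
def ringing_model():
    return GradientChainModel(delay=3.0, lowpass_bandwidth=20.0,
                              eddy_terms=((0.01, 1.5),),
                              resonance_terms=((0.004, 1.2, 2.5),))


@pytest.fixture(scope="module")
def ringing_gstf(triangles, ringing_model):
    measured = [apply_chain(t, ringing_model, tail_us=4000.0) for t in triangles]
    return estimate_gstf(triangles, measured, regularization=1e-6)


class TestEstimateGstf:
    def test_identity_chain_gives_unit_transfer_in_band(self, triangles):
        gstf = estimate_gstf(triangles, triangles, regularization=1e-6)
        band = np.abs(gstf.freq) < 2.0  # kHz, where the triangles carry energy
        assert np.abs(gstf.H[band] - 1.0).max() < 1e-3

    def test_pure_delay_gives_linear_phase(self, triangles):
        model = GradientChainModel(delay=5.0)
        measured = [apply_chain(t, model, tail_us=1000.0) for t in triangles]
        gstf = estimate_gstf(triangles, measured)
        band = (np.abs(gstf.freq) > 0.05) & (np.abs(gstf.freq) < 2.0)
        tau_us = -np.angle(gstf.H[band]) / (2 * np.pi * gstf.freq[band] * 1e3) * 1e6
        np.testing.assert_allclose(tau_us, 5.0, rtol=0.01)

    def test_resonance_appears_as_magnitude_peak_at_model_frequency(
            self, ringing_gstf):
        pos = ringing_gstf.freq > 0.3
        f_peak = ringing_gstf.freq[pos][np.argmax(np.abs(ringing_gstf.H[pos]))]
        df = np.diff(ringing_gstf.freq)[0]
        assert abs(f_peak - 1.2) <= df

    def test_hermitian_symmetry(self, ringing_gstf):
        assert ringing_gstf.hermitian_error() < 1e-12

    def test_all_zero_inputs_rejected(self):
        zeros = [Waveform(np.zeros(100), 5.0)]
        with pytest.raises(ParameterError):
            estimate_gstf(zeros, zeros)


class TestPredictWaveform:
    def test_unit_transfer_is_identity(self, triangles):
        gstf = estimate_gstf(triangles, triangles)
        trap = make_trapezoid(10.0, 200.0, 400.0, 5.0)
        pred = predict_waveform(trap, gstf)
        n = trap.samples.size
        # band-limited identity: small ripple at the sharp corners is allowed
        assert np.abs(pred.samples[:n] - trap.samples).max() < 0.02 * 10.0

    def test_extra_delay_shifts_prediction(self, triangles):
        gstf = estimate_gstf(triangles, triangles)
        trap = make_trapezoid(10.0, 200.0, 400.0, 5.0)
        base = predict_waveform(trap, gstf)
        delayed = predict_waveform(trap, gstf, extra_delay=25.0)
        shifted = np.interp(base.times, base.times + 25.0, base.samples,
                            left=0.0, right=0.0)
        mid = slice(10, base.samples.size - 10)
        assert np.abs(delayed.samples[mid] - shifted[mid]).max() < 0.02 * 10.0

    def test_round_trip_matches_chain_output(self, ringing_gstf, ringing_model):
        trap = make_trapezoid(25.0, 200.0, 500.0, 5.0)
        pred = predict_waveform(trap, ringing_gstf)
        truth = apply_chain(trap, ringing_model, tail_us=900.0)
        n = min(pred.samples.size, truth.samples.size)
        err = np.abs(pred.samples[:n] - truth.samples[:n]).max()
        assert err < 0.01 * np.abs(truth.samples).max()

    def test_linearity(self, ringing_gstf):
        w1 = make_trapezoid(10.0, 200.0, 400.0, 5.0)
        w2 = make_trapezoid(-7.0, 150.0, 450.0, 5.0)
        n = min(w1.samples.size, w2.samples.size)
        combo = Waveform(3.0 * w1.samples[:n] - 2.0 * w2.samples[:n], 5.0)
        p_combo = predict_waveform(combo, ringing_gstf)
        p1 = predict_waveform(Waveform(w1.samples[:n], 5.0), ringing_gstf)
        p2 = predict_waveform(Waveform(w2.samples[:n], 5.0), ringing_gstf)
        np.testing.assert_allclose(p_combo.samples,
                                   3.0 * p1.samples - 2.0 * p2.samples,
                                   atol=1e-10)

    def test_prediction_is_real_valued_and_resamplable(self, ringing_gstf):
        trap = make_trapezoid(10.0, 200.0, 400.0, 5.0)
        pred = predict_waveform(trap, ringing_gstf, output_dwell=2.5)
        assert pred.dwell == 2.5
        assert np.isrealobj(pred.samples)
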