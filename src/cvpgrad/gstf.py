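"""Gradient system transfer function (GSTF) estimation and prediction.

The GSTF is the frequency-domain linear response of the gradient chain.  It
is estimated from pairs of nominal and measured probing waveforms (typically
triangles with staggered flat-top durations so their spectral zeros do not
coincide) and used to predict the delivered waveform for an arbitrary
nominal input by spectral multiplication.

The stacked convolution model ``measured_i = h * nominal_i`` is solved for
the impulse response with Tikhonov regularization.  The DFT diagonalizes the
(circulant-embedded) stacked system, so the regularized solution is computed
per frequency bin as

    H(f) = sum_i X_i*(f) Y_i(f) / (sum_i |X_i(f)|^2 + lambda)

which is then the Fourier transform of the regularized impulse response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import resample

from .errors import ParameterError
from .waveforms import Waveform


@dataclass
class GSTFSpectrum:
    """Complex self-term transfer function on a uniform frequency grid.

    ``freq`` is in kHz, centered on 0 (odd length, symmetric grid).
    ``delay_correction`` (us) is an additive linear-phase delay applied at
    prediction time; it absorbs dwell-time differences between the grids the
    GSTF and the nominal waveforms live on.
    """

    H: np.ndarray
    freq: np.ndarray  # kHz, ascending, symmetric about 0
    dwell_native: float  # us
    delay_correction: float = 0.0

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=complex)
        self.freq = np.asarray(self.freq, dtype=float)
        if self.H.shape != self.freq.shape:
            raise ParameterError("H and freq must share a shape")
        if not np.isfinite(self.H).all():
            raise ParameterError("H must be finite")
        df = np.diff(self.freq)
        if self.freq.size > 1 and not np.allclose(df, df[0]):
            raise ParameterError("freq grid must be uniform")

    @property
    def max_freq(self) -> float:
        """Highest represented frequency, kHz."""
        return float(self.freq.max())

    def hermitian_error(self) -> float:
        """Max |H(-f) - conj(H(f))|; 0 for a real impulse response."""
        return float(np.abs(self.H[::-1] - np.conj(self.H)).max())


def estimate_gstf(nominal: list[Waveform], measured: list[Waveform],
                  regularization: float = 1e-6,
                  delay_correction: float = 0.0) -> GSTFSpectrum:
    """Estimate the GSTF from nominal/measured waveform pairs.

    All waveforms must share one dwell.  ``regularization`` is the Tikhonov
    weight relative to the peak stacked input power (a small positive number;
    it biases |H| toward 0 where the probing inputs carry no energy).
    """
    if len(nominal) == 0 or len(nominal) != len(measured):
        raise ParameterError("need matching, non-empty nominal/measured lists")
    dwell = nominal[0].dwell
    for wf in (*nominal, *measured):
        if wf.dwell != dwell:
            raise ParameterError("all waveforms must share one dwell")
    if regularization < 0:
        raise ParameterError("regularization must be >= 0")

    max_len = max(max(w.samples.size for w in nominal),
                  max(w.samples.size for w in measured))
    n_fft = 2 * max_len + 1  # odd -> symmetric frequency grid

    num = np.zeros(n_fft, dtype=complex)
    den = np.zeros(n_fft)
    for x_wf, y_wf in zip(nominal, measured):
        x = np.fft.fft(x_wf.samples, n_fft)
        y = np.fft.fft(y_wf.samples, n_fft)
        # Relative timing of the pair enters as a linear phase.
        shift = (y_wf.t0 - x_wf.t0) * 1e-6
        if shift:
            f_hz = np.fft.fftfreq(n_fft, d=dwell * 1e-6)
            y = y * np.exp(2j * np.pi * f_hz * shift)
        num += np.conj(x) * y
        den += np.abs(x) ** 2
    if den.max() == 0.0:
        raise ParameterError("all nominal inputs are zero; system is singular")
    lam = regularization * den.max()
    h = num / (den + lam)

    freq_khz = np.fft.fftshift(np.fft.fftfreq(n_fft, d=dwell * 1e-6)) * 1e-3
    return GSTFSpectrum(H=np.fft.fftshift(h), freq=freq_khz,
                        dwell_native=dwell, delay_correction=delay_correction)


def predict_waveform(nominal: Waveform, gstf: GSTFSpectrum,
                     extra_delay: float = 0.0,
                     output_dwell: float | None = None,
                     pad_factor: int = 4) -> Waveform:
    """Predict the delivered waveform: multiply the nominal spectrum by the
    GSTF and transform back.

    The nominal waveform is zero-padded in time (band-limited grid handling —
    no polynomial interpolation between time grids), the GSTF is linearly
    interpolated onto the resulting frequency grid, and frequencies beyond
    the GSTF support are set to zero (the prediction is band-limited to the
    measured response).  ``extra_delay`` (us) plus the spectrum's own
    ``delay_correction`` are applied as a linear phase ramp.
    """
    if pad_factor < 1:
        raise ParameterError("pad_factor must be >= 1")
    n = nominal.samples.size * pad_factor
    f_hz = np.fft.fftfreq(n, d=nominal.dwell * 1e-6)
    spec = np.fft.fft(nominal.samples, n)

    f_khz = f_hz * 1e-3
    h_re = np.interp(f_khz, gstf.freq, gstf.H.real, left=0.0, right=0.0)
    h_im = np.interp(f_khz, gstf.freq, gstf.H.imag, left=0.0, right=0.0)
    h = h_re + 1j * h_im
    h[np.abs(f_khz) > gstf.max_freq] = 0.0

    tau_s = (gstf.delay_correction + extra_delay) * 1e-6
    spec = spec * h * np.exp(-2j * np.pi * f_hz * tau_s)
    out = np.fft.ifft(spec).real[: nominal.samples.size * 2]

    dwell = nominal.dwell
    if output_dwell is not None and output_dwell != nominal.dwell:
        n_out = int(round(out.size * nominal.dwell / output_dwell))
        out = resample(out, n_out)  # Fourier-domain resampling
        dwell = output_dwell
    return Waveform(out, dwell=dwell, t0=nominal.t0,
                    axis_label=nominal.axis_label)


def make_triangle_set(n_triangles: int, amplitude: float, dwell: float,
                      ramp_min: float = 80.0, ramp_max: float = 300.0,
                      ) -> list[Waveform]:
    """Triangular probing gradients with staggered ramp durations.

    Staggering moves the spectral zeros of each triangle so the set jointly
    covers the band without gaps.
    """
    from .waveforms import make_trapezoid

    if n_triangles < 1:
        raise ParameterError("need at least one triangle")
    ramps = np.linspace(ramp_min, ramp_max, n_triangles)
    out = []
    for r in ramps:
        r = max(dwell, round(r / dwell) * dwell)
        out.append(make_trapezoid(amplitude, r, 0.0, dwell))
    return out
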