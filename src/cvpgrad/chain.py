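"""Parametric gradient-chain model and its application to nominal waveforms.

The chain is a linear time-invariant (LTI) system — transport delay,
first-order amplifier/coil low-pass, eddy-current high-pass terms and damped
mechanical-resonance terms — optionally followed by a memoryless
sign-asymmetric gain emulating gradient-amplifier nonlinearity.  A set of
eddy terms coupling the gradient axis into the main field generates a
spatially constant frequency offset dB0(t), and a quadratic concomitant-field
coefficient maps the squared output gradient to a frequency offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .waveforms import Waveform


@dataclass
class GradientChainModel:
    """Physical model of one gradient axis.

    Parameters
    ----------
    delay:
        Pure transport delay, us.
    lowpass_bandwidth:
        -3 dB bandwidth of the first-order amplifier/coil response, kHz.
        ``None`` or ``inf`` disables the low-pass.
    eddy_terms:
        Sequence of ``(amplitude, time_constant_ms)``: each term subtracts
        ``amplitude`` times a first-order high-pass of the input (classic
        eddy-current droop).  Amplitudes are dimensionless fractions.
    resonance_terms:
        Sequence of ``(amplitude, frequency_khz, damping_time_ms)``: damped
        mechanical-resonance oscillations excited by the input slew.
    sign_asymmetry:
        Relative gain difference between positive and negative output values:
        positive samples are scaled by ``1 + a/2``, negative by ``1 - a/2``.
        0 means an odd-symmetric (sign-symmetric) chain.
    kappa0, kappa1:
        Concomitant-field model ``c(r, t) = kappa0 * (1 + kappa1 * r) * G_out(t)**2``
        with ``kappa0`` in Hz/(mT/m)^2 and ``kappa1`` in 1/m (``r`` in m).
        The quadratic amplitude dependence makes ``c`` invariant under sign
        inversion of the gradient, which is what the FCVP subtraction exploits.
    b0_eddy_terms:
        Sequence of ``(amplitude_hz_per_mtm, time_constant_ms)`` generating a
        spatially constant frequency offset dB0(t) as a high-pass response to
        the commanded gradient.
    """

    delay: float = 0.0
    lowpass_bandwidth: float | None = None
    eddy_terms: tuple = ()
    resonance_terms: tuple = ()
    sign_asymmetry: float = 0.0
    kappa0: float = 0.0
    kappa1: float = 0.0
    b0_eddy_terms: tuple = ()

    def __post_init__(self) -> None:
        for amp, tau in self.eddy_terms:
            if not (tau > 0):
                raise ParameterError(f"eddy time constant must be > 0, got {tau}")
        for amp, f0, tau in self.resonance_terms:
            if not (tau > 0):
                raise ParameterError(f"resonance damping time must be > 0, got {tau}")
            if not (f0 > 0):
                raise ParameterError(f"resonance frequency must be > 0, got {f0}")
        for amp, tau in self.b0_eddy_terms:
            if not (tau > 0):
                raise ParameterError(f"B0 eddy time constant must be > 0, got {tau}")
        if self.lowpass_bandwidth is not None and not (self.lowpass_bandwidth > 0):
            raise ParameterError("lowpass_bandwidth must be positive or None")

    # -- frequency responses -------------------------------------------
    def transfer(self, freq_hz: np.ndarray, include_delay: bool = True) -> np.ndarray:
        """Complex LTI transfer function (dimensionless) at ``freq_hz``."""
        f = np.asarray(freq_hz, dtype=float)
        w = 2.0 * np.pi * f
        h = np.ones_like(f, dtype=complex)
        if include_delay and self.delay != 0.0:
            h *= np.exp(-1j * w * self.delay * 1e-6)
        if self.lowpass_bandwidth is not None and np.isfinite(self.lowpass_bandwidth):
            h /= 1.0 + 1j * f / (self.lowpass_bandwidth * 1e3)
        extra = np.zeros_like(f, dtype=complex)
        for amp, tau_ms in self.eddy_terms:
            tau = tau_ms * 1e-3
            extra += -amp * (1j * w * tau) / (1.0 + 1j * w * tau)
        for amp, f0_khz, tau_ms in self.resonance_terms:
            w0 = 2.0 * np.pi * f0_khz * 1e3
            tau = tau_ms * 1e-3
            # FT of sin(w0 t) exp(-t/tau) u(t), times i*w: excited by the slew,
            # transparent at DC.
            extra += amp * (1j * w) * w0 / ((1.0 / tau + 1j * w) ** 2 + w0 ** 2)
        h *= 1.0 + extra
        return h

    def b0_transfer(self, freq_hz: np.ndarray) -> np.ndarray:
        """Transfer from commanded gradient (mT/m) to dB0 (Hz)."""
        f = np.asarray(freq_hz, dtype=float)
        w = 2.0 * np.pi * f
        h = np.zeros_like(f, dtype=complex)
        for amp, tau_ms in self.b0_eddy_terms:
            tau = tau_ms * 1e-3
            h += amp * (1j * w * tau) / (1.0 + 1j * w * tau)
        return h

    @property
    def is_linear(self) -> bool:
        return self.sign_asymmetry == 0.0


def _apply_transfer(samples: np.ndarray, dwell_us: float, h_of_f) -> np.ndarray:
    """Apply a frequency response to padded samples (length preserved)."""
    n = samples.size
    freq = np.fft.rfftfreq(n, d=dwell_us * 1e-6)
    spec = np.fft.rfft(samples)
    return np.fft.irfft(spec * h_of_f(freq), n=n)


def lti_response(samples: np.ndarray, dwell_us: float, model: GradientChainModel,
                 tail_us: float = 0.0) -> np.ndarray:
    """LTI part of the chain applied to a sample array (no sign asymmetry).

    The array is zero-padded by ``tail_us`` (plus padding against FFT
    wrap-around) so lingering responses are captured; the returned array has
    ``len(samples) + round(tail_us / dwell)`` samples.
    """
    n_tail = int(round(tail_us / dwell_us))
    n_out = samples.size + n_tail
    # Extra guard padding so the circular convolution does not wrap into the tail.
    n_pad = n_out + max(n_out // 2, 4096)
    padded = np.zeros(n_pad)
    padded[: samples.size] = samples
    out = _apply_transfer(padded, dwell_us, model.transfer)
    return out[:n_out]


def asymmetric_gain(samples: np.ndarray, sign_asymmetry: float) -> np.ndarray:
    """Pointwise gain ``1 + a/2`` for positive values, ``1 - a/2`` for negative."""
    if sign_asymmetry == 0.0:
        return samples
    return samples + np.abs(samples) * (sign_asymmetry / 2.0)


def apply_chain(nominal: Waveform, model: GradientChainModel,
                tail_us: float = 10000.0) -> Waveform:
    """Pass a nominal waveform through the gradient chain.

    The output grid is extended by ``tail_us`` past the input so lingering
    eddy/resonance responses are visible (they are the effect the compensated
    measurement schemes exist to separate).
    """
    out = lti_response(nominal.samples, nominal.dwell, model, tail_us=tail_us)
    out = asymmetric_gain(out, model.sign_asymmetry)
    return Waveform(out, dwell=nominal.dwell, t0=nominal.t0,
                    axis_label=nominal.axis_label)


def b0_response(samples: np.ndarray, dwell_us: float, model: GradientChainModel,
                tail_us: float = 0.0) -> np.ndarray:
    """dB0(t) in Hz produced by a commanded gradient sample array."""
    n_tail = int(round(tail_us / dwell_us))
    n_out = samples.size + n_tail
    n_pad = n_out + max(n_out // 2, 4096)
    padded = np.zeros(n_pad)
    padded[: samples.size] = samples
    out = _apply_transfer(padded, dwell_us, model.b0_transfer)
    return out[:n_out]
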