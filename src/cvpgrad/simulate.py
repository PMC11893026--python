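"""Synthetic multi-slice FID acquisition for the VP/CVP/FCVP schemes.

For every (prephasing step n, scheme step k, slice m) the simulator passes
all gradient events of the step through the gradient-chain model, accumulates
the spin phase from the excitation instant onward, averages unit phasors over
sub-positions across the slice thickness (producing the dephasing envelope
and the rephasing maxima the weighted least-squares estimation relies on),
and adds complex Gaussian noise.

Field model during the readout, for a spin at position r (mm)::

    f(r, t) = dB0(t) + HZ_PER_MTM_MM * G_out(t) * r
              + kappa0 * (1 + kappa1 * r * 1e-3) * G_out(t)**2      [Hz]

where ``G_out`` is the chain output of all events of the step (gradients
played before the excitation contribute only their lingering response) and
``dB0`` is the B0 eddy-current response of the commanded gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import GradientChainModel, asymmetric_gain, _apply_transfer
from .constants import RAD_PER_MTM_US_MM
from .errors import ParameterError
from .scheme import AcquisitionScheme, SliceSet
from .waveforms import Waveform, place_on_grid

_RAD_PER_HZ_US = 2.0 * np.pi * 1e-6


@dataclass
class FIDDataset:
    """Complex FID signals indexed by (n, k, m, t).

    ``signal[n, k_idx, m, t]`` where ``k_idx`` enumerates ``scheme.steps``
    (``{1, 2}`` for VP, ``{1, 2, 3, 4}`` otherwise).
    """

    signal: np.ndarray
    dwell: float  # readout dwell, us
    slices: SliceSet
    scheme: AcquisitionScheme
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        n, k, m, t = self.signal.shape
        if k != len(self.scheme.steps):
            raise ParameterError("signal step axis inconsistent with scheme")
        if m != self.slices.n_slices:
            raise ParameterError("signal slice axis inconsistent with slices")
        if n != self.scheme.n_prephasers:
            raise ParameterError("signal prephaser axis inconsistent with scheme")

    @property
    def times(self) -> np.ndarray:
        """Readout sample times, us from sequence start."""
        return self.scheme.readout_start + self.dwell * np.arange(self.signal.shape[-1])

    @property
    def n_samples(self) -> int:
        return self.signal.shape[-1]


def _grid(scheme: AcquisitionScheme, dwell_sim: float) -> np.ndarray:
    t_end = scheme.readout_start + scheme.readout_duration
    n = int(np.ceil(t_end / dwell_sim)) + 1
    return dwell_sim * np.arange(n)


def _response(samples_on_grid: np.ndarray, dwell: float, transfer) -> np.ndarray:
    n = samples_on_grid.size
    n_pad = n + max(n // 2, 4096)
    padded = np.zeros(n_pad)
    padded[:n] = samples_on_grid
    return _apply_transfer(padded, dwell, transfer)[:n]


def _cumtrapz_from(y: np.ndarray, dx: float, start_idx: int) -> np.ndarray:
    """Running trapezoid integral of ``y``, zero up to ``start_idx``."""
    yy = y.copy()
    yy[:start_idx] = 0.0
    out = np.zeros_like(yy)
    out[1:] = np.cumsum((yy[1:] + yy[:-1]) / 2.0) * dx
    return out


def simulate_fid(scheme: AcquisitionScheme, model: GradientChainModel,
                 slices: SliceSet, dwell: float = 2.0, noise_sigma: float = 0.0,
                 seed: int | None = None, intra_slice_points: int = 64,
                 dwell_sim: float | None = None) -> FIDDataset:
    """Simulate the full multi-step, multi-slice FID dataset of a scheme.

    Parameters
    ----------
    dwell:
        Readout dwell, us (sample times start at ``scheme.readout_start``).
    noise_sigma:
        Std of the i.i.d. Gaussian noise per real/imaginary channel; requires
        ``seed`` when nonzero (reproducibility contract).
    intra_slice_points:
        Number of sub-positions across the slice thickness used for the
        ideal rectangular slice-profile average.
    dwell_sim:
        Internal field-integration grid, us (default: ``min(1, dwell)``).
    """
    if noise_sigma > 0 and seed is None:
        raise ParameterError("seed is required when noise_sigma > 0")
    if intra_slice_points < 1:
        raise ParameterError("intra_slice_points must be >= 1")
    if not (dwell > 0):
        raise ParameterError("dwell must be positive")

    ds = dwell_sim if dwell_sim is not None else min(1.0, dwell)
    grid = _grid(scheme, ds)
    n_ro = int(round(scheme.readout_duration / dwell)) + 1
    t_ro = scheme.readout_start + dwell * np.arange(n_ro)

    # LTI / B0 responses of each distinct (template, t_start) event, unit scale.
    resp_cache: dict = {}
    b0_cache: dict = {}

    def responses(template: Waveform, t_start: float):
        key = (id(template), t_start)
        if key not in resp_cache:
            placed = place_on_grid(grid, [(template, 1.0, t_start)])
            resp_cache[key] = _response(placed, ds, model.transfer)
            b0_cache[key] = _response(placed, ds, model.b0_transfer)
        return resp_cache[key], b0_cache[key]

    steps = scheme.steps
    n_pre = scheme.n_prephasers
    m_sl = slices.n_slices
    sig = np.empty((n_pre, len(steps), m_sl, n_ro), dtype=complex)

    offs = (np.arange(intra_slice_points) + 0.5) / intra_slice_points - 0.5
    offs = offs * slices.thickness  # mm, sub-positions relative to slice center

    kappa0, kappa1 = model.kappa0, model.kappa1

    for ki, k in enumerate(steps):
        sd = scheme.step_definitions[k]
        exc_idx = int(np.searchsorted(grid, sd.excitation_time))
        for n in range(n_pre):
            g_lin = np.zeros_like(grid)
            b0 = np.zeros_like(grid)
            for tmpl, scale, t_start in scheme.events_for(k, n):
                r, b = responses(tmpl, t_start)
                g_lin = g_lin + scale * r
                b0 = b0 + scale * b
            g_out = asymmetric_gain(g_lin, model.sign_asymmetry)

            int_g = _cumtrapz_from(g_out, ds, exc_idx)
            int_b0 = _cumtrapz_from(b0, ds, exc_idx)
            int_g2 = (_cumtrapz_from(g_out ** 2, ds, exc_idx)
                      if kappa0 != 0.0 else None)

            ig = np.interp(t_ro, grid, int_g)
            ib = np.interp(t_ro, grid, int_b0)
            ig2 = np.interp(t_ro, grid, int_g2) if int_g2 is not None else 0.0

            # Phase slope per mm of position offset (shared by all slices).
            slope = RAD_PER_MTM_US_MM * ig
            if kappa0 != 0.0:
                slope = slope + _RAD_PER_HZ_US * kappa0 * kappa1 * 1e-3 * ig2
            envelope = np.exp(1j * offs[:, None] * slope[None, :]).mean(axis=0)

            for mi, r_mm in enumerate(slices.positions):
                phase = _RAD_PER_HZ_US * ib + slope * r_mm
                if kappa0 != 0.0:
                    phase = phase + _RAD_PER_HZ_US * kappa0 * ig2
                sig[n, ki, mi] = np.exp(1j * phase) * envelope

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        sig = sig + noise_sigma * (rng.standard_normal(sig.shape)
                                   + 1j * rng.standard_normal(sig.shape))

    return FIDDataset(signal=sig, dwell=dwell, slices=slices, scheme=scheme,
                      noise_sigma=noise_sigma)


# ---------------------------------------------------------------------------
# Ground-truth introspection (what the estimators are supposed to recover)
# ---------------------------------------------------------------------------

def simulated_test_gradient(scheme: AcquisitionScheme, model: GradientChainModel,
                         dwell: float, dwell_sim: float | None = None) -> np.ndarray:
    """Chain output of the isolated test gradient at the readout sample times."""
    ds = dwell_sim if dwell_sim is not None else min(1.0, dwell)
    grid = _grid(scheme, ds)
    sign, t_start = scheme.step_definitions[1].events["test"]
    placed = place_on_grid(grid, [(scheme.test_waveform, sign, t_start)])
    out = asymmetric_gain(_response(placed, ds, model.transfer),
                          model.sign_asymmetry)
    n_ro = int(round(scheme.readout_duration / dwell)) + 1
    t_ro = scheme.readout_start + dwell * np.arange(n_ro)
    return np.interp(t_ro, grid, out)


def prephaser_outputs(scheme: AcquisitionScheme, model: GradientChainModel,
                      dwell: float, dwell_sim: float | None = None) -> np.ndarray:
    """Chain outputs of the isolated prephaser events, shape (N, T).

    These are the lingering prephaser fields during the readout window — the
    contribution the CVP/FCVP steps 3-4 measure and VP neglects.
    """
    ds = dwell_sim if dwell_sim is not None else min(1.0, dwell)
    grid = _grid(scheme, ds)
    sign, t_start = scheme.step_definitions[1].events["prephaser"]
    placed = place_on_grid(grid, [(scheme.prephaser_shape, sign, t_start)])
    unit = _response(placed, ds, model.transfer)
    n_ro = int(round(scheme.readout_duration / dwell)) + 1
    t_ro = scheme.readout_start + dwell * np.arange(n_ro)
    out = np.empty((scheme.n_prephasers, n_ro))
    for n, a in enumerate(scheme.prephaser_amplitudes):
        out[n] = np.interp(t_ro, grid, asymmetric_gain(a * unit,
                                                       model.sign_asymmetry))
    return out
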