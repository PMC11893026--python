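"""EPI trajectory calculation, correction, reconstruction and ghost metrics.

Single-shot EPI alternates the readout gradient polarity line by line; any
inconsistency between odd and even lines (delays, eddy currents, mechanical
resonances) aliases into a Nyquist (N/2) ghost at half the field of view in
the phase-encode direction.  This module builds k-space trajectories by
integrating (measured, predicted, or nominal) readout waveforms, applies the
standard 3-echo navigator phase correction, reconstructs images from
arbitrary readout trajectories, scans residual delays against an
out-of-mask intensity cost, and quantifies ghosting.

Reconstruction: the phase-encode direction is sampled on the nominal
Cartesian grid (nominal blips), so the image is formed by an exact 1-D
non-uniform DFT along the readout direction per line (adjoint with
density compensation, or iterative least squares) followed by a uniform DFT
along phase encode.  For this sampling pattern that is the exact operator a
general-purpose NUFFT would approximate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .constants import K_PER_MTM_US
from .errors import ParameterError, TimingError
from .waveforms import Waveform, make_epi_train, make_trapezoid

__all__ = [
    "EPIGeometry", "EPIRawData", "KTrajectory", "GhostReport", "design_epi",
    "integrate_trajectory", "make_phantom", "simulate_epi_raw",
    "navigator_correct", "reconstruct", "ghost_intensity", "optimize_delay",
]


@dataclass
class EPIGeometry:
    """Nominal geometry of a single-shot EPI readout."""

    readout: Waveform  # prewinder + alternating train
    adc_times: np.ndarray  # (n_lines, n_ro), us, sample centers
    k_pe: np.ndarray  # (n_lines,), 1/m, from nominal blips
    fov_mm: float
    matrix_size: int
    dwell_adc: float  # us
    amplitude: float  # mT/m plateau
    echo_spacing: float  # us

    @property
    def n_lines(self) -> int:
        return self.adc_times.shape[0]


@dataclass
class EPIRawData:
    """Raw EPI echoes plus non-phase-encoded reference echoes.

    ``echoes``: (n_lines, n_ro, n_coils); line ℓ was acquired with readout
    polarity ``(-1)**ℓ``.  ``reference_echoes``: (3, n_ro, n_coils) acquired
    before the imaging train with polarities (+, -, +) and no phase encoding.
    """

    echoes: np.ndarray
    reference_echoes: np.ndarray | None
    fov_mm: float
    matrix_size: int
    dwell_adc: float
    k_pe_nominal: np.ndarray
    navigator_phase: float | None = None
    navigator_confident: bool = True

    def __post_init__(self) -> None:
        self.echoes = np.asarray(self.echoes, dtype=complex)
        if self.echoes.ndim == 2:
            self.echoes = self.echoes[:, :, None]
        if self.reference_echoes is not None:
            self.reference_echoes = np.asarray(self.reference_echoes, dtype=complex)
            if self.reference_echoes.ndim == 2:
                self.reference_echoes = self.reference_echoes[:, :, None]
        if self.echoes.shape[0] != self.k_pe_nominal.size:
            raise ParameterError("echo count must match phase-encode lines")

    @property
    def n_coils(self) -> int:
        return self.echoes.shape[2]


@dataclass
class KTrajectory:
    """Per-sample k-space coordinates of an EPI readout.

    ``k_ro[line, sample]`` (1/m) from integrating the readout waveform;
    ``k_pe[line]`` from the nominal blips.  ``echo_center_k`` is k_ro
    interpolated at the temporal center of each line — the standard
    diagnostic of odd/even echo shifts.
    """

    k_ro: np.ndarray
    k_pe: np.ndarray
    echo_center_k: np.ndarray


@dataclass
class GhostReport:
    """Nyquist-ghost quantification and delay-optimization results."""

    gamma: float | None = None  # relative ghost intensity, %
    roi1: tuple | None = None  # (row, col, height, width), pixels
    roi2: tuple | None = None  # roi1 shifted by FOV/2 along phase encode
    optimal_delay: float | None = None  # us
    delay_scan: np.ndarray | None = None  # (n_delays, 2): delay, cost
    polynomial_coeffs: np.ndarray | None = None  # quartic, np.polyfit order


# ---------------------------------------------------------------------------
# Sequence design
# ---------------------------------------------------------------------------

def design_epi(matrix_size: int = 64, fov_mm: float = 200.0,
               dwell_adc: float = 5.0, ramp_time: float = 100.0,
               dwell_wf: float = 1.0, axis_label: str = "x") -> EPIGeometry:
    """Nominal single-shot EPI readout with prewinder and ADC on flat tops.

    The plateau amplitude is chosen so one ADC dwell advances k by exactly
    1/FOV; the prewinder moment centers the echo of every line at k_ro = 0
    under the nominal waveform.
    """
    if matrix_size < 2 or matrix_size % 2:
        raise ParameterError("matrix_size must be even and >= 2")
    fov_m = fov_mm * 1e-3
    dk = 1.0 / fov_m
    amplitude = dk / (K_PER_MTM_US * dwell_adc)
    flat_time = matrix_size * dwell_adc
    if flat_time < ramp_time:
        raise ParameterError("flat top shorter than ramp; reduce ramp_time")

    # Prewinder: moment -A*(ramp+flat)/2 puts k=0 at the first flat-top center.
    pw_flat = (flat_time - ramp_time) / 2.0
    prewinder = make_trapezoid(-amplitude, ramp_time, pw_flat, dwell_wf,
                               axis_label=axis_label)
    train = make_epi_train(amplitude, ramp_time, flat_time, matrix_size,
                           dwell_wf, t0=prewinder.end_time,
                           axis_label=axis_label)
    samples = np.concatenate([prewinder.samples[:-1], train.samples])
    readout = Waveform(samples, dwell=dwell_wf, t0=0.0, axis_label=axis_label)

    echo_spacing = flat_time + 2 * ramp_time
    line_starts = (prewinder.end_time + ramp_time
                   + echo_spacing * np.arange(matrix_size))
    adc = line_starts[:, None] + (np.arange(matrix_size)[None, :] + 0.5) * dwell_adc

    k_pe = (np.arange(matrix_size) - matrix_size // 2) * dk
    return EPIGeometry(readout=readout, adc_times=adc, k_pe=k_pe,
                       fov_mm=fov_mm, matrix_size=matrix_size,
                       dwell_adc=dwell_adc, amplitude=amplitude,
                       echo_spacing=echo_spacing)


# ---------------------------------------------------------------------------
# Trajectory integration
# ---------------------------------------------------------------------------

def integrate_trajectory(readout: Waveform, adc_times: np.ndarray,
                         delay: float = 0.0, k_pe: np.ndarray | None = None,
                         nominal: Waveform | None = None) -> KTrajectory:
    """k-space trajectory from a (possibly delayed) readout waveform.

    The waveform is delayed by ``delay`` us before integration, i.e. the
    cumulative moment is evaluated at ``t - delay``.  The integration origin
    is the documented convention k_ro = 0 at the echo center of the central
    line under the *nominal* waveform (pass ``nominal``; defaults to
    ``readout`` itself), which keeps nominal and measured trajectories
    comparable.
    """
    adc = np.atleast_2d(np.asarray(adc_times, dtype=float))
    shifted = adc - delay
    if shifted.min() < readout.t0 or shifted.max() > readout.end_time:
        raise TimingError("delayed ADC window falls outside waveform support")

    def k_of(wf: Waveform, t: np.ndarray) -> np.ndarray:
        return K_PER_MTM_US * np.interp(t, wf.times, wf.cumulative_moment())

    k_ro = k_of(readout, shifted)

    ref = nominal if nominal is not None else readout
    n_lines, n_ro = adc.shape
    t_center = adc[n_lines // 2, n_ro // 2 - 1: n_ro // 2 + 1].mean() \
        if n_ro % 2 == 0 else adc[n_lines // 2, n_ro // 2]
    k_ro = k_ro - k_of(ref, np.array([t_center]))[0]

    center = (k_ro[:, n_ro // 2 - 1: n_ro // 2 + 1].mean(axis=1)
              if n_ro % 2 == 0 else k_ro[:, n_ro // 2])
    if k_pe is None:
        k_pe = np.zeros(n_lines)
    return KTrajectory(k_ro=k_ro, k_pe=np.asarray(k_pe, dtype=float),
                       echo_center_k=center)


# ---------------------------------------------------------------------------
# Phantom + forward model
# ---------------------------------------------------------------------------

def make_phantom(n: int = 64) -> np.ndarray:
    """Smooth disc phantom with internal structure, values in [0, 1]."""
    i = np.arange(n) - n / 2 + 0.5
    yy, xx = np.meshgrid(i, i, indexing="ij")
    r = np.hypot(yy, xx)
    disc = 0.5 * (1.0 + np.tanh((0.30 * n - r) / 1.5))
    img = disc.copy()
    img += 0.4 * disc * np.exp(-(((yy - 0.10 * n) ** 2 + (xx + 0.08 * n) ** 2)
                                 / (0.06 * n) ** 2))
    img -= 0.3 * disc * np.exp(-(((yy + 0.11 * n) ** 2 + (xx - 0.07 * n) ** 2)
                                 / (0.05 * n) ** 2))
    return np.clip(img, 0.0, None)


def _pixel_coords(n: int, fov_mm: float) -> np.ndarray:
    """Pixel-center coordinates in meters, symmetric about the FOV center."""
    return (np.arange(n) - n / 2 + 0.5) / n * fov_mm * 1e-3


def simulate_epi_raw(phantom: np.ndarray, traj: KTrajectory, fov_mm: float,
                     ref_traj: KTrajectory | None = None,
                     coil_sens: np.ndarray | None = None,
                     noise_sigma: float = 0.0, seed: int | None = None,
                     dwell_adc: float = 5.0) -> EPIRawData:
    """Sample an image along a trajectory: exact discrete forward model.

    ``s(k) = sum_{y,x} rho(y, x) * exp(-2*pi*i*(k_ro*x + k_pe*y))``; the
    reference echoes use ``ref_traj`` (3 lines) with zero phase encoding.
    """
    if noise_sigma > 0 and seed is None:
        raise ParameterError("seed is required when noise_sigma > 0")
    phantom = np.asarray(phantom, dtype=complex)
    n = phantom.shape[0]
    if coil_sens is None:
        coil_sens = np.ones((1, *phantom.shape))
    pos = _pixel_coords(n, fov_mm)

    def sample(k_ro: np.ndarray, k_pe: np.ndarray, img: np.ndarray) -> np.ndarray:
        out = np.empty(k_ro.shape, dtype=complex)
        for line in range(k_ro.shape[0]):
            proj = np.exp(-2j * np.pi * k_pe[line] * pos) @ img  # sum over y
            basis = np.exp(-2j * np.pi * np.outer(k_ro[line], pos))
            out[line] = basis @ proj
        return out

    n_coils = coil_sens.shape[0]
    echoes = np.empty((*traj.k_ro.shape, n_coils), dtype=complex)
    refs = None
    if ref_traj is not None:
        refs = np.empty((*ref_traj.k_ro.shape, n_coils), dtype=complex)
    for c in range(n_coils):
        img = phantom * coil_sens[c]
        echoes[:, :, c] = sample(traj.k_ro, traj.k_pe, img)
        if ref_traj is not None:
            refs[:, :, c] = sample(ref_traj.k_ro,
                                   np.zeros(ref_traj.k_ro.shape[0]), img)

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        echoes = echoes + noise_sigma * (rng.standard_normal(echoes.shape)
                                         + 1j * rng.standard_normal(echoes.shape))
        if refs is not None:
            refs = refs + noise_sigma * (rng.standard_normal(refs.shape)
                                         + 1j * rng.standard_normal(refs.shape))

    return EPIRawData(echoes=echoes, reference_echoes=refs, fov_mm=fov_mm,
                      matrix_size=n, dwell_adc=dwell_adc,
                      k_pe_nominal=traj.k_pe.copy())


# ---------------------------------------------------------------------------
# Navigator correction
# ---------------------------------------------------------------------------

def navigator_correct(raw: EPIRawData, confidence_threshold: float = 0.2
                      ) -> EPIRawData:
    """Constant odd/even phase correction from the 3 reference echoes.

    The middle (odd-polarity) reference echo is time-reversed and its inner
    product with the mean of its two neighbors gives a single constant phase
    offset, whose negation is applied to every second imaging echo.  A
    normalized inner-product magnitude below ``confidence_threshold`` flags
    the estimate as low-confidence (``navigator_confident=False``).
    """
    if raw.reference_echoes is None or raw.reference_echoes.shape[0] < 2:
        raise ParameterError("need >= 2 reference echoes of alternating polarity")
    refs = raw.reference_echoes
    mid = refs[1, ::-1, :]
    neighbors = refs[[0, -1]].mean(axis=0)
    if np.abs(mid).max() == 0.0 or np.abs(neighbors).max() == 0.0:
        raise ParameterError("zero-magnitude reference echoes; cannot estimate "
                             "navigator phase")
    inner = np.sum(mid * np.conj(neighbors))
    phi0 = float(np.angle(inner))
    norm = np.linalg.norm(mid) * np.linalg.norm(neighbors)
    confident = bool(np.abs(inner) >= confidence_threshold * norm)

    echoes = raw.echoes.copy()
    echoes[1::2] *= np.exp(-1j * phi0)
    return replace(raw, echoes=echoes, navigator_phase=phi0,
                   navigator_confident=confident)


# ---------------------------------------------------------------------------
# Reconstruction
# ---------------------------------------------------------------------------

def _line_operators(traj: KTrajectory, n: int, fov_mm: float):
    """Per-line non-uniform DFT matrices exp(-2*pi*i*k x) and PE phasors."""
    pos = _pixel_coords(n, fov_mm)
    fwd = [np.exp(-2j * np.pi * np.outer(traj.k_ro[line], pos))
           for line in range(traj.k_ro.shape[0])]
    pe = np.exp(-2j * np.pi * np.outer(traj.k_pe, pos))  # (n_lines, n_y)
    return fwd, pe


def reconstruct(raw: EPIRawData, traj: KTrajectory, mode: str = "adjoint",
                n_iter: int = 12) -> np.ndarray:
    """Image from raw echoes and a readout trajectory.

    ``mode="adjoint"``: density-compensated adjoint non-uniform DFT along the
    readout per line, inverse DFT along phase encode.  ``mode="lsq"``:
    conjugate-gradient least squares on the full forward model.  Coil images
    are combined root-sum-of-squares; the returned array is the magnitude
    image with phase encode along axis 0.

    Trajectory excursions beyond the nominal Nyquist box (|k| > N/(2 FOV))
    trigger a warning; the samples are kept (they simply map outside the
    principal image band).
    """
    n = raw.matrix_size
    if traj.k_ro.shape != raw.echoes.shape[:2]:
        raise ParameterError("trajectory and raw sample counts must match")
    k_max = n / (2.0 * raw.fov_mm * 1e-3)
    if np.abs(traj.k_ro).max() > 1.02 * k_max:
        warnings.warn("trajectory exceeds the nominal Nyquist box; keeping "
                      "out-of-box samples", stacklevel=2)

    fwd, pe = _line_operators(traj, n, raw.fov_mm)
    n_lines = traj.k_ro.shape[0]
    dk = 1.0 / (raw.fov_mm * 1e-3)

    def adjoint(data: np.ndarray, density: bool) -> np.ndarray:
        """data (n_lines, n_ro) -> complex image (n_y, n_x)."""
        lines_img = np.empty((n_lines, n), dtype=complex)
        for line in range(n_lines):
            d = data[line]
            if density:
                w = np.abs(np.gradient(traj.k_ro[line])) / dk
                d = d * w
            lines_img[line] = fwd[line].conj().T @ d
        return pe.conj().T @ lines_img / (n * n_lines)

    def forward(img: np.ndarray) -> np.ndarray:
        data = np.empty((n_lines, traj.k_ro.shape[1]), dtype=complex)
        proj = pe @ img  # (n_lines, n_x): phase-encode weighted row sums
        for line in range(n_lines):
            data[line] = fwd[line] @ proj[line]
        return data / (n * n_lines)

    coil_imgs = np.empty((raw.n_coils, n, n), dtype=complex)
    for c in range(raw.n_coils):
        data = raw.echoes[:, :, c]
        if mode == "adjoint":
            coil_imgs[c] = adjoint(data, density=True)
        elif mode == "lsq":
            # CG on the normal equations A^H A x = A^H d.
            b = adjoint(data, density=False)
            x = np.zeros_like(b)
            r = b.copy()
            p = r.copy()
            rs = np.vdot(r, r)
            for _ in range(n_iter):
                ap = adjoint(forward(p), density=False)
                alpha = rs / np.vdot(p, ap)
                x += alpha * p
                r -= alpha * ap
                rs_new = np.vdot(r, r)
                if np.abs(rs_new) < 1e-30:
                    break
                p = r + (rs_new / rs) * p
                rs = rs_new
            coil_imgs[c] = x
        else:
            raise ParameterError(f"unknown reconstruction mode {mode!r}")
    return np.sqrt((np.abs(coil_imgs) ** 2).sum(axis=0))


# ---------------------------------------------------------------------------
# Ghost quantification and delay optimization
# ---------------------------------------------------------------------------

def ghost_intensity(image: np.ndarray, roi1: tuple) -> GhostReport:
    """Relative ghost intensity Gamma = 100 * max|ROI1| / max|ROI2|.

    ``roi1 = (row, col, height, width)`` in pixels must lie in a ghost-only
    region outside the object; ROI2 is ROI1 shifted by half the image along
    the phase-encode axis (axis 0, wrapping), i.e. into the object.
    """
    img = np.asarray(image)
    row, col, h, w = roi1
    ny, nx = img.shape
    if not (0 <= row and row + h <= ny and 0 <= col and col + w <= nx
            and h > 0 and w > 0):
        raise ParameterError("roi1 outside image bounds")
    rows2 = (np.arange(row, row + h) + ny // 2) % ny
    m1 = float(np.abs(img[row:row + h, col:col + w]).max())
    m2 = float(np.abs(img[np.ix_(rows2, np.arange(col, col + w))]).max())
    if m2 == 0.0:
        raise ParameterError("ROI2 has zero signal; ROI placement invalid")
    gamma = 100.0 * m1 / m2
    return GhostReport(gamma=gamma, roi1=tuple(roi1),
                       roi2=(int(rows2[0]), col, h, w))


def circular_mask(n: int, center: tuple[float, float] | None = None,
                  radius: float | None = None) -> np.ndarray:
    """Boolean mask, True inside the circle (default: centered, 0.42*n)."""
    cy, cx = center if center is not None else (n / 2 - 0.5, n / 2 - 0.5)
    radius = radius if radius is not None else 0.42 * n
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2


def optimize_delay(raw: EPIRawData, readout: Waveform, adc_times: np.ndarray,
                   delay_grid: np.ndarray | None = None,
                   mask: np.ndarray | None = None,
                   nominal: Waveform | None = None,
                   mode: str = "adjoint",
                   fit_window: int | None = None) -> GhostReport:
    """Find the residual delay minimizing out-of-mask image intensity.

    For each candidate delay the readout waveform is delayed before
    integration, the image reconstructed, and the magnitude outside a
    circular mask covering the phantom summed.  A fourth-degree polynomial is
    fitted to (delay, sum); the optimum is the real root of its derivative
    inside the fitted interval with the smallest fitted value.  If no real
    root lies inside, the grid argmin is returned with a warning.

    ``fit_window`` restricts the quartic fit to that many grid points
    centered on the scan argmin (odd, >= 5), which de-biases the root when
    the scanned interval is much wider than the quartic-like neighborhood of
    the optimum; ``None`` fits all scanned points.
    """
    if delay_grid is None:
        delay_grid = np.arange(-10.0, 10.0 + 1e-9, 0.5)
    delay_grid = np.asarray(delay_grid, dtype=float)
    if delay_grid.size < 5:
        raise ParameterError("need >= 5 delay samples for a quartic fit")
    if mask is None:
        mask = circular_mask(raw.matrix_size)

    costs = np.empty(delay_grid.size)
    for i, delay in enumerate(delay_grid):
        traj = integrate_trajectory(readout, adc_times, delay=delay,
                                    k_pe=raw.k_pe_nominal, nominal=nominal)
        img = reconstruct(raw, traj, mode=mode)
        costs[i] = img[~mask].sum()

    fit_d, fit_c = delay_grid, costs
    if fit_window is not None:
        if fit_window < 5 or fit_window % 2 == 0:
            raise ParameterError("fit_window must be odd and >= 5")
        half = fit_window // 2
        center = int(np.argmin(costs))
        lo_i = max(0, min(center - half, delay_grid.size - fit_window))
        fit_d = delay_grid[lo_i:lo_i + fit_window]
        fit_c = costs[lo_i:lo_i + fit_window]

    coeffs = np.polyfit(fit_d, fit_c, 4)
    droots = np.roots(np.polyder(coeffs))
    lo, hi = fit_d.min(), fit_d.max()
    real = droots[np.abs(droots.imag) < 1e-9].real
    inside = real[(real >= lo) & (real <= hi)]
    if inside.size:
        optimal = float(inside[np.argmin(np.polyval(coeffs, inside))])
    else:
        warnings.warn("no real root of the fitted derivative inside the "
                      "scanned interval; falling back to grid argmin",
                      stacklevel=2)
        optimal = float(delay_grid[np.argmin(costs)])
    return GhostReport(optimal_delay=optimal,
                       delay_scan=np.column_stack([delay_grid, costs]),
                       polynomial_coeffs=coeffs)
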