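"""Gradient waveform container and standard lobe constructors.

A :class:`Waveform` is a uniformly sampled gradient amplitude time course on
one physical axis.  Constructors build the standard shapes used by the
measurement schemes: trapezoids (test gradients, prephasers), alternating
trapezoid trains (EPI readouts), and slice-selection events with rephaser.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError


@dataclass
class Waveform:
    """Uniformly sampled gradient amplitude vs. time on one axis.

    Parameters
    ----------
    samples:
        Gradient amplitude per time point, mT/m.
    dwell:
        Sample spacing, us.  Must be positive.
    t0:
        Time of the first sample relative to sequence start, us.
    axis_label:
        Physical axis the waveform is played on, e.g. ``"x"``.
    """

    samples: np.ndarray
    dwell: float
    t0: float = 0.0
    axis_label: str = "x"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ParameterError("waveform needs a 1-D sample array of length >= 1")
        if not np.isfinite(self.samples).all():
            raise ParameterError("waveform samples must be finite")
        if not (self.dwell > 0):
            raise ParameterError(f"dwell must be positive, got {self.dwell}")

    # -- basic geometry -------------------------------------------------
    @property
    def times(self) -> np.ndarray:
        """Sample-center times in us."""
        return self.t0 + self.dwell * np.arange(self.samples.size)

    @property
    def duration(self) -> float:
        """Time span covered by the sample grid, us."""
        return self.dwell * (self.samples.size - 1)

    @property
    def end_time(self) -> float:
        return self.t0 + self.duration

    # -- moments --------------------------------------------------------
    def moment(self) -> float:
        """Zeroth gradient moment, trapezoidal quadrature, mT/m*us."""
        return float(np.trapezoid(self.samples, dx=self.dwell))

    def cumulative_moment(self) -> np.ndarray:
        """Running integral of the waveform at sample times, mT/m*us."""
        out = np.zeros_like(self.samples)
        out[1:] = np.cumsum((self.samples[1:] + self.samples[:-1]) / 2.0) * self.dwell
        return out

    # -- transforms -----------------------------------------------------
    def shifted(self, dt: float) -> "Waveform":
        """Same samples with the time origin moved by ``dt`` us."""
        return replace(self, samples=self.samples.copy(), t0=self.t0 + dt)

    def scaled(self, factor: float) -> "Waveform":
        return replace(self, samples=self.samples * factor)

    def sample_at(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation of the waveform at times ``t`` (0 outside)."""
        return np.interp(t, self.times, self.samples, left=0.0, right=0.0)


def _from_nodes(node_t: np.ndarray, node_g: np.ndarray, dwell: float, t0: float,
                axis_label: str) -> Waveform:
    """Sample a piecewise-linear node list on a dwell grid that includes the end."""
    if not (dwell > 0):
        raise ParameterError(f"dwell must be positive, got {dwell}")
    duration = float(node_t[-1])
    n = int(round(duration / dwell)) + 1
    t = dwell * np.arange(n)
    g = np.interp(t, node_t, node_g)
    return Waveform(g, dwell=dwell, t0=t0, axis_label=axis_label)


def make_trapezoid(amplitude: float, ramp_time: float, flat_time: float,
                   dwell: float, t0: float = 0.0, axis_label: str = "x") -> Waveform:
    """Symmetric trapezoid lobe: ramp up, flat top, ramp down.

    The continuum integral is ``amplitude * (ramp_time + flat_time)``; on a
    dwell grid whose nodes hit the corners, trapezoidal quadrature reproduces
    it exactly.
    """
    if not (ramp_time > 0):
        raise ParameterError("ramp_time must be positive")
    if flat_time < 0:
        raise ParameterError("flat_time must be non-negative")
    node_t = np.array([0.0, ramp_time, ramp_time + flat_time, 2 * ramp_time + flat_time])
    node_g = np.array([0.0, amplitude, amplitude, 0.0])
    return _from_nodes(node_t, node_g, dwell, t0, axis_label)


def make_epi_train(amplitude: float, ramp_time: float, flat_time: float,
                   n_echoes: int, dwell: float, t0: float = 0.0,
                   axis_label: str = "x") -> Waveform:
    """Alternating-polarity trapezoid train with contiguous ramps.

    Consecutive lobes are sign-inverted; between flat tops the gradient ramps
    linearly from one plateau to the opposite one over ``2 * ramp_time``.
    ``n_echoes == 1`` reduces to :func:`make_trapezoid`.
    """
    if n_echoes < 1:
        raise ParameterError("n_echoes must be >= 1")
    if not (ramp_time > 0):
        raise ParameterError("ramp_time must be positive")
    if flat_time < 0:
        raise ParameterError("flat_time must be non-negative")
    node_t = [0.0]
    node_g = [0.0]
    t = 0.0
    for lobe in range(n_echoes):
        a = amplitude if lobe % 2 == 0 else -amplitude
        # Ramp onto the plateau: from 0 for the first lobe, from the previous
        # plateau otherwise (a single linear segment through zero).
        t += ramp_time if lobe == 0 else 2 * ramp_time
        node_t.append(t)
        node_g.append(a)
        t += flat_time
        node_t.append(t)
        node_g.append(a)
    t += ramp_time
    node_t.append(t)
    node_g.append(0.0)
    return _from_nodes(np.array(node_t), np.array(node_g), dwell, t0, axis_label)


def make_slice_select(amplitude: float, ramp_time: float, flat_time: float,
                      dwell: float, t0: float = 0.0,
                      axis_label: str = "x") -> tuple[Waveform, float]:
    """Slice-selection event: main lobe plus refocusing lobe.

    The rephaser moment cancels the post-excitation half of the main lobe so
    that spins are in phase at the end of the event.  Excitation is taken at
    the center of the main flat top.

    Returns
    -------
    (waveform, excitation_time):
        The composite event and the excitation instant (us, relative to the
        same origin as ``t0``).
    """
    if flat_time < ramp_time:
        raise ParameterError("slice-select flat_time must be >= ramp_time "
                             "(rephaser construction)")
    # Post-excitation moment of the main lobe: A*flat/2 + A*ramp/2.
    reph_flat = (flat_time - ramp_time) / 2.0
    node_t = np.array([
        0.0,
        ramp_time,
        ramp_time + flat_time,
        2 * ramp_time + flat_time,
        3 * ramp_time + flat_time,
        3 * ramp_time + flat_time + reph_flat,
        4 * ramp_time + flat_time + reph_flat,
    ])
    node_g = np.array([0.0, amplitude, amplitude, 0.0,
                       -amplitude, -amplitude, 0.0])
    wf = _from_nodes(node_t, node_g, dwell, t0, axis_label)
    excitation_time = t0 + ramp_time + flat_time / 2.0
    return wf, excitation_time


def place_on_grid(grid_t: np.ndarray, events: list[tuple[Waveform, float, float]]) -> np.ndarray:
    """Sum scaled, shifted waveform events onto a common time grid.

    ``events`` is a list of ``(waveform, scale, t_start)``; each event's own
    ``t0`` is ignored and replaced by ``t_start``.
    """
    total = np.zeros_like(grid_t, dtype=float)
    for wf, scale, t_start in events:
        local = grid_t - t_start
        total += scale * np.interp(local, wf.dwell * np.arange(wf.samples.size),
                                   wf.samples, left=0.0, right=0.0)
    return total
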