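"""Acquisition schemes for the VP / CVP / FCVP measurement methods.

A scheme lays out, for each acquisition step, which gradient events
(slice selection, prephaser, test gradient) are played, with which sign, and
when — together with the excitation instant and a readout window that is
identical across steps.

Step structure
--------------
* **VP** uses steps {1, 2}: step 1 plays slice selection, the n-th prephaser
  between excitation and test gradient, and the test gradient during the
  readout; step 2 is the reference with slice selection only.
* **CVP** adds steps {3, 4}: in step 3 the prephaser is moved *before* the
  excitation (same absolute prephaser/readout timing), so only its lingering
  fields are seen during the readout; step 4 repeats step 3 without the
  prephaser to record the shifted slice-selection background.
* **FCVP** replaces the references by sign-inverted repeats: steps 2 and 4
  negate prephaser and test gradients relative to steps 1 and 3, so that
  subtracting the pairs cancels contributions that are even in the gradient
  amplitude (concomitant fields).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, TimingError
from .waveforms import Waveform, make_trapezoid

VP = "vp"
CVP = "cvp"
FCVP = "fcvp"
METHODS = (VP, CVP, FCVP)


@dataclass
class SliceSet:
    """Slice-center offsets along the tested axis.

    At least two distinct positions are required to separate the spatially
    constant basis function p1(r) = 1 from the linear one p2(r) = r.
    """

    positions: np.ndarray  # mm
    thickness: float  # mm

    def __post_init__(self) -> None:
        self.positions = np.atleast_1d(np.asarray(self.positions, dtype=float))
        if self.positions.size < 2:
            raise ParameterError("need M >= 2 slices to separate p1=1 from p2=r")
        if np.unique(self.positions).size != self.positions.size:
            raise ParameterError("slice positions must be distinct")
        if not (self.thickness > 0):
            raise ParameterError("slice thickness must be positive")

    @property
    def n_slices(self) -> int:
        return self.positions.size


@dataclass
class StepDefinition:
    """Events of one acquisition step.

    ``events`` maps event kind (``"slice_select" | "prephaser" | "test"``) to
    ``(sign, t_start)``; absent kinds are not played.  ``excitation_time`` is
    the absolute excitation instant of this step (us).
    """

    events: dict
    excitation_time: float


@dataclass
class AcquisitionScheme:
    method: str
    prephaser_amplitudes: np.ndarray  # mT/m, scale factors of prephaser_shape
    prephaser_shape: Waveform  # unit-amplitude template (t0 ignored)
    test_waveform: Waveform  # unit template played as-is (t0 ignored)
    slice_select_waveform: Waveform  # composite event template (t0 ignored)
    step_definitions: dict  # k -> StepDefinition
    readout_start: float  # us
    readout_duration: float  # us

    def __post_init__(self) -> None:
        self.prephaser_amplitudes = np.atleast_1d(
            np.asarray(self.prephaser_amplitudes, dtype=float))

    @property
    def steps(self) -> tuple:
        return tuple(sorted(self.step_definitions))

    @property
    def n_prephasers(self) -> int:
        return self.prephaser_amplitudes.size

    def events_for(self, k: int, n: int) -> list[tuple[Waveform, float, float]]:
        """``(template, scale, t_start)`` triples of step ``k``, prephasing step ``n``."""
        tmpl = {"slice_select": self.slice_select_waveform,
                "prephaser": self.prephaser_shape,
                "test": self.test_waveform}
        out = []
        for kind, (sign, t_start) in self.step_definitions[k].events.items():
            scale = sign * (self.prephaser_amplitudes[n] if kind == "prephaser" else 1.0)
            out.append((tmpl[kind], scale, t_start))
        return out


def choose_prephasers(test: Waveform, n_steps: int,
                      prephaser_shape: Waveform | None = None,
                      dwell: float | None = None) -> np.ndarray:
    """Prephaser amplitudes whose moments uniformly span the test gradient's
    cumulative moment.

    The FID magnitude peaks when the (negative) prephaser moment cancels the
    running integral of the test gradient, so spanning
    ``[min, max]`` of the cumulative test moment in ``n_steps`` uniform steps
    places rephasing maxima at roughly uniform time points across the test
    waveform.  For a monotone cumulative moment (e.g. a trapezoid) this is
    ``[0, total moment]``.

    Returns amplitudes (mT/m) for ``prephaser_shape`` (default: unit trapezoid
    with 100 us ramps and 200 us flat top).
    """
    if n_steps < 2:
        raise ParameterError("need N >= 2 prephasing steps")
    if prephaser_shape is None:
        prephaser_shape = make_trapezoid(1.0, 100.0, 200.0,
                                         dwell or test.dwell)
    cum = test.cumulative_moment()
    lo = min(0.0, float(cum.min()))
    hi = max(0.0, float(cum.max()))
    if hi == lo:
        warnings.warn("test waveform has identically zero cumulative moment; "
                      "prephaser amplitudes set to zero", stacklevel=2)
        return np.zeros(n_steps)
    targets = np.linspace(lo, hi, n_steps)
    unit_moment = prephaser_shape.moment()
    if unit_moment == 0.0:
        raise ParameterError("prephaser template has zero moment")
    # Prephaser moment must equal minus the target so the pair cancels.
    return -targets / unit_moment


def build_scheme(method: str, test: Waveform, prephaser_amplitudes,
                 slice_select: Waveform, slice_select_excitation: float,
                 gaps: tuple[float, float, float] = (100.0, 100.0, 100.0),
                 prephaser_shape: Waveform | None = None,
                 readout_duration: float | None = None) -> AcquisitionScheme:
    """Assemble the per-step event layout of a measurement scheme.

    Parameters
    ----------
    method:
        ``"vp"``, ``"cvp"`` or ``"fcvp"``.
    test:
        Test gradient template (its ``t0`` is ignored; it is placed at the
        readout start).
    prephaser_amplitudes:
        N >= 2 plateau scale factors for ``prephaser_shape``.
    slice_select, slice_select_excitation:
        Composite slice-selection event template and the excitation time
        *within* that template (us from its start), e.g. from
        :func:`cvpgrad.waveforms.make_slice_select`.
    gaps:
        ``(g1, g2, g3)``: idle times between slice selection (early position)
        and prephaser, prephaser and slice selection (late position), and
        slice selection (late) and test gradient, us.
    readout_duration:
        Readout window length, us.  Defaults to the test duration + 2 ms so
        lingering oscillations stay visible.

    Timing (identical in all steps): the early slice-selection slot precedes
    the prephaser slot, which precedes the late slice-selection slot, which
    precedes the test/readout.  Steps 1-2 excite in the early slot (prephaser
    between excitation and test); steps 3-4 excite in the late slot
    (prephaser before excitation).
    """
    if method not in METHODS:
        raise ParameterError(f"unknown method {method!r}; expected one of {METHODS}")
    amplitudes = np.atleast_1d(np.asarray(prephaser_amplitudes, dtype=float))
    if amplitudes.size < 2:
        raise ParameterError("need N >= 2 prephaser amplitudes")
    if prephaser_shape is None:
        prephaser_shape = make_trapezoid(1.0, 100.0, 200.0, test.dwell)
    g1, g2, g3 = gaps
    if min(g1, g2, g3) < 0:
        raise TimingError("gaps must be non-negative")

    ss_dur = slice_select.duration
    pre_dur = prephaser_shape.duration
    t_ss_early = 0.0
    t_pre = ss_dur + g1
    t_ss_late = t_pre + pre_dur + g2
    t_test = t_ss_late + ss_dur + g3
    exc_early = t_ss_early + slice_select_excitation
    exc_late = t_ss_late + slice_select_excitation

    # Events must be strictly ordered; overlapping events are a timing error.
    spans = [(t_ss_early, t_ss_early + ss_dur), (t_pre, t_pre + pre_dur),
             (t_ss_late, t_ss_late + ss_dur), (t_test, t_test + test.duration)]
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise TimingError("gradient events overlap; increase gaps")

    ss_early = {"slice_select": (1.0, t_ss_early)}
    ss_late = {"slice_select": (1.0, t_ss_late)}

    def step(events: dict, exc: float) -> StepDefinition:
        return StepDefinition(events=events, excitation_time=exc)

    if method == VP:
        defs = {
            1: step({**ss_early, "prephaser": (1.0, t_pre), "test": (1.0, t_test)},
                    exc_early),
            2: step(dict(ss_early), exc_early),
        }
    elif method == CVP:
        defs = {
            1: step({**ss_early, "prephaser": (1.0, t_pre), "test": (1.0, t_test)},
                    exc_early),
            2: step(dict(ss_early), exc_early),
            3: step({"prephaser": (1.0, t_pre), **ss_late}, exc_late),
            4: step(dict(ss_late), exc_late),
        }
    else:  # FCVP
        defs = {
            1: step({**ss_early, "prephaser": (1.0, t_pre), "test": (1.0, t_test)},
                    exc_early),
            2: step({**ss_early, "prephaser": (-1.0, t_pre), "test": (-1.0, t_test)},
                    exc_early),
            3: step({"prephaser": (1.0, t_pre), **ss_late}, exc_late),
            4: step({"prephaser": (-1.0, t_pre), **ss_late}, exc_late),
        }

    if readout_duration is None:
        readout_duration = test.duration + 2000.0

    return AcquisitionScheme(
        method=method,
        prephaser_amplitudes=amplitudes,
        prephaser_shape=prephaser_shape,
        test_waveform=test,
        slice_select_waveform=slice_select,
        step_definitions=defs,
        readout_start=t_test,
        readout_duration=readout_duration,
    )
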