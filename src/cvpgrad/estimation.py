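"""Field-coefficient estimation by magnitude-weighted least squares.

The FID phase derivative of slice m is modeled as

    f(r_m, t) = d_B0(t) + HZ_PER_MTM_MM * G(t) * r_m  (+ nuisance terms)

and the per-time-point linear systems of the VP, CVP and FCVP schemes are
solved with weights equal to the signal magnitudes: the phase variance of a
complex Gaussian signal is sigma^2 / |S|^2, so the inverse covariance of the
stacked frequency observations is diag(|S|^2).

The design matrices use P = [1, HZ_PER_MTM_MM * r_m], which absorbs the
gyromagnetic factor so the solution is directly [dB0 in Hz, G in mT/m].

Solving data from one scheme with another method's equations
------------------------------------------------------------
A CVP acquisition contains a VP acquisition (steps 1-2), and an FCVP
acquisition can be evaluated with VP or CVP equations if the sign inversion
of its steps 2/4 is carried into the design-matrix P blocks.  The mapping is:

===========  ==========  ======================================================
data scheme  method      rows used (signs of the P/d^VP blocks per step)
===========  ==========  ======================================================
vp           vp          k=1: +P | k=2: 0
cvp          vp          k=1: +P | k=2: 0                       (steps 3-4 unused)
cvp          cvp         k=1: +P,+P_n | k=2: 0 | k=3: +P_n | k=4: 0
fcvp         vp          k=1: +P | k=2: -P
fcvp         cvp         k=1: +P,+P_n | k=2: -P,-P_n | k=3: +P_n | k=4: -P_n
fcvp         fcvp        as cvp-on-fcvp but with per-(n, slice) nuisance columns
===========  ==========  ======================================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import HZ_PER_MTM_MM
from .errors import ParameterError, StructureError
from .scheme import CVP, FCVP, VP, SliceSet
from .simulate import FIDDataset


@dataclass
class FrequencySeries:
    """Instantaneous frequencies f_{n,k}(r_m, t) with magnitude weights."""

    values: np.ndarray  # Hz, shape (N, K, M, T)
    weights: np.ndarray  # |S|, same shape
    dwell: float  # us
    times: np.ndarray  # us
    scheme_method: str
    steps: tuple

    def __post_init__(self) -> None:
        if self.values.shape != self.weights.shape:
            raise ParameterError("values and weights must share a shape")
        if (self.weights < 0).any():
            raise ParameterError("weights must be non-negative")


@dataclass
class DesignMatrix:
    """Stacked coefficient matrix of one method applied to one data scheme.

    Rows are ordered step-major, then prephasing step, then slice
    (all n for k=1, then k=2, ...).  ``layout`` maps unknown-block names to
    column slices; ``step_indices`` selects the used steps on the data's
    step axis.
    """

    A: np.ndarray
    layout: dict
    method: str
    data_method: str
    step_indices: tuple
    n_pre: int
    n_slices: int

    @property
    def n_unknowns(self) -> int:
        return self.A.shape[1]


@dataclass
class FieldCoefficients:
    """Estimated field coefficients d(t) = [dB0(t), G(t)] plus diagnostics.

    ``b0`` carries a caveat: B0 cross-terms of real gradient chains drift and
    are not corrected by these methods; treat dB0 estimates as indicative.
    """

    times: np.ndarray  # us
    b0: np.ndarray  # Hz
    g: np.ndarray  # mT/m
    d_vp: np.ndarray | None  # (N, 2, T): per-prephaser [dB0_n, G_n]
    nuisance: np.ndarray  # (n_nuisance, T)
    nuisance_layout: dict
    condition: np.ndarray  # per-time condition number of the weighted system
    valid: np.ndarray  # bool mask, False where all weights vanished
    method: str
    axis_label: str = "x"


# ---------------------------------------------------------------------------
# Frequency extraction
# ---------------------------------------------------------------------------

def extract_frequency(data: FIDDataset) -> FrequencySeries:
    """Phase-derivative frequencies of an FID dataset.

    The phase is unwrapped along t per trace, differentiated with central
    differences at interior points (one-sided at the edges), and divided by
    2*pi.  Weights are the signal magnitudes at the matching samples.
    """
    if data.n_samples < 2:
        raise ParameterError("need at least 2 time samples to differentiate")
    phase = np.unwrap(np.angle(data.signal), axis=-1)
    dt_s = data.dwell * 1e-6
    freq = np.gradient(phase, dt_s, axis=-1) / (2.0 * np.pi)
    return FrequencySeries(values=freq, weights=np.abs(data.signal),
                           dwell=data.dwell, times=data.times,
                           scheme_method=data.scheme.method,
                           steps=data.scheme.steps)


def median_filter_time(f: FrequencySeries, length: int = 3) -> FrequencySeries:
    """Moving median along t with a symmetrically shrinking window at edges.

    The window keeps an odd size everywhere: at distance i from an edge it
    shrinks to ``2*min(i, (length-1)//2) + 1`` samples, so single-sample
    spikes are removed down to the second sample and edge samples pass
    through unchanged.  Weights are not filtered.
    """
    if length < 1 or length % 2 == 0:
        raise ParameterError("median filter length must be odd and >= 1")
    if length == 1:
        return f
    half = (length - 1) // 2
    x = f.values
    t_len = x.shape[-1]
    out = np.empty_like(x)
    for i in range(t_len):
        w = min(i, t_len - 1 - i, half)
        out[..., i] = np.median(x[..., i - w:i + w + 1], axis=-1)
    return FrequencySeries(values=out, weights=f.weights, dwell=f.dwell,
                           times=f.times, scheme_method=f.scheme_method,
                           steps=f.steps)


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def _p_block(slices: SliceSet) -> np.ndarray:
    r = slices.positions
    return np.column_stack([np.ones_like(r), HZ_PER_MTM_MM * r])


_VALID = {
    (VP, VP), (CVP, VP), (CVP, CVP), (FCVP, VP), (FCVP, CVP), (FCVP, FCVP),
}


def assemble_design(data_method: str, method: str, slices: SliceSet,
                    n_pre: int) -> DesignMatrix:
    """Build the stacked design matrix for ``method`` applied to data acquired
    with ``data_method`` (see module docstring for the sign mapping)."""
    if (data_method, method) not in _VALID:
        raise StructureError(
            f"cannot solve {data_method!r} data with the {method!r} equations")
    m = slices.n_slices
    if m < 2:
        raise StructureError("need M >= 2 slices")
    p = _p_block(slices)
    eye = np.eye(m)
    n = n_pre

    # Sign of the P/d^VP blocks per step, induced by the data scheme.
    fcvp_data = data_method == FCVP
    sign = {1: 1.0, 2: -1.0 if fcvp_data else 0.0,
            3: 1.0, 4: -1.0 if fcvp_data else 0.0}
    # For non-FCVP data, steps 2/4 contain no prephaser/test at all: the sign
    # entry 0 encodes "no P contribution".

    if method == VP:
        steps = (1, 2)
        cols = 2 + m
        layout = {"d": slice(0, 2), "qI": slice(2, 2 + m)}
        a = np.zeros((len(steps) * n * m, cols))
        row = 0
        for k in steps:
            for _ in range(n):
                a[row:row + m, layout["d"]] = sign[k] * p
                a[row:row + m, layout["qI"]] = eye
                row += m
    elif method == CVP:
        steps = (1, 2, 3, 4)
        cols = 2 + 2 * n + 2 * m
        layout = {"d": slice(0, 2)}
        for i in range(n):
            layout[f"d_vp{i + 1}"] = slice(2 + 2 * i, 4 + 2 * i)
        layout["qI"] = slice(2 + 2 * n, 2 + 2 * n + m)
        layout["qII"] = slice(2 + 2 * n + m, cols)
        a = np.zeros((4 * n * m, cols))
        row = 0
        for k in steps:
            for i in range(n):
                if k in (1, 2):
                    if k == 1 or fcvp_data:
                        a[row:row + m, layout["d"]] = sign[k] * p
                        a[row:row + m, layout[f"d_vp{i + 1}"]] = sign[k] * p
                    a[row:row + m, layout["qI"]] = eye
                else:
                    if k == 3 or fcvp_data:
                        a[row:row + m, layout[f"d_vp{i + 1}"]] = sign[k] * p
                    a[row:row + m, layout["qII"]] = eye
                row += m
    else:  # FCVP on FCVP data
        steps = (1, 2, 3, 4)
        cols = 2 + 2 * n + 2 * n * m
        layout = {"d": slice(0, 2)}
        for i in range(n):
            layout[f"d_vp{i + 1}"] = slice(2 + 2 * i, 4 + 2 * i)
        for i in range(n):
            layout[f"cI{i + 1}"] = slice(2 + 2 * n + i * m, 2 + 2 * n + (i + 1) * m)
        off = 2 + 2 * n + n * m
        for i in range(n):
            layout[f"cII{i + 1}"] = slice(off + i * m, off + (i + 1) * m)
        a = np.zeros((4 * n * m, cols))
        row = 0
        for k in steps:
            for i in range(n):
                if k in (1, 2):
                    a[row:row + m, layout["d"]] = sign[k] * p
                    a[row:row + m, layout[f"d_vp{i + 1}"]] = sign[k] * p
                    a[row:row + m, layout[f"cI{i + 1}"]] = eye
                else:
                    a[row:row + m, layout[f"d_vp{i + 1}"]] = sign[k] * p
                    a[row:row + m, layout[f"cII{i + 1}"]] = eye
                row += m

    return DesignMatrix(A=a, layout=layout, method=method,
                        data_method=data_method,
                        step_indices=tuple(range(len(steps))), n_pre=n,
                        n_slices=m)


def assemble_system(freq: FrequencySeries, slices: SliceSet, method: str
                    ) -> tuple[DesignMatrix, np.ndarray, np.ndarray]:
    """Design matrix plus stacked observations/weights per time point.

    Returns ``(design, obs, wts)`` with ``obs``/``wts`` of shape (T, rows),
    row-ordered step-major, then prephasing step, then slice.
    """
    n_pre, n_steps_data, m, t_len = freq.values.shape
    if m != slices.n_slices:
        raise StructureError("frequency slice axis inconsistent with slices")
    dm = assemble_design(freq.scheme_method, method, slices, n_pre)
    n_steps_used = len(dm.step_indices)
    if n_steps_used > n_steps_data:
        raise StructureError(
            f"{method!r} needs {n_steps_used} steps; data has {n_steps_data}")
    # (N, Kused, M, T) -> (T, Kused, N, M) -> (T, rows)
    val = freq.values[:, :n_steps_used]
    wts = freq.weights[:, :n_steps_used]
    obs = np.transpose(val, (3, 1, 0, 2)).reshape(t_len, -1)
    w = np.transpose(wts, (3, 1, 0, 2)).reshape(t_len, -1)
    return dm, obs, w


# ---------------------------------------------------------------------------
# Weighted least squares
# ---------------------------------------------------------------------------

def solve_weighted_ls(a: np.ndarray, f_t: np.ndarray, weights: np.ndarray,
                      ) -> tuple[np.ndarray, float]:
    """Weighted least-squares solution b = (A' W A)^-1 A' W f, W = diag(w^2).

    ``weights`` are signal magnitudes |S| (so W = diag(|S|^2)).  The system is
    solved by an SVD-based least-squares factorization of the row-scaled
    system rather than through explicit normal equations.  Singular or
    rank-deficient systems return the minimum-norm solution; if every weight
    is zero, a NaN vector is returned.

    Returns
    -------
    (b, condition):
        Solution vector and the 2-norm condition number of the weighted
        matrix (inf for rank-deficient systems).
    """
    a = np.asarray(a, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ParameterError("weights must be non-negative")
    if not np.any(w > 0):
        return np.full(a.shape[1], np.nan), np.inf
    aw = a * w[:, None]
    fw = np.asarray(f_t, dtype=float) * w
    b, _, rank, sv = np.linalg.lstsq(aw, fw, rcond=None)
    cond = np.inf if rank < a.shape[1] else float(sv[0] / sv[-1])
    return b, cond


def estimate_waveform(data: FIDDataset, method: str,
                      filter_length: int = 3) -> FieldCoefficients:
    """Full estimation pipeline: phase derivative -> moving median ->
    per-time-point weighted least squares.

    ``method`` may differ from the acquisition scheme where the mapping is
    defined (see module docstring).  Time points where every observation has
    zero magnitude are returned as NaN with ``valid=False`` — never
    interpolated silently.
    """
    freq = extract_frequency(data)
    if filter_length > 1:
        freq = median_filter_time(freq, filter_length)
    dm, obs, wts = assemble_system(freq, data.slices, method)

    t_len = obs.shape[0]
    n_unk = dm.n_unknowns
    b_all = np.full((t_len, n_unk), np.nan)
    cond = np.full(t_len, np.inf)
    valid = np.zeros(t_len, dtype=bool)
    for t in range(t_len):
        if not np.any(wts[t] > 0):
            continue
        b_all[t], cond[t] = solve_weighted_ls(dm.A, obs[t], wts[t])
        valid[t] = np.isfinite(b_all[t]).all()

    d = b_all[:, dm.layout["d"]]
    d_vp = None
    if method in (CVP, FCVP):
        d_vp = np.empty((dm.n_pre, 2, t_len))
        for i in range(dm.n_pre):
            d_vp[i] = b_all[:, dm.layout[f"d_vp{i + 1}"]].T
    nuis_names = [name for name in dm.layout
                  if name not in ("d",) and not name.startswith("d_vp")]
    nuis_cols = [c for name in nuis_names
                 for c in range(*dm.layout[name].indices(n_unk))]
    nuisance = b_all[:, nuis_cols].T
    nuis_layout = {}
    pos = 0
    for name in nuis_names:
        width = len(range(*dm.layout[name].indices(n_unk)))
        nuis_layout[name] = slice(pos, pos + width)
        pos += width

    return FieldCoefficients(times=freq.times, b0=d[:, 0], g=d[:, 1],
                             d_vp=d_vp, nuisance=nuisance,
                             nuisance_layout=nuis_layout, condition=cond,
                             valid=valid, method=method,
                             axis_label=data.scheme.test_waveform.axis_label)


def interpolate_invalid(fc: FieldCoefficients) -> FieldCoefficients:
    """Opt-in linear interpolation across invalid (NaN) time points.

    Returns a new :class:`FieldCoefficients` with ``b0``/``g`` interpolated
    over the gaps flagged by ``valid``; the mask itself is preserved so the
    filled samples remain identifiable.  Estimation never does this
    silently.
    """
    from dataclasses import replace

    if fc.valid.all():
        return fc
    if not fc.valid.any():
        raise ParameterError("no valid time points to interpolate from")
    t_ok = fc.times[fc.valid]

    def fill(y: np.ndarray) -> np.ndarray:
        return np.interp(fc.times, t_ok, y[fc.valid])

    return replace(fc, b0=fill(fc.b0), g=fill(fc.g))


def vp_tail_prediction(data: FIDDataset, tails: np.ndarray) -> np.ndarray:
    """Magnitude-weighted combination of prephaser lingering fields.

    Predicts the VP-minus-CVP difference: each prephasing step contributes to
    the VP solution in proportion to its squared step-1 signal magnitude
    (averaged over slices), so the uncompensated prephaser tails enter as

        sum_n w_n(t) * G_n^VP(t) / sum_n w_n(t),
        w_n(t) = mean_m |S(n, 1, m, t)|^2.

    ``tails`` has shape (N, T), e.g. from
    :func:`cvpgrad.simulate.prephaser_outputs`.
    """
    w = np.mean(np.abs(data.signal[:, 0]) ** 2, axis=1)  # (N, T)
    den = w.sum(axis=0)
    den = np.where(den > 0, den, np.nan)
    return (w * tails).sum(axis=0) / den
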