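"""Canonical benchmark scenarios exercising the full method chain.

Each function builds its inputs from scratch (simulator + estimators), runs
one capability end-to-end and returns the measured quantities.  The defaults
are the package's study conditions: 9 slices spanning +/-20 mm, 5 prephasing
steps, a 10 mT/m trapezoidal test gradient (150 us ramps, 300 us flat top),
a 30 mT/m six-lobe EPI-style test train, and a 64x64 / 200 mm simulated EPI
acquisition at 5 us ADC dwell.

These scenarios double as regression benchmarks (tests) and as the
reproduction entry points used by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .chain import GradientChainModel, apply_chain
from .epi import (circular_mask, design_epi, ghost_intensity,
                  integrate_trajectory, make_phantom, navigator_correct,
                  optimize_delay, reconstruct, simulate_epi_raw)
from .estimation import estimate_waveform, solve_weighted_ls, vp_tail_prediction
from .gstf import estimate_gstf, make_triangle_set, predict_waveform
from .scheme import SliceSet, build_scheme, choose_prephasers
from .simulate import prephaser_outputs, simulate_fid, simulated_test_gradient
from .waveforms import make_epi_train, make_slice_select, make_trapezoid

#: Interior-sample trim: the phase-derivative stencil is one-sided at the
#: first/last readout sample, so recovery is evaluated on interior samples.
EDGE = 2


def _slices9() -> SliceSet:
    return SliceSet(np.linspace(-20.0, 20.0, 9), 3.0)


def _trapezoid_parts(dwell_wf: float = 1.0):
    test = make_trapezoid(10.0, 150.0, 300.0, dwell_wf)
    ss, exc = make_slice_select(6.0, 100.0, 300.0, dwell_wf)
    return test, ss, exc


def _epi_train_parts(dwell_wf: float = 1.0):
    test = make_epi_train(30.0, 100.0, 320.0, 6, dwell_wf)
    ss, exc = make_slice_select(6.0, 100.0, 300.0, dwell_wf)
    return test, ss, exc


def _plateau_indices(data, scheme, n_lobes: int = 6):
    """Readout sample indices of the EPI-train flat-top centers."""
    t = data.times - scheme.readout_start
    centers = 100.0 + 160.0 + np.arange(n_lobes) * (320.0 + 200.0)
    return np.searchsorted(t, centers)


# ---------------------------------------------------------------------------
# Weighted-least-squares oracle
# ---------------------------------------------------------------------------

def wls_oracle_error(n_systems: int = 120, seed: int = 0) -> float:
    """Max relative deviation of the solver from the explicit
    (A' W A)^-1 A' W f normal-equation formula over random systems
    (<= 20 rows, <= 10 unknowns, random positive weights)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_systems):
        rows = int(rng.integers(11, 21))
        cols = int(rng.integers(2, 11))
        a = rng.normal(size=(rows, cols))
        f = rng.normal(size=rows)
        w = rng.uniform(0.1, 3.0, size=rows)
        b, _ = solve_weighted_ls(a, f, w)
        sigma = np.diag(w ** 2)
        ref = np.linalg.solve(a.T @ sigma @ a, a.T @ sigma @ f)
        worst = max(worst, float(np.linalg.norm(b - ref)
                                 / np.linalg.norm(ref)))
    return worst


# ---------------------------------------------------------------------------
# Exact recovery of a trapezoid through a clean chain
# ---------------------------------------------------------------------------

def trapezoid_recovery_errors(dwell: float = 2.0) -> dict:
    """Max |G_hat - G_true| as % of peak for VP, CVP and FCVP on a noiseless
    trapezoid through a band-limited but otherwise clean chain."""
    model = GradientChainModel(delay=2.0, lowpass_bandwidth=15.0)
    test, ss, exc = _trapezoid_parts()
    amps = choose_prephasers(test, 5)
    slices = _slices9()
    out = {}
    sch_cvp = build_scheme("cvp", test, amps, ss, exc, readout_duration=1500.0)
    data_cvp = simulate_fid(sch_cvp, model, slices, dwell=dwell)
    truth = simulated_test_gradient(sch_cvp, model, dwell=dwell)
    peak = float(np.abs(truth).max())
    for method in ("vp", "cvp"):
        g = estimate_waveform(data_cvp, method).g
        out[method] = 100.0 * float(
            np.nanmax(np.abs(g - truth)[EDGE:-EDGE])) / peak
    sch_f = build_scheme("fcvp", test, amps, ss, exc, readout_duration=1500.0)
    data_f = simulate_fid(sch_f, model, slices, dwell=dwell)
    g = estimate_waveform(data_f, "fcvp").g
    out["fcvp"] = 100.0 * float(np.nanmax(np.abs(g - truth)[EDGE:-EDGE])) / peak
    return out


# ---------------------------------------------------------------------------
# Prephaser-tail mechanism (VP vs CVP)
# ---------------------------------------------------------------------------

def prephaser_tail_mechanism(dwell: float = 2.0) -> dict:
    """Damped-resonance prephaser tails overlapping the readout.

    Returns the correlation between the VP-CVP difference and the
    |S|^2-weighted sum of the simulated prephaser lingering fields, plus the
    CVP and VP recovery errors (% of peak).  The correlation excludes samples
    within 30 us of the trapezoid ramp corners, where the finite-difference
    stencil leaves switching spikes in both estimates.
    """
    model = GradientChainModel(delay=2.0, lowpass_bandwidth=15.0,
                               resonance_terms=((0.005, 1.1, 2.0),))
    test, ss, exc = _trapezoid_parts()
    amps = choose_prephasers(test, 5)
    sch = build_scheme("cvp", test, amps, ss, exc, readout_duration=1500.0)
    data = simulate_fid(sch, model, _slices9(), dwell=dwell)
    truth = simulated_test_gradient(sch, model, dwell=dwell)
    peak = float(np.abs(truth).max())
    g_vp = estimate_waveform(data, "vp").g
    g_cvp = estimate_waveform(data, "cvp").g
    tails = prephaser_outputs(sch, model, dwell=dwell)
    pred = vp_tail_prediction(data, tails)

    t = data.times - sch.readout_start
    corners = np.array([0.0, 150.0, 450.0, 600.0])
    keep = np.all(np.abs(t[:, None] - corners[None, :]) > 30.0, axis=1)
    keep[:EDGE] = keep[-EDGE:] = False
    diff = g_vp - g_cvp
    corr = float(np.corrcoef(diff[keep], pred[keep])[0, 1])
    return {
        "correlation": corr,
        "cvp_error_pct": 100.0 * float(
            np.nanmax(np.abs(g_cvp - truth)[EDGE:-EDGE])) / peak,
        "vp_error_pct": 100.0 * float(
            np.nanmax(np.abs(g_vp - truth)[EDGE:-EDGE])) / peak,
    }


# ---------------------------------------------------------------------------
# Concomitant-field mechanism (FCVP vs CVP)
# ---------------------------------------------------------------------------

def concomitant_mechanism(dwell: float = 2.0) -> dict:
    """Quadratic concomitant term on, sign-symmetric chain.

    FCVP cancels the concomitant contribution by its inverted-sign steps;
    CVP (which neglects it) acquires a bias whose sign is the same on
    positive and negative lobes of the EPI-style test train.
    """
    model = GradientChainModel(delay=2.0, lowpass_bandwidth=15.0,
                               kappa0=0.05, kappa1=142.0)
    test, ss, exc = _epi_train_parts()
    amps = choose_prephasers(test, 5)
    slices = _slices9()
    ro = test.duration + 600.0
    sch_c = build_scheme("cvp", test, amps, ss, exc, readout_duration=ro)
    sch_f = build_scheme("fcvp", test, amps, ss, exc, readout_duration=ro)
    data_c = simulate_fid(sch_c, model, slices, dwell=dwell)
    data_f = simulate_fid(sch_f, model, slices, dwell=dwell)
    truth = simulated_test_gradient(sch_c, model, dwell=dwell)
    peak = float(np.abs(truth).max())
    g_cvp = estimate_waveform(data_c, "cvp").g
    g_fcvp = estimate_waveform(data_f, "fcvp").g
    idx = _plateau_indices(data_c, sch_c)
    return {
        "fcvp_error_pct": 100.0 * float(
            np.nanmax(np.abs(g_fcvp - truth)[EDGE:-EDGE])) / peak,
        "cvp_bias_lobes": (g_cvp - truth)[idx],
        "lobe_signs": np.sign(truth[idx]),
    }


# ---------------------------------------------------------------------------
# Amplifier sign-asymmetry mechanism (CVP vs FCVP)
# ---------------------------------------------------------------------------

def asymmetry_mechanism(dwell: float = 2.0,
                        sign_asymmetry: float = 0.02) -> dict:
    """Sign-asymmetric amplifier gain on, concomitant off.

    CVP measures the true (asymmetric) output; FCVP's inverted-sign
    subtraction recovers only the odd component of the amplifier map, so the
    FCVP-CVP difference equals minus the even component -|G|*a/2, sampled
    here at the plateau centers of the EPI-style train.
    """
    model = GradientChainModel(delay=2.0, lowpass_bandwidth=15.0,
                               sign_asymmetry=sign_asymmetry)
    test, ss, exc = _epi_train_parts()
    amps = choose_prephasers(test, 5)
    slices = _slices9()
    ro = test.duration + 600.0
    sch_c = build_scheme("cvp", test, amps, ss, exc, readout_duration=ro)
    sch_f = build_scheme("fcvp", test, amps, ss, exc, readout_duration=ro)
    data_c = simulate_fid(sch_c, model, slices, dwell=dwell)
    data_f = simulate_fid(sch_f, model, slices, dwell=dwell)
    truth = simulated_test_gradient(sch_c, model, dwell=dwell)
    peak = float(np.abs(truth).max())
    g_cvp = estimate_waveform(data_c, "cvp").g
    g_fcvp = estimate_waveform(data_f, "fcvp").g
    idx = _plateau_indices(data_c, sch_c)
    return {
        "cvp_error_pct": 100.0 * float(
            np.nanmax(np.abs(g_cvp - truth)[EDGE:-EDGE])) / peak,
        "fcvp_cvp_diff_lobes": (g_fcvp - g_cvp)[idx],
        "lobe_signs": np.sign(truth[idx]),
    }


# ---------------------------------------------------------------------------
# EPI: delay recovery and ghost ordering
# ---------------------------------------------------------------------------

def delay_recovery(injected_delay: float) -> float:
    """Recover an injected pure chain delay from simulated EPI by scanning
    reconstruction delays against the out-of-mask intensity sum (quartic fit
    on a 9-point window around the scan minimum)."""
    geo = design_epi(64, 200.0, 5.0, 100.0)
    model = GradientChainModel(delay=injected_delay)
    actual = apply_chain(geo.readout, model, tail_us=500.0)
    traj = integrate_trajectory(actual, geo.adc_times, k_pe=geo.k_pe,
                                nominal=geo.readout)
    raw = simulate_epi_raw(make_phantom(64), traj, 200.0, dwell_adc=5.0)
    report = optimize_delay(raw, geo.readout, geo.adc_times,
                            delay_grid=np.arange(-10.0, 10.0 + 1e-9, 0.5),
                            nominal=geo.readout, fit_window=9)
    return float(report.optimal_delay)


def ghost_ordering(roi1: tuple = (1, 24, 5, 16)) -> dict:
    """Relative ghost intensity under three trajectory corrections.

    The chain carries a mechanical resonance near the readout frequency, a
    3 us delay and a 0.2% amplifier sign asymmetry.  The navigator-corrected
    nominal-trajectory reconstruction sees everything as ghosting; the
    GSTF-predicted trajectory removes the LTI part (resonance + delay) but
    not the asymmetry; the true-waveform trajectory removes all of it.
    """
    import warnings

    geo = design_epi(64, 200.0, 5.0, 100.0)
    model = GradientChainModel(delay=3.0, lowpass_bandwidth=30.0,
                               resonance_terms=((0.004, 1.0, 3.0),),
                               sign_asymmetry=0.002)
    actual = apply_chain(geo.readout, model, tail_us=1000.0)
    traj_true = integrate_trajectory(actual, geo.adc_times, k_pe=geo.k_pe,
                                     nominal=geo.readout)
    traj_nom = integrate_trajectory(geo.readout, geo.adc_times, k_pe=geo.k_pe)

    triangles = make_triangle_set(12, 20.0, 5.0, 80.0, 300.0)
    measured = [apply_chain(t, model, tail_us=3000.0) for t in triangles]
    gstf = estimate_gstf(triangles, measured, regularization=1e-6)
    predicted = predict_waveform(geo.readout, gstf)
    traj_gstf = integrate_trajectory(predicted, geo.adc_times, k_pe=geo.k_pe,
                                     nominal=geo.readout)

    ref_traj = integrate_trajectory(actual, geo.adc_times[:3],
                                    k_pe=np.zeros(3), nominal=geo.readout)
    raw = simulate_epi_raw(make_phantom(64), traj_true, 200.0,
                           ref_traj=ref_traj, dwell_adc=5.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # drifted trajectories leave the box
        img_nom = reconstruct(navigator_correct(raw), traj_nom)
        img_gstf = reconstruct(raw, traj_gstf)
        img_true = reconstruct(raw, traj_true)
    return {
        "gamma_nominal_pct": ghost_intensity(img_nom, roi1).gamma,
        "gamma_gstf_pct": ghost_intensity(img_gstf, roi1).gamma,
        "gamma_true_pct": ghost_intensity(img_true, roi1).gamma,
    }


# ---------------------------------------------------------------------------
# GSTF self-consistency
# ---------------------------------------------------------------------------

def gstf_self_consistency() -> float:
    """Estimate a GSTF from 12 simulated triangles and predict an unseen
    trapezoid; returns the max in-band error as % of peak."""
    model = GradientChainModel(delay=3.0, lowpass_bandwidth=20.0,
                               eddy_terms=((0.01, 1.5),),
                               resonance_terms=((0.004, 1.2, 2.5),))
    triangles = make_triangle_set(12, 20.0, 5.0, 80.0, 300.0)
    measured = [apply_chain(t, model, tail_us=4000.0) for t in triangles]
    gstf = estimate_gstf(triangles, measured, regularization=1e-6)
    trap = make_trapezoid(25.0, 200.0, 500.0, 5.0)
    pred = predict_waveform(trap, gstf)
    truth = apply_chain(trap, model, tail_us=float(trap.duration))
    n = min(pred.samples.size, truth.samples.size)
    err = float(np.abs(pred.samples[:n] - truth.samples[:n]).max())
    return 100.0 * err / float(np.abs(truth.samples).max())
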