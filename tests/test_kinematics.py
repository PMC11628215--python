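"""Kinematic preprocessing, slopes, dispersion ellipses, force contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from reach_ofc.analysis import AnalysisConfig, detect_vision_onset, dispersion_ellipse_area
from reach_ofc.analysis.kinematics import (InsufficientDataError, central_difference,
                                           fit_shift_slope, lateral_force_contrast,
                                           lowpass_dual_pass, preprocess_kinematics)
from reach_ofc.regression import DegenerateDesignError, slope_on_shift


def _table(trials):
    """Build (samples, meta) from {trial_id: dict(cols=..., meta=...)}."""
    srows, mrows = [], []
    for tid, info in trials.items():
        n = len(info["t"])
        srows.append(pd.DataFrame({
            "participant": info.get("participant", 0), "trial": tid,
            "t": info["t"],
            "x": info.get("x", np.zeros(n)), "y": info.get("y", np.zeros(n)),
            "fx": info.get("fx", np.zeros(n)), "fy": info.get("fy", np.zeros(n))}))
        mrows.append({"participant": info.get("participant", 0), "trial": tid,
                      "experiment": info.get("experiment", 1),
                      "speed": info.get("speed", "fast"),
                      "uncertainty": info.get("uncertainty", "low"),
                      "shift": info.get("shift", 0.0),
                      "force_dir": info.get("force_dir", 9.0),
                      "is_calibration": False})
    return pd.concat(srows, ignore_index=True), pd.DataFrame(mrows)


def test_constant_position_passes_filter_with_zero_velocity():
    t = np.arange(0, 1, 0.001)
    samples, meta = _table({"a": {"t": t, "x": np.full_like(t, 0.03)}})
    out = preprocess_kinematics(samples)
    np.testing.assert_allclose(out["x"], 0.03, atol=1e-9)
    np.testing.assert_allclose(out["vx"], 0.0, atol=1e-6)


def test_low_frequency_signal_preserved():
    """10 Hz sinusoid through the dual-pass 50 Hz low-pass keeps > 99% of its
    amplitude (squared 4th-order magnitude response at 0.2x cutoff)."""
    t = np.arange(0, 2, 0.001)
    x = np.sin(2 * np.pi * 10 * t)
    y = lowpass_dual_pass(x[None, :], 50.0, 1000.0)[0]
    assert np.max(np.abs(y[500:1500])) > 0.99


def test_central_difference_exact_for_cubics():
    t = np.arange(0, 1, 0.001)
    x = 2.0 * t ** 3 - 0.7 * t ** 2 + 0.3 * t - 1.0
    v = central_difference(x, 0.001)
    v_true = 6.0 * t ** 2 - 1.4 * t + 0.3
    np.testing.assert_allclose(v[2:-2], v_true[2:-2], atol=1e-10)


def test_shift_slope_closed_form_cases():
    shifts = np.array([-0.02, 0.0, 0.02])
    s, _ = slope_on_shift(shifts, np.array([0.01, 0.0, -0.01]))
    assert s == pytest.approx(-0.5)
    s, _ = slope_on_shift(shifts, -shifts)
    assert s == pytest.approx(-1.0)
    s, _ = slope_on_shift(shifts, np.zeros(3))
    assert s == pytest.approx(0.0)
    with pytest.raises(DegenerateDesignError):
        slope_on_shift(np.array([0.02, 0.02]), np.array([1.0, 2.0]))


@given(a=st.floats(-5, 5), b=st.floats(-5, 5))
@settings(max_examples=25, deadline=None)
def test_shift_slope_affine_equivariance(a, b):
    """slope(a*shift + b per-point offset...) responds linearly: values
    v = a*shifts + b give slope exactly a."""
    shifts = np.array([-0.02, 0.0, 0.02])
    s, icpt = slope_on_shift(shifts, a * shifts + b)
    assert s == pytest.approx(a, abs=1e-9)
    assert icpt == pytest.approx(b, abs=1e-9)


def test_fit_shift_slope_recovers_imposed_compensation():
    """Lateral position exactly -0.6 x shift at all times -> slope -0.6."""
    t = np.arange(0, 1.2, 0.001)
    y = np.minimum(t / 2.0, 0.21)          # crosses 8 cm at 160 ms, reaches 21 cm
    trials = {}
    for i, shift in enumerate((-0.02, 0.0, 0.02)):
        trials[f"tr{i}"] = {"t": t, "y": y, "x": np.full_like(t, -0.6 * shift),
                            "shift": shift}
    samples, meta = _table(trials)
    cfg = AnalysisConfig(latencies_ms=(150, 300))
    events = detect_vision_onset(samples, meta, cfg)
    slopes, summary = fit_shift_slope(samples, meta, events, cfg)
    np.testing.assert_allclose(slopes["slope"], -0.6, atol=1e-9)
    assert set(summary["latency_ms"]) == {150, 300}


def test_vision_onset_detection_and_exclusions():
    t = np.arange(0, 1.0, 0.001)
    ramp = np.minimum(t / 2.0, 0.21)
    trials = {
        "ok": {"t": t, "y": ramp},
        "undershoot": {"t": t, "y": ramp * 0.85},        # peaks below 20 cm
        "stalled": {"t": t, "y": np.full_like(t, 0.05)},  # never shows vision
        "exp2slow": {"t": t, "y": ramp, "experiment": 2, "speed": "slow"},
    }
    samples, meta = _table(trials)
    ev = detect_vision_onset(samples, meta).set_index("trial")
    assert ev.loc["ok", "vision_on_t"] == pytest.approx(0.160, abs=1e-9)
    assert ev.loc["ok", "vision_off_t"] - ev.loc["ok", "vision_on_t"] == pytest.approx(0.100)
    assert ev.loc["undershoot", "excluded"] and \
        ev.loc["undershoot", "exclusion_reason"] == "undershoot"
    assert ev.loc["stalled", "excluded"]
    assert ev.loc["exp2slow", "vision_off_t"] - ev.loc["exp2slow", "vision_on_t"] \
        == pytest.approx(0.170)


def test_dispersion_ellipse_area_properties(rng):
    assert dispersion_ellipse_area(np.tile([[1.0, 2.0]], (10, 1))) == pytest.approx(0.0)
    pts = rng.normal(0.0, 1.0, size=(10_000, 2))
    assert dispersion_ellipse_area(pts) == pytest.approx(np.pi, rel=0.05)
    # rotation invariance
    base = rng.normal(0.0, 1.0, size=(5_000, 2)) * np.array([2.0, 1.0])
    th = np.deg2rad(30)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    a0 = dispersion_ellipse_area(base)
    a1 = dispersion_ellipse_area(base @ R.T)
    assert a1 == pytest.approx(a0, rel=0.01)
    with pytest.raises(InsufficientDataError):
        dispersion_ellipse_area(np.array([[0.0, 0.0]]))


def test_lateral_force_contrast_identity_and_zero_case(rng):
    """(right-none)-(left-none) equals right-left to machine precision, and
    identical traces across shifts give a zero contrast."""
    t = np.arange(0, 1.2, 0.001)
    y = np.minimum(t / 2.0, 0.21)
    f = np.sin(2 * np.pi * 1.3 * t)
    d = 0.5 * np.exp(-((t - 0.5) ** 2) / 0.01)
    trials = {}
    for i, (shift, fx) in enumerate({(-0.02): f - d, 0.0: f, 0.02: f + d}.items()):
        trials[f"tr{i}"] = {"t": t, "y": y, "fx": fx, "shift": shift}
    samples, meta = _table(trials)
    events = detect_vision_onset(samples, meta)
    maxima, info = lateral_force_contrast(samples, meta, events, post_s=0.6)
    delta = info["traces"][(0, "low", "fast")]
    onset_idx = np.searchsorted(t, 0.160)
    expected = 2 * d[onset_idx:onset_idx + len(delta)]
    np.testing.assert_allclose(delta, expected, atol=1e-12)
    # identical traces
    trials = {f"e{i}": {"t": t, "y": y, "fx": f, "shift": s}
              for i, s in enumerate((-0.02, 0.0, 0.02))}
    samples, meta = _table(trials)
    maxima, info = lateral_force_contrast(samples, meta,
                                          detect_vision_onset(samples, meta),
                                          post_s=0.6)
    np.testing.assert_allclose(info["traces"][(0, "low", "fast")], 0.0, atol=1e-12)
    assert maxima["max_delta_force"].iloc[0] == pytest.approx(0.0, abs=1e-12)
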