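"""Kinematics and force analysis of trial tables.

A trial table is a pair of DataFrames: ``samples`` with one row per recorded
sample (participant, trial, t, x, y, fx, fy, optional EMG channels) and
``meta`` with one row per trial (condition labels, events). Coordinates are
SI: x lateral (rightward +), y forward, target midline at x = 0 and target
center ``target_distance`` ahead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.signal

from ..ofc.plant import InvalidParameterError
from ..regression import slope_on_shift
from .config import AnalysisConfig

TRIAL_KEY = ["participant", "trial"]


class SchemaError(ValueError):
    """Raised when a trial table violates its declared schema."""


class InsufficientDataError(ValueError):
    pass


class IncompleteCellError(ValueError):
    pass


# ---------------------------------------------------------------------------
# helpers

def _trial_groups(samples: pd.DataFrame) -> dict[tuple, np.ndarray]:
    return samples.groupby(TRIAL_KEY, sort=False).indices


def _uniform_dt(t: np.ndarray) -> float:
    dt = np.diff(t)
    if len(dt) == 0 or dt.min() <= 0 or (np.abs(dt - dt[0]) > 1e-6).any():
        raise SchemaError("non-uniform or non-monotone time grid within a trial")
    return float(dt[0])


def _batched_rows(samples: pd.DataFrame, groups: dict[tuple, np.ndarray],
                  col: str) -> list[tuple[list[tuple], np.ndarray, np.ndarray]]:
    """Group trials by identical length so filters run on stacked matrices."""
    by_len: dict[int, list[tuple]] = {}
    for key, idx in groups.items():
        by_len.setdefault(len(idx), []).append(key)
    out = []
    vals = samples[col].to_numpy()
    for n, keys in by_len.items():
        rows = np.stack([vals[groups[k]] for k in keys])
        idxs = np.stack([groups[k] for k in keys])
        out.append((keys, rows, idxs))
    return out


def central_difference(x: np.ndarray, dt: float) -> np.ndarray:
    """Fourth-order central difference along the last axis (exact through
    quartics in the interior); second-order one-sided stencils at the edges."""
    x = np.asarray(x, dtype=float)
    v = np.empty_like(x)
    v[..., 2:-2] = (-x[..., 4:] + 8 * x[..., 3:-1] - 8 * x[..., 1:-3] + x[..., :-4]) / (12 * dt)
    v[..., 0] = (-3 * x[..., 0] + 4 * x[..., 1] - x[..., 2]) / (2 * dt)
    v[..., 1] = (x[..., 2] - x[..., 0]) / (2 * dt)
    v[..., -2] = (x[..., -1] - x[..., -3]) / (2 * dt)
    v[..., -1] = (3 * x[..., -1] - 4 * x[..., -2] + x[..., -3]) / (2 * dt)
    return v


def lowpass_dual_pass(rows: np.ndarray, cutoff_hz: float, fs: float,
                      order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass; reflect padding
    with pad length well beyond 3x the filter order."""
    sos = scipy.signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    padlen = min(rows.shape[-1] - 1, max(24, 6 * order))
    return scipy.signal.sosfiltfilt(sos, rows, axis=-1, padtype="even", padlen=padlen)


# ---------------------------------------------------------------------------
# operations

def preprocess_kinematics(samples: pd.DataFrame,
                          config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Filter positions (dual-pass Butterworth low-pass) and derive velocities
    from the *raw* positions by fourth-order central difference, then apply
    the same filter to the velocities."""
    config = config or AnalysisConfig()
    groups = _trial_groups(samples)
    out = samples.copy()
    t = samples["t"].to_numpy()
    dts = {key: _uniform_dt(t[idx]) for key, idx in groups.items()}
    for col in ("x", "y"):
        vel = np.empty(len(samples))
        pos = np.empty(len(samples))
        for keys, rows, idxs in _batched_rows(samples, groups, col):
            dt = dts[keys[0]]
            fs = 1.0 / dt
            raw_v = central_difference(rows, dt)
            pos[idxs.ravel()] = lowpass_dual_pass(rows, config.kin_cutoff_hz, fs,
                                                  config.kin_order).ravel()
            vel[idxs.ravel()] = lowpass_dual_pass(raw_v, config.kin_cutoff_hz, fs,
                                                  config.kin_order).ravel()
        out[col] = pos
        out["v" + col] = vel
    return out


def detect_vision_onset(samples: pd.DataFrame, meta: pd.DataFrame,
                        config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Vision onset = first sample with y >= 8 cm; offset follows from the
    experiment/speed-specific viewing duration. Trials that never reach the
    target distance (undershoots) or never cross the vision threshold are
    flagged excluded."""
    config = config or AnalysisConfig()
    groups = _trial_groups(samples)
    y = samples["y"].to_numpy()
    t = samples["t"].to_numpy()
    meta_idx = meta.set_index(TRIAL_KEY)
    rows = []
    for key, idx in groups.items():
        yt = y[idx]
        crossed = yt >= config.vision_threshold_y
        m = meta_idx.loc[key]
        rec = {"participant": key[0], "trial": key[1],
               "vision_on_t": np.nan, "vision_off_t": np.nan,
               "excluded": False, "exclusion_reason": ""}
        if bool(m.get("is_calibration", False)):
            rec["excluded"] = True
            rec["exclusion_reason"] = "calibration"
        elif not crossed.any():
            rec["excluded"] = True
            rec["exclusion_reason"] = "never_crossed_vision_threshold"
        else:
            onset = t[idx][int(np.argmax(crossed))]
            dur = config.vision_duration[(int(m["experiment"]), str(m["speed"]))]
            rec["vision_on_t"] = onset
            rec["vision_off_t"] = onset + dur
            if yt.max() < config.target_distance - config.undershoot_margin:
                rec["excluded"] = True
                rec["exclusion_reason"] = "undershoot"
        rows.append(rec)
    return pd.DataFrame(rows)


def _analysis_trials(meta: pd.DataFrame, events: pd.DataFrame) -> pd.DataFrame:
    """Rightward-force, non-excluded trials (the cells carrying cursor shifts)."""
    ev = events.set_index(TRIAL_KEY)
    m = meta.set_index(TRIAL_KEY)
    joined = m.join(ev[["vision_on_t", "vision_off_t", "excluded"]], how="inner")
    sel = joined[(joined["force_dir"] > 0) & (~joined["excluded"])
                 & (~joined.get("is_calibration", False).astype(bool))]
    return sel.reset_index()


def value_at_latency(samples: pd.DataFrame, trials: pd.DataFrame, col: str,
                     latency_ms: float) -> pd.Series:
    """Sample ``col`` at vision onset + latency for each trial (nearest sample)."""
    groups = _trial_groups(samples)
    t = samples["t"].to_numpy()
    v = samples[col].to_numpy()
    out = {}
    for rec in trials.itertuples():
        key = (rec.participant, rec.trial)
        idx = groups[key]
        target_t = rec.vision_on_t + latency_ms / 1e3
        tt = t[idx]
        if target_t > tt[-1] + 1e-9:
            raise InvalidParameterError(
                f"latency {latency_ms} ms falls beyond trial {key} span")
        out[key] = v[idx[int(np.argmin(np.abs(tt - target_t)))]]
    return pd.Series(out, name=col)


def fit_shift_slope(samples: pd.DataFrame, meta: pd.DataFrame, events: pd.DataFrame,
                    config: AnalysisConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant OLS slope of lateral hand position (relative to the
    target midline) on cursor shift, at each extraction latency.

    Positions are condition means per participant before the regression.
    Returns (per-participant slopes, group mean +/- SEM summary).
    """
    config = config or AnalysisConfig()
    trials = _analysis_trials(meta, events)
    if trials.empty:
        raise InsufficientDataError("no analyzable rightward-force trials")
    rows = []
    for lat in config.latencies_ms:
        xs = value_at_latency(samples, trials, "x", lat)
        tt = trials.set_index(TRIAL_KEY).copy()
        tt["xlat"] = xs
        cell = (tt.groupby(["participant", "speed", "uncertainty", "shift"],
                           observed=True)["xlat"].mean().reset_index())
        for (p, sp, unc), grp in cell.groupby(["participant", "speed", "uncertainty"],
                                              observed=True):
            shifts = grp["shift"].to_numpy()
            slope, intercept = slope_on_shift(shifts, grp["xlat"].to_numpy())
            rows.append({"participant": p, "speed": sp, "uncertainty": unc,
                         "latency_ms": lat, "slope": float(slope),
                         "intercept": float(intercept)})
    slopes = pd.DataFrame(rows)
    summary = (slopes.groupby(["speed", "uncertainty", "latency_ms"], observed=True)["slope"]
               .agg(mean="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)),
                    n="count").reset_index())
    return slopes, summary


def dispersion_ellipse_area(points: np.ndarray) -> float:
    """Area of the 1-SD dispersion ellipse of a 2-D point cloud.

    Principal-axis SDs come from the singular values of the centered cloud;
    area = pi * s1 * s2. Any other coverage level rescales all areas by a
    common constant and leaves every comparison unchanged.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise InsufficientDataError("need at least two 2-D points")
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    sd = s / np.sqrt(len(pts) - 1)
    return float(np.pi * sd[0] * sd[1])


def position_variability(samples: pd.DataFrame, meta: pd.DataFrame, events: pd.DataFrame,
                         config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Dispersion-ellipse area of (x, y) positions at each extraction latency,
    per participant/uncertainty/speed (no-shift rightward-force trials)."""
    config = config or AnalysisConfig()
    trials = _analysis_trials(meta, events)
    trials = trials[trials["shift"] == 0.0]
    rows = []
    for lat in config.latencies_ms:
        xs = value_at_latency(samples, trials, "x", lat)
        ys = value_at_latency(samples, trials, "y", lat)
        tt = trials.set_index(TRIAL_KEY).copy()
        tt["xl"], tt["yl"] = xs, ys
        for (p, sp, unc), grp in tt.groupby(["participant", "speed", "uncertainty"],
                                            observed=True):
            if len(grp) < 3:
                continue
            area = dispersion_ellipse_area(grp[["xl", "yl"]].to_numpy())
            rows.append({"participant": p, "speed": sp, "uncertainty": unc,
                         "latency_ms": lat, "area_cm2": area * 1e4})
    return pd.DataFrame(rows)


def aligned_traces(samples: pd.DataFrame, trials: pd.DataFrame, col: str,
                   post_s: float, pre_s: float = 0.0) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Extract per-trial windows of ``col`` aligned to vision onset.

    Returns (matrix (n_trials, T) nan-padded, the trial frame, time axis in s
    relative to vision onset)."""
    groups = _trial_groups(samples)
    t = samples["t"].to_numpy()
    v = samples[col].to_numpy()
    first = next(iter(groups.values()))
    dt = _uniform_dt(t[first])
    npre, npost = int(round(pre_s / dt)), int(round(post_s / dt))
    mat = np.full((len(trials), npre + npost), np.nan)
    for i, rec in enumerate(trials.itertuples()):
        idx = groups[(rec.participant, rec.trial)]
        tt = t[idx]
        k = int(np.argmin(np.abs(tt - rec.vision_on_t)))
        lo, hi = k - npre, k + npost
        src_lo, src_hi = max(lo, 0), min(hi, len(idx))
        mat[i, src_lo - lo: src_hi - lo] = v[idx[src_lo:src_hi]]
    times = (np.arange(npre + npost) - npre) * dt
    return mat, trials.reset_index(drop=True), times


def lateral_force_contrast(samples: pd.DataFrame, meta: pd.DataFrame,
                           events: pd.DataFrame,
                           config: AnalysisConfig | None = None,
                           post_s: float = 0.9,
                           value_col: str = "fx") -> tuple[pd.DataFrame, dict]:
    """Right-minus-left cursor-shift contrast of the lateral force trace.

    Computed literally as (right - none) - (left - none) per participant;
    algebraically this equals right - left. Returns the per-cell maxima and
    the mean delta traces keyed by (participant, uncertainty, speed).
    """
    config = config or AnalysisConfig()
    trials = _analysis_trials(meta, events)
    shifts = np.sort(trials["shift"].unique())
    if len(shifts) < 3:
        raise IncompleteCellError("need right, none and left shift conditions")
    mat, tf, times = aligned_traces(samples, trials, value_col, post_s)
    rows, traces = [], {}
    for (p, unc, sp), grp in tf.groupby(["participant", "uncertainty", "speed"],
                                        observed=True):
        cond = {}
        for label, s in (("right", shifts.max()), ("none", 0.0), ("left", shifts.min())):
            sel = grp.index[grp["shift"] == s]
            if len(sel) == 0:
                raise IncompleteCellError(
                    f"missing shift {s} for participant {p}, {unc}/{sp}")
            cond[label] = np.nanmean(mat[sel], axis=0)
        delta = (cond["right"] - cond["none"]) - (cond["left"] - cond["none"])
        traces[(p, unc, sp)] = delta
        valid = ~np.isnan(delta)
        rows.append({"participant": p, "uncertainty": unc, "speed": sp,
                     "max_delta_force": float(np.max(delta[valid]))})
    return pd.DataFrame(rows), {"traces": traces, "times": times}
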