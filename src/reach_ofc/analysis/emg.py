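"""EMG preprocessing and contrasts.

Raw EMG is bandpass filtered ([20, 250] Hz, 8th-order dual-pass Butterworth),
rectified, and normalized per muscle by the mean rectified activity during
dedicated calibration trials (a 1 s window starting 0.5 s after the
calibration-force onset). The pectoralis major (PM) channel is calibrated
against rightward-force calibration trials, the posterior deltoid (PD)
against leftward ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.signal

from ..ofc.plant import InvalidParameterError
from .config import AnalysisConfig
from .kinematics import (TRIAL_KEY, IncompleteCellError, _analysis_trials,
                         _batched_rows, _trial_groups, _uniform_dt, aligned_traces)

EMG_CHANNELS = {"emg_pm": "right", "emg_pd": "left"}


class NormalizationError(ValueError):
    """Raised when calibration trials are missing for a muscle/session."""


def bandpass_rectify(rows: np.ndarray, fs: float, band: tuple[float, float],
                     order: int = 8) -> np.ndarray:
    """Dual-pass Butterworth bandpass then full-wave rectification."""
    sos = scipy.signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    padlen = min(rows.shape[-1] - 1, max(48, 6 * order))
    return np.abs(scipy.signal.sosfiltfilt(sos, rows, axis=-1, padtype="even",
                                           padlen=padlen))


def preprocess_emg(samples: pd.DataFrame, meta: pd.DataFrame,
                   config: AnalysisConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter + rectify + calibration-normalize the EMG channels.

    Returns (samples copy with normalized EMG, calibration table). Calibration
    trials are identified by ``is_calibration`` and carry ``cal_direction``
    and ``cal_force_on_t`` in the metadata; normalization is per participant
    and speed session.
    """
    config = config or AnalysisConfig()
    channels = [c for c in EMG_CHANNELS if c in samples.columns]
    if not channels:
        raise NormalizationError("no EMG channels present")
    groups = _trial_groups(samples)
    t = samples["t"].to_numpy()
    out = samples.copy()
    rect = {}
    for col in channels:
        dest = np.empty(len(samples))
        for keys, rows, idxs in _batched_rows(samples, groups, col):
            fs = 1.0 / _uniform_dt(t[groups[keys[0]]])
            dest[idxs.ravel()] = bandpass_rectify(rows, fs, config.emg_band_hz,
                                                  config.emg_order).ravel()
        rect[col] = dest

    meta_idx = meta.set_index(TRIAL_KEY)
    cal_meta = meta[meta.get("is_calibration", False).astype(bool)]
    if cal_meta.empty:
        raise NormalizationError("no calibration trials in the table")
    lo, hi = config.emg_cal_window
    cal_rows = []
    for col in channels:
        want_dir = EMG_CHANNELS[col]
        for (p, sp), grp in cal_meta.groupby(["participant", "speed"], observed=True):
            sel = grp[grp["cal_direction"] == want_dir]
            if sel.empty:
                raise NormalizationError(
                    f"no {want_dir}-force calibration trials for participant {p}, {sp}")
            vals = []
            for rec in sel.itertuples():
                idx = groups[(rec.participant, rec.trial)]
                tt = t[idx] - rec.cal_force_on_t
                win = (tt >= lo) & (tt < hi)
                if not win.any():
                    raise NormalizationError("calibration window outside trial span")
                vals.append(rect[col][idx[win]].mean())
            cal_rows.append({"participant": p, "speed": sp, "channel": col,
                             "cal_value": float(np.mean(vals))})
    cal = pd.DataFrame(cal_rows)

    cal_lookup = cal.set_index(["participant", "speed", "channel"])["cal_value"]
    part = samples["participant"].to_numpy()
    speed = meta_idx["speed"]
    for col in channels:
        norm = rect[col].copy()
        for key, idx in groups.items():
            c = cal_lookup[(key[0], speed[key], col)]
            norm[idx] = norm[idx] / c
        out[col] = norm
    return out, cal


def emg_contrast_window(samples_norm: pd.DataFrame, meta: pd.DataFrame,
                        events: pd.DataFrame,
                        config: AnalysisConfig | None = None,
                        channel: str = "emg_pm") -> pd.DataFrame:
    """Mean right-minus-left-shift EMG over the post-vision analysis window
    (100-250 ms by default), per participant/uncertainty/speed."""
    config = config or AnalysisConfig()
    lo, hi = config.emg_window
    trials = _analysis_trials(meta, events)
    mat, tf, times = aligned_traces(samples_norm, trials, channel, post_s=hi + 0.05)
    win = (times >= lo) & (times < hi)
    if not win.any():
        raise InvalidParameterError("EMG window lies outside the aligned trace")
    shifts = np.sort(tf["shift"].unique())
    rows = []
    for (p, unc, sp), grp in tf.groupby(["participant", "uncertainty", "speed"],
                                        observed=True):
        sides = {}
        for label, s in (("right", shifts.max()), ("left", shifts.min())):
            sel = grp.index[grp["shift"] == s]
            if len(sel) == 0:
                raise IncompleteCellError(
                    f"missing shift {s} for participant {p}, {unc}/{sp}")
            sides[label] = np.nanmean(mat[sel], axis=0)
        delta = sides["right"] - sides["left"]
        rows.append({"participant": p, "uncertainty": unc, "speed": sp,
                     "channel": channel,
                     "delta_emg": float(np.nanmean(delta[win]))})
    return pd.DataFrame(rows)


def emg_delta_traces(samples_norm: pd.DataFrame, meta: pd.DataFrame,
                     events: pd.DataFrame, channel: str = "emg_pm",
                     post_s: float = 0.4,
                     uncertainty: str | None = None) -> tuple[np.ndarray, np.ndarray, list]:
    """Per-participant right-minus-left-shift EMG traces aligned to vision
    onset; returns (matrix (n_participants, T), times, participants)."""
    trials = _analysis_trials(meta, events)
    if uncertainty is not None:
        trials = trials[trials["uncertainty"] == uncertainty]
    mat, tf, times = aligned_traces(samples_norm, trials, channel, post_s=post_s)
    shifts = np.sort(tf["shift"].unique())
    parts, deltas = [], []
    for p, grp in tf.groupby("participant", observed=True):
        r = grp.index[grp["shift"] == shifts.max()]
        l = grp.index[grp["shift"] == shifts.min()]
        if len(r) == 0 or len(l) == 0:
            continue
        deltas.append(np.nanmean(mat[r], axis=0) - np.nanmean(mat[l], axis=0))
        parts.append(p)
    return np.stack(deltas), times, parts
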