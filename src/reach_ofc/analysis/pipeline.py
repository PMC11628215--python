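"""End-to-end behavioral analysis orchestration.

``analyze_experiment`` accepts either one (samples, meta) pair or an iterable
of per-participant pairs (the memory-friendly path for full-size datasets),
runs preprocessing, event detection, and every per-participant readout, then
assembles group summaries and the repeated-measures ANOVAs.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .emg import emg_contrast_window, emg_delta_traces, preprocess_emg
from .kinematics import (detect_vision_onset, fit_shift_slope, lateral_force_contrast,
                         position_variability, preprocess_kinematics)
from .onsets import running_ttest_onset
from .stats import rm_anova


def _as_participant_iter(tables) -> Iterator[tuple[pd.DataFrame, pd.DataFrame]]:
    if isinstance(tables, tuple) and len(tables) == 2 and isinstance(tables[0], pd.DataFrame):
        samples, meta = tables
        for p in meta["participant"].unique():
            yield (samples[samples["participant"] == p],
                   meta[meta["participant"] == p])
    else:
        yield from tables


def analyze_participant(samples: pd.DataFrame, meta: pd.DataFrame,
                        config: AnalysisConfig | None = None,
                        with_emg: bool = True) -> dict:
    """All per-participant readouts for one participant's trials."""
    config = config or AnalysisConfig()
    kin = preprocess_kinematics(samples, config)
    events = detect_vision_onset(kin, meta, config)
    slopes, _ = fit_shift_slope(kin, meta, events, config)
    areas = position_variability(kin, meta, events, config)
    force_max, force_traces = lateral_force_contrast(kin, meta, events, config)
    out = {"slopes": slopes, "areas": areas, "force_max": force_max,
           "force_traces": force_traces, "events": events,
           "n_excluded": int(events["excluded"].sum()
                             - (events["exclusion_reason"] == "calibration").sum())}
    if with_emg and "emg_pm" in samples.columns:
        emg_norm, cal = preprocess_emg(samples, meta, config)
        out["emg_contrast"] = pd.concat(
            [emg_contrast_window(emg_norm, meta, events, config, channel=ch)
             for ch in ("emg_pm", "emg_pd") if ch in samples.columns],
            ignore_index=True)
        deltas = {}
        for unc in meta.loc[~meta["is_calibration"].astype(bool), "uncertainty"].dropna().unique():
            try:
                d, times, _ = emg_delta_traces(emg_norm, meta, events,
                                               uncertainty=unc, post_s=0.4)
                deltas[unc] = (d.mean(axis=0), times)
            except ValueError:
                continue
        out["emg_delta_by_uncertainty"] = deltas
    return out


def analyze_experiment(tables, config: AnalysisConfig | None = None,
                       with_emg: bool = True,
                       with_anova: bool = True) -> dict:
    """Run the full pipeline and assemble group-level tables.

    Returns a dict of tidy DataFrames: per-participant slopes, dispersion
    areas, delta-force maxima, EMG contrasts, their rm-ANOVAs, plus the
    uncertainty-contrast onset of the PM delta-EMG trace (running t-test
    across participants, low vs inf uncertainty).
    """
    config = config or AnalysisConfig()
    parts = [analyze_participant(s, m, config, with_emg=with_emg)
             for s, m in _as_participant_iter(tables)]
    res: dict = {
        "slopes": pd.concat([p["slopes"] for p in parts], ignore_index=True),
        "areas": pd.concat([p["areas"] for p in parts], ignore_index=True),
        "force_max": pd.concat([p["force_max"] for p in parts], ignore_index=True),
        "n_excluded": int(sum(p["n_excluded"] for p in parts)),
    }
    res["slope_summary"] = (res["slopes"]
                            .groupby(["speed", "uncertainty", "latency_ms"], observed=True)["slope"]
                            .agg(mean="mean",
                                 sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)),
                                 n="count").reset_index())
    if with_emg and "emg_contrast" in parts[0]:
        res["emg_contrast"] = pd.concat([p["emg_contrast"] for p in parts],
                                        ignore_index=True)
        # uncertainty contrast of the PM delta trace: low vs inf
        lows, infs = [], []
        times = None
        for p in parts:
            d = p.get("emg_delta_by_uncertainty", {})
            if "low" in d and "inf" in d:
                lows.append(d["low"][0])
                infs.append(d["inf"][0])
                times = d["low"][1]
        if len(lows) >= 2:
            res["emg_onset_low_vs_inf"] = running_ttest_onset(
                np.stack(lows), np.stack(infs), times,
                search_start=config.onset_search_start, alpha=config.onset_alpha,
                persistence=config.onset_persistence)
    if with_anova:
        res["anova"] = {}
        for name, df, dv in (("slope_900ms",
                              res["slopes"][res["slopes"]["latency_ms"] == 900], "slope"),
                             ("max_delta_force", res["force_max"], "max_delta_force")):
            if not df.empty:
                res["anova"][name] = rm_anova(df, dv=dv,
                                              within=["uncertainty", "speed"],
                                              config=config)
        if "emg_contrast" in res:
            pm = res["emg_contrast"]
            pm = pm[pm["channel"] == "emg_pm"]
            res["anova"]["delta_emg_pm"] = rm_anova(pm, dv="delta_emg",
                                                    within=["uncertainty", "speed"],
                                                    config=config)
    return res
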