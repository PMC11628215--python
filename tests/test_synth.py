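"""Synthetic-experiment generator: design counts, determinism, recovery."""

import numpy as np
import pandas as pd
import pytest

from reach_ofc.analysis import AnalysisConfig, analyze_experiment, detect_vision_onset
from reach_ofc.ofc.plant import InvalidParameterError
from reach_ofc.synth import SynthConfig, generate_participant, ground_truth
from reach_ofc.synth.generator import _base_trajectories, expected_ground_truth


def test_design_counts_match_published_protocol(small_synth):
    cfg, samples, meta, truth = small_synth
    reg = meta[~meta["is_calibration"]]
    per_part = reg.groupby("participant").size()
    # 2 sessions x n_blocks x 64 trials
    assert (per_part == 2 * cfg.n_blocks * 64).all()
    one_block = reg[(reg["participant"] == 0) & (reg["speed"] == "fast")
                    & (reg["block"] == 0)]
    assert len(one_block) == 64
    assert (one_block["force_dir"] == 9.0).sum() == 48
    assert (one_block["force_dir"] == -9.0).sum() == 8
    assert (one_block["force_dir"] == 0.0).sum() == 8
    # shifts appear only on rightward-force trials
    assert (reg.loc[reg["force_dir"] <= 0, "shift"] == 0.0).all()
    rw = one_block[one_block["force_dir"] == 9.0]
    counts = rw.groupby(["uncertainty", "shift"], observed=True).size()
    assert (counts == 4).all() and len(counts) == 12


def test_full_size_config_yields_768_trials_per_participant():
    cfg = SynthConfig(n_participants=1, master_seed=0)
    # count from the design arithmetic of one session x 2
    per_session = cfg.n_blocks * (4 * 3 * cfg.reps_rightward
                                  + cfg.n_left_per_block + cfg.n_none_per_block)
    assert 2 * per_session == 768


def test_generation_is_deterministic(small_synth):
    cfg, samples, meta, _ = small_synth
    bases = _base_trajectories(None if False else __import__(
        "reach_ofc").SimulationConfig.default())
    s2, m2 = generate_participant(cfg, 1, bases=bases)
    s1 = samples[samples["participant"] == 1].reset_index(drop=True)
    pd.testing.assert_frame_equal(s1, s2)


def test_undershoot_fraction_exactly_flagged(small_synth):
    cfg, samples, meta, _ = small_synth
    ev = detect_vision_onset(samples, meta)
    merged = ev.merge(meta, on=["participant", "trial"])
    reg = merged[~merged["is_calibration"]]
    # injection is exact per speed session
    n_expected = 2 * int(round(cfg.undershoot_rate * cfg.n_blocks * 64))
    per_part = reg.groupby("participant")["exclusion_reason"].apply(
        lambda s: (s == "undershoot").sum())
    assert (per_part == n_expected).all()
    # generator labels agree with detection
    assert ((reg["exclusion_reason"] == "undershoot")
            == (reg["outcome"] == "undershoot")).all()


def test_experiment2_slow_vision_duration():
    cfg = SynthConfig(n_participants=1, n_blocks=1, experiment=2, master_seed=5)
    s, m = generate_participant(cfg, 0, bases=_base_trajectories(
        __import__("reach_ofc").SimulationConfig.default()))
    ev = detect_vision_onset(s, m).merge(m, on=["participant", "trial"])
    slow = ev[(ev["speed"] == "slow") & (~ev["is_calibration"]) & (~ev["excluded"])]
    np.testing.assert_allclose(slow["vision_off_t"] - slow["vision_on_t"], 0.170)


def test_no_vision_condition_recovers_zero_slope(small_synth):
    """w(inf) = 0: the recovered group slope is statistically
    indistinguishable from zero at late latencies."""
    cfg, samples, meta, _ = small_synth
    res = analyze_experiment((samples, meta), with_emg=False, with_anova=False)
    sl = res["slope_summary"]
    row = sl[(sl["uncertainty"] == "inf") & (sl["latency_ms"] == 900)]
    for _, r in row.iterrows():
        assert abs(r["mean"]) < 2.5 * r["sem"] + 1e-3


def test_antagonist_muscle_carries_no_visual_contrast(small_synth):
    cfg, samples, meta, _ = small_synth
    res = analyze_experiment((samples, meta), with_anova=False)
    pd_rows = res["emg_contrast"].query("channel == 'emg_pd'")
    pm_rows = res["emg_contrast"].query("channel == 'emg_pm'")
    # PD contrast is an order of magnitude below PM at low uncertainty
    pm_low = pm_rows.query("uncertainty == 'low'")["delta_emg"].mean()
    pd_low = pd_rows.query("uncertainty == 'low'")["delta_emg"].abs().mean()
    assert pm_low > 0.3
    assert pd_low < 0.1 * pm_low


def test_ground_truth_serialization_roundtrip(tmp_path, small_synth):
    cfg = small_synth[0]
    truth = ground_truth(cfg)
    p = tmp_path / "truth.json"
    truth.to_json(p)
    back = type(truth).from_json(p)
    assert back.weights == truth.weights
    pd.testing.assert_frame_equal(back.expected_slopes, truth.expected_slopes,
                                  check_dtype=False)


def test_weight_ordering_enforced():
    with pytest.raises(InvalidParameterError):
        SynthConfig(weights={"low": 0.3, "medium": 0.5, "high": 0.2, "inf": 0.0})


def test_expected_truth_shapes():
    cfg = SynthConfig(n_participants=2)
    slopes, emg = expected_ground_truth(cfg)
    assert len(slopes) == 2 * 4 * 5 and len(emg) == 8
    # slopes move toward -w with latency
    s900 = slopes.query("speed=='fast' and uncertainty=='low' and latency_ms==900")
    assert s900["slope"].iloc[0] == pytest.approx(-cfg.weights["low"], abs=0.01)
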