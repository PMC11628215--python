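"""Synthetic two-session reaching experiments with known ground truth.

The generator reproduces the published design exactly: per speed session,
6 blocks x 64 trials, of which 48 carry a rightward 9 N load (4 repetitions
of 4 visual-uncertainty x 3 cursor-shift combinations), 8 a leftward load and
8 no load (2 repetitions per uncertainty), randomized within block; 768
regular trials per participant plus appended EMG calibration trials.

Kinematics ride on the noise-free LQG simulation of the matching speed/load
condition, resampled to 1 kHz. The visually driven correction is injected as
a logistic-in-time lateral displacement with asymptote -w(sigma) * shift,
where the per-uncertainty visual weights w are the ground truth the analysis
pipeline must recover; its second derivative (times the hand mass) is added
to the lateral force channel. EMG channels are envelope-modulated broadband
carriers: the pectoralis major (PM) envelope carries a load-locked burst and
a shift-signed visual response starting a fixed latency (100 ms) after
vision onset, scaled by w(sigma) and a speed gain; the posterior deltoid
(PD) carries no visual response. Participant heterogeneity is lognormal
(Gaussian on log-gains), mean-corrected so group-level expectations equal
the stored ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from ..config import SimulationConfig
from ..ofc.gains import GainSchedules, compute_control_gains, compute_kalman_gains
from ..ofc.plant import InvalidParameterError
from ..ofc.simulate import simulate_trial

SPEEDS = ("fast", "slow")
UNCERTAINTIES = ("low", "medium", "high", "inf")


def _default_weights() -> dict[str, float]:
    return {"low": 0.75, "medium": 0.55, "high": 0.35, "inf": 0.0}


def _default_t50() -> dict[str, float]:
    return {"fast": 0.22, "slow": 0.30}


def _default_rise_rate() -> dict[str, float]:
    return {"fast": 18.0, "slow": 12.0}


def _default_emg_speed_gain() -> dict[str, float]:
    return {"fast": 1.3, "slow": 1.0}


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults follow the published design."""

    n_participants: int = 16
    experiment: int = 1
    n_blocks: int = 6
    reps_rightward: int = 4          # per uncertainty x shift per block
    n_left_per_block: int = 8
    n_none_per_block: int = 8        # 2 per uncertainty
    shift_levels: tuple[float, ...] = (-0.02, 0.0, 0.02)
    weights: dict[str, float] = field(default_factory=_default_weights)
    fs: float = 1000.0
    pre_movement_s: float = 0.25
    post_movement_s: float = 1.2
    onset_jitter_s: float = 0.02
    # visual-correction profile: logistic in time from vision onset
    t50_s: dict[str, float] = field(default_factory=_default_t50)
    rise_rate_hz: dict[str, float] = field(default_factory=_default_rise_rate)
    # EMG model
    visual_latency_s: float = 0.100
    emg_baseline: float = 0.3
    emg_load_burst: float = 0.8
    emg_load_sustain: float = 0.4
    emg_vis_amp: float = 0.5
    emg_cal_level: float = 1.0
    emg_speed_gain: dict[str, float] = field(default_factory=_default_emg_speed_gain)
    emg_add_sd: float = 0.02
    n_cal_blocks: int = 4
    n_cal_reps: int = 2
    cal_duration_s: float = 2.2
    cal_force_on_s: float = 0.2
    # noise / heterogeneity
    kin_meas_sd: float = 0.0003      # m, white measurement noise on positions
    kin_wander_sd: float = 0.0015    # m, slow within-trial lateral wander
    force_noise_sd: float = 0.05     # N
    sigma_log_w: float = 0.12        # participant random effect on weights
    sigma_log_gain: float = 0.10     # participant random effect on EMG gain
    undershoot_rate: float = 0.02
    master_seed: int = 0

    def __post_init__(self) -> None:
        w = self.weights
        order = [w[u] for u in UNCERTAINTIES]
        if sorted(order, reverse=True) != order or w["inf"] != 0.0:
            raise InvalidParameterError(
                "weights must be ordered low >= medium >= high >= inf = 0")
        if self.n_participants < 1 or not 0 <= self.undershoot_rate < 1:
            raise InvalidParameterError("invalid design counts")


@dataclass
class GroundTruth:
    """Generator parameters the analysis pipeline should recover."""

    weights: dict[str, float]
    visual_latency_s: float
    expected_slopes: pd.DataFrame      # speed, uncertainty, latency_ms, slope
    expected_emg_contrast: pd.DataFrame  # speed, uncertainty, contrast
    participant_effects: pd.DataFrame  # participant, w_factor, gain_factor
    master_seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "weights": self.weights,
            "visual_latency_s": self.visual_latency_s,
            "expected_slopes": self.expected_slopes.to_dict(orient="list"),
            "expected_emg_contrast": self.expected_emg_contrast.to_dict(orient="list"),
            "participant_effects": self.participant_effects.to_dict(orient="list"),
            "master_seed": self.master_seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(weights=d["weights"], visual_latency_s=d["visual_latency_s"],
                   expected_slopes=pd.DataFrame(d["expected_slopes"]),
                   expected_emg_contrast=pd.DataFrame(d["expected_emg_contrast"]),
                   participant_effects=pd.DataFrame(d["participant_effects"]),
                   master_seed=d["master_seed"])


# ---------------------------------------------------------------------------
# deterministic building blocks

def rise_profile(tau: np.ndarray, speed: str, cfg: SynthConfig) -> np.ndarray:
    """Normalized logistic correction profile vs time-from-vision-onset.

    0 at vision onset, asymptote 1; rate and midpoint are speed dependent
    (g_fast > g_slow switches the transient speed effect on)."""
    g, t50 = cfg.rise_rate_hz[speed], cfg.t50_s[speed]
    s = expit(g * (tau - t50))
    s0 = expit(-g * t50)
    return np.clip((s - s0) / (1.0 - s0), 0.0, None) * (tau >= 0)


def emg_visual_template(tau: np.ndarray) -> np.ndarray:
    """Visual EMG burst shape vs time from (vision onset + latency):
    50 ms linear rise, 150 ms plateau, 150 ms exponential decay."""
    v = np.clip(tau / 0.05, 0.0, 1.0) * np.exp(-np.clip(tau - 0.2, 0.0, None) / 0.15)
    return v * (tau >= 0)


def emg_load_template(tau: np.ndarray, burst: float, sustain: float) -> np.ndarray:
    """Load-locked agonist response: gamma-like burst plus sustained level."""
    peak = np.clip(tau / 0.05, 0.0, None) * np.exp(1.0 - np.clip(tau / 0.05, 0.0, None))
    return (burst * peak + sustain * (1.0 - np.exp(-np.clip(tau, 0.0, None) / 0.1))) * (tau >= 0)


def _mean_window(f, lo: float, hi: float, n: int = 2000) -> float:
    tau = np.linspace(lo, hi, n, endpoint=False)
    return float(np.mean(f(tau)))


def expected_ground_truth(cfg: SynthConfig,
                          latencies_ms=(150, 300, 500, 700, 900),
                          emg_window=(0.100, 0.250)) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Closed-form group-level expectations implied by the generator."""
    rows, erows = [], []
    for sp in SPEEDS:
        for unc in UNCERTAINTIES:
            w = cfg.weights[unc]
            for lat in latencies_ms:
                s = rise_profile(np.array([lat / 1e3]), sp, cfg)[0]
                rows.append({"speed": sp, "uncertainty": unc,
                             "latency_ms": lat, "slope": -w * s})
            vbar = _mean_window(
                lambda tau: emg_visual_template(tau - cfg.visual_latency_s),
                emg_window[0], emg_window[1])
            erows.append({"speed": sp, "uncertainty": unc,
                          "contrast": 2.0 * cfg.emg_vis_amp * w
                          * cfg.emg_speed_gain[sp] * vbar / cfg.emg_cal_level})
    return pd.DataFrame(rows), pd.DataFrame(erows)


# ---------------------------------------------------------------------------
# LQG base trajectories

def _base_trajectories(sim_cfg: SimulationConfig) -> dict:
    """Noise-free model trajectories per (speed, force_dir), on the model grid."""
    sys_ = sim_cfg.system()
    lay = sys_.layout
    out = {}
    for sp in SPEEDS:
        for fdir in (9.0, -9.0, 0.0):
            proto = sim_cfg.protocol_for(sp, load=abs(fdir))
            n = proto.n_steps(sim_cfg.plant.dt)
            noise = sim_cfg.noise_for("low")
            gains = GainSchedules(L=compute_control_gains(sys_, sim_cfg.cost, n),
                                  K=compute_kalman_gains(sys_, noise, n))
            tr = simulate_trial(proto, gains, sys_, noise, noise_free=True)
            sgn = np.sign(fdir)
            out[(sp, fdir)] = {
                "t": tr.t,
                "x": sgn * tr.x[:, lay.index("pos", 0)],
                "y": tr.x[:, lay.index("pos", 1)],
                "fx": sgn * tr.lateral_force,
                "fy": tr.x[:, lay.index("f_com", 1)] + tr.x[:, lay.index("f_ext", 1)],
                "t_load": (tr.load_step or 0) * sim_cfg.plant.dt,
            }
    return out


def _hold_interp(tgrid: np.ndarray, v: np.ndarray, tq: np.ndarray) -> np.ndarray:
    """Linear interpolation holding the first/last values outside the grid."""
    return np.interp(tq, tgrid, v)


# ---------------------------------------------------------------------------
# per-participant generation

def _session_conditions(cfg: SynthConfig, speed: str,
                        rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for block in range(cfg.n_blocks):
        block_rows = []
        for unc in UNCERTAINTIES:
            for shift in cfg.shift_levels:
                for _ in range(cfg.reps_rightward):
                    block_rows.append((unc, shift, 9.0))
        for i in range(cfg.n_left_per_block):
            block_rows.append((UNCERTAINTIES[i % 4], 0.0, -9.0))
        for i in range(cfg.n_none_per_block):
            block_rows.append((UNCERTAINTIES[i % 4], 0.0, 0.0))
        order = rng.permutation(len(block_rows))
        for j, k in enumerate(order):
            unc, shift, fdir = block_rows[k]
            rows.append({"speed": speed, "block": block, "trial_in_block": j,
                         "uncertainty": unc, "shift": shift, "force_dir": fdir})
    return pd.DataFrame(rows)


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float,
                  sd: float) -> np.ndarray:
    """Slow within-trial wander: heavily low-passed white noise, unit-SD scaled."""
    import scipy.signal
    if sd == 0.0:
        return np.zeros(shape)
    w = rng.standard_normal(shape)
    sos = scipy.signal.butter(2, 2.0, btype="low", fs=fs, output="sos")
    sm = scipy.signal.sosfiltfilt(sos, w, axis=-1)
    scale = np.std(sm) or 1.0
    return sm / scale * sd


def generate_kinematic_trials(cfg: SynthConfig, participant: int, speed: str,
                              rng: np.random.Generator, bases: dict,
                              w_factor: float) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """One speed session of kinematic trials for one participant.

    Returns (samples, meta, internals) where internals carries the per-trial
    vision-onset times and masks needed by the EMG stage.
    """
    meta = _session_conditions(cfg, speed, rng)
    n_trials = len(meta)
    mt = {"fast": 0.4, "slow": 0.7}[speed]
    dur = cfg.pre_movement_s + mt + 0.5 + cfg.post_movement_s
    nt = int(round(dur * cfg.fs))
    t = np.arange(nt) / cfg.fs

    onset = cfg.pre_movement_s + rng.uniform(-cfg.onset_jitter_s, cfg.onset_jitter_s,
                                             size=n_trials)
    n_under = int(round(cfg.undershoot_rate * n_trials))
    under_idx = rng.choice(n_trials, size=n_under, replace=False)
    yscale = np.ones(n_trials)
    yscale[under_idx] = 0.88

    X = np.empty((n_trials, nt))
    Y = np.empty((n_trials, nt))
    FX = np.empty((n_trials, nt))
    FY = np.empty((n_trials, nt))
    trel = t[None, :] - onset[:, None]
    for fdir in (9.0, -9.0, 0.0):
        sel = np.nonzero(meta["force_dir"].to_numpy() == fdir)[0]
        if sel.size == 0:
            continue
        b = bases[(speed, fdir)]
        for i in sel:
            X[i] = _hold_interp(b["t"], b["x"], trel[i])
            Y[i] = _hold_interp(b["t"], b["y"], trel[i]) * yscale[i]
            FX[i] = _hold_interp(b["t"], b["fx"], trel[i])
            FY[i] = _hold_interp(b["t"], b["fy"], trel[i])

    # vision onset from the deterministic forward path (8 cm crossing)
    crossed = Y >= 0.08
    has_vis = crossed.any(axis=1)
    vis_idx = np.argmax(crossed, axis=1)
    t_vis = np.where(has_vis, t[np.minimum(vis_idx, nt - 1)], np.nan)

    # visually driven lateral correction, rightward-load trials only
    shifts = meta["shift"].to_numpy()
    weights = np.array([cfg.weights[u] for u in meta["uncertainty"]]) * w_factor
    tau = t[None, :] - t_vis[:, None]
    prof = rise_profile(np.nan_to_num(tau, nan=-1.0), speed, cfg)
    vis_disp = (-weights * shifts)[:, None] * prof
    X = X + vis_disp
    # the force channel carries the inertial trace of the correction
    acc = np.gradient(np.gradient(vis_disp, 1.0 / cfg.fs, axis=1), 1.0 / cfg.fs, axis=1)
    FX = FX + 1.0 * acc  # hand mass 1 kg

    X += _smooth_noise(rng, X.shape, cfg.fs, cfg.kin_wander_sd)
    X += rng.normal(0.0, cfg.kin_meas_sd, X.shape)
    Y += rng.normal(0.0, cfg.kin_meas_sd, Y.shape)
    FX += rng.normal(0.0, cfg.force_noise_sd, FX.shape)
    FY += rng.normal(0.0, cfg.force_noise_sd, FY.shape)

    trial_ids = [f"{speed}-{b}-{j:02d}" for b, j in
                 zip(meta["block"], meta["trial_in_block"])]
    meta = meta.assign(participant=participant, trial=trial_ids,
                       experiment=cfg.experiment, is_calibration=False,
                       cal_direction="", cal_force_on_t=np.nan,
                       move_onset_t=onset,
                       outcome=np.where(yscale < 1.0, "undershoot", "hit"))
    samples = pd.DataFrame({
        "participant": np.repeat(participant, n_trials * nt),
        "trial": np.repeat(trial_ids, nt),
        "t": np.tile(t, n_trials),
        "x": X.ravel(), "y": Y.ravel(), "fx": FX.ravel(), "fy": FY.ravel(),
    })
    internals = {"t": t, "t_vis": t_vis, "t_load": onset + np.array(
        [bases[(speed, f)]["t_load"] for f in meta["force_dir"]]),
        "meta_core": meta, "nt": nt}
    return samples, meta, internals


def generate_emg_traces(cfg: SynthConfig, speed: str, rng: np.random.Generator,
                        internals: dict, gain_factor: float,
                        w_factor: float) -> dict[str, np.ndarray]:
    """Envelope-modulated broadband EMG for one session's regular trials."""
    meta = internals["meta_core"]
    t = internals["t"]
    n_trials, nt = len(meta), internals["nt"]
    g_sp = cfg.emg_speed_gain[speed]
    shifts = meta["shift"].to_numpy()
    weights = np.array([cfg.weights[u] for u in meta["uncertainty"]]) * w_factor
    fdir = meta["force_dir"].to_numpy()

    tau_load = t[None, :] - internals["t_load"][:, None]
    tau_vis = t[None, :] - (internals["t_vis"] + cfg.visual_latency_s)[:, None]
    load_resp = emg_load_template(np.nan_to_num(tau_load, nan=-1.0),
                                  cfg.emg_load_burst, cfg.emg_load_sustain) * g_sp
    vis_resp = (cfg.emg_vis_amp * g_sp * weights * (shifts / 0.02))[:, None] \
        * emg_visual_template(np.nan_to_num(tau_vis, nan=-1.0))

    env_pm = cfg.emg_baseline + load_resp * (fdir > 0)[:, None] + vis_resp
    env_pd = cfg.emg_baseline + load_resp * (fdir < 0)[:, None]
    env_pm = np.clip(env_pm, 0.05, None) * gain_factor
    env_pd = np.clip(env_pd, 0.05, None) * gain_factor
    pm = env_pm * rng.standard_normal((n_trials, nt)) + rng.normal(
        0.0, cfg.emg_add_sd, (n_trials, nt))
    pd_ = env_pd * rng.standard_normal((n_trials, nt)) + rng.normal(
        0.0, cfg.emg_add_sd, (n_trials, nt))
    return {"emg_pm": pm.ravel(), "emg_pd": pd_.ravel()}


def _calibration_trials(cfg: SynthConfig, participant: int, speed: str,
                        rng: np.random.Generator,
                        gain_factor: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    nt = int(round(cfg.cal_duration_s * cfg.fs))
    t = np.arange(nt) / cfg.fs
    on = (t >= cfg.cal_force_on_s)
    rows_s, rows_m = [], []
    k = 0
    for block in range(cfg.n_cal_blocks):
        for direction in ("right", "left"):
            for _ in range(cfg.n_cal_reps):
                tid = f"cal-{speed}-{k:02d}"
                k += 1
                env_act = (cfg.emg_baseline + (cfg.emg_cal_level - cfg.emg_baseline)
                           * on) * gain_factor
                env_rest = cfg.emg_baseline * gain_factor * np.ones(nt)
                env_pm = env_act if direction == "right" else env_rest
                env_pd = env_act if direction == "left" else env_rest
                fx = 9.0 * on * (1 if direction == "right" else -1)
                rows_s.append(pd.DataFrame({
                    "participant": participant, "trial": tid, "t": t,
                    "x": rng.normal(0, cfg.kin_meas_sd, nt),
                    "y": rng.normal(0, cfg.kin_meas_sd, nt),
                    "fx": fx + rng.normal(0, cfg.force_noise_sd, nt),
                    "fy": rng.normal(0, cfg.force_noise_sd, nt),
                    "emg_pm": env_pm * rng.standard_normal(nt)
                    + rng.normal(0, cfg.emg_add_sd, nt),
                    "emg_pd": env_pd * rng.standard_normal(nt)
                    + rng.normal(0, cfg.emg_add_sd, nt),
                }))
                rows_m.append({"participant": participant, "trial": tid,
                               "speed": speed, "block": block, "trial_in_block": 0,
                               "uncertainty": "", "shift": 0.0, "force_dir": 0.0,
                               "experiment": cfg.experiment, "is_calibration": True,
                               "cal_direction": direction,
                               "cal_force_on_t": cfg.cal_force_on_s,
                               "move_onset_t": np.nan, "outcome": "calibration"})
    return pd.concat(rows_s, ignore_index=True), pd.DataFrame(rows_m)


def generate_participant(cfg: SynthConfig, participant: int,
                         bases: dict | None = None,
                         sim_cfg: SimulationConfig | None = None,
                         with_emg: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Complete two-session dataset for one participant."""
    bases = bases or _base_trajectories(sim_cfg or SimulationConfig.default())
    ss = np.random.SeedSequence([cfg.master_seed, participant])
    rng = np.random.default_rng(ss)
    # mean-corrected lognormal random effects
    w_factor = float(np.exp(rng.normal(0.0, cfg.sigma_log_w) - cfg.sigma_log_w ** 2 / 2))
    gain_factor = float(np.exp(rng.normal(0.0, cfg.sigma_log_gain)
                               - cfg.sigma_log_gain ** 2 / 2))
    frames_s, frames_m = [], []
    for speed in SPEEDS:
        samples, meta, internals = generate_kinematic_trials(
            cfg, participant, speed, rng, bases, w_factor)
        if with_emg:
            emg = generate_emg_traces(cfg, speed, rng, internals, gain_factor, w_factor)
            samples = samples.assign(**emg)
            cal_s, cal_m = _calibration_trials(cfg, participant, speed, rng, gain_factor)
            frames_s.append(cal_s)
            frames_m.append(cal_m)
        frames_s.append(samples)
        frames_m.append(meta)
    return (pd.concat(frames_s, ignore_index=True),
            pd.concat(frames_m, ignore_index=True))


def participant_effects(cfg: SynthConfig) -> pd.DataFrame:
    rows = []
    for p in range(cfg.n_participants):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.master_seed, p]))
        rows.append({"participant": p,
                     "w_factor": float(np.exp(rng.normal(0.0, cfg.sigma_log_w)
                                              - cfg.sigma_log_w ** 2 / 2)),
                     "gain_factor": float(np.exp(rng.normal(0.0, cfg.sigma_log_gain)
                                                 - cfg.sigma_log_gain ** 2 / 2))})
    return pd.DataFrame(rows)


def ground_truth(cfg: SynthConfig) -> GroundTruth:
    slopes, emg = expected_ground_truth(cfg)
    return GroundTruth(weights=dict(cfg.weights),
                       visual_latency_s=cfg.visual_latency_s,
                       expected_slopes=slopes, expected_emg_contrast=emg,
                       participant_effects=participant_effects(cfg),
                       master_seed=cfg.master_seed)


def iter_participants(cfg: SynthConfig, sim_cfg: SimulationConfig | None = None,
                      with_emg: bool = True):
    """Yield (samples, meta) per participant; memory-friendly full-size path."""
    bases = _base_trajectories(sim_cfg or SimulationConfig.default())
    for p in range(cfg.n_participants):
        yield generate_participant(cfg, p, bases=bases, with_emg=with_emg)


def generate_experiment(cfg: SynthConfig, sim_cfg: SimulationConfig | None = None,
                        with_emg: bool = True) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Full dataset bundle (concatenated); prefer ``iter_participants`` for
    the default 16-participant size if memory is a concern."""
    frames = list(iter_participants(cfg, sim_cfg, with_emg=with_emg))
    samples = pd.concat([s for s, _ in frames], ignore_index=True)
    meta = pd.concat([m for _, m in frames], ignore_index=True)
    return samples, meta, ground_truth(cfg)
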