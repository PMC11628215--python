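"""Process and sensory noise model.

Process (motor) noise enters on the commanded-force state only; the external
force and the cursor-hand offset are physically noiseless. Because both are
nevertheless step-perturbed during a trial, the estimator is given small
pseudo process-noise terms on exactly those two states *when computing Kalman
gains* (1% of the motor-noise variance on f_ext, 0.1% on p_offset). Forward
simulations never draw from the pseudo terms.

Sensory noise is diagonal over the observed channels; the visual-uncertainty
manipulation scales the variance of the cursor-position channel only. A scale
of ``inf`` encodes the no-vision condition (cursor channel carries no
information and its Kalman-gain column is exactly zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .plant import InvalidParameterError, StateLayout, OBS_CHANNELS

#: conventional visual-uncertainty levels: variance scaling of the cursor channel
VISUAL_SCALES = {"low": 0.1, "medium": 1.0, "high": 10.0, "inf": math.inf}


def _default_obs_sd() -> dict[str, float]:
    return {"pos": 0.0005, "vel": 0.005, "f_com": 0.05, "f_ext": 0.02, "p_cursor": 0.007}


@dataclass(frozen=True)
class NoiseModel:
    """Noise magnitudes (SDs, per 10 ms step) and the visual-uncertainty scale.

    motor_sd : SD of the additive per-step noise on f_com, N.
    obs_sd : per-channel sensory SDs (m, m/s, N, N, m).
    visual_scale : multiplies the *variance* of the cursor observation.
    f_off / f_ext : pseudo process-noise fractions of the motor variance used
        only when computing Kalman gains.
    c_motor / c_sensory : signal-dependent coefficients (0 = additive model).
    """

    motor_sd: float = 0.01
    obs_sd: dict[str, float] = field(default_factory=_default_obs_sd)
    visual_scale: float = 1.0
    f_off: float = 0.001
    f_ext: float = 0.01
    c_motor: float = 0.0
    c_sensory: float = 0.0

    def __post_init__(self) -> None:
        if self.motor_sd < 0 or any(v < 0 for v in self.obs_sd.values()):
            raise InvalidParameterError("noise SDs must be non-negative")
        if self.visual_scale <= 0:
            raise InvalidParameterError("visual_scale must be positive (use inf for no vision)")
        if self.c_motor < 0 or self.c_sensory < 0:
            raise InvalidParameterError("signal-dependent coefficients must be non-negative")

    @property
    def no_vision(self) -> bool:
        return math.isinf(self.visual_scale)

    def with_visual_scale(self, scale: float) -> "NoiseModel":
        return replace(self, visual_scale=scale)

    def process_cov(self, layout: StateLayout, pseudo: bool = False) -> np.ndarray:
        """Diagonal process covariance Σ_m over the full augmented state.

        With ``pseudo=True`` the estimator's pseudo terms on f_ext and
        p_offset are included (Kalman-gain computation only).
        """
        q = np.zeros(layout.n_states)
        var_m = self.motor_sd ** 2
        for ax in range(layout.dims):
            q[layout.index("f_com", ax)] = var_m
            if pseudo:
                q[layout.index("f_ext", ax)] = self.f_ext * var_m
                q[layout.index("p_offset", ax)] = self.f_off * var_m
        return np.diag(q)

    def sensory_cov(self, layout: StateLayout,
                    inf_as: float | None = None) -> np.ndarray:
        """Diagonal sensory covariance Σ_ω over the observed channels.

        ``inf_as`` substitutes a large finite variance scale for the no-vision
        condition, needed only to keep the stationary Riccati solve
        well-posed; the resulting cursor gain columns are zeroed exactly
        afterwards.
        """
        r = np.zeros(layout.n_obs)
        scale = self.visual_scale
        if self.no_vision:
            if inf_as is None:
                raise InvalidParameterError(
                    "sensory covariance is unbounded in the no-vision condition")
            scale = inf_as
        for ax in range(layout.dims):
            for ch in OBS_CHANNELS:
                v = self.obs_sd[ch] ** 2
                if ch == "p_cursor":
                    v *= scale
                r[layout.obs_index(ch, ax)] = v
        return np.diag(r)


def make_signal_dependent_noise(noise: NoiseModel, c_motor: float,
                                c_sensory: float) -> NoiseModel:
    """Variant whose per-step SDs grow linearly with the corresponding signal.

    Motor SD becomes ``motor_sd + c_motor·|u|`` and each sensory SD
    ``sd·(1 + c_sensory·|signal|/ref)`` evaluated along the trajectory; with
    both coefficients zero this reduces exactly to the additive model.
    """
    if c_motor < 0 or c_sensory < 0:
        raise InvalidParameterError("signal-dependent coefficients must be non-negative")
    return replace(noise, c_motor=c_motor, c_sensory=c_sensory)
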