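"""Analysis-pipeline settings (windows, filters, thresholds)."""

from __future__ import annotations

from dataclasses import dataclass, field

from ..ofc.plant import InvalidParameterError


def _default_vision_duration() -> dict[tuple[int, str], float]:
    # experiment 2 extends the slow-condition viewing time to 170 ms
    return {(1, "fast"): 0.100, (1, "slow"): 0.100,
            (2, "fast"): 0.100, (2, "slow"): 0.170}


@dataclass(frozen=True)
class AnalysisConfig:
    """Windows are half-open [start, end); times in seconds unless suffixed _ms."""

    latencies_ms: tuple[float, ...] = (150, 300, 500, 700, 900)
    kin_cutoff_hz: float = 50.0
    kin_order: int = 4
    emg_band_hz: tuple[float, float] = (20.0, 250.0)
    emg_order: int = 8
    emg_cal_window: tuple[float, float] = (0.5, 1.5)   # s after calibration force onset
    emg_window: tuple[float, float] = (0.100, 0.250)   # s after vision onset
    vision_threshold_y: float = 0.08                   # m forward
    vision_duration: dict[tuple[int, str], float] = field(
        default_factory=_default_vision_duration)
    target_distance: float = 0.20                      # m
    undershoot_margin: float = 0.005                   # m; reached if max y >= target - margin
    onset_alpha: float = 0.05
    onset_persistence: int = 1
    onset_search_start: float = 0.100  # s after vision onset: the feedback-
    # removal time, before which pointwise tests would only yield alpha-rate
    # false crossings
    n_boot: int = 10_000
    alpha_within: float = 0.005
    alpha_trend: float = 0.05
    alpha_between: float = 0.05

    def __post_init__(self) -> None:
        if sorted(self.latencies_ms) != list(self.latencies_ms):
            raise InvalidParameterError("latencies must be sorted")
        for lo, hi in (self.emg_cal_window, self.emg_window, self.emg_band_hz):
            if hi <= lo:
                raise InvalidParameterError("windows must have positive length")
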