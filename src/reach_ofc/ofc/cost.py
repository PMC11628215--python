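"""Quadratic movement cost.

The state cost is zero during the reach itself and penalizes the squared
cursor-target error only during the final stabilization phase (0.5 s by
default). The control penalty R acts on every step, so the urgency of an
upcoming stabilization deadline is what shapes the time course of the control
gains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plant import InvalidParameterError, StateLayout, SystemMatrices


@dataclass(frozen=True)
class CostModel:
    """control_penalty R (per control channel), cursor-position weight during
    stabilization, optional velocity weight, stabilization duration in s."""

    control_penalty: float = 1e-4
    q_pos: float = 1.0
    q_vel: float = 0.0
    stab_duration: float = 0.5

    def __post_init__(self) -> None:
        if self.control_penalty <= 0:
            raise InvalidParameterError("control_penalty must be strictly positive")
        if self.q_pos < 0 or self.q_vel < 0 or self.stab_duration < 0:
            raise InvalidParameterError("cost weights and durations must be non-negative")

    def R(self, dims: int) -> np.ndarray:
        return self.control_penalty * np.eye(dims)

    def stabilization_Q(self, sys: SystemMatrices) -> np.ndarray:
        """State-cost matrix applied during the stabilization phase.

        Penalizes (p_cursor − p_target)² per axis, plus an optional velocity
        term. Expressed through the cursor so that compensating a cursor-hand
        offset is part of the task, as in the experiment.
        """
        layout: StateLayout = sys.layout
        Q = np.zeros((layout.n_states, layout.n_states))
        for ax in range(layout.dims):
            e = np.zeros(layout.n_states)
            e[layout.index("p_cursor", ax)] = 1.0
            e[layout.index("p_target", ax)] = -1.0
            Q += self.q_pos * np.outer(e, e)
            if self.q_vel:
                ev = np.zeros(layout.n_states)
                ev[layout.index("vel", ax)] = 1.0
                Q += self.q_vel * np.outer(ev, ev)
        return Q

    def schedule(self, sys: SystemMatrices, n_steps: int) -> list[np.ndarray]:
        """Per-step Q_t for a horizon of ``n_steps`` whose final
        ``stab_duration`` seconds are the stabilization phase."""
        if n_steps < 1:
            raise InvalidParameterError("horizon must contain at least one step")
        n_stab = min(n_steps, int(round(self.stab_duration / sys.plant.dt)))
        Qstab = self.stabilization_Q(sys)
        zero = np.zeros_like(Qstab)
        return [zero] * (n_steps - n_stab) + [Qstab] * n_stab
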