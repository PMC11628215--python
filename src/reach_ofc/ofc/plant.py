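"""Discrete linear plant for planar reaching.

The hand is a point mass with viscous damping whose commanded force passes
through a first-order muscle filter. Two extra states per movement axis carry
the displayed cursor position and the (unobservable) cursor-hand offset, and a
constant target-position state is appended so the quadratic cost can penalize
cursor-target error. The x- and y-axes are independent, so the full system is
block diagonal over axes.

Per-axis base state order: [pos, vel, f_com, f_ext, p_cursor, p_offset],
followed by the target-position state. Units are SI throughout (m, s, N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: per-axis base state labels, in matrix order
BASE_STATES = ("pos", "vel", "f_com", "f_ext", "p_cursor", "p_offset")
#: per-axis observed channels (p_offset is deliberately unobservable)
OBS_CHANNELS = ("pos", "vel", "f_com", "f_ext", "p_cursor")
TARGET_STATE = "p_target"
AXES = ("x", "y")


class InvalidParameterError(ValueError):
    """Raised for physically meaningless model parameters."""


@dataclass(frozen=True)
class PlantParams:
    """Point-mass plant parameters.

    mass : kg; damping : N·s/m; tau : muscle low-pass time constant, s;
    dt : Euler integration step, s; dims : number of planar axes (1 or 2).
    """

    mass: float = 1.0
    damping: float = 0.1
    tau: float = 0.066
    dt: float = 0.01
    dims: int = 2

    def __post_init__(self) -> None:
        for name in ("mass", "damping", "tau", "dt"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if self.dt >= self.tau:
            raise InvalidParameterError("dt must be smaller than the muscle time constant tau")
        if self.dims not in (1, 2):
            raise InvalidParameterError("dims must be 1 or 2")


@dataclass(frozen=True)
class StateLayout:
    """Index bookkeeping for the axis-blocked augmented state vector."""

    dims: int = 2

    @property
    def n_per_axis(self) -> int:
        return len(BASE_STATES) + 1  # + target state

    @property
    def n_states(self) -> int:
        return self.dims * self.n_per_axis

    @property
    def n_obs(self) -> int:
        return self.dims * len(OBS_CHANNELS)

    def index(self, label: str, axis: int = 0) -> int:
        """Position of state `label` for movement axis `axis` (0=x, 1=y)."""
        if not 0 <= axis < self.dims:
            raise InvalidParameterError(f"axis {axis} out of range for dims={self.dims}")
        base = axis * self.n_per_axis
        if label == TARGET_STATE:
            return base + len(BASE_STATES)
        return base + BASE_STATES.index(label)

    def obs_index(self, channel: str, axis: int = 0) -> int:
        if not 0 <= axis < self.dims:
            raise InvalidParameterError(f"axis {axis} out of range for dims={self.dims}")
        return axis * len(OBS_CHANNELS) + OBS_CHANNELS.index(channel)

    def labels(self) -> list[str]:
        names = list(BASE_STATES) + [TARGET_STATE]
        return [f"{n}_{AXES[a]}" for a in range(self.dims) for n in names]


@dataclass(frozen=True)
class SystemMatrices:
    """Discrete state-space matrices x_{t+1} = A x_t + B u_t, y_t = H x_t."""

    A: np.ndarray
    B: np.ndarray
    H: np.ndarray
    layout: StateLayout
    plant: PlantParams = field(default_factory=PlantParams)


def _axis_block(p: PlantParams) -> tuple[np.ndarray, np.ndarray]:
    """Single-axis (A, B) over [pos, vel, f_com, f_ext, p_cursor, p_offset, p_target]."""
    dt, m, g, tau = p.dt, p.mass, p.damping, p.tau
    n = len(BASE_STATES) + 1
    A = np.zeros((n, n))
    ip, iv, ic, ie, ipc, ioff, itg = range(n)
    A[ip, ip] = 1.0
    A[ip, iv] = dt
    A[iv, iv] = 1.0 - g * dt / m
    A[iv, ic] = dt / m
    A[iv, ie] = dt / m
    A[ic, ic] = 1.0 - dt / tau
    A[ie, ie] = 1.0
    # cursor tracks the hand one step ahead plus the (held) offset
    A[ipc, ip] = 1.0
    A[ipc, iv] = dt
    A[ipc, ioff] = 1.0
    A[ioff, ioff] = 1.0
    A[itg, itg] = 1.0
    B = np.zeros((n, 1))
    B[ic, 0] = dt / tau
    return A, B


def build_discrete_system(plant: PlantParams | None = None,
                          layout: StateLayout | None = None) -> SystemMatrices:
    """Euler-discretized plant, axes stacked block-diagonally.

    The observation matrix returns [pos, vel, f_com, f_ext, p_cursor] per axis;
    the cursor-hand offset and the (internally known) target state are not
    observed.
    """
    plant = plant or PlantParams()
    layout = layout or StateLayout(dims=plant.dims)
    if layout.dims != plant.dims:
        raise InvalidParameterError("layout dims must match plant dims")
    Aa, Ba = _axis_block(plant)
    n = layout.n_states
    A = np.zeros((n, n))
    B = np.zeros((n, plant.dims))
    H = np.zeros((layout.n_obs, n))
    npa = layout.n_per_axis
    for ax in range(plant.dims):
        s = ax * npa
        A[s:s + npa, s:s + npa] = Aa
        B[s:s + npa, ax:ax + 1] = Ba
        for ch in OBS_CHANNELS:
            H[layout.obs_index(ch, ax), layout.index(ch, ax)] = 1.0
    return SystemMatrices(A=A, B=B, H=H, layout=layout, plant=plant)
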