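"""Proportional heading control and waypoint navigation.

The heading angle is steered toward the bearing of the active target by the
proportional law ``dtheta/dt = k * alpha_d`` with ``alpha_d = psi - theta``
wrapped to the shortest arc, discretized by forward Euler at the control
sample rate (default 30 Hz, ``k = 5``).  On the ideal plant the heading
error contracts by the factor ``1 - k*dt`` per step (5/6 for the defaults);
``k*dt >= 2`` makes the discrete loop oscillatorily unstable.

A waypoint plan is navigated by recomputing the desired heading every step
and advancing the active target once the particle comes within the capture
radius.  Because the particle's displacement is ``s * n(theta)``, the
commanded bearing is flipped by pi when the propulsion sign is negative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .field_model import wrap_angle
from .propulsion_sim import (
    CoatingParams,
    FluidField,
    ParticleState,
    propulsion_speed,
    step,
)

__all__ = [
    "ControllerConfig",
    "WaypointPlan",
    "ControlTrace",
    "NavigationTimeout",
    "desired_heading",
    "control_step",
    "navigate",
    "error_series",
    "IdealPlant",
    "SimulatedPlant",
]

_COINCIDENT_TOL = 1e-12


@dataclass(frozen=True)
class ControllerConfig:
    """Proportional controller settings.

    k is the proportional gain (1/s), dt the control interval (s).  The
    discrete loop is stable for k*dt < 2; a warning is issued above 1.
    """

    k: float = 5.0
    dt: float = 1.0 / 30.0
    capture_radius: float = 3.0
    timeout: float = 120.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"gain k must be positive, got {self.k}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.capture_radius <= 0:
            raise ValueError("capture_radius must be positive")
        if self.timeout <= 0:
            raise ValueError("timeout must be positive")
        if self.k * self.dt > 1:
            warnings.warn(
                f"k*dt = {self.k * self.dt:.3f} > 1: heading error will "
                "overshoot each step; the loop diverges for k*dt >= 2",
                stacklevel=2,
            )


@dataclass(frozen=True)
class WaypointPlan:
    """Ordered list of target points (um) with a label."""

    points: tuple[tuple[float, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        pts = tuple((float(p[0]), float(p[1])) for p in self.points)
        if not pts:
            raise ValueError("waypoint plan must be non-empty")
        for a, b in zip(pts, pts[1:]):
            if math.dist(a, b) < _COINCIDENT_TOL:
                raise ValueError(f"consecutive waypoints coincide: {a}")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)


@dataclass
class ControlTrace:
    """Per-step record of a closed-loop navigation run."""

    t: np.ndarray
    theta: np.ndarray
    psi: np.ndarray
    alpha: np.ndarray
    error: np.ndarray
    target_idx: np.ndarray
    x: np.ndarray
    y: np.ndarray
    completed: bool = True
    label: str = ""
    switch_steps: tuple[int, ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "theta_rad": self.theta,
                "psi_rad": self.psi,
                "alpha_rad": self.alpha,
                "error_um": self.error,
                "target_idx": self.target_idx,
                "x_um": self.x,
                "y_um": self.y,
            }
        )

    def export(self, path) -> pd.DataFrame:
        table = self.to_frame()
        table.to_csv(path, index=False)
        return table


class NavigationTimeout(RuntimeError):
    """Navigation did not capture every waypoint within the timeout.

    Carries the partial :class:`ControlTrace` as ``trace``.
    """

    def __init__(self, message: str, trace: ControlTrace):
        super().__init__(message)
        self.trace = trace


def desired_heading(pos, target) -> float:
    """Bearing psi such that n(psi) points from ``pos`` toward ``target``.

    With n = (-cos psi, sin psi, 0), psi = atan2(dy, -dx) for the
    displacement d = target - pos.  Coincident points are degenerate.
    """
    dx = target[0] - pos[0]
    dy = target[1] - pos[1]
    if math.hypot(dx, dy) < _COINCIDENT_TOL:
        raise ValueError("desired heading undefined: position equals target")
    return math.atan2(dy, -dx)


def control_step(theta: float, psi: float, k: float, dt: float) -> float:
    """One proportional update: wrap(theta + k * wrap(psi - theta) * dt)."""
    alpha = wrap_angle(psi - theta)
    return wrap_angle(theta + k * alpha * dt)


class IdealPlant:
    """Noise-free plant: displacement exactly s*speed*dt along n(theta)."""

    def __init__(self, speed: float):
        if speed < 0:
            raise ValueError("speed must be non-negative")
        self.speed = speed

    def __call__(
        self, state: ParticleState, theta: float, dt: float, rng
    ) -> ParticleState:
        return step(state, theta, self.speed, dt)


class SimulatedPlant:
    """Plant backed by the propulsion model and a mucus mobility field."""

    def __init__(
        self,
        coating: CoatingParams,
        f: float,
        beta: float,
        B_s: float = 0.0,
        fluid: FluidField | None = None,
        sigma_xy: float = 0.0,
    ):
        self.coating = coating
        self.f = f
        self.beta = beta
        self.B_s = B_s
        self.fluid = fluid
        self.sigma_xy = sigma_xy

    def __call__(
        self, state: ParticleState, theta: float, dt: float, rng
    ) -> ParticleState:
        m_local = (
            self.fluid.sample(state.x, state.y) if self.fluid is not None else 1.0
        )
        speed = propulsion_speed(
            self.coating, self.f, self.beta, self.B_s, m_local, rng
        )
        return step(state, theta, speed, dt, self.sigma_xy, rng)


def navigate(
    plan: WaypointPlan,
    particle: ParticleState,
    controller: ControllerConfig,
    plant,
    rng: np.random.Generator | None = None,
    theta0: float = 0.0,
) -> ControlTrace:
    """Closed-loop waypoint navigation.

    Each control interval: the bearing to the active target is recomputed,
    the heading updated by the proportional law, and the particle advanced
    by the plant callable ``plant(state, theta, dt, rng) -> state``.  The
    active target advances when the distance to it falls below the capture
    radius; the run completes when the last target is captured and raises
    :class:`NavigationTimeout` (with the partial trace attached) otherwise.
    """
    k, dt = controller.k, controller.dt
    max_steps = int(math.ceil(controller.timeout / dt))
    pts = plan.as_array()
    state = particle
    theta = wrap_angle(theta0)
    idx = 0
    psi = theta  # held value, used only if pos ~ target mid-step
    rows: list[tuple] = []
    switch_steps: list[int] = []
    completed = False
    for i in range(max_steps + 1):
        error = math.dist((state.x, state.y), pts[idx])
        while error < controller.capture_radius:
            if idx == len(pts) - 1:
                completed = True
                break
            idx += 1
            switch_steps.append(i)
            error = math.dist((state.x, state.y), pts[idx])
        t = i * dt
        if completed:
            alpha = wrap_angle(psi - theta)
            rows.append((t, theta, psi, alpha, error, idx, state.x, state.y))
            break
        dx = pts[idx][0] - state.x
        dy = pts[idx][1] - state.y
        if math.hypot(dx, dy) >= _COINCIDENT_TOL:
            psi_raw = math.atan2(dy, -dx)
            psi = psi_raw if state.s > 0 else wrap_angle(psi_raw + math.pi)
        alpha = wrap_angle(psi - theta)
        rows.append((t, theta, psi, alpha, error, idx, state.x, state.y))
        theta = wrap_angle(theta + k * alpha * dt)
        state = plant(state, theta, dt, rng)
    cols = list(zip(*rows))
    trace = ControlTrace(
        t=np.asarray(cols[0]),
        theta=np.asarray(cols[1]),
        psi=np.asarray(cols[2]),
        alpha=np.asarray(cols[3]),
        error=np.asarray(cols[4]),
        target_idx=np.asarray(cols[5], dtype=int),
        x=np.asarray(cols[6]),
        y=np.asarray(cols[7]),
        completed=completed,
        label=plan.label,
        switch_steps=tuple(switch_steps),
    )
    if not completed:
        raise NavigationTimeout(
            f"plan '{plan.label}' not completed within {controller.timeout} s "
            f"(reached target {idx + 1}/{len(pts)})",
            trace,
        )
    return trace


def error_series(trace: ControlTrace) -> pd.DataFrame:
    """Distance to the active target over time, switch jumps preserved."""
    if len(trace.t) == 0:
        raise ValueError("trace is empty")
    return pd.DataFrame({"t_s": trace.t, "error_um": trace.error})
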