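"""Synthetic inputs for the pipeline: rendered frame stacks, mucus mobility
fields, coating presets, and letter waypoint plans.

Everything here is a pure function of its parameters and a seed, so every
pipeline stage is testable without any experimental data.  The renderer
draws an anti-aliased dark disk (default radius 5 um, matching a 10 um
diameter particle) on a bright noisy background at 0.5 um/px; the mucus
generator produces a spatially correlated lognormal mobility multiplier
with unit mean, emulating randomly concentrated mucin glycoproteins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.ndimage import gaussian_filter

from .feedback_controller import WaypointPlan
from .propulsion_sim import CoatingParams, FluidField
from .tracking_velocity import FrameStack

__all__ = [
    "RenderSpec",
    "COATING_NAMES",
    "PRESET_REGIMES",
    "render_frames",
    "make_mucus_field",
    "coating_presets",
    "regime_expectations",
    "make_waypoint_plan",
    "waypoint_labels",
]

COATING_NAMES = ("avidin", "biotin", "biotin_peg3_amine", "biotin_chitosan")
PRESET_REGIMES = (
    "sweep_1_19",
    "sweep_5_50",
    "sweep_10_100",
    "beta_sweep_14Hz",
    "static_sweep_15Hz",
)


@dataclass(frozen=True)
class RenderSpec:
    """Rendering parameters for synthetic microscopy frames."""

    shape: tuple[int, int] = (256, 256)  # (height, width) px
    pixel_size: float = 0.5  # um/px
    radius_um: float = 5.0  # 10 um diameter particle
    background: float = 0.8
    particle: float = 0.2
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.radius_um <= 0:
            raise ValueError("pixel_size and radius_um must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.particle <= 1 and 0 <= self.background <= 1):
            raise ValueError("intensities must lie in [0, 1]")


def render_frames(trajectory, spec: RenderSpec) -> FrameStack:
    """Render a trajectory as a stack of dark-disk frames.

    ``trajectory`` is a sequence of (t, x, y) samples in seconds and um,
    uniformly spaced in time (the frame rate is inferred from the spacing).
    The disk is anti-aliased via per-pixel edge coverage; seeded Gaussian
    noise of sd ``spec.noise_sd`` is added and intensities clipped to
    [0, 1].  A trajectory whose disk would leave the frame is rejected.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim != 2 or traj.shape[1] != 3 or traj.shape[0] < 2:
        raise ValueError("trajectory must be an (N>=2, 3) array of (t, x, y)")
    dts = np.diff(traj[:, 0])
    if np.any(dts <= 0) or not np.allclose(dts, dts[0], rtol=1e-6):
        raise ValueError("trajectory must be uniformly sampled in time")
    fps = 1.0 / dts[0]
    h, w = spec.shape
    r_px = spec.radius_um / spec.pixel_size
    x_px = traj[:, 1] / spec.pixel_size
    y_px = traj[:, 2] / spec.pixel_size
    margin = r_px + 1.0
    if (
        np.any(x_px < margin)
        or np.any(x_px > w - 1 - margin)
        or np.any(y_px < margin)
        or np.any(y_px > h - 1 - margin)
    ):
        raise ValueError("trajectory leaves the frame (disk would be clipped)")
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:h, 0:w]
    frames = np.empty((traj.shape[0], h, w))
    for i, (cx, cy) in enumerate(zip(x_px, y_px)):
        dist = np.hypot(xx - cx, yy - cy)
        coverage = np.clip(r_px + 0.5 - dist, 0.0, 1.0)
        frame = spec.background + (spec.particle - spec.background) * coverage
        if spec.noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.noise_sd, size=frame.shape)
        frames[i] = np.clip(frame, 0.0, 1.0)
    return FrameStack(frames=frames, pixel_size=spec.pixel_size, fps=fps)


def make_mucus_field(
    extent: tuple[float, float, float, float] = (-200.0, 200.0, -200.0, 200.0),
    grid_step: float = 5.0,
    correlation_length: float = 25.0,
    cv: float = 0.25,
    seed: int = 0,
) -> FluidField:
    """Spatially correlated lognormal mobility field with unit mean.

    White Gaussian noise on the grid is smoothed with a Gaussian kernel of
    the requested correlation length, restandardized, exponentiated with
    the lognormal sigma that yields the requested coefficient of variation
    (sigma = sqrt(ln(1 + cv^2))), and rescaled to sample mean 1.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if grid_step <= 0 or correlation_length < 0:
        raise ValueError("grid_step must be > 0 and correlation_length >= 0")
    x0, x1, y0, y1 = extent
    nx = int(round((x1 - x0) / grid_step)) + 1
    ny = int(round((y1 - y0) / grid_step)) + 1
    x = np.linspace(x0, x1, nx)
    y = np.linspace(y0, y1, ny)
    if cv == 0:
        m = np.ones((ny, nx))
    else:
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((ny, nx))
        if correlation_length > 0:
            z = gaussian_filter(z, sigma=correlation_length / grid_step, mode="wrap")
        z = (z - z.mean()) / z.std()
        sigma_ln = np.sqrt(np.log1p(cv * cv))
        m = np.exp(sigma_ln * z)
        m = m / m.mean()
    return FluidField(
        x=x, y=y, m=m, correlation_length=correlation_length, cv=cv, seed=seed
    )


def _load_data(name: str) -> dict:
    with resources.files("mucoswim.data").joinpath(name).open() as fh:
        return json.load(fh)


def coating_presets(regime: str) -> dict[str, CoatingParams]:
    """Named coating parameter sets for one protocol regime.

    The presets are versioned data shipped with the package; they are
    calibrated only to reproduce, in expectation, the qualitative velocity
    orderings of each regime (e.g. PEG fastest in the low-frequency
    high-amplitude regime, chitosan fastest in the high-frequency
    low-amplitude regime, and the non-monotone chitosan response to 1/beta
    at fixed 14 Hz).
    """
    data = _load_data("coating_presets.json")
    if regime not in data["regimes"]:
        raise KeyError(
            f"unknown regime {regime!r}; available: {sorted(data['regimes'])}"
        )
    beta_ref = data["beta_ref"]
    presets = {}
    for name, params in data["regimes"][regime].items():
        presets[name] = CoatingParams(name=name, beta_ref=beta_ref, **params)
    missing = set(COATING_NAMES) - set(presets)
    if missing:
        raise ValueError(f"preset library for {regime} missing coatings: {missing}")
    return presets


def regime_expectations() -> dict:
    """Qualitative velocity-ordering expectations bundled with the presets.

    Keys are regime names; values describe the ordering the preset-driven
    simulations are expected to reproduce in expectation (which coating is
    fastest/slowest at which frequencies, and which coating responds
    non-monotonically to 1/beta at fixed frequency).
    """
    return _load_data("coating_presets.json")["qualitative"]


def waypoint_labels() -> tuple[str, ...]:
    """Labels of the bundled letter plans."""
    return tuple(sorted(_load_data("waypoint_plans.json")["plans"]))


def make_waypoint_plan(label: str) -> WaypointPlan:
    """Bundled schematic letter plan (~50 um extent)."""
    plans = _load_data("waypoint_plans.json")["plans"]
    if label not in plans:
        raise KeyError(f"unknown plan {label!r}; available: {sorted(plans)}")
    return WaypointPlan(points=tuple(map(tuple, plans[label])), label=label)
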