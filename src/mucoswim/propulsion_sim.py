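"""Spontaneous-symmetry-breaking propulsion simulator.

A magnetic microparticle rotating in a rod-climbing-like (viscoelastic)
fluid translates along its rotation axis.  The squeezing effect from normal
stress differences admits two equal and opposite propulsion states (U+, U-):
which one is realized is random when no static field is superimposed, and is
selected deterministically by the sign of the static field once its
magnitude exceeds a threshold.

The constitutive law used here is phenomenological:

    speed = c * <f_rot>(f, f_c(beta)) * g(B_s) * bump(beta) * m(x, y) * (1 + eps)

where ``c`` is a coating-dependent slope (um/s per Hz), ``<f_rot>`` is the
time-averaged rotation rate of an overdamped driven rotor (equal to the
drive frequency f below the step-out frequency f_c, and
``f - sqrt(f^2 - f_c^2)`` above it), ``g`` is an even static-field shaping
factor with g(0) = 1, ``bump`` is an optional resonance-like enhancement in
1/beta, ``m`` is a spatially heterogeneous mucus mobility multiplier with
unit mean, and ``eps`` is multiplicative Gaussian speed noise.

Displacement direction is ``s * n(theta)`` with the propulsion sign
``s = +/-1`` carrying the entire direction reversal between the two states.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .field_model import heading_vector

__all__ = [
    "ParticleState",
    "CoatingParams",
    "FluidField",
    "MobilityBoundsError",
    "mean_rotation_rate",
    "propulsion_sign",
    "propulsion_speed",
    "step",
    "sample_mobility",
    "simulate_fixed_heading",
    "export_trajectory",
]


@dataclass(frozen=True)
class ParticleState:
    """Planar particle state: position (um), propulsion sign, dipole phase."""

    x: float = 0.0
    y: float = 0.0
    s: int = 1
    phi: float = 0.0

    def __post_init__(self) -> None:
        if self.s not in (-1, 1):
            raise ValueError(f"propulsion sign must be -1 or +1, got {self.s}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("position must be finite")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class CoatingParams:
    """Phenomenological propulsion parameters for one surface chemistry.

    Attributes
    ----------
    name : coating label (avidin, biotin, biotin_peg3_amine, biotin_chitosan).
    c : speed slope, um/s per Hz of attained rotation.
    f_c0 : step-out frequency scale at the reference scaling factor, Hz.
    p : exponent of the step-out dependence on beta,
        f_c(beta) = f_c0 * (beta / beta_ref)**p.
    sigma_U : multiplicative speed-noise standard deviation.
    B_th : static-field magnitude below which state selection is random, mT.
    g_shape : even static-field speed shaping, per mT: g = 1 + g_shape*|B_s|.
    bump_amp, bump_inv_beta, bump_width : optional Gaussian velocity
        enhancement centred at 1/beta = bump_inv_beta (resonance-like term;
        off by default).
    beta_ref : reference scaling factor for f_c, mT/Hz.
    """

    name: str
    c: float
    f_c0: float
    p: float = 0.0
    sigma_U: float = 0.0
    B_th: float = 0.1
    g_shape: float = 0.0
    bump_amp: float = 0.0
    bump_inv_beta: float = 3.0
    bump_width: float = 1.0
    beta_ref: float = 0.5

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError(f"speed slope c must be >= 0, got {self.c}")
        if self.f_c0 < 0:
            raise ValueError(f"f_c0 must be >= 0, got {self.f_c0}")
        if self.sigma_U < 0:
            raise ValueError(f"sigma_U must be >= 0, got {self.sigma_U}")
        if self.B_th < 0:
            raise ValueError(f"B_th must be >= 0, got {self.B_th}")
        if self.beta_ref <= 0:
            raise ValueError(f"beta_ref must be > 0, got {self.beta_ref}")

    def step_out_frequency(self, beta: float) -> float:
        """Step-out frequency f_c(beta) = f_c0 * (beta/beta_ref)**p, Hz."""
        if beta <= 0:
            raise ValueError(f"beta must be > 0, got {beta}")
        return self.f_c0 * (beta / self.beta_ref) ** self.p

    def field_shaping(self, B_s) -> float:
        """Even static-field speed factor g(B_s) = 1 + g_shape*|B_s|."""
        return 1.0 + self.g_shape * np.abs(B_s)

    def beta_response(self, beta: float) -> float:
        """Resonance-like enhancement in 1/beta (1.0 when bump_amp == 0)."""
        if self.bump_amp == 0.0:
            return 1.0
        z = (1.0 / beta - self.bump_inv_beta) / self.bump_width
        return 1.0 + self.bump_amp * math.exp(-0.5 * z * z)

    def with_noise_off(self) -> "CoatingParams":
        return replace(self, sigma_U=0.0)


def mean_rotation_rate(f, f_c):
    """Time-averaged rotation rate (Hz) of an overdamped driven rotor.

    Below the step-out frequency the particle rotates synchronously with the
    field (rate f).  Above it the rotor slips periodically and the average
    rate drops to ``f - sqrt(f^2 - f_c^2)``, the classical average of
    ``dphi/dt = omega_c * sin(omega*t - phi)``.
    """
    f_arr = np.asarray(f, dtype=float)
    fc_arr = np.asarray(f_c, dtype=float)
    if np.any(f_arr < 0) or np.any(fc_arr < 0):
        raise ValueError("f and f_c must be non-negative")
    slip = np.sqrt(np.maximum(f_arr * f_arr - fc_arr * fc_arr, 0.0))
    out = np.where(f_arr <= fc_arr, f_arr, f_arr - slip)
    if out.ndim == 0:
        return float(out)
    return out


def propulsion_sign(B_s: float, B_th: float, rng: np.random.Generator) -> int:
    """Select a propulsion state: deterministic above threshold, random below.

    Returns ``sign(B_s)`` when ``|B_s| > B_th``; otherwise draws +1 or -1
    with equal probability (the spontaneously broken, unbiased case).
    """
    if B_th < 0:
        raise ValueError(f"B_th must be >= 0, got {B_th}")
    if abs(B_s) > B_th:
        return 1 if B_s > 0 else -1
    return int(rng.choice((-1, 1)))


def propulsion_speed(
    coating: CoatingParams,
    f: float,
    beta: float,
    B_s: float,
    m_local,
    rng: np.random.Generator | None = None,
):
    """Unsigned propulsion speed (um/s) under the phenomenological law.

    ``m_local`` may be a scalar or an array (one value per simulated
    particle); the multiplicative noise draw matches its shape.  Noise is
    truncated below at -0.9 so the speed stays positive.
    """
    m_local = np.asarray(m_local, dtype=float)
    if np.any(m_local <= 0):
        raise ValueError("mobility multiplier must be positive")
    f_c = coating.step_out_frequency(beta)
    base = (
        coating.c
        * mean_rotation_rate(f, f_c)
        * coating.field_shaping(B_s)
        * coating.beta_response(beta)
        * m_local
    )
    if coating.sigma_U > 0:
        if rng is None:
            raise ValueError("rng is required when sigma_U > 0")
        eps = np.maximum(rng.normal(0.0, coating.sigma_U, size=m_local.shape), -0.9)
        base = base * (1.0 + eps)
    if base.ndim == 0:
        return float(base)
    return base


def step(
    state: ParticleState,
    theta: float,
    speed: float,
    dt: float,
    sigma_xy: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ParticleState:
    """Advance one Euler step: displacement s*speed*dt along n(theta).

    Optional Gaussian positional noise of standard deviation ``sigma_xy``
    (um) is added per axis.  Sign and dipole phase are carried forward.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    n = heading_vector(theta)
    dx = state.s * speed * dt * n.nx
    dy = state.s * speed * dt * n.ny
    if sigma_xy > 0:
        if rng is None:
            raise ValueError("rng is required when sigma_xy > 0")
        dx += rng.normal(0.0, sigma_xy)
        dy += rng.normal(0.0, sigma_xy)
    return replace(state, x=state.x + dx, y=state.y + dy)


class MobilityBoundsError(ValueError):
    """Raised when a mobility query falls outside the field extent."""


@dataclass(frozen=True)
class FluidField:
    """Heterogeneous mucus mobility multiplier sampled on a regular grid.

    ``m`` is indexed ``[iy, ix]`` over strictly increasing axis coordinates
    ``x`` and ``y`` (um).  Values are positive with mean ~1; ``cv`` is the
    coefficient of variation of the generating law and
    ``correlation_length`` its spatial smoothing scale (um).
    """

    x: np.ndarray
    y: np.ndarray
    m: np.ndarray
    correlation_length: float
    cv: float
    seed: int

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.shape != (len(self.y), len(self.x)):
            raise ValueError("mobility grid shape must be (len(y), len(x))")
        if np.any(m <= 0):
            raise ValueError("mobility values must be strictly positive")
        object.__setattr__(self, "m", m)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) in um."""
        return (self.x[0], self.x[-1], self.y[0], self.y[-1])

    def _interpolator(self) -> RegularGridInterpolator:
        interp = getattr(self, "_interp_cache", None)
        if interp is None:
            interp = RegularGridInterpolator(
                (self.y, self.x), self.m, method="linear", bounds_error=True
            )
            object.__setattr__(self, "_interp_cache", interp)
        return interp

    def sample(self, x, y):
        """Bilinear mobility interpolation at (x, y) um; bounds-checked."""
        scalar = np.ndim(x) == 0 and np.ndim(y) == 0
        pts = np.stack(
            [np.asarray(y, dtype=float), np.asarray(x, dtype=float)], axis=-1
        )
        try:
            out = self._interpolator()(pts)
        except ValueError as exc:
            raise MobilityBoundsError(
                f"mobility query outside field extent {self.extent}: {exc}"
            ) from None
        if scalar:
            return float(out.reshape(-1)[0])
        return out

    def save(self, prefix) -> None:
        """Write the grid (plain text) and a JSON sidecar under ``prefix``."""
        prefix = Path(prefix)
        np.savetxt(prefix.with_suffix(".grid.txt"), self.m)
        sidecar = {
            "x_min": float(self.x[0]),
            "x_max": float(self.x[-1]),
            "y_min": float(self.y[0]),
            "y_max": float(self.y[-1]),
            "nx": int(len(self.x)),
            "ny": int(len(self.y)),
            "correlation_length_um": float(self.correlation_length),
            "cv": float(self.cv),
            "seed": int(self.seed),
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, prefix) -> "FluidField":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        m = np.loadtxt(prefix.with_suffix(".grid.txt"))
        m = np.atleast_2d(m)
        x = np.linspace(meta["x_min"], meta["x_max"], meta["nx"])
        y = np.linspace(meta["y_min"], meta["y_max"], meta["ny"])
        return cls(
            x=x,
            y=y,
            m=m,
            correlation_length=meta["correlation_length_um"],
            cv=meta["cv"],
            seed=meta["seed"],
        )


def sample_mobility(fluid: FluidField, x, y):
    """Module-level convenience wrapper around :meth:`FluidField.sample`."""
    return fluid.sample(x, y)


def simulate_fixed_heading(
    coating: CoatingParams,
    f: float,
    beta: float,
    B_s: float,
    fluid: FluidField | None,
    duration: float,
    dt: float,
    theta: float,
    start_xy: np.ndarray,
    signs: np.ndarray,
    rng: np.random.Generator,
    sigma_xy: float = 0.0,
) -> dict[str, np.ndarray]:
    """Vectorized fixed-heading simulation of an ensemble of particles.

    ``start_xy`` has shape (n, 2); ``signs`` shape (n,) with values +/-1.
    Each particle is advanced by Euler steps of ``dt`` for ``duration``
    seconds with the heading held at ``theta``.  Mobility is sampled at the
    current position each step (homogeneous, m = 1, when ``fluid`` is None).

    Returns arrays: ``x``, ``y`` of shape (n_steps+1, n), ``mean_vx`` and
    ``mean_vy`` of shape (n,) (displacement / duration), and ``t``.
    """
    start_xy = np.asarray(start_xy, dtype=float)
    signs = np.asarray(signs)
    n = start_xy.shape[0]
    n_steps = int(round(duration / dt))
    nvec = heading_vector(theta)
    x = np.empty((n_steps + 1, n))
    y = np.empty((n_steps + 1, n))
    x[0] = start_xy[:, 0]
    y[0] = start_xy[:, 1]
    ones = np.ones(n)
    for i in range(n_steps):
        m_local = fluid.sample(x[i], y[i]) if fluid is not None else ones
        speed = propulsion_speed(coating, f, beta, B_s, m_local, rng)
        x[i + 1] = x[i] + signs * speed * dt * nvec.nx
        y[i + 1] = y[i] + signs * speed * dt * nvec.ny
        if sigma_xy > 0:
            x[i + 1] += rng.normal(0.0, sigma_xy, size=n)
            y[i + 1] += rng.normal(0.0, sigma_xy, size=n)
    total_t = n_steps * dt
    return {
        "t": np.arange(n_steps + 1) * dt,
        "x": x,
        "y": y,
        "mean_vx": (x[-1] - x[0]) / total_t,
        "mean_vy": (y[-1] - y[0]) / total_t,
    }


def export_trajectory(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    sign: int,
    speed: np.ndarray,
    path,
) -> pd.DataFrame:
    """Write a single-particle trajectory to CSV (t_s, x_um, y_um, sign, speed_um_s)."""
    table = pd.DataFrame(
        {
            "t_s": np.asarray(t, dtype=float),
            "x_um": np.asarray(x, dtype=float),
            "y_um": np.asarray(y, dtype=float),
            "sign": int(sign),
            "speed_um_s": np.asarray(speed, dtype=float),
        }
    )
    table.to_csv(path, index=False)
    return table
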