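"""Magnetic field synthesis for rotating-field microparticle steering.

A triaxial (approximate Helmholtz) coil system drives a microparticle with a
field that is the superposition of two parts:

* a rotating field of constant amplitude ``B_r`` circling in the plane normal
  to the in-plane heading vector ``n(theta) = (-cos theta, sin theta, 0)``,
  at angular rate ``omega = 2*pi*f``;
* a static field of signed amplitude ``B_s`` directed along ``n``.

The rotating amplitude is slaved to the drive frequency through the scaling
factor ``beta``: ``B_r = beta * f``.  Keeping ``beta`` fixed while sweeping
``f`` keeps the field torque growing with frequency, which delays the
step-out transition of the driven particle.  The total field magnitude is
constant in time: ``|B|^2 = B_s^2 + B_r^2``.

All amplitudes are in millitesla, frequencies in hertz, angles in radians.
Heading convention: ``theta = 0`` points along ``-x``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "FieldConfig",
    "FieldVector",
    "Heading",
    "wrap_angle",
    "rotational_amplitude",
    "field_at",
    "heading_vector",
    "static_sweep_values",
    "export_waveform",
    "waveform_table",
]

TWO_PI = 2.0 * math.pi


def wrap_angle(theta):
    """Wrap an angle (scalar or array) to the half-open interval (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = math.pi - np.remainder(math.pi - theta, TWO_PI)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


def rotational_amplitude(beta: float, f: float) -> float:
    """Rotating-field amplitude B_r = beta * f (mT).

    Parameters
    ----------
    beta : float
        Scaling factor in mT/Hz, must be non-negative.
    f : float
        Drive frequency in Hz, must be non-negative.
    """
    if beta < 0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    if f < 0:
        raise ValueError(f"frequency must be non-negative, got {f}")
    return beta * f


@dataclass(frozen=True)
class FieldConfig:
    """Parameters of the combined rotating + static field.

    Attributes
    ----------
    B_s : signed static amplitude along the heading vector, mT.
    beta : rotating-amplitude scaling factor, mT/Hz (non-negative).
    f : rotation frequency, Hz (non-negative).
    theta : in-plane heading angle, rad; stored wrapped to (-pi, pi].
    max_B_r : optional amplitude cap, mT.  Protocols whose derived
        B_r = beta*f exceed the cap are rejected, mirroring the limited
        drive envelope of a physical coil system.
    """

    B_s: float = 0.0
    beta: float = 0.5
    f: float = 0.0
    theta: float = 0.0
    max_B_r: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in ("B_s", "beta", "f", "theta"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value}")
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")
        if self.f < 0:
            raise ValueError(f"frequency must be non-negative, got {self.f}")
        object.__setattr__(self, "theta", wrap_angle(self.theta))
        if self.max_B_r is not None and self.B_r > self.max_B_r + 1e-12:
            raise ValueError(
                f"rotating amplitude B_r={self.B_r:.3f} mT exceeds the "
                f"configured cap of {self.max_B_r:.3f} mT"
            )

    @property
    def B_r(self) -> float:
        """Rotating amplitude beta*f, mT."""
        return rotational_amplitude(self.beta, self.f)

    @property
    def omega(self) -> float:
        """Angular drive rate 2*pi*f, rad/s."""
        return TWO_PI * self.f


class FieldVector(NamedTuple):
    """Field components (mT) at time t (s)."""

    Bx: float
    By: float
    Bz: float
    t: float


class Heading(NamedTuple):
    """Unit propulsion-direction vector, confined to the x-y plane."""

    nx: float
    ny: float
    nz: float

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


def heading_vector(theta: float) -> Heading:
    """Propulsion direction n = (-cos theta, sin theta, 0)."""
    if not math.isfinite(theta):
        raise ValueError(f"theta must be finite, got {theta}")
    return Heading(-math.cos(theta), math.sin(theta), 0.0)


def field_at(config: FieldConfig, t):
    """Evaluate the field at time(s) ``t``.

    Returns a :class:`FieldVector`.  ``t`` may be a scalar (components are
    floats) or an array (components are arrays of matching shape).

    The static part ``B_s * n`` is orthogonal to the rotating part, which has
    constant magnitude ``B_r``, so ``|B|^2 = B_s^2 + B_r^2`` for all t.
    """
    t_arr = np.asarray(t, dtype=float)
    B_s, B_r, theta, omega = config.B_s, config.B_r, config.theta, config.omega
    cwt = np.cos(omega * t_arr)
    swt = np.sin(omega * t_arr)
    Bx = -B_s * math.cos(theta) + B_r * math.sin(theta) * cwt
    By = B_s * math.sin(theta) + B_r * math.cos(theta) * cwt
    Bz = B_r * swt
    if t_arr.ndim == 0:
        return FieldVector(float(Bx), float(By), float(Bz), float(t_arr))
    return FieldVector(Bx, By, Bz, t_arr)


def static_sweep_values(start: float, stop: float, step: float) -> np.ndarray:
    """Inclusive arithmetic sweep of static-field values (mT).

    The endpoint is included when ``(stop - start) / step`` is integral
    within 1e-9.  A -2 to 2 mT sweep at 0.2 mT increments yields 21 values.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if stop < start:
        raise ValueError(f"stop ({stop}) must be >= start ({start})")
    n_steps = (stop - start) / step
    count = int(math.floor(n_steps + 1e-9)) + 1
    return start + step * np.arange(count)


def waveform_table(
    config: FieldConfig, duration: float, sample_rate: float
) -> pd.DataFrame:
    """Sampled field waveform as a table with columns t_s, Bx_mT, By_mT, Bz_mT."""
    if duration <= 0 or sample_rate <= 0:
        raise ValueError("duration and sample_rate must be positive")
    n = int(round(duration * sample_rate))
    t = np.arange(n + 1) / sample_rate
    vec = field_at(config, t)
    return pd.DataFrame(
        {"t_s": t, "Bx_mT": vec.Bx, "By_mT": vec.By, "Bz_mT": vec.Bz}
    )


def export_waveform(
    config: FieldConfig, duration: float, sample_rate: float, path
) -> pd.DataFrame:
    """Write the sampled waveform to CSV; returns the table written."""
    table = waveform_table(config, duration, sample_rate)
    table.to_csv(path, index=False)
    return table
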