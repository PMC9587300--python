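"""Centroid tracking and velocity analysis for microscopy frame stacks.

The chain mirrors the experimental image-analysis procedure: Otsu
thresholding isolates the dark microparticle, the connected component
nearest the previous bounding box is kept, and an intensity-weighted
centroid gives sub-pixel positions.  Instantaneous velocities are finite
differences between consecutive frames; trajectory velocity plots are
cleaned by replacing speeds beyond 3x the mean with the mean and smoothing
with a 60-point centered moving average.  Frequency sweeps are summarized
as per-frequency mean +/- standard error and fitted by a zero-intercept
line U = slope * f whose R^2 is computed about the mean of U.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import dilation, disk

__all__ = [
    "FrameStack",
    "Track",
    "VelocitySeries",
    "LinearFit",
    "DetectionError",
    "detect_centroid",
    "track_stack",
    "instantaneous_velocity",
    "clean_and_smooth",
    "fit_through_origin",
    "aggregate_trials",
    "load_frame_stack",
]


class DetectionError(RuntimeError):
    """No particle-like component could be found in a frame."""


@dataclass(frozen=True)
class FrameStack:
    """Grayscale frame stack (N, H, W) with intensities in [0, 1]."""

    frames: np.ndarray
    pixel_size: float  # um per px
    fps: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3 or frames.shape[0] < 2:
            raise ValueError("frames must be a (N>=2, H, W) array")
        if self.pixel_size <= 0 or self.fps <= 0:
            raise ValueError("pixel_size and fps must be positive")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return self.frames.shape[0]

    def save(self, path) -> None:
        """Write a multi-page TIFF plus a JSON sidecar with scale and rate."""
        path = Path(path)
        tifffile.imwrite(
            path, self.frames.astype(np.float32), photometric="minisblack"
        )
        sidecar = {"pixel_size_um": self.pixel_size, "fps": self.fps}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_frame_stack(path) -> FrameStack:
    """Load a stack from a multi-page TIFF or a directory of PNG frames.

    A JSON sidecar ``{pixel_size_um, fps}`` must sit next to the TIFF (or
    inside the directory as ``stack.json``).
    """
    path = Path(path)
    if path.is_dir():
        meta = json.loads((path / "stack.json").read_text())
        files = sorted(path.glob("*.png"))
        if len(files) < 2:
            raise ValueError(f"need at least two PNG frames in {path}")
        frames = np.stack([np.asarray(iio.imread(f), dtype=float) for f in files])
        if frames.max() > 1.0:
            frames = frames / 255.0
    else:
        meta = json.loads(path.with_suffix(".json").read_text())
        frames = np.asarray(tifffile.imread(path), dtype=float)
    return FrameStack(frames=frames, pixel_size=meta["pixel_size_um"], fps=meta["fps"])


@dataclass(frozen=True)
class Track:
    """Per-frame centroids (um) and tight bounding boxes (px)."""

    xy: np.ndarray  # (N, 2) um
    bboxes: np.ndarray  # (N, 4) px as (x0, y0, x1, y1)

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float)
        bb = np.asarray(self.bboxes, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2 or bb.shape != (xy.shape[0], 4):
            raise ValueError("xy must be (N, 2) and bboxes (N, 4)")
        object.__setattr__(self, "xy", xy)
        object.__setattr__(self, "bboxes", bb)

    def export(self, path, fps: float) -> pd.DataFrame:
        table = pd.DataFrame(
            {
                "t_s": np.arange(len(self.xy)) / fps,
                "x_um": self.xy[:, 0],
                "y_um": self.xy[:, 1],
            }
        )
        table.to_csv(path, index=False)
        return table


@dataclass(frozen=True)
class VelocitySeries:
    """Frame-to-frame velocities with processing flags.

    ``data`` columns: t_s, vx_um_s, vy_um_s, speed_um_s.  The flags record
    whether the outlier rule and the moving average have been applied.
    """

    data: pd.DataFrame
    smoothed: bool = False
    outlier_cleaned: bool = False

    def export(self, path) -> pd.DataFrame:
        self.data.to_csv(path, index=False)
        return self.data


class LinearFit(NamedTuple):
    """Zero-intercept line U = slope * f with its coefficient of determination."""

    slope: float
    r2: float


def detect_centroid(
    frame: np.ndarray,
    prior_bbox: tuple[float, float, float, float] | None = None,
    pixel_size: float = 1.0,
    dark: bool = True,
):
    """Locate the particle in one frame.

    Otsu-thresholds the frame (particle darker than background by default),
    keeps the connected component nearest the prior bounding-box center
    (largest component if no prior), and returns an intensity-weighted
    sub-pixel centroid in um together with the tight bounding box in px
    as (x0, y0, x1, y1).

    Raises :class:`DetectionError` if no component is found; warns if the
    chosen component touches the image border.
    """
    frame = np.asarray(frame, dtype=float)
    thr = threshold_otsu(frame)
    mask = frame < thr if dark else frame > thr
    # Otsu misbehaves when the particle covers a tiny image fraction and the
    # histogram is dominated by background noise; fall back to the midpoint
    # between the background median and the extreme intensity.
    if mask.mean() > 0.25:
        extreme = frame.min() if dark else frame.max()
        thr = 0.5 * (np.median(frame) + extreme)
        mask = frame < thr if dark else frame > thr
    if not mask.any():
        raise DetectionError("no particle-like component found (empty mask)")
    labels = sk_label(mask)
    regions = regionprops(labels)
    if not regions:
        raise DetectionError("no particle-like component found")
    if prior_bbox is not None:
        cx = 0.5 * (prior_bbox[0] + prior_bbox[2])
        cy = 0.5 * (prior_bbox[1] + prior_bbox[3])
        region = min(
            regions,
            key=lambda r: (r.centroid[1] - cx) ** 2 + (r.centroid[0] - cy) ** 2,
        )
    else:
        region = max(regions, key=lambda r: r.area)
    r0, c0, r1, c1 = region.bbox
    h, w = frame.shape
    if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
        warnings.warn("particle component touches the image border", stacklevel=2)
    # Sub-pixel centroid: weight by background-subtracted darkness over the
    # slightly dilated component so anti-aliased edge pixels contribute.
    region_mask = labels == region.label
    support = dilation(region_mask, disk(2))
    bg = np.median(frame[~support]) if (~support).any() else frame.max()
    weights = np.clip((bg - frame) if dark else (frame - bg), 0.0, None)
    weights = weights * support
    total = weights.sum()
    if total <= 0:
        raise DetectionError("degenerate component: zero total weight")
    rows, cols = np.nonzero(support)
    wv = weights[rows, cols]
    cy_px = float((rows * wv).sum() / total)
    cx_px = float((cols * wv).sum() / total)
    centroid_um = (cx_px * pixel_size, cy_px * pixel_size)
    bbox_px = (float(c0), float(r0), float(c1), float(r1))
    return centroid_um, bbox_px


def track_stack(stack: FrameStack, dark: bool = True) -> Track:
    """Track a single particle through a stack, chaining bounding boxes."""
    xy = []
    bboxes = []
    prior = None
    for frame in stack.frames:
        centroid, bbox = detect_centroid(
            frame, prior_bbox=prior, pixel_size=stack.pixel_size, dark=dark
        )
        xy.append(centroid)
        bboxes.append(bbox)
        prior = bbox
    return Track(xy=np.asarray(xy), bboxes=np.asarray(bboxes))


def instantaneous_velocity(track: Track, fps: float) -> VelocitySeries:
    """Finite-difference velocities v_i = (p_{i+1} - p_i) * fps (um/s)."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    xy = track.xy
    if xy.shape[0] < 2:
        raise ValueError("need at least two frames")
    d = np.diff(xy, axis=0) * fps
    speed = np.hypot(d[:, 0], d[:, 1])
    t = (np.arange(d.shape[0]) + 0.5) / fps
    data = pd.DataFrame(
        {"t_s": t, "vx_um_s": d[:, 0], "vy_um_s": d[:, 1], "speed_um_s": speed}
    )
    return VelocitySeries(data=data)


def clean_and_smooth(
    series: VelocitySeries, window: int = 60, outlier_factor: float = 3.0
) -> VelocitySeries:
    """Outlier replacement followed by a centered moving average.

    Step 1 replaces speeds greater than ``outlier_factor`` times the mean
    speed by that (pre-replacement) mean.  Step 2 applies a centered moving
    average of length ``window`` with truncated windows at the edges.  Both
    steps are recorded in the output flags, and a series already flagged as
    processed passes through unchanged (the operation is idempotent on its
    own output).
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if len(series.data) == 0:
        raise ValueError("series is empty")
    data = series.data.copy()
    cleaned = series.outlier_cleaned
    if not cleaned:
        speeds = data["speed_um_s"].to_numpy().copy()
        mean0 = speeds.mean()
        speeds[speeds > outlier_factor * mean0] = mean0
        data["speed_um_s"] = speeds
        cleaned = True
    smoothed = series.smoothed
    if not smoothed:
        if window >= len(data):
            data["speed_um_s"] = data["speed_um_s"].mean()
        else:
            data["speed_um_s"] = (
                data["speed_um_s"].rolling(window, center=True, min_periods=1).mean()
            )
        smoothed = True
    return VelocitySeries(data=data, smoothed=smoothed, outlier_cleaned=cleaned)


def fit_through_origin(profile) -> LinearFit:
    """Zero-intercept least squares U = slope * f on a velocity profile.

    ``profile`` is either a DataFrame with columns ``f_Hz`` and
    ``mean_um_s`` (as produced by :func:`aggregate_trials`) or a pair of
    arrays ``(f, U)``.  slope = sum(f*U) / sum(f^2); R^2 = 1 - SS_res/SS_tot
    with SS_res about the constrained line and SS_tot about the mean of U.
    """
    if isinstance(profile, pd.DataFrame):
        f = profile["f_Hz"].to_numpy(dtype=float)
        u = profile["mean_um_s"].to_numpy(dtype=float)
    else:
        f, u = (np.asarray(a, dtype=float) for a in profile)
    if f.size < 2:
        raise ValueError("need at least two frequencies")
    denom = float(np.sum(f * f))
    if denom == 0:
        raise ValueError("all frequencies are zero; slope undefined")
    slope = float(np.sum(f * u)) / denom
    ss_res = float(np.sum((u - slope * f) ** 2))
    ss_tot = float(np.sum((u - u.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-30 else -math.inf
    else:
        r2 = 1.0 - ss_res / ss_tot
    return LinearFit(slope=slope, r2=r2)


def aggregate_trials(
    trials: Mapping[float, Sequence[float]] | pd.DataFrame,
) -> pd.DataFrame:
    """Aggregate per-trial mean velocities into a velocity profile.

    Input is either a mapping ``frequency -> list of per-trial means`` or a
    long DataFrame with columns ``f_Hz`` and ``v_um_s``.  Output columns:
    f_Hz (strictly increasing), mean_um_s, se_um_s (sample sd / sqrt(n);
    0 for a single trial, flagged by n = 1), n.
    """
    if isinstance(trials, pd.DataFrame):
        grouped: dict[float, list[float]] = {}
        for f_val, sub in trials.groupby("f_Hz"):
            grouped[float(f_val)] = list(sub["v_um_s"].to_numpy(dtype=float))
        trials = grouped
    if not trials:
        raise ValueError("no trials supplied")
    rows = []
    for f_val in sorted(trials):
        vals = np.asarray(trials[f_val], dtype=float)
        if vals.size == 0:
            raise ValueError(f"no trials at frequency {f_val}")
        n = int(vals.size)
        se = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        rows.append((float(f_val), float(vals.mean()), se, n))
    return pd.DataFrame(rows, columns=["f_Hz", "mean_um_s", "se_um_s", "n"])
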