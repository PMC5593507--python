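"""Ratiometric image-stack processing and ROI measurements.

Paired image stacks excited at 340 and 380 nm are turned into a stack of
340/380 ratio images after background subtraction, masking out pixels whose
background-subtracted 380 nm (denominator) intensity falls below a
threshold — low-intensity pixels would otherwise produce division
artifacts.  Per-cell traces are the per-frame mean ratio over a manually
defined region of interest (ROI), and cell size is measured as Feret's
diameter (the maximum caliper distance) of the ROI.

Coordinates are pixel-centered, 0-based and row-major (y = row, x =
column).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .traces import CellTrace

__all__ = [
    "RatioStack",
    "RoiDefinition",
    "compute_ratio_stack",
    "extract_roi_trace",
    "feret_diameter",
    "load_roi_table",
]

ELLIPSE_BOUNDARY_POINTS = 720


@dataclass
class RatioStack:
    """Stack of 2-D ratio images; masked-out pixels are NaN."""

    frames: np.ndarray  # (T, H, W) float, NaN where masked
    frame_interval: float = 5.0

    @property
    def mask(self) -> np.ndarray:
        """Per-pixel validity (True where a ratio value exists)."""
        return np.isfinite(self.frames)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class RoiDefinition:
    """A single-cell ROI: an ellipse or an explicit pixel set.

    Ellipse parameters are in pixel units: center (x, y), semi-axes (a, b)
    and orientation of the a-axis in radians (counter-clockwise from +x).
    """

    roi_id: str
    center_x_px: float | None = None
    center_y_px: float | None = None
    semi_axis_a_px: float | None = None
    semi_axis_b_px: float | None = None
    orientation_rad: float = 0.0
    pixels: tuple[tuple[int, int], ...] | None = None  # (row, col) pairs
    recording_id: str = ""

    def __post_init__(self) -> None:
        if self.pixels is None:
            params = (
                self.center_x_px, self.center_y_px,
                self.semi_axis_a_px, self.semi_axis_b_px,
            )
            if any(p is None for p in params):
                raise ValueError("ellipse ROI needs center and both semi-axes")
            if self.semi_axis_a_px <= 0 or self.semi_axis_b_px <= 0:
                raise ValueError("semi-axes must be positive")
        elif len(self.pixels) == 0:
            raise ValueError("pixel-set ROI must be nonempty")

    @property
    def is_ellipse(self) -> bool:
        return self.pixels is None

    def pixel_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels whose centers lie inside the ROI."""
        mask = np.zeros(shape, dtype=bool)
        if self.is_ellipse:
            yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
            dx = xx - self.center_x_px
            dy = yy - self.center_y_px
            c, s = np.cos(self.orientation_rad), np.sin(self.orientation_rad)
            u = dx * c + dy * s
            v = -dx * s + dy * c
            mask = (u / self.semi_axis_a_px) ** 2 + (
                v / self.semi_axis_b_px
            ) ** 2 <= 1.0
        else:
            rows, cols = zip(*self.pixels)
            rows, cols = np.asarray(rows), np.asarray(cols)
            if (
                rows.min() < 0 or cols.min() < 0
                or rows.max() >= shape[0] or cols.max() >= shape[1]
            ):
                raise ValueError("ROI pixels outside image bounds")
            mask[rows, cols] = True
        if not mask.any():
            raise ValueError(f"ROI {self.roi_id} has no pixel support")
        return mask

    def boundary_points(self) -> np.ndarray:
        """(x, y) boundary point set used for caliper measurements."""
        if self.is_ellipse:
            theta = np.linspace(
                0.0, 2.0 * np.pi, ELLIPSE_BOUNDARY_POINTS, endpoint=False
            )
            c, s = np.cos(self.orientation_rad), np.sin(self.orientation_rad)
            u = self.semi_axis_a_px * np.cos(theta)
            v = self.semi_axis_b_px * np.sin(theta)
            x = self.center_x_px + u * c - v * s
            y = self.center_y_px + u * s + v * c
            return np.column_stack([x, y])
        rows, cols = zip(*self.pixels)
        return np.column_stack([np.asarray(cols, float), np.asarray(rows, float)])


def _background(
    stack: np.ndarray, method: object, channel: int
) -> np.ndarray:
    """Per-frame background level for one channel.

    ``method`` may be: a scalar (constant level for both channels), a pair
    of scalars (340, 380), an :class:`RoiDefinition` marking a background
    region (per-frame mean inside it), or the string ``"percentile"``
    (1st percentile of each frame).
    """
    n = len(stack)
    if isinstance(method, RoiDefinition):
        mask = method.pixel_mask(stack.shape[1:])
        return stack[:, mask].mean(axis=1).astype(float)
    if isinstance(method, str):
        if method != "percentile":
            raise ValueError(f"unknown background method {method!r}")
        return np.percentile(
            stack.reshape(n, -1).astype(float), 1.0, axis=1
        )
    if isinstance(method, (tuple, list)):
        return np.full(n, float(method[channel]))
    return np.full(n, float(method))


def compute_ratio_stack(
    stack340: np.ndarray,
    stack380: np.ndarray,
    background_method: object = "percentile",
    intensity_threshold: float = 0.0,
    frame_interval: float = 5.0,
) -> RatioStack:
    """340/380 ratio images after background subtraction and thresholding.

    ``ratio = (F340 - bg340) / (F380 - bg380)`` on pixels whose
    background-subtracted 380 nm intensity exceeds ``intensity_threshold``;
    all other pixels are masked (NaN).  A frame in which every pixel is
    masked is retained with a warning.
    """
    stack340 = np.asarray(stack340)
    stack380 = np.asarray(stack380)
    if stack340.shape != stack380.shape:
        raise ValueError("340 and 380 stacks must have identical shapes")
    if stack340.ndim != 3:
        raise ValueError("stacks must be (T, H, W)")
    if intensity_threshold < 0:
        raise ValueError("intensity threshold must be >= 0")

    bg340 = _background(stack340, background_method, 0)
    bg380 = _background(stack380, background_method, 1)
    net340 = stack340.astype(float) - bg340[:, None, None]
    net380 = stack380.astype(float) - bg380[:, None, None]
    valid = net380 > intensity_threshold
    with np.errstate(invalid="ignore", divide="ignore"):
        frames = np.where(valid, net340 / np.where(valid, net380, 1.0), np.nan)
    empty = ~valid.reshape(len(frames), -1).any(axis=1)
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} frame(s) have every pixel masked",
            stacklevel=2,
        )
    return RatioStack(frames=frames, frame_interval=frame_interval)


def extract_roi_trace(ratio_stack: RatioStack, roi: RoiDefinition) -> CellTrace:
    """Per-frame mean of unmasked ratio pixels inside the ROI.

    Frames in which the ROI is fully masked yield NaN.
    """
    mask = roi.pixel_mask(ratio_stack.frames.shape[1:])
    values = ratio_stack.frames[:, mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frames
        trace = np.nanmean(values, axis=1)
    time = np.arange(len(ratio_stack)) * ratio_stack.frame_interval
    return CellTrace(
        cell_id=roi.roi_id, time=time, ratio=trace,
        recording_id=roi.recording_id,
    )


def feret_diameter(roi: RoiDefinition, um_per_px: float = 1.0) -> float:
    """Feret's (maximum caliper) diameter of the ROI, in micrometers.

    The maximum pairwise distance over the ROI boundary; for an ellipse
    this equals the major-axis length.  Computed on the convex hull of the
    boundary point set.
    """
    if um_per_px <= 0:
        raise ValueError("um_per_px must be positive")
    pts = roi.boundary_points()
    unique = np.unique(pts, axis=0)
    if len(unique) < 2 or (
        not roi.is_ellipse and np.ptp(unique, axis=0).max() == 0
    ):
        raise ValueError(f"degenerate ROI {roi.roi_id}: no extent")
    if len(unique) >= 3:
        try:
            hull = ConvexHull(unique)
            unique = unique[hull.vertices]
        except Exception:  # collinear point sets
            pass
    return float(pdist(unique).max()) * um_per_px


def load_roi_table(path) -> list[RoiDefinition]:
    """Read an ROI table CSV (roi_id, center/semi-axis/orientation columns)."""
    df = pd.read_csv(path)
    rois = []
    for _, row in df.iterrows():
        rois.append(
            RoiDefinition(
                roi_id=str(row["roi_id"]),
                center_x_px=float(row["center_x_px"]),
                center_y_px=float(row["center_y_px"]),
                semi_axis_a_px=float(row["semi_axis_a_px"]),
                semi_axis_b_px=float(row["semi_axis_b_px"]),
                orientation_rad=float(row.get("orientation_rad", 0.0)),
            )
        )
    return rois
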