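"""Server-side rasterization: reduce large point/segment collections to
fixed-resolution count grids for a genome × time viewport.

Bins follow the half-open convention [e_i, e_{i+1}) with the top bin closed,
so items sitting exactly on the viewport's maximum edge are kept rather
than silently dropped.  Row 0 of a grid is the lowest-y (most recent time)
row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

YScale = Literal["linear", "log"]


@dataclass(frozen=True)
class Viewport:
    """A rectangular genome (x) × time (y) window, with the y-axis scale."""

    x0: float
    x1: float
    y0: float
    y1: float
    y_scale: YScale = "linear"

    def __post_init__(self):
        if not all(np.isfinite([self.x0, self.x1, self.y0, self.y1])):
            raise ValueError("viewport bounds must be finite")
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError("viewport must satisfy x0 < x1 and y0 < y1")
        if self.x0 < 0:
            raise ValueError("x0 must be >= 0")


@dataclass
class CountGrid:
    """H×W per-pixel aggregate counts plus the bin edges that define it.

    y_bin_edges are in transformed (axis) coordinates; invert with the
    recorded scale/delta.
    """

    counts: np.ndarray  # (H, W) int64
    x_bin_edges: np.ndarray  # (W + 1,)
    y_bin_edges: np.ndarray  # (H + 1,)

    @property
    def shape(self):
        return self.counts.shape

    def total(self) -> int:
        return int(self.counts.sum())


def time_transform(t, scale: YScale = "linear", delta: float = 1.0):
    """Map node/mutation times onto the plotting axis.

    linear → identity; log → log10(t + delta), with delta > 0 keeping
    time-0 samples finite.  Strictly increasing in t either way.
    """
    t = np.asarray(t, np.float64)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if scale == "linear":
        return t if t.ndim else float(t)
    if scale == "log":
        if not delta > 0:
            raise ValueError("delta must be positive for log scale")
        out = np.log10(t + delta)
        return out if out.ndim else float(out)
    raise ValueError(f"unknown scale {scale!r}")


def default_log_delta(times) -> float:
    """Smallest positive time, or 1.0 if there is none."""
    times = np.asarray(times, np.float64)
    pos = times[times > 0]
    return float(pos.min()) if len(pos) else 1.0


def histogram1d(values, n_bins: int, lo: float, hi: float):
    """Counts over n_bins half-open bins [lo, hi]; top bin closed.

    Values outside [lo, hi] are excluded; the total therefore equals the
    number of in-range values.  Returns (counts, bin_edges).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not lo < hi:
        raise ValueError("lo must be < hi")
    values = np.asarray(values, np.float64)
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    return counts.astype(np.int64), edges


def rasterize_points(
    points, viewport: Viewport, width: int, height: int,
    delta: float | None = None,
) -> CountGrid:
    """Bin (x, y) points into a width×height grid over the viewport.

    Each in-viewport point lands in exactly one pixel; y values are passed
    through :func:`time_transform` first (delta only matters on a log
    axis).  The grid total equals the number of points inside the viewport.
    """
    if width < 1 or height < 1:
        raise ValueError("grid dimensions must be >= 1")
    pts = np.asarray(points, np.float64).reshape(-1, 2)
    if delta is None:
        delta = 1.0
    ty = time_transform(pts[:, 1], viewport.y_scale, delta) if len(pts) \
        else np.empty(0)
    ty0 = float(time_transform(viewport.y0, viewport.y_scale, delta))
    ty1 = float(time_transform(viewport.y1, viewport.y_scale, delta))
    counts, x_edges, y_edges = np.histogram2d(
        pts[:, 0] if len(pts) else np.empty(0), np.asarray(ty),
        bins=(width, height),
        range=((viewport.x0, viewport.x1), (ty0, ty1)),
    )
    return CountGrid(counts.T.astype(np.int64), x_edges, y_edges)


def rasterize_segments(
    segments, viewport: Viewport, width: int, height: int,
    delta: float | None = None,
) -> CountGrid:
    """Count, per pixel, the horizontal segments (x_left, x_right, y)
    covering it.

    A segment occupies the single y-row its (transformed) time falls in and
    every column its half-open genome interval overlaps after clipping to
    the viewport.  Diagonal connectors are not rasterized here.
    """
    if width < 1 or height < 1:
        raise ValueError("grid dimensions must be >= 1")
    segs = np.asarray(segments, np.float64).reshape(-1, 3)
    if delta is None:
        delta = 1.0
    x_edges = np.linspace(viewport.x0, viewport.x1, width + 1)
    ty0 = float(time_transform(viewport.y0, viewport.y_scale, delta))
    ty1 = float(time_transform(viewport.y1, viewport.y_scale, delta))
    y_edges = np.linspace(ty0, ty1, height + 1)
    counts = np.zeros((height, width), np.int64)
    if len(segs) == 0:
        return CountGrid(counts, x_edges, y_edges)

    left = np.maximum(segs[:, 0], viewport.x0)
    right = np.minimum(segs[:, 1], viewport.x1)
    ty = time_transform(segs[:, 2], viewport.y_scale, delta)
    # y binning follows histogram1d: half-open bins, top bin closed
    row = np.searchsorted(y_edges, ty, side="right") - 1
    row[ty == y_edges[-1]] = height - 1
    keep = (left < right) & (row >= 0) & (row < height)
    if not np.any(keep):
        return CountGrid(counts, x_edges, y_edges)
    left, right, row = left[keep], right[keep], row[keep]
    # column j overlaps [l, r) iff l < e_{j+1} and r > e_j
    j0 = np.searchsorted(x_edges, left, side="right") - 1
    j0 = np.clip(j0, 0, width - 1)
    j1 = np.searchsorted(x_edges, right, side="left") - 1
    j1 = np.clip(j1, 0, width - 1)
    # difference-array accumulation per row
    diff = np.zeros((height, width + 1), np.int64)
    np.add.at(diff, (row, j0), 1)
    np.add.at(diff, (row, j1 + 1), -1)
    counts = np.cumsum(diff[:, :-1], axis=1)
    return CountGrid(counts, x_edges, y_edges)
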