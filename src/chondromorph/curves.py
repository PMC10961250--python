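"""Lengths of open and closed spline curves through ordered 3D control points.

Used for the total length of Meckel's cartilage measured along its superior
surface (open curve) and for foramen magnum circumference (closed curve).
Control points are interpolated with a through-point cubic spline
parameterized by cumulative chord length (natural ends for open curves,
periodic closure for closed ones), and arc length is obtained by dense
chord sampling of the spline.  A polyline mode measures the control polygon
directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

from .landmarks import read_fcsv

__all__ = ["CurveSpec", "curve_length", "read_fcsv_curve"]


@dataclass
class CurveSpec:
    """Ordered control points (mm) of one measured curve."""

    points: np.ndarray  # (m, 3)
    closed: bool = False
    samples_per_segment: int = 128

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (m, 3) array")
        minimum = 3 if self.closed else 2
        if pts.shape[0] < minimum:
            raise ValueError(
                f"{'closed' if self.closed else 'open'} curve needs at least "
                f"{minimum} points, got {pts.shape[0]}")
        seams = np.vstack([pts, pts[:1]]) if self.closed else pts
        seglen = np.linalg.norm(np.diff(seams, axis=0), axis=1)
        if np.any(seglen == 0):
            raise ValueError("repeated consecutive control points")
        if self.samples_per_segment < 1:
            raise ValueError("samples_per_segment must be >= 1")
        self.points = pts


def _polyline_length(pts: np.ndarray, closed: bool) -> float:
    if closed:
        pts = np.vstack([pts, pts[:1]])
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def curve_length(spec: CurveSpec, mode: str = "spline") -> float:
    """Arc length (mm) of the curve through the control points.

    ``mode="spline"`` integrates the interpolating cubic by dense chord
    sampling (``samples_per_segment`` subdivisions per control-point
    segment); ``mode="polyline"`` returns the control-polygon length, which
    lower-bounds the spline length for points on a convex curve.
    """
    pts = spec.points
    if mode == "polyline":
        return _polyline_length(pts, spec.closed)
    if mode != "spline":
        raise ValueError(f"unknown mode {mode!r}")

    if spec.closed:
        pts = np.vstack([pts, pts[:1]])
    chords = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(chords)])
    bc = "periodic" if spec.closed else "natural"
    spline = CubicSpline(t, pts, bc_type=bc)
    dense = []
    for i in range(len(t) - 1):
        dense.append(np.linspace(t[i], t[i + 1], spec.samples_per_segment,
                                 endpoint=False))
    dense = np.concatenate(dense + [[t[-1]]])
    samples = spline(dense)
    return float(np.linalg.norm(np.diff(samples, axis=0), axis=1).sum())


def read_fcsv_curve(path: str | Path, closed: bool = False,
                    samples_per_segment: int = 128) -> CurveSpec:
    """Build a curve from a 3D Slicer markups fiducial file (point order kept)."""
    points = np.stack([xyz for _, xyz in read_fcsv(path)])
    return CurveSpec(points=points, closed=closed,
                     samples_per_segment=samples_per_segment)
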