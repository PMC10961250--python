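"""Thickness analysis of binary 3D cartilage volumes.

Two complementary measures are provided:

- **Average object thickness** under the parallel-plate model:
  2 x volume / surface area, where 2V/S equals the true thickness of an
  ideal plate (and 2r/3 for a solid sphere).  Surface area comes from a
  triangulated 0.5-level isosurface by default, or from exposed voxel-face
  counting (which overestimates area by up to ~1.5x and is offered only as
  a documented option).

- **Local thickness maps**: each foreground voxel is assigned the diameter
  of the largest ball that contains it and fits entirely inside the object.
  The map is built by taking a Euclidean distance map inside the object,
  then browsing, for each voxel v with distance value d(v), the ball of
  radius R = d(v) centered on v and raising the thickness of every covered
  voxel to at least R; the map is finally doubled to express diameters.
  Three boundary conventions are supported for the distance-map origin set:
  ``included`` (distances measured from background voxel centers just
  outside the object, slightly inflating boundary thickness), ``excluded``
  (from boundary voxels belonging to the object, slightly deflating it),
  and ``averaged`` (the mean of the two maps before propagation; the
  default, giving the smoothest boundary behaviour).

Group comparisons of per-specimen scalars use an exact-enumeration
two-sided Mann-Whitney U test, appropriate for the small group sizes
typical of embryo studies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata
from skimage.measure import marching_cubes, mesh_surface_area

__all__ = [
    "BinaryVolume",
    "ThicknessSummary",
    "ThicknessMap",
    "MannWhitneyResult",
    "average_object_thickness",
    "local_thickness_map",
    "compare_groups",
]

BOUNDARY_MODES = ("included", "excluded", "averaged")


@dataclass
class BinaryVolume:
    """3D boolean voxel grid with isotropic physical spacing in micrometres.

    ``occupancy`` is indexed (z, y, x), 0-based.
    """

    occupancy: np.ndarray
    spacing: float  # um per voxel edge
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy).astype(bool)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3D array")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    def volume_um3(self) -> float:
        return self.voxel_count * self.spacing ** 3


@dataclass(frozen=True)
class ThicknessSummary:
    """Parallel-plate summary: thickness = 2V/S by construction."""

    average_thickness: float      # um
    surface_area: float           # um^2
    volume: float                 # um^3
    surface_to_volume: float      # 1/um (the sr.th ratio)
    surface_method: str


@dataclass
class ThicknessMap:
    """Per-voxel local thickness in um on foreground voxels, 0 elsewhere."""

    values: np.ndarray
    spacing: float
    boundary: str

    def foreground_values(self) -> np.ndarray:
        return self.values[self.values > 0]


def _require_foreground(vol: BinaryVolume) -> None:
    if not vol.occupancy.any():
        raise ValueError("volume has no foreground voxels")


def _mesh_surface_area(occupancy: np.ndarray, spacing: float,
                       smooth_sigma: float = 1.0) -> float:
    """Area of the 0.5-level isosurface of the (lightly smoothed) mask.

    A raw binary mask meshes into a stair-stepped surface whose area
    overestimates the true boundary by ~8-10%; a 1-voxel Gaussian
    pre-smoothing recovers the smooth-surface area to well under 1% on
    spheres and slabs without moving the 0.5-level boundary.
    """
    pad = 1 + int(math.ceil(3 * smooth_sigma))
    field_ = np.pad(occupancy, pad).astype(np.float32)
    if smooth_sigma > 0:
        field_ = ndimage.gaussian_filter(field_, smooth_sigma)
    verts, faces, _, _ = marching_cubes(field_, level=0.5,
                                        spacing=(spacing,) * 3)
    return float(mesh_surface_area(verts, faces))


def _voxel_face_area(occupancy: np.ndarray, spacing: float) -> float:
    padded = np.pad(occupancy, 1)
    exposed = 0
    for axis in range(3):
        for shift in (1, -1):
            neighbor = np.roll(padded, shift, axis=axis)
            exposed += int((padded & ~neighbor).sum())
    return exposed * spacing ** 2


def average_object_thickness(vol: BinaryVolume,
                             surface_method: str = "mesh",
                             smooth_sigma: float = 1.0) -> ThicknessSummary:
    """Average object thickness 2V/S of a binary volume (parallel-plate model).

    ``surface_method="mesh"`` (default) measures S on a closed triangulated
    0.5-level isosurface of the mask after a ``smooth_sigma``-voxel Gaussian
    pre-smoothing; ``"voxel_faces"`` counts exposed voxel faces (which
    overestimates S by up to 1.5x and correspondingly deflates 2V/S).
    """
    _require_foreground(vol)
    volume = vol.volume_um3()
    if surface_method == "mesh":
        surface = _mesh_surface_area(vol.occupancy, vol.spacing, smooth_sigma)
    elif surface_method == "voxel_faces":
        surface = _voxel_face_area(vol.occupancy, vol.spacing)
    else:
        raise ValueError(f"unknown surface method {surface_method!r}")
    sr = surface / volume
    return ThicknessSummary(average_thickness=2.0 / sr, surface_area=surface,
                            volume=volume, surface_to_volume=sr,
                            surface_method=surface_method)


# ---------------------------------------------------------------------------
# Local thickness map

def _squared_distance_maps(fg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer squared EDTs on foreground voxels, in voxel units.

    Returns (a2, b2): squared distance to the nearest background voxel
    center ("included" origin set) and to the nearest boundary foreground
    voxel ("excluded" origin set).  The array border counts as background.
    """
    padded = np.pad(fg, 1)
    d_incl = ndimage.distance_transform_edt(padded)
    a2 = np.rint(d_incl ** 2).astype(np.int64)[1:-1, 1:-1, 1:-1]

    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(padded, structure=structure)
    boundary_fg = padded & ~interior
    d_excl = ndimage.distance_transform_edt(~boundary_fg)
    b2 = np.rint(d_excl ** 2).astype(np.int64)[1:-1, 1:-1, 1:-1]
    return a2, b2


def _in_ball(m2: np.ndarray, a: int, b: int) -> np.ndarray:
    """Exact-integer membership test |w - v|^2 = m2 <= R^2 for R=(sqrt a + sqrt b)/2.

    4 m2 <= a + b + 2 sqrt(ab)  <=>  L := 4 m2 - a - b <= 0, or L^2 <= 4 a b.
    All quantities are integers, so ties are decided exactly.
    """
    L = 4 * m2 - a - b
    return (L <= 0) | ((L * L) <= 4 * a * b)


def _ball_offsets(a: int, b: int) -> np.ndarray:
    """Integer voxel offsets inside the ball of radius (sqrt a + sqrt b)/2."""
    r = int(math.floor((math.sqrt(a) + math.sqrt(b)) / 2.0))
    rng = np.arange(-r, r + 1)
    dz, dy, dx = np.meshgrid(rng, rng, rng, indexing="ij")
    m2 = (dz ** 2 + dy ** 2 + dx ** 2).astype(np.int64)
    inside = _in_ball(m2, a, b)
    return np.stack([dz[inside], dy[inside], dx[inside]], axis=1)


def _radius_from_pair(a: int, b: int) -> float:
    return (math.sqrt(a) + math.sqrt(b)) / 2.0


def local_thickness_map(vol: BinaryVolume,
                        boundary: str = "averaged") -> ThicknessMap:
    """Voxel-wise local thickness: diameter of the largest inscribed ball
    containing each foreground voxel.

    Starts from the Euclidean distance map inside the object (origin set
    chosen by ``boundary``), then propagates each voxel's ball radius to all
    voxels the ball covers, keeping the maximum, and doubles the result into
    a diameter map in physical units (um).
    """
    _require_foreground(vol)
    if boundary not in BOUNDARY_MODES:
        raise ValueError(
            f"boundary must be one of {BOUNDARY_MODES}, got {boundary!r}")
    fg = vol.occupancy
    a2, b2 = _squared_distance_maps(fg)
    if boundary == "included":
        b2 = a2
    elif boundary == "excluded":
        a2 = b2

    zz, yy, xx = np.nonzero(fg)
    pa, pb = a2[zz, yy, xx], b2[zz, yy, xx]
    radii = (np.sqrt(pa) + np.sqrt(pb)) / 2.0
    margin = int(math.ceil(radii.max())) + 1

    shape = tuple(s + 2 * margin for s in fg.shape)
    thick = np.zeros(shape)  # radius units until the final doubling
    coords = np.stack([zz, yy, xx], axis=1) + margin

    # group voxels by (a2, b2) so each ball footprint is built once; process
    # larger balls first so a voxel keeps the largest covering radius
    order = {}
    for i, (a, b) in enumerate(zip(pa.tolist(), pb.tolist())):
        order.setdefault((a, b), []).append(i)
    groups = sorted(order.items(),
                    key=lambda kv: _radius_from_pair(*kv[0]), reverse=True)

    flat = thick.reshape(-1)
    strides = np.array([shape[1] * shape[2], shape[2], 1], dtype=np.int64)
    for (a, b), members in groups:
        radius = _radius_from_pair(a, b)
        if radius == 0.0:
            continue
        offsets = _ball_offsets(a, b) @ strides
        centers = coords[members] @ strides
        chunk = max(1, 4_000_000 // max(len(offsets), 1))
        for start in range(0, len(centers), chunk):
            idx = (centers[start:start + chunk, None] + offsets[None, :]).ravel()
            smaller = flat[idx] < radius
            flat[idx[smaller]] = radius
    core = thick[margin:-margin, margin:-margin, margin:-margin]
    values = np.where(fg, core * 2.0 * vol.spacing, 0.0)
    # zero-radius voxels (excluded-mode boundary) stay 0 but are foreground;
    # that is the documented deflation of the excluded convention
    return ThicknessMap(values=values, spacing=vol.spacing, boundary=boundary)


# ---------------------------------------------------------------------------
# Group comparison

@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str  # "exact" or "normal"


def compare_groups(values_a: Sequence[float], values_b: Sequence[float],
                   max_exact: int = 400_000) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of two groups of per-specimen scalars.

    For small samples (all group splits enumerable within ``max_exact``)
    the exact permutation p-value is computed over every C(n1+n2, n1)
    relabeling, with midranks for ties and
    p = min(1, 2 * min(P(U <= u), P(U >= u))).  Larger samples fall back to
    the normal approximation with tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both groups; p = 1",
                      stacklevel=2)
        return MannWhitneyResult(u=n1 * n2 / 2.0, p_value=1.0, method="exact")
    ranks = rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if math.comb(n1 + n2, n1) <= max_exact:
        eps = 1e-9
        le = ge = total = 0
        base = n1 * (n1 + 1) / 2.0
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - base
            total += 1
            if u <= u_obs + eps:
                le += 1
            if u >= u_obs - eps:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return MannWhitneyResult(u=u_obs, p_value=p, method="exact")

    # normal approximation with tie correction
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (n * (n - 1))
    sigma = math.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    z = (u_obs - mu - 0.5 * np.sign(u_obs - mu)) / sigma if sigma > 0 else 0.0
    from scipy.stats import norm
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return MannWhitneyResult(u=u_obs, p_value=p, method="normal")
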