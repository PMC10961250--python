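"""Synthetic landmark populations and voxel phantoms with known ground truth.

The landmark generator draws specimens from an isotropic Gaussian
perturbation model around a group mean configuration, with planted effects
expressed as exact scalings of landmark subsets (about the subset centroid,
so every within-subset interlandmark distance scales by exactly the stated
factor) or of the whole configuration.  Two-age designs apply
genotype-specific growth scalings to the base mean, producing the four
groups a growth-difference analysis consumes, with every planted form and
growth ratio known exactly at sigma = 0.

Voxel phantoms (slabs, solid spheres, hollow shells, curved tubular rods,
and a hemispherical vault shell with a linear thickness gradient) are
voxelized by center inclusion and carry analytically known thicknesses for
validating the thickness pipeline.

All randomness flows from one integer seed through numpy SeedSequence
spawning, so identical specs give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .edma import GroupSample
from .landmarks import LandmarkConfiguration, pair_labels
from .thickness import BinaryVolume

__all__ = [
    "MC_MEAN",
    "CHONDRO_MEAN",
    "Effect",
    "PopulationSpec",
    "PhantomSpec",
    "default_sigma",
    "apply_effects",
    "planted_distance_ratios",
    "generate_landmark_population",
    "generate_two_age_design",
    "generate_phantom",
]

# 6-landmark Meckel's-cartilage-like horseshoe (mm): anterior tip and
# symphysis on the midline, posterior arm endpoints bilaterally.
MC_MEAN: dict[str, tuple[float, float, float]] = {
    "mca": (0.0, 0.0, 0.0),
    "mcsym": (0.0, 0.35, 0.15),
    "mcpl": (-1.6, 2.6, 0.6),
    "mcppl": (-1.75, 2.85, 0.2),
    "mcpr": (1.6, 2.6, 0.6),
    "mcppr": (1.75, 2.85, 0.2),
}

# 25-landmark chondrocranium-like bilateral cage (mm): three midline points
# (nasal septum and trabecular junction) plus eleven left/right pairs along
# the nasal capsule, lateral walls, cranial base and occipital region.
CHONDRO_MEAN: dict[str, tuple[float, float, float]] = {
    "asep": (0.0, 0.0, 0.4),
    "psep": (0.0, 1.2, 1.0),
    "lppi": (-1.0, 0.8, 0.5),
    "rppi": (1.0, 0.8, 0.5),
    "nct": (0.0, 1.6, 0.6),
    "lncse": (-0.7, 1.8, 1.1),
    "rncse": (0.7, 1.8, 1.1),
    "lao": (-1.1, 2.5, 1.3),
    "rao": (1.1, 2.5, 1.3),
    "laottr": (-1.3, 3.0, 1.5),
    "raottr": (1.3, 3.0, 1.5),
    "lttr": (-1.4, 3.4, 1.6),
    "rttr": (1.4, 3.4, 1.6),
    "lttrpp": (-1.5, 3.9, 1.5),
    "rttrpp": (1.5, 3.9, 1.5),
    "llpca": (-1.7, 4.6, 0.9),
    "rlpca": (1.7, 4.6, 0.9),
    "ltpoa": (-0.8, 5.3, 0.7),
    "rtpoa": (0.8, 5.3, 0.7),
    "llat": (-1.2, 2.9, 0.3),
    "rlat": (1.2, 2.9, 0.3),
    "lcsp": (-0.6, 3.6, 0.2),
    "rcsp": (0.6, 3.6, 0.2),
    "laioc": (-0.5, 5.5, 0.2),
    "raioc": (0.5, 5.5, 0.2),
}


def _coords_array(mean: dict) -> tuple[tuple[str, ...], np.ndarray]:
    names = tuple(mean)
    return names, np.array([mean[a] for a in names], dtype=float)


def default_sigma(mean: dict, fraction: float = 0.02) -> float:
    """Landmark noise sigma (mm) as a fraction of the mean pairwise distance.

    The default 2% matches the digitization-scale noise the study conditions
    assume for landmark placement on embryonic cartilage.
    """
    _, coords = _coords_array(mean)
    return fraction * float(pdist(coords).mean())


@dataclass(frozen=True)
class Effect:
    """Scale the listed landmarks by ``factor`` about their own centroid.

    Every interlandmark distance between two listed landmarks scales by
    exactly ``factor``; distances to unlisted landmarks change by a known
    (computable) amount.  Listing all landmarks gives a uniform scaling of
    the whole configuration.
    """

    landmarks: tuple[str, ...]
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("effect scale factor must be positive")
        if len(set(self.landmarks)) != len(self.landmarks):
            raise ValueError("duplicate landmarks in effect")


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for one synthetic group of specimens."""

    mean: dict[str, tuple[float, float, float]]
    sigma: float  # mm, isotropic per landmark coordinate
    n: int
    genotype: str = "wildtype"
    age: str = "E14.5"
    effects: tuple[Effect, ...] = ()
    seed: int | np.random.SeedSequence | None = 0
    trials: int = 1
    trial_sigma: float = 0.005  # mm, extra digitization noise when trials=2

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.trial_sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.trials not in (1, 2):
            raise ValueError("trials must be 1 or 2")


def _check_effects(effects: Sequence[Effect], names: Sequence[str]) -> None:
    seen: dict[str, float] = {}
    conflicts = []
    for eff in effects:
        unknown = [a for a in eff.landmarks if a not in names]
        if unknown:
            raise ValueError(f"effect references unknown landmarks {unknown}")
        for a in eff.landmarks:
            if a in seen:
                conflicts.append((a, seen[a], eff.factor))
            seen[a] = eff.factor
    if conflicts:
        raise ValueError(
            "contradictory effects; landmarks appear in multiple effects: "
            + ", ".join(f"{a} (x{f1} vs x{f2})" for a, f1, f2 in conflicts))


def apply_effects(mean: dict, effects: Sequence[Effect]) -> dict:
    """Deterministically apply planted effects to a mean configuration."""
    names, coords = _coords_array(mean)
    _check_effects(effects, names)
    out = coords.copy()
    for eff in effects:
        idx = [names.index(a) for a in eff.landmarks]
        center = coords[idx].mean(axis=0)
        out[idx] = center + eff.factor * (coords[idx] - center)
    return {a: tuple(out[i]) for i, a in enumerate(names)}


def planted_distance_ratios(mean: dict, effects: Sequence[Effect]
                            ) -> tuple[tuple[tuple[str, str], ...], np.ndarray]:
    """Exact per-pair distance ratios (effected mean / base mean).

    This is the generator-side oracle for recovery tests: within-effect
    pairs equal the planted factor exactly; all other ratios are whatever
    the deterministic construction implies.
    """
    names, base = _coords_array(mean)
    _, moved = _coords_array(apply_effects(mean, effects))
    labels = pair_labels(names)
    index = {a: i for i, a in enumerate(names)}
    base_d = pdist(base)
    moved_d = pdist(moved)
    # pdist order follows row order of the input; re-order to canonical labels
    order = {}
    k = 0
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            order[frozenset((names[i], names[j]))] = k
            k += 1
    ratio = np.array([moved_d[order[frozenset(p)]] / base_d[order[frozenset(p)]]
                      for p in labels])
    return labels, ratio


def generate_landmark_population(spec: PopulationSpec) -> GroupSample:
    """Draw a synthetic group: effected mean + iid Gaussian landmark noise.

    With ``trials=2`` each specimen yields two digitization trials (the
    specimen's true coordinates plus independent trial noise); downstream
    analyses should average them as in the two-trial error protocol.
    """
    names, _ = _coords_array(spec.mean)
    effected = apply_effects(spec.mean, spec.effects)
    _, coords = _coords_array(effected)
    rng = np.random.default_rng(spec.seed)
    configs: list[LandmarkConfiguration] = []
    for i in range(spec.n):
        true = coords + rng.normal(0.0, spec.sigma, size=coords.shape)
        specimen = f"{spec.genotype}-{spec.age}-{i + 1:02d}"
        if spec.trials == 1:
            configs.append(_make_config(specimen, spec, names, true, trial=1))
        else:
            for t in (1, 2):
                jitter = rng.normal(0.0, spec.trial_sigma, size=coords.shape)
                configs.append(_make_config(specimen, spec, names,
                                            true + jitter, trial=t))
    return GroupSample(label=f"{spec.genotype}:{spec.age}", configurations=configs)


def _make_config(specimen: str, spec: PopulationSpec, names, coords, trial
                 ) -> LandmarkConfiguration:
    return LandmarkConfiguration(
        specimen_id=specimen, genotype=spec.genotype, age=spec.age,
        trial=trial,
        coordinates={a: coords[i] for i, a in enumerate(names)})


def generate_two_age_design(mean: dict, sigma: float,
                            n: dict[tuple[str, str], int],
                            growth_mutant: Sequence[Effect],
                            growth_wildtype: Sequence[Effect],
                            ages: tuple[str, str] = ("E14.5", "E16.5"),
                            seed: int | np.random.SeedSequence = 0,
                            trials: int = 1,
                            ) -> dict[tuple[str, str], GroupSample]:
    """Four groups (2 genotypes x 2 ages) with planted growth.

    Younger groups are drawn around the shared base mean; older means are
    the base with the genotype's growth effects applied, so the growth
    matrix of each genotype — and hence the growth difference matrix — is
    known exactly at sigma = 0.  ``n`` maps (genotype, age) to the group
    size; the study-scale design is {("mutant", young): 5, ("wildtype",
    young): 4, ("mutant", old): 5, ("wildtype", old): 6}.
    """
    younger, older = ages
    root = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    seeds = root.spawn(4)
    out: dict[tuple[str, str], GroupSample] = {}
    growth = {"mutant": tuple(growth_mutant), "wildtype": tuple(growth_wildtype)}
    for i, (genotype, age) in enumerate(
            [("mutant", younger), ("wildtype", younger),
             ("mutant", older), ("wildtype", older)]):
        effects = growth[genotype] if age == older else ()
        spec = PopulationSpec(mean=mean, sigma=sigma, n=n[(genotype, age)],
                              genotype=genotype, age=age, effects=effects,
                              seed=seeds[i], trials=trials)
        out[(genotype, age)] = generate_landmark_population(spec)
    return out


# ---------------------------------------------------------------------------
# Voxel phantoms

PHANTOM_SHAPES = ("slab", "solid_sphere", "hollow_shell", "curved_rod",
                  "vault_shell_with_gradient")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a binary voxel phantom.

    ``grid`` is (nz, ny, nx); geometric parameters are in voxels and the
    phantom (except a slab's in-plane extent, which spans the domain) must
    fit with a 2-voxel margin.  Parameters by shape:

    - slab: thickness
    - solid_sphere: radius
    - hollow_shell: radius (outer), thickness
    - curved_rod: arc_radius (centerline), tube_radius, arc_degrees
    - vault_shell_with_gradient: radius (outer), thickness_pole,
      thickness_equator (linear in polar angle between the two)
    """

    shape: str
    grid: tuple[int, int, int]
    spacing: float = 1.0  # um
    thickness: float | None = None
    radius: float | None = None
    tube_radius: float | None = None
    arc_radius: float | None = None
    arc_degrees: float = 270.0
    thickness_pole: float | None = None
    thickness_equator: float | None = None
    noise_sigma: float = 0.0  # optional surface jitter, voxels
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.shape not in PHANTOM_SHAPES:
            raise ValueError(f"unknown phantom shape {self.shape!r}")
        if len(self.grid) != 3 or any(s < 3 for s in self.grid):
            raise ValueError("grid must be three dimensions of size >= 3")


def _center_grid(grid: tuple[int, int, int]
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nz, ny, nx = grid
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    z, y, x = np.meshgrid(np.arange(nz) - cz, np.arange(ny) - cy,
                          np.arange(nx) - cx, indexing="ij")
    return z, y, x


def _check_margin(extent: float, grid: tuple[int, int, int],
                  axes: Iterable[int] = (0, 1, 2), margin: float = 2.0) -> None:
    for ax in axes:
        if 2 * extent + 2 * margin > grid[ax]:
            raise ValueError(
                f"phantom extent {extent} exceeds grid axis {ax} "
                f"({grid[ax]} voxels) with the required {margin}-voxel margin")


def generate_phantom(spec: PhantomSpec) -> BinaryVolume:
    """Voxelize a phantom by center inclusion.

    With ``noise_sigma > 0`` the implicit surface is jittered by adding
    Gaussian noise to the signed distance before thresholding, roughening
    the boundary without biasing it.
    """
    z, y, x = _center_grid(spec.grid)
    if spec.shape == "slab":
        t = int(_require(spec.thickness, "thickness"))
        if t + 4 > spec.grid[0]:
            raise ValueError("slab thickness does not fit the z extent")
        zi = np.arange(spec.grid[0])[:, None, None] + np.zeros_like(z)
        z0 = (spec.grid[0] - t) // 2
        fg = (zi >= z0) & (zi < z0 + t)  # exactly t consecutive z-slices
        inside = np.minimum(zi - z0 + 0.5, z0 + t - zi - 0.5)
    elif spec.shape == "solid_sphere":
        r = _require(spec.radius, "radius")
        _check_margin(r, spec.grid)
        rr = np.sqrt(z ** 2 + y ** 2 + x ** 2)
        fg = rr <= r
        inside = r - rr
    elif spec.shape == "hollow_shell":
        r = _require(spec.radius, "radius")
        t = _require(spec.thickness, "thickness")
        _check_margin(r, spec.grid)
        rr = np.sqrt(z ** 2 + y ** 2 + x ** 2)
        fg = (rr <= r) & (rr > r - t)
        inside = np.minimum(r - rr, rr - (r - t))
    elif spec.shape == "curved_rod":
        rc = _require(spec.arc_radius, "arc_radius")
        rt = _require(spec.tube_radius, "tube_radius")
        _check_margin(rc + rt, spec.grid, axes=(1, 2))
        _check_margin(rt, spec.grid, axes=(0,))
        half = math.radians(spec.arc_degrees) / 2.0
        theta = np.arctan2(x, y)  # arc symmetric about +y
        in_arc = np.abs(theta) <= half
        d_torus = np.sqrt((np.sqrt(x ** 2 + y ** 2) - rc) ** 2 + z ** 2)
        e1 = np.array([rc * math.sin(half), rc * math.cos(half), 0.0])
        e2 = np.array([-e1[0], e1[1], 0.0])
        d_end1 = np.sqrt((x - e1[0]) ** 2 + (y - e1[1]) ** 2 + z ** 2)
        d_end2 = np.sqrt((x - e2[0]) ** 2 + (y - e2[1]) ** 2 + z ** 2)
        d_arc = np.where(in_arc, d_torus, np.minimum(d_end1, d_end2))
        fg = d_arc <= rt
        inside = rt - d_arc
    elif spec.shape == "vault_shell_with_gradient":
        r = _require(spec.radius, "radius")
        t0 = _require(spec.thickness_pole, "thickness_pole")
        t1 = _require(spec.thickness_equator, "thickness_equator")
        _check_margin(r, spec.grid, axes=(1, 2))
        if r + 4 > spec.grid[0]:
            raise ValueError("vault radius exceeds the z extent with the "
                             "required 2-voxel margin")
        # hemisphere sits on a base plane 2 voxels above the grid floor
        z = np.arange(spec.grid[0])[:, None, None] - 2.0 + np.zeros_like(z)
        rr = np.sqrt(z ** 2 + y ** 2 + x ** 2)
        with np.errstate(invalid="ignore"):
            phi = np.arccos(np.clip(np.where(rr > 0, z / np.maximum(rr, 1e-12),
                                             1.0), -1.0, 1.0))
        t_local = t0 + (t1 - t0) * np.clip(phi / (math.pi / 2.0), 0.0, 1.0)
        fg = (z >= 0) & (rr <= r) & (rr > r - t_local)
        inside = np.where(fg, np.minimum(r - rr, rr - (r - t_local)), -1.0)
    else:  # pragma: no cover - guarded by PhantomSpec
        raise AssertionError(spec.shape)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        fg = (inside + rng.normal(0.0, spec.noise_sigma, size=fg.shape)) > 0
    return BinaryVolume(occupancy=fg, spacing=spec.spacing,
                        provenance={"phantom": spec.shape})


def _require(value, name: str) -> float:
    if value is None:
        raise ValueError(f"phantom parameter {name!r} is required")
    return float(value)
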