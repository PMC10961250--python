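"""3D anatomical landmark data for embryonic cartilage morphometrics.

This module holds the landmark dictionary (Meckel's cartilage and
chondrocranium landmark definitions), per-specimen landmark configurations
with genotype/age/trial metadata, the two-trial digitization error protocol
(percent difference per landmark, with a re-measurement threshold), and the
construction of form matrices — the vector of all unique pairwise
interlandmark distances that downstream EDMA/GDMA and PCA operate on.

Coordinates are stored in millimetres throughout; readers convert from
micrometres when a table declares ``unit`` as ``um``.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

__all__ = [
    "LandmarkDefinition",
    "LandmarkConfiguration",
    "FormMatrix",
    "TrialErrorReport",
    "load_definitions",
    "definition_subset",
    "mc_abbreviations",
    "chondrocranium_abbreviations",
    "pair_labels",
    "interlandmark_distances",
    "percent_difference",
    "average_trials",
    "read_landmark_table",
    "write_landmark_table",
    "read_fcsv",
    "fcsv_to_configuration",
]

GENOTYPES = ("mutant", "wildtype")
_AGE_RE = re.compile(r"^E\d+(\.\d+)?$")

_UNIT_TO_MM = {"mm": 1.0, "um": 1e-3, "µm": 1e-3, "micron": 1e-3}


@dataclass(frozen=True)
class LandmarkDefinition:
    """One row of the landmark dictionary."""

    index: int
    abbreviation: str
    description: str
    tissue: str  # "MC" (Meckel's cartilage) or "C" (chondrocranium)

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"landmark index must be >= 1, got {self.index}")
        if self.tissue not in ("MC", "C"):
            raise ValueError(f"tissue must be 'MC' or 'C', got {self.tissue!r}")


def load_definitions() -> tuple[LandmarkDefinition, ...]:
    """Load the packaged 31-landmark dictionary (6 MC + 25 chondrocranium).

    Indices are contiguous from 1 and abbreviations unique; both are
    re-validated on load.
    """
    text = resources.files("chondromorph.data").joinpath(
        "landmark_definitions.csv").read_text()
    rows = list(csv.DictReader(text.splitlines()))
    defs = tuple(
        LandmarkDefinition(int(r["index"]), r["abbreviation"],
                           r["description"], r["tissue"])
        for r in rows
    )
    _validate_definitions(defs)
    return defs


def _validate_definitions(defs: Sequence[LandmarkDefinition]) -> None:
    abbrevs = [d.abbreviation for d in defs]
    if len(set(abbrevs)) != len(abbrevs):
        dupes = sorted({a for a in abbrevs if abbrevs.count(a) > 1})
        raise ValueError(f"duplicate landmark abbreviations: {dupes}")
    indices = sorted(d.index for d in defs)
    if indices != list(range(1, len(defs) + 1)):
        raise ValueError("landmark indices must be contiguous from 1")


def definition_subset(defs: Sequence[LandmarkDefinition],
                      tissue: str) -> tuple[LandmarkDefinition, ...]:
    return tuple(d for d in defs if d.tissue == tissue)


def mc_abbreviations(defs: Sequence[LandmarkDefinition] | None = None) -> tuple[str, ...]:
    defs = load_definitions() if defs is None else defs
    return tuple(d.abbreviation for d in definition_subset(defs, "MC"))


def chondrocranium_abbreviations(
        defs: Sequence[LandmarkDefinition] | None = None) -> tuple[str, ...]:
    defs = load_definitions() if defs is None else defs
    return tuple(d.abbreviation for d in definition_subset(defs, "C"))


@dataclass
class LandmarkConfiguration:
    """One digitization of one specimen: named 3D landmarks plus metadata.

    ``coordinates`` maps abbreviation -> (x, y, z) in mm, in the canonical
    order of the definition set.  ``missing`` lists abbreviations from the
    definition set for which no coordinates were recorded.
    """

    specimen_id: str
    genotype: str
    age: str
    trial: int | str  # 1, 2, or "averaged"
    coordinates: dict[str, np.ndarray]
    missing: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(
                f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if not _AGE_RE.match(self.age):
            raise ValueError(f"age must look like 'E14.5', got {self.age!r}")
        if self.trial not in (1, 2, "averaged"):
            raise ValueError(f"trial must be 1, 2 or 'averaged', got {self.trial!r}")
        coords = {}
        for abbrev, xyz in self.coordinates.items():
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (3,):
                raise ValueError(f"landmark {abbrev!r}: expected 3 coordinates")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"landmark {abbrev!r}: non-finite coordinates")
            coords[abbrev] = arr
        self.coordinates = coords

    @property
    def abbreviations(self) -> tuple[str, ...]:
        return tuple(self.coordinates)

    def age_number(self) -> float:
        return float(self.age[1:])

    def coordinate_array(self, subset: Sequence[str] | None = None) -> np.ndarray:
        """(K, 3) array of coordinates for ``subset`` (default: all present)."""
        subset = tuple(self.coordinates) if subset is None else tuple(subset)
        miss = [a for a in subset if a not in self.coordinates]
        if miss:
            raise KeyError(
                f"specimen {self.specimen_id}: missing landmarks {miss}")
        return np.stack([self.coordinates[a] for a in subset])

    def centroid(self, subset: Sequence[str] | None = None) -> np.ndarray:
        return self.coordinate_array(subset).mean(axis=0)


@dataclass(frozen=True)
class FormMatrix:
    """All unique interlandmark distances of one configuration or group mean.

    ``labels[k]`` is the (abbrev_i, abbrev_j) pair, i < j in canonical
    (definition-index) order; ``distances[k]`` the Euclidean length in mm.
    """

    labels: tuple[tuple[str, str], ...]
    distances: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "distances",
                           np.asarray(self.distances, dtype=float))
        if len(self.labels) != self.distances.shape[0]:
            raise ValueError("labels and distances length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    def as_series(self) -> pd.Series:
        return pd.Series(self.distances,
                         index=[f"{a}-{b}" for a, b in self.labels])


@dataclass(frozen=True)
class TrialErrorReport:
    """Signed percent difference in placement per landmark between two trials."""

    pd_values: dict[str, float]
    threshold: float = 5.0

    @property
    def flagged(self) -> frozenset[str]:
        return frozenset(a for a, v in self.pd_values.items()
                         if abs(v) > self.threshold)


def _canonical_order(abbrevs: Iterable[str],
                     defs: Sequence[LandmarkDefinition] | None = None) -> tuple[str, ...]:
    defs = load_definitions() if defs is None else defs
    index = {d.abbreviation: d.index for d in defs}
    abbrevs = tuple(abbrevs)
    unknown = [a for a in abbrevs if a not in index]
    if unknown:
        raise ValueError(f"unknown landmark abbreviations: {unknown}")
    return tuple(sorted(abbrevs, key=index.__getitem__))


def pair_labels(abbrevs: Sequence[str],
                defs: Sequence[LandmarkDefinition] | None = None
                ) -> tuple[tuple[str, str], ...]:
    """Canonical (i, j), i < j pair ordering, lexicographic by landmark index.

    This ordering is shared by every downstream form/growth/difference matrix.
    """
    ordered = _canonical_order(abbrevs, defs)
    return tuple((ordered[i], ordered[j])
                 for i in range(len(ordered)) for j in range(i + 1, len(ordered)))


def interlandmark_distances(config: LandmarkConfiguration,
                            subset: Sequence[str] | None = None,
                            defs: Sequence[LandmarkDefinition] | None = None
                            ) -> FormMatrix:
    """Form matrix: Euclidean distances for all unordered landmark pairs.

    For K landmarks the result has K*(K-1)/2 entries (e.g. 300 for the
    25-landmark chondrocranium set, 15 for the 6-landmark MC set).
    """
    subset = tuple(config.coordinates) if subset is None else tuple(subset)
    miss = sorted(set(subset) & set(config.missing)) + [
        a for a in subset if a not in config.coordinates and a not in config.missing]
    if miss:
        raise ValueError(
            f"specimen {config.specimen_id}: landmarks {miss} are missing "
            "from this configuration")
    ordered = _canonical_order(subset, defs)
    if len(ordered) < 2:
        raise ValueError("need at least 2 landmarks for a form matrix")
    coords = config.coordinate_array(ordered)
    return FormMatrix(pair_labels(ordered, defs), pdist(coords))


def _scalar_summary(config: LandmarkConfiguration, abbrev: str,
                    method: str) -> float:
    x = config.coordinates[abbrev]
    if method == "centroid_norm":
        return float(np.linalg.norm(x - config.centroid()))
    if method == "origin_norm":
        return float(np.linalg.norm(x))
    raise ValueError(f"unknown PD method {method!r}")


def percent_difference(trial1: LandmarkConfiguration,
                       trial2: LandmarkConfiguration,
                       threshold: float = 5.0,
                       method: str = "centroid_norm") -> TrialErrorReport:
    """Per-landmark percent difference PD = (n2 - n1) / n2 * 100 between trials.

    ``n_t`` is a scalar summary of the landmark's position in trial t:

    - ``centroid_norm`` (default): Euclidean norm of the landmark relative to
      that trial's configuration centroid — invariant to a global translation
      between digitizing sessions;
    - ``origin_norm``: raw Euclidean norm of the coordinate vector.

    Landmarks with |PD| above ``threshold`` percent are flagged for
    re-measurement.
    """
    _check_compatible(trial1, trial2)
    out: dict[str, float] = {}
    for abbrev in trial1.coordinates:
        n1 = _scalar_summary(trial1, abbrev, method)
        n2 = _scalar_summary(trial2, abbrev, method)
        if n2 == 0.0:
            out[abbrev] = 0.0 if n1 == 0.0 else math.inf
        else:
            out[abbrev] = (n2 - n1) / n2 * 100.0
    return TrialErrorReport(out, threshold)


def average_trials(trial1: LandmarkConfiguration,
                   trial2: LandmarkConfiguration) -> LandmarkConfiguration:
    """Coordinate-wise mean of the two digitization trials."""
    _check_compatible(trial1, trial2)
    coords = {a: (trial1.coordinates[a] + trial2.coordinates[a]) / 2.0
              for a in trial1.coordinates}
    return replace(trial1, trial="averaged", coordinates=coords)


def _check_compatible(a: LandmarkConfiguration, b: LandmarkConfiguration) -> None:
    if a.specimen_id != b.specimen_id:
        raise ValueError(
            f"trials belong to different specimens: {a.specimen_id!r} vs "
            f"{b.specimen_id!r}")
    sa, sb = set(a.coordinates), set(b.coordinates)
    if sa != sb:
        raise ValueError(
            f"mismatched landmark sets; symmetric difference: "
            f"{sorted(sa ^ sb)}")


# ---------------------------------------------------------------------------
# File formats

_REQUIRED_COLUMNS = ("specimen", "genotype", "age", "trial", "landmark",
                     "x", "y", "z")


def read_landmark_table(path: str | Path,
                        defs: Sequence[LandmarkDefinition] | None = None,
                        genotype_map: dict[str, str] | None = None,
                        ) -> list[LandmarkConfiguration]:
    """Read a long-format CSV/TSV landmark table.

    Required columns: specimen, genotype, age, trial, landmark, x, y, z;
    optional ``unit`` ("mm" default, "um" converted at read time).  One
    configuration is returned per (specimen, trial); definition-set landmarks
    absent from a configuration are recorded in its ``missing`` set.

    ``genotype_map`` optionally maps file genotype labels (e.g. allele names)
    onto the canonical "mutant"/"wildtype".
    """
    path = Path(path)
    defs = load_definitions() if defs is None else defs
    known = {d.abbreviation for d in defs}
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path.name}: missing columns {missing_cols}")

    bad = sorted(set(df["landmark"]) - known)
    if bad:
        raise ValueError(f"{path.name}: unknown landmark abbreviations {bad}")

    for col in ("x", "y", "z"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad_rows = df.index[numeric.isna() & df[col].notna()]
        if len(bad_rows):
            # +2: 1-based line numbers plus the header row
            raise ValueError(
                f"{path.name}: non-numeric {col!r} value "
                f"{df.loc[bad_rows[0], col]!r} at row {bad_rows[0] + 2}")
        df[col] = numeric

    unit = df["unit"] if "unit" in df.columns else pd.Series("mm", index=df.index)
    factors = unit.fillna("mm").map(_UNIT_TO_MM)
    if factors.isna().any():
        raise ValueError(
            f"{path.name}: unknown unit {unit[factors.isna()].iloc[0]!r}")
    for col in ("x", "y", "z"):
        df[col] = df[col] * factors

    configs: list[LandmarkConfiguration] = []
    for (specimen, trial), grp in df.groupby(["specimen", "trial"], sort=True):
        genotype = str(grp["genotype"].iloc[0])
        if genotype_map:
            genotype = genotype_map.get(genotype, genotype)
        trial_val: int | str = trial
        if isinstance(trial, str) and trial.isdigit():
            trial_val = int(trial)
        coords = {row.landmark: np.array([row.x, row.y, row.z])
                  for row in grp.itertuples()}
        ordered = _canonical_order(coords, defs)
        configs.append(LandmarkConfiguration(
            specimen_id=str(specimen),
            genotype=genotype,
            age=str(grp["age"].iloc[0]),
            trial=trial_val,
            coordinates={a: coords[a] for a in ordered},
            missing=frozenset(known - set(coords)),
        ))
    return configs


def write_landmark_table(configs: Iterable[LandmarkConfiguration],
                         path: str | Path) -> None:
    """Write configurations to the long-format CSV the reader consumes (mm)."""
    rows = []
    for c in configs:
        for abbrev, xyz in c.coordinates.items():
            rows.append({"specimen": c.specimen_id, "genotype": c.genotype,
                         "age": c.age, "trial": c.trial, "landmark": abbrev,
                         "x": xyz[0], "y": xyz[1], "z": xyz[2], "unit": "mm"})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fcsv(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Read a 3D Slicer markups fiducial file (.fcsv).

    Returns (label, xyz) tuples in file order; coordinates are taken from the
    x,y,z columns (2nd-4th) of the standard fcsv layout and assumed mm.
    """
    points: list[tuple[str, np.ndarray]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if len(parts) < 12:
                raise ValueError(f"{Path(path).name}: malformed fcsv row {line!r}")
            xyz = np.array([float(parts[1]), float(parts[2]), float(parts[3])])
            points.append((parts[11], xyz))
    return points


def fcsv_to_configuration(path: str | Path, specimen_id: str, genotype: str,
                          age: str, trial: int | str = 1,
                          label_map: dict[str, str] | None = None,
                          defs: Sequence[LandmarkDefinition] | None = None,
                          ) -> LandmarkConfiguration:
    """Build a configuration from a Slicer fiducial file.

    ``label_map`` maps fiducial labels to landmark abbreviations; unmapped
    labels must already be valid abbreviations.
    """
    defs = load_definitions() if defs is None else defs
    known = {d.abbreviation for d in defs}
    coords: dict[str, np.ndarray] = {}
    for label, xyz in read_fcsv(path):
        abbrev = (label_map or {}).get(label, label)
        if abbrev not in known:
            raise ValueError(f"unknown landmark abbreviation {abbrev!r}")
        coords[abbrev] = xyz
    ordered = _canonical_order(coords, defs)
    return LandmarkConfiguration(
        specimen_id=specimen_id, genotype=genotype, age=age, trial=trial,
        coordinates={a: coords[a] for a in ordered},
        missing=frozenset(known - set(coords)))
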