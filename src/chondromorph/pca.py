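"""Principal component analysis of form and shape from interlandmark distances.

Form space: the covariance PCA of ln-transformed interlandmark distances,
so both size and shape contribute.  Shape space: each specimen's distances
are first divided by that specimen's geometric mean distance (leaving only
proportions), then ln-transformed and analysed the same way.  Total variance
in form space decomposes exactly into shape variance plus size variance,
where size variance is the part removed by the geometric-mean scaling —
algebraically equal to (number of pairs) x Var(per-specimen mean ln-distance).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .edma import GroupSample

__all__ = [
    "DistanceDataset",
    "PCAResult",
    "VarianceDecomposition",
    "distance_dataset",
    "form_space_pca",
    "shape_space_pca",
    "variance_decomposition",
    "scores_to_frame",
]


@dataclass
class DistanceDataset:
    """Specimens x pairs matrix of interlandmark distances with metadata."""

    specimen_ids: tuple[str, ...]
    genotypes: tuple[str, ...]
    ages: tuple[str, ...]
    distances: np.ndarray  # (n_specimens, n_pairs), mm
    labels: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        n, p = self.distances.shape
        if not (len(self.specimen_ids) == len(self.genotypes)
                == len(self.ages) == n):
            raise ValueError("metadata length does not match distance rows")
        if len(self.labels) != p:
            raise ValueError("pair labels do not match distance columns")
        if np.any(self.distances <= 0):
            i, k = np.argwhere(self.distances <= 0)[0]
            raise ValueError(
                f"non-positive distance for pair {self.labels[k]} in specimen "
                f"{self.specimen_ids[i]}; ln-transform undefined")

    @property
    def n(self) -> int:
        return self.distances.shape[0]


def distance_dataset(*groups: GroupSample,
                     subset: Sequence[str] | None = None) -> DistanceDataset:
    """Pool one or more groups into a single distance dataset."""
    ids, genos, ages, rows = [], [], [], []
    labels = None
    for g in groups:
        lab, d = g.distance_matrix(subset)
        if labels is None:
            labels = lab
        elif lab != labels:
            raise ValueError("groups use different landmark subsets")
        for c, row in zip(g.configurations, d):
            ids.append(c.specimen_id)
            genos.append(c.genotype)
            ages.append(c.age)
            rows.append(row)
    return DistanceDataset(tuple(ids), tuple(genos), tuple(ages),
                           np.stack(rows), labels)


@dataclass(frozen=True)
class PCAResult:
    space: str  # "form" or "shape"
    eigenvalues: np.ndarray        # descending, length n_components
    loadings: np.ndarray           # (n_pairs, n_components)
    scores: np.ndarray             # (n_specimens, n_components), zero mean
    total_variance: float          # trace of the covariance of the variables
    variance_fraction: np.ndarray  # eigenvalues / total_variance

    @property
    def n_components(self) -> int:
        return self.eigenvalues.shape[0]


def _cov_pca(x: np.ndarray, space: str) -> PCAResult:
    """Covariance PCA of variables in ``x`` via SVD of the centered data.

    With n specimens and p >> n variables the SVD works in the specimen-space
    dual, so at most n-1 nonzero eigenvalues are reported.  Component sign is
    fixed by making each component's largest-magnitude loading positive.
    """
    n, p = x.shape
    if n < 3:
        raise ValueError("PCA needs at least 3 specimens")
    xc = x - x.mean(axis=0)
    # total variance of the transformed variables (ddof=1 covariance trace)
    total = float((xc ** 2).sum() / (n - 1))
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(n - 1, p)
    s, vt = s[:k], vt[:k]
    eigvals = s ** 2 / (n - 1)
    loadings = vt.T
    # deterministic sign: largest |loading| entry positive per component
    for j in range(k):
        imax = np.argmax(np.abs(loadings[:, j]))
        if loadings[imax, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = xc @ loadings
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, eigvals / total, 0.0)
    return PCAResult(space, eigvals, loadings, scores, total, frac)


def form_space_pca(ds: DistanceDataset) -> PCAResult:
    """PCA of ln-transformed distances (size and shape together)."""
    return _cov_pca(np.log(ds.distances), "form")


def shape_space_pca(ds: DistanceDataset) -> PCAResult:
    """PCA of ln distances scaled by each specimen's geometric mean.

    Dividing by the per-specimen geometric mean and taking logs is the same
    as centering each specimen's ln-distance row, so any uniform rescaling of
    a specimen leaves its shape variables (and scores) unchanged.
    """
    logd = np.log(ds.distances)
    shape_vars = logd - logd.mean(axis=1, keepdims=True)
    return _cov_pca(shape_vars, "shape")


@dataclass(frozen=True)
class VarianceDecomposition:
    """Form variance = shape variance + size variance (squared-ln units)."""

    form: float
    shape: float
    size: float


def variance_decomposition(ds: DistanceDataset) -> VarianceDecomposition:
    """Split total ln-distance variance into shape and size components.

    Form variance is the summed variance of all ln-distances; shape variance
    the summed variance of the geometric-mean-scaled (row-centered) ln
    variables; their difference is the variance due to size alone and is
    non-negative by the algebraic identity size = n_pairs x Var(row mean).
    """
    if ds.n < 2:
        raise ValueError("variance decomposition needs at least 2 specimens")
    logd = np.log(ds.distances)
    form = float(logd.var(axis=0, ddof=1).sum())
    centered = logd - logd.mean(axis=1, keepdims=True)
    shape = float(centered.var(axis=0, ddof=1).sum())
    return VarianceDecomposition(form, shape, form - shape)


def scores_to_frame(ds: DistanceDataset, result: PCAResult,
                    n_components: int | None = None) -> pd.DataFrame:
    """Tidy specimen scores (with genotype/age labels) for plotting."""
    k = result.n_components if n_components is None else min(
        n_components, result.n_components)
    df = pd.DataFrame({
        "specimen": ds.specimen_ids,
        "genotype": ds.genotypes,
        "age": ds.ages,
    })
    for j in range(k):
        df[f"PC{j + 1}"] = result.scores[:, j]
    return df


def loadings_to_frame(result: PCAResult,
                      labels: Sequence[tuple[str, str]]) -> pd.DataFrame:
    df = pd.DataFrame({
        "landmark_a": [a for a, _ in labels],
        "landmark_b": [b for _, b in labels],
    })
    for j in range(result.n_components):
        df[f"PC{j + 1}"] = result.loadings[:, j]
    return df
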