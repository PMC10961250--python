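"""Growth matrices and growth difference matrix analysis (GDMA).

Growth for one genotype is summarized cross-sectionally: the mean form
matrix of the older group is divided elementwise by that of the younger
group, giving a growth matrix (GM) whose entries > 1 indicate that a linear
distance lengthened with age.  The growth difference matrix (GDM) compares
two genotypes' growth as the elementwise ratio mutant GM / wildtype GM.
Because growth is estimated from different specimens at each age, the
bootstrap resamples specimens independently within each of the four groups
and recomputes the full GDM per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .edma import (DifferenceMatrix, GroupSample, _central_distances,
                   _resampled_means, expanded_alpha, percentile_ci)

__all__ = ["GrowthMatrix", "growth_matrix", "growth_difference_matrix"]


@dataclass(frozen=True)
class GrowthMatrix:
    """Elementwise older/younger mean-form ratio for one genotype."""

    labels: tuple[tuple[str, str], ...]
    ratio: np.ndarray
    genotype: str
    older_age: str
    younger_age: str

    def __post_init__(self) -> None:
        if np.any(self.ratio <= 0):
            raise ValueError("growth ratios must be positive")


def _check_age_order(older: GroupSample, younger: GroupSample) -> tuple[str, str]:
    age_o, age_y = older.age, younger.age
    if float(age_o[1:]) <= float(age_y[1:]):
        raise ValueError(
            f"older group age {age_o} must be strictly later than {age_y}")
    return age_o, age_y


def growth_matrix(older: GroupSample, younger: GroupSample,
                  estimator: str = "arithmetic",
                  subset: Sequence[str] | None = None) -> GrowthMatrix:
    """GM for one genotype: older mean form / younger mean form, elementwise."""
    if older.genotype != younger.genotype:
        raise ValueError(
            f"growth matrix mixes genotypes: {older.genotype} vs "
            f"{younger.genotype}")
    age_o, age_y = _check_age_order(older, younger)
    lab_o, d_o = older.distance_matrix(subset)
    lab_y, d_y = younger.distance_matrix(subset)
    if lab_o != lab_y:
        raise ValueError("landmark subsets of the two age groups differ")
    ratio = _central_distances(d_o, estimator) / _central_distances(d_y, estimator)
    return GrowthMatrix(lab_o, ratio, older.genotype, age_o, age_y)


def growth_difference_matrix(mutant_older: GroupSample,
                             mutant_younger: GroupSample,
                             wildtype_older: GroupSample,
                             wildtype_younger: GroupSample,
                             alpha: float = 0.10, n_boot: int = 10_000,
                             seed: int | None = None,
                             estimator: str = "arithmetic",
                             ci_method: str = "expanded",
                             subset: Sequence[str] | None = None
                             ) -> DifferenceMatrix:
    """GDM: (mutant GM) / (wildtype GM) elementwise with bootstrap CIs.

    Entries > 1 flag linear distances that grew more in the mutant between
    the two ages (reported as growth difference percent = (ratio - 1) * 100);
    entries < 1 flag reduced growth.  Bootstrap replicates resample all four
    groups independently; significance per distance follows from the
    percentile interval (default α = 0.10) excluding 1.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    groups = (mutant_older, mutant_younger, wildtype_older, wildtype_younger)
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.label!r}: bootstrap requires n >= 2")
    _check_age_order(mutant_older, mutant_younger)
    _check_age_order(wildtype_older, wildtype_younger)

    labels = None
    dists = []
    for g in groups:
        lab, d = g.distance_matrix(subset)
        if labels is None:
            labels = lab
        elif lab != labels:
            raise ValueError("landmark subsets differ across the four groups")
        dists.append(d)
    d_mo, d_my, d_wo, d_wy = dists

    def gdm_of(mo, my, wo, wy):
        return (mo / my) / (wo / wy)

    point = gdm_of(*(_central_distances(d, estimator) for d in dists))

    rng = np.random.default_rng(seed)
    n_pairs = len(labels)
    samples = np.empty((n_boot, n_pairs))
    chunk = 2000
    for start in range(0, n_boot, chunk):
        stop = min(start + chunk, n_boot)
        m = stop - start
        reps = []
        for d in dists:
            idx = rng.integers(0, d.shape[0], size=(m, d.shape[0]))
            reps.append(_resampled_means(d, idx, estimator))
        samples[start:stop] = gdm_of(*reps)
    if ci_method == "expanded":
        alpha_q = expanded_alpha(alpha, [d.shape[0] for d in dists])
        lo, hi = percentile_ci(samples, alpha_q, point, "percentile")
    else:
        lo, hi = percentile_ci(samples, alpha, point, ci_method)

    label = (f"growth[{mutant_older.genotype} "
             f"{mutant_younger.age}->{mutant_older.age}]")
    den_label = (f"growth[{wildtype_older.genotype} "
                 f"{wildtype_younger.age}->{wildtype_older.age}]")
    return DifferenceMatrix(labels, point, label, den_label, alpha=alpha,
                            n_boot=n_boot, seed=seed, ci_low=lo, ci_high=hi)
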