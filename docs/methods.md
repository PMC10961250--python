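# Methods

This note documents the models and procedures implemented in
`chondromorph`, the parameter defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices that affect results.

## Landmark data and measurement error

A specimen is represented by a named 3D landmark configuration (mm). The
packaged landmark dictionary has 31 entries — 6 on Meckel's cartilage (MC)
and 25 on the chondrocranium — and fixes a canonical ordering; all
downstream pair-indexed vectors use the lexicographic (i, j), i < j order
of these indices, so form matrices, difference matrices and PCA loadings
are always aligned.

Digitization error is controlled by a two-trial protocol: every specimen
is digitized twice and a signed percent difference

    PD = (n2 − n1) / n2 × 100

is computed per landmark, where `n_t` is a scalar summary of the
landmark's position in trial t. The default summary is the Euclidean norm
of the landmark relative to the trial's configuration centroid, which is
invariant to a global translation between digitizing sessions; the raw
coordinate-vector norm is available as `method="origin_norm"`. Landmarks
with |PD| above the threshold (default 5%) are flagged for re-measurement.
Analysis uses the coordinate-wise average of the two trials. Averaging
coordinates is not the same as averaging distances: for noncollinear
noise the averaged-coordinate distance is strictly shorter, which is the
desired behavior (it averages out digitization displacement rather than
accumulating it).

Configurations missing any landmark of an analysis subset are excluded
from that analysis (with a logged warning) rather than imputed.

## EDMA form comparison

Each configuration is reduced to its form matrix, the vector of all
K(K−1)/2 unique interlandmark distances. Groups are summarized by a mean
form matrix; the default estimator is the arithmetic mean of per-specimen
distances per pair. Two alternatives are available: `rms`
(sqrt of the mean squared distance) and `rms-corrected`
(sqrt(mean(d²) − var(d)), a moment estimator that removes the first-order
upward bias that landmark noise induces in squared distances; it falls
back to `rms` when the correction would go negative). Note that the
arithmetic mean estimates the *population mean distance*, which for
distances that are short relative to the landmark noise exceeds the
distance between the mean landmark positions — a property of the
estimator visible on sub-millimetre pairs in the tests.

The form difference matrix (FDM) is the elementwise ratio of two groups'
mean form matrices, mutant group in the numerator by convention so ratios
above 1 read as "larger in the mutant". Significance per distance is
localized by a nonparametric bootstrap: specimens are resampled with
replacement independently within each group, the ratio is recomputed per
replicate (default `n_boot = 10,000`; the test-suite uses 1,000), and a
confidence interval is formed per pair; a pair is significant when its
interval excludes 1. Default `alpha = 0.10`.

### Confidence interval construction

Plain percentile intervals of the bootstrap ratio distribution are
markedly anti-conservative at the group sizes this package targets
(n = 4–6): the bootstrap distribution of a mean understates the sampling
spread by a factor ≈ sqrt((n−1)/n) per group and ignores the Student-t
heaviness of small-sample estimates. Measured on null simulations
(n = 5 vs 5, σ = 2% of mean distance), plain percentile flags ~19% of
pairs at nominal α = 0.10. The default interval is therefore an
**expanded percentile** interval: the quantile levels [α/2, 1−α/2] are
replaced by

    α*/2 = Φ( sqrt(g) · t_{α/2, df} ),   df = Σ (n_i − 1),
    g = Σ 1/(n_i − 1) / Σ 1/n_i,

which restores near-nominal empirical rates (~0.10–0.13 in the same
simulations) while remaining fully nonparametric. Plain `percentile` and
bias-corrected `bc` intervals are available as options. Significance
testing uses a 1e-9 relative guard around 1 so that degenerate exact-null
intervals perturbed only by float rounding are never flagged.

### Reporting bins

Significant distances are classified by the magnitude of their percent
difference (ratio − 1) × 100, rounded to integer percent: below 5%
(counted apart), 5–10%, and 11% or greater. Rounded 10% falls in the
lower bin, matching the conventional "5%–10%" / "11% and above" reporting
labels. Bin edges are configurable.

## Growth and growth differences (GDMA)

Growth for one genotype is cross-sectional: the mean form matrix of the
older age group divided elementwise by that of the younger group (growth
matrix, GM). The growth difference matrix GDM = GM(mutant)/GM(wildtype)
compares growth between genotypes per linear distance; entries above 1
mean the distance grew more in the mutant. Because the ages are different
specimens, the bootstrap resamples all four groups independently per
replicate and recomputes the full GDM — no longitudinal pairing is
modeled. CI construction and significance are as for the FDM (expanded
percentile, α = 0.10 default). GDM computed directly is algebraically
identical to the elementwise quotient of the two growth matrices, and is
invariant to any uniform rescaling applied to all four groups.

## Form-space and shape-space PCA

Form space is the covariance PCA of ln-transformed interlandmark
distances. Shape space first divides each specimen's distances by that
specimen's geometric mean distance (over the analysis subset only), then
ln-transforms; equivalently, each specimen's ln-distance row is centered,
so shape scores are exactly invariant to per-specimen rescaling. With n
specimens and p ≫ n distance variables the eigendecomposition is obtained
from the SVD of the centered data (the specimen-space dual), and at most
n − 1 nonzero eigenvalues are reported. Component signs are fixed by
making each component's largest-magnitude loading positive, so plots are
reproducible.

Total variance decomposes exactly:

    form variance  = Σ_pairs Var(ln d)
    shape variance = Σ_pairs Var(ln d − mean_pairs ln d)
    size variance  = form − shape = p · Var(mean_pairs ln d) ≥ 0.

The identity holds to float precision and is asserted at 1e-9 relative in
the tests.

## Thickness of binary volumes

Volumes are boolean (z, y, x) grids with isotropic spacing in μm (NRRD
and NIfTI header spacings are taken as mm and converted; TIFF stacks
require an explicit spacing).

**Average object thickness** uses the parallel-plate model, 2·V/S. V is
the foreground voxel count times spacing³. S is, by default, the area of
the triangulated 0.5-level isosurface of the mask after a 1-voxel
Gaussian pre-smoothing: meshing a raw binary mask produces a
stair-stepped surface whose area overestimates the smooth boundary by
~8–10% (measured on digitized spheres), while the lightly smoothed
isosurface recovers continuum areas to well under 1% on spheres and slabs
without displacing the boundary. Voxel-face counting is available as an
option; it overestimates S by up to ~1.5× and correspondingly deflates
2V/S, which matters when comparing surface-to-volume ratios across tools.
2V/S equals the exact thickness of an ideal plate and 2r/3 for a solid
sphere; both limits are verified on phantoms (a slab's rim adds
perimeter·t to S, so plate-like behavior requires a large in-plane
aspect — at 200×200×10 the rim alone depresses 2V/S by ~9%).

**Local thickness maps** assign each foreground voxel the diameter of the
largest ball that contains it and lies entirely inside the object. The
algorithm computes a Euclidean distance map inside the object, then for
each voxel v with distance value d(v) browses the ball of radius
R = d(v) centered on v and raises the thickness of every covered voxel to
at least R; the map is finally doubled to give diameters, in μm. The
distance-map origin set follows one of three boundary conventions:

- `included`: distances measured from background voxel centers just
  outside the object (slightly inflates boundary thickness; a 10-slab maps
  to exactly 10, a single voxel to 2);
- `excluded`: from boundary voxels belonging to the object (deflates; the
  10-slab maps to 8, a single voxel to 0);
- `averaged` (default): the mean of the two maps before propagation (the
  10-slab maps to 9, a single voxel to 1).

Ball membership is decided in exact integer arithmetic: with a = d²_incl
and b = d²_excl (both integers in voxel units) a voxel at squared offset
m belongs to the ball iff 4m − a − b ≤ 0 or (4m − a − b)² ≤ 4ab, so there
are no floating-point ties. The implementation groups voxels by (a, b),
processes radii in descending order and scatters each ball once; it is
verified voxel-for-voxel against an exhaustive inscribed-ball oracle on
random volumes, and is invariant to 90° rotations and background padding.

**Group comparison** of per-specimen scalars uses a two-sided
Mann–Whitney U test computed by exact enumeration of all C(n1+n2, n1)
group labelings (midranks for ties; p = min(1, 2·min(P(U≤u), P(U≥u)))),
falling back to the tie-corrected normal approximation only when the
enumeration would exceed 400,000 labelings. Fully separated groups of
5 vs 4 give p = 2/126 ≈ 0.016 and 5 vs 6 give p = 2/462 ≈ 0.004.

## Curve lengths

Open and closed curves through ordered 3D control points are measured as
the arc length of an interpolating cubic spline (chord-length
parameterization; natural end conditions for open curves, periodic for
closed), integrated by dense chord sampling at 128 subdivisions per
segment — at that density a further doubling changes the length by less
than 0.01%. A polyline mode measures the control polygon instead. Surface
projection ("constrained to model") is not reproduced: the spline lives
in free space, which slightly shortcuts curves that hug a convex surface;
lengths from surface-constrained tools are therefore comparable only
approximately.

## Synthetic data

The landmark generator draws specimens as a mean configuration plus iid
isotropic Gaussian noise per landmark coordinate — the simplest model
consistent with the distance-based analysis; correlated noise is not
modeled. The default noise scale is 2% of the mean interlandmark distance
of the configuration, a digitization-scale magnitude for embryonic
cartilage landmarks. Two shipped mean configurations mirror the real
landmark sets: a 6-landmark MC-like horseshoe and a 25-landmark
chondrocranium-like bilateral cage, so tests exercise the true pair
counts (15 and 300). Two-trial output adds independent per-trial
digitization noise (default 5 μm).

Planted effects scale a landmark subset about the subset's own centroid:
every within-subset distance then scales by exactly the stated factor
(listing all landmarks gives a uniform size effect), giving exact σ = 0
oracles for FDM and GDM recovery; distances with one endpoint in the
subset change by a deterministic, computable amount, and
`planted_distance_ratios` returns the exact per-pair oracle. Overlapping
effects with different factors are rejected. Two-age designs apply
genotype-specific growth effects to a shared base mean, so the planted
GDM (e.g. 1.6/1.4 = 8/7 on a block) is exact at σ = 0. All randomness
flows from one integer seed through SeedSequence spawning.

Voxel phantoms (slab, solid sphere, hollow shell, curved tubular rod, and
a hemispherical vault shell whose thickness varies linearly from pole to
equator) are voxelized by center inclusion and carry analytic thickness
ground truth. The generator emulates geometry only — not anatomical
covariance structure, staining artifacts, or segmentation noise — so
passing tests demonstrate correctness of the measurement chain, not
robustness to real imaging defects.

## Problem sizes used in validation

The validation battery (test suite and `scripts/acceptance.py`) runs at
the study-scale group sizes (5 vs 4 and 5 vs 6 specimens), with
n_boot = 1,000 bootstrap replicates, 100 simulation repeats for
planted-effect recovery, 200 null group-pairs for calibration, and
phantoms up to radius-20 spheres and 800×800 slabs — sizes chosen so the
full battery completes in about a minute while keeping Monte Carlo error
comfortably inside the asserted tolerances.

## Known limitations

- The expanded percentile interval corrects the dominant small-n
  miscalibration but is still a bootstrap: exactness is not guaranteed,
  and empirical rates at α = 0.10 sit in roughly [0.08, 0.14].
- Mean-form estimation by arithmetic averaging of distances carries the
  positive noise bias described above for distances comparable to the
  noise scale.
- Local thickness is quantized by the voxel grid; values on thin
  structures are reliable only to about one voxel, and the three boundary
  conventions differ by up to two voxels on a slab.
- Anisotropic voxel grids are not supported (resample first).
- No Procrustes superimposition, parametric EDMA null distributions,
  omnibus form tests, growth-curve fitting beyond two ages, or geodesic
  (surface-constrained) curve measurement.
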