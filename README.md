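# chondromorph

Quantitative morphometrics of embryonic cartilage from PTA-enhanced microCT
data: landmark-based **Euclidean Distance Matrix Analysis** (EDMA) and
**growth difference matrix analysis** (GDMA) with bootstrap confidence
intervals, **form- and shape-space PCA** of interlandmark distances, **3D
thickness analysis** of binary cartilage segmentations (parallel-plate
average thickness and voxel-wise local thickness maps), and **spline curve
lengths** (e.g. Meckel's cartilage length, foramen magnum circumference).

The package targets studies of embryonic chondrocranium and Meckel's
cartilage (MC) phenotypes — for example FGFR3-related chondrodysplasia
models — where groups are small (4–6 specimens per genotype and age),
landmarks are digitized twice per specimen, and cartilage masks come from
microCT segmentations. A synthetic-data module generates landmark
populations and voxel phantoms with known ground truth so that every stage
of the pipeline is testable without any imaging data.

## Methods at a glance

- **Form matrix** `FM(A)`: the vector of all K(K−1)/2 unique interlandmark
  distances of a configuration with K landmarks (300 for the 25-landmark
  chondrocranium set, 15 for the 6-landmark MC set). EDMA compares groups
  without superimposition via the **form difference matrix**
  `FDM = FM(mutant) / FM(wildtype)` (elementwise ratio of group mean forms).
  Per-distance significance comes from nonparametric bootstrap confidence
  intervals (specimens resampled within groups, default α = 0.10, small-
  sample expanded percentile intervals); a distance is *localized* as
  different when its interval excludes 1.
- **Growth matrix** `GM = FM(older) / FM(younger)` per genotype, and
  **growth difference matrix** `GDM = GM(mutant) / GM(wildtype)`, with the
  four groups bootstrapped independently.
- **Form space / shape space PCA**: covariance PCA of ln-distances (form),
  and of ln-distances scaled by each specimen's geometric mean (shape).
  Total variance decomposes exactly as *form = shape + size*.
- **Average object thickness** = 2·V/S (parallel-plate model); **local
  thickness** per voxel = diameter of the largest inscribed ball containing
  it (distance transform + ball propagation, with included / excluded /
  averaged boundary conventions). Group scalars are compared with an exact
  two-sided Mann–Whitney U test.
- **Curve lengths**: through-point cubic splines over ordered control
  points, open or periodically closed.

See `docs/methods.md` for the full model description, parameter defaults,
and numerical choices.

## Worked example

Plant a 12% widening of the posterior MC block in the mutant group
(5 mutants vs 4 wildtypes, landmark noise at 2% of the mean distance) and
localize it with EDMA:

```python
from chondromorph.synth import (MC_MEAN, Effect, PopulationSpec,
                                default_sigma, generate_landmark_population)
from chondromorph.edma import (bootstrap_difference_ci, classify_differences,
                               difference_to_frame)

sigma = default_sigma(MC_MEAN)          # 2% of the mean interlandmark distance
mutant = generate_landmark_population(PopulationSpec(
    MC_MEAN, sigma, n=5, genotype="mutant",
    effects=(Effect(("mcpl", "mcppl", "mcpr", "mcppr"), 1.12),), seed=11))
wildtype = generate_landmark_population(PopulationSpec(
    MC_MEAN, sigma, n=4, seed=12))

fdm = bootstrap_difference_ci(mutant, wildtype, alpha=0.10,
                              n_boot=10_000, seed=1)
bins = classify_differences(fdm)
print(difference_to_frame(fdm, bins).round(3).to_string(index=False))
print("bin counts:", bins.counts())
```

Output (abridged):

```
landmark_a landmark_b  ratio  percent_difference  ci_low  ci_high  significant           bin
       mca      mcsym  0.879             -12.100   0.739    1.051        False
       mca       mcpl  1.036               3.572   1.010    1.067         True    larger <5%
     mcsym       mcpr  1.072               7.237   1.045    1.099         True larger 5%-10%
      mcpl       mcpr  1.138              13.773   1.109    1.166         True  larger >=11%
     mcppl      mcppr  1.132              13.172   1.101    1.158         True  larger >=11%
      mcpr      mcppr  1.180              18.012   1.039    1.390         True  larger >=11%
bin counts: {'larger': {'<5%': 3, '5%-10%': 5, '>=11%': 5},
             'smaller': {'<5%': 0, '5%-10%': 0, '>=11%': 0}}
```

Reading it: each row is one interlandmark distance; `ratio` > 1 means
longer in the mutant group. The distances *within* the planted posterior
block recover the planted ~12–14% elongation and land in the "larger
≥11%" reporting bin; distances with one endpoint in the block show
intermediate, smaller increases; and the purely anterior distance
(`mca–mcsym`) is not significant. The very short `mcpl–mcppl` distance is
noisy at this sample size and is (correctly) not flagged.

## Command-line pipeline

```sh
chondromorph simulate --config sim.yaml  --seed 3 --out sim/
chondromorph form     --config form.yaml --seed 1 --out results/form/
chondromorph growth   --config form.yaml --seed 1 --out results/growth/
chondromorph thickness --config thick.yaml --seed 0 --out results/thick/
chondromorph curves   --config curves.yaml --seed 0 --out results/curves/
```

Configs are YAML (landmark table path, `subset: MC|chondrocranium`,
`alpha`, `n_boot`, volume/curve entries, ...); every run writes tidy CSVs
plus a JSON manifest (config, seed, version, group sizes) that reproduces
it bit-exactly. Landmark tables are long-format CSV/TSV
(`specimen,genotype,age,trial,landmark,x,y,z[,unit]`); 3D Slicer `.fcsv`
fiducial files are read for both landmarks and curves; volumes are NRRD,
NIfTI, or TIFF stacks.

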