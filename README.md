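# gbiq — grid-based image quantification

`gbiq` quantifies multi-channel fluorescent micrographs **without cell
segmentation**. Segmentation pipelines need many hand-tuned parameters and
struggle outright on densely packed material — stem-cell colonies, embryonic
mesoderm — where cell boundaries are genuinely ambiguous. `gbiq` sidesteps
the problem: it tiles each channel with fixed g×g pixel grids and records,
for every grid, the **median** and **interquartile range (IQR)** of its g²
pixel intensities together with the grid coordinate. One parameter (the grid
size g), no thresholds, fully reproducible.

The grid table then supports a standard analysis chain, all included here:

* **Mixture-model classification** of grids (EM-fitted Gaussian mixtures,
  component count and covariance family chosen by BIC; a k-means f(K)
  suggestion is available as an independent check);
* the **Median_IQR filter**: clustering the counterstain (median, IQR)
  pairs and keeping the classes that are brighter than average *and* more
  uniform than average selects grids lying inside cell nuclei — no
  segmentation required — plus a grid-size scan/advisor built on it;
* **group statistics**: Brunner–Munzel rank test (robust to unequal
  variances and ties), fixed-bandwidth Gaussian kernel densities, fold
  changes of grid-median means;
* a **penalized additive model** (cubic B-spline smooths, GCV-selected
  smoothing, Wald-type term tests) that attributes a target factor's decline
  to one of two spatially collinear candidate regulators;
* **synthetic scene generators** with pixel-level ground truth (dense
  colonies with reporter subpopulations; striped tissue with a planted
  causal asymmetry), so the whole pipeline is testable end to end.

It is aimed at bench scientists who need quick, non-arbitrary quantitative
readouts from dense fluorescent material, and at image-analysis developers
who want a segmentation-free baseline with a fully inspectable statistical
chain.

## The statistics in brief

For a channel raster I and grid size g, grid (i, j) covers pixels
`I[(i−1)g : ig, (j−1)g : jg]` (1-based grid coordinates, top-left origin,
trailing pixels dropped), and

    GridMedian(i, j) = median of the g² intensities
    GridIQR(i, j)    = Q3 − Q1 (linear-interpolation quantiles)

Medians and IQRs are preferred over means and SDs because fewer than ⌈g²/2⌉
corrupted pixels cannot move a grid's median — debris and impulse noise are
absorbed. Grid classification uses Gaussian mixtures with BIC
(−2·logL + p·ln n, minimized); two-group comparisons use the Brunner–Munzel
statistic for p̂ = P(X<Y) + ½P(X=Y); regulatory inference fits
y = α + s₁(x₁) + s₂(x₂) + ε with penalized spline smooths. Details, defaults
and numerical conventions: [docs/methods.md](docs/methods.md).

## Worked example

Generate a synthetic colony (41 nuclei, a 17% planted marker up-shift in
reporter(+) cells) and run the full chain:

```python
from gbiq import generate_colony
from gbiq.pipeline import colony_workflow

scene = generate_colony(seed=0)          # 240x240, 3 channels, ground truth
res = colony_workflow(scene.image, counterstain="H33342",
                      reporter="EGFP", marker="antiOct4", g=20, seed=0)

print(len(res.matrix))                   # 144   (12 x 12 grids at g=20)
print(len(res.filter_result.selected))   # 84    nucleus-pure grids kept
print(res.n_positive, res.n_negative)    # 48 36  reporter(+) / (-) grids
print(round(res.fold_change, 4))         # 1.1483 marker fold change
print(f"{res.bm_test.p_value:.3g}")      # 8.38e-12
```

Reading the numbers: the 240×240 image yields 144 grids; the Median_IQR
filter keeps 84 of them as nucleus-pure; mixture sub-classification splits
those into 48 reporter(+) and 36 reporter(−) grids; the marker fold change
between the groups, 1.148, recovers the planted 1.17 up to the expected
attenuation from background light and mixed-population grids, and the
Brunner–Munzel test confirms the shift is far beyond noise.

The same flow is available from the shell:

```bash
gbiq simulate --kind colony --seed 0 -o scene/
gbiq quantify -g 20 --channel H33342=scene/colony-seed0_H33342.tif \
    --channel EGFP=scene/colony-seed0_EGFP.tif \
    --channel antiOct4=scene/colony-seed0_antiOct4.tif -o grids.csv
gbiq filter grids.csv --counterstain H33342 -o filtered.csv
gbiq scan-gridsize --counterstain H33342 --nucleus-count 41 \
    --channel H33342=scene/colony-seed0_H33342.tif -o scan.csv
```

Subcommands: `quantify`, `filter`, `classify`, `scan-gridsize`, `compare`,
`gam`, `simulate`, `run` (full pipeline from a YAML/JSON config). Exit
codes: 0 success, 1 data error, 2 configuration error.

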