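# Methods

## The quantification model

`gbiq` quantifies multi-channel fluorescent micrographs without segmenting
cells. Each channel is tiled with non-overlapping g x g pixel grids anchored
at the top-left corner; trailing pixels (`height mod g`, `width mod g`) are
discarded. Every grid contributes one observation: the sample median and the
interquartile range (IQR) of its g^2 pixel intensities, stored with 1-based
(row, column) grid coordinates. Means and standard deviations are available
on request but are not the defaults: a debris speck or saturated noise
pixels covering fewer than half a grid's pixels cannot move that grid's
median at all, while the mean shifts in proportion to the contamination.
This robustness is a property test in the suite and a quantity the
acceptance script measures (the mean absolute shift of grid medians under
5% impulse noise, relative to the shift of grid means).

Quantiles use linear interpolation between order statistics (numpy's
`"linear"` method, equivalently type 7 of the common statistical-environment
convention), fixed so IQR values reproduce bit-for-bit. Statistics are
computed in floating point; medians ending in .5 are never rounded.

The grid size g is the method's single mandatory parameter. The working
rule, supported by the grid-size scan: a nucleus should span roughly 2 x 2
grids. Grids much smaller than a nucleus sample the same nucleus several
times (pseudo-replication); grids larger than a nucleus mix cellular
compartments and inflate every IQR.

## Grid classification

Grid records are classified with Gaussian finite mixtures fitted by EM,
implemented in `gbiq.mixture` so that every quantity entering model
selection is inspectable:

* Four covariance families (shared isotropic, per-component isotropic,
  diagonal, full), a deliberate reduction of the larger model zoo found in
  mixture packages: the families differ in their BIC free-parameter counts
  (1, k, kd, kd(d+1)/2 covariance parameters respectively).
* BIC = -2 loglik + p ln n, **minimized**; ties resolve toward smaller k,
  then the simpler family. The full (k, family) scan is retained in
  `scan_`.
* Initialization: k-means++ seed centers, 10 restarts. Restarts are triaged
  with a 30-iteration burn-in and the best is refined to convergence
  (relative log-likelihood change < 1e-8, at most 500 iterations); the
  log-likelihood trace of the winning run is stored and is checked to be
  non-decreasing in the tests.
* Covariances are regularized by adding 1e-6 x (mean feature variance) to
  the diagonal.
* Features are used on the raw intensity scale. Grid medians within an
  image set are already commensurable, and standardizing would distort the
  relative weighting of channels that the biology motivates.

A cluster-count suggestion independent of the mixture machinery is provided
by k-means with the f(K) distortion-ratio criterion (weight schedule
a_2 = 1 - 3/(4d), a_K = a_{K-1} + (1 - a_{K-1})/6; a K is eligible when
f(K) < 0.85, and the minimizing eligible K wins, else 1).

Advisory class designations ("reporter(+)", "reporter(-)", "void", "other")
are derived from cluster mean profiles — lowest counterstain = void,
highest reporter among the rest = reporter(+), highest remaining
counterstain = reporter(-). They are cosmetic; numeric labels are
authoritative and never altered.

## The Median_IQR filter

A grid lying entirely inside a nucleus is bright in the counterstain and
uniform (small IQR); a grid straddling a nucleus boundary is bright but
heterogeneous. The filter clusters the (counterstain median, counterstain
IQR) pairs with the BIC-selected mixture and keeps every class satisfying
both criteria, strictly:

1. class mean of median intensity > overall mean of median intensity, and
2. class mean IQR < overall mean IQR,

where "overall" averages over all grid records (not raw pixels) — the
filter operates on the grid matrix. Several passing classes are unioned.
When no class passes (the over-large-grid symptom), a documented fallback
selects the single class with the highest mean median intensity among
classes strictly brighter than the overall mean, and flags itself; if not
even that exists the filter errors ("no nucleus-like class").

The grid-size advisor runs the filter at each candidate g and excludes
candidates where (i) the selected-class grid count reaches twice a manually
counted nucleus number (grid too small — multiple sampling per nucleus), or
(ii) the fallback fired (grid too large). Survivors are ranked by
selected-class mean median intensity, ties broken by selected-class grid
count. Both exclusions and the ranking are reported in a human-readable
rationale.

## Downstream statistics

**Brunner-Munzel test.** Implemented from its definition: midranks over the
pooled sample estimate the stochastic superiority p = P(X<Y) + 0.5 P(X=Y);
the studentized statistic uses the rank-variance estimators of both samples
with Satterthwaite-type degrees of freedom, and two-sided p-values from the
t distribution. Ties are handled by midranks. Completely separated samples
(zero rank variance with p-hat 0 or 1) return the limiting test (infinite
statistic, p = 0); fully tied data raise an error. The implementation is
cross-checked in the tests against a double-loop counting oracle, a
permutation null, and an independent library implementation.

**Kernel density estimation.** The fixed-bandwidth Gaussian KDE evaluated
on a uniform grid spanning the data range +/- 4 bandwidths. Intensities are
explicitly normalized to [0, 1] by 2^bit_depth - 1 before density
estimation, making a bandwidth like 0.05 meaningful across bit depths; the
normalization is never implicit.

**Fold change** is the ratio of group means of per-grid medians; the
reference group is the denominator.

**Penalized additive model.** The regulatory-inference model
y = a + s_1(x_1) + s_2(x_2) + e with penalized cubic B-spline smooths:

* Basis: cubic B-splines on uniform knots over each predictor's observed
  range (default 10 functions per smooth), with the sum-to-zero constraint
  absorbed by a null-space reparameterization.
* Penalty: squared second divided differences of the coefficients taken on
  the Greville abscissae. Its null space is exactly the linear trend, so a
  smooth with smoothing parameter -> infinity collapses onto an ordinary
  linear fit (a numerical contract verified in the tests at lambda = 1e6,
  where the penalized solve is still well-conditioned).
* Smoothing parameters: generalized cross-validation over the Cartesian
  product of per-term grids 10^-3..10^3 in 25 logarithmic steps, with the
  model-df term inflated by gamma = 1.4 — the usual correction for GCV's
  tendency to undersmooth.
* Inference: per-term effective degrees of freedom (trace of the
  corresponding influence-matrix block) and a Wald-type test of the
  penalized coefficients against the Bayesian covariance, using a
  pseudo-inverse of rank floor(edf)+1 and an F reference distribution. The
  rank convention is mildly conservative for terms shrunk toward their null
  space; simulated pure-noise responses reject at 3-5% at nominal 5% (a
  calibration test in the suite).

No multiple-testing correction is applied anywhere; p-values are two-sided
throughout.

## Pipelines

The colony chain (quantify -> Median_IQR filter -> mixture
sub-classification on all channel medians -> reporter comparison) labels
reporter(+) grids by splitting the sub-cluster mean reporter levels at
their largest gap, so a graded reporter population spanning several
clusters is unioned correctly, and reports the marker fold change with its
Brunner-Munzel test.

The tissue chain (quantify -> filter -> k-means-suggested, BIC-fitted
mixture on the factor medians -> additive model within the class expressing
all factors) additionally **thins the target class to a checkerboard of
grids** (no two kept grids share an edge) before the additive model. When
nuclei are as large as a grid or larger, adjacent grids resample the same
nucleus; such pseudo-replication overstates the effective sample size and
makes smooth-term tests anticonservative — exactly the "multiple sampling
to a nucleus" concern that also drives the grid-size advisor. Thinning
restores approximately independent observations; it can be disabled
(`thin_spacing=1`).

## Synthetic scenes

The generators exist so every pipeline branch is testable against pixel-
level ground truth. They emulate structure, not photorealism.

**Geometry.** Dense colonies and tissues are modeled as bounded Voronoi
tessellations of seed points: each nucleus is the set of pixels nearest its
seed within ~1.2 nominal radii, boundaries between neighbours are thin
(1 px) and slightly dimmed (x0.88), interstitial dips are closed
morphologically (packed cells deform to fill space), and free edges roll
off over ~3 px (out-of-focus light at colony rims). Cells are disjoint by
construction yet space-filling, as in a confluent colony; isolated cells
come out round. Disk-shaped nuclei with gaps between them were rejected
during design: with non-overlapping disks, circle packing caps the achievable
nucleus coverage of any grid near 91%, making "grids fully inside nuclei"
geometrically impossible at realistic densities, which contradicts how the
filter is supposed to behave on dense colonies.

**Colony scenes** (default 240 x 240 px, 8-bit): 41 nuclei of nominal
radius 15-19 px grown into one compact colony (a nucleus then spans about
2 x 2 grids at g = 20, the scale the grid-size rule prefers), a
reporter(+) fraction of 0.6 with graded reporter brightness (uniform
0.55-1.0 of full scale), per-nucleus lognormal counterstain and marker
brightness (sigma = 0.10), a marker fold change of 1.17 in reporter(+)
nuclei, two larger dimmer feeder nuclei, background 6, Gaussian read noise
sigma = 3. The planted 1.17 is recovered by the full pipeline as ~1.13:
background light and grids overlapping both subpopulations attenuate the
ratio slightly, which is the expected behaviour of the measurement, not an
error in it.

**Striped tissue scenes** (default 800 x 800 px): nuclei of nominal radius
11 px on a jittered hexagonal lattice tiling the section; three Gaussian
stripe bands in which factors B and C are expressed with independent
per-nucleus lognormal brightness (sigma = 0.25 — immunostained factors
vary strongly cell to cell, and that variation is what lets the additive
model separate C from the spatially collinear B); the target factor A obeys
A = 150 - effect x C + N(0, 8) per nucleus, with effect = 0.6 by default
and independent of B given C. Tests and the acceptance script run these
scenes at 400 x 400 px with two stripes — the same nucleus, stripe and
grid scales, on a smaller canvas.

**Corruption injectors**: impulse noise sets a chosen fraction (< 0.5) of
pixels to the maximum intensity; debris adds small saturated ragged blobs.
Both are identity at zero intensity of corruption.

All generators are bit-reproducible under a seed, and scenes serialize to
grayscale TIFFs plus a cell-table CSV that round-trip exactly.

## Problem sizes used by tests and the acceptance script

Colony checks run at the default 240 x 240 scale (robustness over 100
seeds in the tests, 50 in the script; filter purity over 20 and 10 seeds;
fold-change recovery over 10 seeds in each). Mixture-recovery checks use 100
(tests) or 60 (script) replicates of n = 500 planted mixtures with k
scanned over 1..6. Tissue inference runs 20 planted + 50 null seeds in the
tests and 10 + 15 in the script, at 400 x 400 px. These sizes were chosen
as the smallest at which the binomial acceptance rates quoted in the test
docstrings are stable.

## Known limitations

* No optical point-spread-function model, photobleaching, z-structure or
  uneven illumination in the generators; passing tests show the pipeline's
  statistical machinery works on idealized dense-tissue geometry, not that
  it is robust to every real acquisition artifact.
* The filter's criteria compare class means only; a class straddling the
  overall means can flip selection under small perturbations of the
  clustering, which is why selected-grid counts vary by a few grids across
  seeds.
* Smooth-term p-values are approximate (penalized Wald with estimated
  scale); they are calibrated in simulation but inherit GCV's smoothing
  variability.
* Grid observations are spatially correlated whenever nuclei span several
  grids; outside the tissue chain's thinning step, no correction is applied
  (fold changes and rank tests on grid classes share this caveat with the
  method itself).
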