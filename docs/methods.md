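# Methods

This note documents the models and procedures implemented in `kdisomap`,
the choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## Feature extraction: spatially enhanced uniform LBP

A local binary pattern labels each pixel by thresholding P sampling
points on a circle of radius R at the center intensity (neighbor >=
center sets the bit) and reading the bits as an integer. Conventions are
frozen and documented in `kdisomap.lbp`: bit p is the p-th least
significant bit; sampling starts straight up and proceeds
counter-clockwise; off-grid samples are bilinearly interpolated; labels
exist only where the full neighborhood fits (a ceil(R)-pixel border is
excluded), and the region grid partitions that labeled area. Uniform
patterns (at most two 0/1 transitions around the circle) receive
individual histogram bins and all others share one bin: P(P-1)+3 bins,
i.e. 59 for P = 8. The default operator is the uniform (8, 2) code with
a 6x7 grid of near-equal regions, giving 42 x 59 = 2478 features on a
110x150 face crop. Region histograms are raw counts by default;
`normalize=True` divides each region block by its pixel count.

Face normalization maps the two eye centers to a horizontal line 55 px
apart, centered at one third of the height of a 110x150 output crop
(faces are roughly two eye-distances wide and three tall), by a
closed-form two-point similarity transform with bilinear resampling;
out-of-frame regions are edge-replicated with a warning.

## Kernel discriminant distance

A Gaussian kernel kappa(x,y) = exp(-||x-y||^2 / (2 sigma^2)), sigma = 1
by default, induces the kernel Euclidean distance d^2 = 2 - 2 kappa in
[0, 2). The supervised dissimilarity applies a bounded increasing
transform within classes and an inflating one between classes:

    D(x, y) = 1 - exp(-d^2 / beta)      same label
    D(x, y) = exp(+d^2 / beta) - alpha  different labels

beta is the average kernel Euclidean distance over unordered sample
pairs (self-pairs excluded; an all-identical dataset is rejected because
the transform divides by beta). alpha in [0, 1], default 0.5, controls
how much the two branches may interleave; at alpha = 0 every
between-class value (>= 1) strictly exceeds every within-class value
(< 1). Both branches are strictly increasing in d, so neighbor ranking
is preserved within each branch. The two branches are intentionally
discontinuous across the class boundary — that gap is the discriminant
signal — so no smoothing is applied.

Units note: beta averages the distance d (not d^2) while the exponent
uses d^2/beta. The convention is internally consistent and frozen.

## Geodesic spectral embedding

Both embeddings build a k-nearest-neighbor graph (k = 10 default, union
symmetrization, ties to the smaller index) on an input dissimilarity
matrix — plain Euclidean for the unsupervised variant, the discriminant
distance for the supervised one — run Dijkstra shortest paths for all
pairs, double-center the squared geodesics K(D^2) = -1/2 H D^2 H, and
embed with the top-d eigenpairs, Y = Lambda^{1/2} V^T. A disconnected
graph raises an error naming the component sizes and suggesting a larger
k; `auto_connect=True` instead bridges components repeatedly through the
globally shortest inter-component edge.

Constant shifting. K(D^2) is generally not positive semi-definite. The
minimal constant c* such that adding c to every off-diagonal geodesic
yields a PSD kernel K*(c) = K(D^2) + 2c K(D) + c^2 H / 2 (with K(D) the
double-centered first-power matrix) is the largest eigenvalue of the
block matrix [[0, 2K(D^2)], [-I, -4K(D)]]; if that eigenvalue carries a
non-negligible imaginary part numerically, a bisection on the minimum
eigenvalue of K*(c) is used instead. Measurement drove an important
default: on the swiss-roll benchmark (800 points, k = 10) the minimal
shift is c* ~ 45-66 — the same order as the manifold diameter — because
c* grows with the graph-path overestimation of manifold distances.
Embedding with that shift inflates the trailing spectrum and distorts
the recovered distances in a rank-2 readout (Pearson correlation with
true manifold distances drops from >= 0.9995 to as low as 0.986).  Since
the retained top-d eigenvalues are positive anyway, the default embeds
the unshifted kernel and clamps any negative trailing eigenvalues to
zero (with a warning); `shift="mercer"` applies c = max(c*, 0) when a
certified Mercer kernel matrix is required, and the PSD theorem is
verified in the test suite. Eigenvector signs are fixed by making each
vector's largest-magnitude entry positive.

Out-of-sample projection. A new point is wired to its k nearest training
points; its geodesic to training point i is min_j [edge(new, j) +
geo(j, i)] over those neighbors. The distances are shifted like the
training ones (by the model's c, off-diagonal only), converted to a
centered kernel column with the training row/grand means, and projected
as y = Lambda^{-1/2} V^T k — the same kernel trick as in kernel PCA,
and exactly consistent with the training coordinates. For the supervised
embedding a test label is unknown, so test edges use the bounded
within-class transform 1 - exp(-d^2/beta) of the kernel Euclidean
distance; this preserves neighbor ranking but cannot reproduce the
label-aware training geodesics, so a query identical to a training point
short-circuits to that point's coordinates (this also underlies the
training self-consistency guarantee). Known limitation: when classes
overlap, a boundary query whose nearest training points span two classes
short-circuits the inflated between-class geodesics and its coordinates
shrink toward the origin; the supervised embedding's out-of-sample
advantage is therefore claimed only for well-separated classes.

## Baselines

PCA (SVD of centered data), Fisher LDA (generalized symmetric
eigenproblem with a ridge of 1e-6 x trace on the within-class scatter,
at most c-1 dimensions), kernel PCA (eigendecomposition of the
double-centered kernel matrix; Gaussian by default, linear kernel
available, in which case coordinates equal PCA up to sign), and kernel
LDA solved as LDA in the numerically full-rank kernel-PCA coordinate
space — an equivalent, well-conditioned formulation of the kernelized
Fisher problem. Out-of-sample projection is a matrix product for the
linear methods and the centered-kernel-column trick for the kernel ones.

## Evaluation protocol

Folds partition subjects (never images), with fold sizes differing by at
most one subject, deterministically from a seed. Per fold, every
embedding is fitted on the training folds only at its maximal swept
dimension; leading coordinate blocks give the smaller dimensions (the
spectral methods are nested in d). The held-out fold is projected
out-of-sample and classified by 1-NN (Euclidean metric, distance ties to
the smallest training index). Accuracy is aggregated as mean +/- sd
across folds per (method, dimension, alpha) cell; the dimension grid
merges [2, 100] step 5 with [2, 10] step 1, and the alpha grid is
0, 0.1, ..., 1. Cells whose embedding fails (e.g. a disconnected graph)
are logged and skipped rather than aborting the sweep. Two
alpha-selection protocols exist: `sweep` reports the full grid and the
best cell by outer test accuracy (optimistic, exploratory), and `inner`
chooses alpha per dimension by an inner subject-grouped cross-validation
within the training folds, so the held-out fold never influences any
fitted quantity. The reported dispersion is the standard deviation
across the ten folds.

## Synthetic data

Swiss roll: the classic spiral (t cos t, h, t sin t) with t uniform on
[1.5 pi, 4.5 pi] and h uniform on [0, 10]; the true unrolled coordinates
(arc length s(t) = (t sqrt(1+t^2) + asinh(t))/2, h) are exposed, and the
noiseless map to 3-D is an exact isometry. The height range was set by
the requirement that at the benchmark operating point (N = 800, k = 10)
the 10-NN radius stays below half the 2 pi gap between windings even on
the sparser outer winding; with the wider classic height of 21 the graph
short-circuits across windings in a large fraction of seeds and the
benchmark measures sampling luck instead of isometry recovery.

Expression-style image set: 7 classes x 20 subjects x 2 images of
110x150 gray images. Each class is an oriented sinusoidal grating
(orientation and frequency distinct per class) plus a Gaussian blob
moving along a class-specific circular path; both the grating phase and
the blob position are driven by a per-image latent parameter, so each
class traces a one-parameter nonlinear manifold in pixel space. Each
subject adds a fixed smooth random low-frequency intensity field, and
i.i.d. Gaussian pixel noise (sd 4) is added before clipping to [0, 255].
The `class_separation` knob interpolates all class parameters toward a
common base (0 = identically distributed classes, 1 = default); the
`subject_variability` knob scales the subject fields. Subjects are
balanced across classes so subject-grouped folds are class-balanced.

What passing means. Because LBP is deliberately insensitive to smooth
intensity fields, the default set is separable by construction: raw-LBP
1-NN under subject-grouped CV already reaches 100%, and the embedding
comparison at the defaults is a tie at the top rather than a strict
ordering. The benchmarks therefore demonstrate that the pipeline
preserves separable structure end-to-end (features -> supervised
embedding -> out-of-sample projection -> classifier), that accuracy
collapses to chance when class structure is removed (separation 0 or
permuted labels), and that accuracy is monotone in the separation knob.
They do not emulate the pose/identity/illumination variability of real
face databases, and results on them say nothing about absolute accuracy
on real data.

Kernel scale. The experiments on the synthetic image set use
frequency-normalized region histograms: with raw counts the squared
distances between 2478-dimensional count vectors are of order 10^4-10^6
and the sigma = 1 Gaussian kernel saturates (all kernel distances ->
sqrt 2), which collapses the out-of-sample edge ranking. Normalized
histograms put pairwise squared distances at order 1, where sigma = 1 is
informative. The feature extractor's default remains raw counts.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated
data: the method-ordering benchmark uses the default 280-image set with
the reduced sweep d in {2, 10, 20}, alpha in {0, 0.5, 1} (10 seeds in
the test suite, 3 in the acceptance script); the inner-alpha variant is
exercised at 2 seeds with a 3-fold inner split; the PSD check draws 20
random datasets with N <= 60; the swiss-roll benchmark uses 800 points,
k = 10, d = 2. These sizes are the package's chosen operating points for
its reference checks.

## Numerical choices

Squared kernel distances in [-1e-12, 0] are clamped to zero; larger
negatives raise (non-Mercer input). Negative trailing eigenvalues are
clamped with a warning before taking square roots. Distance ties in
k-NN selection and 1-NN classification resolve to the smallest index
via stable sorts. The LDA ridge is 1e-6 of the within-class scatter
trace. Degenerate inputs rejected with errors: images smaller than the
operator neighborhood, empty histogram regions, coincident eye centers,
all-identical samples (beta = 0), k outside [1, N-1], embedding
dimension outside [1, N].
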