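# Methods

`spatnet` quantifies the spatial organization of organelles in single cells
imaged by multiplexed immunofluorescence. The unit of analysis is one
segmented cell with named marker channels (e.g. DAPI, Nucleolin, TOM20,
HSP60, GOLPH4, ATF6), a cell mask and an optional nucleus mask. This note
records the models, the parameters that matter, the numerical conventions,
and what the synthetic data can and cannot demonstrate.

## Intensity quality control

Each channel passes through three independent, independently callable steps,
applied by the CLI in this order:

1. **Rolling-ball background subtraction.** The background estimate is the
   grayscale morphological opening of the image by a disk of radius
   `rolling_ball_radius_px` (default 50 px). Opening removes every structure
   narrower than the disk, so the radius must exceed the width of genuine
   foreground structures. The synthetic-pipeline configurations use 25 px:
   blobs in the generated 256×256 cells have σ ≤ 5 px (≲20 px footprint),
   so a 25 px ball rolls over them. The ImageJ sliding-paraboloid dialect is
   not reproduced; plain opening is the standard formalization.
2. **Percentile rescaling.** Intensities are linearly mapped so that the
   20th percentile of the cell-mask pixels (background) goes to 0 and the
   99.9th percentile (saturation) to 1, clipping outside [0, 1] and zeroing
   pixels outside the mask. Percentiles use linear interpolation between
   closest ranks. A constant region is a degenerate input (the map is
   undefined), reported as an error rather than a guess.
3. **Otsu foreground masking.** The threshold maximizes between-class
   variance over a 256-bin histogram of min–max-stretched mask-interior
   values; foreground uses a strict `>` comparison. The implementation is an
   explicit exhaustive search over all 255 splits so the convention is fully
   specified (library Otsu variants differ in bin-edge handling); tests
   compare it against an independent brute-force evaluation.

Best-focus selection scores each z-slice by the variance of its Laplacian
response (sharp images have heavy-tailed second derivatives) and takes the
argmax, ties to the lowest index. Cycle-to-cycle registration is
integer-pixel translation recovered by phase correlation, which matches the
translational drift of repeated coverslip imaging; rotation, scaling and
subpixel refinement are out of scope.

## Colocalization

Two complementary per-cell metrics per marker pair:

* **Pearson correlation** of the raw paired intensities over *all* cell-mask
  pixels (not only foreground), threshold-free. Constant channels make r
  undefined and raise a degenerate-input error, so heatmaps can exclude
  them explicitly.
* **Pixel-overlap fraction** |A∩B| / (|A|+|B|) of the two Otsu foreground
  masks: 0 for disjoint markers, 0.5 iff the masks are identical. The
  denominator reading "total area of both markers" is ambiguous between
  |A|+|B| and |A∪B|; the former is the default, the Jaccard form is a
  config switch (`overlap_denominator: union`).

Scatter samples draw up to 50,000 mask pixels without replacement (pooling
across cells precedes sampling when a plot covers several cells), min–max
scale each channel over the sample, and weight each point by a Gaussian
kernel density estimate with Scott's-rule bandwidth. Exact KDE evaluation is
O(n²); above `kde_max_train` points (default 2000) the KDE is fitted on a
seeded subsample and evaluated everywhere, the standard density-scatter
approximation. Marker area uses binary opening then closing with a 3×3
square structuring element (one iteration each): opening deletes isolated
noise pixels, closing fills pinholes, and solid convex regions pass through
unchanged — the 4-connected cross was rejected because it clips the corners
of rectangular regions.

## Statistics

**Group comparison** uses the two-sided Mann–Whitney U test with midrank tie
handling: the exact null distribution when n·m ≤ 400 and the data are
tie-free, otherwise the normal approximation with continuity and tie
corrections. All-tied samples have zero rank variance; the test then reports
U = nm/2 and p = 1. Significance tiers follow the usual convention
(ns ≥ 0.05, * < 0.05, ** < 0.01, *** < 0.001, **** ≤ 10⁻⁴). No
multiple-testing correction is applied; tables carry raw p values so users
can apply their own.

**Radial KS procedure.** A marker's 2D foreground pattern is reduced to the
1D sample of Euclidean distances from each foreground pixel to the
unweighted center of mass of the cell mask; two markers of the same cell are
compared by the two-sample Kolmogorov–Smirnov test (asymptotic two-sided p).
The null hypothesis is that similar proteins share a spatial distribution
within the cell. The test runs on the raw distance samples, not on a binned
histogram — binning only loses power, and the binned statistic converges to
the ECDF form as bins shrink. Distances are unweighted by default; passing
per-pixel intensities switches to weighted ECDFs with Kish effective sample
sizes.

A caveat that matters in practice: KS assumes independent draws, but
foreground pixels are spatially autocorrelated (all pixels of one organelle
blob move together), which makes pixel-level KS anti-conservative. The
package's own positive/negative control (`radial_control_spec`) therefore
uses punctate markers (300 blobs, σ = 1.2 px) and decimates each radial
sample to 200 pixels before testing, so draws approximate independence.
Under that recipe the opposed-bias positive control is detected in 20/20
seeds at p < 0.01 while the matched-spec negative control rejects in ≤ 4/20
at α = 0.05 — mildly above the nominal 5% because two independent 300-blob
textures genuinely differ at the O(1/√300) level. Pixel-dense markers
violate the iid assumption more strongly; treat small per-cell KS p values
on dense markers as descriptive, not calibrated.

## Pixel phenotyping

Every cell-mask pixel becomes a feature vector of its per-marker intensities
(each marker min–max scaled over the mask; constant channels map to zero
rather than erroring). K-Means (Lloyd, k-means++ initialization, 10
seed-derived restarts, best inertia kept) partitions the pixels; the
published analysis fixed k = 10 and that remains the default. The elbow
criterion is formalized as the k maximizing the second-order forward
difference of the inertia curve over `k_range` (default 2…15), i.e. maximal
discrete curvature; the per-k inertia table is always emitted so alternative
criteria can be audited. Each k is additionally warm-started from the
previous k's centroids plus the worst-fit point, which guarantees the
inertia curve is non-increasing — without it, restart noise can produce
spurious negative curvature. Groups (BM vs UC) are clustered independently.
Organelle product images multiply two min–max scaled channels pixel-wise
inside the mask, highlighting joint hotspots on [0, 1].

## Superpixel texture

Each marker image is partitioned into up to `n_superpixels` (default 250)
superpixels by SLIC — spatially regularized K-Means in (row, col, intensity)
space — restricted to the cell mask, with compactness 0.1 on the
[0, 1]-scaled intensity. SLIC's connectivity cleanup can split regions; any
excess is merged into the dominant neighbor so the realized count never
exceeds the target. Six focus-measure functionals are averaged per
superpixel: mean intensity; mean squared 4-neighbor Laplacian (energy);
sum-modified Laplacian |I∗kx|+|I∗ky| with the classical (−1, 2, −1) kernels;
the diagonal variant adding both 1/√2-scaled diagonal kernels (absolute
responses summed — the classical sum-modified-Laplacian convention);
mean squared deviation of the Laplacian from its cell-mask mean; and mean
squared deviation of the intensity from its cell-mask mean. Deviations are
taken from mask-wide means by default, which yields an exact law-of-total-
variance identity (area-weighted mean of per-superpixel gray-level variance
equals the mask-wide variance, tested to 1e−10); per-superpixel reference
means are available behind a flag. Means (not sums) make features
independent of superpixel area. All convolutions use edge-inclusive
reflective padding.

## Morphology

Per marker and cell, the Otsu foreground is measured as one object (union of
all components, since one area/major/minor triple is reported per marker):
pixel-count area, µm² area via the squared pixel size (0.1083 µm/px
default), and axis lengths 4·√λ from the eigenvalues of the normalized
second central moment matrix — the "ellipse with identical normalized second
moments" convention of standard morphometry suites. Feature tables are
z-scored per column (sample SD, constant columns to zero) and ordered by
average-linkage hierarchical clustering on correlation distance
d = 1 − Pearson; leaf orders and merge trees are emitted as data, and
rendering is left to the user. Constant rows make correlation undefined and
raise unless the fallback (distance 1 to everything) is enabled.

## Synthetic data: what it emulates and what it does not

The generator builds elliptical cells (nucleus ellipse inside a cell
ellipse) whose markers are sums of Gaussian blobs. Blob centers are placed
at a uniform angle and a Beta-distributed fraction of the boundary radius:
bias 0 gives Beta(2, 1), the area-uniform law; positive/negative bias moves
mass to the periphery/center monotonically. Pairwise colocalization is
injected by copying a fraction of one marker's centers into another
(`overlap_targets`); fraction 1 with equal blob counts reproduces the
saturating overlap of 0.5 after Otsu masking. Noise follows shot-plus-read
order: Poisson on signal+background, then additive Gaussian, then clipping
at zero. Background is restricted to the cell interior, mirroring a masked
real pipeline. Everything is reproducible from one seed; population seeds
derive deterministically from a master seed.

Defaults emulate the study design at desk scale: 256×256 px at 0.1083 µm/px,
a 6-marker panel (DAPI and Nucleolin nuclear; TOM20/HSP60 punctate with
overlap target 0.7; GOLPH4 center-biased; ATF6 spread), amplitudes on a
16-bit camera scale, background 20, Gaussian read noise σ = 10, and a 7 + 7
BM/UC population in which UC staining is 1.5× brighter, reflecting the
higher UC marker expression the analysis is meant to detect. Cell geometry
varies per cell by shrink-only scaling (0.85–1×) and re-rotation.

Passing tests on this data shows that the pipeline recovers planted
colocalization, radial structure, cluster counts and group differences under
Poisson/Gaussian noise. It does not show robustness to what the generator
omits: staining/bleaching chemistry, cycle misregistration beyond pure
translation, non-elliptical morphology, intensity-dependent background, or
segmentation errors — cell masks are inputs here, as they were drawn
manually in the original workflow.

## Numerical conventions and degenerate inputs

* Row-major, 0-based (row, col) coordinates; row 0 at the top.
* Intensities are float64 in original camera units until an operation
  explicitly normalizes; integer TIFFs load value-for-value.
* Constant inputs raise `DegenerateInputError` wherever an operation is
  undefined on them (rescaling, Otsu, Pearson, product images, correlation
  distance) instead of returning a conventional value; blank channels are
  tolerated exactly where the pipeline must continue (pixel-matrix columns
  scale to zero).
* Ties: Otsu's argmax takes the lowest split; best-focus takes the lowest
  index; the elbow takes the smallest k; Mann–Whitney uses midranks.
* K-Means uses scikit-learn's Lloyd with seed-derived initializations
  (relative tolerance 1e-4, ≤300 iterations); determinism is exercised by a
  byte-identical double run of the full CLI chain.
* Registration shifts are reported in the centered range (−H/2, H/2] ×
  (−W/2, W/2].

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated data:
96×96 two-marker cells for metric checks, 192×192 punctate cells for the
radial controls (20 seeds), 600-point planted 4-cluster data for elbow
recovery (20 seeds), 2000 null replicates of 20-vs-20 for the Mann–Whitney
attained size, and a 14-cell 256×256 population for the end-to-end
determinism run — sizes at which every check completes in minutes on one
CPU while keeping the per-cell pixel counts (≈20–25 k mask pixels) in the
regime of the real 60× acquisitions.

## Known limitations

* The rolling-ball radius is a free parameter with no in-package estimator;
  it must exceed the foreground structure scale.
* Per-cell KS p values on pixel-dense markers are anti-conservative (see
  above).
* Registration is integer translation only.
* The elbow criterion is one formalization of "maximal curvature"; emitted
  inertia tables allow re-analysis under others.
* The nucleus mask is Otsu-on-DAPI (within the cell mask) rather than a
  propagation-based two-stage segmentation; per-marker regions are likewise
  plain Otsu foregrounds.
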