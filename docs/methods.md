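# Methods

This note documents the models, parameter choices and numerical decisions
behind `qdmi`, and what the synthetic benchmarks do and do not demonstrate.

## The assay being modeled

3D quantitative DNA-methylation imaging (3D-qDMI) is a cell-by-cell
image-cytometry assay: interphase nuclei are counterstained with DAPI
(proxying local genomic-DNA density, hence chromatin condensation) and
immunostained for 5-methylcytosine (MeC, global DNA methylation), imaged as
3D confocal stacks (nominal voxel 120 × 120 × 250 nm, 12-bit), and analyzed
nucleus by nucleus.  The pipeline has four stages: nuclear segmentation,
population-homogeneity filtering, per-nucleus texture features, and
population statistics against growth behavior.

## Segmentation

The DAPI volume is binarized at an image-inherent global threshold.  We
instantiate "image-inherent" as Otsu's method; the returned threshold is
placed midway between the two observed intensities straddling Otsu's raw
(histogram-binned) cut, which makes it strictly separate the two classes and
makes thresholding exactly equivariant under intensity rescaling.  Holes are
filled per z-slice (nucleolus-like voids count toward nuclear volume).
Seeds are local maxima of the Euclidean distance transform computed with
physical sampling (so axial anisotropy does not skew them), suppressed below
a minimum separation (default 0.7 × the expected nuclear radius — the
separation is a free parameter since no seed rule is inherent to the data).
Nuclei are delineated by a seeded 3D watershed on the inverted distance
transform; ties follow the watershed's stable flooding order, so identical
inputs give identical labelings.  ROIs touching the stack border or below a
minimum volume are excluded, with counts logged for provenance
(`found = kept + border_excluded + small_excluded + kl_excluded`).

## Codistribution filtering

Each nucleus is summarized by the 64 × 64 joint histogram of its (DAPI, MeC)
pixel intensities over population-wide bin edges, and scored against the
population mean histogram with the Kullback-Leibler divergence (base 2).
Both tables receive a per-bin pseudocount ε = 1/(total bins)² before
renormalization — small enough to leave the tables essentially undistorted
while keeping every log ratio finite.  A larger pseudocount (one that adds
~1 unit of total mass) flattens the histograms enough to cap attainable
divergences below the published dissimilarity cut, which is why the default
is quadratic in the bin count.

The dissimilarity cut is 4.5 bits, the published operating point for
populations of more than a thousand nuclei.  Scoring against the *inclusive*
population mean bounds any single cell's divergence by log2(n), so at
desk-scale population sizes the cut must be rescaled:
`calibrate_threshold(n) = 4.5 · log2(n) / log2(1000)`.  At n = 20 this gives
~1.9 bits; planted inverted-texture nuclei score ~2.2–2.6 bits while normal
nuclei stay below ~1.1, so the filter separates cleanly.  M-phase-like
figures need no dedicated detector: a compact, uniformly bright body has a
codistribution far from any interphase reference and is flagged by the same
cut.

## Topological voxel analysis

Nuclei are partitioned into cubes of 500 nm per side (set by the resolution
limit of the modeled imaging system; at the nominal pitch one cube is
5 × 5 × 2 pixels).  The lattice is anchored at each ROI's bounding-box
corner, making features translation invariant; partial boundary cubes are
retained and weighted by their occupancy, since discarding them would bias
against the nuclear periphery.  Per cube:

* `cond` = mean DAPI intensity / per-image robust scale, clipped to [0, 1];
* `meth` = the same for MeC;
* `assoc` = fraction of the cube's pixels whose channels agree in
  thresholded state (both-low or both-high).  A cube entirely low (or high)
  in both channels scores 1: the degenerate case is continuous with the
  generic one.

The robust scale is the 99.5th percentile of within-ROI intensities per
channel (the maximum is fragile to hot pixels at 12 bits); the low-intensity
thresholds for `assoc`, LID% and LIM% are per-image Otsu cuts on the pooled
within-ROI sample, shared by all nuclei of a field so per-nucleus values are
comparable.  Computing thresholds per image (rather than per experiment) is
a choice; both are exposed in the configuration.

Per-nucleus scalars are occupancy-weighted means of the per-cube values.
Radial topology uses the normalized position r of each cube: distance from
the ROI centroid to the cube's occupied-pixel centroid, divided by the
centroid-to-surface distance *along the same ray* (a plain centroid distance
would conflate ellipsoidal shape with topology), clipped to [0, 1].  The ray
is marched in steps of half the smallest pixel pitch; the surface is the
first step outside the ROI mask.  Profiles are occupancy-weighted shell
means over equal-width r-shells; empty shells are reported as missing, and
across-population dispersion (per-shell mean, SD, CV) ignores them.

## Population statistics

Growth rate is the inverse population doubling time, with growth-arrested
(senescent) samples at rate 0 — the natural zero of an inverse-doubling-time
axis.  Correlations are Pearson r on sample-level means (doubling time is a
sample-level quantity; per-cell weighting is exposed as an option but not
default).  Trends are fitted with a four-parameter logistic
y = L/(1 + exp(−k(x − x₀))) + b by multi-start least squares.  Model
selection fits linear, logarithmic, quadratic, exponential and logistic
candidates, compares complexity tiers by extra-sum-of-squares F-tests at
α = 0.05, and breaks ties within a tier (non-nested, equally complex models)
by AICc.  Group contrasts use Welch's t-test, since population tables are
plainly heteroscedastic.

## The phantom generator

Phantoms emulate fields of interphase nuclei: non-overlapping ellipsoids
(rejection-sampled placement), a latent smooth texture field per nucleus
(Gaussian random field plus `n_foci` heterochromatin bumps) rank-transformed
to quantiles, and per-channel thresholding of a noisy copy of that field —
the top `cond_level` quantile fraction becomes condensed (high-DAPI)
chromatin and the top `mec_level` fraction methylated (high-MeC) chromatin.
The latent-field correlation between channels defaults to 0.95: methylated
DNA is a subset of the DNA DAPI stains, so the signals colocalize strongly;
this puts measured `assoc` in the 0.75–0.88 range typical of real
populations.  Fields are degraded by anisotropic Gaussian blur (approximate
confocal PSF; 200/200/350 nm defaults), Poisson shot noise plus Gaussian
read noise, and 12-bit quantization.

Phenotype presets encode the growth-behavior scheme the pipeline is meant to
recover: `mec_level`/`cond_level` order senescent < cancer < proliferating,
and senescent nuclei are enlarged (~1.7× volume).  A G2-phase mimic enlarges
nuclei by 1.8× in volume at identical texture statistics — G2 nuclei hold
twice the DNA but pack it into less than twice the volume (synchronized
populations show ratios around 1.6–1.8×).  Planted outliers come in two
modes: `mitotic-compact` (a compact, uniformly bright-DAPI body at ~45% of
the original volume) and `inverted-texture` (MeC inverted about its local
midrange, flipping the joint histogram onto the anti-diagonal).

The texture contrast between condensed and open chromatin is 2:1.  This is
deliberately conservative: it guarantees that the global Otsu threshold
lands on the background/nucleus split rather than inside the intra-nuclear
bimodal histogram.  A consequence is that absolute `cond`/`meth` values sit
higher than real-data tables; the phantoms are calibrated to preserve
*orderings and invariances*, not absolute feature values, and all benchmark
claims are of that form.

### What the phantoms do not model

Senescence-associated heterochromatin foci morphology, photobleaching, tile
overlap and stitching, chromatic shift between channels, and depth-dependent
attenuation.  Passing benchmarks therefore show that the pipeline recovers
planted orderings, volumes and outliers under confocal-like blur and noise —
not that it reproduces any specific instrument's absolute feature scales.

## Problem sizes and numerical checks

Tests and the acceptance script run at a 2×-binned geometry (voxel
240 × 240 × 500 nm, nuclear radii ~1.8–2.8 µm, 10–50 nuclei per field,
up to 30 nuclei per group), chosen so the whole benchmark suite completes in
a few minutes on one CPU; every property checked (partition conservation,
orderings, divergence separation, fit recovery) is scale-free.  Flatness of
radial profiles on uniform phantoms is judged by a chi-square test over
shells against the pixel-level sampling error (p > 0.01), the statistically
correct reading of "flat within sampling error" for multiple shells.
Degenerate inputs are handled explicitly: constant images raise (no
threshold separable), constant responses return fits flagged degenerate
(slope unidentifiable), empty masks give empty seed lists, and empty
histogram shells are missing rather than zero.

## Known limitations

* The seeded watershed uses the unmodified inverse-distance-transform relief;
  intensity-based reliefs are accepted by the interface but not default.
* `assoc` is a thresholded-state agreement fraction, not a Pearson/Manders
  colocalization coefficient; the two need not agree numerically.
* The K-L dissimilarity cut is binning-dependent; 4.5 is honored as the
  default for large populations, with the log2(n) rescaling for small ones.
* Fields of view are analyzed independently and pooled; tile stitching is
  out of scope.
* Ki-67 is carried only as a qualitative annotation; its intensities are not
  quantified.
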