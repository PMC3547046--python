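# Methods

This note documents the models, conventions and numerical choices behind
`cellcov`, and what the synthetic benchmark does and does not demonstrate.

## Dual-tree complex wavelet transform

The transform runs four separable real wavelet decompositions in parallel,
one per combination of a "tree a" and a "tree b" filter chain along each
image axis. At level 1 both trees share one odd-length biorthogonal
analysis pair — the standard CDF 9/7 filters, shipped as plain text in
`src/cellcov/data/filters.txt` — and tree b is realised as the one-sample
translate of tree a by taking the odd sample phase of an undecimated
filtering (one input sample = half an output sample after decimation). At
levels ≥ 2, tree a uses Kingsbury's 14-tap orthonormal quarter-shift
lowpass (group delay a quarter sample before centre) and tree b its time
reverse, so the two lowpass chains stay offset by half a sample at every
scale; highpass filters follow by quadrature mirroring. The printed
coefficients are projected onto exact DC constraints at load time
(`sum h0 = √2`, `H0(π) = 0`, `sum h1 = 0`), a ~1e−9 per-tap adjustment
that removes spurious detail response on flat regions while leaving the
orthonormality residual at the 1e−8 level of the published precision.

Corresponding detail bands of the four trees are recombined as
z₁ = ((aa − bb) + j(ab + ba))/2 and z₂ = ((aa + bb) + j(ba − ab))/2, each
selecting one half of the 2-D frequency plane. Band order is fixed as
(+15°, +45°, +75°, −75°, −45°, −15°); the labels were pinned empirically
with sinusoidal grating probes (the test suite asserts that a grating at
each nominal orientation excites its band most). Level-2 magnitudes are
used as features: they are closer to an analytic (one-sided) response
than level 1 and therefore more shift-stable; the suite quantifies this
against a critically-sampled single-tree baseline built from the same
filters (relative magnitude change under a 1-pixel shift must be under
half the baseline's, and measures ~0.1–0.48×).

Boundaries use symmetric (mirror) extension everywhere. Odd-sized inputs
are symmetrically padded to even size before each decimation, so a
level-ℓ band has shape ⌈shape/2^ℓ⌉; the classification pipeline crops
images to a multiple of 4 beforehand, making the averaged grid exactly
shape/4. The averaged image is the tree-a/tree-a approximation divided by
the filter chain's DC gain, so a constant image c maps to constant c. No
inverse transform is implemented; classification never needs one.

## Directional difference scores

For pixel p, radius k and orientation α, the score ingredient is
f(p) − f(p_k) with p_k = (row − k sin α, col + k cos α) rounded to the
nearest pixel; rows grow downward, so positive α walks counter-clockwise
on the displayed image. Conventions fixed package-wide:

* sign is centre minus ring point (the opposite choice flips feature
  signs, which the correlation normalisation absorbs);
* ring radii are the integers k = 1…L with L = 5 by default;
* nearest-pixel rounding rather than interpolation — at 45° multiples the
  offsets are near-integers, and rounding keeps the statistic exactly
  reproducible by the brute-force enumeration oracle used in the tests;
* 8 orientations at 45° spacing over the full circle (differences are
  signed, so α and α + 180° are distinct);
* score planes are defined at every pixel by mirror-extending the image,
  keeping them the same size as the averaged image.

The aggregator (median / max / mean over the L ring differences) is what
distinguishes the F1 / F2 / F3 feature mappings.

## Covariance descriptors

Per-pixel features are stacked as [I_avg, six |w| magnitudes, eight
scores] (d = 15) or, for the classical F4 mapping, [I, |∂I/∂x|, |∂I/∂y|,
|∂²I/∂x²|, |∂²I/∂y²|] via central differences (d = 5). Pixel coordinates
are deliberately excluded: subwindows are sampled across the image, so
absolute position carries no class information here.

The window descriptor is the sample covariance with divisor n − 1. The
normalised variant divides off-diagonal entries by the product of the two
standard deviations (entries with variance below ε = 1e−12 are zeroed
instead) and *keeps raw variances on the diagonal*, so the diagonal-only
ablation — feeding the SVM variance values alone — remains meaningful.
Matrices are vectorised to the upper triangle in row-major order.
Descriptor vectors are z-scored per dimension before the SVM, with
statistics from the training folds only: RBF kernels on features spanning
orders of magnitude (intensities ~1e−1, score variances ~1e−4) otherwise
collapse to a few dominant coordinates.

## Segmentation and sampling

Pixel intensities are modelled as a two-component 1-D Gaussian mixture
fitted by EM, written out explicitly so the per-iteration log-likelihood
trajectory is available (monotonicity is asserted in tests).
Initialisation is a deterministic split at the intensity median with
equal weights; variances are floored at 1e−8; iteration stops when the
per-sample log-likelihood improves by less than 1e−6 (default) or after
200 iterations. Images above 10⁶ pixels are subsampled (seeded) for
fitting. The larger-variance component is the foreground — cell pixels
scatter both above and below the background level, so a threshold on the
mean would fail. The mask is refined by binary closing (square element,
default 5) then median filtering (default 9); kernel sizes can be chosen
by maximising contrast − λ·uniformity (inter-region contrast in pooled
standard deviations, minus the pixel-weighted within-region variance
fraction, λ = 1) over a candidate grid — an explicit, swappable stand-in
for classic segmentation-quality scores. The full-resolution mask is
reduced to the averaged grid by a ≥50% vote over 4×4 blocks.

Subwindows are drawn by rejection sampling with uniform top-left
proposals (windows may overlap): accept iff foreground fraction > 0.5 and
window intensity variance > whole-image variance, both evaluated on the
averaged image — the raster actually being classified. Integral images
make each proposal O(1); the default budget is 10 000·N proposals, and
exhaustion raises an error carrying the observed acceptance rate.
Defaults: N = 20 windows of 32×32 grid pixels (≈128 px at full
resolution).

## Classification protocol

One-vs-one multiclass SVM with RBF kernel (scikit-learn's SVC), C = 10
and γ = 1/d by default — dataset-scale-dependent values that live in
`RunConfig` and are embedded in every persisted model and report. An
image's voted label is the mode of its N subwindow predictions; ties are
broken by the larger per-class decision score summed over the image's
vectors, then lexicographically. Cross-validation is
leave-one-image-per-class: K balanced folds, fold i testing on the i-th
image (manifest order) of every class; standardisation and SVM fitting
never see test-fold vectors. Per-image sampling seeds derive from the run
seed and a CRC of the image identifier, so entire experiments are
reproducible bit-for-bit from (manifest, config).

## The synthetic benchmark

The generator emulates the structure this pipeline targets: a bright,
nearly flat background (mean 0.85); darker foreground blobs (mean 0.5) —
round discs or elongated bars covering ~55% of the frame; oriented
sinusoidal texture inside the blobs with a high-frequency carrier (0.18
cycles/px, tuned to the level-2 wavelet band) plus a low-frequency
component (carrier/4.5, which survives the 4× averaging and drives the
directional scores); Gaussian pixel noise (σ = 0.04). Nuisance variation
mimics real acquisition: per-image contrast (±15%) and frequency (±8%)
jitter, and per-blob contrast jitter (0.6–1.35×) standing in for local
density and focal-depth variation. Images are 512×512 so an analysis
window covers ~1/16 of the frame, and blob sizes are fixed in absolute
pixels — bigger frames contain more cells, as micrographs do — so a
window always straddles several cells. With these conditions the
foreground/background mean gap (0.35) is far above the 3×noise floor the
generator enforces, and EM segmentation reaches IoU ≈ 0.95+ against the
generated truth masks.

The four default classes are designed to probe specific parts of the
descriptor:

* two single-orientation round-blob classes at +30° and −30° — a mirror
  pair that absolute axis-aligned derivative statistics (mapping F4)
  provably cannot distinguish, while the oriented wavelet bands can;
* a moment-matched pair at 45°/135° with elongated blobs: in the "plaid"
  class half the blobs carry both orientations superimposed and half are
  smooth; in the "mixed" class every blob carries exactly one of the two
  orientations. Each oriented component is then "on" in half the blobs at
  the same amplitude in both classes, so every per-feature variance has
  the same distribution — but the two diagonal wavelet magnitudes
  co-occur in one class and exclude each other in the other, flipping the
  sign of their spatial correlation. Only the covariance structure
  separates this pair, which is what makes the diagonal-only ablation
  land strictly below the full descriptor. Cell axes split evenly between
  the two orientations in both classes so blob-edge energy is
  class-neutral; in the mixed class the texture runs along the cell axis.

An orientation-free control spec provides two isotropic-texture classes
(ring-spectrum noise at 0.02 vs 0.08 cycles/px) that differ only in
texture frequency, where the classical derivative mapping suffices.

What passing the benchmark does **not** show: robustness to uneven
illumination, optics (defocus blur, vignetting), staining variation,
cell-density extremes, or morphologies whose discriminative signal is not
oriented texture. The generator renders stylised geometry, not cells; the
end-to-end numbers certify that the pipeline's machinery — transform,
scores, descriptors, segmentation, sampling, voting, protocol — extracts
exactly the signals it claims to, under realistic nuisance variation, not
that real cell lines are classifiable at any particular accuracy.

## Problem sizes and runtime

The shipped experiments use sizes chosen to keep a full run on one CPU
core in the low minutes: the default benchmark is 4 classes × 10 images
of 512×512 (leave-one-image-per-class → 10 folds; ~10 s per
configuration after ~15 s of rendering), unit fixtures are 32×32–384×384,
and the brute-force oracle comparisons run on fifty 32×32 images. The
acceptance script completes in a few seconds.

## Known limitations

* The forward transform only; no reconstruction.
* Segmentation is global two-class; confluent images with no visible
  background violate its model (and the sampler's foreground constraint
  becomes vacuous).
* The quarter-shift filter set is fixed at 14 taps; the data-file format
  accepts alternative sets but none are bundled.
* `select_kernels` scores candidates on a single image; per-dataset
  kernel selection is left to the caller.
* Windows are square and axis-aligned; no rotation-invariant pooling.
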