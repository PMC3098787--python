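# Methods

This note records the models, parameter choices, numerical conventions, and
known limitations of the package, in the order the pipeline applies them.

## Gray-level co-occurrence features

Images are quantized per image by a linear min-max map onto `G = 32` gray
levels (configurable). Per-image quantization makes the descriptor invariant
to global exposure and staining offsets; the cost is that absolute intensity
information is discarded, which is intended for texture description.
A constant image quantizes to all zeros.

Co-occurrence counting is *ordered* (no symmetrization): `counts[i, j]`
counts pixels with value `i` whose neighbour at displacement `(dx, dy)`
holds `j`, with out-of-bounds pairs skipped, so the total equals
`(W - |dx|) (H - |dy|)`. The descriptor is therefore sensitive to rotations
other than 180 degrees, which is deliberate. Displacements for the polar
offset grid use nearest-integer rounding (ties to even) of
`(r cos(theta), r sin(theta))`; at 45 degrees the distances 1..4 map to
(1,1), (1,1), (2,2), (3,3) — the duplicate at distance 2 is an accepted
consequence of grid rounding and keeps the 16-offset layout uniform.

Twelve statistics are computed per normalized matrix, in a fixed documented
order (energy, entropy, contrast, correlation, variance, homogeneity, sum
variance, sum entropy, difference variance, cluster prominence, cluster
shade, inverse difference normalized). Conventions:

- entropies are in bits; `0 * log 0 := 0`;
- correlation is 0 when a marginal standard deviation vanishes;
- "variance" is the sum-of-squares form `sum (i - mu_x)^2 p(i,j)`;
- sum variance is the second moment of `p_{x+y}` about the *sum average*
  (the classical formula's reference to sum entropy is treated as a typo,
  following common practice);
- the inverse difference normalized (INN) form `sum p / (1 + |i-j|/G)` is
  included rather than the plain inverse difference; the statistic set is a
  configurable argument because the canonical 12-of-13 choice is a
  convention, not a mathematical necessity.

## Daubechies and Gabor descriptors

The wavelet block uses the four-tap Daubechies filter (`db2` in PyWavelets,
i.e. D4) with symmetric (half-sample) boundary extension, two decomposition
levels, and reports (mean, std) of each of the six detail matrices. The
decomposition is exactly invertible; symmetric extension avoids boundary
artifacts leaking into the statistics.

Gabor kernels come from `skimage.filters.gabor_kernel` with bandwidth 1.
Orientations are `k pi / 6`, `k = 0..5`; frequencies start at 0.25
cycles/pixel and halve per scale (0.25, 0.125, 0.0625, 0.03125). These
values are package defaults (the source method states the bank size but not
the frequency ladder). Each kernel is DC-corrected (mean subtracted) so
response magnitudes ignore the absolute intensity level. The image is split
into a 4 x 5 grid of non-overlapping cells (remainder pixels join the last
cell); per cell and kernel the (mean, std) of the response magnitude is
reported, 960 values in total. The 4 x 5 grid is the reading consistent
with the printed 4 x 5 x 48 = 960 dimension; the grid is configurable.

## Curvelet transform

The forward transform follows the wrapping construction: FFT of the image,
multiplication by a smooth scale/angle window per wedge, wrapping of each
windowed wedge onto a small rectangle, inverse FFT per wedge.

Window design is the load-bearing choice. Scales are square concentric
coronae measured by `r = 2 max(|xi_1|, |xi_2|)` (normalized frequencies), so
dyadic cutoffs `rho_j = 2^{-(nscales - j)}` tile the plane out to the grid
corners. Radial and angular profiles are Meyer-style: transition ramps use
the polynomial `nu(t) = t^4 (35 - 84 t + 70 t^2 - 20 t^3)` inside sine and
cosine half-windows, so adjacent windows satisfy `sin^2 + cos^2 = 1`
pointwise and the squares of all windows sum to exactly 1 over the whole
frequency plane. That admissibility identity is what makes the frame tight;
it is asserted directly by a test, and the measured round-trip and Parseval
errors are ~1e-15, far inside the 1e-6 contract.

Angle counts double every second scale toward the fine end
(`nangles_coarse * 2^((j-1)//2)`), the coarsest scale is one low-pass
subband, and by default the finest scale is a single isotropic wavelet-type
subband (required to obtain the 1+16+32+32+1 = 82 layout; a full curvelet
finest ring is also available). Wedge orientation is indexed
counterclockwise from the positive horizontal frequency axis.

Wrapping is implemented as extraction of the minimal rectangle enclosing a
wedge's frequency support. Tile side lengths are rounded up to a divisor of
the grid size whenever that costs at most a factor of two; on dyadic grids
a spatial translation by a whole number of tile-grid periods is then an
exact circular shift of each subband's coefficients, so per-subband mean
magnitudes are exactly translation-invariant for such shifts (tested at
machine precision). On sizes without usable divisors (e.g. prime 373) the
tight support is kept and this invariance is only approximate; the
reconstruction and energy identities are unaffected.

For real images the transform stays real: opposite wedges carry conjugate
information, so each pair is stored as `sqrt(2) Re` and `sqrt(2) Im` of one
complex wedge. This preserves subband count, energy, and invertibility.
Nyquist rows/columns of even-sized grids are self-conjugate; angular
windows are explicitly symmetrized there so the pairing is exact.

Subband statistics are computed on coefficient *magnitudes* (wedge
coefficients are near zero-mean signed values, so signed means carry almost
no information). Eight statistics are supported (mean, std, norm, energy,
variance, skewness, kurtosis, entropy), emitted subband-major in a fixed
canonical order. Entropy uses the squared-coefficient distribution
(`p_i = c_i^2 / sum c^2`, `0 log 0 := 0`, all-zero subband -> 0); skewness
and kurtosis are standardized central moments (kurtosis non-excess), defined
as 0 for constant subbands; "variance" is the sample variance of the
magnitudes (i.e. std squared).

## Fusion and normalization

Per-feature min/max is fitted on the training rows only and applied as an
affine map onto [-1, 1]; constant training columns map to 0; test values
outside the training range are not clipped (clipping would destroy ordering
information and anything else would leak test statistics into
preprocessing). Blocks are concatenated in the given order with
block-qualified column names; the default combined descriptor
GLCM + curvelet(mean, std, entropy) is 192 + 246 = 438-dimensional.

## Random-subspace ensemble

The subspace dimensionality is `M = rint(fraction * d)` with ties rounded
to even (this reproduces 241, 350, 328, and 372 for the 438-dim space at
55/80/75/85 %; half-up rounding would give 329 at 75 %). Each of the `L`
members draws `M` distinct feature indices uniformly; features may recur
across members. Member hidden widths are drawn uniformly from 30..50
(inclusive) for diversity; the single-network baseline uses 20 hidden
units.

The base classifier is a single-hidden-layer perceptron with logistic
hidden units and one output per class (`sklearn` MLPClassifier), trained
full-batch with L-BFGS for at most 500 iterations. L-BFGS is this package's
optimizer choice: a quasi-Newton batch method in the same family as
conjugate-gradient training and the closest available contract match.

Voting is by hard member labels; ties are broken by the larger summed
member probability among tied labels, then by the smallest class index, so
runs are deterministic. A master seed expands through
`numpy.random.SeedSequence` into per-run and per-member child seeds:
identical seeds give bit-identical reports, while members and runs stay
statistically independent.

Evaluation is repeated stratified holdout: per class,
`floor(n * test_fraction)` samples (at least 1) are held out; a *fresh*
ensemble — new subspaces, new member seeds — is trained per run; the
row-normalized confusion matrix (percent) and accuracy are averaged over
runs (default 100; the bundled tests use 10 to keep runtimes in seconds).

## Synthetic data

The generator emulates multi-class texture datasets in which classes differ
by orientation, spatial frequency, and second-order statistics — exactly the
axes the GLCM and curvelet blocks measure. Each image sums an oriented
sinusoidal grating (amplitude 1, random phase per image), a unit-variance
`1/f^beta` random field (amplitude 0.6), Gaussian blobs with sigma 2-5 px at
a Poisson density (amplitude 1.2), and Gaussian pixel noise, then maps to
8-bit by per-image min-max. Default recipes use 5 classes with orientations
`c pi / 5`, frequencies geometric from 0.06 to 0.16 cycles/pixel, spectral
slopes 1.0-2.0, blob densities 2e-4 to 8e-4 per pixel, and noise sigma 0.05.
These defaults are intentionally easy — classes are well separated in both
feature families — so end-to-end tests exercise the machinery, not the
difficulty of the problem.

What passing on this data does *not* show: robustness to intra-class
morphological variability, uneven illumination, debris/artifacts, class
imbalance, or subtle inter-class similarity, all of which real microscopy
benchmarks contain. Accuracies on the synthetic data are therefore upper
bounds of convenience, not performance claims about real datasets.

## Degenerate inputs and numerical conventions

- Constant images: quantize to zeros; all GLCM mass at (0, 0); wavelet and
  DC-corrected Gabor features vanish; curvelet detail subbands vanish.
- All-zero subbands/columns: statistics and normalized values are defined
  as 0 rather than NaN.
- Images must be at least 5x5 for GLCM, 8 per side for the wavelet block,
  and `2^nscales` per side (minimum 8) for the curvelet geometry.
- Feature CSVs are written with 12 significant digits; configs and
  evaluation reports are JSON with rejected unknown keys.

## Problem sizes used in bundled checks

Unit and property tests run on 8x8 to 512x512 rasters; the end-to-end
pipeline check uses the default synthetic dataset (5 classes x 20 images of
256 x 256), a 5-member ensemble at 80 % subspace fraction, and 10 holdout
runs; the structural subband count is computed on a 1024 x 1024 random
image. These sizes were chosen so the whole suite completes in well under a
minute of compute per heavy test while still covering odd, non-square, and
large-image code paths.
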