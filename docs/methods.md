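# Methods

This note documents the models and numerical choices behind `colonymorph`,
what the synthetic-data generator does and does not emulate, and the known
limitations of each stage.

## Colony segmentation

**Model.** Phase-contrast colonies are distinguished from their background
by oriented texture rather than by intensity: single-point thresholding
fails because the intensity histograms of colony and background overlap
heavily. The texture operator is a Gabor filter bank derived from a mother
filter — a Gaussian-windowed complex exponential with center frequency
`U_h` — by rotation (K orientations, `θ_n = nπ/K`) and scaling (S scales,
factor `a = (U_h/U_l)^(1/(S−1))`, so center frequencies run geometrically
from `U_h` down to `U_l`). The Gaussian widths follow the minimal-redundancy
design in which adjacent half-peak magnitude iso-curves in the frequency
plane are tangent:

    σ_u = (a − 1) U_h / ((a + 1) √(2 ln 2))
    σ_v = tan(π/2K) · (U_h − 2 ln 2 · σ_u²/U_h) / √(2 ln 2 − (2 ln 2 σ_u/U_h)²)

Summing the K rotated filters at each scale gives one approximately
rotation-invariant complex kernel per scale (adjacent scales' half-peak
radii coincide exactly by construction; the tests verify this to 1%).
Each kernel is made exactly zero-mean so constant images produce zero
response. The per-pixel moduli of the S filtered images (reflection
boundary handling) form the texture feature vector.

**Parameters.** Defaults: `S = 4`, `K = 6`, `U_l = 0.05`, `U_h = 0.4`
cycles/pixel, kernel radius `⌈3/U_l⌉ = 60` px. The frequency band spans the
texture scales of colonies imaged at 10×; kernel support covers three
periods of the lowest-frequency filter.

**Angular ripple.** The tangency design at K = 6 leaves a measurable
orientation ripple: the coefficient of variation of the accumulated
frequency-magnitude gain over angle at each scale's center radius is 0.052
(computed analytically from the Gaussian-bump sum; the bank stores a 0.06
tolerance and refuses designs worse than that). A further consequence of
accumulating complex filters over the half-plane `[0, π)` is that the
*pointwise* response magnitude is only approximately covariant under image
rotation: for textures oriented near the accumulation boundary, the
response to a real sinusoid splits between conjugate frequency pairs and
beats spatially. Magnitude statistics and the resulting masks are
insensitive to this (rotating an image by 90° changes the segmented mask on
~0.3% of pixels, all at the colony boundary).

**Foreground/background delineation.** Two-class K-means over the per-pixel
S-vectors, with centroids initialized at the per-dimension lowest and
highest responses (deterministic — no random restarts are needed or used).
The cluster with the larger centroid norm is foreground. Because two-class
K-means always splits *something*, a texture-free image would yield an
arbitrary ~50/50 split; segmentation therefore declares the foreground
empty when the centroid-norm ratio falls below `min_contrast = 3.0`.
On the fixture suite the ratio is ~1.5 for background-only images and
10–12 for colony images of either polarity, so the guard has wide margins
on both sides. Masks are cleaned by morphological closing (radius 2 px) and
hole filling; colonies are 8-connected components of at least
`min_area = 200` px (excludes single-cell debris at 10×).

**Limitations.** Touching colonies are not separated (no watershed); masks
inherit a boundary halo of roughly the spatial support of the
strongest-responding scale, which caps fixture IoU at ~0.85–0.93.

## Morphometric fingerprint

Each colony is represented by log10 area plus the magnitudes of 32 Zernike
moments (Teague's discrete formulation) of the gradient-magnitude image:
the colony centroid maps to the disk center and the minimal enclosing
radius to ρ = 1, making the fingerprint translation invariant; moment
magnitudes add rotation invariance; the gradient (3×3 central differences)
adds contrast-reversal and shading invariance; normalizing by `|A_00|`
removes overall contrast and bounds the features.

The default moment set is all valid (n, m) pairs with 2 ≤ n ≤ 9 plus
(10,0), (10,2), (10,4), (10,6) — 32 magnitudes, hence a 33-dimensional
vector with size. (0,0) and (1,1) are excluded as degenerate after
normalization and centering. The sampled polynomials are orthogonal to
within 2% (diagonal-normalized Gram) for disks of radius ≥ 64 px.

Numerical notes: rotation invariance of the discrete moments is limited by
rim discretization — the radial polynomials all peak at ρ = 1, so
fields with substantial mass at the enclosing radius drift by several
percent under rotation while rim-tapered fields (the realistic case for
gradient content, which decays toward the enclosing circle) drift by
< 0.2%. Moments are reported unnormalized complex internally; only
magnitudes enter the fingerprint. Border-touching regions are fingerprinted
but flagged as possibly truncated.

## Consensus clustering of cell lines

Lines contribute unequal numbers of heterogeneous colonies, so line
similarity is measured on equal-size resamples: per iteration, 6 colonies
per line are drawn without replacement, pooled (features z-scored within
the pool), k-means clustered (10 restarts from the iteration's RNG
stream), and each pair of lines is scored by the exact two-sample
Kolmogorov–Smirnov p-value between their cluster-label samples. Cluster
labels are nominal; they are canonicalized per iteration by sorting
clusters by centroid norm (descending) so runs are reproducible. (The KS
statistic on categorical labels is order-sensitive; the canonical order is
a documented convention, and users comparing against other conventions
should expect somewhat different consensus values but the same block
structure.) The consensus matrix is the element-wise mean (median
available) over 100 iterations, with unit diagonal.

The exact KS tail `P(D ≥ d)` is computed by lattice-path counting over all
interleavings (exact integer arithmetic, cached on the integer deviation),
used for samples up to 12 per side; larger samples fall back to the
asymptotic approximation.

**Model selection.** For each k in 2…7 the empirical CDF of off-diagonal
consensus entries is summarized by its area A(k) (equal to `1 − mean` for
entries in [0, 1]); the proportional increase is Δ(2) = A(2) and
Δ(k) = (A(k) − A(k−1))/A(k−1). The selected k\* is the argmax of Δ over
k ≥ 3 when that peak exceeds 0.02 (a declared, configurable threshold);
otherwise 2. If the consensus distribution is literally identical across k,
no structure is detected and k\* is None with a warning. The final
partition cuts an average-linkage dendrogram of `1 − consensus` at k\*,
which also provides the heat-map ordering.

## Molecular association

**Replicates** are collapsed to one column per line by mean (default) or
median before any screen.

**Cluster discrimination.** One-vs-rest moderated t: per-gene pooled
variances `s_g²` (d_g df) are shrunk toward an empirical-Bayes scaled
inverse-chi-square prior `(d0, s0²)` fitted across genes by moment matching
on log variances (digamma/trigamma closed forms; trigamma inverted by
Newton iteration). Posterior variances are
`(d0·s0² + d_g·s_g²)/(d0 + d_g)`; p-values use d0 + d_g df (normal when d0
is infinite); BH FDR follows. Setting d0 = 0 recovers the ordinary t-test;
d0 = ∞ shrinks every variance to the prior, in which case genes order by
|group-mean difference|. The estimator is cross-checked against the
reference R implementation in the test suite. Default report threshold for
differential tables: FDR < 0.001.

**Feature regression.** The per-line morphological feature is the median
(configurable to mean) of the line's colony fingerprints; size
(log10 area) is the default feature. The linear screen uses Pearson r
(signed square root of the coefficient of determination of the
least-squares line). The logistic screen min-max normalizes the feature
into (ε, 1−ε) with ε = 10⁻³, applies z = logit(y), and correlates
expression with z; an exact logistic relationship yields r = 1.

**Permutation p-values.** The feature-to-line assignment is shuffled
M = 10,000 times (exchangeable null); each gene's p counts permuted
correlations at least as extreme as the observed one *in the direction of
the observed sign* (ties count, with a 10⁻¹² float tolerance; the literal
count is stored, and p below 1/M is additionally flagged). BH adjustment
is applied within each sign taxonomy; default report threshold FDR < 0.05.

Because the one-sided direction is chosen from the observed correlation,
the null rejection rate at nominal level α is 2α (the taxonomy p-value is
Uniform(0, ½) under the null, measured 0.10 at α = 0.05 on 10,000 null
genes). This selection effect is intrinsic to the sign-taxonomy
construction; rankings within a taxonomy, the permutation floor 1/M, and
BH ordering are unaffected, but the raw taxonomy p should not be read as a
calibrated two-sided p.

## Synthetic data generator

The generator defines the study conditions used by every end-to-end test:
24 lines split evenly over three archetypes, 12 colonies per line, 224²
images, 1000 genes.

- **Geometry.** Round: disk with low-order Fourier radius perturbation
  (solidity > 0.9). Grape-like: 5 overlapping lobes on a ring plus a
  connecting core (single connected component). Stellate: core disk with 6
  tapering radial processes. Mean radii 32/40/48 px with a per-line size
  factor U(0.85, 1.15) and per-colony jitter, so colony size varies both
  within and between lines.
- **Appearance.** Interiors carry band-limited oriented noise (0.18
  cycles/px, random orientation per colony) with amplitude 0.35×
  `texture_amplitude` plus a small mean offset (0.15×), on a background of
  mid-gray, low-frequency shading and pixel noise (sd 0.02). The offset is
  small relative to the texture swing, so thresholding fails but the
  intensity ordering between colony and background is well defined.
  Polarity is an exact negation about mid-gray: identical truth masks,
  reversed intensity ordering.
- **Expression.** RMA-like log2 scale: per-gene baseline N(7, 1), line
  noise sd 0.25. Twenty genes are shifted by +2.0 in the stellate group;
  five genes are linear in per-line median log10 colony size and five are
  linear in the logit of the min-max-normalized size (generated on
  (0.05, 0.95) so the analysis-side ε-clipping at the extremes is a modest,
  realistic mismatch). With zero noise the linear link yields r = 1
  exactly.

What the generator does **not** emulate: phase-contrast optics (halos,
shade-off), touching or overlapping colonies, uneven illumination beyond
smooth shading, probe-level microarray artifacts, or correlated gene
modules. Passing end-to-end tests therefore demonstrates that the chain
recovers planted structure under controlled conditions, not that it is
robust to every artifact of real cultures.

## Problem sizes and determinism

End-to-end checks run the default study (288 images, 224², 6 consensus
sweeps × 100 iterations) per seed; the acceptance script runs five seeds
with M = 2000 permutations per association screen, about 8 minutes on one
CPU. All randomness flows from explicit seeds through
`numpy.random.Generator`; identical configuration and seed reproduce
byte-identical CSV artifacts.
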