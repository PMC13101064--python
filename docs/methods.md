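# Methods

This note documents the models, conventions and design choices behind
`mpmtex`, in the spirit of a methods appendix: what is computed, under what
assumptions, with which defaults, and what the synthetic phantoms do and do
not establish about real tissue.

## Synthetic tissue phantoms

The generator emulates the structure of a two-preparation MPM cohort of
pancreatic tissue, not its optics. Per channel it renders a noiseless
full-field "truth" image and then cuts it into tile z-stacks with
acquisition artifacts.

**Texture model.** Autofluorescence channels (NADH, FAD, lipofuscin,
porphyrin) are fields of Gaussian blobs (cellular fluorescence): blob
centers uniform at `blob_density` = 800 per megapixel, amplitudes
`blob_intensity` × U(0.5, 1.5) counts with σ = 3 px. The SHG channel is a
field of straight fiber segments (collagen): `fiber_density` = 120 per
megapixel, mean length 80 px, Gaussian cross-section σ = 2 px, amplitude
`fiber_intensity` = 9000 counts. Class contrast enters only through
multiplicative effects, reflecting the dominant visible difference between
tumor and normal tissue in this setting — collagen density and brightness:
tumors get `tumor_shg_density_mult` = 2.0 and
`tumor_shg_brightness_mult` = 1.5 on the SHG channel and a blob-size shift
(`tumor_blob_sigma_mult` = 1.25) in the autofluorescence channels.
Preparation contrast is a global per-channel brightness multiplier for
fixed-frozen samples (1.5, and 1.8 for SHG, where the preparation
difference is largest); because brightness records are FAD-normalized, the
testable consequence is a ~1.2× higher normalized SHG brightness for
frozen samples. Fixed-frozen samples carry no NADH channel (mounting-medium
fluorescence at that excitation wavelength in the real protocol); the rule
is enforced structurally rather than simulated.

**Acquisition artifacts.** Tiles are crops of the truth at known grid
positions (13×13, 256 px, 10% overlap by default; `overlap_px =
round(0.10·256) = 26`, so the stitched side is 13·256 − 12·26 = 3016 px).
Each of the `n_z` = 5 z-slices gets defocus modeled as Gaussian blur of
1.2·|dz| px and attenuation 1 − 0.15·|dz| (focus at the stack center), a
radial vignette `1 − s·(r/r_corner)²` with s = 0.25, Poisson shot noise and
Gaussian read noise (σ = 30 counts), then rounding and clipping to
[0, 65535]. The vignette field is normalized to mean 1 (a gain convention):
this makes flat-field correction, defined as `tile / (flat / mean(flat))`,
an exact inverse of the vignetting up to rounding, which the tests exploit.
An optional per-sample log-normal gain jitter stands in for the manual
per-channel gain adjustment of the real acquisition; it defaults to off
because its real magnitude is unknowable.

**Determinism.** (design, params, seed) determine every output bit.
Per-sample seeds derive from `SeedSequence([master, index])` over a fixed
cell order, so cohorts are reproducible and order-independent.

**What the phantoms do not show.** No optical PSF, no spectral crosstalk,
no per-site processing variability, and — importantly — much weaker
inter-feature correlation than real tissue produces: on phantom cohorts
the mean-|r| filter at 0.45 typically retains all features (real data shed
roughly 60% of features there). Passing tests on phantoms therefore
validates the machinery and its statistical behavior, not clinical
performance.

## Preprocessing

Assembly follows the acquisition pipeline: per-tile flat-field correction,
stitching of each z-slice at known grid positions, then a per-pixel max
projection. Stitching needs no registration search because tile positions
are exact; overlap strips are blended with complementary linear feather
ramps (weights (k+1)/(ov+1) summing to 1 across the strip), and a
"first-wins" mode provides bit-exact reassembly for round-trip tests.
Brightness is the mean over strictly positive pixels of the stitched
max-projection image (zero = background mask), normalized per sample by
the FAD channel mean, so FAD ≡ 1 and is reported as not-comparable in
group tests. Pseudo-RGB composites min-max rescale each channel over its
nonzero pixels to 8 bits; an all-zero channel stays black. The tile-dataset
export partitions samples (never tiles) into train/validation/test as
floor(0.70·N) / floor(0.15·N) / remainder — remainder-to-test keeps the
held-out set non-empty — crops the duplicated overlap from top/left
interior tile edges, and optionally augments training tiles with their 8
dihedral variants.

## Texture features

Images are linearly quantized to G = 64 equal-width gray levels (configurable;
a 65536² GLCM would be meaningless at these sample sizes). Pixel pairs at
distance 1 are accumulated in both orders for each of the four directions
0°/45°/90°/135°, each directional matrix normalized to sum 1, and the four
averaged — the tissue is treated as rotationally symmetric, and the tests
verify exact invariance of all features under rotations and transposition.
Background zeros are *not* excluded from GLCMs (the zero-mask applies only
to brightness). The 13 Haralick statistics use natural logarithms and
0·log 0 := 0, with fixed degenerate conventions: correlation f3 := 0 when a
marginal σ vanishes; f12 := 0 when max(HX, HY) = 0; f13's exponent argument
is clamped at 0. Two circulating ambiguities are resolved explicitly: sum
variance f7 is computed about the sum average f6 (the classical text prints
f8 there, a known misprint), and difference variance f10 is the variance of
the difference distribution, with an uncentred-moment variant available as
`f10_variant="raw_moment"`. The feature table has width 13 × channels:
65 for the five-channel FFPE arm, 52 for the four-channel combined arm.

## Group statistics

Feature and brightness comparisons use Welch's t-test when **both** groups
pass Shapiro-Wilk at α = 0.05 (the gate is applied per comparison), and a
two-sided Mann-Whitney U test otherwise (scipy's policy: exact for small
untied samples, midrank/continuity-corrected normal approximation
otherwise). Feature p-values are Benjamini-Hochberg adjusted jointly across
the retained features; significance tiers count the thresholds
(0.1, 0.05, 0.02) the adjusted p falls below. Brightness comparisons are
per channel with tighter thresholds (0.05, 0.01, 0.001) and no adjustment;
a channel constant across both groups (FAD by construction) is reported as
not-comparable rather than silently significant.

## Feature selection and LDA

Reduction keeps features whose mean |Pearson r| against all other features
is below 0.45, computed once on the full table; constant features score 1.
An optional cap keeps the lowest-scoring features for scaled-down runs.
Fisher's LDA uses the pooled within-class covariance with equal class
priors and a projected-midpoint threshold (the cohorts are near-balanced);
a ridge of 1e-6·trace(Σ)/d is added only when Σ is singular to working
precision and is recorded on the model. Predictions are exactly invariant
to per-feature affine rescaling, so no standardization is needed (z-scores
are produced only for plotting outputs).

The exhaustive search evaluates every C(F, n) subset by leave-one-out
cross-validation for n = 1…n_max. The LOOCV score of a subset is the
integer count of correctly classified left-out samples, so subset ties are
exact, and the only randomness in the procedure is the uniform seeded
tie-break among maximal subsets. The repeated runs (default 100 per n)
therefore share one deterministic evaluation of all subsets and differ only
in the tie-break — mathematically identical to independently repeating the
full search, and what makes a unique best subset yield a per-run accuracy
standard deviation of exactly 0. Per-(n, run) seeds derive from
`SeedSequence([master, n, run])`. ROC curves per n pool the left-out
discriminant scores of each run's chosen subset across all runs; AUC is the
trapezoidal area, equal to the Mann-Whitney normalization. n_max is a
configuration parameter (5 for the FFPE arm, 6 for the combined arm by
default), not auto-detected from a plateau.

## Problem sizes used in tests and the acceptance script

Tests and `scripts/acceptance.py` keep the full cohort composition
(27/21/7/7) and analysis settings but scale the image geometry to 2×2
grids of 64–128-px tiles with 1–2 z-slices, and cap retained features at
the 12 lowest mean-|r| scores with n_max = 3 for the subset search; with
the generator defaults this reproduces the qualitative headline behavior
(SHG-channel features dominate selection, accuracy near-perfect by n = 3,
accuracy monotone in the SHG effect size) in minutes on one CPU.

## Known limitations

- Phantom realism is deliberately minimal (straight fibers, isotropic
  blobs, uncorrelated channels); absolute accuracies on phantoms exceed
  what heterogeneous patient tissue yields.
- The exhaustive search is O(C(F, n)·N) model fits; it is intended for the
  post-reduction regime (F ≈ 23, n ≤ 6), not for wide feature sets.
- Stitching assumes exact stage positions; there is no registration
  fallback for real mosaics with stage drift.
- Mann-Whitney small-sample behavior follows scipy's exact/asymptotic
  switching rather than a fixed n > 20 rule.
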