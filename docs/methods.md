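# Methods

## Filter construction

The 2D Log-Gabor transfer function is assembled on the FFT frequency grid
of the target ROI shape, with per-axis normalized frequencies in
[−0.5, 0.5) and DC at index (0, 0). Radius is `hypot(u, v)` and the polar
angle `atan2(v, u)`; for non-square inputs the per-axis normalization is
kept (all default paths use square 32×32 ROIs, where the distinction is
moot).

Two conventions deserve a note:

* **Radial denominator.** The radial factor is
  `exp(−(ln(r/f₀))² / (2 (ln σᵣ)²))` — the Gaussian-on-log-axis form with
  `ln σᵣ` in the denominator. This is the only reading under which the
  usual bandwidth correspondences hold: the closed form for the
  half-amplitude bandwidth, `2·√(2 ln 2)·|ln σᵣ| / ln 2` octaves, gives
  0.98 octaves at σᵣ = 0.75 and 2.03 at σᵣ = 0.55, which the test suite
  verifies against numeric root finding of the half-amplitude crossings.
* **DC singularity.** The logarithm is undefined at r = 0; the DC bin's
  radius is substituted with a dummy value before the log and the transfer
  forced to exactly 0 there, so the filters have no DC response and
  constant images map to identically zero.

The angular factor wraps its argument through `atan2(sin Δ, cos Δ)` so the
lobe is continuous across ±π. Only one lobe is kept (no symmetrization
about the origin), so spatial responses are complex; all downstream stages
use the real part. No auxiliary low-pass prefilter is applied. Filters are
applied by frequency-domain multiplication — circular convolution, output
shape equals input shape.

**Orientation semantics.** θ₀ is a *wave-vector* angle: a grating whose
wave vector points at θ₀ excites the θ₀ filter maximally. A spatial bar or
vein stroke drawn *along* direction α has its spectral energy concentrated
at wave-vector angle α ± π/2, so stroke orientation α maps to filter
orientation (α + π/2) mod π. The synthetic-data tests encode this
perpendicular relationship explicitly.

## Orientation selection

For each scale independently, every training ROI is filtered by all
candidate orientations and the magnitude (|Re|) responses of all pixels
across all orientation maps are sorted descending; walking that list, a
pixel contributes only at its first appearance, i.e. to the orientation of
its maximum response. This "sorted-walk" statistic equals the per-pixel
argmax histogram, and the suite asserts the equivalence exactly on random
map sets (ties quantized to make the stable tie rule — lowest orientation
index first — actually bite). A variant in which visited entries are
marked per (orientation, pixel) pair was considered and rejected: every
such pair occurs exactly once in the sorted list, so every orientation
would receive the same count and the histogram would carry no information.

Per-image histograms are normalized to sum to 1 before accumulation, so
each training image carries equal weight regardless of its dynamic range.
The per-scale retention counts `n_S` are configuration (default
[2, 7, 7, 2]); the algorithm chooses *which* angles, never how many. Ties
in the final ranking break toward the lower orientation index, making the
selection fully deterministic.

Layer 2 reuses layer 1's selection by default (K₁ = K₂ = 18). An opt-in
`reselect_layer2` flag re-runs the selection over the layer-1 output maps
instead; on the synthetic benchmark the two choices agree on the mid-scale
angle sets (asserted in the suite), and the cheaper default is used
throughout.

## Encoding

The binary-hash layer thresholds each of a parent's K₂ child maps at
strictly-positive (a response of exactly 0 contributes no bit) and packs
the bits with weights 2^(k−1) in layer-2 filter order. With K₂ = 18 a code
map takes values in [0, 2^18 − 1]; histograms are therefore kept sparse
end-to-end (CSR rows; Euclidean distances computed on the sparse
representation without densifying). An optional `hash_group_size` splits
the K₂ bits into consecutive groups of at most g bits — smaller, denser
histograms in the PCANet style — but the single-group mode is the default
and the tested mode.

Blocks are non-overlapping, row-major, default 8×8 on 32×32 ROIs (B = 16);
shapes the block does not divide are rejected rather than silently padded.
Histograms are raw counts (no per-block normalization), so the feature
entries of one image always sum to K₁ × pixel count — a conservation law
the tests assert. Images are grayscale floats in [0, 1] with no mean
subtraction (the filters are band-pass and remove DC anyway).

## ROI preprocessing

Raw finger frames are localized with the eight 3×3 Kirsch compass masks
(coefficients 5/−3, reflective padding), taking the per-pixel maximum
response. The gradient map is binarized at μ + kσ with k the smallest of
{1, 2, 3} whose edge density stays below a ceiling (default 10% of
pixels) — a three-level dynamic threshold that adapts to image quality; the
exact quality-classification rule this stands in for is not published, so
the density heuristic is an explicit, documented stand-in. The upper and
lower finger boundaries are taken as the strongest near-horizontal edge
rows in the top and bottom image halves; the interior band plus a small
horizontal margin is cropped and bilinearly resized to the network input
(32×32), clipping to [0, 1]. When no boundaries are found the full frame
is used with a logged warning. Datasets that ship pre-cropped ROIs bypass
the search entirely (`bypass=True`) and are only resized; a same-shape
resize is a bit-equal no-op.

## Evaluation protocol

Open-set: finger identities are split disjointly (default 50/50, all
sessions of one finger on one side), the orientation selection is fitted on
the training identities only, and all scoring happens on the test
identities. All intra-class pairs are genuine and all inter-class pairs
imposter; above a pair budget (default 10⁶) imposter pairs are uniformly
subsampled with the run seed. Acceptance is distance-based (accept iff
d ≤ t); FAR/FRR are swept over all distinct scores plus a below-minimum
sentinel, and the EER is linearly interpolated between the two thresholds
bracketing the FAR = FRR crossing. Rank-1 accuracy is leave-one-out over
the test set — every sample probes all others — the most symmetric
convention when no gallery/probe split is prescribed. Reports average over
iterations (each with its own deterministic split seed); a fixed seed
reproduces every serialized number bit-for-bit.

## Synthetic data

The generator emulates the geometry of NIR vein imagery rather than its
photometry: dark, smooth, slightly wobbly strokes (Gaussian cross-section)
on a brighter background, additive Gaussian noise, small rigid intra-class
jitter. Class geometry is a deterministic function of (class key, global
seed); sample jitter and noise of (class key, sample index, seed).
Defaults — 20 classes × 6 samples at 32×32, 3–6 strokes of width 2–6 px,
background 0.8, stroke depth 0.45, noise σ = 0.03, jitter ±1.5 px
translation and ±0.05 rad rotation — are sized so the mid radial scales
(wavelengths 4.4 and 9.7 px) carry most of the oriented energy, matching
the regime the diamond allocation is designed for, with class overlap low
enough that a working pipeline should identify essentially every probe.

What the generator does **not** model: illumination non-uniformity,
scattering blur, sensor fixed-pattern noise, finger posture changes beyond
rigid jitter, or session-to-session appearance drift. Passing the
synthetic benchmark therefore demonstrates the pipeline's mechanics
(filtering, selection, encoding, matching, metrics) and its behaviour on
well-separated curvilinear texture — not field performance on real vein
databases, which depends on exactly the nuisances listed above.

One consequence shows up in the per-scale sweep: the smallest scale
(wavelength 2 px) mostly sees noise and verifies poorly (EER ≈ 30%), as
expected, but the *coarsest* scale remains highly discriminative here
because the rigid-jitter-only class model leaves coarse stroke layout
almost intact — real databases degrade it much more. The mid-scales-beat-
extremes trend is therefore asserted on the average of the two extreme
scales against the average of the two mid scales.

## Problem sizes and numerical choices

The default test and acceptance runs use the 120-image synthetic benchmark,
8×8 images for the brute-force convolution oracle, and 10⁵ samples for the
Monte-Carlo EER limit cases — sizes at which every oracle can be computed
exactly or to well under the asserted tolerances in seconds. Tolerances:
the convolution oracle is asserted at 1e−8 max absolute deviation (observed
~1e−16); the selection oracle is exact; octave closed form vs. root finding
at 1e−6; Monte-Carlo EERs at ±1 percentage point. Tie-breaks everywhere
resolve toward the lower index, and every random draw flows from an
explicit integer seed.

## Known limitations

* The feature dimension is conceptually 2^K₂·K₁·B (~7.5×10⁷ at defaults);
  only sparse workflows are supported at that width.
* The ROI localizer assumes a roughly horizontal finger spanning the frame;
  heavily rotated fingers need external prealignment.
* `n_S` (how many orientations each scale keeps) is configuration, not
  learned; choosing it automatically is open.
* Only two convolutional layers are supported; the architecture is
  deliberately shallow.
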