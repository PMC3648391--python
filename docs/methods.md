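# Methods

## Scope

`strokeflow` implements the quantitative analysis chain of a rat
MCAO (middle cerebral artery occlusion) early-exercise study design: laser
speckle contrast flowmetry to relative cerebral blood flow (rCBF), TTC
infarct volumetry by the indirect method, CD31+ microvessel density, and the
group-level statistics (mean ± SEM, one-way ANOVA, Fisher's protected LSD).
Because such studies deposit no raw images, a synthetic-data module generates
every input with analytically known ground truth, and all validation is
property-based against that truth.

## Speckle contrast model

Dynamic speckle recorded with exposure `T` has squared contrast

    k^2 = beta * (tau_c / 2T) * (1 - exp(-2T / tau_c)),

where `tau_c` is the speckle decorrelation time (velocity ∝ 1/tau_c) and
`beta` ∈ (0, 1] the coherence factor of the rig. This is the classic
Lorentzian form in which `k^2` equals the plain exposure average
`(beta/T) ∫_0^T |g1(t)|^2 dt` of the squared field correlation
`g1(t) = exp(-t/tau_c)`; the triangular-windowed variant
`k^2 = beta (tau_c/T) {1 + (tau_c/2T)[exp(-2T/tau_c) - 1]}` is a well-known
alternative that differs only in the weighting of the correlation integral.
We adopt the plain form as the package's single source of truth (generator
and inversion both use it, so the choice cancels out of every ratio the
pipeline reports); the quadrature oracle in the tests integrates the matching
boxcar integral. `beta` defaults to 1 for synthetic data — it is a rig
property that cancels from rCBF ratios in any case.

Parameters and defaults: exposure `T = 5 ms`, frame rate 23 fps, 12-bit
detector — the acquisition regime of a typical cranial-window LSCI setup.

## Synthetic speckle generator

The generator is statistical, not physical: per pixel, frame intensities are
i.i.d. gamma draws with shape `M = 1/k^2(tau_c, T, beta)` and a common mean,
then rounded and clipped to the detector bit depth. A gamma variate with
shape `M` has coefficient of variation `1/sqrt(M) = k`, so the temporal
sample contrast converges to the model contrast exactly — which is what the
estimators need for verification. What this deliberately omits: spatial
speckle grain correlation, shot/read noise beyond quantization, motion. A
passing pipeline therefore demonstrates estimator correctness, not
robustness to real-world artifacts.

`mean_intensity` defaults to 10% of full scale. The clipped upper-tail mass
of a gamma(shape `M`) at 10× its mean is below 1e-6 for every `M ≥ 1`
(every `k ≤ 1`), so quantization bias is negligible; at substantially
higher means the near-exponential tails of low-`M` speckle would clip
measurably. A configurable floor `k^2 ≥ 1e-4` rejects parameter maps whose
gamma shape would exceed 1e4 (numerically pointless and overflow-prone).

## Contrast estimation and flow index

`temporal_contrast` implements aggregation over frames: per pixel, for each
disjoint block of 100 consecutive frames, `k = SD/mean` (sample SD with the
n−1 denominator, so small-block oracles match exactly); per-block images are
averaged pixel-wise — e.g. 50 blocks for a 15-min session. Pixels with
non-positive block mean are excluded from that block and masked if no block
is usable. `spatial_contrast` (odd moving window, border masked) is the
config-selectable alternative; which estimator produced an image is recorded
in its metadata, since the underlying acquisition text of such studies is
usually ambiguous between the two.

`flow_index = 1/max(k, k_floor)^2` with `k_floor = 1e-3`: the inversion is
unbounded as k → 0, so floored pixels are flagged explicitly and excluded
from every downstream mean — they encode measurement failure, not fast flow.

## ROI and rCBF ratios

The measured zone is 6 mm × 4 mm, 2 mm lateral and 1 mm anterior to bregma,
covering MCA territory. The offsets do not uniquely fix the rectangle, so the
package's convention places the ROI's medial-posterior corner at that point
(rectangle extending lateral and anterior); it is logged in every output and
configurable. Pixel rectangles are half-open, 0-based, `ceil(extent/pitch)`
pixels. The per-session scalar is the arithmetic mean of per-pixel `1/k^2`
over valid ROI pixels (pixel-wise inversion then mean, rather than
`1/mean(k)^2` — a documented convention), and rCBF is the ratio of that
scalar to the same animal's baseline. Sessions with under 90% valid ROI
pixels are rejected. Because contrast is a ratio statistic, rCBF is invariant
to detector gain and mean illumination.

## TTC phantoms and infarct volumetry

Phantom sections are mirrored half-ellipse hemispheres about a vertical
midline on an exactly mirror-symmetric pixel grid; the pale (infarct) region
is a half-ellipse segment scaled by `sqrt(f)` so its area is exactly the
fraction `f` of the hemisphere, strictly inside it, for any `f < 1`. Ground
truth is reported twice: analytically from ellipse areas, and pixel-exactly
from the noise-free label masks (the two agree to discretization error,
< 0.5 percentage points at the default 0.05 mm/px). Pipeline recovery is
judged against the pixel-exact value, since that is the truth of the
rendered image.

Segmentation: background by absolute brightness threshold (phantom
background is near-black; the threshold is operator-configurable for real
photographs), then a pale/viable split on the red-dominance score
`R − (G+B)/2` via Otsu within tissue. Otsu always splits, even a unimodal
histogram, so the split is accepted only when the two class means separate
by at least 40 gray levels — below that the section is declared
infarct-free. A manual threshold overrides both. Morphological cleanup
removes specks below 20 px and fills holes.

The indirect percentage is computed from thickness-weighted sums across
sections, `100 (Σ t·A_contra − Σ t·A_ipsi_normal) / Σ t·A_contra`, not a
mean of per-section percentages — volume semantics; with the equal 2-mm
sections the weights cancel. The midline defaults to the tissue centroid
column (adequate for symmetric phantoms; real sections need operator input).

## Vessel density

Fields are homogeneous-Poisson: counts `~ Poisson(λ · area)`, centroids
uniform inside the field minus a border margin. The 400× field area is not
derivable from magnification alone, so it is a free calibration parameter
defaulting to 0.25 mm² per field. Detection thresholds the stain score
(intensity for grayscale, `(R+G)/2 − B` brown dominance for DAB-like RGB)
with Otsu plus the same class-separation guard (50 gray levels) so blank
fields yield zero cells rather than thresholded noise; connected components
are size-filtered to [5, 2000] px and counted per component — two touching
cells merge into one count, a documented limitation. Density is pooled:
total count over total sampled area of the five random fields (field area,
not section area, as denominator). An optional minimum-separation mode makes
detector fixtures exact but thins the point process, so it stays off when
Poisson calibration matters.

## Statistics

Mean ± SEM (sample SD/√n; single observations report SEM as missing, never
zero). One-way ANOVA by direct sum-of-squares decomposition with p from the
F distribution; Fisher's PLSD as pairwise pooled-variance t tests on
`MS_within` with `N − k` df, flags gated on omnibus `p < α` (the
"protected" rule) and no further multiplicity adjustment. An unprotected
mode exists for sensitivity analysis, and a Kruskal–Wallis alternative is
provided for the ordinal 0–7 neuro scores — the study-design default
analyzes them with the same ANOVA machinery, a documented caveat rather
than an endorsement.

Ordinal scores are generated as rounded, clipped normals about each group
mean (SD default 1.0, the order of the dispersion such studies report on
the 0–7 scale).

## Problem sizes and numerical choices

Calibration runs use image grids small enough that Monte-Carlo error, not
compute, dominates the comparison: contrast calibration on 8×8 stacks of
50×100 frames; full-pipeline rCBF on a 0.25 mm/px window (ROI 16×24 px)
with 10 blocks of 100 frames; 50 random six-section TTC phantoms at
0.05 mm/px; 1,000 replicate animals for density calibration; 10,000 null
simulations for the protected-LSD error rate. At these sizes the rCBF ratio
carries a standard error of ~0.3% and the estimators' small-sample biases
(sample-CV bias at n = 100 per block, Jensen bias of 1/k² averaging) are an
order of magnitude below the ±0.02 acceptance band. All randomness flows
from explicit per-call seeds (`numpy` `default_rng`/`SeedSequence`); fixed
seed ⇒ bit-identical stacks, phantoms, tables and derived measurements.

## Known limitations

- The gamma-marginal speckle generator has no spatial grain, so
  `spatial_contrast` calibrates on i.i.d. fields only; on real speckle its
  window statistics depend on speckle/pixel size matching.
- Segmentation defaults are tuned to the phantom's color model; real TTC
  photographs need threshold overrides and operator midlines.
- Merged cells under-count; no stereological correction is applied.
- The ANOVA/PLSD layer assumes normal homoscedastic errors; for n = 6
  groups this is an approximation inherited from the study design.
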