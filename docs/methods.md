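# Methods

## Scope

`evquant` models two measurement processes around EV-surface CD98 in
hepatocellular carcinoma: (i) multiplex single-vesicle fluorescence imaging
with co-expression profiling against the tetraspanins CD63 and CD9, and
(ii) the CD98+ EV Index — an ExoCounter-style well count, background-
corrected by same-disc PBS controls and normalized to total EV
concentration — evaluated as a binary classifier for early HCC. Because no
raw images or patient tables are publicly deposited, both workflows are
driven by synthetic generators whose parameters are fitted to the published
summary statistics; everything downstream of the generators is blind to the
planted truth.

## Synthetic imaging model

A field is four co-registered channels (total stain, CD63, CD9, CD98).
Each vesicle is an isotropic 2-D Gaussian spot (surrogate for the
diffraction-limited point-spread function at 20×; `psf_sigma` default
1.3 px, truncated at 4σ) at a subpixel center, with per-channel integrated
amplitudes. Marker-channel amplitude is exactly zero when the vesicle does
not carry that marker, so positivity has an unambiguous ground truth.
Rendering order: spot signal → optional 4×4 linear crosstalk mixing of the
signal (before background, identity by default) → additive per-channel
background (100 ADU) → Poisson shot noise on signal+background → additive
Gaussian read noise (sd 2 ADU, generic sCMOS model) → clip/round to uint16.
All stochastic steps derive from one explicit seed; renders are
bit-reproducible.

Defaults were chosen once to represent a well-calibrated assay:

| parameter | default | rationale |
|---|---|---|
| field | 512×512 px, 269 spots | three fields ≈ 807 vesicles, the published profiling size |
| min separation | 8 px (≥ 6σ) | NTA showed vesicles do not aggregate; spots resolvable |
| total-stain amplitude | log-normal, mean 2000, sd 600 | size/labeling heterogeneity is right-skewed; bright enough that detection is near-complete |
| marker amplitude | log-normal, mean 2500, sd 800 | positive markers sit far above the 3σ decision boundary, as in published images where marker spots are clearly visible |
| background / read noise | 100 / 2 ADU | generic camera floor |

The planted combination frequencies reproduce the published single-EV
profile. The printed summaries (marginals CD63 77.7%, CD9 26.9%, CD98
33.0%; triple-negative 22.1%; CD63+/CD98− 44.9%; CD9+/CD98− 6.7%) pin seven
of the eight combination masses up to one degree of freedom: they force
P(CD9 only) = 0 and leave P(triple+) + P(CD9+CD98+ only) = 0.202. We fix
P(triple+) = 0.200, consistent with the observation that CD98+ vesicles are
predominantly co-positive with CD63 and/or CD9, giving

    (−,−,−)=0.221  (63)=0.382  (9)=0.000  (63,9)=0.067
    (98)=0.000  (63,98)=0.128  (9,98)=0.002  (63,9,98)=0.200

What the generator does *not* emulate: optical aberrations, STED-resolution
detail, vesicle aggregation (available only as a stress-test mode via
`min_separation=0`), photobleaching, spatially varying illumination, and
3-D defocus. Passing tests therefore validate the analysis logic and its
statistical calibration, not robustness to those real-data artifacts.

## Segmentation

Histogram: 256 bins over the image's own [min, max]. For integer images the
bin count is clamped so bins are at least one intensity level wide;
sub-unit bins on quantized data create empty "comb" bins whose distance to
the triangle chord is spuriously maximal next to the histogram peak (on a
pure-noise field this collapses the threshold onto the peak and floods the
mask). Triangle threshold: chord from the peak bin to the farthest occupied
bin on the peak's longer-tail side; the winning bin maximizes perpendicular
point-to-chord distance over strictly interior bins. Conventions, all
tested: tail-length ties resolve to the higher-intensity side; distance
ties resolve toward the bin nearest the peak, then to the lower bin; with
no interior bin the peak bin is used; the returned threshold is the winning
bin's upper edge and foreground is strictly `>` threshold. Segmentation is
therefore invariant under adding a constant to the image.

Cleanup: binary opening with a disk (radius 1) then hole filling; 8-connected
labeling; area gate [2, 100] px². The upper bound admits one full PSF
footprint (~85 px at 4σ truncation, reached when the threshold sits just
above background in noise-free fields) while rejecting merged doublets and
debris; the lower bound removes specks that survive nothing else. Two spots
closer than the PSF width merge into one component — watershed splitting is
out of scope. A background-only noisy field yields zero components (any
above-threshold noise pixels are isolated and do not survive opening); a
perfectly constant field raises a degenerate-histogram error.

## Positivity and co-expression

The total-stain mask is the only detection pass; its pixel set is reused in
every channel, so per-vesicle measurements are co-registered by
construction. Local background per vesicle and channel is the *median* over
an annulus (dilations by r_in = 2 and r_out = 5 px, differenced), excluding
pixels of any foreground component so close neighbors cannot contaminate
it; an empty annulus falls back to the global median (logged). Corrected
mean = raw mean − background, floored at 0. A marker is positive when the
corrected mean exceeds `k_sigma` (default 3) times the channel's robust
background sd (1.4826 × MAD over pixels away from all vesicles). With noise
disabled the rule degenerates to "any signal at all", which makes the
noise-free end-to-end identity exact. The decision rule is a package
choice — published pipelines rarely state theirs — and `k_sigma` is
exposed in configuration.

Tables count the 8 combinations per field and pool by summing counts across
fields (not averaging fractions), with all fractions relative to detected
total-stain-positive vesicles; the triple-negative class is retained.

## Cohort model

Per group, the true index is log-normal with `mu = ln(median)` and sigma
solved from `median·(e^{zσ} − e^{−zσ}) = IQR` (z = 0.6745, bracketed root
finding to |f| < 1e-10). Group summaries: healthy n = 50, median 3.548, IQR
3.821 (fitted σ ≈ 0.767); HCC n = 136, median 9.761, IQR 16.405 (σ ≈ 1.129)
— strongly right-skewed, which motivated the two-parameter log-normal as
the minimal faithful family. Forward model per subject: total EV
concentration log-normal (median 2×10¹⁰ particles/mL, σ_log 0.4 — a
realistic post-size-exclusion plasma range), latent well count
`index·(concentration/10⁹) + control mean`, observed sample count
Poisson(latent), and 2 PBS control wells per 16-well disc, each
Poisson(mean 25). Covariates (sex, smoking, alcohol, cirrhosis, age, and
for HCC subjects AFP, tumor size, stage) are drawn independently of the
index within group, mirroring the published null associations; frequencies
not printed in the source summaries (cirrhosis 0.30/0.02, stage I fraction
0.5, tumor-size log-normal median 4 cm, AFP log-normal median 20 ng/mL with
σ_log 2.5 for heavy tail) were fixed once as plumbing. `noise=False`
replaces all Poisson draws by their means, making the index round-trip
exact — the basis of the recovery identities in the tests.

The index estimator is slightly biased upward at small counts because the
score floors at zero; with the default concentration scale the signal is
~70 counts against a control mean of 25, and the group-median bias observed
across 100 seeds is under 5%, well inside the 15% sampling band the
recovery checks use.

## Diagnostics conventions

- Control normalization is subtraction (background capture events are
  additive per disc), floored at zero; a ratio mode is deliberately not the
  default. Index scale constant 10⁹ particles/mL puts indices in the
  single-digit range of the published tables; both are configurable.
- ROC thresholds are midpoints between consecutive distinct scores plus
  ±∞ sentinels; a positive call is `index ≥ threshold`. Trapezoidal AUC
  with this construction equals the tie-corrected Mann–Whitney
  `U/(n₁n₀)` (asserted to 1e-12 in tests). Youden ties resolve to the
  lowest cutoff, favoring sensitivity in a screening context; confusion at
  a fixed cutoff also uses `≥`.
- Welch's t (Satterthwaite df) and Pearson χ² (no continuity correction, as
  is standard when reproducing uncorrected published statistics) come from
  scipy; both-groups-constant-and-equal input returns t = 0, p = 1. The
  pooled two-proportion z-test is implemented directly; its z² equals the
  uncorrected 2×2 χ² (asserted to 1e-10), and a degenerate pooled
  proportion (0 or 1) returns z = 0, p = 1 by convention.
- Stratified k-fold is a within-class shuffled round-robin: per-fold class
  counts are within one of exact proportionality (136 HCC + 50 healthy at
  k = 5 gives 27/27/27/27/28 and 10 per fold), and folds partition the
  cohort. Logistic regression is IRLS with ridge jitter 1e-8, max 100
  iterations, tolerance 1e-8 on the coefficient step; features are
  standardized on each training fold with frozen parameters applied to the
  test fold. Complete separation is flagged and the last iterate returned.
  The default CV feature set is the index alone; covariates can be appended
  by passing a feature matrix.
- No multiple-testing correction is applied anywhere; comparisons are
  reported as raw per-test p-values.

## Problem sizes

The recovery checks run at the study's own sizes: three 512×512 fields
(~807 vesicles) per replicate, 20 replicates for co-expression recovery;
cohorts of 50 + 136 subjects, 100 replicates for median-index and
group-separation checks. These sizes keep the full suite and the
reproduction script to a few minutes on one CPU.

## Known limitations

- Merged spots are counted once; dense fields bias counts low (fractions
  are unaffected in expectation because detection is independent of marker
  combination).
- The triangle threshold assumes a dominant background mode with a signal
  tail; images that are mostly foreground violate its geometry.
- The positivity threshold (3σ) trades false positives against dim-marker
  false negatives; at the default amplitudes both error rates are
  negligible, but dimmer assays require recalibrating `k_sigma`.
- The cohort generator draws covariates independently of the index; it
  cannot, by construction, probe confounding (an optional dependence knob
  would be needed for power studies of adjusted models).
- AFP is generated only for diseased subjects, so AFP-based comparators can
  only be evaluated as sensitivity-at-fixed-cutoff, not as full ROC against
  healthy controls.
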