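# evquant

Single-extracellular-vesicle (EV) multiplex fluorescence quantification and
CD98+ EV Index diagnostics.

Liquid-biopsy studies of hepatocellular carcinoma (HCC) have proposed the
transmembrane oncoprotein CD98 (SLC3A2) as an EV-surface biomarker: plasma
vesicles are captured per well on an optical-disc reader, counted against
PBS negative-control wells, and normalized to the total EV concentration
from nanoparticle tracking analysis. In parallel, single-vesicle
fluorescence imaging quantifies how CD98 co-localizes with the canonical
tetraspanins CD63 and CD9 on individual vesicles. `evquant` implements both
workflows as a tested, reusable Python library, with synthetic-data
generators standing in for the microscope images and the patient cohort so
every stage can be validated against planted ground truth.

## What it computes

**Imaging.** Fields contain four co-registered channels: a total-membrane
stain (labels every vesicle) and three antibody channels (CD63, CD9, CD98).
Vesicles are segmented in the total-stain channel by a global triangle
threshold — the histogram bin maximizing the perpendicular distance to the
chord from the peak `(b_p, h_p)` to the far end of its longer tail
`(b_e, h_e)` — followed by morphological opening, hole filling,
connected-component labeling and area gating. The detected mask is applied
unchanged to each marker channel; per vesicle *i* and channel *c*,

    corrected_ic = max(0, mean(I_c over mask_i) − median(I_c over annulus_i))

and marker *c* is called positive when `corrected_ic > k·σ_c` with `σ_c`
the robust (MAD-based) background noise and `k = 3` by default. Counts of
the 8 marker combinations are pooled across fields; all fractions use the
total number of detected vesicles as denominator.

**Diagnostics.** Per subject,

    score = max(0, sample_well_count − mean(control_well_counts))
    CD98+ EV Index = score / (total EV concentration / 10⁹ particles/mL)

evaluated by ROC analysis (tie-aware trapezoidal AUC, identical to the
Mann–Whitney statistic `U/(n₁n₀)`), the Youden-optimal cutoff
(`argmax` of sensitivity + specificity − 1), Welch's t-test, Pearson χ²,
a pooled two-proportion z-test, and logistic regression under stratified
5-fold cross-validation (IRLS, per-training-fold standardization).

## Worked example

```sh
python examples/cohort_diagnostics.py
```

```
subjects: 50 healthy, 136 HCC
median index  healthy: 3.850   HCC: 8.215
AUC: 0.732
Youden cutoff: 6.09 (J = 0.483)
sensitivity: 0.60   specificity: 0.88
Welch t = 6.54, p = 8.22e-10
5-fold CV: mean AUC 0.732, mean accuracy 0.704
```

One simulated cohort (seed 1): the healthy and HCC groups are drawn from
log-normal index distributions fitted to the published median/IQR
summaries, pushed through Poisson well counts and control/concentration
normalization. The index separates the groups (Welch p ≈ 1e-9) with an
AUC near 0.73 and a Youden cutoff near 6 — the cross-validated logistic
model confirms the single-feature discrimination is stable out of sample.

`examples/profile_single_ev_field.py` runs the imaging pipeline on one
simulated field (269/269 vesicles detected; marginal positivity CD63 0.770,
CD9 0.245, CD98 0.331 against planted 0.777/0.269/0.330), and
`examples/line_scan_colocalization.py` prints per-channel line-scan
profiles whose coincident peaks demonstrate co-localization on a single
vesicle.

The same stages are scriptable from a shell:

```sh
evquant run-all --seed 1 --out-dir out/   # fields, co-expression CSV, cohort CSV, summary JSON
evquant diagnose --seed 1 --cutoff 6 --out-dir out/
```

## Layout

- `src/evquant/synthetic_imaging.py` — field generator (Gaussian PSF spots,
  Poisson + read noise, planted combinations), TIFF/CSV/JSON I/O
- `src/evquant/segmentation.py` — triangle threshold, morphology, labeling,
  area gate
- `src/evquant/positivity.py` — mask transfer, local background, positivity
  calls, co-expression tables, line scans
- `src/evquant/cohort.py` — log-normal median/IQR fitting, subject table
  generator
- `src/evquant/diagnostics.py` — index construction, ROC/Youden/confusion,
  Welch/χ²/z tests, stratified CV logistic regression
- `src/evquant/pipeline.py`, `src/evquant/cli.py` — orchestration and the
  `evquant` command
- `docs/methods.md` — model assumptions, parameter choices, numerical
  conventions and limitations
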