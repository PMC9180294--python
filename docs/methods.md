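# Methods

This note records the models behind each pipeline stage, the defaults that
matter, and the design choices made where the methodology was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design

`StudyDesign` fixes the sampling layout: two maturity stages (half-red,
red) × 3 harvests × 4 biological samples, with 11 e-nose, 5 FTIR and 8
imaging technical replicates per sample. FTIR pools each harvest into one
sample per stage (6 samples). The default design therefore yields 264
e-nose observations, 30 spectra and 192 image observations. A single seed
on the design determines every generated number.

## Synthetic data

### Quantile-matched sampling

Each sensor and colour feature is specified per stage as a
`QuantileSpec` — median with 5th/95th percentiles, the form in which such
panels are tabulated. Draws are produced by mapping standard normals
through side-specific scales, (median−p5)/1.645 below the median and
(p95−median)/1.645 above it, then **clipping** (censoring) to [p5, p95].
The side-specific scales honour asymmetric printed summaries; clipping
parks the ~5% tail mass on the interval edges, so for large n the
empirical median and 5th/95th percentiles reproduce the specification
essentially exactly while the support never leaves [p5, p95]. The
censoring matters: features whose printed per-stage ranges are disjoint
(sensor S7, lightness L\*) then have disjoint supports in the generated
data, which is what makes their ROC AUC exactly 1. A side effect is that
the distribution mean can differ from the median by up to ≈0.4·|scale
difference|; for near-symmetric specifications this is negligible.

### Replicate nesting

Technical replicates of one biological sample share a random intercept.
The unit-variance draw decomposes as z = aₛ + e with Var(e) = 0.10 and
Var(aₛ) = 0.90: technical scatter is the small component, biological
sample-to-sample variability the large one. This split reproduces the
qualitative behaviour the battery must expose — replicate clouds tighter
than the spread of sample medians in score plots, and mixed-model
p-values that stay non-significant for sensors whose stage medians differ
by less than the biological noise (S4, S10) while the clearly separated
sensors reach p < 0.001.

### E-nose traces

A trace is a saturating exponential rise (τ = 8 s) that reaches its
plateau exactly by 65 s and holds it on an 80 s, 1 Hz grid, plus 0.2%
relative sensor noise. Only the 70–75 s window value is contractually
meaningful; the rise shape is cosmetic.

### FTIR spectra

A spectrum is a sum of Gaussian bands with per-stage amplitudes:
3295 cm⁻¹ (broad νOH envelope, σ = 160, amplitude 1.00 → 0.72 from
half-red to red), 1717 cm⁻¹ (νC=O, 0.22 → 0.42) and 1026 cm⁻¹ (sugar
fingerprint, 0.55 → 0.95) carry the ripening signal; 2928/2891 cm⁻¹
(νCH) and ~1400 cm⁻¹ (δCH₂) are stage-invariant. On top: a linear
baseline (offset sd 0.02, tilt sd 0.006), a per-spectrum multiplicative
scatter factor (lognormal, sd 0.08) so SNV is non-trivially exercised,
lognormal amplitude jitter at the sample (4%) and replicate (1.3%)
levels, and white noise of sd 0.001 AU — the realistic magnitude for a
32-scan DTGS ATR measurement. Larger noise values make the position of
the broad-band loading extremum indeterminate (its top is flat over tens
of cm⁻¹), which is physically wrong for an instrument of this class.

### Berry images

Each lot renders n ellipse berries on a dark noisy background in a
non-overlapping grid (error if they cannot fit). A berry's surface is
split exactly, by pixel count, into a red-toned top fraction
(target ± 0.03 jitter, truncated to [0,1]; endpoint requests 0 and 1 are
honoured exactly) and a green-toned remainder, so the returned masks are
usable as ground truth: red ∪ green = berry and red ∩ green = ∅ by
construction. Surface colours (red ≈ (185, 32, 40), green ≈
(110, 150, 55), background ≈ (9, 10, 12)) are chosen so the R channel
separates foreground from background while R−G separates red from green
flesh — the contrast structure the segmentation pipeline assumes.
Default frame 864×1024 (the 3.2-MPixel sensor's aspect at reduced
resolution). The optional 24-patch calibration chart uses a synthetic
in-package palette spanning the gamut; patches are rendered noise-free at
known boxes, so affine calibration against them is exactly invertible.

Per stage, the default red surface fraction is 0.5 (half-red, by
definition 50% red) and 1.0 (red, fully coloured).

### Chemistry and volatiles

Per biological sample, titratable acidity TA (%), total phenols TP
(mg/100 g) and antioxidant activity AA share a positive latent factor and
decline from half-red to red (TA 0.90 → 0.70); total soluble solids TSS
(°Brix) oppose that factor and rise (8.8 → 9.8). The 55 generic VOC
columns (relative peak area) load log-linearly on a common aroma factor
elevated in red fruit; 2-methylbutanoic acid (Ac4) and mesifurane (F1)
follow their own weaker latent, so correlation-profile clustering
isolates them as a second VOC cluster.

### What the generator does *not* emulate

Real berry morphology (calyx, touching fruit, specular highlights),
harvest-time trends beyond a label, instrument drift, atmospheric CO₂/H₂O
bands, and chromatographic detail of the VOC panel. Passing tests
demonstrate that the pipeline recovers structure *of the kind the study
design implies* at realistic noise levels — not performance on real
images or spectra.

## Feature extraction

- **E-nose**: the 70–75 s window mean, endpoints inclusive. On the 1 Hz
  grid this equals the trapezoidal area divided by the window width to
  within 0.1% (asserted in tests rather than choosing silently between
  the "average response" and "area under the curve" readings).
- **FTIR**: SNV uses the sample (n−1) standard deviation; constant
  spectra are rejected. The second derivative is Savitzky–Golay (default
  window 15 points, cubic), chosen over finite differences for noise
  robustness; edges use the fitted polynomial of the terminal windows.
  The default grid is 600–4000 cm⁻¹ step 1 — the only uniform grid
  consistent with 3401 variables.
- **Imaging**: Otsu thresholds for both segmentations. The primary mask
  erodes with a disk (radius 2 px at ~864-px frames, scaled with size),
  fills holes by border flood-fill, and by default restores the rim with
  a matching dilation so the cleanup is area-neutral. The red/green split
  thresholds clip(R−G, 0, 255) inside the berry mask; when the two Otsu
  classes are closer than 30 intensity levels the surface is treated as
  single-toned and a fixed threshold of 40 decides red vs green —
  without this guard Otsu would bisect the noise of a fully red berry.
  CIELAB uses the standard sRGB → XYZ (D65, 2°) → Lab route; the studio
  lamps' 5500 K spectrum is absorbed by chart calibration when used.
  Features are per-pixel Lab values averaged over the lot mask; Chroma
  and hue derive from the averaged a\*/b\*. Hue is atan(b\*/a\*) in
  radians (not atan2): published hue magnitudes of 0.4–0.6 rad sit in the
  first quadrant, where the conventions agree.

## Univariate battery

The mixed model y₍ₛᵣ₎ = μ + β·stage + aₛ + e₍ₛᵣ₎ is fitted by REML. For
balanced layouts the variance components come from the within/between
mean squares in closed form, and the Wald t on β with between-sample
degrees of freedom (S − 2) is then *exactly* the two-sample t-test on the
per-sample replicate means — the reduction tested against scipy and used
to keep the 1000-replication type-I-error check fast. Unbalanced layouts
profile the REML criterion over λ = σₐ²/σₑ² with the GLS fit closed-form
per λ (Woodbury on the block-diagonal marginal covariance); statsmodels
MixedLM serves as an independent cross-check in the tests, not in the
implementation, because its Wald test is normal-based while this battery
needs the between-sample-df t convention (Satterthwaite df are out of
scope). Grouping is at the biological-sample level: replicates within a
sample share the intercept.

BH adjustment uses the step-up max-min construction; rejection means
adjusted p ≤ δ. Fold change is the ratio of stage medians (midpoint
convention for even n); both ratio directions are reported because
published tables of this kind occasionally print either direction.
Percentiles use linear interpolation throughout.

ROC AUC is the tie-corrected rank statistic, folded to ≥ 0.5 with the
raw value and direction retained — published batteries report AUC ≥ 0.5
regardless of effect direction. The CI is a stratified bootstrap
percentile interval (default B = 2000): DeLong's variance degenerates at
AUC = 1, which these data genuinely contain, while the bootstrap then
returns the honest degenerate interval [1, 1].

## PCA and Q²

PCA is the SVD of the preprocessed matrix; R² per component is the
squared singular value over the total sum of squares. Loading signs are
fixed (largest-magnitude element positive) for reproducibility.

Q² = 1 − PRESS/TSS is the single largest methodological choice, since
chemometric software rarely documents its scheme. Here: observations are
dealt to folds venetian-blind **at the biological-sample level** (after
sorting by sample id), so replicates of one sample never straddle the
train/test split — row-level folds would leak replicate information and
inflate Q². For each fold the model, including centring/scaling
parameters, is refit on the remainder; each held-out element x₍ᵢⱼ₎ is
predicted from a projection that excludes variable j (Sherman–Morrison on
the orthonormal loadings), avoiding the trivial Q² ≈ R² self-prediction
of naive row projection. PRESS accumulates in the training-preprocessed
coordinates and TSS is that of the full-data preprocessed matrix.
Whether element-wise or row-wise deletion was used by any given published
analysis is generally unknowable; the element-wise scheme is the
conservative default and is documented as such.

Headline R²/Q² values from any particular real dataset depend on those
raw data and are not reproduction targets here; the tests instead verify
the properties that make the statistic meaningful (Q² ≤ R², near-R² on
low-rank structure, ≤ 0.1 on pure noise, seed determinism).

## Correlation maps

Two-block Pearson coefficients with two-sided t-test p-values
(α = 0.05). Clustering operates on the correlation *profiles* (rows or
columns of the ρ matrix) with Ward linkage on Euclidean distances — the
natural object for a two-block heatmap, where a feature is characterised
by how it correlates with the other block. The cluster count is selected
by maximum mean silhouette width over k = 2..min(8, n−1) (ties to the
smallest k; the cap reflects the 2–3 clusters such panels exhibit).
Degenerate inputs (fewer than 3 features, identical profiles) are
signalled, not guessed. Heatmaps are dendrogram-ordered with cluster
colour bars; non-significant cells are rendered hollow but kept at full
precision in the companion TSV (`%.17g`, exact round-trip). Very wide
axes (a full spectrum) can skip column clustering and stay in natural
wavenumber order.

## Band reporting

The PC1 loading's dominant bands are its local extrema ranked by absolute
value. The loading is first smoothed with a 61-point cubic
Savitzky–Golay filter: on a broad band's flat top the raw extremum
position is noise-dominated, and a symmetric polynomial-preserving
smoother relocates it without bias for symmetric bands. Peaks then need
a prominence of 5% of the loading range, so noise wiggles riding on a
band do not produce duplicate reports.

## Pipeline defaults and problem sizes

The CLI analyses with 2 PCA components, 7 venetian-blind folds (clamped
to the sample count), B = 1000 bootstrap resamples and δ = α = 0.05, and
renders images at 432×512 — half the generator's native default, a
resolution at which segmentation accuracy is unchanged (tests assert the
ground-truth recovery at both scales) while a full 192-image run
completes in well under a minute. The test suite exercises the full
264/30/192-observation design for the statistics and reduced designs for
pipeline plumbing.

## Known limitations

- The LME assumes a single random intercept; no replicate-level serial
  structure or heteroscedasticity across stages.
- Satterthwaite/Kenward–Roger degrees of freedom are not implemented;
  between-sample df are exact for balanced designs and a good
  approximation for the mildly unbalanced ones this design produces.
- Colour calibration is affine in RGB; strong nonlinear casts (gamma
  errors) are only partially corrected.
- The silhouette criterion cannot return k = 1; a single homogeneous
  cluster is reported as the degenerate-input error instead.
- Hue via atan breaks down if a lot's mean a\* approaches 0; the berry
  colours of interest keep a\* well positive.
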