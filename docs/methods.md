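# Methods

This note records the models, defaults and numerical choices behind
`dfirscreen`, and what the synthetic experiments do and do not establish.

## Frequency axes

The fingerprint region 1000–1800 cm⁻¹ is represented by three presets:
`FULL_199` is 199 points from 1000 cm⁻¹ at 4 cm⁻¹ spacing (1000…1792; the
count is taken as authoritative over the nominal upper edge, since every
data-volume figure downstream uses 199), `DF_14` is the 14-point discrete
acquisition set {1000, 1030, 1080, 1482, 1520, 1546, 1570, 1600, 1630,
1654, 1686, 1726, 1734, 1770}, and `DF_9` is its 9-point subset {1482…1726}
that drops the three low-frequency baseline points and the high-frequency
tail. Downsampling between axes uses linear interpolation between the two
bracketing source points (several `DF_14` values do not lie on the 4 cm⁻¹
grid, so nearest-neighbour mapping would introduce ±2 cm⁻¹ ties); a target
value coinciding with a source value passes through exactly.

## Synthetic forward model

The generator exists so every downstream stage is testable without
instrument data. It emulates the statistical structure the analysis
assumes; it is not a physical simulation of droplet drying or detector
response.

**Unit-thickness absorptivity ε(ν).** A sum of Gaussian bands: amide I
(1651 cm⁻¹, FWHM 45, amplitude 1.0), amide II (1548, 45, 0.6), minor bands
at 1080/1310/1400/1740 (amplitudes 0.06–0.15), and a very broad band
(amplitude 0.25) standing in for the unstructured serum background, so
that no fingerprint frequency has near-zero mean absorbance and the
1000–1080 cm⁻¹ points act as a flat quasi-baseline. Band positions are the
canonical protein assignments; all amplitudes are package choices, as no
absolute absorbance scale exists for these deposits.

**Coffee-ring thickness.** t(r) = c·edge(r) + (R_t − c)·exp(−(r − R)²/2w²)
with centre thickness c = 1, ring/centre ratio 1.6, spot radius
R = 100 µm, ring scale w = 12 µm; edge(r) is 1 inside the spot and decays
with scale w outside; t ≡ 0 beyond R + 3w. The ring-to-centre ratio is
chosen so that ring pixels exceed the QC saturation threshold (thick-rim
rejection is part of the intended behaviour) while remaining below the
detector clip.

**Artefacts and noise.** Per pixel: baseline offset ~ U(0, 0.02) AU and
slope ~ U(±2·10⁻⁵) AU/cm⁻¹ (a mild scattering tilt), i.i.d. Gaussian noise
of SD 0.01 AU per pixel-frequency, and hard clipping at 2.0 AU. Per spot:
a log-normal thickness scale (σ = 0.05) emulating deposition variability.

**Patients and classes.** Each patient draws amide band centres
(class shift + N(0, 1.5 cm⁻¹) jitter) and an amide I/II amplitude-ratio
factor (class factor × log-normal jitter, σ = 0.02). The default cancer
effect shifts amide I by −4 cm⁻¹ and amide II by +3 cm⁻¹ with ratio factor
1.05 — directions chosen to mimic the observed full→sparse centroid
behaviour while keeping classification non-trivial. The 50-spot cohort
uses per-class variants of this effect with skin the weakest, so per-class
accuracies spread realistically.

**Determinism.** One cohort seed; per-spot parameter and noise substreams
are derived as `SeedSequence([seed, spot_index, stream])`, so any spot can
be re-rendered in isolation and full runs are bit-reproducible.

**Problem sizes.** The simulation instrument preset images a 320 µm field
of view at 5 µm pixels (64 × 64 per spot; ~1 250 in-spot pixels), a
deliberate desk-scale choice that preserves every pipeline behaviour
(ring/centre contrast, QC statistics, averaging gains) at a small fraction
of the full-resolution mosaic volume. The replicate study uses 40
replicates; the cohort uses 5 classes × 10 patients.

## Quality control

Rules, in priority order background > saturated > scatter:

* **background** — integrated absorbance (trapezoid over the axis) below
  5% of the image maximum;
* **saturated** — any absorbance ≥ 1.8 AU, or a run of ≥ 3 consecutive
  frequencies flat at the cube's global maximum (clipped plateau below the
  nominal limit);
* **scatter** — per-pixel least-squares offset/slope over the baseline
  window (1000–1080 cm⁻¹ ∩ axis): |slope| > 2.5·10⁻³ AU/cm⁻¹, offset >
  0.6 AU, or any absorbance below −0.05 AU. The offset/slope limits sit
  above the intrinsic serum baseline absorbance and tilt of the thickest
  deposits (≈0.45 AU and 1.8·10⁻³ AU/cm⁻¹ at ring thickness), so only
  artefact-like excursions trip them. The 9-frequency axis has no
  baseline-window points; the pipeline then skips the scatter rule with a
  warning recorded in the mask.

A k-means segmentation (k = 4 by default: background, good, thick-rim,
distorted; fixed seed; spectra min-max scaled per pixel so shape rather
than thickness drives the clusters) adds spatial consistency: any cluster
in which more than half the members carry a defect flag has its remaining
members relabelled with the cluster's modal defect. If the cube collapses
to fewer distinct scaled shapes than k (noise-free limits), k is clamped.
All thresholds are package defaults and are echoed into every QC summary.

## Spot spectra and features

Good pixels are assigned to the layout cell containing them; a cell whose
good pixels touch the cell boundary is flagged (stitching artefact), and
cells with fewer than 25 good pixels are excluded with a recorded reason.
The processing order is: per-frequency unweighted mean over good pixels →
min-max scale to [0, 1] → optional truncation to [1482, 1770] cm⁻¹.
Scaling before truncation is the default because variability is reduced
further by truncating already-scaled spectra; the alternative order is
available by calling the primitives directly.

The peak centroid uses inclusive windows [1600, 1700] (amide I) and
[1500, 1600] (amide II); the shared 1600 cm⁻¹ point belongs to both (an
exclusive variant is a window argument away). Negative absorbances are
clipped to zero inside the window. Note the centroid of a band embedded in
a mixture is attenuated relative to the band's own shift — neighbouring
bands and the background act as fixed weights — so centroid differences
between classes are systematically smaller than the underlying centre
shifts; tests that check translation recovery do so on isolated bands.

ΔAbs is the mean across frequencies of the per-frequency replicate sample
SD (n−1 denominator); interpreting the "average change in absorbance" as a
mean absolute deviation instead is available by flag. Mean RSD averages
100·SD/mean over frequencies with positive mean (others are excluded and
counted). In the replicate experiment the three presets are acquired as
independent noisy measurements of the same physical replicate (shared
thickness and band-jitter draws, independent noise). Under these
conditions ΔAbs orders FULL ≤ DF_14 ≤ DF_9 and mean RSD orders
DF_14 ≤ DF_9; the full grid's mean RSD is *comparable* to the 14-point
set's rather than smaller, because the discrete frequencies sit
preferentially on the high-absorbance bands while the full grid spends
most points in the low-signal quasi-baseline — a composition effect that
no spectrally-uniform noise model can invert.

## Classification protocol

Features are the min-max scaled absorbances on the 14-frequency axis. For
one cancer class and one run: grid-search (C, γ) by stratified 3-fold CV
accuracy on the training set of the first held-out patient (10 controls +
9 cancer; folds shuffled by the run seed), fix the winning pair, then
train/test every patient leave-one-out with it. Ties in CV accuracy go to
the smallest C, then the smallest γ. Three runs with consecutive seeds
differ only in their fold shuffles; each patient's decision is the modal
vote, and the fraction of unanimous triples is reported.

The C grid is the conventional log₂ ladder 2⁻⁵…2¹⁵. The γ grid is a
symmetric log₂ ladder 2⁻⁹…2⁹ applied **relative to** the variance-scale
reference 1/(n_features·Var(X)): min-max scaled spot spectra concentrate
at very small pairwise distances (median squared distance ~5·10⁻³), so
absolute γ values in the usual range leave the RBF kernel effectively
constant and every grid cell degenerates to the same underfit predictor;
anchoring the ladder to the data scale spans underfit to overfit
regardless of feature scaling. The SVM is unweighted, matching the
protocol it implements.

**Calibration.** Because training sets contain 10 controls but only 9
cancer spectra and only cancer patients are ever tested, the protocol is
not exactly chance-calibrated under a zero-effect null: the measured mean
cancer-call rate over hundreds of null cohorts is ~0.42–0.47 (a residual
majority-class bias arising when the noisy 19-sample CV selects
low-capacity grid cells whose intercept-dominated regions default to the
majority class). Re-weighting classes overcorrects (~0.63) and departs
from the protocol, so the small conservative bias is retained and
documented rather than patched. Power behaves as expected: accuracy is
monotone in the amide I shift magnitude and reaches 100% on strongly
separable cohorts.

## What passing tests show — and what they don't

The test suite establishes internal correctness (oracle equivalence of
centroids, replicate statistics and QC flags; conservation, monotonicity
and seeding contracts of the generator; bit-reproducibility of full runs)
and qualitative behaviours (reproducibility degrading toward the sparsest
axis, classifier power rising with effect size) on synthetic data whose
structure the generator itself defines. They do not certify instrument
performance: real serum spectra have richer band structure, correlated
noise, focus and atmospheric artefacts, and unknown effect sizes, so
absolute accuracies, ΔAbs/RSD magnitudes and centroid positions on real
data will differ from the synthetic values.
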