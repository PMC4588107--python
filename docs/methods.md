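# Methods

This note documents the models and procedures implemented in `nirsbci`, the
defaults chosen where the design was genuinely open, and what the synthetic
data can and cannot demonstrate.

## Probe geometry and the topographic grid

A channel ("point of interrogation") is a source–detector pair at the
pairing distance (3.0 cm); its midpoint localizes the measurement. The
default coordinates place 5 sources and 3 detectors in a trapezoid such that
exactly 9 pairs sit at 3.0 cm. These coordinates are a reconstruction: only
the 9-channel/3-cm constraints of the instrument are known, so they are
config-overridable, and nothing downstream depends on the absolute scale
(the grid mapping is scale invariant).

The topographic image raster is a 21-row trapezoid with parallel sides of 21
and 61 pixels; row widths grow linearly, a pixel belongs to the mask when
its center lies inside (boundary inclusive), giving 861 = ½(21+61)·21 mask
pixels. Channel midpoints are mapped by a per-row affine ("trapezoid
normalized") map: the narrow extreme of the channel layout lands on row 0,
the wide extreme on the last row, and each row's lateral extent is stretched
to the mask half-width at that row. A single global affine cannot map the
midpoint trapezoid onto the pixel trapezoid (their parallel-side ratios
differ), which is why the per-row form is used; it is invariant to uniform
scaling, translation, and reflection of the probe coordinates.

## Optics (MBLL)

Concentration changes are obtained by inverting the two-wavelength modified
Beer–Lambert system with base-10 extinction coefficients from the standard
compiled hemoglobin spectra (Gratzer/Kollias tabulation as distributed by
Prahl): ε(690) = (0.276, 2.052), ε(830) = (0.974, 0.693) mM⁻¹cm⁻¹ for
(HbO, Hb). The differential pathlength factor defaults to 6.0 at both
wavelengths (common adult-forehead convention) and the source–detector
distance to 3 cm. Since no instrument-specific ε/DPF values are available,
absolute µM scaling is conventional; every downstream feature is a slope, so
classification is invariant to this common scale. The reference intensity I₀
is the per-channel, per-wavelength mean over each block's 30-s baseline
(the protocol guarantees one per block); epochs additionally subtract their
first filtered sample, so any residual offset is irrelevant.

Whether filtering should precede or follow the MBLL inversion is not
determined by the design; concentrations are filtered here. At the optical
densities involved (|ΔOD| ≲ 0.02) the log nonlinearity is negligible, so
the order has no practical effect.

## Filtering and segmentation

The low-pass is a third-order Chebyshev type-I IIR (0.1 dB passband ripple,
passband edge 0.1 Hz, stopband from 0.5 Hz at ≤ −37 dB per the analog
prototype), realized as second-order sections and applied causally — a
single forward pass, matching a real-time feedback setting (zero-phase
filtering is available behind a flag). tHb is re-derived as HbO + Hb after
filtering. Task epochs are half-open 20-s windows from task onset
(625 samples at 31.25 Hz), 0-based sample indexing.

## Features

All features are least-squares slopes against a time axis normalized to
[0, 1] per window (0–5, 0–10, 0–15, 0–20 s). Normalizing time rather than
amplitude keeps slopes comparable across window lengths while leaving the
amplitude scale interpretable; features are therefore offset invariant and
homogeneous of degree 1 in the signal.

Spatial features summarize per-sample topographies: the 9 channel values are
interpolated to the mask pixels with Clough–Tocher cubic scattered-data
interpolation (exact at the channels and for planar fields) and reduced to
the orthonormal discrete Chebyshev (Tchebichef) moments η_pq, p+q ≤ 4,
computed with the unit-norm three-term recurrence on the 21×61 rectangle
with zeros outside the mask. Both operations are linear in the channel
values, so the extractor precomputes the composite (15×9) channel-to-moment
operator once and applies it to whole epochs; an oracle test confirms it
equals the explicit interpolate-then-sum path. Moment frames are computed at
every filtered sample (31.25 Hz); the 8 Hz feedback refresh of the original
display is a display property, not an analysis one.

One subtlety: for a spatially uniform frame the interpolated image is
constant *on the mask* but zero outside, so higher-order moments respond to
the mask shape itself. Moment slopes of a uniform ramp are consequently the
ramp slope times the mask's moment vector, not zero beyond order (0,0).

## Feature selection (FCBF)

Features are discretized into 10 equal-width bins fitted on the training
fold only, ranked by symmetrical uncertainty with the class
(SU = 2·I(X;Y)/(H(X)+H(Y)), base-2), kept when SU > δ with δ = 0, and pruned
by the approximate-Markov-blanket rule: walking the ranking, a feature j is
removed when an already-kept i has SU(i, j) ≥ SU(j, class) (with a 1e-12
tolerance guarding float-path differences at exact equality). Ties in the
ranking break by feature index; an empty selection falls back to the single
top-SU feature with a logged warning. Test folds never reach selection; a
leakage test asserts the training rows passed to fitting partition exactly
against the test folds.

## Classifier

The base learner is a two-class pooled-covariance linear discriminant. The
covariance uses the maximum-likelihood normalization (scatter/n), which
makes the discriminant exactly invariant under duplicating the training
sample, and receives a ridge γ·tr(Σ)/p·I with γ = 1e-6 so tiny folds with
few selected features stay well-posed. Bagging draws 10 bootstrap resamples
(training-fold size, with replacement; resamples missing a class are
redrawn, bounded retries); ensemble prediction is the member majority with
5–5 ties broken by the summed discriminant score. Each binary task-pair
unit holds three such ensembles — temporal, spatial, combined — with FCBF
refit per unit and per feature set; the unit's output is their majority
(three voters, two labels: never tied). Multi-class prediction tallies all
C(n,2) binary winners and returns the plurality class; ties go to the tied
class with the lowest index in the subset — deterministic and seed-free.

## Evaluation

Accuracy is the mean over 10 iterations of stratified 10-fold
cross-validation (100 fold accuracies); stratification keeps the 60
trials/class balanced across folds. Personalization evaluates every C(6,n)
subset (15/20/15/6 for n = 2…5) and returns the argmax, ties resolved to the
lexicographically smallest subset. Chance limits use the exact
Clopper–Pearson binomial interval around x = round(n_trials/n_classes)
successes at the per-class trial count (60 by default, α = 0.05); a Wald
option exists. At n = 60 and α = 0.05 the two-class limits are
(36.8 %, 63.2 %). An accuracy "exceeds chance" when it is above the upper
limit.

## Correlation stage

Per-participant best two-class accuracies are correlated with
characteristics: continuous variables (verbal IQ, the five session-averaged
7-point Likert items) via Pearson when the Shapiro–Wilk test does not reject
normality at 0.05, otherwise Spearman (logged); dichotomous demographics
(gender, handedness) via Spearman on 0/1 codes. P-values are two-sided,
significance is flagged at α = 0.1, missing values are dropped pairwise
(e.g. a participant who skipped the IQ test reduces that row's n by one),
and age is excluded by default because a homogeneous age range makes the
test uninformative. No multiple-comparison correction is applied by
default; Benjamini–Hochberg is available behind a flag.

## Synthetic-study generator

The generator emulates the protocol exactly: per block one 30-s baseline
then 24 intervals of 20 s task + 17 s rest, each of 6 tasks 4× per block in
a within-block randomized order; 5 sessions × 3 blocks ⇒ 60 trials/task;
9 channels at 31.25 Hz. Every random draw comes from a named substream of a
single seed, so runs are bit-reproducible and noise components are
individually re-generable.

Task responses are a canonical double-gamma HRF (peak 6 s, undershoot 16 s,
ratio 1/6) convolved with the 20-s task boxcar and scaled by a task-specific
signature over the 9 channels. Defaults: HbO amplitude 0.4 µM × signature,
Hb = −0.35 × HbO (tHb their sum, exactly). The signature map is designed so
task pairs span a wide range of separability — mental math and
relaxing-with-focus have strong opposite-signed patterns (the planted most
separable pair), word generation shadows mental math, slow counting shadows
happy thoughts, unconstrained rest is near-silent — because exercising
personalization requires exactly that heterogeneity.

Trial-to-trial variability, the dominant accuracy limiter in practice, has
two parts: a lognormal per-trial scale on the whole pattern (σ = 0.3) and a
per-trial, per-channel additive activation (σ = 0.5 µM) with the same HRF
time course, fully correlated across chromophores like a systemic
component. Background noise comprises the Mayer wave (0.1 Hz, 0.2 µM, with
phase random-walk), respiration (uniform in 0.2–0.4 Hz, 0.1 µM), cardiac
(1.1 Hz, 0.1 µM), 1/f drift (0.2 µM) and white noise (0.05 µM); Hb receives
the same processes at 0.4× amplitude. The optical forward model inverts the
MBLL exactly (round-trip < 1e-6 µM with noise off) and adds multiplicative
measurement noise of relative s.d. 1e-3. With these defaults the best task
pair of a simulated participant reaches ~90–95 % two-class CV accuracy and
the weakest pairs sit at chance; the "strong responder" preset
(`EffectSpec.strong()`, 3× amplitude) saturates the best pair near 100 %.
No effect sizes or SNRs are available for the original recordings, so these
magnitudes are free parameters chosen to reproduce a plausible accuracy
landscape; they were fixed before the acceptance runs and are not fitted to
any reported accuracy.

Participant profiles draw verbal IQ from N(100, 12²), Likert items from
clipped normals within [1, 7], and demographics from Bernoulli draws. An
optional coupling makes each participant's effect scale
exp(coupling·z(IQ) + jitter); negative coupling reproduces the
neural-efficiency direction (lower IQ → larger responses → higher accuracy)
as a *generator assumption*, used only to verify that the correlation stage
recovers a planted sign — not as a claim about the mechanism.

### What the synthetic data do not show

The generator's linear HRF + additive noise world omits scalp/systemic
compartments, motion artifacts, optode-coupling drift, session-to-session
nonstationarity, and habituation/learning. Passing tests therefore
demonstrate that the analysis pipeline is correct and well-calibrated
(e.g. shuffled labels fall inside the chance interval; planted structure is
recovered), not that any particular accuracy level is attainable on real
recordings.

## Problem sizes and numerical choices

Tests and the acceptance script simulate one to ten participants with one to
five sessions; the full five-session, single-participant two-class
personalization (360 epochs, 15 subsets × 100 folds) runs in tens of
seconds because feature extraction is a fixed linear operator and the LDA
folds are tiny. Degenerate inputs are rejected early with specific errors
(no channel at the pairing distance, singular extinction systems, unstable
filter designs, classes below the fold count, zero-variance correlation
inputs). Tie-breaks are deterministic everywhere (feature index, summed
discriminant score, lowest task index, lexicographic subsets), so fixed
seeds reproduce results bit for bit.
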