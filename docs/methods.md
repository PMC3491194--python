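# Methods

`dualbead` models a dual-platform MALDI-TOF serum-profiling study: every
serum sample is worked up twice — weak-cation-exchange (WCX) beads whose
eluates are acquired in linear mode (960–11,024 Da, broad unresolved
peaks) and reversed-phase C18 (RPC18) beads acquired in reflectron mode
(600–4,000 Da, isotopically resolved peptides) — spotted in quadruplicate,
quantified into two peak matrices, classified per platform by double
cross-validated linear discriminant analysis, and fused at the prediction
level. This note records the models, the parameter choices and why, and
what the synthetic experiments do and do not demonstrate.

## Synthetic cohorts

**Peak heights.** A sample's log peak heights are
`base + cv·(ρ·u_g + sqrt(1−ρ²)·ε) + ln2·log2FC·[case]`, where `u_g` is a
latent per-sample factor shared by all marker peaks of one *factor group*
and `ε` is peak-specific. Groups model parent proteins: discriminating
serum peptides are largely cleavage fragments of a few proteins
(fibrinogen alpha, complement C3f and ITIH4 in the reversed-phase
peptidome), and fragments of one protein co-vary strongly. The RPC18
markers are grouped into three such families (7/5/4 peaks), the WCX
markers into two (5/5); loading ρ = 0.7 gives within-family pairwise
correlations near 0.5. The biological draw is made once per sample and
shared by its replicates; technical noise, calibration drift and spotting
failures are per spectrum.

**Effect sizes.** The clinical study publishes no fold changes, so the
defaults are a documented choice: |log2 FC| = 0.6 at biological CV 0.35
on 10 WCX markers (negative — cases lower, matching the sign pattern of
the published t values) and 16 RPC18 markers (positive). This calibration
was chosen so the *standard* scenario lands in the published performance
regime (single-platform AUC ≈ 0.9, combined ≈ 0.95) and was frozen before
the acceptance experiments were written. The *complementary* scenario
keeps effects on half of each platform's markers (5 WCX / 8 RPC18), with
the WCX per-peak effect scaled by √(8/5) so both platforms carry equal
total signal — mirroring the near-equal single-platform performance of
the clinical cohorts (AUC 0.91 vs 0.89). The *null* scenario removes all
effects but keeps the covariance structure.

**Spectra.** Peaks are Gaussian with FWHM affine in m/z (WCX
2.0 + 1.5·10⁻³·m Da, giving ~5 Da at 2 kDa; RPC18 0.05 + 5·10⁻⁵·m Da,
resolving the 1.00235 Da isotope spacing on a 0.02 Da grid). RPC18 peaks
are rendered as singly charged isotope clusters whose relative abundances
follow a Poisson law with rate λ = 4.75·10⁻⁴ × mass — the averagine-style
approximation, adequate below ~4 kDa. The chemical baseline decays
exponentially from the low-mass end; technical noise is multiplicative
Gaussian per grid point (CV 0.08); the mass axis of each spectrum is
multiplied by 1 + drift·10⁻⁶ with drift ~ N(0, 150 ppm) for linear mode
and N(0, 80 ppm) for reflectron mode. Spotting failures (probability
0.02 per spot, matching the 0.7–2.7 % exclusion rates of the real
cohorts) leave only a tiny noise floor, small enough that a failed spot's
total ion current stays well under the no-signal threshold on both grids.

**What the simulator does not model:** chemical-noise matrix clusters,
multiply charged ions, detector saturation, peak-shape asymmetry,
spot-to-spot intensity gradients, or batch effects. Passing tests show
the *pipeline* behaves correctly under a plausible generative model; they
are not evidence about any particular clinical dataset.

## Profile processing

**Baseline.** Morphological: a moving minimum (window 500 Da WCX / 5 Da
RPC18 — much wider than any peak, much narrower than the baseline's decay
length) smoothed by a moving average (window/5), subtracted and clipped
at zero. The estimator never increases an intensity and never produces a
negative one. Its residual on a pure exponential baseline of decay length
L is ≈ A·(1 − e^(−w/2L)): under 5 % for w ≤ L/10.

**Internal recalibration.** Calibrant peptides: m/z 1465.8, 1778.1,
1865.2, 2602.5, 2931.5 for RPC18 with tolerances interpolated linearly
from 100 ppm (at 1465.8) to 300 ppm (at 2931.5); seven visually selected
peaks 1866.1–9290.9 for WCX with a configurable ±1000 ppm tolerance
(linear-mode accuracy; the study states none). Matching is two-stage:
a coarse pass (window twice the widest tolerance) estimates the median
relative shift of the spectrum — the *alignment* step — and the stated
per-calibrant tolerances then apply around the shifted positions. A
single-pass matcher would cap recoverable drift at the third-widest
tolerance (~155 ppm); the two-stage form recovers the full ±300 ppm
reflectron drift range. Within a search window the calibrant is the
*lowest-m/z local maximum above half the window maximum*, because above
~2.1 kDa the second isotope of a peptide is taller than the monoisotopic
peak and a plain argmax would return the wrong isotope. Apex positions
are refined by a three-point parabola (sub-grid accuracy; noise-free
planted drifts recover to well under 1 ppm RMS, and ≤ 10 ppm is the
accepted bound). The affine fit `m' = a·m_obs + b` is ordinary least
squares of expected on observed positions and requires ≥ 3 matched
calibrants; fewer marks a calibration failure.

**QC.** A spectrum is excluded when its (baseline-corrected) total ion
current falls below 5 % of the platform's cohort median — the no-signal
rule — or, by default, when recalibration failed (an unalignable spectrum
cannot be quantified in fixed windows; the original study is silent on
this case, so the behaviour is configurable). Exclusion decisions depend
on the cohort only through the median TIC and are therefore invariant to
spectrum ordering. A cohort exceeding a 2.5 % exclusion rate warns.
Percentages are reported half-up at one decimal, the convention that
reproduces the published 2.7 % (33/1,228) and 0.7 % (8/1,228) exactly.

## Quantification

Fixed windows per platform (the "reference file"): WCX windows scale with
local peak width (2.5 × FWHM clipped to 5–30 Da, one apex); RPC18 uses
0.49 Da windows per isotope, three isotopes per peptide, summed into one
cluster intensity. Windows are half-open `[lo, hi)` so adjacent isotope
windows partition the axis; reference sets reject overlapping windows at
construction. The per-window statistic is the apex (maximum) intensity —
robust across the very different window widths; an integral option was
considered and rejected because the broad WCX windows would then weight
peak width as much as height. Isotope-distribution QC compares observed
isotope ratios with the Poisson envelope and demotes a cluster whose
ratio deviates by more than 50 % (relative) to missing *for that
replicate only*; isotopes expected below 10 % of the monoisotopic
abundance are not tested (they sit at the noise floor and carry no
diagnostic power). Replicate averaging takes the arithmetic mean over
non-excluded replicates, ignoring demoted cells; a sample with no
surviving replicate is dropped with an error naming it, and a cell with
no surviving measurement is reported as 0 with a warning (the peak is
effectively absent for that sample).

## Classification

**Base rule.** Per platform: log(1+x) transform, per-peak centring and
scaling by the pooled *within-class* SD, projection onto the leading
principal components, and Fisher LDA with Gaussian class-conditionals on
the components. Within-class scaling matters: scaling by the total SD
normalizes every column to unit variance and thereby erases exactly the
between-class variance that lets the unsupervised reduction retain a
displaced peak — with total-SD scaling an arbitrarily strong isolated
marker is provably invisible to correlation PCA. All statistics
(means, scales, components, covariances) come from training folds only.
The pooled covariance is the n-normalized (maximum-likelihood) estimator,
which makes the fit invariant to duplicating the training set; a singular
covariance receives a logged ridge of 10⁻⁸ × trace. Class priors default
to the *cohort* prevalence — a study-design constant — rather than
training-fold proportions, because a training fold's prevalence is
mechanically anti-correlated with its held-out fold's composition, which
systematically skews cross-validated posterior probabilities against the
minority class (the effect is dramatic for leave-one-out).

**Double CV.** The outer loop (leave-one-out, or stratified k-fold with
optional repeated partitions whose held-out probabilities are averaged)
is purely for assessment; for each outer training set an inner stratified
5-fold CV selects the PCA dimension from {0, 1, 2, 5, 10} by minimum
deviance (ties to the smaller dimension; a one-standard-error parsimony
rule is available). Dimension 0 is the intercept-only null model — on
uninformative data the rule can honestly decline to discriminate instead
of chasing chance structure. Every sample receives exactly one held-out
probability per partition; probability vectors are clipped to
[10⁻⁶, 1−10⁻⁶] before any log-loss. Single full-scale runs default to
leave-one-out; the simulation studies use stratified 5-fold with 3
repeated partitions, which keeps the well-documented pooled-CV AUC
pessimism negligible at n = 100.

**Fusion.** The two platforms' held-out probability vectors p¹, p² are
combined at the prediction level. MIX is the linear mixture
α·p¹ + (1−α)·p², with α chosen on a 101-point grid by minimum deviance
inside the combiner's own stratified CV layer over samples (ties toward
α = 0.5); each fold's candidate set includes the prior-only constant, and
the fitted mixture is used only when it beats that constant by one
standard error of the paired per-sample deviance difference on the
training part — so two uninformative inputs combine to an honestly flat
prediction. RF (random forest, 300 trees, minimum leaf 5, seeded) and LG
(essentially unregularized logistic regression) are confirmatory
combiners under the same cross-validated scheme. Spectrum-level fusion
is out of scope: a 1 Da linear-mode grid and a 0.02 Da reflectron grid
cannot meaningfully be summed into one spectrum.

**Metrics.** Sensitivity, specificity and total recognition rate at the
0.5 posterior cut (samples exactly at the threshold are called cases);
Brier score as plain mean squared error (the convention matching the
published 0.084–0.11 magnitudes); deviance with natural logs on clipped
probabilities; AUC as the Mann–Whitney rank statistic with half credit
for ties. The quadrant summary places each sample in the
(x = p_RPC18, y = p_WCX) plane with the published numbering — 1 =
upper-left, 2 = upper-right, 3 = lower-left, 4 = lower-right — counting
quadrant-1/4 samples as discordant and recovered when the combined rule
classifies them correctly.

## Marker selection

The weighted discriminant coefficient of a peak is the canonical
discriminant direction (unit pooled within-class variance, cases
projecting higher) of each outer training fold, back-projected from
component space to standardized peak space, multiplied by the peak's
pooled within-class SD there, and averaged over folds. It measures the
peak's contribution to the discriminant on a dimensionless scale; scores
negate exactly under a label flip. Peaks with |coefficient| above a
platform cut-off form the reduced panel (the clinical analysis used ±2
for WCX keeping 10 of 48 peaks and ±3.75 for RPC18 keeping 16 of 42; the
coefficient scale depends on effect sizes, so synthetic runs set their
own cut-off, 0.15 by default), on which the within-platform rule is
refit under the full double CV to check that performance survives
selection. The per-peak univariate statistics are pooled-variance
Student's t tests (Welch optional) on the case − control mean difference
with a 95 % CI; no multiple-testing correction by default (none is used
in the clinical analysis; Benjamini–Hochberg is available).

## Simulation studies and their problem sizes

The standard experiments (in `dualbead.experiments`) use cohorts of 100
samples at the study prevalence (34 cases / 66 controls), generated at
the peak-matrix level — the biological and technical-replicate layers of
the simulator, i.e. what the classifier sees after preprocessing — with
stratified 5-fold outer CV over 3 repeated partitions, 20 seeds each:

* **Null calibration** — zero effects; mean held-out AUC per platform and
  for MIX stays near 0.5, the behavioural no-leakage check.
* **Fusion benefit** — complementary cohorts; MIX deviance below both
  single platforms in ≥ 18/20 cohorts, the qualitative mirror of the
  published "deviance improved markedly for the combination".
* **Marker recovery** — one strong marker (log2 FC = 1, CV 0.35) among 29
  noise peaks tops the coefficient ranking; under the null the t test
  flags ~5 % of peaks (99 % binomial bounds).
* **Drift recovery** — noise-free reflectron spectra with planted drifts
  up to ±300 ppm recalibrate to ≤ 10 ppm residual RMS (in practice ≪ 1).

Full spectrum rendering is exercised at the complete 307 × 4 scale by the
cohort-accounting check and by the end-to-end run of the reproduction
script. These sizes were chosen as the smallest at which the effects of
interest are comfortably resolved.

## Known limitations

* The generative model is additive-Gaussian on the log scale with block
  covariance; real serum profiles show heavier tails, intensity-dependent
  noise and batch structure.
* The no-signal rule keys on total ion current; a spectrum with signal
  only outside the quantification windows would pass QC yet contribute
  little.
* The weighted-coefficient scale is not comparable across studies —
  cut-offs must be recalibrated per dataset.
* Pooled cross-validated probabilities retain a small pessimistic
  ranking bias at small n even with cohort priors and repeated
  partitions; per-fold averaging of AUC would remove it but would not
  produce the per-sample probability vectors the fusion stage needs.
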