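# Methods

This note records the scientific and numerical choices behind the
pipeline, in the order the method runs.

## Records, labels, groups

A recording is three bipolar abdominal channels (CH1 = E2−E1, CH2 = E2−E3,
CH3 = E4−E3) sampled at 20 Hz for ~30 minutes, with two gestational ages in
the header: the week at recording and the week at delivery. Labels and
groups are pure threshold functions of those weeks: delivery strictly
before week 37.0 is *preterm*; recording strictly before week 26.0 places
the subject in the *early* cohort (PE-TE), otherwise *late* (PL-TL). The
strict-inequality reading of "prior to the Nth week" is a convention;
both thresholds are module constants. TPEHG-style headers store each
channel in several pre-filtered versions; the reader takes the raw
signals (indices 0/4/8 of a 12-signal header by default, configurable)
and applies this package's own filter. Records with missing gestational
metadata are skipped with a warning during cohort loads rather than
aborting the load.

## Preprocessing

Fourth-order Butterworth band-pass, 0.08-4 Hz, realised in second-order
sections (the 0.08 Hz corner at fs = 20 Hz is ill-conditioned in transfer-
function form) and applied forward-backward. Zero-phase application was
chosen over causal because it preserves contraction timing; the squared
magnitude response (effective order 8) is what the filter-gain tests
check. A causal option remains behind `FilterSpec(zero_phase=False)`.
Five minutes are trimmed from each end *after* filtering, so the discarded
segments absorb the transients; a 30-minute record leaves a 24,000-sample
analysis segment.

## Empirical mode decomposition

Sifting with the two classical IMF conditions (extrema/zero-crossing
counts differ by at most one; envelope mean near zero). Choices the
classical description leaves open, frozen here:

* **Stopping.** A candidate is accepted when the count condition holds
  and either the Cauchy criterion `SD = Σ(y_{k−1}−y_k)²/Σy_{k−1}² < 0.2`
  or the envelope-mean ratio `mean|m|/mean|y| < 0.01` is met. Hard cap of
  100 sift iterations; hitting it logs a warning and keeps the current
  candidate (under-sifting distorts less than over-smoothing).
* **Envelopes.** Natural cubic splines. Natural (rather than not-a-knot)
  boundary conditions are frozen for reproducibility across spline
  implementations.
* **End effects.** The first and last two extrema are mirrored about the
  signal ends before spline fitting.
* **Plateaus.** A run of equal samples bounded by opposite slopes is one
  extremum at the floor-midpoint index.

Decomposition keeps at most four IMFs (high to low frequency) and stops
early on a (near-)monotone residue. Reconstruction is exact by
construction and asserted at 1e−8 relative in tests; an independently
coded loop-based sifting of the same procedure serves as a second route in
the test suite.

## Features

Six parameter-free descriptors per channel × IMF (72 total), ordered
channel-major then IMF then kind (RMS, MTKE, WLE, SE, KFD, HE):

* **WLE** is implemented literally as the log-energy sum `Σ ln(x[n]²+ε)`
  with ε = 1e−12 guarding zeros; natural log.
* **SE** is the Shannon entropy of the amplitude histogram, 128
  equal-width bins over the sample range, base-2 logs, zero for a
  constant signal. The bin count is structural, not tuned; it is the one
  configurable knob in the feature set.
* **KFD** uses `ln(N−1)/(ln(N−1)+ln(D/L))` with curve length
  L = Σ|xᵢ−xᵢ₋₁| and diameter D = maxⱼ|x₁−xⱼ|; D ≤ L gives KFD ≥ 1, and
  a strictly monotone waveform (D = L) returns exactly 1.
* **HE** uses the rescaled-range convention: S is the standard deviation,
  R the range of the cumulative sum of mean-centred samples. The literal
  alternative (range of the centred samples themselves) is available via
  `hurst(x, cumulative_range=False)`. Note the single-scale R/S estimate
  has a known positive small-sample bias (~0.53 for white noise at
  N = 10⁴), which is fine for a discriminative feature.

If a degenerate channel yields fewer than four IMFs, the missing slots are
filled from the final residue and the record is flagged — the 72-column
contract survives while the anomaly stays visible.

## Balancing

Synthetic minority rows are convex combinations of two real minority
parents, which keeps every synthetic value inside its parents' per-feature
range by construction. "Self-adaptive" is realised without user-set
neighbourhood parameters: a sample's generative weight is the rank of its
mean distance to the rest of the minority cloud (sparser regions get more
synthetic mass), and partners come from its ⌈√(m−1)⌉ nearest minority
neighbours. Interpolation weights are Uniform(0,1). A plain SMOTE strategy
(uniform parents, k = 5) sits behind the same interface for comparison.
Balancing runs per cohort group, after feature extraction.

## Feature screening

Two-sided Mann-Whitney U per feature, term vs preterm, selection at raw
p < 0.05. U = min(U₁, U₂) with midranks for ties; pooled n ≤ 16 uses exact
enumeration of all group assignments, larger samples the normal
approximation with tie and continuity corrections (verified to agree with
the standard asymptotic implementation to 1e−12). No multiple-testing
correction by default — the screen is a filter, not an inference; a Holm
option exists for sensitivity analysis. The screen runs on the balanced
table, matching the stage order of the pipeline; screening before
balancing is possible by calling the stages directly.

## Classification protocol

The central rule: **no real preterm row ever enters training or
validation.** All real preterm rows go to the test set, all synthetic
preterm rows to training, and term rows split 70/30 at a per-repeat seed.
This is asserted programmatically on every repeat, not merely intended.
Min-max normalisation uses training statistics only (test values may leave
[0,1]; a degenerate training feature passes through as 0.5).

Hyperparameters are tuned by Gaussian-process expected improvement
(Matern-5/2 surrogate, random initialisation, 256-candidate acquisition
maximisation) over mean stratified 10-fold CV AUC, with a seeded
random-search fallback. Default budget: 30 evaluations. Search boxes:
AdaBoost (10-500 estimators log-scale, learning rate 0.01-1), RBF-SVM
(C, γ ∈ 1e−3-1e3), decision tree (depth 1-20, min leaf 1-20), random
forest (50-500 trees, depth 2-20).

Test metrics: confusion counts at the 0.5 probability threshold give
Sen = 100·TP/(TP+FN), Spe = 100·TN/(TN+FP), Acc; the ROC is built by
sweeping all distinct scores and AUC by trapezoidal integration, which
equals the rank statistic U/(n₁n₂) (asserted to 1e−12). The sensitivity
restricted to real preterm rows is reported alongside. "Mean" metrics are
means over `n_repeats` full pipeline repetitions (default 10) with
per-repeat balancing/split seeds — the only reading that yields a
distribution of sensitivities for classifier comparison, done by pairwise
paired t-tests with Holm step-down adjustment.

## Synthetic cohorts

The generator emulates the geometry of the real recordings (20 Hz,
1800 s, three channels) and one physiological premise: preterm records
have stronger and more frequent contractions. Contractions are Poisson-
arriving Hann-windowed chirps inside 0.1-3 Hz, 20-60 s long; defaults are
0.3 bursts/min at amplitude 1.0 (term) vs 0.8 bursts/min at amplitude 2.0
(preterm). Out-of-band contaminants — slow drift at 0.01-0.05 Hz and
5-9 Hz noise — are included so the band-pass filter has observable work
(50 Hz mains is unrepresentable at fs = 20 and omitted). Channels are one
latent source plus correlated noise (shared-noise fraction 0.7). What the
generator does **not** model: uterine electrophysiology, electrode
geometry, fetal/maternal ECG, artifacts, or the weak, overlapping class
separation of real cohorts. Passing end-to-end tests therefore
demonstrates that the machinery is correct and the protocol is honoured
under a detectable effect — not that real-data accuracy would match; the
generator's class gap is deliberately large, and the near-ceiling metrics
on synthetic cohorts reflect that gap, not clinical performance.

## Problem sizes used in checks

The end-to-end check runs the PE-TE cohort shape (143 term + 19 preterm
records, full 1800 s each), AdaBoost only, 5 repeats, tuning budget 10 —
sizes chosen to exercise the full method at the published cohort geometry
while keeping a single-CPU run in minutes. Property checks use 100 random
signals (EMD, features), 10,000 null simulations (test size), and 50
random score sets (AUC identity).

## Known limitations

* Single-scale R/S Hurst and histogram entropy are simple conventions;
  the literature contains many variants.
* The self-adaptive over-sampler follows the stated contract (parameter-
  free, density-adaptive, interpolative, exact balance), not a specific
  third-party implementation.
* Screening on the balanced table lets synthetic rows influence feature
  choice; the stage order is faithful to the pipeline but debatable.
* With all real preterm rows in the test set, test sets across repeats
  share those rows; repeat variability reflects term sampling, balancing
  and tuning randomness only.
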