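# Methods

`driftseize` implements a patient-specific seizure-prediction pipeline for
long-term scalp EEG, with explicit adaptation to concept drift — the slow or
abrupt changes in brain dynamics (medication tapering, sleep/wake structure,
recording conditions) that degrade a classifier trained once and frozen.
This note records the model, its assumptions, the tunable parameters, and
the numerical and design choices a maintainer would want to know.

## The prediction problem

Each lead seizure (separated from the previous seizure by at least the
independence gap, default 4.5 h) defines a *seizure occurrence period* (SOP)
of 10–50 min, preceded by a *seizure prediction horizon* (SPH) of 10 min.
An alarm raised at time *t* is a correct prediction if a seizure onset falls
in `(t + SPH, t + SPH + SOP]`: the patient gets at least SPH minutes of
warning, and the seizure is expected within the following SOP minutes.
Epochs are labelled preictal inside `[onset − SPH − SOP, onset − SPH)` and
interictal elsewhere; SPH, ictal and a configurable postictal exclusion
window (default 30 min) belong to neither class and are dropped from
training.

## Pipeline

1. **Pre-processing** — zero-phase mains notch (Q = 20, 50/100 Hz) followed
   by a 4th-order Butterworth band-pass (0.5–100 Hz), then segmentation
   into 5-s non-overlapping epochs. The notch runs first because the slow
   band-pass edge response would otherwise smear notch transients over
   seconds. Filter edge transients are confined to roughly the first/last
   second; the functions expect continuous recordings, not snippets.
2. **Features** — 59 univariate linear features per epoch per channel:
   relative spectral power in eight bands (delta, theta, alpha, beta, four
   gamma sub-bands skipping the 47–53 and 97–103 Hz notch gaps), all 28
   pairwise band-power ratios, spectral edge frequency at the 50/75/90/95 %
   power percentiles and edge power at 50/75/90 % (range 0.5–100 Hz), alpha
   peak frequency, total power, power-weighted mean frequency, db4 wavelet
   detail energies D1–D5 (periodization boundary), the four statistical
   moments (kurtosis non-excess), the three Hjorth parameters (derivative =
   first differences), and the decorrelation time (first autocorrelation
   crossing of 1/e, capped at half the epoch). Spectra are Hann-tapered
   periodograms (0.2 Hz resolution on 5-s epochs, Parseval-consistent);
   band intervals are half-open `[low, high)`; the ratio guard is
   `eps = 1e-12`. The registry is data-driven and serialisable; 59 entries
   are enforced unless explicitly overridden.
3. **Retraining schedule** — Add-One-Forget-One: the model is retrained
   after every seizure on the three most recent past seizures and tested on
   the next unseen one; a Chronological variant (keep all past seizures) is
   available behind a flag. Patients need at least four lead seizures.
4. **Hyperparameters** — grid search over SVM cost
   (2⁻¹⁰ … 2², powers of two), number of features (10/20/30/40, one-way
   ANOVA-F filter ranking, ties to the smaller column index) and SOP
   (10–50 min in 5-min steps). Each combination is scored by
   leave-one-seizure-out over the three training seizures with the
   geometric mean of sample sensitivity and specificity; ties break toward
   the smaller SOP (shorter occurrence periods burden the patient less),
   then smaller cost, then fewer features. Standardisation (z-scoring,
   population SD, zero-variance features flagged and mapped to 0) and
   feature ranking are fitted inside each fold; the test seizure is never
   touched.
5. **Class imbalance** — the control pipeline uses systematic random
   undersampling (majority class sampled at a fixed stride through
   chronological order with a seeded random phase); the drift-adaptive
   pipelines use inverse-frequency class weights normalised so weighted
   counts are conserved.
6. **Alarms** — the binary classifier outputs are smoothed by the Firing
   Power, a causal moving average over one SOP of epochs with zero-padded
   warm-up; an alarm fires on an upward crossing of the fixed 0.5 threshold
   (half of the unit scale, deliberately untuned) outside refractory
   periods. Each alarm opens a refractory period equal to the SOP; a trace
   still at/above threshold when refractory expires re-alarms immediately,
   so a saturated trace yields exactly one alarm per refractory period.
   FPR/h divides false alarms by interictal hours minus all refractory
   time the alarms opened.
7. **Statistical validation** — surrogate analysis: each tested seizure's
   onset is redrawn uniformly within its own interictal interval (at least
   SPH + SOP from the interval start so the surrogate preictal fits),
   seizure by seizure, 30 times; the unchanged alarms are rescored and a
   one-sample t-test asks whether the real sensitivity exceeds the
   surrogate distribution (α = 0.05). A degenerate surrogate distribution
   (zero variance) is decided by direct comparison.

## Drift adapters

All three are blind adapters (no drift-detection trigger); they differ in
*which past data* the final SVM learns from at each retraining.

**Backwards-Landmark Window (BLW).** Candidate windows grow backwards from
the most recent training timestamp in 1-hour steps; an SVM (inverse-
frequency class weights) is trained per candidate and scored by a
leave-one-out estimate of its error. The default estimator is the
classical ξα bound, `|{i : α_i R² + ξ_i ≥ 1}| / n`, with α the dual
coefficients, ξ the hinge slacks and R² the largest kernel self-similarity;
it upper-bounds (and is computed alongside, in tests, against) the exact
leave-one-out error obtained by n retrainings. The window minimising the
estimate wins (smallest window on ties); the search stops once the best
estimate has not improved over the last 12 hours of window growth. The
estimate is computed on the whole candidate window by default
(`eval_on="latest_batch"` evaluates only the newest hour instead).

**Seizure-batch Regression (SbR).** For every non-empty chronological
subset of the training seizures, an L2-regularised logistic regression
(C = 1, balanced class weights, intercept excluded from the comparison) is
fitted on the standardised selected features, and its weight vector is
compared — by the angle `θ(w₁, w₂) = arccos(w₁·w₂ / (‖w₁‖‖w₂‖))` — with a
reference regression fitted on the most recent seizure alone. Small angles
mean "same concept". Because the reference subset itself sits at exactly
0°, selection uses a tie band: subsets within 45° of the minimum (the
midpoint between aligned and orthogonal) are tied, and the tie breaks
toward the larger subset — more data from the same concept. The final SVM
trains on the selected subset.

**Dynamic Weighted Ensemble (DWE).** One base SVM per 1-hour period of the
training span, each trained on its own period's rows so that a period
overlapping a preictal window captures that seizure's concept;
pure-interictal hours borrow the current-concept preictal rows (the last
2 h before the most recent training seizure — the ensemble's definition of
the current concept) so every base model is trainable. Base models are
weighted by their accuracy on that same 2-hour concept window
(normalised to sum to 1; all-zero accuracies fall back to uniform with a
warning) and combined by weighted voting, with the 0.5 tie voting preictal
to favour sensitivity. Periods with fewer than 12 interictal epochs are
skipped.

A design note on DWE: weighting strictly by accuracy is a soft mechanism.
If pure-interictal base models were given a pooled preictal class from
*all* training seizures, a majority of stale-concept models could never be
outvoted after a concept inversion (weights are bounded by 1), and the
ensemble would collapse onto the static model; tying the borrowed preictal
class to the current concept is what lets the ensemble adapt, and is
consistent with its own current-concept assumption.

## Synthetic data

The generator emulates the *statistical structure* the pipeline consumes —
not clinically realistic EEG morphology (no spikes, artefact taxonomy or
montage effects). Two tiers share one specification (≥ 4 lead seizures,
default 4.5-h independence gaps, preictal duration default 20 min, SPH
10 min, drift schedules: none, abrupt sign-flip from seizure *k*, or
gradual decay `1 − rate·k` floored at −1):

* **Raw-signal tier** — per channel, unit-RMS 1/f background scaled to
  20 µV and band-limited to 0.5–128 Hz (so relative band powers of the
  background sum to ~1 over the analysis range); preictal windows add
  band-centre sinusoids whose amplitude is calibrated analytically so the
  boosted bands' relative power rises by `signal_band_boost` (default
  0.25) — verified end-to-end through the feature battery to within a few
  percent; ictal segments are 3-min high-amplitude amplitude-modulated
  4-Hz rhythms. A negative drift multiplier moves the burst to the theta
  carrier (signature inversion).
* **Feature-stream tier** — per-epoch rows drawn directly from class
  distributions: per-column base mean ~ N(0, 4) and SD ~ U(0.5, 1.5), AR(1)
  temporal correlation (coefficient 0.9 per 5-s epoch, rescaled as
  `0.9^(w/5)` for epoch length *w* so correlation is a property of elapsed
  time), and a preictal mean shift of `effect_size` (default 1.5) SD on a
  named signature subset (alpha up, delta down, theta up, Hjorth mobility
  and mean frequency up), identically in every channel block.

What passing tests show — and do not show — about real data: the synthetic
preictal state is a stationary mean shift with Gaussian AR(1) noise, so
tests demonstrate that the machinery (labelling, selection, adaptation,
alarm logic, validation) behaves correctly and that the adapters recover
planted drifts; they cannot demonstrate clinical prediction performance,
which depends on real preictal electrophysiology and artefact structure.

## Problem sizes

Unit and end-to-end tests, and the acceptance script, run compact
feature-stream cohorts: 1 channel, 30–60-s epochs, 2.5-h seizure spacing
(4.5-h where the 2-h DWE concept window or the surrogate geometry needs
headroom), 4–5 seizures per patient, reduced hyperparameter grids. These
are the package's own simulation-scale choices; all structural invariants
(≥ 4 lead seizures, preictal inside its own gap, chronology) hold at every
scale, and the raw-signal tier is exercised end-to-end on compressed
(~2-h) recordings.

## Known limitations

* **The surrogate t-test is anti-conservative for chatty predictors.** The
  one-sample t-test treats the achieved sensitivity as a fixed constant,
  ignoring its own binomial variance (typically 2–3 tested seizures per
  patient). Measured here: a no-skill predictor emitting the preictal base
  rate almost never alarms and is validated for 0/100 synthetic patients;
  but an SVM *trained on pure-noise features* predicts near the 0.5 Firing
  Power threshold, alarms at high coverage, and is falsely validated for
  roughly 30 % of patients at realistic seizure spacing. Validation
  verdicts should therefore always be read alongside FPR/h.
* The ξα estimate is a bound, not an unbiased estimate; it is pessimistic
  on small windows, which biases BLW mildly toward larger windows on
  stationary data (the desired behaviour, but not a calibrated error).
* FPR/h subtracts the full refractory period of every alarm from the
  denominator without capping at the recording end; with alarms near the
  end of short test spans the denominator can reach zero (FPR/h = ∞).
* The CNN-based artefact removal used upstream of the original feature
  battery is out of scope; standard band-pass/notch filtering stands in,
  so gamma-band features on real scalp EEG would retain muscle artefact.
* EDF files are read (via MNE) but not written; the lossless text
  round-trip format is CSV plus a JSON annotation sidecar.
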