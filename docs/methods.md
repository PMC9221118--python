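# Methods

## Signal model and what the simulator emulates

The simulator produces 14-channel recordings mimicking a consumer EEG
headset: 10–20 montage (AF3, F7, F3, FC5, T7, P7, O1, O2, P8, T8, FC6, F4,
F8, AF4), 128 Hz sampling, 16-bit ADC, amplitudes in µV referenced as
acquired (the reference scheme is not modeled; signals are treated as
already referenced).

During each stimulus event the four prefrontal channels carry one alpha
oscillator (centered 10 Hz) and one beta oscillator (centered 20 Hz).
Oscillators are amplitude-stable sinusoids with a slow random-walk phase
drift (0.02 rad/sample, linewidth ≈ 0.01 Hz), so their window-averaged power
is exactly A²/2 while remaining non-phase-locked across events and channels.
Per-channel band powers are solved analytically from the planted per-emotion
targets:

* the arousal target fixes total beta power as `arousal × total alpha power`,
  spread equally over the four channels;
* the valence target splits the F3+F4 alpha-power sum S (default 2 µV²) as
  `αF4 = (S+V)/2`, `αF3 = (S−V)/2`; the inversion is under-determined, so it
  is made unique by setting each AF-channel alpha power to the F-channel
  mean (S/2). Valence targets must satisfy |V| < S.

Default planted layout (arousal ratio, valence µV²): happy (2.0, +1.0),
sad (0.5, −0.5), angry (2.5, −1.0), fear (2.2, −0.8) — the standard Thayer
plane with happy as the only positive-valence emotion, sad the only
low-arousal one.

All channels carry independent 1/f background noise (spectral shaping of
white noise, flattened below 1 Hz, scaled to a target RMS; default 10 µV,
a realistic resting-EEG amplitude). Transitions carry background only.
Non-frontal channels exist so montage handling and file IO are exercised;
they never carry signal.

What the simulator does *not* emulate: ERP morphology, ocular/EMG artifacts
(a synthetic high-amplitude transient injector stands in), volume
conduction, inter-channel correlation of background noise, and
non-stationarity of band power within an event. Passing tests therefore
demonstrate that the estimators and decoders are correct and calibrated on
signals obeying the band-power model — not that real paediatric EEG would
yield the same effect sizes.

## Preprocessing

Band-pass filtering is a 4th-order Butterworth applied forward–backward
(`sosfiltfilt`), giving zero phase so epochs stay aligned; bands are alpha
8–12 Hz and beta 12–28 Hz. "Instantaneous" band power is realized as a
sliding window: mean of squared band-filtered samples over 1 s windows
(≥ 8 alpha cycles) hopped every 0.25 s. Windows overlapping the first or
last second of a recording are dropped as filter warm-up. A window whose
center lies inside `[onset, onset + duration)` belongs to that stimulus;
windows straddling an event boundary therefore mix event and transition
signal, which biases per-event mean valence ≈ 2.5% low (the arousal ratio
is immune because alpha and beta share the envelope).

Artifact rejection replaces manual visual inspection with two reproducible
rules: reject a window if any prefrontal channel exceeds ±100 µV inside it,
or if its total frontal alpha+beta power has a z-score > 5 across the
recording. Both thresholds are configurable; `∞` disables a rule.

Degenerate inputs: a zero alpha denominator drops the window (logged)
rather than clamping, keeping the ratio interpretable; recordings shorter
than one window yield an empty series with a warning.

## Features and normalization

Arousal and valence are computed exactly as the four-channel sums/difference
printed above (not means — the two differ only by a constant). Features are
z-scored per participant-session by default, which removes inter-session
gain/impedance drift and makes sessions comparable; per-participant-study
scope is available. Normalization happens after epoching; since the z-score
is an affine map, order only matters through which windows enter the
moments, and epoch-restricted moments match the decoding instance set.

## Decoding

The classifier is a feed-forward network with exactly 2 input, 3+3 hidden
and 4 output nodes — tanh hidden activations, softmax/cross-entropy output,
full-batch L-BFGS training, max 2,000 iterations, tolerance 1e-6, seeded
initialization (scikit-learn `MLPClassifier`). Evaluation is stratified
k-fold cross-validation (default k=10): folds disjoint, exhaustive, class
proportions preserved to ±1 instance; repeats re-draw fold assignments and
average. The decoding instance is one feature window (not one epoch),
matching the instantaneous-feature design; epoch-level grouping would
remove within-epoch leakage but is not the modeled procedure. The
comparison model is a linear-kernel SVM (C=1): arousal/valence class
layouts are generally not linearly separable, and on XOR-style layouts the
network retains a large margin over any linear rule. Model comparison uses
an exact paired sign-flip permutation test over per-fold accuracies (2^k
assignments enumerated for k ≤ 20), two-sided.

## Centroids

For one condition and session, an emotion's centroid is the mean
(valence, arousal) of its z-scored feature windows pooled across
participants (experimental group only by default). "Normalized averages"
is realized as a joint max-abs rescale of the four centroids into [−1, 1]²,
which preserves geometry and per-axis rank order. Quadrant agreement
compares sign patterns against the expected plane layout; a centroid lying
exactly on an axis is indeterminate, counted as neither match nor mismatch.

## Response statistics

Verbal responses are simulated per stimulus: correct with probability
`clamp(p0 + δ·(session−1), 0, 1)` for the experimental group (δ = 0 for
controls), errors uniform over the three remaining emotions. Defaults
p0 = 0.5, δ = 0.1 give a strong, reliably detectable improvement over four
sessions while the control group stays flat.

Analysis operates on integer correct counts (0–12 per condition block) so
ranks stay exact. A Shapiro–Wilk gate (α = 0.05) routes paired differences
to parametric vs. non-parametric tests. The within-session comparison
(first vs. third no-music block, paired within each session, one summed
pair per participant) uses the Wilcoxon matched-pairs signed-ranks test
with zeros dropped (the classic rule; the effective n is reported) and an
exact null distribution for n ≤ 25, computed by dynamic programming over
tied average ranks — scipy's exact path refuses ties, which integer counts
produce routinely. The across-session comparison (first-session NM1 vs.
post-study NM1) is the paired t-test per group; with two repeated measures
this *is* the repeated-measures ANOVA (F = t², asserted against statsmodels
and pingouin in the tests). Reports carry the mean difference, SD and SE of
differences.

Calibration: under the null response model both planned tests reject at
0.05 ± 0.02 over 500 simulations (the slight conservatism of the
within-session test comes from the discreteness of the exact Wilcoxon
null).

## Pipeline, determinism, problem sizes

`run_pipeline` simulates verbal responses for the whole cohort (all
sessions) and EEG for a configurable subset (default 6 per group) in the
two cells the comparisons use: session 1 and the post-study visit. Every
per-stage seed is derived from the config seed via a CRC of the
participant/session key, so runs are byte-identical regardless of process
or iteration order; every serialized artifact embeds the config hash and
seed. Participant-level failures are logged and skipped, not fatal.

The test suite and the acceptance script run everything at desk scale:
single-session recordings (36 stimuli, ≈ 9 min of signal) for recovery and
centroid checks, 1,000-instance feature sets for chance-level convergence,
500 simulations for test calibration. These sizes give Monte-Carlo standard
errors comfortably inside the asserted tolerances.

## Known limitations

* The valence estimator is a raw power difference (µV²), not a log-ratio;
  its scale depends on the planted alpha level, which is why tolerances on
  valence are stated against the planted difference.
* Simulated band powers are stationary within events; estimator variance on
  real data would be larger, so decoding accuracies here are optimistic.
* The EDF writer is minimal (plain EDF, 1 s records, per-channel symmetric
  physical range); it zero-pads to whole records and quantizes to 16 bits.
* Verbal-response correctness is i.i.d. given the session; no per-item
  difficulty, learning within a session, or participant heterogeneity.
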