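# Methods

This note documents the models and procedures capscan implements, the
parameters that matter, the numerical choices made where the design was
open, and what the synthetic-data tests do and do not demonstrate.

## Signal model and preprocessing

Input is single-channel scalp EEG in microvolts. Preprocessing is a 4th-order
Butterworth bandpass (0.25–40 Hz) applied forward–backward for zero phase,
with padding long enough (3/f_low seconds) to damp the multi-second
transients of the 0.25 Hz corner. Samples with |amplitude| > 100 µV are
flagged as artifacts along with a ±0.5 s window around each offender; flagged
samples are excluded from all amplitude statistics but never interpolated.
Before envelope computation, flagged spans are zero-filled — a rejected
500 µV spike would otherwise leak Hilbert-transform tails into the envelope
seconds away from the artifact.

Amplitude throughout means the analytic (Hilbert) envelope smoothed by a
0.5 s moving average. The smoothing matters: the instantaneous envelope of
background EEG is Rayleigh-like and exceeds 1.5× its median about a fifth of
the time, so thresholding the raw envelope would fragment detection; the
0.5 s average makes the 1.5× criterion a statement about sustained amplitude.
The running baseline b(t) is the median smoothed envelope of unmasked samples
over a sliding 60 s window, updated every second. A median was chosen so that
a Phase A burst (seconds long) cannot inflate its own reference; windows that
are fully masked carry the previous value forward.

## CAP detection and subtyping

Detection scans the per-sample indicator envelope ≥ 1.5·b(t). Runs separated
by dips shorter than 0.5 s are merged (debounce); merged runs shorter than
2 s are treated as background — they neither become Phase A nor interrupt a
Phase B stretch, since an excursion below the minimum activation duration is
not a scoreable event. Qualifying runs become Phase A events, truncated at
60 s; the below-threshold stretch from the end of one qualifying run to the
start of the next becomes a Phase B when it lasts at least 2 s. Sequences are
maximal alternating A–B chains with at least 2 complete cycles
(`sequence.min_cycles`, following standard CAP scoring convention; the
trailing unpaired A is dropped).

Subtype rules are applied to band-power fractions in the printed order with
inclusive boundaries (δ = 60% exactly is A1, never A2). Band powers come from
a wavelet-packet decomposition: a full db16 packet tree to the depth where
subbands are ≤ 2 Hz wide, frequency-ordered, periodization mode, Parseval
coefficient energies, with each subband's energy assigned to the four
clinical bands in proportion to frequency-interval overlap. Two choices here
were driven by measurement, not convention. First, a plain multilevel
decomposition was rejected because its dyadic detail bands straddle the
alpha/beta split and, at the depths needed to reach the delta band, boundary
artifacts dominate the few coefficients per subband — a pure 10 Hz tone
measured as majority-delta. The uniform packet tiling with a longer (db16)
filter keeps a 10 Hz tone ≥ 98% in alpha. Second, the lowest subband's
nominal interval starts at 0 Hz, but everything below the 0.5 Hz highpass
edge is filtered out upstream, so its effective width is clipped at 0.5 Hz;
without the clip, delta power is systematically under-credited by ~25% of
that subband.

Phase A segments contain background EEG underneath the burst, and background
in NREM is delta-heavy, which biases mixed and fast subtypes toward A1/A2.
Subtyping therefore uses background-corrected fractions: the per-band power
of a same-length chunk of the longest quiescent stretch is subtracted
(clipped at zero) before normalizing. Using a same-length reference keeps
both estimates at the same packet depth, which depends on segment length.

The CAP rate counts epochs whose label is not in {SLEEP-REM, SLEEP-S0} and
flags the recording when the rate strictly exceeds 30% ("exceeds" read as
strict inequality; a rate of exactly 30% is not flagged).

## Features and reduction

Per-event features: raw-segment moments (mean, variance, biased skewness and
excess kurtosis, with the degenerate constant-segment case defined as 0);
absolute band powers and fractions; envelope morphology (peak amplitude,
time above half peak, rise slope from onset to peak). The reduction fits a
200-tree random forest on labeled events, keeps features with importance at
or above the mean importance (a `top_k` override exists), standardizes them,
and projects onto the smallest number of principal components whose
cumulative explained variance reaches 96%. The component count is
data-driven; three components (F1–F3) is a typical outcome on real CAP
features but is not enforced.

## Sequence dataset and classifier

Encoded annotation rows (Sleep Stage, Position, Location integer-coded by
sorted label; Event kept categorical as the target) are cut into consecutive
non-overlapping windows of 10 steps per patient — windows never straddle
patients, matching the strict patient-level split used for train/val/test.
The final partial window is zero-padded with a mask; padded steps are
excluded from the loss and all metrics. Per-step inputs are the metadata
columns plus F1..Fk when signal features are available. Class weights are
inverse-frequency, w_c = N/(K·n_c), which makes w_c·n_c constant across
classes — a uniformly wrong predictor then pays the same weighted loss at
any imbalance, a property the tests assert.

The classifier is a stack of L ∈ [1,3] LSTM layers returning per-step
outputs (first layer 64–256 units, subsequent layers halved to a floor of
32), each followed by batch normalization and dropout (0.2–0.5), then a
time-distributed ReLU dense layer (32–128 units) and a time-distributed
softmax head, so the model emits class probabilities at every time step.
It is implemented directly in numpy — forward and backward passes, Adam,
gradient clipping at global norm 5 — which keeps the package free of a
deep-learning framework dependency and makes runs bit-reproducible under a
seed; the backward pass is verified against finite differences in the test
suite. Training uses class-weighted categorical cross-entropy averaged over
unpadded steps, ReduceLROnPlateau (factor 0.5, patience 3, floor 1e-5) and
early stopping (patience 10) on validation loss; learning rate starts at
0.001. Dropout is applied between blocks, not inside recurrent transitions.

## Hyperparameter search

Hyperband runs successive-halving brackets (η = 3) of uniformly sampled
configurations at growing resource (training epochs), then returns the
bounding box of the top-q distinct survivors (q = max(3, 10% of
evaluations)), inflated by 10% per side and clipped to the original box.
Ranking deduplicates configurations first — survivors re-scored at each rung
would otherwise dominate the top-q list and collapse the box. PSO then
maximizes the objective inside the (narrowed) box: 30 particles,
c1 = c2 = 2.0, inertia linear from 0.9 to 0.4 across 50 iterations,
per-dimension uniform r1, r2, velocities clamped to half the box range,
positions clipped with the velocity zeroed on clipped dimensions, fitness
ties keeping the earlier particle. Discrete dimensions (layer count, unit
counts, batch size) are searched in continuous relaxation and rounded at
evaluation and decode time; rounding cannot leave the box.

## Statistics

One-vs-rest AUC per class from the Mann–Whitney rank statistic with midrank
ties (equivalent to trapezoid integration of the empirical ROC, asserted to
1e-10). Bootstrap CIs are percentile intervals over resamples stratified by
class, so no resample loses a class and leaves the metric undefined; BCa was
not used because only the interval level is specified. DeLong's test
computes both AUCs from placement values and the variance of their
difference from the structural-component covariance; identical scores give
z = 0 and p = 1 by convention. The test's pairing assumption holds for two
score vectors on the same labels; comparing AUCs of *different* classes
breaks it, and the API documents that such use is heuristic. Cohen's kappa
uses the standard (p_o − p_e)/(1 − p_e) with reliability "High" iff
κ ≥ 0.85.

Attributions use deterministic occlusion: the drop in the sample's
top-predicted class probability (mean over steps) when one input cell is
replaced by the background mean, with background defaulting to 100 seeded
training samples. The three published aggregation views are means of
|attribution| over the complementary axes; their grand means coincide by
construction, which the tests assert to 1e-12.

## Synthetic data: what it emulates, and what it does not

The generator exists so that every stage has planted ground truth.
Background is 1/f-weighted 0.5–30 Hz Gaussian noise rescaled so its median
smoothed envelope equals the requested baseline (default 10 µV, a realistic
NREM C4-A1 scale). Phase A bursts are continuous-phase FM cosines whose
instantaneous frequency time-multiplexes the four bands in exact proportion
to the subtype's band weights (A1: 85% δ; A2: 45/20/20/15; A3: 5/10/42.5/42.5
— each satisfying its rule with margin), with the frequency schedule smoothed
over 0.3 s. This construction was chosen after additive noise-carrier bursts
failed a basic requirement: a planted "2× baseline" burst must actually
measure as 2× baseline, and delta-band carriers beat against the delta-heavy
background at sub-hertz rates, rippling the envelope beyond calibration. The
FM carrier has a flat envelope by construction; it is crossfaded over the
background (0.25 s ramps) and its plateau is calibrated — 5th percentile of
the smoothed envelope against the maximum per-second running baseline the
detector itself measures over the event span, iterated twice — so the
planted amplitude factor is exactly the quantity the detector thresholds on.
Bursts may only be planted in NREM stage blocks; REM and wake segments stay
event-free, and the annotation table mirrors the stage track and planted
events one row per second.

Consequences for interpretation: passing the closure tests (recall,
precision and subtype accuracy all 1.0 over 20 seeds at factors ≥ 2) shows
the detector implements its stated rules faithfully and that the
generator/analyzer pair is consistent. It does not show clinical
performance: real A phases have variable morphology, ambiguous onsets,
spindle/K-complex lookalikes and inter-scorer disagreement, none of which
the generator emulates. The `noise_level` parameter adds wideband noise on
top, and subtype accuracy degrades monotonically with it, but this is a
sensitivity probe, not a realism claim.

## Problem sizes

The test suite and examples run at deliberately small scale, chosen as the
smallest sizes at which each property is meaningfully exercised: 2-minute
recordings at 128 Hz for detection, 500×12 feature matrices for the
reduction, 40–60 sequences of 10 steps with 64-unit single-layer models for
learning checks, and 30×50 swarms only where the search itself is under
test. All randomness flows from explicit seeds; fixed seeds reproduce runs
exactly, including training histories.

## Known limitations

Single-channel analysis only; no EOG/EMG/ECG integration. The midnight
wrap-around of annotation clock times is not resolved (durations drive all
arithmetic). The detector's debounce (0.5 s), envelope smoothing (0.5 s) and
burst ramp (0.25 s) are design constants validated on synthetic data, not
fitted to clinical recordings. AASM arousal scoring and spindle/K-complex
detection are out of scope.
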