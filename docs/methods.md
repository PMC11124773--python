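# Methods

This note records the model assumptions, the parameter choices that
matter, the numerical decisions taken where the procedure was genuinely
open, and what the synthetic benchmark can and cannot show.

## Signal front end

Input audio is mono PCM WAV; integer samples are scaled by the
full-scale value of their bit depth (32768 for PCM16), so write/read
round-trips are bit-exact. The working rate is 16 kHz; clinical-style
44.1 kHz input is down-sampled with a polyphase anti-aliasing resampler
(`scipy.signal.resample_poly`, ratio 160/441).

The band-pass is a 3rd-order Butterworth with corners at 200 and
8000 Hz, chosen because swallowing sounds carry energy above ~750 Hz
with a main component near 3.5 kHz while throat-microphone rumble sits
low. Two degeneracies are handled explicitly:

* at the 16 kHz working rate the 8 kHz corner coincides with Nyquist,
  where a digital band-pass design is ill-posed; the filter becomes a
  200 Hz high-pass of the same order, which is the same transfer
  function in the representable band;
* filtering is causal (a single forward `sosfilt` pass) so the detector
  could run in real time; zero-phase forward–backward filtering is a
  config switch (`zero_phase`), as is the order of band-pass vs.
  resampling (`bandpass_before_resample`, default band-pass first at the
  native rate, where the 8 kHz corner is genuine).

## Loud-event detection

Framing is 410 samples with a 160-sample hop (25.6 ms / 10 ms). Frame
energy is the plain sum of squares (not the mean) and the log is natural;
an additive floor of ε = 1e−12 inside the log keeps silent frames
finite. All three choices are conventions fixed for reproducibility and
exposed in the config.

The loudness threshold is *relative*: a frame is loud iff its linear
energy exceeds 7.5 % of the recording's maximum frame energy
(equivalently, log energy within ln 0.075 ≈ −2.59 of the maximum). A
percentage is only meaningful on the linear scale, which is how the
threshold is implemented; the comparison is strict (`>`). Relative
thresholding makes detection exactly invariant to a global recording
gain — a property the tests assert bit-for-bit.

Runs of loud frames become events; each event is padded by 6 frames
(0.06 s) per side, clipped to the track; padded events separated by less
than 0.12 s are merged, iterated to a fixpoint (padding precedes
merging; the gap is the count of frames strictly between two events
times the hop period; "less than" is taken literally, so a 0.12 s gap
does not merge). The implementation is verified against a brute-force
restatement of this definition on random tracks.

Labelling: an event is a swallow iff the intersection of the event with
the union of the expert swallow intervals is at least 35 % of the
*event's* duration, boundary inclusive. Measuring the overlap relative
to the event (rather than the annotation or the union) follows the
phrasing "loud events overlapped swallowing-sound intervals by 35 % or
more"; all three denominators are selectable
(`overlap_denominator`). Annotated swallows too quiet to cross the
energy threshold yield no event; they are surfaced through the
`detection_recall` diagnostic instead of being fabricated.

## Features

Frames are taken from the same 410/160 grid after a pre-emphasis filter
(y[n] = x[n] − 0.97·x[n−1]; the coefficient is the standard speech
default, the procedure states none). Each frame is Hamming-windowed and
zero-padded to a 1024-point FFT. A 40-channel triangular mel filter bank
(mel(f) = 2595·log10(1 + f/700), edges equally spaced in mel from 0 Hz
to Nyquist, weights evaluated at continuous bin frequencies) is applied
to the **power** spectrum for MFCC and the **amplitude** spectrum for
MFMC. Filter-bank outputs are floored at 1e−10 before the log.

MFCC uses the orthonormal type-II DCT and keeps c1…c12. Dropping c0 is
the most common reading of "12-dimensional MFCC" and buys an exact
property: a global gain shifts the log mel spectrum uniformly, which
lives entirely in c0, so MFCC features are gain-invariant. The
alternative c0…c11 convention is available (`mfcc_include_c0`). MFMC
keeps the 40 log amplitudes directly; a gain a shifts every MFMC
coordinate by ln a — the tests assert both identities numerically.

Event pooling: per coefficient over the event's frames — mean, sample
SD (n−1), median, range (max − min), and Fisher–Pearson skewness
g1 = m3/m2^{3/2} with 0 returned when the variance vanishes (avoids NaN
on degenerate events). "Dynamic features" are the same five statistics
of the simple first differences between consecutive frames; regression-
window deltas would also be defensible but first differences are the
simplest reading. A single-frame event has zero spread statistics and
all-zero delta statistics. An event's frames are all grid frames from
its padded start frame to its end frame (the padded event is the unit
of classification).

Pattern vectors concatenate, per base feature (MFCC block before MFMC),
the selected statistics in the order mean, SD, median, range, skewness,
base statistics before delta statistics, coefficients in index order.
The fourteen patterns and their dimensions:
P1–P5 cumulatively add the five statistics (MFCC: 12→60; MFMC: 40→200),
P6 adds the delta statistics (120 / 400), MIX P1 = all five statistics
of both bases (260), MIX P2 = MIX P1 plus deltas (520).

## Classifiers

**Linear SVM.** Soft-margin primal with C = 0.05 by default (selected
upstream by grid search; `tune_regularization` reruns such a search on
any grid, ties resolving to the smaller C). Training is libsvm
(`sklearn.svm.SVC`, linear kernel) followed by an exact active-set
refinement of the dual on the final working set: libsvm stops at a small
but nonzero KKT violation, and the refinement (which never worsens the
primal objective) closes that residual so the returned objective matches
an independent convex solve to ~1e−12. Sample weights — used by
boosting — scale each sample's share of C. Platt scaling is fitted on
the training-set decision scores by maximum likelihood with the
regularised targets (N₊+1)/(N₊+2) and 1/(N₋+2), the standard guard
against degenerate sigmoids on separable training scores.

**MLP.** One hidden layer of d + 2 tanh units (the "+2" rule for the
hidden width), softmax output, mean cross-entropy loss, trained
full-batch with Møller's scaled conjugate gradient. Stopping: 2000
epochs (one SCG iteration per epoch) or gradient norm below 1e−6 — the
tolerance is unstated upstream and fixed here; on the synthetic data SCG
typically converges within a few dozen iterations. Initialisation is
Glorot-uniform from a seeded generator, making training bit-reproducible
for a fixed seed. A single hidden layer is assumed because the
unit-count rule defines exactly one width.

**Ensemble (ELM).** AdaBoost.M1 over a fixed budget of ten base
learners, five linear SVMs and five MLPs, interleaved SVM, MLP, SVM, …
by default (`learner_order="blocks"` trains all SVMs first). SVMs
consume the boosting distribution directly through per-sample C scaling;
MLPs train on a weighted resample of size N drawn from the distribution
with a fixed sub-seed (the classical resampling fallback, since loss
re-weighting is not specified). Per round: weighted error εₜ, vote
weight αₜ = ½ ln((1−εₜ)/εₜ), multiplicative re-weighting
exp(−αₜ y hₜ(x)) and renormalisation. Degenerate rounds: εₜ = 0 gets the
capped αₜ at ε = 1e−6 and the loop continues (keeping the ten-learner
architecture); εₜ ≥ ½ discards the learner and resets the distribution
to uniform. Prediction is the sign of Σ αₜhₜ(x) with confidence
Σ{α : h=+1}/Σα; an exact tie is called non-swallow, the conservative
clinical default (a missed swallow is surfaced by recall metrics, a
false swallow call is not).

## Evaluation

Stratified 5-fold CV (shuffled, seeded). Stratification is not stated
upstream but with a ~1:3 class imbalance unstratified folds risk a
training split losing a class entirely; it is switchable
(`stratify=False`). Features are z-scored per fold with statistics
fitted on the training split only (zero-variance features clamp to
scale 1); whether the upstream system standardised at all is unstated,
so both modes run (`standardize`). Metrics are computed at full
precision and displayed to two decimals. Ratios with zero denominators
are reported as NaN with a warning, never silently as zero; NaNs are
excluded from fold means. Both class views are reported fold-by-fold
(sens(class0) = spec(class1) holds by construction and is asserted);
the macro-F1 averages the two views' mean F1, and a pooled micro-F1
over all held-out predictions is reported alongside, labelled
unambiguously.

## Synthetic scenes

The generator reproduces the *statistical* structure of bedside
recordings, not physiology: sparse events on a quiet Gaussian floor,
swallow bursts as band-limited noise (750–3500 Hz) with 2–4 sharper
clicks and a rise/decay envelope; distractors as low-frequency modulated
noise (respiration, centroid < 600 Hz), a decaying broadband burst
(cough), a harmonic stack with 100–250 Hz fundamental and 5 Hz vibrato
(speech), and 1/√f noise (environment). Durations are truncated normal
with swallow mean 1.34 s and non-swallow mean 0.67 s, matching the
clinical event-duration statistics; the reported swallow-duration SD
(4.19 s) implies a heavy right tail that makes dense placement
infeasible, so the default SD is capped at 0.74 s with the log-normal
heavy-tail variant behind `heavy_tail=True`. Events are placed without
overlap with ≥ 0.5 s guard gaps, slack distributed by a Dirichlet draw.

Each event is normalised to a common *peak short-time level* (RMS of its
loudest 410-sample stretch) with ±2 dB per-event jitter, and `snr_db`
sets that peak level against the noise-floor RMS. Peak-level rather than
whole-event RMS normalisation reflects what "loud event" means to a
relative energy detector; without it, smooth events (respiration) sit an
order of magnitude below clicky ones (cough) and the 7.5 % threshold
stops being meaningful. Everything is deterministic in the scene seed.

**What the benchmark shows.** At the default 20 dB SNR the archetypes
are cleanly separable and the pipeline scores at or near 100 % — the
benchmark validates the machinery (detection geometry, feature
identities, leakage-free CV, ensemble mechanics), not clinical
difficulty. Real recordings add variable SNR, overlapping sound
sources, inter-patient variability and annotation ambiguity, none of
which the generator emulates; clinical performance claims require
clinical data. Degrading `snr_db` produces the expected monotone decay
(the test suite asserts non-increase from 20 → 0 dB), with detection
collapsing below ~8 dB as the noise floor crosses the relative
threshold.

## Problem sizes

The default test and acceptance configuration uses 10 scenes × 30 s
(120 events, 520-dimensional MIX P2 features) for the end-to-end run,
200 random tracks for the detector oracle, 20 instances (N ≤ 30, d ≤ 5)
for the SVM oracle, and 5000 scores for Platt recovery — sizes at which
every oracle is exact and the full suite runs in well under a minute of
compute for each stage.

## Known limitations

* Event boundaries are frame-quantised (10 ms); no sub-frame accuracy.
* The MLP trains full-batch; very large event sets would need batching.
* The ensemble's MLP resampling step means ensemble training is
  stochastic across seeds (deterministic for a fixed seed).
* Platt calibration is fitted on held-in training scores, which can be
  optimistic; cross-validated calibration scores would be a refinement.
* The generator's archetypes are stylised; see above.
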