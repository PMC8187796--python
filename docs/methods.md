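# Methods

`prosmile` models one question: in a therapy session where a child
interacts with a small walking (and occasionally falling) humanoid
robot, how well does smiling in the 10 seconds before an opportunity to
help predict that the child actually helps? The package contains the
measurement chain (EMG smile detection fused with video annotation),
the reduction of each episode to binary flags, the probability model,
and a synthetic-data generator that stands in for the study recordings.

## The probability model

Each walking or falling episode is one *case* with binary flags coded
over the 10 s preceding the prosocial-behavior onset (or, when no
helping occurred, the 10 s following the robot's movement that could
have triggered it):

| flag | meaning |
|------|---------|
| S    | any smile overlapping the window |
| H    | head direction toward the robot maintained (≥ 8 of 10 coded seconds; configurable) |
| A    | approach toward the robot (any coded second) |
| P    | a prompt by therapist or parent inside the window |
| PB   | prosocial behavior followed (the outcome) |

The core object is the joint probability table over (S, PB) with its
marginals, and the Bayes-rule conditional P(PB|S) = P(S,PB)/P(S).
Two arithmetic modes are carried everywhere:

* **exact** — ratios of integer counts;
* **rounded** — every cell proportion is first rounded half-up to 2
  decimals and all arithmetic uses the rounded values. This mode
  reproduces how such small-sample tables are conventionally printed
  and read; at n = 36 the difference is visible (0.42/0.50 = 0.84
  rounded vs 15/18 = 0.833 exact; the smile share of helping is 66%
  rounded vs 65% exact), which is why results always show both.

Prediction uses conditional probability tables P(PB | pattern) over a
predictor subset of {S, H, P} estimated as training relative
frequencies (no pseudo-counts by default; an optional smoothing
parameter adds them). A case is predicted positive when its pattern's
probability exceeds 0.5; a probability of exactly 0.5 falls back to the
training-majority outcome, and a pattern never seen in training falls
back to the training PB rate. Approach (A) is carried on every case but
is not a predictor: in the observed chain it is almost an alias of the
outcome.

Validation is subject-wise leave-one-out cross-validation: each fold
holds out *all* cases of one participant, fits on the rest, and scores
the held-out cases; the reported accuracy is the unweighted mean over
participants (per-case pooling is available as an option). Subject-wise
folding is the only defensible unit here because cases within a child
are strongly dependent. The implementation is checked against an
independent brute-force fold enumeration on randomized toy sets.

## EMG smile detection

The wearable records 4 differential channels over the smiling muscles.
The chain is:

1. **Band-pass 50–350 Hz**, 4th-order Butterworth applied
   forward-backward (`sosfiltfilt`). Zero phase matters because
   detected onsets are compared with millisecond video annotation;
   the band removes sub-20 Hz motion artifacts and drift while keeping
   the surface-EMG energy band.
2. **ICA** (FastICA, deflation, seeded) into 4 components. Component
   order is fixed by descending reconstructed-variance contribution and
   signs by non-negative skewness, so the decomposition is fully
   reproducible. The unmixing matrix is stored on the classifier and
   reused verbatim at inference — training and classification always
   share one linear view of the data.
3. **RMS envelope** over non-overlapping 100 ms frames (trailing
   partial frame dropped). 100 ms gives a 10 Hz feature rate, matching
   the 1-s behavioral coding resolution with an order of magnitude to
   spare.
4. **Per-participant network**: one hidden layer (default width 16,
   rectified units) with a logistic output, fitted by full-batch
   L-BFGS under a small L2 penalty (α = 1e-4). At session scale (a few
   hundred to a few thousand frames) full-batch fitting is exact,
   deterministic given the seed, and fast; stochastic training with
   early stopping proved unreliable on these small, class-imbalanced
   frame sets (it can stall at the majority classifier). Frames from
   the neutral-baseline period are forced to be negative examples, and
   frames whose broadband power exceeds the 99th percentile are dropped
   from training — an operational reading of "train on the less noisy
   stretches".
5. **Binarization and smoothing**: probability > 0.5 (configurable),
   then detected intervals separated by < 200 ms are merged and
   intervals < 300 ms dropped. This suppresses frame flicker; both
   thresholds are configurable and the merge is strict (a gap of
   exactly 200 ms stays split).

Only the video-unobservable fragments ever receive EMG-estimated
smiles: `estimate_unobserved` clips detections to those fragments, and
`fuse_smiles` refuses EMG intervals outside them or video intervals
inside them, which makes the fused total duration exactly the sum of
its parts.

## Synchronization and windows

The EMG logger records a tag at the moment the session starts (the
therapist presses a time tagger when opening the door); the annotation
has a `session_start` event. The synchronization offset is defined by
mapping the tagged sample onto that event, after which EMG detections
live on the session clock. All intervals are half-open
`[onset_ms, offset_ms)`, 0-based milliseconds.

Six analysis windows are extracted per session, anchored on the first
walking and first falling episode only: (a) the first minute after
session start; (b)/(c) the minute before/after the first
walking-situation prosocial behavior; (d) the minute before the first
falling-situation prosocial behavior; (e) the first smile while the
robot is down (zero-length if none); (f) the minute after the robot is
righted. Windows are clipped at session bounds with the clipping
flagged; missing anchors yield explicitly reported missing windows. For
window (d) an alternative anchor — one minute before the robot's fall
itself — is supported (`fall_anchor="robot_fall"`), because the two
published descriptions of that timing differ; the default follows the
prosocial-behavior anchor and every window records which anchor it
used.

Per-second coding of the 10-s pre-window marks a second positive for a
behavior when that behavior's intervals cover at least 500 ms of it.
The 500 ms threshold is a declared convention (the source protocol says
only that coding happened every second); it is configurable. The H flag
requires ≥ 8 of the 10 seconds head-positive ("maintained" head
direction), also configurable.

Inter-rater reliability for two coders uses ICC(2,1) — two-way random
effects, absolute agreement, single measure (computed via pingouin,
cross-checked against textbook mean-square formulas in the tests).
With 2 coders and n items the F test has df = (n−1, n−1). Absolute
agreement is the right variant because the coders' absolute durations,
not just their rankings, carry the analysis.

## The synthetic generator

**EMG.** A recording is a fixed linear mixture (drawn once from
`mixing_seed`) of three latent sources: two smile-muscle burst sources
— band-limited (50–350 Hz) unit-RMS noise gated by the simulated smile
intervals with Tukey on/off ramps — and one always-on tonic source at
0.35 RMS in the same band. Added to the mixture are white noise at
`snr_db` (default 15 dB, a clean wearable recording; the pipeline's
duration-recovery guarantee is stated for ≥ 10 dB) and Poisson
motion-artifact bursts (default 3/min): 1–15 Hz, 0.3–1 s, five times
the burst amplitude, so the band-pass stage demonstrably earns its
keep. Smiles arrive as a Poisson process (default 4/min, 1–4 s each,
non-overlapping); sampling is 1 kHz, comfortably above twice the upper
band edge. The generator emulates the *statistical* structure a
detector cares about — burst-gated band energy in a fixed mixture —
not the physiology: there are no motor-unit potentials, no electrode
impedance drift, no cross-talk model. Passing detection tests here
therefore shows the chain recovers gated band-limited sources at
realistic SNR, not that it would hit the same numbers on clinical
recordings.

**Behavior.** Sessions follow a 1-s discrete chain per situation: the
robot moves; the child smiles with probability p_S (default 0.5); a
smiling child keeps heading toward the robot (p_H|S = 0.9), approaches
given heading (p_A|H = 14/15), and helps given approaching
(p_PB|A = 1.0); a non-smiling child is prompted with probability 0.55
and helps given the prompt with probability 0.8. The implied joint is
available in closed form, and those defaults make it exactly the
published 2×2 table: 0.5·0.9·(14/15)·1.0 = 0.42 and
0.5·0.55·0.8 = 0.22. No-smile voluntary helping is deliberately
outside the chain, which makes "helped without smiling ⇒ was prompted"
hold by construction, mirroring the observed regularity. Each drawn
chain is materialized as timeline intervals/events placed so that
re-coding the 10-s window recovers the drawn flags exactly — the
simulator and the coder are held consistent by tests, not by sharing
code paths.

**Case tables.** `generate_case_table(n, joint, seed)` converts a 2×2
joint into exact integer counts by largest-remainder rounding (floors
plus units to the largest fractional remainders, ties by cell order),
guaranteeing the counts sum to n; 36 × (0.42, 0.08, 0.22, 0.28) gives
(15, 3, 8, 10). Cases are dealt round-robin to 12 synthetic
participants after a seeded shuffle so that subject-wise
cross-validation has meaningful folds.

## Numerical and design choices

* Rounding is decimal half-up (via `decimal.Decimal`), never banker's;
  the rounded mode is the default for report output, exact mode for
  inference on counts.
* Probability-table invariants (Bayes identity, total probability) are
  asserted in exact mode to 1e-12.
* Degenerate inputs fail loudly: constant or duplicated EMG channels
  (rank-deficient covariance), single-class training labels, timelines
  with overlapping same-label intervals, zero-probability conditioning
  events, a participant owning every case.
* Problem sizes in the test suite and acceptance script are desk-scale
  by design: one 120-s, 1 kHz synthetic recording exercises the signal
  chain; chain-calibration checks use 10,000 generated cases; the
  published-number checks use the 36-case fixture. The full suite runs
  in well under five minutes on one CPU.

## Known limitations

* The EMG generator's linear instantaneous mixture is kind to ICA by
  construction; convolutive mixing or moving electrodes would degrade
  separation in ways not modeled here.
* Session-level duration summaries (the mean ± SD tables) describe the
  synthetic chain, not the study's recordings; they are format-
  compatible, not value-comparable.
* The published per-group cross-validation accuracies depend on the
  study's actual 36 cases, which are not bundled; the LOO-CV machinery
  is instead verified by oracle equivalence and parameter recovery.
* ICC supports exactly two coders; more would need the full two-way
  random-effects machinery exposed, which pingouin provides but the
  timeline model does not currently organize.
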