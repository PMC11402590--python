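# Methods

## Problem and model

Wrist-worn accelerometers record triaxial acceleration in gravitational
units (g) at 15–100 Hz. Step counting from the wrist must separate gait
from the many non-gait arm movements that also produce acceleration
peaks. `wriststep` therefore uses a two-stage hybrid: classify *when* the
wearer walks, then count peaks only there.

**Signal conditioning.** The working signal is the vector magnitude
`v_i = sqrt(ax² + ay² + az²) − 1`, which removes static gravity in any
device orientation; it is clipped to ±2 g (bounding transients before
they spread through the filter) and low-pass filtered with a 4th-order
Butterworth at 5 Hz — above the frequency content of human cadence
(≤ ~3.3 Hz), below wrist-impact harmonics. Filtering is applied
forward–backward (`filtfilt`, odd-reflection edge padding): phase
cancellation keeps peak times unshifted, which matters because step
timestamps feed minute-level cadence. Whether the filter should be
causal was an open choice; zero-phase was selected for that reason. The
forward–backward pass squares the magnitude response, so the effective
stopband attenuation at 10 Hz (fs = 100 Hz) is (1 + 2⁸)⁻¹ ≈ 0.0039,
comfortably under the 0.07 single-pass bound the tests assert.

**Epoching and labels.** Recordings are cut into contiguous 10-s epochs;
a trailing partial window is discarded because the classifier expects
fixed-length inputs. With ground truth available, an epoch is *walking*
iff at least 4 step timestamps fall in its half-open window.

**Walk classifier.** The classifier is a backend interface whose
contract is a per-epoch walk probability (hard label at 0.5). The
default backend is a logistic model on 10 deterministic features of the
epoch's vector magnitude: mean, SD, quartiles, dominant frequency and
power in the 0.5–4 Hz gait band, spectral entropy, the autocorrelation
maximum over 0.3–1.2 s lags (the physiologic step-period band), and zero
crossing rate. An SGD backend demonstrates the iterative path: constant
learning rate 1e-4, validation log-loss monitored each pass, stopping
after 5 passes without improvement and restoring the best-validation
weights (best-so-far, the less ambiguous reading of "weights before
early stopping"). Training protocol, shared by all backends:

- *Grouped 80/20 split*: whole participants go to train or validation,
  never both.
- *Augmentation*: each training epoch is rotated about a random axis
  (angle ~ U[0, 2π), axis uniform on the sphere) and its axes permuted
  uniformly over the 6 orders. For VM-derived features this is an exact
  no-op (isometry), which the tests assert; it is retained in the
  protocol so raw-signal backends train rotation invariant.
- *Class reweighting*: weights `w_c ∝ target_c / empirical_c` rescale
  the empirical class balance to 10 % walk / 90 % non-walk, the balance
  seen in 24-h free-living observation; short annotated training
  sessions otherwise over-represent walking.

**Grouped, stratified k-fold.** Stratification under grouping is
reconciled greedily: participants in decreasing epoch-count order (rng
tie order) are assigned to the fold with the fewest participants,
breaking ties toward the fold whose walk fraction lands closest to the
global fraction. Fold sizes differ by at most one participant.

**HMM smoother.** A two-state HMM (hidden truth walk/non-walk, observed
classifier label) is fitted by supervised counting on the validation
split: add-one-smoothed within-participant bigram transitions, add-one
confusion emissions, add-one first-label initials. Test sequences are
smoothed by log-space Viterbi with a 1e-12 probability floor. Hard-label
emissions (a 2×2 confusion matrix) were chosen over probability
emissions: they match the fit data and keep the exhaustive-enumeration
oracle exact; probabilistic emissions are a possible extension. Score
ties resolve toward non-walk so smoothing never fabricates walking.
Decoding restarts at each participant and after any gap.

**Peak detection.** A reported peak is a strict local maximum with
topographic prominence ≥ `prominence_g`, half-prominence width within
the width constraint, and ≥ `distance_s` separation from every other
reported peak; conflicts are resolved greedily by descending height
(ties toward the earlier index). Constraints are applied before
suppression. The width constraint defaults to an *upper* bound
(`width_mode="max"`), reading the heuristic as "maximum peak width" —
wide humps are arm swing, not steps; the common library convention of a
minimum width is available behind `width_mode="min"`. Detection runs on
the concatenated signal of each maximal run of consecutive predicted
walking epochs, so a step straddling an epoch boundary is not lost;
strict per-epoch counting is available via `merge_runs=False`.

**Tuning.** Exhaustive grid search over prominence 0.1–1.0 g (step
0.1), distance 0.2–2.0 s (step 0.2), width {0.01, 0.1–1.0 step 0.1} s —
1100 cells — minimising the mean absolute per-item step-count error on
validation walking runs. The endpoints are fixed; the step sizes are
this package's choice. Ties break toward larger prominence, then larger
distance, then larger width (the most conservative detector).
Peak geometry (maxima, prominences, widths) is computed once per signal
and reused across cells.

**Daily summaries.** Steps are binned into half-open minute slots on a
(days × 1440) grid aligned to the recording clock's midnight. Nonwear is
an episode of ≥ 60 consecutive minutes with every axis' within-minute SD
below 13 mg (standard cohort practice); minutes without data are nonwear
by definition. Nonwear minutes are imputed with the mean of the same
minute-of-day over worn days (slots worn on no day impute 0 with a
warning; worn slots are never altered). Median daily steps is the median
of per-day totals over valid days — by default days fully covered by the
recording with ≥ 1 worn minute; partial first/last days still donate to
imputation. 1-min peak cadence is the mean over valid days of each day's
highest minute. QC flags: wear < 72 h, any hour-of-day never worn,
mean |VM| > 100 mg (strict inequalities: exactly 72 h and exactly 100 mg
pass). A `poor_calibration` flag slot exists for pipelines that run
external gain/offset calibration; this package never sets it.

**Agreement metrics.** All step-count error metrics are per participant
(not pooled): MAPE = mean |pred−true|/true × 100; mean bias = mean
signed percent error (negative = undercount); Spearman ρ on ranks;
Bland–Altman limits `mean(d) ± 1.96·SD(d)` with sample SD and no
small-sample t correction. Participants with zero true steps are
excluded from percent-error metrics with a warning. Undefined
classification ratios are NaN with a warning, not 0.

## Synthetic data

The simulator generates the study conditions the pipeline is tested
under. A walking bout draws inter-step intervals
`60/cadence × (1 + jitter·z)` (floored at 0.3 of the base interval),
places a half-sine impulse of amplitude `step_impulse_g` per step on the
vertical body axis (peak exactly at the step time, duration
min(0.3 s, half the step period)), adds an arm-swing sinusoid at half
the step frequency, the gravity vector, a random rigid rotation of the
whole bout, and white Gaussian noise. Defaults: cadence 100 steps/min,
jitter CV 0.05, impulse 0.5 g, arm-swing ratio 0.2, noise SD 0.03 g —
ordinary free-living walking with a clean wrist signal. Sedentary time
is gravity plus 20 mg per-axis micro-movement noise (above the 13 mg
nonwear threshold, so sitting still is not mistaken for off-wrist);
fidgeting adds sparse transients of 0.02–0.06 g, deliberately below the
0.1 g prominence floor of the tuning grid; nonwear is exactly constant
gravity.

Presets: `oxwalk_like` (≈ 1 h free living at 25 Hz, walking a minority
of epochs), `clemson_like` (15 Hz; a steady ~10-min regular walk, 8
stop-and-go semiregular bouts, 12 short irregular bursts — ≈ 37 min of
activity), `week_long` (15 Hz, 7 × 24 h with a daily walking routine of
~70 min and a 2-h afternoon nonwear gap on day 3). All randomness flows
from one seed; per-participant substreams are derived by hashing the
participant id (CRC32) into the seed sequence, so cohorts are
reproducible participant by participant.

What the simulator does *not* emulate: real wrist biomechanics (impact
transients, asymmetric swing, push-off double peaks), non-gait rhythmic
activities (cycling, typing, tooth-brushing), device calibration error,
and sampling dropouts. Passing tests therefore demonstrate correctness
of the pipeline's machinery and its recovery behaviour under idealised
gait — not free-living accuracy on real devices, which requires
annotated human data.

## Numerical choices and edge cases

- Sample rate is inferred as 1/median(Δt) when undeclared; a declared
  rate wins conflicts with a logged warning. Resampling is per-axis
  linear interpolation (simple, monotone, adequate at 15–100 Hz;
  documented so a band-limited scheme can be swapped in).
- Filter inputs shorter than the default `filtfilt` pad length fall back
  to the longest valid pad.
- Plateau maxima (exactly equal neighbours) are not peaks; peak spacing
  is compared as `|i − j| ≥ distance_s · fs` in float.
- Viterbi and its test oracle accumulate log scores in the same order,
  so path-score comparisons in tests are exact, not tolerance-based.
- Degenerate inputs: empty epoch sets, single-class training data,
  constant vectors in rank correlation, and zero-denominator metric
  cells all raise or warn explicitly rather than returning silent zeros.
- Model archives are plain JSON (coefficients, scaler, HMM matrices,
  detector params, seed), making training byte-reproducible and the
  artifact text-only.

## Problem sizes

The bundled evaluation uses a 10-participant, ~1-h `oxwalk_like` cohort
(≈ 3 800 epochs, ≈ 9 800 true steps) under grouped 10-fold
cross-validation, and one 7-day `week_long` recording (≈ 9.1 M samples,
≈ 50 000 true steps) for the daily-summary metrics. These sizes exercise
every pipeline stage — including nonwear imputation across days — while
keeping a full run in minutes on one CPU; larger cohorts are a flag away
in `make_fixture_cohort`.

## Known limitations

- The default feature backend is linear; heavily overlapping activity
  classes (e.g. slow shuffling vs vigorous fidgeting) would need a
  stronger backend behind the same interface.
- The smoother's 10-s granularity cannot recover walking bouts shorter
  than one epoch; steps in epochs below the 4-step label threshold at
  bout edges are systematically missed, a small negative bias visible in
  the cross-validation results.
- Nonwear detection assumes true off-wrist periods are near-zero
  variance; a device left on a vibrating surface would read as worn.
- Time zones and daylight-saving shifts are out of scope: timestamps are
  seconds on a single local clock.
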