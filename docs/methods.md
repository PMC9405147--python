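# Methods

## Overview

`tailsense` is an event-prediction pipeline for parturition in cattle based
on a tail-base wearable that records four channels at 3-min cadence: skin
temperature (ST, 20–45 °C at 0.05 °C resolution), activity intensity
(0–102.3 at 0.2), roll angle (−3 to +3 rad at 0.05 rad), and Y-axis
acceleration (−1000 to +1000 mg at 4 mg; positive when the tail hangs down,
negative when raised). The pipeline stages are: hourly aggregation, derived
signals, feature extraction, class-weighted SVM classification under
leave-one-animal-out (LOOA) cross-validation, two-stage alert generation,
event-level evaluation, and permutation feature importance. Housing
conditions — tethering (tie-stall) and untethering (free-stall/pen) — are
treated as separate populations end to end: separate training sets,
hyperparameters, and evaluations.

## Preprocessing

Missing records are forward-filled at the 3-min record level *before*
aggregation. Filling raw records rather than hourly aggregates keeps the
hourly statistics consistent with what an online system would compute from
a last-value-hold stream; records before a channel's first observation stay
missing and the hours containing them are excluded. A channel with no
observations at all is a hard error naming the channel and animal.

Posture is classified per record: lying iff |roll| > threshold, standing at
or below it (the tie goes to standing so the rule is a strict inequality).
The threshold is a calibration constant of the attachment geometry, not a
physiological quantity; it is exposed in configuration with default 1.0 rad,
which cleanly separates the generator's standing (≈0.2 rad) and lying
(≈1.5 rad) roll levels.

Hour bins are clock-aligned and left-closed right-open. Per bin: max ST,
mean activity, mean tail index, 3 min × (lying records), and the number of
posture switches. A switch is attributed to the hour of the *later* record,
so each hourly value is a pure function of that hour's records plus the last
record of the previous hour; with 20 slots per hour the count is at most 20.
Hours not covered by 20 valid records (the partial hours at the stream edges
and any hour still containing unfilled values) are dropped.

## Derived signals

- **rST(h)** = ST_max(h) − mean(ST_max(h−24), ST_max(h−48), ST_max(h−72)).
  Subtracting the same-clock-hour mean of the previous three days removes
  any exactly 24-h-periodic component (this is tested as an identity). The
  first 72 h of each deployment are warm-up and yield no values.
- rST is smoothed with an EWMA, `EWMA_t = αX_t + (1−α)EWMA_{t−1}`,
  initialized at the first valid value, α = 0.1 (a conventional value for
  slow physiological drifts; configurable). Only rST is smoothed — the
  ratio signals are already window aggregates.
- **rAct, rLying** = (sum over hours [h−23, h]) / (sum over [h−47, h−24]).
  "Last K h" always means the K hours up to and including the current hour,
  and the prior window abuts it without a gap.
- **rPost** = mean over last 6 h / mean over last 7–30 h; **rTail** = mean
  over last 3 h / mean over last 4–27 h. The shorter numerator windows match
  the later onset of these behaviours (posture changes ≈ 6–12 h, tail
  raising ≈ 2–6 h before calving).
- Denominator guard: posture-change counts can be zero and the tail index is
  signed, so a prior-window aggregate with |denominator| < ε (ε = 10⁻⁶ in
  natural units) marks the hour invalid rather than producing an unbounded
  ratio. The tail ratio's sign is preserved, not clamped.

An hour is *valid* when all five derived values are finite; the overall
warm-up is 72 h (the rST requirement dominates).

## Features and labels

Each signal contributes eight features per model horizon: minimum and
maximum over a short and a long trailing window, and the differences
current − min (≥ 0) and current − max (≤ 0). Windows are 12 h/24 h for
rST, rAct, rLying, rPost and 6 h/12 h for rTail in the 24-h model; 6 h/12 h
and 3 h/6 h respectively in the 6-h model. That yields 40 sensor features;
the signed days to the expected calving date ("Days") brings the predictor
count to 41. Days is positive before the expected date and crosses zero at
it, so it decreases monotonically through a deployment. Feature rows exist
only at hours where every window is fully valid; every feature is a function
of current and past hours only (a no-look-ahead identity is tested by
truncation).

Labels: positive from H hours before to 6 h after calving (H = 24 or 6),
closed on both ends at hour resolution. Post-calving rows up to +6 h are
positive in *training* — they share the physiological state of calving — but
alerts raised at or after calving are excluded from *evaluation*, which
scores prediction only.

## Classification

Features are standardized to zero mean and unit variance with parameters
learned on the training fold only; constant features are dropped with a
warning. The classifier is a soft-margin RBF SVM with an asymmetric class
weight: the positive class's misclassification cost is multiplied by the
weight, the negative class stays at 1. The published hyperparameters are
used as defaults, keyed by horizon and housing: sigma 0.008 (tethering) /
0.0037 (untethering); cost 0.46 / 0.026 (24-h) and 0.1 / 0.03 (6-h); weight
1.5 / 3.5. `sigma` is interpreted in the e1071/libsvm "gamma" convention,
K(u,v) = exp(−sigma·‖u−v‖²) — the original models were fitted with that
library — and the mapping is explicit in the code so an alternative
convention is a one-line change. A grid-search utility scores candidate
hyperparameters on an internal animal-wise validation split (balanced
accuracy) but deliberately does not auto-select.

Under LOOA, each animal's hours are predicted by a model trained on all
other animals of the same housing group; scaling parameters are likewise
fold-pure. This is the subject-wise split appropriate for deployment on a
new animal.

## Alerts and evaluation

- A **24-h alert** is raised at the third hour of a run of ≥ 3 consecutive
  positive predictions (the earliest moment the rule is satisfied). Alerts
  within 12 h after an already retained alert are considered related and
  merged into it, keeping the earliest time; merging is idempotent.
- A **6-h alert** requires a 6-h-model positive at an hour that is also a
  24-h-model positive; consecutive qualifying hours are grouped into one
  alert at their first hour. Grouping (rather than per-hour alerts) keeps
  the false-positive unit consistent with the merged 24-h alerts.
- An alert is a **true positive** iff calving occurs in
  (alert time, alert time + H]. A calving with no true-positive alert is one
  false negative; every other pre-calving alert is one false positive.
  Sensitivity = 100·TP/(TP+FN) over calvings; precision = 100·TP/(TP+FP).
  A calving is counted once even if several alerts hit it; the additional
  hitting alerts are neither extra TPs nor FPs, but all their lead times
  enter the alert-to-calving interval summary (mean ± standard error).
  Undefined metrics (zero denominators) are reported as undefined, not 0.

## Permutation importance

Importance of a feature is the factor by which the model's classification
error increases when that feature's column is randomly permuted, computed
on the model fitted to *all* of a group's data with in-sample error, with
the per-feature median and empirical 90% quantile over 20 repeats
(configurable). When the baseline error is exactly zero the ratio is
ill-defined; numerator and denominator are floored at ε = 1/(2·n_rows) and
the row is flagged. An uninformative feature scores ≈ 1 by construction.

## Synthetic herd generator

The generator emulates the documented structure of real deployments:
attachment 15.0 ± 4.6 days before the expected calving date (truncated to
[6, 30] d), recording until ≥ 24 h after calving, calving-date offsets
normal with mean −0.5, SD 2.9 d (tethering) and mean 1.4, SD 4.5 d
(untethering), truncated to ±14 d and additionally so the sensor is attached
at least one day before calving; all channels quantized and clipped to the
sensor specification; records dropped missing-at-random (default 2%).

Signals: ST is a 38.0 °C baseline with a 0.3 °C-amplitude circadian cosine
(peak 18:00) plus the biphasic drop — linear to −0.5 °C over [−36 h, −16 h],
plateau, then a further −1.0 °C over the last 6 h, recovering linearly over
12 h post partum — and 0.25 °C Gaussian noise. Posture is an alternating
bout process (exponential bouts, lying mean 50 min, standing 70 min)
expressed through the roll angle; from the posture onset both bout means are
divided by a rate factor (2.0 from −24 h for tethering, 2.5 from −6 h for
untethering), and for untethered animals lying bouts additionally shorten
(×0.5 from −24 h). Activity rises by +6.0 units from −18 h for untethered
animals only; the tail index steps from +200 mg to −200 mg at −12 h in both
conditions. Behavioural effects persist to +6 h after calving. Direction
and onset hours follow the published mean curves; the raw-signal magnitudes
are not published anywhere, so the defaults are this package's choice of a
clearly detectable but noise-dominated-at-the-record-level signal, and all
of them are configurable.

What the generator does **not** model: ambient-temperature coupling, parity,
breed and fetal-breed differences, diurnal activity rhythms, sensor
detachment or drift, and autocorrelated (non-i.i.d.) record noise. Passing
end-to-end tests therefore demonstrates that the pipeline recovers the
designed signal structure under realistic noise, missingness, and calving
date uncertainty — not field performance on real herds.

## Numerical and design choices

- Tie-breaks: roll exactly at the threshold → standing; labels closed on
  both window ends; the 24-h alert timestamp is the third consecutive
  positive hour (the published mean lead times are consistent with an
  early-run convention, which is also the operationally honest choice — the
  alert exists from that hour).
- EWMA recursion skips invalid hours and continues across them.
- Degenerate inputs: empty series, single-class training data, empty
  hyperparameter grids, and all-missing channels raise errors naming the
  offender; insufficient history is warm-up, not an error.
- Determinism: every stochastic component draws from a generator seeded by
  (scenario seed, animal index); identical config + seed reproduce every
  stage artifact byte for byte.

## Problem sizes

The default scenario is 20 animals (10 per housing condition) observed for
~15 days each — about 7,200 records and 300 feature hours per animal — which
exercises the full LOOA design (10 folds per group, four models) in a few
seconds on one CPU. Unit tests use 2–4 animal herds with ~6.5-day
deployments. The permutation-importance stage dominates runtime when
enabled (41 features × 20 repeats × 4 models).

## Known limitations

- The published hyperparameters were tuned on the original herd data. On
  the synthetic default herd the untethered 6-h model (sigma 0.0037, cost
  0.03, weight 3.5) predicts positive over long pre-calving stretches, so
  its grouped alerts are timestamped too early and score poorly; the
  tethered 6-h model and both 24-h models transfer well. Re-running the
  grid-search utility on synthetic data would recover better-suited values,
  but defaults stay faithful to the published ones.
- Event scoring of an alert whose horizon extends past the end of
  monitoring follows the same (alert, alert + H] rule; no censoring
  correction is applied.
- The between-condition inferential statistics of the original study
  (Fisher's exact test, generalized score statistic, Steel test, t-test)
  are descriptive of that herd and are out of scope; the package reports
  metrics, not between-condition inference.
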