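# Methods

This note records the model, the parameter choices that matter, what the
synthetic generator does and does not emulate, and the numerical decisions a
maintainer would otherwise have to reverse-engineer.

## Detector model

The per-channel detector is an adaptive-windowing mean-change test.  The
window W holds the raw recent history explicitly (no bucket compression);
after each arrival every split W = W0 ⊕ W1 is tested and a drift is declared
if |mean(W0) − mean(W1)| ≥ ε.  When several splits qualify, the *oldest* one
is reported, maximising the amount of stale data discarded; after
truncation the scan repeats on the retained suffix until no cut remains, so
one arrival can shrink the window several times.  The exhaustive scan is
vectorised over splits with prefix sums (O(n) per update) and exists so the
detector can be checked step-for-step against a brute-force oracle; the
logarithmic-memory bucket approximation of the classic algorithm is
deliberately out of scope.

Two thresholds are implemented:

* **`bernstein` (default).**  ε = √((2/m)·σ̂²_W·ln(2/δ′)) + (2/(3m))·ln(2/δ′)
  with δ′ = δ/n, m = 1/(1/n0 + 1/n1), and σ̂²_W the ddof-1 variance of the
  whole window.  The variance term adapts the test to the stream's scale;
  the linear term dominates for extreme splits (n1 of a few samples) and is
  what stops single heavy-tailed spikes from firing the test.  Note the
  linear term is scale-*dependent* (it assumes order-one data); the pipeline
  therefore standardises each channel first (see Calibration).
* **`hoeffding`.**  ε = √((1/(2m))·ln(4n/δ)).  Valid for data confined to a
  unit range, where a singleton split would need an impossible mean gap to
  fire.  On unbounded noise its extreme splits fire constantly (measured:
  ≈ 3 × 10² spurious drifts per 5,000 i.i.d. N(0,1) samples at δ = 0.002,
  versus ≈ 0 for the default bound), so it is not the default; it is kept
  because its closed form is directly testable and appropriate for
  pre-normalised bounded inputs.

Degenerate inputs: windows shorter than two elements never cut; a
zero-variance window has ε > 0 from the linear term, so constant streams
never fire; non-finite samples are rejected before they enter the window
(the analyser skips them with a diagnostic naming channel and timestamp).
Ties (|Δmean| exactly ε) count as cuts; with continuous noise they have
measure zero.

## Sensitivity regulation

Each channel owns a `DeltaController`.  The drift rate is cumulative over
the stream lifetime — accumulated detections over samples analysed — and is
compared against `last_rate`, the rate recorded at the last δ change, not at
the last chunk.  One training step runs per chunk of 2,000 samples (2 s at
1 sample/ms): rate up ⇒ δ := δ/10, rate down ⇒ δ := δ·10, inside
[lower, upper] = [10⁻⁹, 1.0], one decade per step.  A boundary-blocked move
leaves `last_rate` untouched; equal rates change nothing.  δ is stored as an
integer decade exponent and recomputed as upper·10⁻ᵏ, so the decade
invariant is exact.  The boundary values are configurable; the defaults span
the range over which the default bound's sensitivity usefully varies, with
the upper boundary equal to the mandated ultra-sensitive start value 1.0.

In the agent runtime the training step does not re-feed data through the
live detector (that would double-count every sample).  The retrain task
queries the channel's newest chunk of records from the knowledge base,
counts the stored drift verdicts into the controller — which is exactly the
accumulated-detections-over-samples rate definition — steps δ once, and
publishes the new value to the detector between predictions.  The
instrumentation counter `training_ops_in_predict` asserts the contract: it
stays zero over any run.  The standalone `train_on_chunk` loop (feed a raw
chunk, count, step, publish) is the same procedure for offline use.

## Calibration and scaling

The Bernstein threshold's linear term assumes order-one data, while raw EMG
is O(100 µV).  Each pipeline analyser therefore estimates a channel scale —
the standard deviation of a 1-second calibration prefix (1,000 samples) —
and feeds the detector `value/scale`.  Calibration samples are persisted
with `predicted=false` (every delivered sample yields exactly one knowledge
base record) but do not enter the detector.  A zero calibration deviation
(constant input) falls back to scale 1.  This is the package's cold-start
mitigation alongside the planner's all-channels guard; one second matches
the planner's decision window.

## Planner and executor

n_drift counts *distinct* channels with at least one drift-flagged record in
a tumbling `window_ms` (default 1,000 ms) window keyed on the monitored
timestamp, so decisions are independent of processing latency.  The rule
fires iff `min_drifts ≤ n_drift < max_drifts` (defaults 2 and 8): the lower
bound encodes paired limb musculature, the upper excludes the all-channels
cold-start signature.  Tumbling (non-overlapping) windows give at most one
alert per second.  A window is decided when the planner has seen a record
beyond its end (watermark) or at end of stream; repeated polls never see a
record twice (cursor on the insertion order).  The executor delivers alerts
in order, holds them while the sink is unavailable (informing the planner),
and drains the queue in order on recovery.

All pipeline timestamps are logical stream time anchored at a fixed epoch,
which makes reruns of the same input byte-identical; wall-clock operation is
available by running the agents with a real clock.

## Synthetic streams

The generator emulates the *statistical shape* the pipeline consumes: 8
channels at 1 sample/ms, zero-centred heavy-tailed noise (Laplace by
default — spiky like EMG but with finite moments; Gaussian available),
values rounded to integer microvolt counts, and deterministic drift events
(variance multipliers or mean shifts in σ units) on chosen channels and
intervals.  Events transform an already-drawn base matrix, so channels not
named in any event are bit-identical to an event-free run with the same
seed — which is also how the locality property is tested.  Overlapping
same-kind events contradict each other; the later-listed wins with a
warning.

Defaults: 100 µV per-channel deviation; the showcase drift event is a ×16
variance jump (a 4× amplitude burst, the scale of a rest-to-contraction
transition or gross movement artefact) on the two left-leg channels at
t = 5,000 ms.  The sampling interval is taken as 1 ms per row throughout.

What the generator does **not** emulate: motor-unit physiology (firing-rate
spectra, recruitment), cross-channel correlation during real movement,
baseline wander, powerline interference, or sensor dropout.  Passing tests
therefore demonstrate the detection and voting machinery under controlled
distribution changes, not clinical performance on real recordings.

## Problem sizes in the test and acceptance suites

Oracle equivalence runs 50 streams of 1,500 samples (stationary, mean-shift
and variance-shift thirds); false-positive control uses 50 stationary
streams of 5,000 samples; the end-to-end runs use 9,637-row recordings, the
size of the public punching-exercise file the input dialect comes from.
These sizes keep each suite within a couple of minutes on one CPU while
leaving every measured effect far from its decision boundary.

## Known limitations

* The exhaustive window makes one update O(n); at desk scale (≤ 10⁴-sample
  windows) this is milliseconds, but unbounded streams eventually want the
  bucketed approximation or a window cap.
* The decade grid for δ is coarse by construction; the controller oscillates
  one decade around its operating point rather than converging.
* The voting rule assumes the 8-channel layout; other channel counts work
  (`min_drifts`/`max_drifts` are configurable) but the pairs rationale is
  specific to bilateral musculature.
* The in-process bus preserves subscription/availability/back-pressure
  semantics but not network failure modes of a distributed transport.
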