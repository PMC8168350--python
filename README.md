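# driftmon

Concept-drift monitoring for multi-channel physiological streams, built as a
small multi-agent system.

Surface electromyography (EMG) records muscle-cell action potentials in
microvolts, one sample per millisecond per muscle.  The signal is spiky and
non-stationary: a genuine change in a patient's movement or the onset of
muscular fatigue shows up as a change in the *distribution* of the stream —
typically its variance — rather than as any single anomalous value.  A
per-channel change detector flags such distribution shifts, but a single
detector on a single muscle also fires on noise.  `driftmon` addresses both
problems for researchers and engineers who monitor multi-channel sensor
streams: each channel gets its own streaming detector with a self-tuned
sensitivity, and a voting planner turns per-channel detections into alerts
only when the cross-channel pattern is physiologically plausible.

## The method

**Per-channel detector.**  Each channel runs an adaptive-windowing (ADWIN
style) change detector.  The detector keeps a variable-length window
W of the most recent samples and, on every arrival, examines every split of
W into an older part W0 and a newer part W1.  A concept drift is declared as
soon as

&nbsp;&nbsp;&nbsp;&nbsp;|mean(W0) − mean(W1)| ≥ ε(n0, n1)

for some split, where the default threshold is the variance-adaptive bound

&nbsp;&nbsp;&nbsp;&nbsp;ε = √( (2/m) · σ̂²_W · ln(2/δ′) ) + (2/(3m)) · ln(2/δ′),

with m the harmonic mean of the subwindow sizes n0 and n1, σ̂²_W the sample
variance of the whole window, and δ′ = δ/n the confidence shared across the
n candidate splits.  On a drift the older subwindow is dropped (W0 is
replaced by W1) and the scan repeats.  Larger δ ⇒ smaller ε ⇒ a more
sensitive detector.  A simpler range-normalised Hoeffding threshold,
ε = √( (1/(2m)) · ln(4n/δ) ), is available as `bound="hoeffding"` for data
confined to a unit range.

**Adaptive sensitivity.**  δ starts at 1.0 (ultra-sensitive) and is
re-regulated every 2 s of stream by the observed *drift rate* — accumulated
detections over samples analysed.  A rising rate divides δ by 10, a falling
rate multiplies it by 10, saturating inside [10⁻⁹, 1]; the reference rate is
only re-anchored when δ actually moves, so boundary-blocked steps do not
inject noise.  Retraining runs as a task separate from prediction: the δ
visible to the prediction path changes only between predictions, at chunk
boundaries.

**Agents over a shared knowledge base (MAPE-K).**  Monitors capture samples
and forward them to subscribed, available analysers; analysers predict and
persist every verdict to an append-only relational knowledge base; the
planner polls the knowledge base, partitions stream time into tumbling
1-second windows, and counts the distinct muscles with a drift in each
window (n_drift); executors append fired alerts to a CSV sink, holding them
in order while the sink is down.  The voting rule is

&nbsp;&nbsp;&nbsp;&nbsp;alert ⇔ 2 ≤ n_drift < 8.

At least two muscles, because limb muscles come in pairs — a real change on
one side of the body shows on at least two channels, so single-channel
detections are discarded as false positives.  Strictly fewer than all eight,
because all channels flagging at once is the signature of the cold start,
when every detector is still calibrating.

## Worked example

Simulate a 9,637-row, 8-channel recording (1 sample/ms, spiky Laplace noise
at 100 µV per channel) with a ×16 variance jump on the two left-leg muscles
from t = 5,000 ms, then run it through the monitor:

```bash
cat > example.yaml <<'YAML'
synthetic:
  n_samples: 9637
  events:
    - {at_ms: 5000, channels: [6, 7], kind: variance_scale, magnitude: 16.0}
YAML
driftmon simulate --config example.yaml --seed 1 --out punch.csv
driftmon run --input punch.csv --kb kb.sqlite --out alerts.csv
```

The run prints:

```
rows read:            9637
rows skipped:         0
predictions written:  77096
raw drifts total:     19
  left_bicep         0
  left_hamstring     3
  left_thigh         16
  left_tricep        0
  right_bicep        0
  right_hamstring    0
  right_thigh        0
  right_tricep       0
alerts fired:         1
```

and `alerts.csv` contains the single fired alert:

```
window_start_ms,window_end_ms,n_drift,identifiers,decided_at
5000,6000,2,left_hamstring;left_thigh,2000-01-01 00:00:06.000
```

Every one of the 77,096 per-sample predictions (9,637 rows × 8 channels) is
in the knowledge base `kb.sqlite`; 19 of them are raw per-channel drift
detections, all on the two injected muscles; the planner collapses them into
exactly one alert, in the first decision window after the jump — the
19-to-1 reduction is the false-positive suppression the voting rule exists
for.  Reruns are byte-identical.

The same machinery is available as a library (`driftmon.AdwinDetector`,
`DeltaController`, `run_pipeline`, …) and accepts real recordings in the
headerless 8-column delimited dialect of public physical-action EMG
datasets.

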