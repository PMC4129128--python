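# adlsense

Non-intrusive recognition of **activities of daily living (ADL)** from
ambient smart-home sensors: a synthetic single-occupant home simulator, a
linear-time sorting pipeline for sensor packets, a rule-based
forward-chaining classifier, and event-level evaluation with activity
maps.

## The problem

Clinicians caring for older adults — in particular people with dementia —
need to know how well a patient copes with everyday activities at home:
how often they sleep, groom, cook, eat, or sit idle, and for how long.
Questionnaires are unreliable; cameras, microphones, and body-worn
sensors are intrusive. An alternative is a handful of small wireless
boxes, one per room (plus one on the fridge door and one on the toilet
flush handle), each sampling five ambient channels at 0.2 Hz:
temperature (°C), absolute humidity (g/m³), luminance (lx), passive
infrared motion (binary), and acceleration magnitude (m/s²). Daily
living perturbs these channels in activity-specific ways — a shower
raises bathroom humidity, cooking warms the kitchen and rattles the
fridge door, a flush shakes the flush handle, television imposes a
characteristic light level — so an inference engine with hand-authored
rules can recover which ADL happened when.

`adlsense` implements that whole stack, plus the piece such studies
usually leave out: a simulator that generates labeled ambient data for a
virtual resident, so the classifier can be developed and scored with no
hardware and no human subjects.

## The method

**Packets.** Each box emits one packet per 5 s: a handshake (timestamp,
date, node number, supply voltage, status word) plus the five ambient
values, protected by an even-parity bit over the serialized payload.
Single-bit corruption is always detected; double flips inside one record
are the classic parity blind spot (tested and documented).

**Sorting.** Captured packets are first partitioned into one bucket per
room by a stable single-pass Bucketsort (node id ↦ compartment is a
bijection), then each bucket is ordered chronologically by a
least-significant-digit Radixsort over the intra-day time key
(second-of-minute, minute, hour, day, month) — overall `O(n)` per home
and provably equal to a global stable sort by (compartment, date, time),
which the test suite checks against a comparison-sort oracle.

**Classification.** Motion episodes per room become candidate activity
windows (gap tolerance 120 s, with a single-occupant closure across
quiet gaps). For each window an *ambient value matrix* — (box, channel)
× time slice of the sorted streams — is summarized into features
(duration, endpoint deltas, motion density, luminance range and level,
appliance transient counts). A forward-chaining inference engine sweeps
the windows against a declarative rule repository: each rule carries a
target ADL, compartment scope, duration bounds, feature predicates,
optional prior-fact requirements ("a sleeping fact must start within
30 min after this window"), and a unique priority used for conflict
resolution (smallest priority number wins). Newly classified events are
appended to the fact database immediately, so fact-dependent rules fire
in later passes — iteration continues to a fixpoint or a configurable
cap. Example: a 6-minute bathroom window with a light change, one
flush-handle transient, and no humidity/temperature shift is
*toileting*; the same room for 25 minutes with a +6 g/m³ humidity rise
is *grooming*.

**Evaluation.** Classifier output is correlated with the resident's
ground-truth protocol (switch-device log merged with paper log-book
corrections) by greedy one-to-one event matching (overlap ≥ 50% of the
shorter event; an epoch mode is available). Per-ADL sensitivity
`100·TP/(TP+FN)` and one-vs-rest specificity `100·TN/(TN+FP)` are
reported with unweighted (macro) overall averages, alongside
day × time-of-day activity maps with a routine-regularity score.

## Worked example

Simulate two homes for three days, classify, and score — all in a few
lines:

```python
from adlsense.pipeline import run_synthetic_benchmark

result = run_synthetic_benchmark(n_homes=2, n_days=3, seed=42)
print(result.metrics)
print("reliability:", result.integrity.reliability_pct, "%")
```

```
ADL                        N    TP    FN    FP   Sens %   Spec %
sleeping                   9     9     0     0    100.0    100.0
grooming                   5     5     0     1    100.0    98.25
toileting                 18    18     0     0    100.0    100.0
getting_ready_for_bed      4     3     1     0     75.0    100.0
cooking                    7     7     0     0    100.0    100.0
eating                     7     7     0     0    100.0    100.0
watching_tv                5     5     0     0    100.0    100.0
seated_activity            7     7     0     0    100.0    100.0
Total                     62    61     1     1    96.88    99.78
reliability: 99.52 %
```

Reading this: the two simulated residents performed 62 observable
activities; 61 were recovered at ≥ 50% overlap. One pre-bed bathroom
visit was absorbed into a neighboring window (a miss), and one window
fired the grooming rule spuriously (a false positive for grooming,
which costs specificity only for that label). The transmission
reliability reflects the configured 0.47% packet-loss rate of the
simulated radio link.

The same chain is available from the shell:

```bash
adlsense simulate --days 3 --homes 1 --seed 5 --out sim/
adlsense sort --in sim/home00.packets.csv --out sorted/
adlsense classify --sorted sorted/ --out events.csv
adlsense evaluate --events events.csv --truth sim/home00.truth.csv --out metrics.json
adlsense report --events events.csv --map map.png
```

or as one reproducible run: `adlsense run --config config.json`.

## Layout

```
src/adlsense/
  domain.py     labels, channels, layouts, packets, events
  codec.py      CSV/JSONL packet serialization with even parity
  simulate.py   resident routines, emission models, lossy packetization
  sortpipe.py   Bucketsort + Radixsort + integrity accounting
  features.py   window segmentation, ambient value matrices, features
  rules.py      rule schema, default rulebase, forward-chaining engine
  evaluate.py   log merging, event matching, metrics, activity maps
  pipeline.py   end-to-end orchestration and the closed-loop benchmark
  cli.py        the `adlsense` command
docs/methods.md   model assumptions, parameter choices, limitations
```
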