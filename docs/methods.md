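# Methods

This note documents the models behind `adlsense`, the parameters that
matter, the design decisions taken where the design was genuinely open,
and what the closed-loop tests do and do not demonstrate.

## 1. Data model

A sensor packet is one 0.2 Hz transmission from one box: handshake
(timestamp as integer seconds-of-day on the 5 s grid, calendar date,
node id, supply voltage, opaque status word) plus five ambient readings
in a fixed channel order — temperature (°C), absolute humidity (g/m³),
luminance (lx), PIR motion (binary), acceleration magnitude (m/s²).
Acceleration is a single magnitude, not a 3-axis vector: the classifier
only consumes appliance transients (fridge door, flush handle), for
which a magnitude suffices. There are no time zones and no DST; all
per-day structure (sorting keys, activity-map bins) lives on the
intra-day timeline.

The text codec (CSV and JSONL dialects) appends an even-parity bit
computed over the UTF-8 bytes of the serialized payload. This detects
every single-bit corruption and none of the double-bit corruptions
within one record — an inherent parity property, surfaced in the test
suite rather than hidden. Corrupted packets are *flagged*
(`parity_ok=False`) and counted, never silently dropped; they retain
the record as received so that re-serializing a corrupted capture
preserves both the corruption and its parity verdict.

One deliberate modeling fix: a full day of one box is exactly
17,280 packets (86,400 s / 5 s) with 5 ambient values each. Published
deployment summaries of this kind of system can disagree internally on
values-per-packet arithmetic; this implementation pins 5 values/packet
as the sensor list dictates and derives all volume arithmetic from it.

## 2. Synthetic resident and home

### Routine generation

The generator is an agent-based scheduler, not a trace replayer.
Per day it places:

- a nightly **sleeping** block (start ≈ 23:00, duration log-normal with
  median 7.5 h, clamped to 6.5–8.5 h), split into separate sleeping
  events by a Poisson number (default 0.6/night) of nocturnal toilet
  visits kept ≥ 90 min from the sleep edges;
- **getting ready for bed** attached contiguously to the front of every
  sleeping block (4–14 min, bathroom);
- anchored daytime activities with per-anchor occurrence probabilities:
  morning **grooming** (~20 min after wake, 18–48 min), **toileting**
  (2–3 anchors, 3–12 min), **cooking** (lunch anchor p=0.9, dinner
  anchor p=0.3, 13–55 min), **watching TV** (evening, 30–120 min,
  clamped to end ≥ 30 min before bedtime), **seated activity**
  (daytime anchors, 26–90 min);
- **eating** following every cooking event after a 2–10 min lag.
  The pairing probability defaults to 1.0: the default rulebase infers
  eating from a *preceding cooking fact*, so a resident who always eats
  what they cook is the configuration under which label recovery is
  well-posed. Unpaired (delivered-food) eating can be simulated by
  lowering `eating_after_cooking_prob`, at a known sensitivity cost.

`structure_level` ∈ [0, 1] controls regularity: timing jitter is
Gaussian with SD `jitter_base_s · (1 − structure_level)` (45 min at 0),
and at `structure_level = 1` all sampling collapses to medians and
threshold inclusion, so every day is an exact 24 h-shifted copy of the
previous one. Collisions are resolved by shifting an event past the
blocking interval (12 attempts, 3 min spacing) or dropping it; a profile
whose expected total demand exceeds 24 h/day raises a scheduling error
up front.

The tail of a *virtual previous night* is emitted as a sleeping event
clipped at the start of the observation range, so the house is never
empty while the resident is actually asleep on the morning of day 0.
The `alzheimer` preset (structure 0.3, 5–8.5 h fragmented sleep, 2.0
nocturnal visits/night) exists only for the qualitative
routine-regularity contrast; no numeric claim attaches to it.

Between events the resident putters through the kitchen and dining room
in 2–6 min dwells with high movement. This matters twice: idle dwells
provide the cross-room motion evidence that separates consecutive
same-room activities, and their high motion density (≈ 0.85) keeps
idle-only windows from satisfying the low-density eating/seated rules.

### Emission model

Channel physics are deliberately simple and fully parameterized
(`EmissionModel`):

| effect | default | shape |
|---|---|---|
| shower humidity pulse | +6 g/m³ | linear rise over event, exp decay τ = 20 min |
| cooking pulse | +2 °C, +1.5 g/m³ | same shape, kitchen |
| fridge/flush transient | 3 m/s² spike | ≥ 1 per cooking / at toileting end |
| outdoor daylight | 300 lx peak, 06:30–19:00 half-sine | per-room attenuation 0.02 (bathroom) – 0.8 (living room) |
| lamp / TV | 200 lx / 40 lx | lamp on when occupied & dark; TV level replaces it; sleeping leaves lights off |
| PIR | P(trigger)=0.95 per 5 s of movement, 10 s hold, 10⁻⁴ false rate | per-activity movement rates 0.01 (sleep) – 0.7 (cooking) |
| Gaussian noise SD | 0.05 °C, 0.15 g/m³, 2 lx, 0.02 m/s² | additive, luminance/acceleration clipped at 0 |

The bathroom is modeled as near-windowless (attenuation 0.02) so that
any visit requires the lamp — the "light conditions change" predicate
of the bathroom rules is then informative at every hour. Appliance
boxes report the room's ambient channels but no PIR (they face the
appliance); segmentation is driven by wall boxes only.

`EmissionModel.noise_free()` zeroes the Gaussian SDs and makes the PIR
deterministic (trigger probability 1, false rate 0). This is the
configuration of the closed-loop oracle.

### Packet link

Every sample becomes a packet; each packet is independently dropped
with probability 0.0047 (matching a ~99.53% link reliability) and
bit-corrupted with probability 0.0005. Corruption is physical: the
record is serialized, one payload digit bit is flipped, and the packet
is re-decoded, so the `parity_ok` flag is the parity check's verdict,
not an assumption. Per-home seeds derive from the master seed via a
`SeedSequence`, making multi-home studies byte-reproducible.

## 3. Segmentation and features

Candidate windows are maximal presence episodes per room built from PIR
motion: episodes merge across gaps ≤ 120 s; windows < 60 s are
discarded. On top of this sits a **single-occupant closure**:
consecutive episodes in the same room also merge across longer quiet
gaps when no *other* room accumulates ≥ 8 motion-active samples in the
gap. The rationale: a lone resident who stops moving (sleeping, reading)
and triggers nothing elsewhere has not left the room, whereas one or two
isolated PIR false triggers elsewhere (≤ 3 samples each after hold
dilation) are noise, not a sighting. Without the closure, sleeping
(motion density ≤ 0.05) would fragment into sub-minute episodes and be
unrecoverable; with a lower blocker threshold, false triggers would
split the night instead.

Each window's ambient value matrix takes the room's wall box(es) plus
appliance boxes (kitchen/bathroom), padded by ±60 s so endpoint deltas
see the pre/post-activity baseline (lamp off, pre-shower humidity).
Missing samples (packet loss) are masked, never interpolated. Features:
window duration and start time; motion density over the unpadded core;
temperature/humidity deltas as differences of 30 s median endpoints
(robust to single-sample noise); luminance mean (core) and range
(padded; "light change" at ≥ 20 lx); a TV signature flag (mean in
25–60 lx); and appliance transient counts (excursions > 1.5 m/s² above
the window's median baseline, separated ≥ 10 s).

## 4. Rule engine

Rules are declarative JSON: target label, compartment scope, duration
bounds, conjunctive predicates with `any_of` groups for disjunctions,
optional prior-fact requirements, and a unique priority. The parser
validates ids, priorities, feature names, comparators, and duration
ordering, and round-trips. The engine sweeps candidates in time order;
the first fully satisfied rule in priority order labels the window
(conflict resolution = smallest priority number, i.e. the order in
which the rules were authored), and the event immediately joins the
fact database, so later windows in the same pass can depend on it.
Passes repeat until no new fact appears (≤ `max_iterations`, default
5 — exceeding it logs a warning and returns the partial result). The
database is append-only during a run, which gives the monotonicity and
termination guarantees the tests assert.

The shipped rulebase (priorities 1–9; grooming's disjunction is two
rules at adjacent priorities because predicates are conjunctive):

1. sleeping — bedroom, ≥ 1 h, mean luminance ≤ 20 lx, motion ≤ 0.05
2. grooming (shower) — bathroom, 10–60 min, Δhumidity ≥ 3 g/m³
3. grooming (long) — bathroom, 15–60 min, light change
4. getting ready for bed — bathroom, 2–20 min, light change, a sleeping
   fact starting ≤ 30 min after the window
5. toileting — bathroom, 2–15 min, light change, ≥ 1 flush transient,
   |Δhumidity| < 2 g/m³, |Δtemperature| < 1 °C
6. cooking — kitchen, 10–90 min, ≥ 1 fridge transient, Δtemp ≥ 0.5 °C
   or Δhumidity ≥ 1 g/m³
7. eating — dining room/kitchen, 10–60 min, motion ≤ 0.6, a cooking
   fact ending ≤ 45 min before the window
8. watching TV — living room, 20 min–5 h, TV signature, motion ≤ 0.3
9. seated activity — living room, 20 min–5 h, daytime, no TV signature,
   motion ≤ 0.5 (the deliberate low-priority fallback)

These thresholds are calibrated against the default emission model and
exposed as configuration (`adlsense rules --out rules.json`); they are
engineering choices, not empirical claims about any real deployment.
"Does not change significantly" is operationalized as fixed per-channel
thresholds rather than statistical tests, because the engine is a
parameterized look-up, not an estimator.

## 5. Evaluation

Event matching is greedy, one-to-one, in time order: a truth event is a
true positive when an unmatched same-label classified event overlaps it
by ≥ 50% of the shorter of the two (the common activity-recognition
convention; configurable). Unmatched classified events are false
positives. Specificity needs a negative universe that an event-level
protocol does not define; the default is one-vs-rest over ground-truth
events (a false positive of label L "claims" at most one other-label
truth event; TN = the rest), with a per-epoch mode (default 60 s) as
the alternative reading. Overall figures are macro (unweighted) means
of the eight per-ADL values — the arithmetic that connects per-activity
rates to overall rates when classes are imbalanced. Sensitivity for a
never-performed activity is *undefined*, not zero.

Activity maps rasterize events onto a day × 5 min grid (majority label
per bin, ties to the earlier-starting event); the regularity score is
the mean bin agreement between consecutive days.

In the closed-loop benchmark, scoring excludes events that the
recording window truncates: the final night's sleeping block runs past
the end of observation, and the getting-ready interval attached to it
depends on that unobservable sleep. Both truth and classifier events
overlapping that tail are dropped symmetrically.

## 6. Problem sizes and numerical choices

The shipped benchmark simulates 10 residents × 5 days (≈ 6.0 million
packets end to end) and finishes in ~35 s on one CPU; homes are
processed sequentially to bound memory. The noise-free closed loop uses
3 homes × 3 days. Loss-rate convergence is checked at 10⁶ packets
against a 99% binomial interval, and the sorting oracle at 10⁵ packets.
Tie-breaks and degenerate inputs are pinned down explicitly: stable
sorts everywhere (equal timestamps keep arrival order), an empty rule
list is a valid repository that classifies nothing, an all-quiet home
yields no candidate windows, a window falling entirely into a
packet-loss gap raises an explicit empty-matrix error, and reliability
of an empty stream is 100% by convention.

## 7. What the closed loop does and does not show

The noise-free invariant — every per-ADL sensitivity and specificity
100%, zero false positives — demonstrates that the rulebase is
*complete and consistent with respect to the emission model*: every
behavior the simulator can produce leaves a recoverable signature, and
no rule fires without one. Under default noise the benchmark's macro
sensitivity/specificity (≈ 98–99%) exceed the levels reported for
comparable real deployments (≈ 91/93), as they must: the simulator
omits exactly the things that make real homes hard — multi-occupancy,
pets, visitors, unmodeled heat/humidity sources (weather, open
windows), sensor drift, furniture occlusion, and imperfect ground-truth
protocols. Passing the closed loop therefore validates the *software
chain*, not field performance; the synthetic figures are upper bounds,
and the real-world numbers serve only as floors the cleaner benchmark
must clear.

Known limitations: single resident only; rules are hand-calibrated to
the default emissions (changing one without the other degrades
recovery, by design); the 5-component radix key assumes recordings
within one calendar year (a year pass is added automatically when
violated); humidity is treated as absolute (g/m³) throughout; no
real-time/streaming inference.
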