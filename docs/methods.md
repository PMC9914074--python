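# Methods

## Problem and model

An excretion-nursing device must decide, from a temperature sensor, a
humidity sensor and an ammonia sensor mounted in its toilet bowl,
which of four events just occurred: urine only (A), stool only (B),
urine and stool together (C), or nothing (D). `excare` implements the
decision-level fusion used for that task — Dempster–Shafer (D-S)
evidence theory over a detection basis of per-channel excursion
intervals — together with the traditional direct threshold classifier
it is compared against, a synthetic data generator that emulates the
bench conditions, the device's actuator workflow, and paired
statistical evaluation.

### Frame of discernment

The frame has three atoms: urine-present `u`, stool-present `s`,
nothing `n`. The four events are the focal sets A = {u}, B = {s},
C = {u, s}, D = {n}. Modelling the combined event C as the **union**
of A and B is forced by the combination rule used for the device: its
normalization coefficient counts A∩C = A and B∩C = B as
non-conflicting, which is only coherent if C ⊇ A, B. A consequence
worth stating plainly: in this algebra, mass on C is *weak* evidence —
it never contradicts A or B, so any accumulated singleton support
eventually dominates it (see "Known limitations").

### Detection basis

Excursions above the indoor baseline (x °C, y %RH, z ppm; ammonia
floored at 0) are classified against the interval table shipped as
`table1.yaml`:

| channel | stool (B) | urine (A) | both (C) | none (D) |
|---|---|---|---|---|
| temperature (°C) | 0.5 < x < 2 | x > 1.8 | 0 < x < 1 | ≈ 0 |
| humidity (%RH) | 5 < y < 12 | y > 20 | 12 < y < 20 | ≈ 0 |
| ammonia (ppm) | 1 < z < 2 | z > 2 | 1 < z < 2 | ≈ 0 |

The baselines (default 22 °C / 40 %RH / 0 ppm — typical indoor
conditions) are configuration, not constants: the same table applies
in any room once its `environment:` section is set.

Note two built-in ambiguities of the table itself: stool and both
share the *identical* ammonia band, and their temperature bands
overlap in (0.5, 1). Humidity is the only channel that separates B
from C cleanly.

### Membership and basic probability assignment

The printed inequalities are strict and give no probability rule, so
fuzzification is a design choice of this package:

* **Trapezoidal membership** per channel × event: 1 inside the
  interval, a linear ramp of the channel's *softness* outside each
  finite edge (defaults 0.3 °C, 3 %RH, 0.5 ppm — of the order of the
  sensor accuracies). An interval whose lower edge sits at 0 ramps
  *up inside* instead, so a vanishing excursion carries no membership.
* **NONE** is a triangular peak at 0 whose half-width is the channel's
  smallest positive lower bound (0.5 °C, 5 %RH, 1 ppm): exact zeros
  never occur under noise, so "no excursion" needs a neighborhood.
* **Mass assignment** (`scheme="union"`, the default): support a
  singleton shares with C belongs to the union — to C itself —
  and only the singleton's excess stays on it:
  m_A ∝ max(0, μ_A − μ_C), m_B ∝ max(0, μ_B − μ_C), m_C ∝ μ_C,
  m_D ∝ μ_D, normalized to 1; if everything is numerically zero the
  full mass goes to D. This is the standard evidence-theory treatment
  of ambiguous evidence: an ammonia reading in the 1–2 ppm band
  asserts "stool or stool-and-urine", i.e. the disjunction, not a
  50/50 split. The naive normalized-membership alternative
  (`scheme="proportional"`) is retained for comparison; under it the
  combined event C is *never* decided (splitting shared support hands
  Dempster's specificity preference a permanent B majority), which is
  why it is not the default.

### Fusion pipeline

Per session (default 3 cycles × 2 reads per channel):

1. **Screening** — reads farther than 3 scaled median absolute
   deviations (MAD × 1.4826) from the per-channel *session* median are
   dropped; a cycle is never emptied by the screen. This also absorbs
   the ammonia sensor's detection-floor censoring (readings below
   1 ppm report 0, and isolated zeros get screened out when the rest
   of the session reads above the floor).
2. Surviving reads are averaged per cycle and converted to deltas.
3. Per cycle, the three channel BPAs M1 (temperature), M2 (humidity),
   M3 (ammonia) are combined with Dempster's rule; the three cycle
   results are then combined across cycles; the maximal fused mass
   decides, ties broken BOTH > STOOL > URINE > NONE (prefer the most
   complete cleaning action).

Masses are floored at 1e-4 and renormalized before every combination,
so a certain-but-conflicting sensor pair degrades gracefully instead
of hitting the undefined K = 0 case; the raw `combine` still raises on
genuine total conflict.

Repeated combination *polarizes* mass toward singletons; it is not
decision-preserving. A composite-heavy assignment such as
(0.3, 0.2, 0.4, 0.1) decides BOTH but flips to URINE after one
self-combination — the test suite demonstrates this rather than
assuming the opposite.

### Direct (baseline) classifier

The traditional method reads each channel once (the session mean),
checks which intervals contain it — crisp, half-open at shared
boundaries so a value exactly at an edge belongs to the upper class,
NONE matching an exact zero only — and takes a majority vote across
the three channels, ties resolved by the same fixed order, no votes at
all meaning NONE.

### Evaluation

Both classifiers run on the same trials, so accuracies are compared
with McNemar's paired chi-square on the discordant counts b (fused
wrong, direct right) and c (fused right, direct wrong):
χ² = (|b−c|−1)²/(b+c) with continuity correction (uncorrected variant
by flag), significant at α = 0.05 when χ² > 3.841; b + c = 0 reports
not-applicable.

### Workflow simulator

Actuator schedules are exact event timestamps from the printed
process timings: stool/both flushing runs both flush valves and the
pump for 10 s with the vacuum joining at 5 s and stopping at 18 s;
urine flushing waits 10 s (time to detect a following stool), then
valve + pump 5 s and vacuum alone 10 s; cleaning runs 15 s (both
cleaning valves + pump + vacuum for stool/both; the urine cleaning
valve for urine — the urine cleaning duration is not printed and is
assumed equal to stool's); drying runs the heater 8 min and the fan
10 min. Full workflows last 633 s (stool/both) and 640 s (urine).
Alarms: side angle outside ±30°, clean-water level below threshold,
dirt level above threshold; any alarm sounds the buzzer.

## Synthetic data generator

`simulate_dataset` emulates the bench data collection with no
hardware: each event draws one true excursion per channel uniformly
within its class's basis interval (unbounded sides capped at 4 °C /
45 %RH / 10 ppm for urine; NONE has zero excursion), holds it constant
for the session, and observes it through the datasheet model —
Gaussian read noise (defaults 0.4 °C / 4 %RH / 0.6 ppm, of the order
of the sensor accuracies plus environmental fluctuation), range
clipping (−40–80 °C, 0–99.9 %RH, ammonia 1–300 ppm reporting 0 below
1 ppm) and 0.1-step output quantization. Datasets are balanced,
shuffled, and byte-reproducible from a single seed.

What it does **not** emulate: gas transport and diffusion dynamics,
inter-subject and diet variation, drifting room baselines, sensor
aging. Passing tests therefore show correctness of the *method* under
idealized-but-noisy conditions, not clinical performance.

## Benchmark findings and known limitations

On the default benchmark (2000 sessions, seed 1; `scripts/acceptance.py`
recomputes these) the fused pipeline reaches **80.0%** overall
accuracy versus **82.75%** for the direct classifier; the McNemar
test on the discordant pairs is significant. Per class, fusion is
near-perfect on urine, stool and none (≥ 96% each) but recovers only
~25% of combined urine-and-stool events. This is a structural
property, not a tuning artifact:

* For masses supported on B and C only, n-fold Dempster combination
  gives fused B ∝ Π(bᵢ+cᵢ) − Πcᵢ against C ∝ Πcᵢ: a ratchet. One
  cycle in which one channel grants any singleton more mass than C
  converts the whole session to that singleton, and no later cycle
  can win mass back for C.
* The generator draws class excursions uniform up to the interval
  edges while per-cycle noise (e.g. 2.83 %RH on a 2-read humidity
  mean) straddles the shared boundaries, so such singleton "jolts"
  occur in a third or more of true-combined sessions whatever the
  membership shape.

Halving the noise puts the same pipeline at 90.3% and ahead of the
direct classifier (84.8%) — the method's headline behaviour is real
but lives at lower noise than the default study conditions. At zero
noise the direct classifier is exact and the pipeline is ≈ 99%: the
residual errors are combined events whose small temperature excursion
quantizes to exactly 0 at the 0.1 °C resolution, making the
temperature BPA NONE-certain against two BOTH-certain channels —
Dempster's well-known near-total-conflict pathology, which epsilon
flooring bounds but cannot repair.

Other limitations: the frame is fixed at {u, s, n} (no general
frames); only Dempster's rule is provided (no Yager/PCR5-style
conflict redistribution); intervals are not learned from data; the
urine 10 s delay is a fixed wait, not a closed-loop re-detection
(a hook exists for callers that want one).

## Numerical choices

Mass validity tolerance 1e-9; combination floor 1e-4; MAD screen
threshold 3 (scaled, consistent-for-normal); decision ties by fixed
severity order; fusion is a left fold (associative to 1e-9, verified
against a brute-force subset-lattice implementation on 10^4 random
pairs). Problem sizes used by the shipped tests and the acceptance
script: 2000-session benchmarks, 200-session zero-noise and
permutation checks — sizes at which a full run completes in seconds
while class accuracies carry standard errors under one percentage
point.
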