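# remowear

Device-agnostic wrist-accelerometry analytics and symptom-triggered
remote-monitoring simulation for frailty-aligned mobility metrics.

Remote geriatric assessment needs home-collected, reproducible measures
of the functional side of frailty — inactivity, slowness, endurance,
overall intensity — plus honest accounting of how well older
participants keep up with the prompts that drive data collection.
`remowear` implements the full analytic core of such a deployment for
researchers in digital health and geriatric oncology:

* **Signal pipeline** — raw 10 Hz triaxial counts (±8 g, 4,096
  counts/g) → calibrated 1-s epochs → non-wear mask → step events →
  per-24-h metrics with validity rules.
* **Prompt engine** — the symptom-triggered sampling state machine
  (self-rated health every 5–9 days, symptom follow-up chains, weekly
  scale, conditional 48-h watch sessions) with a seeded cohort
  simulator.
* **Engagement reporting** — end-to-end completeness vs
  participant-attributable adherence, 4-week-block engagement, SUS
  scoring, geriatric-assessment change flags; a transcribed
  deployment completion table ships as a fixture.
* **Synthetic data** — scripted wrist signals (gait of known cadence,
  sedentary wear with posture shifts, non-wear) with exact ground
  truth, so the whole system is testable at desk scale.

## The metrics

For each initiated 48-h session (split into two 24-h intervals at the
initiation time, not midnight):

* **steps** — two-stage detection: windows labelled moving/not-moving
  from time-domain and gait-band (0.6–2.5 Hz) features, then regularly
  spaced peaks with physiologic timing (intervals in [0.33, 1.67] s,
  runs of ≥ 4, pairwise spread ≤ 0.35 s) in the zero-phase band-passed
  vector magnitude;
* **cadence** ("best pace") — the 90th percentile of per-minute step
  counts over minutes with ≥ 1 step;
* **LWB** (longest walking bout) — the largest maximal run of steps
  with inter-step gaps ≤ 3 s, capped at 2 h;
* **Activity Index** — per 1-s epoch,
  `AI_t = sqrt(max(0, (1/3) Σ_axes (σ²_axis,t − σ̄²) / σ̄²))`
  where σ̄² is the device's systematic noise variance estimated from
  quiet-stationary wear; summed hourly over worn daytime epochs
  (07:00–19:00) and per 48-h session the larger 24-h summary is
  retained;
* **validity** — an interval is analyzable iff non-wear ≤ 1.5 h
  (≥ 90-min spans quiet on ≥ 2 of 3 axes, padded 15 min each side) and
  ≥ 300 detected steps.

Adherence distinguishes **end-to-end completeness**
(completed/scheduled, device failures in the denominator) from
**participant-attributable adherence**
(completed/(scheduled − device-failed)).

## Worked example

```python
from datetime import datetime
from remowear import process_raw_session
from remowear.synth import ActivityScript, Segment, generate_accel

script = ActivityScript(
    segments=[
        Segment("stationary_wear", 2 * 3600),
        Segment("gait", 1800, cadence=110, amplitude_g=0.3),
        Segment("stationary_wear", 3 * 3600),
        Segment("gait", 600, cadence=90, amplitude_g=0.25),
        Segment("stationary_wear", 2 * 3600),
        Segment("nonwear", 95 * 60),
        Segment("stationary_wear", 3600),
    ],
    seed=17, start=datetime(2026, 1, 10, 9, 0),
)
raw, truth = generate_accel(script)
m = process_raw_session(raw, session_id="example-day").intervals[0]
```

Running `python examples/01_scripted_day_pipeline.py` prints:

```
ground truth: 4200 steps, 95 min non-wear
detected:     4200 steps (100.0% of truth)
cadence p90:  110.0 steps/min  (best-pace metric; the brisk bout)
LWB:          3300 steps over 1800 s  (endurance metric)
activity idx: 52855  (daytime 07:00-19:00 intensity sum)
non-wear:     2.08 h incl. 15-min padding -> valid=False ['excess_nonwear']
```

The detector recovers every scripted step; the 90th-percentile cadence
lands on the brisk bout's 110 steps/min; the 30-min walk is the LWB;
and the 95-min charger block plus padding exceeds the 1.5-h budget, so
the interval is (correctly) excluded from step-derived analyses.

The other example scripts cover cohort simulation
(`02_simulate_cohort.py`), the packaged completion-table fixture
(`03_engagement_from_fixture.py`), and usability / GA-change scoring
(`04_usability_and_ga_flags.py`).

## Command line

```
remowear synth accel --script day.yaml --out raw.csv --truth truth.json
remowear process --raw raw.csv --out proc/
remowear simulate --n 10 --seed 7 --out sim/
remowear report --ledger sim/ledger.csv --out rep/
remowear report --fixture --out rep/        # packaged completion table
```

Every run writes a `manifest.json` with the config hash, seed, and
package version; outputs are byte-identical given (config, seed).

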