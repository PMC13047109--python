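# Methods

This note documents the models and procedures `remowear` implements,
the defaults and why they hold, what the synthetic generator does and
does not emulate, and the design choices made where the design was
genuinely open.

## Signal model and units

The target sensor reports triaxial acceleration as integer counts at a
nominal 10 Hz, ±8 g range, 4,096 counts/g; conversion is exactly
`g = counts / 4096` per axis. All thresholds below are in g (1 mg =
0.001 g). Timestamps are seconds relative to a local-clock anchor;
epoch boundaries align to integer seconds from the first sample so
segmentation is independent of clock phase. Duplicate timestamps keep
the first observation and gaps are preserved as empty epochs
(`n_samples = 0`, NaN statistics) — samples are never fabricated.

## Calibration

A fixed scalar bias is estimated from quiet-stationary wear:
10-s windows stepped at 1 s whose vector-magnitude (VM) SD stays below
13 mg, merged into intervals of ≥ 60 s. The 13 mg threshold is the
conventional low-movement SD cut for wrist devices of this class; the
scalar-VM (rather than per-axis orientation) correction suffices
because every downstream metric consumes VM or per-axis variance.
Given ≥ 60 s of stationary data:

* `bias = median(VM_stationary) − 1 g`;
* `noise_floor = 3 × SD(VM_stationary)`;
* `σ̄² = mean per-axis variance over stationary 1-s epochs` (floored
  at 1e−12 g² to keep the Activity Index defined on noiseless input).

Recordings with no usable stationary interval fall back to the
configured defaults (bias 0, noise floor 13 mg, σ̄² = (13 mg)²) so
short sessions never abort. Per-epoch `vm_bc` subtracts 1 g and the
bias, clamps deviations inside the noise floor — and any residual
negatives — to zero.

## Non-wear

A span is non-wear when per-axis variability stays below 13 mg on ≥ 2
of 3 axes over ≥ 90 contiguous minutes. The 90-min horizon is made
local by evaluating rolling 30-min sub-blocks stepping 1 min: the span
qualifies iff every sub-block inside it is quiet. Per sub-block the
axis SD combines within-epoch variance and between-epoch mean drift
(law of total variance), so both tremor-scale motion and posture
changes defeat it; sub-blocks with under half their epochs present are
never quiet. Detected spans are padded by 15 min on each side (clamped
to the record, overlaps merged) and the padded extent counts toward
the 1.5-h validity budget — padding exists to keep edge effects out of
analysis, so padded epochs are excluded like the core. A brute-force
scan over all ≥ 90-min windows reproduces the mask exactly on short
records (tested).

## Step detection

Two stages, all parameters config-exposed:

1. **Moving/not-moving.** Non-overlapping 5-s windows are *moving*
   when VM SD ≥ 30 mg, the dominant non-DC frequency lies in the gait
   band 0.6–2.5 Hz, and ≥ 50% of non-DC spectral power falls in that
   band. This is a fixed threshold rule rather than a trained
   classifier: deterministic, inspectable, and tunable where no
   training corpus exists.
2. **Peak detection.** The VM is band-passed 0.6–2.5 Hz with a
   zero-phase 2nd-order Butterworth (zero-phase so peak timestamps —
   hence cadence and bout boundaries — are unbiased). Local maxima
   inside moving windows must exceed
   `max(50 mg, 0.6 × RMS(band-passed window))` — adaptive per-window
   sensitivity with an absolute floor against noise. Surviving peaks
   are split into maximal runs whose successive intervals lie in
   [0.33, 1.67] s and differ pairwise by ≤ 0.35 s; runs of ≥ 4 peaks
   emit one step per peak. Steps inside non-wear epochs are removed.

10 Hz is the contract rate; other rates are rejected unless explicit
linear resampling is enabled.

## Daily metrics

Each initiated session spans 48 h from the initiation press and splits
into `[t0, t0+24h)` and `[t0+24h, t0+48h)` — session-anchored, not
calendar-anchored, because the monitoring window begins at initiation.
Per interval:

* **cadence** = 90th percentile (linear interpolation) of per-minute
  counts over minutes with ≥ 1 step; 0 with a flag when no minute
  steps;
* **LWB**: bouts are maximal step runs with gaps ≤ 3 s (3 s preserves
  slow-gait continuity while breaking at genuine rests); steps beyond
  2 h after the bout's first step are not counted and duration caps at
  7,200 s; the bout with the most steps wins, ties to the earliest;
* **Activity Index**: `AI_t = sqrt(max(0, mean_axes((σ²_a,t − σ̄²)/σ̄²)))`
  per 1-s epoch, summed (not averaged — the daily magnitudes ~10⁴–10⁵
  arise from summation; config-exposed) over worn epochs whose
  local-clock hour is in [07:00, 19:00), restricted to the interval.
  The daytime filter uses clock time regardless of the session anchor.
  The summary is marked missing when under 50% of the interval's
  daytime seconds have a worn, sampled epoch; it is retained even when
  step-validity fails, since it carries its own coverage requirement;
* **validity**: non-wear ≤ 1.5 h AND ≥ 300 steps AND any coverage,
  boundaries inclusive (exactly 1.5 h or exactly 300 steps is valid —
  the exclusion rules are phrased as strict inequalities). Steps are
  counted after non-wear masking.

Per session, the larger of the two 24-h Activity Index summaries is
retained and valid intervals are counted.

## Prompt engine

Simulated time advances in whole minutes, local clock, no DST. Every
prompt is available 48 h; completion at exactly +48 h counts
(inclusive boundary). Rules:

* **SRH** (self-rated health; excellent/very good/good/fair/poor):
  first prompt at deployment start, then gaps drawn uniformly from
  {5,…,9} days. Uncompleted-by-24 h primary SRH and scale prompts emit
  exactly one reminder instance at +24 h, itself a scheduled instance
  (matching how deployed platforms count reminder/duplicate prompts).
  Watch prompts emit no reminders — initiation is a single act on the
  device. Scale reminders are config-exposed.
* **Triggers**: fair/poor SRH issues a symptom survey and a watch
  prompt; good-or-better issues a watch prompt with probability
  `p_random_watch` (default 0.5 — the protocol specifies random
  selection without a rate; the draw is made per SRH response, which
  is one of two defensible readings of "random selection among
  good-or-better weeks").
* **Symptom chains**: a completed symptom response with any item grade
  ≥ 2 opens a follow-up chain re-prompting at response+3 d until a
  completed response with all grades ≤ 1. An expired chain prompt
  re-prompts at issue+3 d (the chain keeps sampling); an expired
  *initial* symptom survey opens no chain, since no grade exists. At
  most one chain is open per participant; a fair/poor SRH during an
  open chain issues no second initial survey.
* **Attribution**: a pending prompt past expiry becomes `expired`
  unless a logged device-failure event overlaps its window, in which
  case `device_failed`. Conservation — scheduled = completed + expired
  + device_failed per participant × modality — is asserted on every
  simulated ledger.

RNG: one named substream per participant per purpose (scheduling,
random selection, behavior), derived from the single run seed, so
edits to one behavior parameter do not reshuffle unrelated draws.

## Behavior model defaults

The cohort generator's defaults emulate the observed conditions of a
12-week, 10-participant deployment of this protocol: completion
probabilities 0.86 (SRH), 0.87 (symptom), 0.83 (scale), 0.74 (watch,
participant-attributable); watch device-failure rate 0.13 per prompt
(≈ 8/62); 80% of participants starting at good-or-better SRH; SRH
evolving as an ordinal random walk with 0.03 extra mass toward worse
health; completion delays exponential with mean 6 h truncated at 48 h
(most people answer within hours, so reminders stay the exception).

## Synthetic signals: what they do and do not emulate

The generator renders three regimes at 10 Hz integer counts:

* **gait** — a two-harmonic waveform at the step frequency
  (fundamental + 25% second harmonic on the gravity axis, 50%
  quadrature component on a horizontal axis, ~10 mg noise), giving
  exactly one VM peak per step and closed-form ground truth
  (`steps = cadence × duration / 60`);
* **stationary wear** — gravity with posture changes every 3–8 min
  (rotations of 0.2–0.4 rad toward quadrant diagonals). Rotations
  leave the VM quiet — so these spans remain usable for calibration —
  while moving the per-axis means enough that the non-wear rule always
  sees wear, including in boundary sub-blocks diluted by an adjacent
  non-wear block;
* **non-wear** — fixed orientation, 2 mg noise, below every detection
  threshold.

This gives unambiguous labels and exact recovery, which is the point;
it does **not** emulate real wrist data's variable step morphology,
arm-swing asymmetry, orientation changes during gait, missing samples,
or low-amplitude shuffling gait. Passing the recovery suite therefore
demonstrates that the pipeline's rules are implemented correctly and
are mutually consistent — not that the detector achieves any
particular accuracy on free-living recordings, which requires
validation against annotated hardware data.

## Engagement accounting

The completeness table keeps device failures in the denominator
(end-to-end view); participant-attributable adherence removes them.
Block engagement pools all modalities into one fraction per 28-day
block anchored at each participant's deployment date (the protocol's
"prompted interactions" reads as pooled; per-modality rows are also
emitted). Device-failed prompts leave block denominators — engagement
measures participant behavior. A trailing partial block whose
scheduled prompts span < 7 days is dropped from the criterion. The
study criterion is met when ≥ 6 of 10 participants reach ≥ 50% in
every retained block (thresholds inclusive). Printed-style percentages
round half-up, matching how such tables are reported (e.g.
40/62 → 65), exposed as a formatting option.

SUS: `2.5 × Σ [odd items: v−1; even items: 5−v]` over ten 1–5 items,
no imputation. GA change flags (week 12 vs baseline): G8 decline ≥ 1,
CARG increase ≥ 1, CIRS-G increase ≥ 1, any G8-SRH downgrade, FACT-G
decline > 3; instruments missing a timepoint are recorded unevaluable.

## Packaged fixtures

`COMPLETION_TABLE` transcribes a real deployment's per-participant
scheduled/completed/incomplete counts; `table2_ledger()` synthesizes
timestamps consistent with those counts (instances spread evenly over
the 84-day window, statuses proportionally interleaved so per-block
rates match overall rates). `FULL_DEPLOYMENT_INITIATIONS` is a
synthetic per-participant allocation of the 40 full-deployment watch
initiations across the nine analyzable participants — only the total
is study-reported, and only the total feeds the recoverable-interval
arithmetic (40 × 2 = 80).

## Problem sizes and numerical choices

The test suite and acceptance script run on desk-scale inputs chosen
as the smallest sizes that exercise each rule: 2-min gait bouts for
step recovery, ≤ 6-h records for brute-force non-wear equivalence,
24-h constructed epoch series for Activity Index closed forms, and
10-participant × 84-day cohorts (plus 1,000 seeded schedules for the
gap law) for the prompt engine. Variance computations use the
population convention (ddof = 0) throughout; percentile interpolation
is linear; all clamps (`max(0, ·)`) are applied before square roots so
metrics are defined on degenerate inputs (zero variance, empty
intervals, no stepping minutes).

## Known limitations

* Step detection is tuned to the 10 Hz contract rate; resampling from
  other rates is linear and unvalidated.
* The moving/not-moving rule and peak-detector parameters are
  literature-conventional defaults, not fitted to hardware data.
* The non-wear rule cannot distinguish genuinely motionless wear
  (e.g., sleep with a still arm) from off-wrist time; that is a
  property of the rule family, not of this implementation.
* The behavior model draws completion independently per prompt; it
  does not model within-participant streaks, learning, or attrition.
* Clock handling assumes a fixed local offset (no DST transitions).
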