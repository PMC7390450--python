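# Methods

## Sleep definition and the six parameters

Sleep is called on 1-minute count bins: a sleep bout is a maximal run of
consecutive zero-count bins lasting at least 5 minutes (`MIN_SLEEP_MIN`).
Shorter zero runs are wake. DAM hardware often logs finer than one minute
(commonly every 6 s); the reader sums finer rows into minute bins, so the
minute grid is the canonical resolution and resampling conserves every
count. Gaps in a recording are hard errors, never zero-filled: a fabricated
zero minute is indistinguishable from sleep.

Parameters are computed per analysis window (default day ZT 0–12 and night
ZT 12–24, per recording day). Windowing rules:

- **Clipping.** A bout spanning a window border contributes its clipped
  segment to each side, and each side counts the segment as an episode.
  This conserves total sleep across windows (day + night + waking minutes
  = 1440 exactly) at the cost of counting a boundary bout twice in the two
  windows' episode counts. A clipped segment shorter than 5 min keeps
  sleep status — the parent bout qualified.
- **Latency.** Referenced to nominal lights-off, ZT 720 of the window's
  day, in *every* schedule including constant darkness, so latency remains
  comparable across conditions. When no bout starts at/after lights-off
  within the window (e.g. any day window, or a night with no sleep),
  latency is censored at the window length (720 min) and flagged
  `latency_censored`; censored values keep group means defined but should
  be treated as lower bounds.
- **Activity index.** Counts outside sleep segments divided by waking
  minutes within the window. Undefined (NaN + flag) when the fly slept the
  whole window; NaNs are dropped per-parameter in group statistics.
- **mean sleep** with zero episodes is defined as 0 (frequency 0), keeping
  group means defined for badly sleep-deprived flies.

Dead-fly hygiene: `exclude_dead_flies` flags flies with zero counts over
the final 24 h. It is **off by default** — the analysis makes no silent
exclusions — but the report always lists the flagged flies.

## Protocols

Zeitgeber time maps local clock 08:00 → ZT 0 (lights-on) and 20:00 →
ZT 720 (lights-off); the mapping and its inverse are exact and periodic in
1440 min. Built-in schedules: LD (12:12, no stimuli); DMS (LD photoperiod
plus a 5-s mechanical shake every 30 min over ZT 720–1440 → 24 shakes per
night); DLS (LD plus a 10-min light pulse every 60 min over the night → 12
pulses); DD (never lit, no stimuli). The first DMS/DLS delivery is placed
at ZT 720 exactly; the within-night phase of the trains is a convention,
chosen once, since only event count and spacing matter downstream.
Schedules serialize to YAML so custom protocols need no code.

## Statistics

Both tests are implemented from their definitions (scipy supplies only the
t/F distribution functions; scipy's own test functions serve as independent
cross-checks in the test suite):

- **Student's t** (unpaired, two-tailed, pooled variance),
  df = n₁+n₂−2. Zero pooled variance with equal means returns p = 1 by
  convention; with unequal means it is an error, not a silent infinity.
- **One-way ANOVA + Fisher's LSD vs vehicle.** F = MS_between/MS_within;
  each non-reference arm is compared with the vehicle using the pooled
  MS_within and its df, two-tailed, uncorrected (the LSD convention).
  With two groups LSD reduces algebraically to the pooled t-test; the
  suite asserts equality to 1e-12 relative tolerance.
- **Normalization.** Percent change is computed per fly against the
  vehicle *mean*; the portfolio error bar is the SEM of those per-fly
  values (default), with a delta-method alternative (group SEM divided by
  the vehicle mean) behind `sem_method="delta"`. A zero vehicle mean falls
  back to raw differences, marked in the `units` column.
- **Stars**: ns ≥ 0.05 > \* ≥ 0.01 > \*\* ≥ 0.001 > \*\*\* ≥ 0.0001 > \*\*\*\*.

No multiple-testing correction is applied beyond LSD's design: the screen
is a ranking instrument, and per-comparison error is the convention it
inherits.

## The simulator

Each fly is an alternating-renewal process on a minute grid. Wake and
sleep bout durations are drawn from an exponential (default) or gamma
distribution whose mean depends on the phase — photoperiod light status at
bout onset — then rounded to whole minutes (minimum 1), so ground-truth
bouts tile the timeline and align exactly with analysis bins. Waking
minutes emit Poisson(λ) counts; sleeping minutes emit 0. Each night's
first sleep onset at/after lights-off is delayed by `latency_shift`
minutes. Stimulus onsets falling strictly inside a sleep bout truncate it
with probability `arousal_prob` (light pulses act exactly like shakes at
this level of description; one landing on the onset minute itself does not
prevent falling asleep). Treatments multiply the sleep-bout means, the
waking rate and the latency shift before sampling.

Defaults (chosen once as field-realistic, with no numeric calibration to
any published dataset): λ = 2.5 counts/waking-minute; control female
sleep-bout means 15 min (lit) / 35 min (dark) and wake-bout means
30 / 15 min; latency shift 20 min; arousal probability 0.9. The
`control_male` preset sleeps more at night (dark sleep mean 45 min); `ad_*`
presets model amyloid-beta flies with 0.6× sleep-bout means and a 60-min
latency shift; `drug_*` presets perturb one model parameter each for screen
testing. Under the defaults a control female sleeps roughly 200–250 min by
day and 450–550 min by night, with night latencies of tens of minutes —
the right order for healthy flies.

**What the generator does and does not emulate.** It reproduces the
statistical structure the analysis relies on — consolidated bouts, light-
schedule dependence, stimulus-evoked arousal, latency, sex/genotype/drug
contrasts — and is deterministic per seed (cohort fly seeds are spawned
from one `SeedSequence`). It does **not** claim fidelity to real flies'
bout-duration distributions (unknown; the renewal-with-exponential choice
is a stated stand-in), circadian anticipation, homeostatic rebound after
deprivation, or the jet-lag arousal seen in real constant-darkness
experiments: because bout means key on light status, constant darkness
here *lengthens* day sleep rather than fragmenting it. Screen and recovery
tests compare arms within one schedule, so that limitation does not touch
them; profile-shape claims about DD should not be read off the simulator.

**Censoring.** Ground-truth sleep bouts shorter than 5 min are legitimate
in simulation but invisible to the detector. Every truth-vs-pipeline
comparison therefore applies the ≥5-min censor on the truth side
(`GroundTruth.censored_mean_sleep`), never relaxing the detector. The
residual difference — wake minutes that happen to emit zero counts and
extend a detected bout — is a fraction of a minute per bout at the default
λ and is covered by the 3-SE recovery tolerance.

## Validation study sizes

Chosen to characterise the pipeline tightly while keeping the whole suite
fast: bout-caller oracle agreement on 200 random 1000-bin traces;
conservation checks over 8-fly cohorts under all four protocols; LSD↔t
equality on 100 random fixtures; type-I calibration on 10,000 simulated
null replicates (99% binomial CI around 0.05); mean-sleep recovery on
50-fly cohorts at night bout means 10/30/60 min; screen power over 100
replicates of an 8-arm, 16-fly/arm DD screen whose index arm lengthens
sleep bouts 1.5×. A screen arm is scored as recovered when any of its
total-sleep rows (day or night window) is significant with the correct
sign; the matching null-arm false-positive bound is the 99% binomial CI of
the same two-look event (nominal rate 1−0.95² ≈ 0.0975).

## Numerical and interface conventions

- Windows and bouts are half-open ZT intervals in minutes; ZT accumulates
  across days (minute 1500 = ZT 60 of day 1).
- The DAM writer anchors wall-clock time at 2020-01-01 08:00 = ZT 0 of
  day 0; the reader derives ZT from the clock column, so round-trips are
  exact on counts and light always, and on timestamps within one ZT day.
- Monitor files carry 43 tab-separated columns (index, date, time, status,
  six device fields, light sensor, 32 counts); unknown status codes warn
  but are kept. When finer rows are summed into a bin, the bin's light
  status is the majority of its rows.
- Cohorts larger than 32 flies split across monitor files, never
  truncating.
- `build_portfolio` requires ≥2 flies with finite values per group and
  names the offending group otherwise; the vehicle row is pinned to
  exactly 0% and `ns`.

## Known limitations

- Single-beam DAM data undercounts micro-movements; the 5-min rule is the
  field convention, not a physiological ground truth.
- Latency censoring at 720 min biases group means upward in windows with
  little post-lights-off sleep; the flag column lets users drop censored
  values if they prefer.
- The simulator's renewal assumption makes bout durations memoryless;
  real fly sleep shows heavier-tailed night bouts.
- No arousal-threshold/sleep-depth staging, no pharmacokinetics, no
  dose-response modelling: one concentration per arm, as in typical
  first-pass screens.
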