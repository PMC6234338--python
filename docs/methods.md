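# Methods

`cogbattery` re-implements, as a headless and scriptable engine, the
measurement machinery of a gamified cognitive test battery delivered
through a mobile app: five short game-format tasks, a reduced
Morningness-Eveningness questionnaire (rMEQ), a synthetic cohort simulator,
and the cohort-analysis pipeline used to study demographic and engagement
effects on performance. This note documents the models, the parameters
that matter, the numerical choices, and what the synthetic data can and
cannot show.

## Task engines

Each engine is a pure function of a *responder* (a callback object
supplying the behavior) and a seeded `numpy.random.Generator`, so any run
replays bit-identically from its seed. Scores never depend on wall-clock
time; all timelines are simulated.

### React — four-choice vigilance

Eight trials. After a uniform 2–7 s foreperiod one of four buttons becomes
the target; a correct tap within the 600 ms response window scores

    S(l) = S_trial                          l <= 100 ms
    S(l) = S_trial * (1 - (l - 100)/500)    100 < l <= 600 ms

and premature taps, wrong buttons and timeouts score 0. The published
rules fix the window, the grace period and the zero cases but not the
point scale; we set `S_trial = 62.5` (session maximum 500) so that
plausible cohort mean session scores around 400 are representable. The
decay is linear — the simplest curve consistent with "points decrease with
elapsed milliseconds". A trial that times out is scored 0 rather than
re-presented.

### Super Snap — 2-back

Shapes are drawn i.i.d. uniformly from six symbols (the stream
distribution is unstated in the source task; i.i.d. uniform is the
simplest defensible null and yields a ~1/6 match density). The session
starts at 60 points, loses 6 per miss or false alarm (floored at 0), and
ends when 10 matches have been presented or 10 responses made, whichever
is first. The 1.5 s exposure / 1.5 s inter-stimulus timeline is carried in
trial metadata for latency-aware responders; the responder decision itself
is abstracted to tap / no-tap per item.

### Spin — mental rotation

The stimulus set is 18 patterns of filled cells in a 3×3 grid, each with
1–3 four-connected groups and no rotational symmetry. The original
published set is not reproduced anywhere accessible, so the package ships
a canonical stand-in: a deterministic enumeration of all 3×3 grids in
ascending 9-bit code order, keeping the first 18 with 2–6 filled cells
(avoiding trivial and near-full grids), 1–3 groups, no rotational
symmetry, no rotation-equivalence to an earlier selection, and — one
constraint beyond the stated ones — no reflection equal to any rotation,
which guarantees a reflection foil can never coincide with the rotated
target. A trial rotates the target by 90/180/270° (clockwise) and offers
the rotated target plus its vertical and horizontal reflections in
shuffled order. A session shuffles all 18 patterns without replacement and
ends at 45 s or set exhaustion; a response counts if it completes within
the limit. Reported score is 2.5 points per correct judgment (the in-app
scale is unstated; the cohort means reported for this game exceed 18, so
score cannot equal the correct count; 2.5 aligns the maximum with the
tracking game at 45) and `n_correct` is always reported alongside.

### Track — multiple object tracking

Six trials at set sizes 8, 8, 9, 9, 11, 11 (increasing order). Balls of
radius 0.035 live in the unit square; 3 are targets. After a 3 s static
preview the array moves for 5 s at a 60 Hz tick: each frame the speed is
multiplied by a uniform factor in [0.9, 1.1] (clamped to [0.1, 0.4]
arena/s) and the heading perturbed by ±10°; these jitter bounds are our
choice, the source stating only that speed and direction change randomly
each frame. Ball–wall and ball–ball collisions are resolved by reflection
plus positional correction, iterated until the non-overlap and in-bounds
invariants hold exactly — so no ball ever overlaps another or leaves the
arena, verified after every step in the test sweep. After the motion phase
the responder taps up to 3 balls; each correctly tapped target scores 2.5
(maximum 45), non-responses counting as incorrect.

### Hotspot — action acquisition

Five attempts per session. Each attempt hides a circular target of exactly
5% arena area (radius √(0.05/π), analytic) placed uniformly over the
feasible region. The responder supplies a ball trajectory sampled at
60 Hz over the attempt limit. Success requires 500 ms of in-target time
within a sliding 1 s window; the published phrase is ambiguous between
cumulative and consecutive dwell, and we implement **cumulative** within
the window. The feedback signal (the in-game color change) is the
in-target indicator delayed by 100 ms, represented as a state trace.
Scoring: half the attempt maximum for discovery (any target entry), the
other half decaying linearly with the success time from attempt onset to
zero at the limit. The attempt maximum (10) and time limit (15 s) are not
published; both are configurable.

### Sessions

A session presents a chosen subset of the five games in an order shuffled
from the session RNG; the responder may skip any game. The mood item (a
visual-analog slider mapped affinely to 1–10) is asked every session;
wake-time and sleep-duration items only on the first session of a calendar
day. All of these may be absent (declined), and records preserve that.

## rMEQ scoring

The five-item reduced scale sums to 4–25 and partitions into five
chronotype classes: definitely evening 4–7, moderately evening 8–11,
neither 12–17, moderately morning 18–21, definitely morning 22–25. The
item wording and per-item admissible scores (1–5, 1–4, 1–5, 1–5,
{0, 2, 4, 6}) follow the standard reduced scale and live in a packaged
JSON config so an alternative key can be swapped without code changes; all
downstream analysis depends only on the total and the class.

## Synthetic cohort

The simulator produces ground-truth-known datasets shaped like a
self-selected mobile-app cohort. Per participant:

- **Age**: 18 + Gamma(2.2, 8) rounded, plus a 5% spike at the 18-year
  floor (the lowest selectable age in such an app); ~7.4% decline to
  report age, ~1.7% gender; 40% of reporters are male.
- **Chronotype**: the rMEQ total is built from a latent that is linear in
  standardized age with slope 0.298 (the age–morningness correlation the
  battery is designed to exhibit), then discretized to 4–25 around mean
  13.2, SD 4.
- **Engagement and attrition**: session counts follow a zero-truncated
  gamma-mixed Poisson (mean 5.0, dispersion 1.5, log-scale spread 0.6,
  capped at 60) whose expectation rises with a latent engagement score
  correlated 0.32 with age. These values were fixed once so the default
  configuration reproduces an observed-scale age–plays correlation of
  ~0.2 and a steep qualitative attrition funnel (~30% single-session
  users, ~1% reaching 30 sessions); the funnel is a qualitative
  emulation, not a fit.
- **Ability and practice**: per-game standardized latent abilities, with
  expected skill following the saturating learning curve
  `asymptote − depth·exp(−rate·(play−1))`, depth 0.8 SD, rate 0.35 for
  all games except the vigilance game, whose rate is 0 (too simple to
  show practice). Gender effects are additive skill shifts of ±d/2 with
  defaults d = 0.45 (rotation), 0.30 (action acquisition), 0.12
  (vigilance), 0.10 (tracking), 0 (2-back); age effects are linear per
  decade beyond 35 (−0.30 vigilance, −0.27 rotation, −0.25 2-back, −0.09
  tracking, 0 action acquisition). Per-session noise SD 0.3.
- **Response models** mapping skill to behavior are deliberately minimal
  parametric forms: shifted-lognormal latencies (vigilance, rotation),
  logistic hit and false-alarm probabilities (2-back), a binomial
  tracking capacity over the 3 targets with a small set-size penalty
  (tracking), and an exponential search time followed by settled dwell
  (action acquisition). They are the minimum structure needed for the
  analyses to have recoverable signal, not cognitive models.
- **Mood** follows an AR(1) around a personal baseline, uncoupled from
  performance by default (matching the null association the analysis
  protocol is designed to detect); a coupling parameter exists for
  recovery tests. A time-of-day performance hook exists but defaults off.

Randomness is threaded from a single master seed via
`numpy.random.SeedSequence` spawns, so `simulate_dataset` is
bit-reproducible.

**What passing tests on synthetic data do not show**: the simulator makes
no claim to reproduce the real cohort's score distributions, its
device/platform effects, selection mechanisms behind engagement, or any
time-of-day structure. Recovery results demonstrate that the pipeline
estimates what the generator encodes — not that the generator matches
human data.

## Analysis pipeline

Per participant and game: number of plays, mean score over all plays, and
the mean of plays 4–6 only (the practice-controlled "early snapshot",
defined only when at least 6 plays exist). The protocol then applies:

- **Adherence filter**: at least 4 plays of the game (removing
  participants who only ever "practiced").
- **Outlier exclusion**: the most extreme 1% of mean scores. "Most
  extreme" is ambiguous; the default is a symmetric two-tail trim (0.5%
  per tail, counts rounded, ties broken by participant id for
  determinism), with an absolute-deviation-from-median variant available.
  Participants missing the demographic needed by an analysis are excluded
  before trimming.
- **Gender ANCOVA**: mean score ~ gender + plays-beyond-4, Type-II sums
  of squares, no interaction; partial η² = SS_effect/(SS_effect +
  SS_residual); the covariate is coded as plays beyond the cutoff
  (raw plays available by option). The covariate's F and partial η² are
  reported alongside.
- **Plays t test**: pooled two-sample t on play counts by gender
  (df = n₁+n₂−2), confirming the covariate is not confounded with gender.
- **Age-stratified ANOVA**: one-way ANOVA of the early snapshot across
  seven decade bins (<20, 20–29, …, 60–69, ≥70; age 70 falls in the top
  bin), η² = SS_between/SS_total. Empty bins are dropped with df adjusted.
- **Correlations**: Pearson r with t-based p (age–plays, age–chronotype,
  group-level mood–performance); per-participant Spearman ρ across
  sessions for the individual-level mood analysis, averaging over
  participants and counting those skipped for zero variance.
- **Practice curves**: group mean score at each play index with the
  non-increasing count of participants remaining.

Degrees of freedom follow standard conventions — (1, n−3) for the
two-term ANCOVA, (k−1, n−k) for the one-way ANOVA; because some published
reports print (k−1, n−1), results also carry that echo in `df_print`.
No multiple-testing correction is applied across games (matching the
protocol); a Holm adjustment can be applied downstream if desired.

## Numerical choices and degenerate inputs

- Linear-model results are validated against explicit normal-equations
  oracles on small fixtures to 1e-8 relative tolerance; one-way SS
  decompositions satisfy SS_between + SS_within = SS_total to the same
  tolerance.
- Degenerate t-test inputs (both groups zero-variance) return t = 0,
  p = 1 when means agree and ±∞, p = 0 otherwise.
- Zero-variance inputs to correlations are rejected, not coerced.
- The physics step resolves collisions iteratively (up to 100 sweeps)
  until the exact invariants hold; with the default tick (1/60 s) and
  speed cap, one or two sweeps suffice in practice.
- Outlier trimming on an already-trimmed set would remove more; for
  idempotent re-application, flags from `flag_outliers` on the original
  set should be reused.

## Problem sizes used by the test suite

The statistical acceptance checks run at sizes chosen to keep the full
suite to a few minutes on one CPU while preserving each claim: type-I
calibration of the gender ANCOVA uses 200 simulated null cohorts of 150
participants (vigilance game only — the cheapest engine — rejection rate
within ±2% of the 5% level); sign recovery uses 15 cohorts of 600
participants of the rotation game at d = 0.4; the η̂²-monotone-in-d check
uses cohorts of 800 at d ∈ {0, 0.2, 0.4}; the physics sweep runs 10⁴
steps at set size 11 for 20 seeds; the practice-curve check uses 500
simulated participants per play index, comparing the play-10 group mean
to the simulated asymptote within 2%.

## Known limitations

- The shipped 18-pattern set is a constraint-faithful stand-in, not the
  original published stimuli; difficulty-level splits of the original set
  are not modeled.
- Score scales not printed in the published rules (React trial maximum,
  Spin points per correct, Hotspot maximum and time limit) are package
  defaults; absolute score values are therefore comparable only within
  this implementation.
- The dwell criterion is cumulative-within-window by choice; a
  consecutive-dwell variant would lower Hotspot scores slightly.
- Responder models are not cognitive models; latency distributions,
  capacity limits and learning rates are plausible but uncalibrated.
- Time-of-day and chronotype-by-performance analyses are deliberately out
  of scope; the simulator only reserves hooks for them.
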