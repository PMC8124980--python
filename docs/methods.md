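# Methods

## Game engine

The engine is a deterministic discrete-time state machine sampled at
1 Hz. At each tick the attention meter value `a ∈ {0, …, 100}` is
classified attentive iff `a ≥ threshold` (default 50). The meter value
exactly at the threshold counts as attentive; the meter therefore
splits into an attentive upper half of 51 values and an inattentive
lower half of 50. Within level ℓ the level score evolves as

    s_t = max(0, s_{t−1} + gain_ℓ)      if attentive,
    s_t = max(0, s_{t−1} − penalty_ℓ)   otherwise,

and the level is cleared at the first tick with `s_t ≥ target_ℓ`; the
score then resets to 0 for the next level (surplus points are
discarded). Clearing the last level finishes the session; reaching the
session cap (default 300 s) first ends it as a timeout. There is no
demotion: the level index never decreases, and the floor at zero means
a player can stall but not regress. Ticks are integral seconds; no
sub-second interpolation is attempted.

The default level targets (90, 144, 196, 240, 700) are fixed by the
gain schedule and the intended perfect-play times: `target = gain × t*`
with `t* = 5, 9, 14, 20, 70 s`, so `perfect_play_times` — the smallest
`t` with `t × gain ≥ target` per level — returns those times exactly
and a constant-100 session completes in 118 s.

`run_session` is implemented vectorised per level: with floor-at-zero
dynamics the score follows a Lindley recursion, so
`s_t = S_t − min(0, min_{k≤t} S_k)` where `S` is the cumulative sum of
per-tick deltas, and the clearing tick is the first crossing of the
target. The scalar `step` function defines the reference semantics and
the test suite asserts tick-for-tick equivalence of the two paths on
random streams.

Edge cases chosen where the behaviour was open: a stream that runs out
before the session finishes and before the cap ends the session with a
`timeout` event (the session is uncompleted); a non-final level-up
landing exactly on the cap is likewise recorded as `timeout`.
Meditation values are carried through logs untouched and never
influence the engine.

## Synthetic attention streams

Real meters come from a proprietary algorithm whose temporal statistics
in children are not published; the simulator therefore uses the
simplest process with tunable mean, spread and persistence: a latent
stationary Gaussian AR(1),

    x_t = μ + φ (x_{t−1} − μ) + ε_t,   ε_t ~ N(0, σ²(1−φ²)),

started from its stationary law, clipped to [0, 100] and then rounded
to integers. μ and σ are the latent (pre-clip) stationary moments in
meter units; clipping biases realised moments when μ sits near a bound
(at the defaults the bias is negligible, and the test suite checks
realised mean and lag-1 autocorrelation on long streams). Clipping is
applied before rounding.

Default profiles: control-like μ = 60, σ = 12; ADHD-like μ = 48,
σ = 18; φ = 0.7 for both. These encode the qualitative group contrast
(lower and more variable attention in the ADHD-like group) at a
persistence that makes second-to-second meter values strongly but not
perfectly correlated. Under these defaults essentially all control-like
subjects complete the game within 300 s while almost no ADHD-like
subjects do, so the completion split mostly coincides with the group
split; the profiles are ordinary configuration and can be moved to
produce partial completion within either group.

What the simulator does *not* model: the EEG itself, power bands, the
proprietary meter algorithm, artefacts (blinks, electrode pops),
learning or fatigue within a session, and between-subject heterogeneity
within a group (all subjects of a group share one profile). Passing
direction/power tests on these cohorts therefore shows that the
pipeline detects the programmed contrast under idealised stationary
noise — not that real cohorts would separate with the same power.

Per-subject seeds are drawn from the cohort seed and recorded in the
cohort manifest, so any single session is regenerable from the manifest
alone.

## CARAS-R indices

From correct answers `A` and errors `E`: effectiveness `AE = A − E`
and the impulsivity-control index `ICI = (A − E)/(A + E) × 100` (in
percent, undefined at `A + E = 0`). ICI is scale-invariant and
strictly monotone (increasing in `A`, decreasing in `E`). Binary
classification — effective iff `AE ≥ cutoff_AE`, impulsive iff
`ICI < cutoff_ICI` — requires caller-supplied raw-score cutoffs
because the age-normed enneatype tables that define the published
groupings are proprietary and are not reproduced. ICI is written to
one decimal place in output files; full precision is kept in memory.

## Screening statistics

Per-level comparisons use the pooled-variance (Student) two-sample
t-test with `df = n₁ + n₂ − 2` and two-sided p-values; the pooled form
is the one whose df arithmetic matches group sizes such as 52 + 23 → 73
and 38 + 14 → 50. Subjects whose session never entered a level are
excluded from that level's comparison (df shrinks accordingly); a level
where either group has fewer than two contributing subjects is reported
as not testable rather than raising. Zero pooled variance with equal
means yields t = 0, p = 1; with unequal means it is rejected as
degenerate input.

The Bonferroni family is the set of per-level tests within one grouping
(m = 5 under the default five-level game, also when some levels are not
testable); separate groupings are separate families. Decisions use
`p ≤ α/m`. p-values are printed to three decimals in text output and
kept at full precision in machine output.

On the "more variable" direction of the group contrast: the per-level
variability measure used in the end-to-end checks is the variance of
the recorded attention *samples* within a level (pooled within group),
which reflects the generative σ directly. The across-subject variance
of per-subject level means is deliberately not used as the direction
check: it scales inversely with the time a subject spends in the level,
and since slower groups spend longer per level it can reverse direction
at intermediate levels even when the generative variability is strictly
larger — an averaging artefact, not a contrast in attentional
variability.

## Problem sizes in the test suite

The end-to-end distributional checks use 200 independent default
cohorts (52 + 23 subjects) for the direction/power and
attention-vs-time properties, and 1000 replicate cohorts with identical
profiles in both groups for type-I calibration, judged within three
Monte-Carlo standard errors of α = 0.05. Engine invariants are checked
over randomized sessions totalling more than 10⁴ ticks. These sizes
give Monte-Carlo standard errors well below the margins being asserted
(e.g. ±0.007 on a rejection rate at 1000 replicates).

## Known limitations

- The attentive/inattentive boundary at exactly 50 is a design choice;
  original implementations of such games may break the tie either way.
- The simulator's stationarity assumption excludes drift, fatigue and
  neurofeedback learning effects, all plausible in real sessions.
- Classification cutoffs for effectiveness/impulsivity are study
  configuration; no norms are bundled, so absolute prevalence numbers
  from `contingency_summary` are only as meaningful as the cutoffs
  supplied.
- The pooled t-test assumes equal group variances; under the default
  profiles the groups differ in variance by construction, which the
  pooled form absorbs into a conservative-to-liberal error within the
  calibration band checked by the null simulation.
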