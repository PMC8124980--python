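# attnscreen

Tools for screening attentional traits with a threshold-based
neurofeedback game driven by a 1 Hz consumer-EEG attention meter.

Single-electrode BCI headsets (a dry electrode at Fp1) emit a scalar
*attention meter* — an integer in 0–100, once per second. A simple
neurofeedback game turns this meter into a behavioural read-out: each
second the player is *attentive* when the meter is at or above a
threshold (default 50) and earns points on the current level, or loses
points otherwise. Clearing five increasingly demanding levels within a
five-minute session requires sustained attention, so completion, speed
and per-level mean attention separate children with attention
difficulties from controls. `attnscreen` is aimed at researchers who
want to prototype or power such screening studies: it provides

- **a deterministic game engine** (`attnscreen.engine`): the 1 Hz
  state machine, session logs, and perfect-play arithmetic;
- **a synthetic cohort simulator** (`attnscreen.cohort`): bounded AR(1)
  attention streams with control-like and ADHD-like profiles;
- **CARAS-R indices** (`attnscreen.caras`): effectiveness
  `AE = A − E` and the impulsivity-control index
  `ICI = (A − E)/(A + E) × 100 %`;
- **screening statistics** (`attnscreen.screening`): per-level
  pooled-variance two-sample *t*-tests with Bonferroni control,
  completion splits and contingency summaries;
- **file formats and a CLI** (`attnscreen.io`, `attnscreen.cli`).

## The model

Level *ℓ* awards `gain_ℓ` points per attentive second and removes
`penalty_ℓ` per inattentive second (score floored at 0); the level is
cleared when the score reaches `target_ℓ`. The default schedule is

| level | 0 | 1 | 2 | 3 | 4 |
|---|---|---|---|---|---|
| gain (pts/s) | +18 | +16 | +14 | +12 | +10 |
| penalty (pts/s) | −2 | −3 | −4 | −5 | −6 |
| target (pts) | 90 | 144 | 196 | 240 | 700 |

so a constantly-attentive player clears the levels in 5, 9, 14, 20 and
70 s — 118 s in total, under two minutes — while the 300 s cap leaves
ample slack for imperfect play.

Synthetic meters are a latent stationary Gaussian AR(1),
`x_t = μ + φ(x_{t−1} − μ) + ε_t`, clipped to [0, 100] and rounded;
default profiles are control-like (μ = 60, σ = 12) and ADHD-like
(μ = 48, σ = 18) with φ = 0.7. Group screening tests each level with
the pooled two-sample *t* statistic (df = n₁ + n₂ − 2, two-sided) and
rejects at the Bonferroni-corrected threshold α/5.

## Worked example

```sh
$ attnscreen perfect-play
level   seconds
0       5
1       9
2       14
3       20
4       70
total   118

$ attnscreen simulate-cohort --n-control 52 --n-adhd 23 --seed 1 --out cohort
wrote 75 sessions to cohort (53 completed); manifest: cohort/manifest.csv

$ attnscreen analyze --cohort cohort --out report.csv
control_vs_adhd level 0: t(73) = 6.40, p = 0.000 *
control_vs_adhd level 1: t(73) = 4.83, p = 0.000 *
control_vs_adhd level 2: t(73) = 6.05, p = 0.000 *
control_vs_adhd level 3: t(73) = 8.90, p = 0.000 *
control_vs_adhd level 4: t(73) = 16.31, p = 0.000 *
...
```

`perfect-play` prints the minimal seconds per level for a player whose
meter never drops below the threshold. `simulate-cohort` writes one
session CSV per subject plus a manifest from which every session can be
regenerated (per-subject seeds are recorded). `analyze` compares the
two groups' per-level mean attention: with 52 + 23 subjects each test
has 73 degrees of freedom, and under the default (well-separated)
profiles every level is significant after Bonferroni correction — the
`*`. The report CSV holds group sizes, means, *t*, df, *p* and both raw
and corrected decisions per level.

CARAS-R tables are scored with explicit raw-score cutoffs (published
norm tables are not shipped):

```sh
attnscreen caras --input ae.csv --out scored.csv \
    --effectiveness-cutoff 20 --impulsivity-cutoff 40
```

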