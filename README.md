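# sitpose

Outcome measures and statistics for robot-assisted **seated posture
training** studies, with a seeded synthetic-cohort simulator.

The package targets a three-arm randomized design in which healthy adults
train multidirectional seated reaching with a trunk-support robot, either
in physical reality (PR) or with an augmented-reality (AR) or
virtual-reality (VR) headset. It implements the complete measurement and
analysis chain such a study needs:

- **Functional reach test score (FRTS)** — for each of the eight principal
  reach directions (F, FD, D, BD, B, BND, ND, FND at 45° increments), the
  distance between the start and the farthest fingertip position,
  `FRTS = max_t ‖p(t) − p(0)‖`.
- **Sitting workspace area** — the polygon connecting the eight farthest
  trunk center-of-mass points, ordered by angle about their centroid;
  its shoelace area summarizes dynamic sitting balance.
- **Center-of-pressure (COP) posturography** — total excursion
  `Σ‖Δp_k‖` (m), mean velocity (cm/s), and approximate entropy
  `ApEn(m, r) = Φ_m(r) − Φ_{m+1}(r)` with self-matches (Pincus), default
  `m = 2`, `r = 0.2·SD`, on the centered resultant displacement.
- **High-intense-activity rate** —
  `HIAR = (time outside the baseline reaching hull) / (total training time)`,
  where the baseline hull is the convex polygon encompassing all baseline
  fingertip samples.
- **Reach task score** — cumulative target level (basic/medium/hard = 1/2/3)
  over 96 training bouts (12 rounds × 8 directions); targets sit at 100 %,
  110 % and 120 % of baseline FRTS.
- **Questionnaire scoring** — SSQ (16 items, pre/post), ITQ, PQ, GEQ, UEQ on
  a 7-point Likert scale, normalized as `Σ items / (7 · n_items)`, plus a
  0–1 immersion score locating each system on the reality–virtuality
  continuum (PR ≡ 0).
- **Statistics** — split-plot (mixed between-within) ANOVA for measures
  observed at both test times, one-way between-groups ANOVA for one-shot
  measures, Shapiro–Wilk and Levene assumption checks, and Bonferroni
  post-hoc contrasts gated on omnibus significance, with partial η² per
  effect.

Raw series are validated and zero-phase filtered (4th-order Butterworth;
10 Hz for 100 Hz kinematics, 6 Hz for the 56 Hz pressure-mat COP) before
any metric is computed.

Because no recordings ship with the package, a first-class synthetic
generator (`sitpose.synthetic`) produces seeded cohorts with the full study
structure — minimum-jerk reaches with programmed pre→post gains, an
Ornstein–Uhlenbeck sway model with a regularity knob, saturating per-round
learning curves, and latent-trait Likert responses — so every stage of the
pipeline is testable end to end.

## Worked example

```python
from sitpose import CohortConfig, Study, StudyConfig, MixedAnova

config = StudyConfig(cohort=CohortConfig(n_per_group=8, seed=7))
report = Study(config).run()
print(report.summary())
```

prints (excerpt):

```
Study report (schema v1), seed=7, n={'AR': 8, 'PR': 8, 'VR': 8}

frts_mean:
  AR: T0 0.296+/-0.009  T1 0.384+/-0.020  p_within=3.328e-06
  PR: T0 0.307+/-0.009  T1 0.340+/-0.011  p_within=0.0001132
  VR: T0 0.303+/-0.017  T1 0.415+/-0.033  p_within=4.282e-06

mean_velocity:
  AR: T0 4.678+/-0.144  T1 4.719+/-0.079  p_within=0.5228
  PR: T0 4.719+/-0.217  T1 7.277+/-0.117  p_within=4.663e-09
  VR: T0 4.714+/-0.150  T1 4.771+/-0.102  p_within=0.3605

hiar:
  AR: 0.325+/-0.004
  PR: 0.192+/-0.009
  VR: 0.326+/-0.003
```

Each block is a Table-1-style grid: mean ± SD per arm at baseline (T0) and
post-training (T1) with the within-arm paired p value. With the default
generator settings the programmed effect pattern is visible directly: all
arms improve their reach, the XR arms improve more; only the PR arm speeds
up its COP; the XR arms spend ~70 % more of their training time beyond the
baseline reach limits (HIAR).

The statistics layer follows the statsmodels idiom — a model object built
from a long-format DataFrame whose `fit()` returns a results object:

```python
res = MixedAnova.from_metric_table(report.metric_table, "workspace_area").fit()
print(res.summary())
```

```
MixedAnova: dv='value'
effect               df         F         p  partial eta^2
group            2,  21    11.068    0.0005          0.513
time             1,  21   284.766    0.0000          0.931
interaction      2,  21    29.274    0.0000          0.736
Levene W=7.176, p=0.0042
```

`res.posthoc()` returns the Bonferroni pairwise contrasts of the
pre→post change (here: AR > PR and VR > PR highly significant), and
`report.save(out_dir)` writes `report.json` plus all intermediate CSV
tables. Identical config and seed give byte-identical reports.

A thin CLI wraps the same pipeline:

```bash
sitpose simulate --config study.yaml --out cohort/ --seed 1
sitpose analyze --in cohort/ --out results/
sitpose report --config study.yaml --seed 1 --out results/ --figures
```

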