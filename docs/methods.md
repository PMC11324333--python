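# Methods

This note documents the models, parameter choices and numerical conventions
behind `sitpose`: what the synthetic cohort generator simulates, how each
outcome measure is defined, how the statistics layer decomposes variance,
and what the test suite does and does not establish about real recordings.

## Study design being modeled

A three-arm randomized experiment on seated postural control. Subjects sit
without foot support; a trunk-support robot applies assistive forces when
they move beyond their stability limits. Before and after training, each
subject performs an eight-direction maximal seated reach test (directions
F, FD, D, BD, B, BND, ND, FND at 45° increments; F = forward, D = dominant
side). Training consists of 12 rounds × 8 bouts of reaching toward targets
at three difficulty levels, with the direction sequence shuffled per round.
Kinematics are sampled at 100 Hz, the seat-mat center of pressure (COP) at
56 Hz. Self-report instruments (7-point Likert): SSQ pre/post (16 items),
ITQ pre, and PQ/GEQ/UEQ post; PQ is only administered in the two
headset arms.

Coordinate frame: origin at the neutral seated trunk position, x toward
the dominant side, y forward, units meters. All eight direction vectors are
ideal 45°-grid unit vectors from this frame; targets are placed along them.

## Preprocessing

- Validation rejects non-monotone timestamps and non-finite samples;
  drop-outs spanning ≤ 0.1 s (≈ 10 samples at 100 Hz) are linearly
  interpolated, longer gaps are an error naming the interval.
- Low-pass filtering is a 4th-order Butterworth applied forward and
  backward (`scipy.signal.sosfiltfilt`) per coordinate axis: 10 Hz for
  kinematics, 6 Hz for COP. Zero-phase filtering was chosen because phase
  lag would bias the timing of farthest-reach samples; the cost is that the
  magnitude response is squared, so the nominal cutoff is attenuated to
  0.5 amplitude (−6 dB) rather than −3 dB. Whole-phase series are filtered
  before segmentation into per-trial analyses.

## Outcome measures

**FRTS.** Maximum Euclidean distance of the fingertip from its start
sample; ties broken by the earliest sample. An along-direction projection
variant is available (`frts_mode="projection"`) but the Euclidean reading
of "distance between start and farthest position" is the default. The
default is planar; 3-D columns are accepted.

**Targets and task score.** Basic targets sit at the baseline FRTS along
the ideal direction vector, medium at 110 %, hard at 120 %. A bout's level
is the highest target whose along-direction distance the bout's reach
amplitude covers, or 0 for a miss (the generator can undershoot; real
protocols may not record misses, so level 0 is allowed but not required).
The task score is the plain sum over the 96 bouts, range 0–288.

**Workspace area.** The eight farthest trunk-COM points (one per
direction, same tie-break as FRTS) ordered counterclockwise by angle about
their centroid form the sitting workspace polygon — the points are
connected directly, which can give a non-convex star polygon; area by the
shoelace rule (via shapely). Per-round workspaces reuse the same
construction on each round's eight bouts, using the COM trajectories
(a belt-center switch would be a one-line change in `AnalysisOptions`).

**HIAR.** The baseline reaching workspace is the convex hull of all
baseline-test fingertip samples ("a polygon that encompasses all trajectory
points" read as the minimal convex one; alpha shapes would need an extra
parameter). Each training sample is classified against this hull; a sample
contributes its preceding inter-sample interval to the numerator when
strictly outside. Points within 1e-9 m of the boundary count as inside. No
sub-sample crossing interpolation is performed — at 100 Hz the attribution
bias is below 10 ms per crossing. Bouts are accumulated as sums of
numerators and denominators, so concatenation artifacts between bouts never
enter the time accounting.

**COP measures.** Total excursion is the summed Euclidean step length (m);
mean velocity is excursion over duration, reported in cm/s. Approximate
entropy follows Pincus with self-matches included:
`ApEn = Φ_m(r) − Φ_{m+1}(r)`, `Φ_m(r) = (N−m+1)⁻¹ Σ ln C_i^m(r)` with
Chebyshev template distance. Defaults m = 2, r = 0.2 × SD of the input
series. The input series is the centered resultant displacement
√(x̃² + ỹ²) — a single scalar series consistent with the conventional 0–2
reporting range; a per-axis-mean mode is provided for sensitivity analysis.
Reported values are clipped to [0, 2] with a warning; the raw statistic is
available (`clip=False`) and genuinely exceeds 2 when template matches are
sparse (small absolute r on broadband signals). For the same reason ApEn is
not monotone in r: it rises while matches are sparse, peaks (~0.4 SD on
white noise), and only then decreases as coarser tolerance admits more
matches.

**Questionnaires.** Uniform Likert normalization: sum of items over
7 × n_items. With 1–7 anchoring the attainable floor is 1/7, not 0 — a
deliberate consequence of conventional anchoring. No weighted SSQ subscales
are computed; the uniform normalization is used for all instruments.
The immersion score is an externally supplied raw/max checklist ratio,
normalized to [0, 1]; the PR arm is 0 by definition.

## Statistics

Measures observed at both test times (FRTS, workspace area, COP variables,
SSQ) are analyzed with a split-plot ANOVA: the between-subjects stratum
splits into group SS and subjects-within-groups SS (the error for the group
test); the within-subjects stratum into time, group × time, and the
within error. With only two within-levels, sphericity holds trivially and
no Greenhouse–Geisser correction is needed. Partial η² is
SS_effect/(SS_effect + SS_error) with each effect's own error term. One-shot
measures (HIAR, task score, ITQ/PQ/GEQ/UEQ) use one-way between-groups
ANOVA, where partial η² reduces to η² = SS_between/SS_total.

Assumption checks: Shapiro–Wilk (3 ≤ n ≤ 5000, with Q-Q coordinates for
plotting) and Levene's test (center = mean by default; median gives
Brown–Forsythe). Degenerate inputs (constant samples, zero within-group
deviation variance) raise explicit errors rather than returning NaN.

Post-hoc contrasts run only when the omnibus effect is significant at
α = 0.05. For the mixed design the follow-up compares the per-subject
pre→post change between groups; contrasts use the pooled one-way error
term and Bonferroni adjustment over the k = 3 group pairs (k is a choice;
the package exposes the raw p values alongside). The eight per-direction
FRTS ANOVAs are reported both uncorrected and Bonferroni-corrected over the
8-direction family, since correction across directions is a judgment call.

Small negative sums of squares arising from floating-point subtraction are
clamped to zero; a zero error variance yields F = 0 for a null effect and
F = ∞ otherwise, rather than NaN.

## Synthetic cohort generator

The generator's defaults encode the design: 3 groups × 21 subjects, 8
directions, 12 × 8 training bouts, 100 Hz trials of 3 s, 56 Hz COP. No raw
trajectory statistics are published for this kind of study, so magnitudes
(baseline reach 0.30 ± 0.04 m, positional noise SD 3 mm, sway diffusion
~0.03 m/√s) are illustrative choices at physiologically plausible scales,
fixed once; the *programmed contrasts* between arms and times are what the
pipeline is expected to recover.

- **Reach kinematics**: minimum-jerk out-and-back profile
  (10τ³ − 15τ⁴ + 6τ⁵ up, mirrored down) along the direction unit vector,
  peak displacement = amplitude, plus i.i.d. Gaussian positional noise.
  Chosen as the standard smooth point-to-point model with no free shape
  parameters. The trunk COM is a scaled copy of fingertip displacement
  (coupling 0.35) measured from the trial's first sample — a stand-in for
  marker-based COM estimation, which is out of scope.
- **Pre→post gains**: post-test amplitudes are baseline × group gain
  (defaults 1.1 PR, 1.3 AR/VR) × a per-subject lognormal factor (CV 5 %).
- **Training rounds**: amplitudes follow a saturating exponential from
  baseline toward a per-group plateau (defaults: plateau = group gain,
  rate 0.35 PR / 0.55 XR per round), with 6 % per-bout lognormal jitter.
  Bout target levels derive deterministically from amplitude vs target
  distance.
- **Sway**: planar Ornstein–Uhlenbeck process (exact AR(1) discretization)
  mixed with a deterministic two-frequency oscillation:
  `(1−w)·OU + w·osc`. Diffusion sets path length, the mixing weight w sets
  regularity (higher w → lower ApEn), mean reversion both confines the sway
  and raises ApEn. Default cells: pre (all arms) a = 1/s, σ = 0.030,
  w = 0.68, 20 s; PR post σ = 0.045, w = 0.62, 20 s (faster, slightly less
  regular); XR post a = 2, σ = 0.022, w = 0.50, 36 s (same velocity, less
  regular, longer epochs → larger excursion). Per-round recordings (10 s)
  interpolate pre→post parameters along the learning curve.
- **Questionnaires**: per-subject latent traits on [0, 1] (group/phase
  means as configured, SD 0.05) map to item responses via a discretized
  truncated normal centered at 1 + 6·latent (item SD 0.6). Default latents
  raise post-training SSQ only in VR and give the XR arms higher GEQ/UEQ.
- **Determinism**: every subject draws from an independent child stream of
  the config seed (`SeedSequence.spawn`), so cohorts are reproducible and
  insensitive to generation order; serialized cohorts round-trip exactly
  (17-significant-digit CSV floats parsed with round-trip precision).

What the generator does **not** emulate: assistive-force dynamics and
cable tensions, marker occlusion/relabeling, anthropometric COM estimation,
non-stationary fatigue effects, item-level questionnaire structure
(subscales, reverse-coded items), or any coupling between reach kinematics
and sway beyond the programmed group/time cells. Passing tests therefore
demonstrate that the measurement chain recovers known effects from data
with the study's statistical structure — not that it is robust to every
artifact of real motion capture.

## Problem sizes in the test suite

Simulation-heavy checks (type-I error of the interaction test over 1000
seeded cohorts; recovery of the programmed gain pattern over 200 cohorts)
keep the design size n = 21/group but use reduced reach trials (1 s at
25 Hz, reach tests only) — the tested statistics operate on per-trial
summaries, so trial resolution beyond what defines the maximum cleanly is
immaterial. Geometry and entropy oracles run at the sizes stated in their
tests (e.g. 10⁶-point Monte-Carlo area sampling, N = 300 entropy signals).
The acceptance script runs the full-resolution default study (63 subjects,
100 Hz, all blocks), completing in well under a minute on one CPU.

## Known limitations

- The split-plot decomposition assumes a balanced within design (both
  times per subject); unbalanced group sizes are handled, missing cells are
  rejected rather than imputed.
- Mean velocity is total excursion over duration; if epochs differ in
  length between arms (as the XR post-training default does), excursion and
  velocity are not redundant, which is intentional.
- ApEn values depend on (m, r) and on the 6 Hz prefilter; comparisons are
  only meaningful within a fixed parameter set.
- The Likert floor of 1/7 compresses low-end contrasts (relevant for SSQ,
  whose latents sit near the floor).
- `point_in_polygon` treats a 1e-9 m band around the boundary as inside;
  HIAR is insensitive to this except for trajectories riding the hull.
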