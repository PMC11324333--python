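"""Seeded synthetic cohorts with the statistical structure of the study design.

The generator emulates a three-arm randomized experiment (physical-reality
PR, augmented-reality AR, virtual-reality VR; equal group sizes) of
robot-assisted seated reach training: an eight-direction baseline reach
test, 12 training rounds of 8 bouts each with shuffled direction order, a
post-training reach test, seat-mat center-of-pressure (COP) recordings, and
Likert questionnaires.  Programmed effects -- multiplicative pre-to-post
reach gains per group, a saturating per-round learning curve, group- and
time-dependent sway parameters, and per-instrument latent questionnaire
levels -- are the quantities the downstream metrics and statistics are
expected to recover.

Models (chosen for smoothness and a minimal number of interpretable knobs):

* reach kinematics: a minimum-jerk out-and-back profile along the
  direction's unit vector, peak displacement = amplitude, plus i.i.d.
  Gaussian positional noise; the trunk COM is a scaled copy (default
  coupling 0.35) of the fingertip displacement;
* sway: a planar Ornstein-Uhlenbeck process (exact discretization at
  56 Hz) optionally mixed with a deterministic oscillation; the mixing
  weight tunes regularity (approximate entropy) downward while the
  diffusion sets path length;
* questionnaires: item responses drawn from a discretized truncated normal
  centered at ``1 + 6 * latent`` on the 1-7 scale.

All randomness derives from the config seed; identical configs produce
byte-identical serialized cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sp_signal

from .exceptions import ConfigurationError
from .preprocess import TimeSeriesPlanar
from .questionnaires import LIKERT_MAX, LIKERT_MIN, QuestionnaireResponse
from .reach import (
    DIRECTIONS,
    N_TRAINING_ROUNDS,
    ReachTrial,
    direction_unit_vector,
    place_targets,
)

__all__ = [
    "SwayParams",
    "RoundCurve",
    "CohortConfig",
    "SubjectRecord",
    "generate_reach_trial",
    "generate_cop_series",
    "generate_questionnaire",
    "generate_cohort",
    "validate_subject_record",
    "cohort_to_dir",
    "cohort_from_dir",
]

GROUPS: tuple[str, ...] = ("PR", "AR", "VR")
PHASES: tuple[str, ...] = ("pre", "post")


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SwayParams:
    """Parameters of the planar sway model for one group x time cell.

    mean_reversion : 1/s
        Ornstein-Uhlenbeck pull toward the neutral position.
    diffusion : m/sqrt(s)
        OU noise intensity; sets path length / excursion.
    osc_weight : in [0, 1]
        Mixing weight of a deterministic oscillation; higher values make
        the sway more regular (lower approximate entropy).
    osc_freq : Hz, osc_amp : m
        Frequency and amplitude of the deterministic component.
    duration : s
        Length of the recording epoch.
    """

    mean_reversion: float = 1.0
    diffusion: float = 0.03
    osc_weight: float = 0.5
    osc_freq: float = 0.4
    osc_amp: float = 0.02
    duration: float = 20.0

    def __post_init__(self) -> None:
        if self.diffusion < 0:
            raise ConfigurationError("diffusion must be non-negative")
        if self.mean_reversion < 0:
            raise ConfigurationError("mean_reversion must be non-negative")
        if not 0 <= self.osc_weight <= 1:
            raise ConfigurationError("osc_weight must lie in [0, 1]")
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")


@dataclass(frozen=True)
class RoundCurve:
    """Saturating-exponential learning curve for training-round amplitudes.

    The reach amplitude at round ``r`` (1-based) is::

        base * (1 + (plateau - 1) * (1 - exp(-rate * r)) / (1 - exp(-rate * R)))

    with R = 12 rounds, so the curve starts near baseline and saturates at
    ``plateau`` times baseline by the final round.  ``plateau = 1`` gives a
    flat (zero-learning) curve.
    """

    rate: float = 0.35
    plateau: float = 1.0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ConfigurationError("learning rate must be non-negative")
        if self.plateau <= 0:
            raise ConfigurationError("plateau must be positive")

    def factor(self, round_index: int) -> float:
        """Multiplicative amplitude factor at 1-based ``round_index``."""
        if self.rate == 0:
            return 1.0
        num = 1.0 - np.exp(-self.rate * round_index)
        den = 1.0 - np.exp(-self.rate * N_TRAINING_ROUNDS)
        return float(1.0 + (self.plateau - 1.0) * num / den)


def _default_gains() -> dict[str, float]:
    return {"PR": 1.1, "AR": 1.3, "VR": 1.3}


def _default_round_curves() -> dict[str, RoundCurve]:
    return {
        "PR": RoundCurve(rate=0.35, plateau=1.1),
        "AR": RoundCurve(rate=0.55, plateau=1.3),
        "VR": RoundCurve(rate=0.55, plateau=1.3),
    }


def _default_sway_params() -> dict[str, dict[str, SwayParams]]:
    # pre-training sway identical across arms; post-training cells encode the
    # programmed pattern: faster sway only in PR, less regular (higher-ApEn)
    # and longer-excursion sway in the two XR arms at unchanged velocity
    pre = SwayParams(mean_reversion=1.0, diffusion=0.030, osc_weight=0.68, duration=20.0)
    pr_post = SwayParams(mean_reversion=1.0, diffusion=0.045, osc_weight=0.62, duration=20.0)
    xr_post = SwayParams(mean_reversion=2.0, diffusion=0.022, osc_weight=0.50, duration=36.0)
    return {
        "PR": {"pre": pre, "post": pr_post},
        "AR": {"pre": pre, "post": xr_post},
        "VR": {"pre": pre, "post": xr_post},
    }


def _default_likert_latent() -> dict[str, dict[str, dict[str, float]]]:
    # instrument -> group -> phase -> latent mean on [0, 1]
    ssq_low, ssq_high = 0.03, 0.10
    return {
        "SSQ": {
            "PR": {"pre": ssq_low, "post": ssq_low},
            "AR": {"pre": ssq_low, "post": ssq_low},
            "VR": {"pre": ssq_low, "post": ssq_high},
        },
        "ITQ": {g: {"pre": 0.42} for g in GROUPS},
        "PQ": {"AR": {"post": 0.28}, "VR": {"post": 0.62}},
        "GEQ": {"PR": {"post": 0.25}, "AR": {"post": 0.55}, "VR": {"post": 0.55}},
        "UEQ": {"PR": {"post": 0.30}, "AR": {"post": 0.60}, "VR": {"post": 0.60}},
    }


def _default_item_counts() -> dict[str, int]:
    return {"SSQ": 16, "ITQ": 18, "PQ": 19, "GEQ": 19, "UEQ": 10}


def _default_immersion() -> dict[str, float]:
    # normalized positions of the systems on the reality-virtuality continuum
    return {"PR": 0.0, "AR": 0.22, "VR": 0.78}


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort.

    The defaults encode the study design (3 groups x 21 subjects, 8
    directions, 12 rounds x 8 bouts, 100 Hz kinematics, 56 Hz COP) with
    illustrative effect magnitudes: reach gains 1.1 (PR) vs 1.3 (AR, VR),
    faster post-training sway only in PR, less regular (higher-entropy)
    post-training sway in AR and VR, and questionnaire latents that raise
    post-training simulator sickness only in VR.
    """

    n_per_group: int = 21
    groups: tuple[str, ...] = GROUPS
    baseline_reach_m: tuple[float, float] = (0.30, 0.04)  # mean, SD across subjects
    gain_by_group: Mapping[str, float] = field(default_factory=_default_gains)
    gain_subject_cv: float = 0.05
    round_curve: Mapping[str, RoundCurve] = field(default_factory=_default_round_curves)
    bout_amplitude_cv: float = 0.06
    sway_params: Mapping[str, Mapping[str, SwayParams]] = field(
        default_factory=_default_sway_params
    )
    round_cop_duration_s: float = 10.0
    likert_latent: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=_default_likert_latent
    )
    likert_subject_sd: float = 0.05
    likert_response_sd: float = 0.6
    item_counts: Mapping[str, int] = field(default_factory=_default_item_counts)
    immersion: Mapping[str, float] = field(default_factory=_default_immersion)
    noise_sd_m: float = 0.003
    com_ratio: float = 0.35
    trial_duration_s: float = 3.0
    rate_hz: float = 100.0
    cop_rate_hz: float = 56.0
    include_training: bool = True
    include_cop: bool = True
    include_questionnaires: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if tuple(self.groups) != GROUPS:
            raise ConfigurationError(f"groups must be {GROUPS}")
        mean, sd = self.baseline_reach_m
        if mean <= 0 or sd < 0:
            raise ConfigurationError("baseline reach mean must be > 0 and SD >= 0")
        for g in self.groups:
            if g not in self.gain_by_group or not self.gain_by_group[g] > 0:
                raise ConfigurationError(f"gain for group {g} must be positive")
        if self.gain_subject_cv < 0 or self.bout_amplitude_cv < 0:
            raise ConfigurationError("coefficients of variation must be >= 0")
        if self.noise_sd_m < 0 or self.likert_subject_sd < 0 or self.likert_response_sd < 0:
            raise ConfigurationError("SDs must be >= 0")
        if self.trial_duration_s <= 0 or self.rate_hz <= 0 or self.cop_rate_hz <= 0:
            raise ConfigurationError("durations and rates must be positive")
        if not 0 < self.com_ratio:
            raise ConfigurationError("com_ratio must be positive")

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = list(self.groups)
        d["baseline_reach_m"] = list(self.baseline_reach_m)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "baseline_reach_m" in d:
            d["baseline_reach_m"] = tuple(d["baseline_reach_m"])
        if "groups" in d:
            d["groups"] = tuple(d["groups"])
        if "round_curve" in d:
            d["round_curve"] = {
                g: rc if isinstance(rc, RoundCurve) else RoundCurve(**rc)
                for g, rc in d["round_curve"].items()
            }
        if "sway_params" in d:
            d["sway_params"] = {
                g: {
                    ph: sp if isinstance(sp, SwayParams) else SwayParams(**sp)
                    for ph, sp in by_phase.items()
                }
                for g, by_phase in d["sway_params"].items()
            }
        return cls(**d)


# --------------------------------------------------------------------------
# element generators


def _minimum_jerk_out_and_back(n: int) -> np.ndarray:
    """Normalized out-and-back displacement profile on ``n`` samples (0->1->0)."""
    t = np.linspace(0.0, 1.0, n)
    tau = np.where(t <= 0.5, 2.0 * t, 2.0 * (1.0 - t))
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _reach_trial_from_rng(
    direction: str,
    amplitude: float,
    start: np.ndarray,
    noise_sd: float,
    rate: float,
    duration: float,
    com_ratio: float,
    rng: np.random.Generator,
) -> ReachTrial:
    n = int(round(duration * rate)) + 1
    timestamps = np.arange(n) / rate
    u = direction_unit_vector(direction)
    profile = amplitude * _minimum_jerk_out_and_back(n)
    fingertip = start + profile[:, None] * u
    if noise_sd > 0:
        fingertip = fingertip + rng.normal(0.0, noise_sd, size=fingertip.shape)
    # COM displacement is measured from the trial's own first sample, the
    # same reference ReachTrial.start_position uses
    com = com_ratio * (fingertip - fingertip[0])
    return ReachTrial(
        direction=direction,
        fingertip=TimeSeriesPlanar(timestamps, fingertip, rate),
        com=TimeSeriesPlanar(timestamps, com, rate),
        start_position=fingertip[0],
    )


def generate_reach_trial(
    direction: str,
    amplitude: float,
    start: Sequence[float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    rate: float = 100.0,
    seed: int | np.random.Generator = 0,
    duration: float = 3.0,
    com_ratio: float = 0.35,
) -> ReachTrial:
    """One directional reach: minimum-jerk out-and-back plus Gaussian noise.

    The noise-free fingertip path moves ``amplitude`` meters out along the
    direction's unit vector and back; the trunk COM is ``com_ratio`` times
    the fingertip displacement.  Identical seeds give identical trials.
    """
    if not amplitude > 0:
        raise ConfigurationError("amplitude must be positive")
    if not rate > 0 or not duration > 0:
        raise ConfigurationError("rate and duration must be positive")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _reach_trial_from_rng(
        direction, amplitude, np.asarray(start, dtype=float), noise_sd, rate,
        duration, com_ratio, rng,
    )


def generate_cop_series(
    duration: float,
    sway: SwayParams = SwayParams(),
    seed: int | np.random.Generator = 0,
    rate: float = 56.0,
) -> TimeSeriesPlanar:
    """Planar sway series: Ornstein-Uhlenbeck plus deterministic oscillation.

    The OU component uses the exact discretization
    ``x[k+1] = x[k] * exp(-a dt) + sigma * sqrt((1 - exp(-2 a dt)) / (2 a)) * eps``
    per axis; the deterministic component is a planar Lissajous-type
    oscillation.  The two are mixed as ``(1 - w) * OU + w * osc``, so weight
    1 with zero diffusion gives a perfectly regular path and diffusion 0
    with weight 0 a constant series.
    """
    if not duration > 0:
        raise ConfigurationError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    dt = 1.0 / rate
    a, sigma = sway.mean_reversion, sway.diffusion
    ou = np.zeros((n, 2))
    if sigma > 0:
        if a > 0:
            decay = np.exp(-a * dt)
            scale = sigma * np.sqrt((1.0 - np.exp(-2.0 * a * dt)) / (2.0 * a))
        else:  # pure Brownian motion
            decay = 1.0
            scale = sigma * np.sqrt(dt)
        eps = rng.standard_normal((n - 1, 2))
        # AR(1) recursion x[k] = decay * x[k-1] + scale * eps[k] as an IIR filter
        ou[1:] = sp_signal.lfilter([scale], [1.0, -decay], eps, axis=0)
    osc = sway.osc_amp * np.column_stack(
        [np.sin(2 * np.pi * sway.osc_freq * t),
         np.cos(2 * np.pi * 0.7 * sway.osc_freq * t) - 1.0]
    )
    xy = (1.0 - sway.osc_weight) * ou + sway.osc_weight * osc
    return TimeSeriesPlanar(t, xy, rate)


def generate_questionnaire(
    latent: float,
    n_items: int,
    seed: int | np.random.Generator = 0,
    response_sd: float = 0.6,
) -> tuple[int, ...]:
    """Item responses in {1..7} from a discretized truncated normal.

    Responses center on ``1 + 6 * latent`` with SD ``response_sd`` (item
    units), rounded to the nearest integer and clipped to the scale.  The
    expected normalized score increases with ``latent``.
    """
    if not 0 <= latent <= 1:
        raise ConfigurationError("latent must lie in [0, 1]")
    if n_items < 1:
        raise ConfigurationError("n_items must be >= 1")
    if response_sd < 0:
        raise ConfigurationError("response_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    center = 1.0 + 6.0 * latent
    raw = np.full(n_items, center)
    if response_sd > 0:
        raw = raw + rng.normal(0.0, response_sd, size=n_items)
    items = np.clip(np.rint(raw), LIKERT_MIN, LIKERT_MAX).astype(int)
    return tuple(int(i) for i in items)


# --------------------------------------------------------------------------
# cohort assembly


@dataclass
class SubjectRecord:
    """All recordings of one synthetic subject.

    ``training_rounds`` is a list of 12 rounds, each a list of 8
    :class:`ReachTrial` in shuffled direction order; ``bout_levels`` the
    matching reached-target levels (0 = miss, 1-3 = basic/medium/hard).
    COP fields and questionnaires may be ``None``/empty when the config
    disabled them.
    """

    subject_id: str
    group: str
    pre_trials: dict[str, ReachTrial]
    post_trials: dict[str, ReachTrial]
    training_rounds: list[list[ReachTrial]]
    bout_levels: list[list[int]]
    cop_pre: TimeSeriesPlanar | None = None
    cop_post: TimeSeriesPlanar | None = None
    cop_by_round: list[TimeSeriesPlanar] = field(default_factory=list)
    questionnaires: list[QuestionnaireResponse] = field(default_factory=list)


def validate_subject_record(rec: SubjectRecord) -> SubjectRecord:
    """Check the structural invariants of a subject record."""
    for phase, trials in (("pre", rec.pre_trials), ("post", rec.post_trials)):
        if set(trials) != set(DIRECTIONS):
            raise ConfigurationError(
                f"{rec.subject_id} {phase}-test directions {sorted(trials)} != "
                f"{sorted(DIRECTIONS)}"
            )
    if rec.training_rounds:
        if len(rec.training_rounds) != N_TRAINING_ROUNDS:
            raise ConfigurationError(
                f"{rec.subject_id}: expected {N_TRAINING_ROUNDS} training rounds"
            )
        for i, rnd in enumerate(rec.training_rounds):
            if sorted(t.direction for t in rnd) != sorted(DIRECTIONS):
                raise ConfigurationError(
                    f"{rec.subject_id} round {i + 1} does not cover all 8 directions"
                )
        if len(rec.bout_levels) != N_TRAINING_ROUNDS or any(
            len(levels) != len(DIRECTIONS) for levels in rec.bout_levels
        ):
            raise ConfigurationError(f"{rec.subject_id}: malformed bout levels")
    return rec


def _interp_sway(pre: SwayParams, post: SwayParams, f: float, duration: float) -> SwayParams:
    """Linear interpolation of sway parameters, fraction ``f`` from pre to post."""
    mix = lambda a, b: (1.0 - f) * a + f * b  # noqa: E731
    return SwayParams(
        mean_reversion=mix(pre.mean_reversion, post.mean_reversion),
        diffusion=mix(pre.diffusion, post.diffusion),
        osc_weight=mix(pre.osc_weight, post.osc_weight),
        osc_freq=mix(pre.osc_freq, post.osc_freq),
        osc_amp=mix(pre.osc_amp, post.osc_amp),
        duration=duration,
    )


def _generate_subject(
    subject_id: str, group: str, config: CohortConfig, rng: np.random.Generator
) -> SubjectRecord:
    mean, sd = config.baseline_reach_m
    base = {
        d: max(0.05, rng.normal(mean, sd)) for d in DIRECTIONS
    }
    gain = config.gain_by_group[group] * float(
        np.exp(rng.normal(0.0, config.gain_subject_cv))
    ) if config.gain_subject_cv > 0 else config.gain_by_group[group]

    def trial(direction: str, amplitude: float) -> ReachTrial:
        return _reach_trial_from_rng(
            direction, amplitude, np.zeros(2), config.noise_sd_m,
            config.rate_hz, config.trial_duration_s, config.com_ratio, rng,
        )

    pre_trials = {d: trial(d, base[d]) for d in DIRECTIONS}
    post_trials = {d: trial(d, base[d] * gain) for d in DIRECTIONS}

    training_rounds: list[list[ReachTrial]] = []
    bout_levels: list[list[int]] = []
    curve = config.round_curve.get(group, RoundCurve())
    if config.include_training:
        targets = place_targets({d: base[d] for d in DIRECTIONS})
        for r in range(1, N_TRAINING_ROUNDS + 1):
            factor = curve.factor(r)
            order = [DIRECTIONS[i] for i in rng.permutation(len(DIRECTIONS))]
            round_trials: list[ReachTrial] = []
            round_levels: list[int] = []
            for d in order:
                amp = base[d] * factor
                if config.bout_amplitude_cv > 0:
                    amp *= float(np.exp(rng.normal(0.0, config.bout_amplitude_cv)))
                round_trials.append(trial(d, amp))
                round_levels.append(targets.level_reached(d, amp))
            training_rounds.append(round_trials)
            bout_levels.append(round_levels)

    cop_pre = cop_post = None
    cop_by_round: list[TimeSeriesPlanar] = []
    if config.include_cop:
        sway_pre = config.sway_params[group]["pre"]
        sway_post = config.sway_params[group]["post"]
        cop_pre = generate_cop_series(sway_pre.duration, sway_pre, rng, config.cop_rate_hz)
        cop_post = generate_cop_series(sway_post.duration, sway_post, rng, config.cop_rate_hz)
        if config.include_training:
            for r in range(1, N_TRAINING_ROUNDS + 1):
                f = curve.factor(r)
                # map the amplitude curve onto [0, 1] progress pre -> post
                progress = (f - 1.0) / (curve.plateau - 1.0) if curve.plateau != 1.0 else 1.0
                sway_r = _interp_sway(
                    sway_pre, sway_post, progress, config.round_cop_duration_s
                )
                cop_by_round.append(
                    generate_cop_series(sway_r.duration, sway_r, rng, config.cop_rate_hz)
                )

    questionnaires: list[QuestionnaireResponse] = []
    if config.include_questionnaires:
        for instrument, by_group in config.likert_latent.items():
            if group not in by_group:
                continue
            for phase, latent_mean in by_group[group].items():
                latent = float(
                    np.clip(rng.normal(latent_mean, config.likert_subject_sd), 0.0, 1.0)
                )
                items = generate_questionnaire(
                    latent, config.item_counts[instrument], rng, config.likert_response_sd
                )
                questionnaires.append(
                    QuestionnaireResponse(instrument=instrument, phase=phase, items=items)
                )

    return validate_subject_record(
        SubjectRecord(
            subject_id=subject_id,
            group=group,
            pre_trials=pre_trials,
            post_trials=post_trials,
            training_rounds=training_rounds,
            bout_levels=bout_levels,
            cop_pre=cop_pre,
            cop_post=cop_post,
            cop_by_round=cop_by_round,
            questionnaires=questionnaires,
        )
    )


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Generate the full cohort: ``3 * n_per_group`` validated subjects.

    Each subject draws from an independent child stream of the config seed,
    so the cohort is reproducible and insensitive to generation order.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(len(config.groups) * config.n_per_group)
    cohort: list[SubjectRecord] = []
    k = 0
    for group in config.groups:
        for j in range(config.n_per_group):
            subject_id = f"{group}{j + 1:02d}"
            rng = np.random.default_rng(seeds[k])
            cohort.append(_generate_subject(subject_id, group, config, rng))
            k += 1
    return cohort


# --------------------------------------------------------------------------
# CSV serialization


def _trial_rows(
    rec: SubjectRecord, phase: str, round_idx: int, bout_idx: int, trial: ReachTrial
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject": rec.subject_id,
            "group": rec.group,
            "phase": phase,
            "round": round_idx,
            "bout": bout_idx,
            "direction": trial.direction,
            "t": trial.fingertip.timestamps,
            "x_fingertip": trial.fingertip.values[:, 0],
            "y_fingertip": trial.fingertip.values[:, 1],
            "x_com": trial.com.values[:, 0],
            "y_com": trial.com.values[:, 1],
        }
    )


def cohort_to_dir(cohort: Sequence[SubjectRecord], config: CohortConfig, out: Path | str) -> Path:
    """Serialize a cohort to CSV files plus a ``manifest.yaml`` echoing the config.

    Files: ``trajectories.csv``, ``cop.csv``, ``questionnaires.csv``,
    ``bout_levels.csv``, ``manifest.yaml``.  Floats are written with 17
    significant digits so deserialization is value-exact.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)

    traj_frames: list[pd.DataFrame] = []
    cop_frames: list[pd.DataFrame] = []
    q_rows: list[dict] = []
    level_rows: list[dict] = []
    for rec in cohort:
        for d in DIRECTIONS:
            traj_frames.append(_trial_rows(rec, "pre", 0, 0, rec.pre_trials[d]))
            traj_frames.append(_trial_rows(rec, "post", 0, 0, rec.post_trials[d]))
        for r, rnd in enumerate(rec.training_rounds, start=1):
            for b, trial in enumerate(rnd, start=1):
                traj_frames.append(_trial_rows(rec, "training", r, b, trial))
        for r, levels in enumerate(rec.bout_levels, start=1):
            for b, (trial, level) in enumerate(zip(rec.training_rounds[r - 1], levels), start=1):
                level_rows.append(
                    {"subject": rec.subject_id, "group": rec.group, "round": r,
                     "bout": b, "direction": trial.direction, "level": level}
                )
        for phase, cop in (("pre", rec.cop_pre), ("post", rec.cop_post)):
            if cop is not None:
                cop_frames.append(
                    pd.DataFrame(
                        {"subject": rec.subject_id, "group": rec.group, "phase": phase,
                         "round": 0, "t": cop.timestamps,
                         "x": cop.values[:, 0], "y": cop.values[:, 1]}
                    )
                )
        for r, cop in enumerate(rec.cop_by_round, start=1):
            cop_frames.append(
                pd.DataFrame(
                    {"subject": rec.subject_id, "group": rec.group, "phase": "training",
                     "round": r, "t": cop.timestamps,
                     "x": cop.values[:, 0], "y": cop.values[:, 1]}
                )
            )
        for q in rec.questionnaires:
            for i, score in enumerate(q.items, start=1):
                q_rows.append(
                    {"subject": rec.subject_id, "group": rec.group,
                     "instrument": q.instrument, "phase": q.phase,
                     "item": i, "score": score}
                )

    fmt = "%.17g"
    pd.concat(traj_frames, ignore_index=True).to_csv(
        out / "trajectories.csv", index=False, float_format=fmt
    )
    (pd.concat(cop_frames, ignore_index=True) if cop_frames else pd.DataFrame(
        columns=["subject", "group", "phase", "round", "t", "x", "y"]
    )).to_csv(out / "cop.csv", index=False, float_format=fmt)
    pd.DataFrame(
        q_rows, columns=["subject", "group", "instrument", "phase", "item", "score"]
    ).to_csv(out / "questionnaires.csv", index=False)
    pd.DataFrame(
        level_rows, columns=["subject", "group", "round", "bout", "direction", "level"]
    ).to_csv(out / "bout_levels.csv", index=False)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return out


def _series_from_frame(df: pd.DataFrame, cols: tuple[str, ...], rate: float) -> TimeSeriesPlanar:
    return TimeSeriesPlanar(
        df["t"].to_numpy(), df[list(cols)].to_numpy(), rate
    )


def cohort_from_dir(path: Path | str) -> tuple[list[SubjectRecord], CohortConfig]:
    """Load a cohort serialized by :func:`cohort_to_dir`."""
    path = Path(path)
    with open(path / "manifest.yaml") as fh:
        config = CohortConfig.from_dict(yaml.safe_load(fh))
    # round_trip parsing keeps deserialized floats bit-identical to the
    # %.17g-formatted values, so re-analysis reproduces reports exactly
    traj = pd.read_csv(path / "trajectories.csv", float_precision="round_trip")
    cop = pd.read_csv(path / "cop.csv", float_precision="round_trip")
    quest = pd.read_csv(path / "questionnaires.csv")
    levels = pd.read_csv(path / "bout_levels.csv")

    def trial_from_rows(rows: pd.DataFrame) -> ReachTrial:
        direction = rows["direction"].iloc[0]
        fingertip = _series_from_frame(rows, ("x_fingertip", "y_fingertip"), config.rate_hz)
        com = _series_from_frame(rows, ("x_com", "y_com"), config.rate_hz)
        return ReachTrial(
            direction=direction, fingertip=fingertip, com=com,
            start_position=fingertip.values[0],
        )

    cohort: list[SubjectRecord] = []
    for subject, sub_traj in traj.groupby("subject", sort=True):
        group = sub_traj["group"].iloc[0]
        pre_trials: dict[str, ReachTrial] = {}
        post_trials: dict[str, ReachTrial] = {}
        rounds: dict[int, dict[int, ReachTrial]] = {}
        for (phase, rnd, bout, direction), rows in sub_traj.groupby(
            ["phase", "round", "bout", "direction"], sort=True
        ):
            t = trial_from_rows(rows)
            if phase == "pre":
                pre_trials[direction] = t
            elif phase == "post":
                post_trials[direction] = t
            else:
                rounds.setdefault(int(rnd), {})[int(bout)] = t
        training_rounds = [
            [rounds[r][b] for b in sorted(rounds[r])] for r in sorted(rounds)
        ]
        sub_levels = levels[levels["subject"] == subject]
        bout_levels = [
            [int(v) for v in sub_levels[sub_levels["round"] == r].sort_values("bout")["level"]]
            for r in sorted(sub_levels["round"].unique())
        ]
        sub_cop = cop[cop["subject"] == subject]
        cop_pre = cop_post = None
        cop_by_round: list[TimeSeriesPlanar] = []
        for (phase, rnd), rows in sub_cop.groupby(["phase", "round"], sort=True):
            series = _series_from_frame(rows, ("x", "y"), config.cop_rate_hz)
            if phase == "pre":
                cop_pre = series
            elif phase == "post":
                cop_post = series
        for rnd in sorted(sub_cop.loc[sub_cop["phase"] == "training", "round"].unique()):
            rows = sub_cop[(sub_cop["phase"] == "training") & (sub_cop["round"] == rnd)]
            cop_by_round.append(_series_from_frame(rows, ("x", "y"), config.cop_rate_hz))
        questionnaires = []
        sub_q = quest[quest["subject"] == subject]
        for (instrument, phase), rows in sub_q.groupby(["instrument", "phase"], sort=True):
            items = tuple(int(s) for s in rows.sort_values("item")["score"])
            questionnaires.append(
                QuestionnaireResponse(instrument=instrument, phase=phase, items=items)
            )
        cohort.append(
            validate_subject_record(
                SubjectRecord(
                    subject_id=str(subject), group=group,
                    pre_trials=pre_trials, post_trials=post_trials,
                    training_rounds=training_rounds, bout_levels=bout_levels,
                    cop_pre=cop_pre, cop_post=cop_post, cop_by_round=cop_by_round,
                    questionnaires=questionnaires,
                )
            )
        )
    return cohort, config
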