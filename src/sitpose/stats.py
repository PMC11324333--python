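"""Split-plot and one-way ANOVA with assumption checks and Bonferroni post-hocs.

The study design crosses one between-subjects factor (intervention group:
PR, AR, VR) with one within-subjects factor (test time: T0 baseline, T1
post-training).  Measures observed at both times (reach scores, workspace
area, COP variables, simulator sickness) are analyzed with a mixed
between-within (split-plot) ANOVA; measures observed once (HIAR, reach task
score, questionnaire scores) with a one-way between-groups ANOVA.  Partial
eta squared is reported per effect from its own error term
(SS_effect / (SS_effect + SS_error)); with two within-subject levels
sphericity holds trivially and no correction is applied.

Normality (Shapiro-Wilk plus Q-Q coordinates) and homoscedasticity
(Levene's test) checks accompany every ANOVA.  When the omnibus test is
significant at alpha, pairwise group contrasts follow, using the pooled
error term and Bonferroni-adjusted p values (k = 3 group pairs).

The models follow the statsmodels idiom: construct from a long-format
DataFrame, call :meth:`fit`, receive a results object with an
``anova_table`` and a ``summary()``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .exceptions import ConfigurationError, DataQualityError, DesignError

__all__ = [
    "AnovaResult",
    "AnovaResults",
    "MixedAnova",
    "OneWayAnova",
    "bonferroni_adjust",
    "pairwise_bonferroni",
    "levene_test",
    "normality_check",
    "NormalityResult",
]

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class AnovaResult:
    """One effect line of an ANOVA table."""

    effect: str
    df_num: int
    df_den: int
    F: float
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float


class AnovaResults:
    """Fitted ANOVA: effect records, assumption checks, and post-hoc access.

    Attributes
    ----------
    effects : dict mapping effect name to :class:`AnovaResult`
    anova_table : pandas.DataFrame, one row per effect
    levene : (statistic, p) of the homoscedasticity check
    """

    def __init__(
        self,
        model: "MixedAnova | OneWayAnova",
        effects: Sequence[AnovaResult],
        levene: tuple[float, float] | None = None,
    ) -> None:
        self.model = model
        self.effects = {e.effect: e for e in effects}
        self.levene = levene

    @property
    def anova_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect": e.effect, "df_num": e.df_num, "df_den": e.df_den,
                    "F": e.F, "p": e.p, "partial_eta_sq": e.partial_eta_sq,
                    "ss_effect": e.ss_effect, "ss_error": e.ss_error,
                }
                for e in self.effects.values()
            ]
        )

    def posthoc(
        self, effect: str | None = None, alpha: float = ALPHA_DEFAULT
    ) -> pd.DataFrame | None:
        """Bonferroni pairwise group contrasts, gated on omnibus significance.

        For the mixed design the contrasts compare the per-subject
        pre-to-post change between groups (the interaction follow-up); for
        the one-way design they compare the group means.  Returns ``None``
        when the omnibus effect is not significant at ``alpha``.
        """
        effect = effect or self.model.default_posthoc_effect
        omnibus = self.effects[effect]
        if omnibus.p > alpha:
            return None
        return pairwise_bonferroni(self.model.posthoc_frame(), "value", "group")

    def summary(self) -> str:
        lines = [f"{type(self.model).__name__}: dv={self.model.dv!r}"]
        lines.append(
            f"{'effect':<14}{'df':>9}{'F':>10}{'p':>10}{'partial eta^2':>15}"
        )
        for e in self.effects.values():
            lines.append(
                f"{e.effect:<14}{e.df_num:>4},{e.df_den:>4}{e.F:>10.3f}"
                f"{e.p:>10.4f}{e.partial_eta_sq:>15.3f}"
            )
        if self.levene is not None:
            lines.append(f"Levene W={self.levene[0]:.3f}, p={self.levene[1]:.4f}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<AnovaResults {list(self.effects)}>"


class MixedAnova:
    """Mixed between-within (split-plot) ANOVA on a long-format table.

    Parameters
    ----------
    data
        Long-format DataFrame with one row per subject x time.
    dv, subject, between, within
        Column names of the dependent variable, subject identifier,
        between-subjects factor and within-subjects (time) factor.

    The design must be balanced in time: every subject observed at every
    within level.  Group sizes may differ.
    """

    default_posthoc_effect = "interaction"

    def __init__(
        self,
        data: pd.DataFrame,
        dv: str = "value",
        subject: str = "subject",
        between: str = "group",
        within: str = "time",
    ) -> None:
        self.dv, self.subject, self.between, self.within = dv, subject, between, within
        required = {dv, subject, between, within}
        missing = required - set(data.columns)
        if missing:
            raise DesignError(f"missing columns: {sorted(missing)}")
        self.data = data[[subject, between, within, dv]].copy()
        self._validate()

    @classmethod
    def from_metric_table(cls, table: pd.DataFrame, metric: str) -> "MixedAnova":
        """Build from the pipeline's long metric table (rows with a
        ``metric`` column) for one named metric."""
        sub = table[table["metric"] == metric]
        if sub.empty:
            raise DesignError(f"metric {metric!r} not present in the table")
        return cls(sub)

    def _validate(self) -> None:
        d = self.data
        if d[self.dv].isna().any():
            bad = d.loc[d[self.dv].isna(), self.subject].unique()
            raise DesignError(f"missing values for subjects: {sorted(map(str, bad))}")
        times = sorted(d[self.within].unique())
        if len(times) < 2:
            raise DesignError("within factor needs at least 2 levels")
        counts = d.groupby([self.subject, self.within], observed=True).size()
        if (counts != 1).any():
            bad = sorted({s for s, _ in counts[counts != 1].index})
            raise DesignError(f"duplicated cells for subjects: {bad}")
        per_subject = d.groupby(self.subject, observed=True)[self.within].nunique()
        incomplete = sorted(per_subject[per_subject != len(times)].index.astype(str))
        if incomplete:
            raise DesignError(f"subjects missing a time point: {incomplete}")
        groups = d.groupby(self.between, observed=True)[self.subject].nunique()
        if len(groups) < 2:
            raise DesignError("need at least 2 groups")
        small = sorted(groups[groups < 2].index.astype(str))
        if small:
            raise DesignError(f"groups with fewer than 2 subjects: {small}")

    def fit(self) -> AnovaResults:
        d = self.data
        y = d[self.dv].to_numpy(dtype=float)
        grand = y.mean()
        n_obs = y.size
        subj_group = d.groupby(self.subject, observed=True)[self.between].first()
        a = subj_group.nunique()  # groups
        b = d[self.within].nunique()  # times
        n_subjects = len(subj_group)

        ss_total = float(((y - grand) ** 2).sum())
        subj_means = d.groupby(self.subject, observed=True)[self.dv].mean()
        ss_subjects = float(b * ((subj_means - grand) ** 2).sum())

        group_sizes = subj_group.value_counts()
        group_means = d.groupby(self.between, observed=True)[self.dv].mean()
        ss_group = float(
            sum(b * group_sizes[g] * (group_means[g] - grand) ** 2 for g in group_means.index)
        )
        ss_subj_within = ss_subjects - ss_group  # between-subjects error

        time_means = d.groupby(self.within, observed=True)[self.dv].mean()
        time_sizes = d.groupby(self.within, observed=True).size()
        ss_time = float(sum(time_sizes[t] * (time_means[t] - grand) ** 2 for t in time_means.index))

        cell = d.groupby([self.between, self.within], observed=True)[self.dv].agg(["mean", "size"])
        ss_cells = float((cell["size"] * (cell["mean"] - grand) ** 2).sum())
        ss_interaction = ss_cells - ss_group - ss_time
        ss_within = ss_total - ss_subjects
        ss_error_within = ss_within - ss_time - ss_interaction

        df_group = a - 1
        df_subj_within = n_subjects - a
        df_time = b - 1
        df_interaction = (a - 1) * (b - 1)
        df_error_within = (n_subjects - a) * (b - 1)

        # sums of squares obtained by subtraction can go minutely negative
        tiny = 1e-12 * max(ss_total, 1.0)

        def effect(name: str, ss: float, df: int, ss_err: float, df_err: int) -> AnovaResult:
            if df_err <= 0 or ss_err < -tiny:
                raise DesignError(f"degenerate error term for effect {name}")
            ss, ss_err = max(ss, 0.0), max(ss_err, 0.0)
            ms, ms_err = ss / df, ss_err / df_err
            if ms_err > 0:
                F = ms / ms_err
            else:  # zero error variance: F is 0 for a null effect, infinite otherwise
                F = 0.0 if ms <= tiny else np.inf
            p = float(sp_stats.f.sf(F, df, df_err)) if np.isfinite(F) else 0.0
            pes = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
            return AnovaResult(name, df, df_err, float(F), p, float(pes), float(ss), float(ss_err))

        effects = [
            effect("group", ss_group, df_group, ss_subj_within, df_subj_within),
            effect("time", ss_time, df_time, ss_error_within, df_error_within),
            effect("interaction", ss_interaction, df_interaction, ss_error_within, df_error_within),
        ]
        lev = self._levene()
        return AnovaResults(self, effects, levene=lev)

    def _levene(self) -> tuple[float, float] | None:
        # homoscedasticity of the per-subject changes across groups
        frame = self.posthoc_frame()
        groups = [g["value"].to_numpy() for _, g in frame.groupby("group", observed=True)]
        try:
            return levene_test(groups)
        except DataQualityError:
            return None

    def posthoc_frame(self) -> pd.DataFrame:
        """Per-subject within-change (last minus first time level) by group."""
        d = self.data
        times = sorted(d[self.within].unique())
        wide = d.pivot_table(
            index=[self.subject, self.between], columns=self.within,
            values=self.dv, observed=True,
        ).reset_index()
        delta = wide[times[-1]] - wide[times[0]]
        return pd.DataFrame({"subject": wide[self.subject],
                             "group": wide[self.between], "value": delta})


class OneWayAnova:
    """One-way between-groups ANOVA on a long-format table."""

    default_posthoc_effect = "group"

    def __init__(
        self, data: pd.DataFrame, dv: str = "value", between: str = "group",
        subject: str = "subject",
    ) -> None:
        self.dv, self.between, self.subject = dv, between, subject
        missing = {dv, between} - set(data.columns)
        if missing:
            raise DesignError(f"missing columns: {sorted(missing)}")
        self.data = data.copy()
        sizes = self.data.groupby(between, observed=True)[dv].size()
        if len(sizes) < 2:
            raise DesignError("need at least 2 groups")
        small = sorted(sizes[sizes < 2].index.astype(str))
        if small:
            raise DesignError(f"groups with fewer than 2 values: {small}")
        if self.data[dv].isna().any():
            raise DesignError("missing values in the dependent variable")

    @classmethod
    def from_metric_table(cls, table: pd.DataFrame, metric: str) -> "OneWayAnova":
        sub = table[table["metric"] == metric]
        if sub.empty:
            raise DesignError(f"metric {metric!r} not present in the table")
        return cls(sub)

    def fit(self) -> AnovaResults:
        d = self.data
        y = d[self.dv].to_numpy(dtype=float)
        grand = y.mean()
        ss_total = float(((y - grand) ** 2).sum())
        by_group = d.groupby(self.between, observed=True)[self.dv]
        ss_between = float(
            (by_group.size() * (by_group.mean() - grand) ** 2).sum()
        )
        ss_within = ss_total - ss_between
        k = by_group.ngroups
        df_between = k - 1
        df_within = y.size - k
        if df_within <= 0:
            raise DesignError("no residual degrees of freedom")
        ms_b, ms_w = ss_between / df_between, ss_within / df_within
        F = ms_b / ms_w if ms_w > 0 else np.inf
        p = float(sp_stats.f.sf(F, df_between, df_within)) if np.isfinite(F) else 0.0
        eta_sq = ss_between / ss_total if ss_total > 0 else 0.0
        result = AnovaResult(
            "group", df_between, df_within, float(F), p, float(eta_sq),
            float(ss_between), float(ss_within),
        )
        groups = [g.to_numpy() for _, g in by_group]
        try:
            lev = levene_test(groups)
        except DataQualityError:
            lev = None
        return AnovaResults(self, [result], levene=lev)

    def posthoc_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": self.data[self.between], "value": self.data[self.dv]}
        )


def bonferroni_adjust(p_values: Sequence[float], k: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, p * k)`` with ``k`` = number of comparisons."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p values must lie in [0, 1]")
    k = len(p) if k is None else k
    if k < 1:
        raise ConfigurationError("number of comparisons must be >= 1")
    return np.minimum(1.0, p * k)


def pairwise_bonferroni(
    frame: pd.DataFrame, dv: str = "value", between: str = "group"
) -> pd.DataFrame:
    """All pairwise group contrasts using the pooled one-way error term.

    Each contrast is a t test with the pooled within-group mean square as
    the error variance (the convention of standard ANOVA post-hocs), and
    Bonferroni adjustment over the number of pairs.
    """
    by_group = frame.groupby(between, observed=True)[dv]
    means, sizes = by_group.mean(), by_group.size()
    k = by_group.ngroups
    df_err = int(sizes.sum() - k)
    ss_within = float(by_group.apply(lambda v: ((v - v.mean()) ** 2).sum()).sum())
    ms_err = ss_within / df_err
    rows = []
    pairs = list(itertools.combinations(sorted(means.index), 2))
    for g1, g2 in pairs:
        diff = means[g1] - means[g2]
        se = np.sqrt(ms_err * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        t = diff / se if se > 0 else np.inf
        p = float(2 * sp_stats.t.sf(abs(t), df_err)) if np.isfinite(t) else 0.0
        rows.append(
            {"group_1": g1, "group_2": g2, "mean_diff": float(diff),
             "t": float(t), "df": df_err, "p_raw": p}
        )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = bonferroni_adjust(out["p_raw"].to_numpy(), len(pairs))
    return out


def levene_test(
    groups: Sequence[np.ndarray], center: str = "mean"
) -> tuple[float, float]:
    """Levene's homoscedasticity test (``center="median"`` = Brown-Forsythe).

    Raises :class:`DataQualityError` for degenerate inputs: fewer than two
    groups, any group with fewer than two values, or zero within-group
    deviation variance (all groups constant).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise DataQualityError("Levene's test needs >= 2 groups with >= 2 values each")
    if center not in ("mean", "median"):
        raise ConfigurationError("center must be 'mean' or 'median'")
    centers = [np.mean(g) if center == "mean" else np.median(g) for g in groups]
    deviations = np.concatenate([np.abs(g - c) for g, c in zip(groups, centers)])
    if np.allclose(deviations, deviations[0]):
        raise DataQualityError("zero within-group deviation variance; Levene undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, p = sp_stats.levene(*groups, center=center)
    if not np.isfinite(stat):
        raise DataQualityError("Levene statistic undefined for these groups")
    return float(stat), float(p)


@dataclass(frozen=True)
class NormalityResult:
    """Shapiro-Wilk outcome with Q-Q plot coordinates for visual inspection."""

    W: float
    p: float
    normal: bool
    qq_theoretical: np.ndarray = field(repr=False, default=None)
    qq_sample: np.ndarray = field(repr=False, default=None)


def normality_check(values: Sequence[float], alpha: float = ALPHA_DEFAULT) -> NormalityResult:
    """Shapiro-Wilk normality test plus Q-Q coordinates.

    Valid for 3 <= n <= 5000 non-constant samples; ``normal`` is the
    non-rejection flag at ``alpha``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise DataQualityError(f"Shapiro-Wilk valid for 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise DataQualityError("constant sample: normality test undefined")
    W, p = sp_stats.shapiro(x)
    (theoretical, ordered), _ = sp_stats.probplot(x, dist="norm")
    return NormalityResult(
        W=float(W), p=float(p), normal=bool(p > alpha),
        qq_theoretical=theoretical, qq_sample=ordered,
    )
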