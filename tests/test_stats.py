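"""Split-plot and one-way ANOVA against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from oracles import one_way_ss_oracle, split_plot_cell_mean_oracle
from scipy import stats as sp_stats

from sitpose.exceptions import ConfigurationError, DataQualityError, DesignError
from sitpose.stats import (
    MixedAnova,
    OneWayAnova,
    bonferroni_adjust,
    levene_test,
    normality_check,
    pairwise_bonferroni,
)

# toy split-plot table, 2 subjects per group, values (T0, T1)
TOY = {
    "PR": [(3.0, 5.0), (4.0, 7.0)],
    "AR": [(5.0, 9.0), (6.0, 9.0)],
    "VR": [(7.0, 7.0), (8.0, 9.0)],
}
# frozen from the independent cell-mean oracle on TOY
TOY_EXPECTED = {
    "ss_group": 20.666666666666664,
    "ss_subj_within": 4.75,
    "ss_time": 14.083333333333334,
    "ss_interaction": 4.666666666666667,
    "ss_error_within": 0.75,
    "F_group": 6.526315789473678,
    "F_time": 56.33333333333333,
    "F_interaction": 9.333333333333334,
}


def toy_frame():
    rows = []
    for group, subjects in TOY.items():
        for i, (t0, t1) in enumerate(subjects):
            sid = f"{group}{i}"
            rows.append({"subject": sid, "group": group, "time": "T0", "value": t0})
            rows.append({"subject": sid, "group": group, "time": "T1", "value": t1})
    return pd.DataFrame(rows)


def random_balanced_frame(rng, a=3, n=5, b=2):
    rows = []
    for g in range(a):
        for s in range(n):
            for t in range(b):
                rows.append(
                    {"subject": f"g{g}s{s}", "group": f"G{g}", "time": f"T{t}",
                     "value": float(rng.normal(g * 0.3 + t * 0.5, 1.0))}
                )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_toy_table_matches_cell_mean_oracle(self):
        res = MixedAnova(toy_frame()).fit()
        g, t, i = res.effects["group"], res.effects["time"], res.effects["interaction"]
        assert g.ss_effect == pytest.approx(TOY_EXPECTED["ss_group"], abs=1e-8)
        assert g.ss_error == pytest.approx(TOY_EXPECTED["ss_subj_within"], abs=1e-8)
        assert t.ss_effect == pytest.approx(TOY_EXPECTED["ss_time"], abs=1e-8)
        assert i.ss_effect == pytest.approx(TOY_EXPECTED["ss_interaction"], abs=1e-8)
        assert i.ss_error == pytest.approx(TOY_EXPECTED["ss_error_within"], abs=1e-8)
        assert g.F == pytest.approx(TOY_EXPECTED["F_group"], abs=1e-8)
        assert t.F == pytest.approx(TOY_EXPECTED["F_time"], abs=1e-8)
        assert i.F == pytest.approx(TOY_EXPECTED["F_interaction"], abs=1e-8)
        assert (g.df_num, g.df_den) == (2, 3)
        assert (t.df_num, t.df_den) == (1, 3)
        assert (i.df_num, i.df_den) == (2, 3)

    def test_random_tables_match_oracle_and_conserve_ss(self, rng):
        for _ in range(20):
            a, n = 3, int(rng.integers(3, 8))
            frame = random_balanced_frame(rng, a=a, n=n)
            y = (
                frame.pivot_table(index=["group", "subject"], columns="time",
                                  values="value")
                .to_numpy()
                .reshape(a, n, 2)
            )
            oracle = split_plot_cell_mean_oracle(y)
            res = MixedAnova(frame).fit()
            assert res.effects["group"].F == pytest.approx(oracle["F_group"], abs=1e-8)
            assert res.effects["time"].F == pytest.approx(oracle["F_time"], abs=1e-8)
            assert res.effects["interaction"].F == pytest.approx(
                oracle["F_interaction"], abs=1e-8
            )
            ss_parts = (
                res.effects["group"].ss_effect
                + res.effects["group"].ss_error
                + res.effects["time"].ss_effect
                + res.effects["interaction"].ss_effect
                + res.effects["interaction"].ss_error
            )
            assert ss_parts == pytest.approx(oracle["ss_total"], abs=1e-8)

    def test_matches_pingouin_cross_check(self, rng):
        pingouin = pytest.importorskip("pingouin")
        frame = random_balanced_frame(rng, n=7)
        res = MixedAnova(frame).fit()
        pg = pingouin.mixed_anova(
            data=frame, dv="value", within="time", between="group", subject="subject"
        ).set_index("Source")
        assert res.effects["group"].F == pytest.approx(pg.loc["group", "F"], rel=1e-9)
        assert res.effects["time"].F == pytest.approx(pg.loc["time", "F"], rel=1e-9)
        assert res.effects["interaction"].F == pytest.approx(
            pg.loc["Interaction", "F"], rel=1e-9
        )
        assert res.effects["group"].p == pytest.approx(pg.loc["group", "p_unc"], rel=1e-9)
        assert res.effects["group"].partial_eta_sq == pytest.approx(
            pg.loc["group", "np2"], rel=1e-9
        )
        assert res.effects["interaction"].partial_eta_sq == pytest.approx(
            pg.loc["Interaction", "np2"], rel=1e-9
        )

    def test_uniform_shift_gives_zero_group_and_interaction(self):
        # identical baseline values in every group, post = pre + the same
        # constant for everyone: both the group and interaction SS vanish
        rows = []
        for group in ("PR", "AR", "VR"):
            for i, v in enumerate([1.0, 2.0, 3.5]):
                sid = f"{group}{i}"
                rows.append({"subject": sid, "group": group, "time": "T0", "value": v})
                rows.append({"subject": sid, "group": group, "time": "T1", "value": v + 2.0})
        res = MixedAnova(pd.DataFrame(rows)).fit()
        assert res.effects["interaction"].ss_effect == pytest.approx(0.0, abs=1e-12)
        assert res.effects["group"].ss_effect == pytest.approx(0.0, abs=1e-12)

    def test_missing_time_point_names_subject(self):
        frame = toy_frame().iloc[:-1]
        with pytest.raises(DesignError, match="VR1"):
            MixedAnova(frame).fit()

    def test_partial_eta_sq_in_unit_interval(self, rng):
        res = MixedAnova(random_balanced_frame(rng)).fit()
        for e in res.effects.values():
            assert 0.0 <= e.partial_eta_sq <= 1.0

    def test_summary_mentions_effects(self, rng):
        text = MixedAnova(toy_frame()).fit().summary()
        for token in ("group", "time", "interaction"):
            assert token in text
        # the toy table has identical within-group deltas, so the Levene
        # check degenerates there; a noisy table reports it
        noisy = MixedAnova(random_balanced_frame(rng)).fit().summary()
        assert "Levene" in noisy


class TestOneWayAnova:
    def test_identical_groups_give_zero_f(self):
        frame = pd.DataFrame(
            {"subject": list("abcdef"),
             "group": ["PR", "PR", "AR", "AR", "VR", "VR"],
             "value": [2.0, 3.0, 2.0, 3.0, 2.0, 3.0]}
        )
        res = OneWayAnova(frame).fit()
        assert res.effects["group"].F == pytest.approx(0.0, abs=1e-12)

    def test_toy_table_matches_ss_oracle(self, rng):
        groups = [rng.normal(0, 1, 6), rng.normal(0, 1, 6), rng.normal(1, 1, 6)]
        oracle = one_way_ss_oracle(groups)
        rows = [
            {"subject": f"g{i}s{j}", "group": f"G{i}", "value": float(v)}
            for i, g in enumerate(groups)
            for j, v in enumerate(g)
        ]
        res = OneWayAnova(pd.DataFrame(rows)).fit()
        e = res.effects["group"]
        assert e.ss_effect == pytest.approx(oracle["ss_between"], abs=1e-8)
        assert e.ss_error == pytest.approx(oracle["ss_within"], abs=1e-8)
        assert e.F == pytest.approx(oracle["F"], abs=1e-8)
        assert (e.df_num, e.df_den) == oracle["df"]
        # cross-check against scipy
        f_sp, p_sp = sp_stats.f_oneway(*groups)
        assert e.F == pytest.approx(f_sp, rel=1e-10)
        assert e.p == pytest.approx(p_sp, rel=1e-10)

    def test_eta_squared_is_between_over_total(self, rng):
        groups = [rng.normal(i, 1, 8) for i in range(3)]
        oracle = one_way_ss_oracle(groups)
        rows = [
            {"subject": f"g{i}s{j}", "group": f"G{i}", "value": float(v)}
            for i, g in enumerate(groups)
            for j, v in enumerate(g)
        ]
        res = OneWayAnova(pd.DataFrame(rows)).fit()
        assert res.effects["group"].partial_eta_sq == pytest.approx(
            oracle["ss_between"] / oracle["ss_total"], abs=1e-10
        )

    def test_small_group_rejected(self):
        frame = pd.DataFrame(
            {"subject": list("abc"), "group": ["PR", "PR", "AR"], "value": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(DesignError, match="AR"):
            OneWayAnova(frame)


class TestBonferroni:
    def test_simple_multiplication(self):
        assert bonferroni_adjust([0.01], 3)[0] == pytest.approx(0.03)

    def test_capped_at_one(self):
        assert bonferroni_adjust([0.5], 3)[0] == 1.0

    def test_order_preserving(self, rng):
        p = np.sort(rng.uniform(size=10))
        adj = bonferroni_adjust(p, 4)
        assert np.all(np.diff(adj) >= 0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ConfigurationError):
            bonferroni_adjust([1.2], 2)

    def test_pairwise_uses_pooled_error_and_adjusts(self, rng):
        frame = pd.DataFrame(
            {
                "group": np.repeat(["PR", "AR", "VR"], 10),
                "value": np.concatenate(
                    [rng.normal(0, 1, 10), rng.normal(2, 1, 10), rng.normal(2, 1, 10)]
                ),
            }
        )
        out = pairwise_bonferroni(frame)
        assert len(out) == 3
        assert np.all(out["p_bonferroni"] >= out["p_raw"])
        assert np.all(out["p_bonferroni"] <= 1.0)
        assert set(out["df"]) == {27}


class TestLeveneAndNormality:
    def test_unequal_variances_detected(self, rng):
        rejections = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            groups = [r.normal(0, 1, 50), r.normal(0, 10, 50), r.normal(0, 1, 50)]
            _, p = levene_test(groups)
            rejections += p < 0.05
        assert rejections > 90

    def test_null_p_values_roughly_uniform(self):
        ps = []
        for seed in range(300):
            r = np.random.default_rng(seed)
            groups = [r.normal(0, 1, 20), r.normal(1, 1, 20), r.normal(2, 1, 20)]
            ps.append(levene_test(groups)[1])
        ks = sp_stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_matches_scipy_directly(self, rng):
        groups = [rng.normal(0, s, 30) for s in (1.0, 1.5, 2.0)]
        stat, p = levene_test(groups)
        stat_sp, p_sp = sp_stats.levene(*groups, center="mean")
        assert stat == pytest.approx(stat_sp, rel=1e-12)
        assert p == pytest.approx(p_sp, rel=1e-12)

    def test_constant_groups_raise_not_nan(self):
        with pytest.raises(DataQualityError):
            levene_test([np.ones(5), np.full(5, 2.0)])

    def test_shapiro_null_rejection_rate(self):
        rejections = 0
        n_seeds = 300
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            res = normality_check(r.normal(size=21))
            rejections += not res.normal
        assert 0.02 <= rejections / n_seeds <= 0.08

    def test_shapiro_power_against_exponential(self):
        rejections = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            res = normality_check(r.exponential(size=50))
            rejections += not res.normal
        assert rejections > 80

    def test_constant_sample_rejected(self):
        with pytest.raises(DataQualityError):
            normality_check(np.ones(10))

    def test_qq_coordinates_shape(self, rng):
        res = normality_check(rng.normal(size=30))
        assert res.qq_theoretical.shape == res.qq_sample.shape == (30,)
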