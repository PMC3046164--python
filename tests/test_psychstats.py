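"""Scalar-variability diagnostics, per-subject regressions, repeated-measures
ANOVA and cross-condition agreement."""

import math

import numpy as np
import pandas as pd
import pytest

from numotion import (ObserverParams, condition_correlation,
                      per_subject_regression, rm_anova_2way,
                      scalar_variability_report, simulate_estimates)


def make_table(rows):
    return pd.DataFrame(rows, columns=["subject", "condition", "numerosity",
                                       "bar_height", "estimate", "trial"])


# ---------------------------------------------------------------------------
# scalar variability


class TestScalarVariability:
    def test_slope_near_one_for_constant_cv(self, default_table):
        rep = scalar_variability_report(default_table)
        for cond in ("first_order", "second_order"):
            assert 0.7 < rep.per_condition[cond].slope_log_se_log_mean < 1.3
            assert rep.per_condition[cond].r_log_se_log_mean > 0.5
        assert rep.mean_cv == pytest.approx(0.33, abs=0.06)

    def test_additive_constant_sd_noise_gives_flat_slope(self):
        """With constant-SD (non-scalar) noise, log SE is flat in log mean."""
        rng = np.random.default_rng(0)
        rows = []
        for s in range(1, 31):
            for phi in range(10, 31):
                for t in range(6):
                    est = phi + rng.normal(0, 2.0)
                    rows.append((s, "first_order", phi, 2.6,
                                 max(est, 1.0), t))
        rep = scalar_variability_report(make_table(rows))
        slope = rep.per_condition["first_order"].slope_log_se_log_mean
        assert abs(slope) < 0.45  # far from the scalar-variability slope of 1

    def test_noiseless_table_reports_degenerate(self):
        rows = [(s, "first_order", phi, 2.6, float(phi), t)
                for s in range(1, 4) for phi in range(10, 31)
                for t in range(3)]
        rep = scalar_variability_report(make_table(rows))
        assert rep.per_condition["first_order"].degenerate
        assert math.isnan(rep.per_condition["first_order"]
                          .slope_log_se_log_mean)

    def test_single_observation_cells_warned(self):
        rows = [(s, "first_order", phi, 2.6, float(phi + s), 0)
                for s in range(1, 6) for phi in range(10, 31)]
        with pytest.warns(UserWarning, match="single observation"):
            scalar_variability_report(make_table(rows))

    def test_bias_table_has_bonferroni_column(self, default_table):
        rep = scalar_variability_report(default_table)
        assert {"condition", "numerosity", "bias", "t", "p",
                "p_bonferroni"} <= set(rep.bias.columns)
        ok = rep.bias.dropna()
        assert (ok["p_bonferroni"] >= ok["p"] - 1e-12).all()
        assert len(rep.bias) == 42


# ---------------------------------------------------------------------------
# per-subject regression


class TestPerSubjectRegression:
    def _table(self, estimates, numerosities, heights, subject=1,
               condition="first_order"):
        return make_table([
            (subject, condition, n, h, e, i)
            for i, (n, h, e) in enumerate(zip(numerosities, heights,
                                              estimates))])

    def test_perfect_numerosity_predictor(self, rng):
        nums = np.repeat(np.arange(10, 31), 6)
        heights = rng.uniform(2.1, 3.1, nums.size)
        table = self._table(nums.astype(float), nums, heights)
        res = per_subject_regression(table, 1, "first_order")
        assert res.coef_numerosity == pytest.approx(1.0, abs=0.02)
        assert res.coef_height == pytest.approx(0.0, abs=0.05)
        assert res.adj_r_squared == pytest.approx(1.0, abs=0.01)

    def test_pure_noise_gives_null_adjusted_r2(self):
        vals = []
        for seed in range(200):
            rg = np.random.default_rng(seed)
            nums = np.repeat(np.arange(10, 31), 6)
            heights = rg.uniform(2.1, 3.1, nums.size)
            ests = rg.uniform(5, 40, nums.size)
            res = per_subject_regression(
                self._table(ests, nums, heights), 1, "first_order")
            vals.append(res.adj_r_squared)
        # adjusted R^2 is unbiased near 0 under the null
        assert abs(np.mean(vals)) < 0.01

    def test_recovers_known_standardized_effects(self):
        """126 rows (the per-condition trial count), true standardized
        effects 0.8 on numerosity and 0 on height."""
        rg = np.random.default_rng(3)
        nums = np.repeat(np.arange(10, 31), 6).astype(float)
        heights = rg.uniform(2.08, 3.12, nums.size)
        z = np.log(nums)
        z = (z - z.mean()) / z.std(ddof=1)
        beta = 0.8
        noise_sd = math.sqrt(1 - beta ** 2)
        y = beta * z + rg.normal(0, noise_sd, nums.size)
        ests = np.exp(y * 0.3 + 3.0)  # any affine map of log estimate
        res = per_subject_regression(self._table(ests, nums, heights), 1,
                                     "first_order")
        se_n = abs(res.coef_numerosity / res.t_numerosity)
        se_h = abs(res.coef_height / res.t_height) \
            if res.t_height != 0 else 0.3
        assert abs(res.coef_numerosity - beta) < 3 * se_n
        assert abs(res.coef_height) < 3 * se_h
        assert res.df_resid == 123 and res.nobs == 126

    def test_standardized_coefs_invariant_to_predictor_rescaling(self, rng):
        nums = np.repeat(np.arange(10, 31), 6).astype(float)
        heights = rng.uniform(2.08, 3.12, nums.size)
        ests = nums ** 0.8 * np.exp(rng.normal(0, 0.2, nums.size))
        t1 = self._table(ests, nums, heights)
        # raw predictors rescaled by a positive constant (affine in logs)
        t2 = self._table(ests, nums * 13.7, heights * 0.21)
        r1 = per_subject_regression(t1, 1, "first_order")
        r2 = per_subject_regression(t2, 1, "first_order")
        assert r1.coef_numerosity == pytest.approx(r2.coef_numerosity,
                                                   abs=1e-10)
        assert r1.coef_height == pytest.approx(r2.coef_height, abs=1e-10)

    def test_constant_predictor_errors(self):
        nums = np.repeat(np.arange(10, 31), 6)
        table = self._table(nums.astype(float), nums,
                            np.full(nums.size, 2.6))
        with pytest.raises(ValueError, match="bar_height"):
            per_subject_regression(table, 1, "first_order")

    def test_too_few_rows_errors(self, default_table):
        with pytest.raises(ValueError, match=">= 10 rows"):
            per_subject_regression(default_table.head(5), 1, "first_order")


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def anova_ss_oracle(Y):
    """Brute-force sums of squares for a subjects x A x B within design,
    written with explicit loops (independent of the vectorized route)."""
    S, A, B = Y.shape
    grand = Y.mean()
    ss = {k: 0.0 for k in ("A", "B", "AB", "AS", "BS", "ABS")}
    mA = [Y[:, a, :].mean() for a in range(A)]
    mB = [Y[:, :, b].mean() for b in range(B)]
    mS = [Y[s].mean() for s in range(S)]
    for a in range(A):
        ss["A"] += S * B * (mA[a] - grand) ** 2
    for b in range(B):
        ss["B"] += S * A * (mB[b] - grand) ** 2
    for a in range(A):
        for b in range(B):
            m = Y[:, a, b].mean()
            ss["AB"] += S * (m - mA[a] - mB[b] + grand) ** 2
    for s in range(S):
        for a in range(A):
            m = Y[s, a, :].mean()
            ss["AS"] += B * (m - mS[s] - mA[a] + grand) ** 2
    for s in range(S):
        for b in range(B):
            m = Y[s, :, b].mean()
            ss["BS"] += A * (m - mS[s] - mB[b] + grand) ** 2
    for s in range(S):
        for a in range(A):
            for b in range(B):
                resid = (Y[s, a, b] - Y[s, a, :].mean() - Y[s, :, b].mean()
                         - Y[:, a, b].mean() + mS[s] + mA[a] + mB[b] - grand)
                ss["ABS"] += resid ** 2
    return ss


def table_from_cells(Y, nums=None):
    S, A, B = Y.shape
    conds = ["first_order", "second_order"][:A]
    nums = nums or list(range(10, 10 + B))
    rows = []
    for s in range(S):
        for a, cond in enumerate(conds):
            for b, num in enumerate(nums):
                rows.append((s + 1, cond, num, 2.6, math.exp(Y[s, a, b]), 0))
    return make_table(rows)


class TestRmAnova:
    def test_matches_hand_oracle_small_design(self):
        """3 subjects x 2 x 2, hand-enterable numbers; agreement to 6
        decimals with the loop-based sums-of-squares oracle."""
        Y = np.array([
            [[1.0, 2.0], [2.5, 3.0]],
            [[1.2, 1.9], [2.2, 3.3]],
            [[0.8, 2.2], [2.6, 2.9]],
        ])
        ss = anova_ss_oracle(Y)
        res = rm_anova_2way(table_from_cells(Y, nums=[10, 11]),
                            log_transform=True)
        F_A = (ss["A"] / 1) / (ss["AS"] / 2)
        F_B = (ss["B"] / 1) / (ss["BS"] / 2)
        F_AB = (ss["AB"] / 1) / (ss["ABS"] / 2)
        assert res.order.F == pytest.approx(F_A, abs=1e-6)
        assert res.numerosity.F == pytest.approx(F_B, abs=1e-6)
        assert res.interaction.F == pytest.approx(F_AB, abs=1e-6)
        assert res.order.eta_sq_partial == pytest.approx(
            ss["A"] / (ss["A"] + ss["AS"]), abs=1e-6)

    def test_design_degrees_of_freedom(self, default_table):
        """11 subjects x 2 conditions x 21 numerosities -> (1,10) and
        (20,200)."""
        res = rm_anova_2way(default_table)
        assert (res.order.df_num, res.order.df_den) == (1, 10)
        assert (res.numerosity.df_num, res.numerosity.df_den) == (20, 200)
        assert (res.interaction.df_num, res.interaction.df_den) == (20, 200)
        for eff in (res.order, res.numerosity, res.interaction):
            assert eff.F >= 0
            assert 0 <= eff.eta_sq_partial <= 1

    def test_agrees_with_pingouin(self, default_table):
        """Independent cross-check against pingouin's two-way rm_anova."""
        pg = pytest.importorskip("pingouin")
        cell = default_table.groupby(
            ["subject", "condition", "numerosity"])["estimate"].mean() \
            .reset_index()
        cell["log_est"] = np.log(cell["estimate"])
        aov = pg.rm_anova(data=cell, dv="log_est",
                          within=["condition", "numerosity"],
                          subject="subject", detailed=True)
        res = rm_anova_2way(default_table)
        by_source = {row["Source"]: row for _, row in aov.iterrows()}
        assert res.order.F == pytest.approx(by_source["condition"]["F"],
                                            rel=1e-6)
        assert res.numerosity.F == pytest.approx(
            by_source["numerosity"]["F"], rel=1e-6)
        inter = [v for k, v in by_source.items() if "*" in k][0]
        assert res.interaction.F == pytest.approx(inter["F"], rel=1e-6)

    def test_null_calibration(self):
        """No-effect data: mean F near 1 and type-I rate near alpha."""
        n_seeds = 300
        rejections = {"order": 0, "numerosity": 0, "interaction": 0}
        Fs = {k: [] for k in rejections}
        for seed in range(n_seeds):
            rg = np.random.default_rng(seed)
            Y = rg.normal(0, 1, size=(6, 2, 5))
            res = rm_anova_2way(table_from_cells(Y))
            for k in rejections:
                eff = getattr(res, {"order": "order",
                                    "numerosity": "numerosity",
                                    "interaction": "interaction"}[k])
                Fs[k].append(eff.F)
                rejections[k] += eff.p < 0.05
        se_rate = math.sqrt(0.05 * 0.95 / n_seeds)
        df_den = {"order": 5, "numerosity": 20, "interaction": 20}
        for k in rejections:
            # a central F(d1, d2) has mean d2/(d2-2), near 1
            expected = df_den[k] / (df_den[k] - 2)
            se = np.std(Fs[k]) / math.sqrt(n_seeds)
            assert abs(np.mean(Fs[k]) - expected) < 3 * se
            assert abs(rejections[k] / n_seeds - 0.05) < 3 * se_rate

    def test_pure_gain_gives_order_effect_without_interaction(self):
        params = ObserverParams(
            condition_gain={"first_order": 1.2, "second_order": 1.0},
            cv=0.2, round_responses=False)
        table = simulate_estimates(range(10, 31), 11, 6, params, seed=2)
        res = rm_anova_2way(table)
        assert res.order.F > 10
        assert res.interaction.F < 2.5

    def test_missing_cells_error(self, default_table):
        broken = default_table[~((default_table["subject"] == 3)
                                 & (default_table["numerosity"] == 17))]
        with pytest.raises(ValueError, match="missing"):
            rm_anova_2way(broken)


# ---------------------------------------------------------------------------
# cross-condition agreement


class TestConditionCorrelation:
    def test_identical_conditions_give_r_one(self):
        rows = []
        for phi in range(10, 31):
            for cond in ("first_order", "second_order"):
                for t in range(6):
                    rows.append((1, cond, phi, 2.6, float(phi + t), t))
        assert condition_correlation(make_table(rows), 1) == \
            pytest.approx(1.0)

    def test_independent_noise_averages_to_zero(self):
        vals = []
        for seed in range(300):
            rg = np.random.default_rng(seed)
            rows = [(1, cond, phi, 2.6, float(rg.uniform(5, 40)), t)
                    for cond in ("first_order", "second_order")
                    for phi in range(10, 31) for t in range(2)]
            vals.append(condition_correlation(make_table(rows), 1))
        assert abs(np.mean(vals)) < 3 * np.std(vals) / math.sqrt(len(vals))

    def test_shared_power_law_gives_positive_r(self):
        vals = []
        for seed in range(30):
            table = simulate_estimates(range(10, 31), 1, 6,
                                       ObserverParams(), seed=seed)
            vals.append(condition_correlation(table, 1))
        assert np.mean(vals) > 0.5

    def test_zero_variance_reported_as_nan(self):
        rows = [(1, cond, phi, 2.6, 20.0 if cond == "first_order"
                 else float(phi), t)
                for cond in ("first_order", "second_order")
                for phi in range(10, 31) for t in range(2)]
        with pytest.warns(UserWarning, match="zero variance"):
            r = condition_correlation(make_table(rows), 1)
        assert math.isnan(r)
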