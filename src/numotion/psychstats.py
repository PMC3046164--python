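"""Analysis chain for numerosity-estimate tables.

Four stages, all pure functions of a tidy estimate table
(subject, condition, numerosity, bar_height, estimate, trial):

* scalar-variability diagnostics — does the SD of estimates grow in
  proportion to their mean (slope of log SE on log mean near 1, CV flat in
  the mean)?
* per-subject multiple regression of log estimate on log numerosity and
  log mean bar height (standardized coefficients);
* classical two-way within-subjects ANOVA (motion order x numerosity) on
  log cell means, each effect tested against its subject-interaction error
  term, with partial eta squared;
* per-subject Pearson correlation between the two conditions' mean
  estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# scalar variability


@dataclass(frozen=True)
class ConditionScalarVar:
    """Scalar-variability diagnostics for one condition."""

    slope_log_se_log_mean: float
    r_log_se_log_mean: float
    adj_r2_se_vs_mean: float
    degenerate: bool = False


@dataclass(frozen=True)
class ScalarVarReport:
    """``cv_vs_mean_r2`` regresses each (subject, condition, numerosity)
    cell's CV on the across-subject mean estimate of its cell, which does
    not share the cell's own sampling noise; ``cv_vs_cell_mean_r2`` uses
    the cell's own mean as regressor and is inflated by the small-sample
    correlation between a cell's sample CV and sample mean."""

    per_condition: dict
    cv_vs_mean_r2: float
    cv_vs_cell_mean_r2: float
    mean_cv: float
    bias: pd.DataFrame  # per (condition, numerosity): bias, t, p, p_bonferroni


def _adj_r2(y: np.ndarray, x: np.ndarray) -> float:
    import statsmodels.api as sm
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return float(res.rsquared_adj)


def scalar_variability_report(table: pd.DataFrame,
                              se_convention: str = "between_subjects"
                              ) -> ScalarVarReport:
    """Diagnose scalar variability in an estimate table.

    Group-level means and SEs per (condition, numerosity) use, by default,
    the between-subject convention: SE = SD of the subjects' per-cell means
    / sqrt(S).  With ``se_convention="pooled"`` the SE is instead the SD of
    all raw estimates in the (condition, numerosity) cell divided by the
    square root of their count.
    CVs (SD/mean over the repetitions of one cell) are computed per
    (subject, condition, numerosity) and pooled.  Cells with a single
    observation are excluded with a warning; an all-zero-SE (noiseless)
    condition is reported as a degenerate fit rather than an error.
    """
    counts = table.groupby(["subject", "condition", "numerosity"])[
        "estimate"].count()
    if (counts < 2).any():
        bad = counts[counts < 2]
        warnings.warn(
            f"excluding {len(bad)} cell(s) with a single observation from "
            "the CV computation", stacklevel=2)
    # per-subject cell means and CVs
    cell = table.groupby(["subject", "condition", "numerosity"])["estimate"] \
        .agg(["mean", "std", "count"]).reset_index()
    cv_cells = cell[cell["count"] >= 2].copy()
    cv_cells["cv"] = cv_cells["std"] / cv_cells["mean"]

    if se_convention not in ("between_subjects", "pooled"):
        raise ValueError(f"unknown se_convention: {se_convention}")
    per_condition = {}
    for cond, sub in cell.groupby("condition"):
        if se_convention == "between_subjects":
            # across-subject mean and SE per numerosity
            g = sub.groupby("numerosity")["mean"].agg(["mean", "std",
                                                       "count"])
        else:
            raw = table[table["condition"] == cond]
            g = raw.groupby("numerosity")["estimate"].agg(["mean", "std",
                                                           "count"])
        mean_est = g["mean"].to_numpy()
        se = (g["std"] / np.sqrt(g["count"])).to_numpy()
        pos = se > 0
        if pos.sum() < 2:
            per_condition[cond] = ConditionScalarVar(
                slope_log_se_log_mean=float("nan"),
                r_log_se_log_mean=float("nan"),
                adj_r2_se_vs_mean=float("nan"), degenerate=True)
            continue
        slope, _, r, _, _ = stats.linregress(np.log(mean_est[pos]),
                                             np.log(se[pos]))
        per_condition[cond] = ConditionScalarVar(
            slope_log_se_log_mean=float(slope),
            r_log_se_log_mean=float(r),
            adj_r2_se_vs_mean=_adj_r2(se, mean_est),
        )

    if len(cv_cells) >= 3 and cv_cells["cv"].std() > 0:
        import statsmodels.api as sm
        group_mean = cv_cells.groupby(["condition", "numerosity"])["mean"] \
            .transform("mean").to_numpy()
        cv = cv_cells["cv"].to_numpy()
        cv_r2 = float(sm.OLS(cv, sm.add_constant(group_mean)).fit().rsquared)
        cv_cell_r2 = float(sm.OLS(
            cv, sm.add_constant(cv_cells["mean"].to_numpy())).fit().rsquared)
    else:
        cv_r2 = cv_cell_r2 = float("nan")
    mean_cv = float(cv_cells["cv"].mean()) if len(cv_cells) else float("nan")

    # per-numerosity bias tests across subjects (uncorrected + Bonferroni)
    bias_rows = []
    for (cond, num), sub in cell.groupby(["condition", "numerosity"]):
        diffs = sub["mean"].to_numpy() - num
        if len(diffs) >= 2 and np.std(diffs) > 0:
            t, p = stats.ttest_1samp(diffs, 0.0)
        else:
            t, p = float("nan"), float("nan")
        bias_rows.append((cond, num, float(np.mean(diffs)), float(t), float(p)))
    bias = pd.DataFrame(bias_rows, columns=["condition", "numerosity",
                                            "bias", "t", "p"])
    m = bias["p"].notna().sum()
    bias["p_bonferroni"] = np.minimum(bias["p"] * max(m, 1), 1.0)
    return ScalarVarReport(per_condition=per_condition, cv_vs_mean_r2=cv_r2,
                           cv_vs_cell_mean_r2=cv_cell_r2, mean_cv=mean_cv,
                           bias=bias)


# ---------------------------------------------------------------------------
# per-subject multiple regression


@dataclass(frozen=True)
class RegressionResult:
    """Multiple regression of log estimate on log numerosity and log bar
    height, with z-scored (standardized) coefficients."""

    adj_r_squared: float
    p_overall: float
    coef_numerosity: float
    t_numerosity: float
    p_numerosity: float
    coef_height: float
    t_height: float
    p_height: float
    df_resid: int
    nobs: int


def per_subject_regression(table: pd.DataFrame, subject, condition: str
                           ) -> RegressionResult:
    """Tables-style regression for one subject and condition.

    All three variables (log estimate, log numerosity, log mean bar height)
    are z-scored before the OLS fit, so the coefficients are standardized.
    Degrees of freedom are the standard nobs - 3 (two predictors plus
    intercept).
    """
    import statsmodels.api as sm

    sub = table[(table["subject"] == subject)
                & (table["condition"] == condition)]
    if len(sub) < 10:
        raise ValueError(
            f"need >= 10 rows for subject {subject!r}/{condition}, "
            f"got {len(sub)}")
    logs = {}
    for col in ("estimate", "numerosity", "bar_height"):
        v = np.log(sub[col].to_numpy(dtype=float))
        sd = v.std(ddof=1)
        if sd <= 1e-10 * max(1.0, abs(v.mean())):
            raise ValueError(f"constant predictor: {col}")
        logs[col] = (v - v.mean()) / sd
    X = sm.add_constant(np.column_stack([logs["numerosity"],
                                         logs["bar_height"]]))
    res = sm.OLS(logs["estimate"], X).fit()
    return RegressionResult(
        adj_r_squared=float(res.rsquared_adj),
        p_overall=float(res.f_pvalue),
        coef_numerosity=float(res.params[1]),
        t_numerosity=float(res.tvalues[1]),
        p_numerosity=float(res.pvalues[1]),
        coef_height=float(res.params[2]),
        t_height=float(res.tvalues[2]),
        p_height=float(res.pvalues[2]),
        df_resid=int(res.df_resid),
        nobs=int(res.nobs),
    )


# ---------------------------------------------------------------------------
# two-way repeated-measures ANOVA


@dataclass(frozen=True)
class AnovaEffect:
    F: float
    df_num: int
    df_den: int
    p: float
    eta_sq_partial: float
    ss_effect: float
    ss_error: float


@dataclass(frozen=True)
class AnovaResult:
    """Within-subjects 2-way ANOVA: order, numerosity, order x numerosity."""

    order: AnovaEffect
    numerosity: AnovaEffect
    interaction: AnovaEffect

    def to_frame(self) -> pd.DataFrame:
        rows = {name: vars(getattr(self, name))
                for name in ("order", "numerosity", "interaction")}
        return pd.DataFrame(rows).T


def rm_anova_2way(table: pd.DataFrame, log_transform: bool = True
                  ) -> AnovaResult:
    """Classical two-way within-subjects ANOVA on (log) cell means.

    Repetitions are collapsed to one mean per (subject, condition,
    numerosity) cell first — with S subjects, 2 conditions and K
    numerosities the dfs are (1, S-1) for condition and (K-1, (K-1)(S-1))
    for numerosity and the interaction.  Each effect is tested against its
    own subject-by-effect interaction mean square.  No sphericity
    correction is applied.  Partial eta squared is
    SS_effect / (SS_effect + SS_error).

    Raises ``ValueError`` listing any missing (subject, condition,
    numerosity) cells.
    """
    cell = table.groupby(["subject", "condition", "numerosity"],
                         sort=True)["estimate"].mean()
    if log_transform:
        cell = np.log(cell)
    subjects_all = sorted(table["subject"].unique())
    conds_all = sorted(table["condition"].unique())
    nums_all = sorted(table["numerosity"].unique())
    full = pd.MultiIndex.from_product(
        [subjects_all, conds_all, nums_all],
        names=["subject", "condition", "numerosity"])
    missing = full.difference(cell.index)
    if len(missing):
        raise ValueError(
            "incomplete design; missing (subject, condition, numerosity) "
            "cells: " + "; ".join(map(str, missing.tolist()[:10])))
    wide = cell.unstack(["condition", "numerosity"])
    subjects = wide.index.to_numpy()
    conds = wide.columns.get_level_values(0).unique()
    nums = wide.columns.get_level_values(1).unique()
    S, A, B = len(subjects), len(conds), len(nums)
    # Y[s, a, b]
    Y = np.empty((S, A, B))
    for ai, a in enumerate(conds):
        for bi, b in enumerate(nums):
            Y[:, ai, bi] = wide[(a, b)].to_numpy()
    grand = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)
    m_ab = Y.mean(axis=0)

    ss_a = S * B * np.sum((m_a - grand) ** 2)
    ss_b = S * A * np.sum((m_b - grand) ** 2)
    ss_ab = S * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = B * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = A * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (Y - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :]
             - grand)
    ss_abs = np.sum(resid ** 2)

    def effect(ss_eff: float, df_eff: int, ss_err: float, df_err: int
               ) -> AnovaEffect:
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else float("inf")
        p = float(stats.f.sf(F, df_eff, df_err)) if np.isfinite(F) else 0.0
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        return AnovaEffect(F=float(F), df_num=df_eff, df_den=df_err, p=p,
                           eta_sq_partial=float(eta), ss_effect=float(ss_eff),
                           ss_error=float(ss_err))

    return AnovaResult(
        order=effect(ss_a, A - 1, ss_as, (A - 1) * (S - 1)),
        numerosity=effect(ss_b, B - 1, ss_bs, (B - 1) * (S - 1)),
        interaction=effect(ss_ab, (A - 1) * (B - 1), ss_abs,
                           (A - 1) * (B - 1) * (S - 1)),
    )


# ---------------------------------------------------------------------------
# cross-condition agreement


def condition_correlation(table: pd.DataFrame, subject) -> float:
    """Pearson r between one subject's per-numerosity mean estimates in the
    two conditions (repetitions averaged first).

    Returns NaN, with a warning, if either condition has zero variance.
    """
    sub = table[table["subject"] == subject]
    means = sub.groupby(["condition", "numerosity"])["estimate"].mean() \
        .unstack("condition")
    if means.isna().any().any() or means.shape[1] != 2:
        raise ValueError(f"subject {subject!r} lacks complete data in both "
                         "conditions")
    a, b = (means.iloc[:, 0].to_numpy(), means.iloc[:, 1].to_numpy())
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn(f"zero variance for subject {subject!r}; correlation "
                      "undefined", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


# ---------------------------------------------------------------------------
# report assembly / plotting


def analyze_table(table: pd.DataFrame) -> dict:
    """Run the full chain on a complete-design table and return a
    JSON-serializable report."""
    report: dict = {}
    sv = scalar_variability_report(table)
    report["scalar_variability"] = {
        "per_condition": {c: vars(v) for c, v in sv.per_condition.items()},
        "cv_vs_mean_r2": sv.cv_vs_mean_r2,
        "cv_vs_cell_mean_r2": sv.cv_vs_cell_mean_r2,
        "mean_cv": sv.mean_cv,
    }
    anova = rm_anova_2way(table)
    report["anova"] = {k: vars(getattr(anova, k))
                       for k in ("order", "numerosity", "interaction")}
    regs = {}
    corr = {}
    for s in sorted(table["subject"].unique()):
        regs[str(s)] = {c: vars(per_subject_regression(table, s, c))
                        for c in sorted(table["condition"].unique())}
        corr[str(s)] = condition_correlation(table, s)
    report["per_subject_regression"] = regs
    report["condition_correlation"] = corr
    return report


def plot_estimates(table: pd.DataFrame, out_path=None):
    """Linear-linear and log-log plots of mean estimate vs numerosity per
    condition, with between-subject error bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cell = table.groupby(["subject", "condition", "numerosity"])[
        "estimate"].mean().reset_index()
    fig, axes = plt.subplots(2, 1, figsize=(6, 8))
    for cond, marker, fill in (("first_order", "o", "black"),
                               ("second_order", "o", "none")):
        sub = cell[cell["condition"] == cond]
        g = sub.groupby("numerosity")["estimate"].agg(["mean", "std", "count"])
        se = g["std"] / np.sqrt(g["count"])
        for ax in axes:
            ax.errorbar(g.index, g["mean"], yerr=se, fmt=marker,
                        markerfacecolor=fill, color="black", label=cond,
                        capsize=2)
    axes[1].set_xscale("log")
    axes[1].set_yscale("log")
    for ax in axes:
        ax.set_xlabel("numerosity")
        ax.set_ylabel("estimated numerosity")
        ax.legend()
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
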