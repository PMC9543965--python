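"""Group statistics: case–control tests, correlations, change models, remission.

Case–control comparisons use independent t-tests (Welch by default) for
variables flagged parametric, Mann–Whitney U otherwise and chi-square for
categorical variables, with Bonferroni adjustment (raw p multiplied by the
declared comparison count, capped at 1).  Pre/post intervention effects are
assessed per arm with change-score regression: the change Δy is regressed on
an intercept plus the model's covariates, and the intercept's two-sided test
is reported.  Model 1 (intercept only) is algebraically the paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .cohort import BASELINE, FOLLOW_UP, CohortTable


@dataclass
class ComparisonResult:
    """Outcome of one per-variable test."""

    variable: str
    test: str
    group_summaries: Dict[str, str]
    statistic: float
    p_raw: float
    p_adjusted: float
    m_comparisons: int
    covariates: List[str] = field(default_factory=list)

    def to_row(self) -> dict:
        row = {
            "variable": self.variable,
            "test": self.test,
            "statistic": self.statistic,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "m_comparisons": self.m_comparisons,
            "covariates": "+".join(self.covariates),
        }
        row.update({f"summary_{g}": s for g, s in self.group_summaries.items()})
        return row


def bonferroni(p_raw: float, m: int) -> float:
    """Adjusted p = min(1, raw p × m)."""
    if m < 1:
        raise ValueError("comparison count m must be >= 1")
    return min(1.0, float(p_raw) * m)


def assess_normality(values, alpha: float = 0.05) -> str:
    """Shapiro–Wilk flag: 'parametric' if normality is not rejected at alpha.

    A deterministic surrogate for visual histogram/Q-Q assessment; the flag
    can be overridden per variable in configuration.
    """
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if v.size < 3:
        raise ValueError(f"need >= 3 non-missing values, got {v.size}")
    if np.ptp(v) == 0:
        raise ValueError("constant values: normality is undefined")
    _, p = sps.shapiro(v)
    return "parametric" if p >= alpha else "nonparametric"


def _summarize(values: np.ndarray, flag: str) -> str:
    if flag == "parametric":
        return f"{np.mean(values):.2f} ± {np.std(values, ddof=1):.2f}"
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{med:.2f} ({q3 - q1:.2f})"


def compare_case_control(
    table: CohortTable,
    variables: Optional[Sequence[str]] = None,
    m: Optional[int] = None,
    flags: Optional[Dict[str, str]] = None,
    equal_var: bool = False,
    group_col: str = "group",
) -> List[ComparisonResult]:
    """Two-group test per variable with Bonferroni adjustment over the run.

    Continuous variables are tested with Welch's t (``equal_var=True`` for
    the pooled form) when flagged parametric, Mann–Whitney U otherwise;
    categorical variables with a chi-square test on the 2×c contingency
    table.  Variables with fewer than 2 observations in either group are
    skipped with a warning entry.  ``m`` defaults to the number of variables
    tested.
    """
    groups = [g for g in table.data[group_col].dropna().unique()]
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    if variables is None:
        variables = table.variables
    m_eff = m if m is not None else len(variables)
    flags = flags or {}

    results: List[ComparisonResult] = []
    for var in variables:
        fam = table.schema.get(var, {}).get("family", "normal")
        a = table.data.loc[table.data[group_col] == groups[0], var].dropna().to_numpy()
        b = table.data.loc[table.data[group_col] == groups[1], var].dropna().to_numpy()

        if fam == "bernoulli":
            obs = np.array(
                [
                    [np.sum(a == 1), np.sum(a == 0)],
                    [np.sum(b == 1), np.sum(b == 0)],
                ]
            )
            if (obs.sum(axis=0) == 0).any():
                results.append(
                    ComparisonResult(var, "skipped (degenerate)", {}, np.nan, np.nan, np.nan, m_eff)
                )
                continue
            stat, p, _, _ = sps.chi2_contingency(obs, correction=False)
            summaries = {
                str(groups[0]): f"{int(obs[0, 0])} ({100 * obs[0, 0] / len(a):.0f})",
                str(groups[1]): f"{int(obs[1, 0])} ({100 * obs[1, 0] / len(b):.0f})",
            }
            results.append(
                ComparisonResult(
                    var, "chi-square", summaries, float(stat), float(p), bonferroni(p, m_eff), m_eff
                )
            )
            continue

        if len(a) < 2 or len(b) < 2:
            results.append(
                ComparisonResult(var, "skipped (n<2)", {}, np.nan, np.nan, np.nan, m_eff)
            )
            continue

        flag = flags.get(var)
        if flag is None:
            try:
                flag = (
                    "parametric"
                    if assess_normality(a) == "parametric" and assess_normality(b) == "parametric"
                    else "nonparametric"
                )
            except ValueError:
                flag = "nonparametric"

        if flag == "parametric":
            stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
            test = "t (pooled)" if equal_var else "t (Welch)"
        else:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            test = "Mann-Whitney U"
        summaries = {
            str(groups[0]): _summarize(a, flag),
            str(groups[1]): _summarize(b, flag),
        }
        results.append(
            ComparisonResult(
                var, test, summaries, float(stat), float(p), bonferroni(p, m_eff), m_eff
            )
        )
    return results


def correlation_matrix(
    table: CohortTable,
    set_a: Sequence[str],
    set_b: Sequence[str],
    group: str,
    group_col: str = "group",
):
    """Pearson r and two-sided p for every (set_a, set_b) pair within a group.

    Uses pairwise-complete observations; pairs with fewer than 3 complete
    observations or degenerate variance are flagged NaN.
    """
    sub = table.data.loc[table.data[group_col] == group]
    r = pd.DataFrame(index=list(set_a), columns=list(set_b), dtype=float)
    p = pd.DataFrame(index=list(set_a), columns=list(set_b), dtype=float)
    for va in set_a:
        for vb in set_b:
            cols = [va] if va == vb else [va, vb]
            pair = sub[cols].dropna()
            x, y = pair[va].to_numpy(), pair[vb].to_numpy()
            if len(pair) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                r.loc[va, vb] = np.nan
                p.loc[va, vb] = np.nan
                continue
            res = sps.pearsonr(x, y)
            r.loc[va, vb] = res.statistic
            p.loc[va, vb] = res.pvalue
    return r, p


CHANGE_MODEL_COVARIATES = {
    1: [],
    2: ["weight_change", "weight_baseline"],
    3: ["hba1c_change", "hba1c_baseline"],
}


def _paired_wide(table: CohortTable, variable: str, arm: Optional[str]) -> pd.DataFrame:
    df = table.data
    if arm is not None:
        df = df.loc[df["arm"] == arm]
    wide = df.pivot(index="subject_id", columns="timepoint", values=variable)
    if BASELINE not in wide.columns or FOLLOW_UP not in wide.columns:
        raise ValueError(f"{variable}: need both baseline and follow-up rows")
    return wide.dropna()


def prepost_change_model(
    table: CohortTable,
    variable: str,
    model_id: int = 1,
    arm: Optional[str] = None,
    m: int = 1,
    weight_var: str = "weight",
    hba1c_var: str = "hba1c_mmol_mol",
    log10_scale: Optional[bool] = None,
) -> ComparisonResult:
    """Within-arm pre/post change model for one variable.

    Regresses the change score Δy (follow-up − baseline, on the analysis
    scale: log10 for biomarkers) on an intercept plus the model's
    covariates — Model 1: none; Model 2: Δweight and baseline weight;
    Model 3: ΔHbA1c and baseline HbA1c — and reports the intercept's
    two-sided test against zero, Bonferroni-adjusted by ``m``.

    Covariates are mean-centered within the fitted sample so the intercept
    is the covariate-adjusted mean change (the adjusted time effect), not an
    extrapolation to covariate value zero.
    """
    if model_id not in CHANGE_MODEL_COVARIATES:
        raise ValueError(f"unknown model id {model_id}")
    if log10_scale is None:
        log10_scale = table.schema.get(variable, {}).get("family") == "log10normal"

    wide = _paired_wide(table, variable, arm)
    y_pre = wide[BASELINE].to_numpy(dtype=float)
    y_post = wide[FOLLOW_UP].to_numpy(dtype=float)
    if log10_scale:
        y_pre, y_post = np.log10(y_pre), np.log10(y_post)
    dy = y_post - y_pre

    covs = CHANGE_MODEL_COVARIATES[model_id]
    X = pd.DataFrame(index=wide.index)
    if model_id == 2:
        w = _paired_wide(table, weight_var, arm).loc[wide.index]
        X["weight_change"] = w[FOLLOW_UP] - w[BASELINE]
        X["weight_baseline"] = w[BASELINE]
    elif model_id == 3:
        h = _paired_wide(table, hba1c_var, arm).loc[wide.index]
        X["hba1c_change"] = h[FOLLOW_UP] - h[BASELINE]
        X["hba1c_baseline"] = h[BASELINE]

    n, n_cov = len(dy), len(covs)
    if n - n_cov - 1 < 1:
        raise ValueError(
            f"{variable}: {n} pairs cannot support model {model_id} "
            f"({n_cov} covariates)"
        )

    if n_cov:
        Xc = X.to_numpy(dtype=float)
        design = sm.add_constant(Xc - Xc.mean(axis=0))
    else:
        design = np.ones((n, 1))
    fit = sm.OLS(dy, design).fit()
    stat = float(fit.tvalues[0])
    p = float(fit.pvalues[0])
    if np.allclose(dy, 0):
        stat, p = 0.0, 1.0  # no change at all: degenerate SE, define exactly

    summaries = {
        "baseline": f"{np.mean(y_pre):.3f} ± {np.std(y_pre, ddof=1):.3f}",
        "follow_up": f"{np.mean(y_post):.3f} ± {np.std(y_post, ddof=1):.3f}",
        "change": f"{np.mean(dy):.3f}",
    }
    return ComparisonResult(
        variable=variable,
        test=f"change-model-{model_id}",
        group_summaries=summaries,
        statistic=stat,
        p_raw=p,
        p_adjusted=bonferroni(p, m),
        m_comparisons=m,
        covariates=list(covs),
    )


def classify_remission(fasting_glucose, hba1c_percent, on_glucose_lowering_meds):
    """Diabetes remission flag after intervention.

    True iff (fasting glucose < 7.0 mmol/L OR HbA1c < 6.5%) and the subject
    no longer requires glucose-lowering medication.  Returns None when both
    measures are missing (undetermined).  Accepts scalars or array-likes.
    """

    def _one(g, h, meds):
        g_miss = g is None or (isinstance(g, float) and np.isnan(g))
        h_miss = h is None or (isinstance(h, float) and np.isnan(h))
        if g_miss and h_miss:
            return None
        if bool(meds):
            return False
        below = (not g_miss and g < 7.0) or (not h_miss and h < 6.5)
        return bool(below)

    if np.isscalar(fasting_glucose) or fasting_glucose is None:
        return _one(fasting_glucose, hba1c_percent, on_glucose_lowering_meds)
    return [
        _one(g, h, m)
        for g, h, m in zip(fasting_glucose, hba1c_percent, on_glucose_lowering_meds)
    ]


def convert_hba1c(ifcc_mmol_per_mol, decimals: Optional[int] = None):
    """IFCC (mmol/mol) to NGSP (%) master equation: % = 0.09148·IFCC + 2.152."""
    value = 0.09148 * np.asarray(ifcc_mmol_per_mol, dtype=float) + 2.152
    if decimals is not None:
        value = np.round(value, decimals)
    return float(value) if value.ndim == 0 else value


def results_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Tidy one-row-per-test table for CSV export."""
    return pd.DataFrame([r.to_row() for r in results])
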