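"""Cohort statistics: group comparisons, univariate screen, backward
elimination, and paired pre/post contrasts.

The ladder mirrors a standard observational-study analysis: three-group
one-way ANOVA with Tukey HSD (chi-square for categorical variables),
per-candidate univariate linear regressions of the ALPS index with a
p < 0.2 screen, backward elimination at p-removal 0.1 with optional
forced adjustment covariates (crude / minimally adjusted / fully
adjusted model variants), and paired-samples t tests for within-arm
treatment change. No multiple-testing correction is applied across the
univariate screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "GroupComparisonResult",
    "UnivariateResult",
    "RegressionResult",
    "PairedResult",
    "compare_groups",
    "univariate_screen",
    "backward_select",
    "paired_prepost",
    "ADJUST_MODEL_I",
    "ADJUST_MODEL_II",
]

ADJUST_MODEL_I = ("gender", "age")
ADJUST_MODEL_II = ("gender", "age", "education", "moca", "mmse", "bai", "bdi", "psqi", "ess", "isi")

_COLLINEARITY_CONDITION_LIMIT = 1e8


@dataclass
class GroupComparisonResult:
    variable: str
    kind: str  # "anova" | "chi2"
    statistic: float
    p: float
    group_stats: dict  # group -> (mean, sd, n) for continuous; counts for categorical
    pairwise: dict = field(default_factory=dict)  # (g1, g2) -> Tukey-adjusted p


@dataclass
class UnivariateResult:
    variable: str
    beta: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    flagged: bool  # passes the p < p_screen gate for the multivariate stage


@dataclass
class RegressionResult:
    model_tag: str  # "crude" | "model_I" | "model_II" | custom
    params: dict  # term -> (beta, ci_low, ci_high, p)
    retained: list  # candidate terms surviving elimination
    adjusted_for: list
    trace: list  # [(removed term, p at removal), ...]
    n: int


@dataclass
class PairedResult:
    variable: str
    group: str
    n_pairs: int
    n_excluded: int
    mean_diff: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    degenerate: bool = False


def _numeric_frame(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Model frame with gender recoded as a 0/1 indicator (male = 0)."""
    df = table[columns].copy()
    if "gender" in columns:
        df["gender"] = (table["gender"].astype(str) == "female").astype(float)
    return df.astype(float)


def compare_groups(table: pd.DataFrame, variable: str, timepoint: str = "pre") -> GroupComparisonResult:
    """Three-group comparison at one timepoint.

    Continuous variables: one-way ANOVA F with Tukey HSD pairwise
    adjusted p-values. Categorical variables: Pearson chi-square on the
    group x level contingency table.
    """
    sub = table[table["timepoint"] == timepoint]
    groups = sorted(sub["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")

    if not pd.api.types.is_numeric_dtype(sub[variable]):
        contingency = pd.crosstab(sub["group"], sub[variable])
        chi2, p, _, _ = sps.chi2_contingency(contingency.to_numpy(), correction=False)
        counts = {g: contingency.loc[g].to_dict() for g in contingency.index}
        return GroupComparisonResult(variable, "chi2", float(chi2), float(p), counts)

    samples = {g: sub.loc[sub["group"] == g, variable].dropna().to_numpy(float) for g in groups}
    for g, x in samples.items():
        if x.size < 2:
            raise ValueError(f"group {g} has fewer than 2 observations of {variable}")
    f_stat, p = sps.f_oneway(*samples.values())
    stats_by_group = {g: (float(x.mean()), float(x.std(ddof=1)), int(x.size)) for g, x in samples.items()}

    values = np.concatenate(list(samples.values()))
    labels = np.concatenate([[g] * samples[g].size for g in groups])
    pairwise = {}
    if len(groups) >= 2 and np.ptp(values) > 0:
        tk = pairwise_tukeyhsd(values, labels)
        for (g1, g2), padj in zip(
            [(tk.groupsunique[i], tk.groupsunique[j]) for i, j in zip(*np.triu_indices(len(tk.groupsunique), 1))],
            tk.pvalues,
        ):
            pairwise[(str(g1), str(g2))] = float(padj)
    else:
        pairwise = {pair: 1.0 for pair in [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]}

    # identical groups give F = 0/0 in scipy; report the no-effect limit
    if not np.isfinite(f_stat):
        f_stat, p = 0.0, 1.0
    return GroupComparisonResult(variable, "anova", float(f_stat), float(p), stats_by_group, pairwise)


def _fit_ols(y: np.ndarray, X: pd.DataFrame) -> sm.regression.linear_model.RegressionResultsWrapper:
    design = sm.add_constant(X, has_constant="add")
    return sm.OLS(y, design).fit()


def univariate_screen(
    table: pd.DataFrame,
    outcome: str = "alps",
    candidates: list[str] | None = None,
    p_screen: float = 0.2,
    patients_only: bool = True,
    timepoint: str = "pre",
) -> list[UnivariateResult]:
    """One simple linear regression of the outcome per candidate.

    Restricted to patient rows (group != HC) at the given timepoint by
    default, matching a patients-only association analysis. Candidates
    with zero variance are skipped with a warning. Flagging at
    p < ``p_screen`` feeds the backward-elimination stage.
    """
    sub = table[table["timepoint"] == timepoint]
    if patients_only:
        sub = sub[sub["group"] != "HC"]
    if candidates is None:
        candidates = [c for c in sub.columns if c not in ("subject_id", "group", "timepoint", outcome, "alps_true")]

    results = []
    for cand in candidates:
        frame = _numeric_frame(sub, [cand]).join(sub[outcome].astype(float)).dropna()
        x = frame[cand].to_numpy()
        y = frame[outcome].to_numpy()
        if np.ptp(x) == 0:
            warnings.warn(f"candidate {cand!r} has zero variance; skipped", stacklevel=2)
            continue
        fit = _fit_ols(y, frame[[cand]])
        ci = fit.conf_int().loc[cand]
        p = float(fit.pvalues[cand])
        results.append(
            UnivariateResult(
                variable=cand,
                beta=float(fit.params[cand]),
                ci_low=float(ci[0]),
                ci_high=float(ci[1]),
                p=p,
                n=int(len(frame)),
                flagged=bool(p < p_screen),
            )
        )
    return results


def backward_select(
    table: pd.DataFrame,
    outcome: str = "alps",
    screened: list[str] | None = None,
    adjust: list[str] | tuple[str, ...] = (),
    p_removal: float = 0.1,
    model_tag: str = "crude",
    patients_only: bool = True,
    timepoint: str = "pre",
) -> RegressionResult:
    """Backward elimination at ``p_removal`` with forced adjustment terms.

    Starting from all screened candidates plus the adjustment set, the
    candidate with the largest p >= p_removal is dropped and the model
    refit until every remaining candidate has p < p_removal. Adjustment
    covariates are never eliminated. Ties in the maximal p (within
    1e-12) are broken by dropping the candidate declared later, making
    the procedure deterministic.
    """
    if not screened:
        raise ValueError("screened candidate list must be non-empty")
    adjust = list(adjust)
    overlap = set(adjust) & set(screened)
    if overlap:
        raise ValueError(f"terms cannot be both candidates and adjustments: {sorted(overlap)}")

    sub = table[table["timepoint"] == timepoint]
    if patients_only:
        sub = sub[sub["group"] != "HC"]
    terms = adjust + list(screened)
    frame = _numeric_frame(sub, terms).join(sub[outcome].astype(float)).dropna()
    n = len(frame)
    if n <= len(terms) + 2:
        raise ValueError(f"n = {n} too small for {len(terms)} predictors")

    X = frame[terms]
    std = X.std(ddof=0).replace(0.0, 1.0)
    cond = np.linalg.cond(sm.add_constant((X - X.mean()) / std, has_constant="add"))
    if cond > _COLLINEARITY_CONDITION_LIMIT:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ValueError(f"design is collinear (condition {cond:.2e}); most correlated columns: {worst}")

    y = frame[outcome].to_numpy()
    candidates = list(screened)
    trace: list[tuple[str, float]] = []
    while True:
        fit = _fit_ols(y, frame[adjust + candidates])
        pvals = {c: float(fit.pvalues[c]) for c in candidates}
        if not pvals:
            break
        worst_p = max(pvals.values())
        if worst_p < p_removal:
            break
        # tie-break: among candidates within 1e-12 of the max p, drop the
        # one declared last
        tied = [c for c in candidates if worst_p - pvals[c] <= 1e-12]
        drop = tied[-1]
        trace.append((drop, pvals[drop]))
        candidates.remove(drop)

    final_terms = adjust + candidates
    fit = _fit_ols(y, frame[final_terms]) if final_terms else _fit_ols(y, frame[[]])
    params = {}
    conf = fit.conf_int()
    for term in final_terms:
        params[term] = (
            float(fit.params[term]),
            float(conf.loc[term, 0]),
            float(conf.loc[term, 1]),
            float(fit.pvalues[term]),
        )
    return RegressionResult(
        model_tag=model_tag,
        params=params,
        retained=list(candidates),
        adjusted_for=adjust,
        trace=trace,
        n=n,
    )


def paired_prepost(table: pd.DataFrame, variable: str, group: str) -> PairedResult:
    """Paired-samples t test of post minus pre within one treatment arm.

    Subjects missing either timepoint are excluded and counted. All
    differences identical is a degenerate case: reported with t = 0,
    p = 1 when the common difference is zero, otherwise with the exact
    mean difference flagged as degenerate.
    """
    sub = table[table["group"] == group]
    wide = sub.pivot_table(index="subject_id", columns="timepoint", values=variable, aggfunc="first")
    if "pre" not in wide.columns or "post" not in wide.columns:
        raise ValueError(f"group {group} lacks both timepoints for {variable}")
    complete = wide.dropna(subset=["pre", "post"])
    n_excluded = int(len(wide) - len(complete))
    diffs = (complete["post"] - complete["pre"]).to_numpy(float)
    n = diffs.size
    if n < 2:
        raise ValueError("fewer than 2 complete pre/post pairs")

    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd <= 1e-12 * max(1.0, abs(mean_diff)):
        if mean_diff == 0.0:
            return PairedResult(variable, group, n, n_excluded, 0.0, 0.0, 0.0, 0.0, 1.0, degenerate=True)
        t = np.inf if mean_diff > 0 else -np.inf
        return PairedResult(variable, group, n, n_excluded, mean_diff, mean_diff, mean_diff, float(t), 0.0, degenerate=True)

    t, p = sps.ttest_rel(complete["post"], complete["pre"])
    half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return PairedResult(
        variable, group, n, n_excluded, mean_diff, mean_diff - half, mean_diff + half, float(t), float(p)
    )
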