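"""Cohort-level statistics: ANCOVA, LSD post hocs, Cohen's d, rank tests.

Group differences in the waveform features are tested with an analysis of
covariance (OLS with a group factor plus age, gender and task-performance
covariates; type-III factor F, equal here to the nested-model comparison F
since the factor is the only categorical term).  Pairwise contrasts use
Fisher's LSD (unadjusted t tests on covariate-adjusted means, pooled
residual variance) with Cohen's d from the raw group values.  Demographic
variables are screened for normality and compared with Kruskal-Wallis /
Mann-Whitney U / chi-squared tests; feature-to-clinical correlations use
Spearman's rho.  Two-tailed alpha = 0.05 throughout.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors

logger = logging.getLogger(__name__)

__all__ = [
    "AncovaResult",
    "PosthocResult",
    "DemographicTable",
    "ancova",
    "lsd_posthoc",
    "cohens_d",
    "replicate_cohens_d",
    "spearman_correlations",
    "demographic_table",
    "fh_grouping",
    "ancova_null_rejection_rate",
    "nested_f",
]

DEFAULT_COVARIATES = ("age_years", "gender", "vft_performance")

_FH_LEVEL_COL = {
    "any": "fh_any_psychiatric",
    "major": "fh_major_psychiatric",
    "same": "fh_same_disorder",
}


# ---------------------------------------------------------------------------
# effect size
# ---------------------------------------------------------------------------

def cohens_d(x, y) -> float:
    """Pooled-SD standardized mean difference, mean(x) - mean(y).

    Pooled SD = sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)) with sample
    variances; computed from raw group values (not covariate-adjusted).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each sample needs n >= 2, got {n1} and {n2}")
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0.0:
        raise ValueError("pooled SD is zero; Cohen's d undefined")
    return float((x.mean() - y.mean()) / math.sqrt(pooled_var))


def replicate_cohens_d(
    delta: float,
    n1: int,
    n2: int,
    n_rep: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Mean and Monte-Carlo SE of Cohen's d over ``n_rep`` two-group draws.

    Group 1 ~ N(delta, 1) of size ``n1``, group 2 ~ N(0, 1) of size ``n2``;
    d is group 1 minus group 2, so its expectation is approximately ``delta``
    (up to the small-sample bias of the plug-in estimator).
    """
    ds = np.empty(n_rep)
    for i in range(n_rep):
        ds[i] = cohens_d(rng.normal(delta, 1.0, n1), rng.normal(0.0, 1.0, n2))
    return float(ds.mean()), float(ds.std(ddof=1) / math.sqrt(n_rep))


# ---------------------------------------------------------------------------
# ANCOVA
# ---------------------------------------------------------------------------

@dataclass
class AncovaResult:
    dependent: str
    factor_levels: list[str]
    F: float
    df_num: int
    df_den: int
    p: float
    covariates: list[str]
    n_used: int
    n_dropped: int
    #: fitted OLS results (treatment coding) kept for post hoc contrasts
    model: object = field(repr=False, default=None)
    #: per-level raw dependent values, for effect sizes
    group_values: dict = field(repr=False, default_factory=dict)


@dataclass
class PosthocResult:
    pair: tuple[str, str]
    adjusted_mean_diff: float
    lsd_p: float
    cohens_d: float


def _merge(features: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    data = features.merge(subjects, left_on="subject_id", right_on="id",
                          how="inner", suffixes=("", "_subj"))
    if len(data) < len(features):
        raise ValueError("some feature rows have no matching subject")
    return data


def _encode_covariates(data: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        col = data[cov]
        if cov == "gender":
            col = col.map({"female": 0.0, "male": 1.0})
        cols[cov] = pd.to_numeric(col)
    return pd.DataFrame(cols, index=data.index)


def ancova(
    features: pd.DataFrame,
    subjects: pd.DataFrame,
    dependent: str = "integral_value",
    grouping: str | pd.Series = "diagnosis",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> AncovaResult:
    """Covariate-adjusted omnibus group comparison of one feature.

    ``grouping`` is either a column of the subject table or a Series indexed
    by subject id (NaN labels excluded) -- the latter supports derived
    groupings such as HC / FH+ / FH-.  QC-failing rows and rows with missing
    dependent or covariate values are dropped (count logged and reported).
    Raises on groups with fewer than 2 usable subjects.
    """
    data = _merge(features, subjects)
    if isinstance(grouping, str):
        data["_group"] = data[grouping]
    else:
        data["_group"] = data["id"].map(grouping)

    n_start = len(data)
    data = data[data["qc_pass"].astype(bool)]
    data = data.dropna(subset=["_group", dependent])
    cov = _encode_covariates(data, covariates)
    keep = cov.notna().all(axis=1)
    data, cov = data[keep], cov[keep]
    n_dropped = n_start - len(data)
    if n_dropped:
        logger.info("ancova(%s): dropped %d of %d rows (QC fail or missing)",
                    dependent, n_dropped, n_start)

    levels = sorted(data["_group"].unique())
    counts = data["_group"].value_counts()
    small = [lv for lv in levels if counts.get(lv, 0) < 2]
    if len(levels) < 2 or small:
        raise ValueError(f"degenerate design: groups {small or levels} "
                         "have fewer than 2 subjects")

    y = data[dependent].to_numpy(dtype=float)
    dummies = pd.get_dummies(data["_group"], dtype=float).reindex(
        columns=levels).iloc[:, 1:]                      # treatment coding
    x_full = sm.add_constant(pd.concat([dummies, cov], axis=1), has_constant="add")
    x_red = sm.add_constant(cov, has_constant="add")
    fit_full = sm.OLS(y, np.asarray(x_full)).fit()
    fit_red = sm.OLS(y, np.asarray(x_red)).fit()
    f_stat, p_val, df_num = fit_full.compare_f_test(fit_red)

    group_values = {lv: data.loc[data["_group"] == lv, dependent]
                    .to_numpy(dtype=float) for lv in levels}
    return AncovaResult(
        dependent=dependent,
        factor_levels=levels,
        F=float(f_stat),
        df_num=int(df_num),
        df_den=int(fit_full.df_resid),
        p=float(p_val),
        covariates=list(covariates),
        n_used=len(data),
        n_dropped=int(n_dropped),
        model=fit_full,
        group_values=group_values,
    )


def lsd_posthoc(
    result: AncovaResult,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[PosthocResult]:
    """Fisher's LSD pairwise contrasts after a fitted ANCOVA.

    Each contrast is an unadjusted t test on the difference of
    covariate-adjusted group means, using the omnibus model's residual
    variance and df; no multiplicity correction.  Cohen's d accompanies each
    pair, computed from the raw (unadjusted) group values.
    """
    levels = result.factor_levels
    if pairs is None:
        pairs = list(itertools.combinations(levels, 2))
    out = []
    k = len(levels)
    n_params = len(result.model.params)
    for a, b in pairs:
        if a not in levels or b not in levels:
            raise ValueError(f"unknown group level in pair ({a!r}, {b!r})")
        # params: [const, level2..levelk effects (vs level1), covariates]
        contrast = np.zeros(n_params)
        if a != levels[0]:
            contrast[levels.index(a)] = 1.0
        if b != levels[0]:
            contrast[levels.index(b)] = -1.0
        tt = result.model.t_test(contrast)
        out.append(PosthocResult(
            pair=(a, b),
            adjusted_mean_diff=float(np.atleast_1d(tt.effect)[0]),
            lsd_p=float(np.atleast_1d(tt.pvalue).ravel()[0]),
            cohens_d=cohens_d(result.group_values[a], result.group_values[b]),
        ))
    return out


def fh_grouping(
    subjects: pd.DataFrame,
    level: str = "any",
    diagnosis: str | None = None,
    pooled_label: str = "PSY",
) -> pd.Series:
    """Derived HC / FH+ / FH- labels, indexed by subject id.

    ``diagnosis`` restricts the patient side to one diagnosis (e.g. the
    HC / SCZ+ / SCZ- design); ``None`` pools all patients under
    ``pooled_label``.  Patients with unknown family history at the requested
    nesting level get NaN and are excluded from any model using the labels.
    """
    col = _FH_LEVEL_COL[level]
    labels = {}
    for _, row in subjects.iterrows():
        if row["diagnosis"] == "HC":
            labels[row["id"]] = "HC"
            continue
        if diagnosis is not None and row["diagnosis"] != diagnosis:
            labels[row["id"]] = np.nan
            continue
        tag = diagnosis if diagnosis is not None else pooled_label
        flag = row[col]
        labels[row["id"]] = (np.nan if flag is None or (isinstance(flag, float)
                             and np.isnan(flag))
                             else f"{tag}{'+' if flag else '-'}")
    return pd.Series(labels, name="fh_group")


# ---------------------------------------------------------------------------
# correlations and demographics
# ---------------------------------------------------------------------------

def spearman_correlations(
    features: pd.DataFrame,
    subjects: pd.DataFrame,
    variables: Sequence[str],
    feature_cols: Sequence[str] = ("integral_value", "centroid_value_s"),
) -> pd.DataFrame:
    """Tie-corrected Spearman rho between each feature and each clinical
    variable, pairwise-complete, two-sided p; rows with n < 3 or an all-tied
    variable carry NaN statistics."""
    data = _merge(features, subjects)
    data = data[data["qc_pass"].astype(bool)]
    rows = []
    for feat in feature_cols:
        for var in variables:
            sub = data[[feat, var]].apply(pd.to_numeric, errors="coerce").dropna()
            n = len(sub)
            if n < 3 or sub[var].nunique() < 2 or sub[feat].nunique() < 2:
                rows.append(dict(feature=feat, variable=var,
                                 rho=np.nan, p=np.nan, n=n))
                continue
            rho, p = stats.spearmanr(sub[feat], sub[var])
            rows.append(dict(feature=feat, variable=var,
                             rho=float(rho), p=float(p), n=n))
    return pd.DataFrame(rows)


@dataclass
class DemographicTable:
    tests: pd.DataFrame          # variable, test, statistic, df, p, normality_p
    summaries: pd.DataFrame      # per group mean +/- SD or counts


CONTINUOUS_DEMOGRAPHICS = (
    "age_years", "education_years", "premorbid_iq", "vft_performance",
    "cpz_eq_mg_day", "onset_age_years", "illness_duration_years",
)
CATEGORICAL_DEMOGRAPHICS = ("gender", "handedness")


def demographic_table(
    subjects: pd.DataFrame,
    group_col: str = "diagnosis",
    continuous: Sequence[str] = CONTINUOUS_DEMOGRAPHICS,
    categorical: Sequence[str] = CATEGORICAL_DEMOGRAPHICS,
    ks_mode: str = "lilliefors",
) -> DemographicTable:
    """Group comparison of demographic variables, mirroring a Table-1 layout.

    Continuous variables are screened for normality (Kolmogorov-Smirnov;
    ``lilliefors`` estimates the reference parameters from the data,
    ``fitted`` uses a plain KS against the fitted normal) and compared with
    Kruskal-Wallis (Mann-Whitney U for exactly two groups); categorical
    variables with Pearson's chi-squared (no continuity correction).
    """
    groups = [g for g, _ in subjects.groupby(group_col, sort=True)]
    test_rows, summary_rows = [], []
    for var in continuous:
        if var not in subjects.columns:
            continue
        per_group = {g: pd.to_numeric(sub[var], errors="coerce").dropna()
                     for g, sub in subjects.groupby(group_col, sort=True)}
        usable = {g: v for g, v in per_group.items() if len(v) >= 2}
        if len(usable) < 2:
            logger.info("demographic_table: skipping %s (all-missing)", var)
            continue
        pooled = pd.concat(list(usable.values()))
        if ks_mode == "lilliefors" and len(pooled) >= 5:
            _, ks_p = lilliefors(pooled, dist="norm")
        else:
            _, ks_p = stats.kstest(pooled, "norm",
                                   args=(pooled.mean(), pooled.std(ddof=1)))
        if len(usable) == 2:
            a, b = list(usable.values())
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            test, df = "Mann-Whitney U", None
        else:
            stat, p = stats.kruskal(*usable.values())
            test, df = "Kruskal-Wallis", len(usable) - 1
        test_rows.append(dict(variable=var, test=test, statistic=float(stat),
                              df=df, p=float(p), normality_p=float(ks_p)))
        for g in groups:
            v = per_group.get(g, pd.Series(dtype=float))
            summary_rows.append(dict(
                variable=var, group=g, n=len(v),
                summary=(f"{v.mean():.1f} ± {v.std(ddof=1):.1f}"
                         if len(v) >= 2 else "—")))
    for var in categorical:
        if var not in subjects.columns:
            continue
        table = pd.crosstab(subjects[group_col], subjects[var])
        table = table.loc[:, table.sum(axis=0) > 0]
        if table.shape[0] < 2 or table.shape[1] < 2:
            continue
        chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
        test_rows.append(dict(variable=var, test="chi-squared",
                              statistic=float(chi2), df=int(df), p=float(p),
                              normality_p=np.nan))
        for g in groups:
            counts = "/".join(str(int(c)) for c in table.loc[g])
            summary_rows.append(dict(variable=var, group=g,
                                     n=int(table.loc[g].sum()), summary=counts))
    return DemographicTable(pd.DataFrame(test_rows), pd.DataFrame(summary_rows))


# ---------------------------------------------------------------------------
# Monte-Carlo calibration
# ---------------------------------------------------------------------------

def nested_f(y: np.ndarray, x_full: np.ndarray, x_red: np.ndarray):
    """F statistic(s) comparing nested OLS designs; ``y`` may be a matrix of
    replicate columns.  Returns (F, df_num, df_den)."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] != x_full.shape[0]:
        y = y.T
    q_full, _ = np.linalg.qr(x_full)
    q_red, _ = np.linalg.qr(x_red)
    tot = np.sum(y * y, axis=0)
    rss_full = tot - np.sum((q_full.T @ y) ** 2, axis=0)
    rss_red = tot - np.sum((q_red.T @ y) ** 2, axis=0)
    df_num = x_full.shape[1] - x_red.shape[1]
    df_den = y.shape[0] - x_full.shape[1]
    f = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
    return f, df_num, df_den


def ancova_null_rejection_rate(
    n_groups: int = 2,
    n_per_group: int = 30,
    n_covariates: int = 0,
    n_rep: int = 5000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> float:
    """Empirical type-I error of the omnibus group F under the null.

    The design (balanced groups, standard-normal covariates) is fixed across
    replicates; the response is pure N(0, 1) noise, so every rejection is a
    false positive.  The F statistic is the same nested-model comparison the
    :func:`ancova` fit reports, computed here by projection for speed.
    """
    rng = rng or np.random.default_rng()
    n = n_groups * n_per_group
    dummies = np.zeros((n, n_groups - 1))
    for g in range(1, n_groups):
        dummies[g * n_per_group:(g + 1) * n_per_group, g - 1] = 1.0
    covs = (rng.normal(size=(n, n_covariates))
            if n_covariates else np.empty((n, 0)))
    const = np.ones((n, 1))
    x_full = np.hstack([const, dummies, covs])
    x_red = np.hstack([const, covs])
    y = rng.normal(size=(n, n_rep))
    f, df_num, df_den = nested_f(y, x_full, x_red)
    crit = stats.f.isf(alpha, df_num, df_den)
    return float(np.mean(f > crit))
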