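"""Pre-registered inferential layer.

All ANOVA-family statistics are computed from explicit sums of squares so a
reviewer can audit every term; scipy supplies only the reference
distributions (central/noncentral F, studentized range — the latter
evaluated by numerical integration inside scipy, not table lookup).

Data enter as tidy long tables: one row per (subject, within-level), with a
``group`` column for the between factor and optional covariate columns.
Subjects missing any within-level are incomplete cases; the pre-registered
plan drops them listwise, which callers opt into via ``on_incomplete="drop"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaResult",
    "PosthocResult",
    "CorrelationResult",
    "AssumptionReport",
    "IncompleteDataError",
    "mixed_anova",
    "oneway_rm_anova",
    "fixed_anova",
    "ancova",
    "posthoc",
    "correlation",
    "assumption_checks",
    "choose_correlation",
]


class IncompleteDataError(ValueError):
    def __init__(self, subjects: Sequence) -> None:
        self.subjects = list(subjects)
        super().__init__(f"subjects with incomplete within-levels: {self.subjects}")


class SingularModelError(ValueError):
    pass


@dataclass(frozen=True)
class AnovaResult:
    """One ANOVA table plus bookkeeping of dropped subjects."""

    table: pd.DataFrame
    dropped_subjects: tuple = ()

    def effect(self, source: str) -> pd.Series:
        return self.table.set_index("source").loc[source]


def _complete_cases(df: pd.DataFrame, subject: str, within: str,
                    on_incomplete: str) -> tuple[pd.DataFrame, tuple]:
    counts = df.groupby(subject)[within].nunique()
    levels = df[within].nunique()
    bad = counts.index[counts != levels].tolist()
    if not bad:
        return df, ()
    if on_incomplete == "drop":
        logger.warning("dropping %d incomplete subjects: %s", len(bad), bad)
        return df[~df[subject].isin(bad)], tuple(bad)
    raise IncompleteDataError(bad)


def mixed_anova(df: pd.DataFrame, dv: str = "value", within: str = "within",
                between: str = "group", subject: str = "subject",
                correction: bool = False,
                on_incomplete: Literal["raise", "drop"] = "raise") -> AnovaResult:
    """Split-plot (repeated-measures x between-groups) ANOVA.

    Strata: the between-groups effect is tested against subjects-within-
    groups; the within (e.g. blocks) main effect and the group x within
    interaction against the subject x within residual.  Sphericity is
    assumed (ε = 1) by default; ``correction=True`` adds Greenhouse–Geisser
    corrected p-values for the within-stratum effects.
    """
    df, dropped = _complete_cases(df, subject, within, on_incomplete)
    if df[between].nunique() < 2 or df[within].nunique() < 2:
        raise ValueError("need >= 2 groups and >= 2 within-levels")
    if df.duplicated([subject, within]).any():
        raise ValueError("duplicated (subject, within-level) rows")
    if df.groupby(subject)[between].nunique().gt(1).any():
        raise ValueError("a subject appears in more than one group")

    y = df[dv].to_numpy(dtype=float)
    n_obs = len(y)
    m = df[within].nunique()
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    subj_means = df.groupby(subject)[dv].mean()
    subj_group = df.groupby(subject)[between].first()
    group_means = df.groupby(between)[dv].mean()
    within_means = df.groupby(within)[dv].mean()
    cell_means = df.groupby([between, within])[dv].mean()
    n_per_group = subj_group.value_counts()
    n_subj = len(subj_means)

    ss_between_subj = float(m * ((subj_means - grand) ** 2).sum())
    ss_group = float(m * sum(n_per_group[g] * (group_means[g] - grand) ** 2
                             for g in group_means.index))
    ss_subj_within = ss_between_subj - ss_group
    ss_within_lvl = float(n_subj * ((within_means - grand) ** 2).sum())
    ss_cells = float(sum(n_per_group[g] * (cell_means[(g, w)] - grand) ** 2
                         for g, w in cell_means.index))
    ss_inter = ss_cells - ss_group - ss_within_lvl
    ss_error_within = ss_total - ss_between_subj - ss_within_lvl - ss_inter

    k = len(group_means)
    df_group, df_serr = k - 1, n_subj - k
    df_within, df_inter = m - 1, (k - 1) * (m - 1)
    df_werr = (n_subj - k) * (m - 1)

    def row(source, ss, dfree, err_ss, err_df):
        ms, err_ms = ss / dfree, err_ss / err_df
        f = ms / err_ms if err_ms > 0 else (0.0 if ss <= 1e-12 else math.inf)
        p = float(sps.f.sf(f, dfree, err_df)) if math.isfinite(f) else 0.0
        return {"source": source, "SS": ss, "df": dfree, "MS": ms, "F": f, "p": p}

    rows = [
        row(between, ss_group, df_group, ss_subj_within, df_serr),
        {"source": f"subjects({between})", "SS": ss_subj_within, "df": df_serr,
         "MS": ss_subj_within / df_serr, "F": np.nan, "p": np.nan},
        row(within, ss_within_lvl, df_within, ss_error_within, df_werr),
        row(f"{between}*{within}", ss_inter, df_inter, ss_error_within, df_werr),
        {"source": "residual", "SS": ss_error_within, "df": df_werr,
         "MS": ss_error_within / df_werr, "F": np.nan, "p": np.nan},
    ]
    table = pd.DataFrame(rows)

    if correction:
        eps = _gg_epsilon(df, dv, within, subject)
        table["eps_gg"] = np.nan
        table["p_gg"] = np.nan
        for src, dfree in ((within, df_within), (f"{between}*{within}", df_inter)):
            i = table.index[table["source"] == src][0]
            f_val = table.at[i, "F"]
            table.at[i, "eps_gg"] = eps
            table.at[i, "p_gg"] = float(sps.f.sf(f_val, dfree * eps, df_werr * eps))
    return AnovaResult(table=table, dropped_subjects=dropped)


def _gg_epsilon(df: pd.DataFrame, dv: str, within: str, subject: str) -> float:
    """Greenhouse–Geisser ε from the pooled within-subject covariance."""
    wide = df.pivot(index=subject, columns=within, values=dv)
    s = np.cov(wide.to_numpy(), rowvar=False)
    m = s.shape[0]
    centered = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    num = np.trace(centered) ** 2
    den = (m - 1) * np.sum(centered ** 2)
    return float(np.clip(num / den, 1.0 / (m - 1), 1.0))


def oneway_rm_anova(df: pd.DataFrame, dv: str = "value", within: str = "time",
                    between: str = "group", subject: str = "subject",
                    **kw) -> AnovaResult:
    """Pre/post repeated-measures ANOVA with a between-groups factor.

    The pre-registered survey analysis: two within-levels (pre, post) per
    subject, three treatment groups between; the group x time interaction is
    the effect of interest.  Identical error strata to :func:`mixed_anova`.
    """
    return mixed_anova(df, dv=dv, within=within, between=between,
                       subject=subject, **kw)


def fixed_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-factor ANOVA over named groups (one value per subject)."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    all_y = np.concatenate(arrays)
    grand = all_y.mean()
    ss_between = float(sum(len(a) * (a.mean() - grand) ** 2 for a in arrays))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_b, df_w = len(names) - 1, len(all_y) - len(names)
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    f = ms_b / ms_w if ms_w > 0 else (0.0 if ss_between <= 1e-12 else math.inf)
    table = pd.DataFrame([
        {"source": "group", "SS": ss_between, "df": df_b, "MS": ms_b,
         "F": f, "p": float(sps.f.sf(f, df_b, df_w))},
        {"source": "residual", "SS": ss_within, "df": df_w, "MS": ms_w,
         "F": np.nan, "p": np.nan},
    ])
    return AnovaResult(table=table)


# --------------------------------------------------------------------------
# ANCOVA via the general linear model
# --------------------------------------------------------------------------

def _design(df: pd.DataFrame, between: str, covariates: Sequence[str],
            include_group: bool) -> np.ndarray:
    n = len(df)
    cols = [np.ones(n)]
    for c in covariates:
        cols.append(df[c].to_numpy(dtype=float))
    if include_group:
        levels = sorted(df[between].unique())
        for lvl in levels[1:]:  # treatment coding, first level reference
            cols.append((df[between] == lvl).to_numpy(dtype=float))
    return np.column_stack(cols)


def _rss(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), rank


def ancova(df: pd.DataFrame, dv: str = "value", between: str = "group",
           covariates: Sequence[str] = ()) -> AnovaResult:
    """Between-groups effect adjusted for covariates (GLM extra-SS F test).

    Fits y ~ covariates + group and y ~ covariates; the group effect is the
    extra-sum-of-squares F.  Each covariate also gets a drop-one F.  Raises
    :class:`SingularModelError` on collinear covariates (naming them) or on
    a zero-residual fit (covariate identical to the outcome).
    """
    y = df[dv].to_numpy(dtype=float)
    x_full = _design(df, between, covariates, include_group=True)
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        bad = [c for c in covariates
               if np.linalg.matrix_rank(_design(df, between, [c], False)) < 2]
        raise SingularModelError(
            f"collinear design; suspect covariates: {bad or list(covariates)}")
    rss_full, _ = _rss(x_full, y)
    df_resid = len(y) - x_full.shape[1]
    if df_resid <= 0:
        raise SingularModelError("no residual degrees of freedom")
    if rss_full <= 1e-10 * max(1.0, float(y @ y)):
        raise SingularModelError("zero residual variance: a covariate "
                                 "reproduces the outcome exactly")
    k = df[between].nunique()
    rows = []

    def extra_ss_row(source, x_reduced, df_effect):
        rss_red, _ = _rss(x_reduced, y)
        ss = rss_red - rss_full
        ms = ss / df_effect
        f = ms / (rss_full / df_resid)
        rows.append({"source": source, "SS": ss, "df": df_effect, "MS": ms,
                     "F": f, "p": float(sps.f.sf(f, df_effect, df_resid))})

    extra_ss_row(between, _design(df, between, covariates, False), k - 1)
    for c in covariates:
        others = [cc for cc in covariates if cc != c]
        extra_ss_row(c, _design(df, between, others, True), 1)
    rows.append({"source": "residual", "SS": rss_full, "df": df_resid,
                 "MS": rss_full / df_resid, "F": np.nan, "p": np.nan})
    return AnovaResult(table=pd.DataFrame(rows))


# --------------------------------------------------------------------------
# Post-hoc procedures
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PosthocResult:
    pair: tuple[str, str]
    mean_difference: float
    statistic: float
    critical_value: float
    p_adjusted: Optional[float]
    reject: bool
    procedure: str


def posthoc(groups: Mapping[str, Sequence[float]],
            procedure: Literal["scheffe", "tukey", "newman_keuls"],
            alpha: float = 0.05,
            omnibus_significant: Optional[bool] = None) -> list[PosthocResult]:
    """All pairwise comparisons after a one-way omnibus test.

    Scheffé uses the simultaneous criterion F* = (k−1)·F_{α,k−1,df_e};
    Tukey (Tukey–Kramer for unequal n) compares the studentized range
    statistic to q_{α,k,df_e}; Newman–Keuls steps down with range-dependent
    quantiles q_{α,r,df_e} and the usual protection rule (a non-significant
    range blocks all ranges nested inside it).  Newman–Keuls p-values are
    the per-step tail probabilities, not simultaneous error rates.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if omnibus_significant is False:
        logger.warning("post-hoc %s requested without a significant omnibus test",
                       procedure)
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    df_err = sum(len(a) for a in arrays.values()) - k
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_err

    def q_stat(g1, g2):
        a, b = arrays[g1], arrays[g2]
        se = math.sqrt(mse / 2 * (1 / len(a) + 1 / len(b)))
        return abs(a.mean() - b.mean()) / se if se > 0 else 0.0

    results: list[PosthocResult] = []
    if procedure == "scheffe":
        f_crit = sps.f.ppf(1 - alpha, k - 1, df_err)
        names = list(arrays)
        for i in range(k):
            for j in range(i + 1, k):
                a, b = arrays[names[i]], arrays[names[j]]
                diff = a.mean() - b.mean()
                f_stat = diff ** 2 / (mse * (1 / len(a) + 1 / len(b)))
                p = float(sps.f.sf(f_stat / (k - 1), k - 1, df_err))
                results.append(PosthocResult(
                    pair=(names[i], names[j]), mean_difference=float(diff),
                    statistic=float(f_stat), critical_value=float((k - 1) * f_crit),
                    p_adjusted=p, reject=bool(f_stat > (k - 1) * f_crit),
                    procedure="scheffe"))
        return results

    if procedure == "tukey":
        q_crit = float(sps.studentized_range.ppf(1 - alpha, k, df_err))
        names = list(arrays)
        for i in range(k):
            for j in range(i + 1, k):
                q = q_stat(names[i], names[j])
                p = float(sps.studentized_range.sf(q, k, df_err))
                results.append(PosthocResult(
                    pair=(names[i], names[j]),
                    mean_difference=float(arrays[names[i]].mean()
                                          - arrays[names[j]].mean()),
                    statistic=float(q), critical_value=q_crit, p_adjusted=p,
                    reject=bool(q > q_crit), procedure="tukey"))
        return results

    if procedure == "newman_keuls":
        order = sorted(arrays, key=lambda g: arrays[g].mean())
        blocked: set[tuple[int, int]] = set()
        span_results: dict[tuple[int, int], PosthocResult] = {}
        for span in range(k, 1, -1):  # widest ranges first
            for i in range(0, k - span + 1):
                j = i + span - 1
                g1, g2 = order[i], order[j]
                q = q_stat(g1, g2)
                q_crit = float(sps.studentized_range.ppf(1 - alpha, span, df_err))
                p = float(sps.studentized_range.sf(q, span, df_err))
                reject = q > q_crit and (i, j) not in blocked
                if not reject:
                    for ii in range(i, j + 1):
                        for jj in range(ii + 1, j + 1):
                            blocked.add((ii, jj))
                span_results[(i, j)] = PosthocResult(
                    pair=(g1, g2),
                    mean_difference=float(arrays[g1].mean() - arrays[g2].mean()),
                    statistic=float(q), critical_value=q_crit, p_adjusted=p,
                    reject=reject, procedure="newman_keuls")
        return [span_results[key] for key in sorted(span_results)]

    raise ValueError(f"unknown procedure {procedure!r}")


# --------------------------------------------------------------------------
# Correlations and assumption checks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    method: str
    r: float
    n: int
    tails: str
    p: float


def correlation(x: Sequence[float], y: Sequence[float],
                method: Literal["pearson", "spearman"] = "pearson",
                tails: Literal["one", "two"] = "two",
                direction: Literal["positive", "negative"] = "positive",
                ) -> CorrelationResult:
    """Pearson or (tie-corrected, mid-rank) Spearman correlation.

    One-tailed p-values honor the pre-registered ``direction``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    alternative = ("two-sided" if tails == "two"
                   else "greater" if direction == "positive" else "less")
    if method == "pearson":
        res = sps.pearsonr(x, y, alternative=alternative)
    elif method == "spearman":
        res = sps.spearmanr(x, y, alternative=alternative)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method=method, r=float(res.statistic), n=len(x),
                             tails=tails, p=float(res.pvalue))


@dataclass(frozen=True)
class AssumptionReport:
    normality_ok: Optional[bool]
    homoscedasticity_ok: Optional[bool]
    linearity_ok: Optional[bool]
    degenerate: bool
    statistics: dict


def assumption_checks(x: Sequence[float], y: Optional[Sequence[float]] = None,
                      alpha: float = 0.05) -> AssumptionReport:
    """Normality / homoscedasticity / linearity screen.

    With ``y`` given, fits y ~ x by least squares and tests residual
    normality (Shapiro–Wilk), homoscedasticity (Breusch–Pagan) and linearity
    (extra-SS F for a quadratic term).  With ``x`` alone it is treated as a
    residual vector and only normality is screened.  Drives the
    pre-registered Pearson → Spearman fallback.
    """
    x = np.asarray(x, dtype=float)
    stats_out: dict = {}
    if y is None:
        if np.std(x) == 0 or len(x) < 8:
            return AssumptionReport(None, None, None, True, stats_out)
        w, p = sps.shapiro(x)
        stats_out["shapiro"] = (float(w), float(p))
        return AssumptionReport(p > alpha, None, None, False, stats_out)

    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 8:
        raise ValueError("need paired samples with n >= 8")
    if np.std(x) == 0 or np.std(y) == 0:
        return AssumptionReport(None, None, None, True, stats_out)

    design = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    w, p_norm = sps.shapiro(resid)
    stats_out["shapiro"] = (float(w), float(p_norm))

    from statsmodels.stats.diagnostic import het_breuschpagan
    bp_stat, bp_p, _, _ = het_breuschpagan(resid, design)
    stats_out["breusch_pagan"] = (float(bp_stat), float(bp_p))

    quad = np.column_stack([design, x ** 2])
    rss_lin = float(resid @ resid)
    beta_q, *_ = np.linalg.lstsq(quad, y, rcond=None)
    rss_quad = float(((y - quad @ beta_q) ** 2).sum())
    df_resid = len(y) - 3
    if rss_quad <= 0 or df_resid <= 0:
        lin_ok, stats_out["linearity_f"] = None, None
    else:
        f_lin = (rss_lin - rss_quad) / (rss_quad / df_resid)
        p_lin = float(sps.f.sf(f_lin, 1, df_resid))
        stats_out["linearity_f"] = (float(f_lin), p_lin)
        lin_ok = p_lin > alpha
    return AssumptionReport(
        normality_ok=p_norm > alpha,
        homoscedasticity_ok=bp_p > alpha,
        linearity_ok=lin_ok,
        degenerate=False,
        statistics=stats_out,
    )


def choose_correlation(x: Sequence[float], y: Sequence[float],
                       tails: Literal["one", "two"] = "two",
                       direction: Literal["positive", "negative"] = "positive",
                       alpha: float = 0.05) -> CorrelationResult:
    """Pearson when assumptions hold, else the pre-registered Spearman fallback."""
    report = assumption_checks(x, y, alpha=alpha)
    pearson_ok = (not report.degenerate
                  and report.normality_ok and report.homoscedasticity_ok
                  and (report.linearity_ok is not False))
    method = "pearson" if pearson_ok else "spearman"
    return correlation(x, y, method=method, tails=tails, direction=direction)
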