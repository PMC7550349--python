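"""Group-level inference for the scored psychophysiology data.

Wraps the standard test battery used for differential-conditioning
analyses: two-tailed paired t tests (Cohen's d = mean difference / sd of
differences), repeated-measures and mixed-design ANOVAs (Type III, partial
eta squared), Bonferroni-corrected pairwise post-hocs with 95% confidence
intervals on the raw mean difference, and the Kruskal-Wallis test for
ordinal ratings.  ANOVAs are delegated to pingouin; post-hoc contrasts and
effect sizes are computed here.

For the 2-level within-subject factors no sphericity correction is needed
(it is the identity there); for 3-level factors the Greenhouse-Geisser
epsilon and corrected p are additionally reported alongside the uncorrected
degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "StatResult",
    "Contrast",
    "paired_t",
    "two_sample_t",
    "rm_anova",
    "mixed_anova",
    "bonferroni_posthoc",
    "kruskal_wallis",
]


@dataclass
class StatResult:
    """One test: statistic, degrees of freedom, p, effect size, CI."""

    test: str                       # paired_t | rm_anova | mixed_anova | posthoc_t | kruskal_wallis
    name: str
    statistic: float
    df: float | tuple[float, float]
    p: float
    effect_size: float | None = None
    effect_size_kind: str | None = None   # "cohen_d" or "partial_eta_sq"
    ci: tuple[float, float] | None = None
    correction: str = "none"              # "none" or "bonferroni"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError("p must lie in [0, 1]")

    def as_row(self) -> dict:
        df = self.df
        df1, df2 = (df if isinstance(df, tuple) else (df, float("nan")))
        lo, hi = self.ci if self.ci is not None else (float("nan"), float("nan"))
        return {
            "test": self.test,
            "name": self.name,
            "statistic": self.statistic,
            "df1": df1,
            "df2": df2,
            "p": self.p,
            "effect_size": self.effect_size,
            "effect_size_kind": self.effect_size_kind,
            "ci_low": lo,
            "ci_high": hi,
            "correction": self.correction,
        }


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------

def paired_t(x: Sequence[float], y: Sequence[float], name: str = "") -> StatResult:
    """Two-tailed paired t test with Cohen's d = mean(diff) / sd(diff)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if np.all(diff == 0.0):
            # identical samples: no effect by definition
            return StatResult(
                test="paired_t", name=name, statistic=0.0, df=float(diff.size - 1),
                p=1.0, effect_size=0.0, effect_size_kind="cohen_d", ci=(0.0, 0.0),
            )
        raise ValueError("zero variance of paired differences")
    n = diff.size
    se = sd / math.sqrt(n)
    t = float(diff.mean() / se)
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t), df))
    tcrit = sps.t.ppf(0.975, df)
    ci = (float(diff.mean() - tcrit * se), float(diff.mean() + tcrit * se))
    return StatResult(
        test="paired_t", name=name, statistic=t, df=float(df), p=p,
        effect_size=float(diff.mean() / sd), effect_size_kind="cohen_d", ci=ci,
    )


def two_sample_t(a: Sequence[float], b: Sequence[float], name: str = "") -> StatResult:
    """Two-tailed independent-samples t with pooled sd and pooled-sd Cohen's d."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0.0:
        raise ValueError("zero pooled variance")
    se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    mean_diff = float(a.mean() - b.mean())
    t = mean_diff / se
    df = na + nb - 2
    p = float(2.0 * sps.t.sf(abs(t), df))
    tcrit = sps.t.ppf(0.975, df)
    return StatResult(
        test="two_sample_t", name=name, statistic=float(t), df=float(df), p=p,
        effect_size=mean_diff / math.sqrt(sp2), effect_size_kind="cohen_d",
        ci=(mean_diff - tcrit * se, mean_diff + tcrit * se),
    )


# ---------------------------------------------------------------------------
# ANOVAs
# ---------------------------------------------------------------------------

def _anova_rows(
    table: pd.DataFrame, test: str, name_prefix: str = ""
) -> list[StatResult]:
    error_rows = table[table["Source"].astype(str).str.lower().isin(
        ("within", "residual", "error")
    )]
    ss_error = float(error_rows["SS"].iloc[0]) if len(error_rows) == 1 and "SS" in table else None
    df_error = (
        float(error_rows["DF"].iloc[0])
        if len(error_rows) == 1 and "DF" in table.columns
        else None
    )
    out = []
    for _, row in table.iterrows():
        source = str(row["Source"])
        if source.lower() in ("within", "residual", "error"):
            continue
        df1 = float(row.get("ddof1", row.get("DF1", row.get("DF", np.nan))))
        df2 = float(row.get("ddof2", row.get("DF2", np.nan)))
        if math.isnan(df2) and df_error is not None:
            df2 = df_error
        p = float(row.get("p_unc", row.get("p-unc", np.nan)))
        fval = float(row["F"])
        np2 = row.get("np2", None)
        np2 = None if np2 is None or pd.isna(np2) else float(np2)
        ss = float(row["SS"]) if "SS" in row.index and not pd.isna(row["SS"]) else None
        if math.isnan(fval) and ss is not None and abs(ss) < 1e-12:
            # degenerate constant-input design: no effect variance at all
            fval, p, np2 = 0.0, 1.0, 0.0
        extra = {}
        if ss is not None:
            extra["SS"] = ss
        if ss_error is not None:
            extra["SS_error"] = ss_error
        for k in ("p_GG_corr", "p-GG-corr", "eps", "sphericity", "W_spher"):
            if k in row.index and not pd.isna(row[k]):
                extra[k] = row[k]
        out.append(
            StatResult(
                test=test,
                name=f"{name_prefix}{source}",
                statistic=fval,
                df=(df1, df2),
                p=p,
                effect_size=np2,
                effect_size_kind="partial_eta_sq",
                extra=extra,
            )
        )
    return out


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: str | list[str],
    subject: str,
    name_prefix: str = "",
) -> list[StatResult]:
    """Repeated-measures ANOVA (one or two within-subject factors).

    Balanced complete cells are required; missing cells raise instead of
    being imputed.  Effects are reported with partial eta squared; for
    factors with more than two levels the Greenhouse-Geisser epsilon and
    corrected p are attached in ``extra`` while the uncorrected integer
    degrees of freedom remain the headline values.
    """
    within_list = [within] if isinstance(within, str) else list(within)
    _check_complete(data, dv, within_list, subject)
    one_way = len(within_list) == 1
    with np.errstate(invalid="ignore", divide="ignore"):  # constant input
        table = pg.rm_anova(
            data=data, dv=dv, within=within_list[0] if one_way else within_list,
            subject=subject, detailed=True, effsize="np2", correction=one_way,
        )
    return _anova_rows(table, "rm_anova", name_prefix)


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    between: str,
    subject: str,
    name_prefix: str = "",
) -> list[StatResult]:
    """Mixed-design ANOVA: one within factor (2 or 3 levels), one between.

    Error strata follow the standard split-plot decomposition (between
    effects against subjects-within-groups, within effects against the
    subject x within interaction).  Each between group needs >= 2 subjects.
    """
    counts = data.groupby(between)[subject].nunique()
    if (counts < 2).any():
        raise ValueError(f"each {between!r} group needs >= 2 subjects, got {dict(counts)}")
    _check_complete(data, dv, [within], subject)
    table = pg.mixed_anova(
        data=data, dv=dv, within=within, subject=subject, between=between,
        effsize="np2",
    )
    return _anova_rows(table, "mixed_anova", name_prefix)


def _check_complete(df: pd.DataFrame, dv: str, within: list[str], subject: str) -> None:
    if df[dv].isna().any():
        raise ValueError("missing values in the dependent variable (no imputation)")
    cells = df.groupby([subject, *within], observed=True).size()
    if (cells != 1).any():
        raise ValueError("design must have exactly one observation per subject x cell")
    per_subject = df.groupby(subject, observed=True).size()
    if per_subject.nunique() != 1:
        raise ValueError("unbalanced design: subjects have differing cell counts")


# ---------------------------------------------------------------------------
# Post-hoc contrasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contrast:
    """One pairwise comparison over a long-format condition table.

    kind "paired": conditions *a* vs *b* within subjects (optionally within
    one between-group).  kind "between": groups *a* vs *b* at one condition.
    """

    kind: str                   # "paired" or "between"
    a: str
    b: str
    group: str | None = None    # restrict a paired contrast to one group
    condition: str | None = None  # condition at which to compare groups
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("paired", "between"):
            raise ValueError("contrast kind must be 'paired' or 'between'")


def bonferroni_posthoc(
    table: pd.DataFrame,
    contrasts: list[Contrast],
    dv: str = "value",
    subject: str = "subject_id",
    condition: str = "condition",
    group: str | None = "group",
) -> list[StatResult]:
    """Pairwise t tests with Bonferroni correction over *contrasts*.

    Within-subject contrasts use paired t tests, between-group contrasts use
    pooled-sd two-sample t tests; each corrected p is ``min(1, m * p)`` with
    ``m = len(contrasts)``.  Confidence intervals stay at the uncorrected
    95% level on the raw mean difference.
    """
    m = len(contrasts)
    results = []
    for con in contrasts:
        sub = table
        if con.kind == "paired":
            if con.group is not None:
                if group is None:
                    raise ValueError("contrast restricted by group but no group column given")
                sub = table[table[group] == con.group]
            wide = sub.pivot(index=subject, columns=condition, values=dv)
            for lbl in (con.a, con.b):
                if lbl not in wide.columns:
                    raise ValueError(f"unknown condition label {lbl!r}")
            res = paired_t(wide[con.a].to_numpy(), wide[con.b].to_numpy(),
                           name=con.name or f"{con.a} vs {con.b}")
        else:
            if group is None:
                raise ValueError("between contrast requires a group column")
            sub = table if con.condition is None else table[table[condition] == con.condition]
            ga = sub[sub[group] == con.a][dv].to_numpy()
            gb = sub[sub[group] == con.b][dv].to_numpy()
            if ga.size == 0 or gb.size == 0:
                raise ValueError(f"unknown group label in contrast {con}")
            res = two_sample_t(ga, gb, name=con.name or f"{con.a} vs {con.b}")
        res.test = "posthoc_t"
        res.p = min(1.0, res.p * m)
        res.correction = "bonferroni"
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: Sequence[Sequence[float]], name: str = "") -> StatResult:
    """Kruskal-Wallis H (tie-corrected) with chi-square p.

    All-identical observations are a degenerate case returning H = 0, p = 1.
    """
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 groups with >= 1 observation each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return StatResult(
            test="kruskal_wallis", name=name, statistic=0.0,
            df=float(len(groups) - 1), p=1.0,
        )
    h, p = sps.kruskal(*arrays)
    return StatResult(
        test="kruskal_wallis", name=name, statistic=float(h),
        df=float(len(groups) - 1), p=float(p),
    )
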