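"""Confidence-resolved behavioral statistics.

For each subject, trials are grouped by recognition response (recollection,
high/low-confidence old, low/high-confidence new) and the mean crowd-sourced
memorability Pr of the trials' images computed per category.  Categories
with enough data across subjects enter a one-way repeated-measures ANOVA
with Mauchly's sphericity test, a Greenhouse-Geisser correction applied
when sphericity is rejected, partial eta-squared effect size, and
Bonferroni-corrected paired post-hoc comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .config import RESPONSE_LEVELS
from .errors import InsufficientTrialsError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class AnovaResult:
    """One-way within-subjects ANOVA with sphericity handling.

    ``df1``/``df2`` are the degrees of freedom actually used for ``p``:
    the uncorrected pair (k-1, (k-1)(n-1)) when sphericity holds, or that
    pair multiplied by the Greenhouse-Geisser epsilon when Mauchly's test
    rejects at 0.05.  ``eta_sq`` is partial eta-squared,
    df1*F / (df1*F + df2).
    """

    F: float
    df1: float
    df2: float
    p: float
    eta_sq: float
    epsilon: float
    corrected: bool
    df1_uncorrected: int
    df2_uncorrected: int
    p_uncorrected: float
    mauchly_w: float
    mauchly_chi2: float
    mauchly_df: int
    mauchly_p: float
    n_subjects: int
    n_categories: int
    pairwise: pd.DataFrame = field(repr=False, default=None)


def mean_pr_by_response(
    trials: pd.DataFrame,
    memtable: pd.DataFrame,
    min_trials: int = 5,
    min_subjects: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject mean memorability of each response category, with
    inclusion flags.

    A category qualifies for the ANOVA only when at least ``min_subjects``
    subjects have at least ``min_trials`` trials of it (both default 5).
    Means are returned for all categories regardless, so excluded ones can
    still be described.

    Returns ``(means, inclusion)``: means is subjects x categories (NaN for
    empty cells); inclusion has one row per category with the qualifying
    subject count and an ``included`` flag.
    """
    missing = set(trials["image_id"]) - set(memtable.index)
    if missing:
        raise ParameterError(f"trials reference unscored images, e.g. {sorted(missing)[:3]}")
    df = trials.copy()
    df["Pr"] = memtable["Pr"].reindex(df["image_id"]).to_numpy()
    means = df.pivot_table(index="subject_id", columns="response", values="Pr",
                           aggfunc="mean").reindex(columns=list(RESPONSE_LEVELS))
    counts = df.pivot_table(index="subject_id", columns="response", values="Pr",
                            aggfunc="count").reindex(columns=list(RESPONSE_LEVELS)).fillna(0)
    qualifying = (counts >= min_trials).sum(axis=0)
    inclusion = pd.DataFrame(
        {
            "response": list(RESPONSE_LEVELS),
            "n_qualifying_subjects": [int(qualifying[c]) for c in RESPONSE_LEVELS],
        }
    )
    inclusion["included"] = inclusion["n_qualifying_subjects"] >= min_subjects
    if inclusion["included"].sum() < 2:
        raise InsufficientTrialsError("fewer than 2 response categories qualify for the ANOVA")
    return means, inclusion


def rm_anova(matrix: pd.DataFrame) -> AnovaResult:
    """One-way repeated-measures ANOVA over a complete subjects x categories
    matrix.

    Mauchly's W is tested on k(k-1)/2 - 1 degrees of freedom; when its p
    falls below 0.05 the reported df/p are Greenhouse-Geisser corrected
    (epsilon multiplies both df), and the uncorrected values are kept
    alongside.  With k = 2 sphericity holds trivially and no test is run.
    """
    mat = pd.DataFrame(matrix).dropna()
    n, k = mat.shape
    if n < 3 or k < 2:
        raise ParameterError(f"need >=3 subjects and >=2 categories, got {n}x{k}")
    long = mat.reset_index(names="subject").melt(
        id_vars="subject", var_name="cond", value_name="y"
    )
    aov = pg.rm_anova(data=long, dv="y", within="cond", subject="subject",
                      correction=True, effsize="np2", detailed=True)
    row = aov.iloc[0]
    df1_u, df2_u = k - 1, (k - 1) * (n - 1)
    eps = float(row["eps"])

    if k == 2:
        mauchly_w, mauchly_chi2, mauchly_df, mauchly_p = 1.0, 0.0, 0, 1.0
        corrected = False
    else:
        sph = pg.sphericity(long, dv="y", within="cond", subject="subject")
        mauchly_w = float(sph.W)
        mauchly_chi2 = float(sph.chi2)
        mauchly_df = int(sph.dof)
        mauchly_p = float(sph.pval)
        corrected = mauchly_p < 0.05

    F = float(row["F"])
    p_unc = float(row["p_unc"])
    if corrected:
        df1, df2 = eps * df1_u, eps * df2_u
        p = float(row["p_GG_corr"])
    else:
        df1, df2 = float(df1_u), float(df2_u)
        p = p_unc

    return AnovaResult(
        F=F,
        df1=df1,
        df2=df2,
        p=p,
        eta_sq=float(row["np2"]),
        epsilon=eps,
        corrected=corrected,
        df1_uncorrected=df1_u,
        df2_uncorrected=df2_u,
        p_uncorrected=p_unc,
        mauchly_w=mauchly_w,
        mauchly_chi2=mauchly_chi2,
        mauchly_df=mauchly_df,
        mauchly_p=mauchly_p,
        n_subjects=n,
        n_categories=k,
        pairwise=pairwise_bonferroni(mat),
    )


def pairwise_bonferroni(matrix: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests over all k(k-1)/2 category pairs, Bonferroni corrected:
    p_corr = min(1, p_raw * n_pairs)."""
    mat = pd.DataFrame(matrix).dropna()
    pairs = list(combinations(mat.columns, 2))
    rows = []
    for a, b in pairs:
        res = stats.ttest_rel(mat[a], mat[b])
        rows.append(
            {
                "a": a,
                "b": b,
                "t": float(res.statistic),
                "p_raw": float(res.pvalue),
                "p_bonf": float(min(1.0, res.pvalue * len(pairs))),
            }
        )
    return pd.DataFrame(rows)


def behavior_analysis(
    trials: pd.DataFrame,
    memtable: pd.DataFrame,
    history: str,
    min_trials: int = 5,
    min_subjects: int = 5,
) -> tuple[AnovaResult, pd.DataFrame, pd.DataFrame]:
    """The full confidence-resolved analysis for one item history.

    Restricts trials to the given history ('old' or 'new'), computes
    category means, drops categories failing the inclusion rule, and runs
    the repeated-measures ANOVA over the remainder.  Subjects with any
    missing included-category cell are dropped (complete-case), and the
    returned df reflect the subjects actually analyzed.
    """
    sub = trials[trials["history"] == history]
    means, inclusion = mean_pr_by_response(sub, memtable, min_trials, min_subjects)
    keep = inclusion.loc[inclusion["included"], "response"].tolist()
    matrix = means[keep].dropna()
    if len(matrix) < means.shape[0]:
        logger.info("%s-history ANOVA: %d of %d subjects complete",
                    history, len(matrix), means.shape[0])
    return rm_anova(matrix), means, inclusion
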