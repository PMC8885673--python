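"""Paired statistics on analyte panels and host covariates.

Covers the trial's secondary readouts: Wilcoxon signed-rank tests on
paired cytokine/chemokine/SCFA concentrations, the screening table of
mediators with |percent change| > 5 and p < 0.2, fold changes and
percent reductions of group means, exclusion of the multi-autoantibody
subgroup, dietary-fiber standardisation against the 14 g / 1000 kcal
intake guideline, CD4 memory:naive ratios, and Pearson correlations with
index change.

The "paired Wilcoxon" procedure is the Wilcoxon signed-rank test on the
paired differences (exact null for n <= 25, normal approximation with
continuity correction above), with zero differences dropped by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AnalytePanel
from .errors import CoinflamError, DegenerateTestError

#: Dietary-fiber intake guideline: grams of fiber per 1000 kcal per day.
IOM_FIBER_G_PER_1000_KCAL = 14.0

EXACT_N_MAX = 25  # exact signed-rank null up to this many nonzero pairs


def paired_signed_rank(
    pre,
    post,
    alternative: str = "two-sided",
    zero_method: str = "wilcox",
):
    """Wilcoxon signed-rank test on paired differences (post - pre).

    Exact p-value when the number of nonzero differences is <= 25 and
    there are no ties among |differences|; otherwise the normal
    approximation with continuity correction.  ``zero_method`` follows
    scipy ("wilcox" drops zero differences; "pratt" keeps them in the
    ranking).

    Returns
    -------
    (statistic, p_value) : tuple of float
        The statistic is W+, the sum of ranks of positive differences.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise CoinflamError("pre and post must be equal-length 1-D arrays")
    d = post - pre
    n_nonzero = int(np.count_nonzero(d))
    if n_nonzero == 0:
        raise DegenerateTestError("all paired differences are zero")
    if n_nonzero < 5:
        raise CoinflamError(
            "need at least 5 nonzero paired differences for the signed-rank test"
        )
    ties = len(np.unique(np.abs(d[d != 0]))) < n_nonzero
    method = "exact" if (n_nonzero <= EXACT_N_MAX and not ties) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(
            post, pre,
            alternative=alternative,
            zero_method=zero_method,
            correction=(method == "approx"),
            method=method,
        )
    return float(res.statistic), float(res.pvalue)


def fold_change_of_means(pre_mean: float, post_mean: float) -> float:
    """post_mean / pre_mean."""
    if pre_mean <= 0:
        raise CoinflamError("pre mean must be positive for a fold change")
    return post_mean / pre_mean


def percent_reduction_of_means(pre_mean: float, post_mean: float) -> float:
    """100 * (pre_mean - post_mean) / pre_mean; positive = reduction."""
    if pre_mean <= 0:
        raise CoinflamError("pre mean must be positive")
    return 100.0 * (pre_mean - post_mean) / pre_mean


def percent_change_of_means(pre_mean: float, post_mean: float) -> float:
    """Signed percent change of the group mean, 100*(post-pre)/pre."""
    if pre_mean <= 0:
        raise CoinflamError("pre mean must be positive")
    return 100.0 * (post_mean - pre_mean) / pre_mean


def mediator_change_table(
    panel: AnalytePanel,
    abs_change_threshold: float = 5.0,
    p_threshold: float = 0.2,
    change_on: str = "group_means",
) -> pd.DataFrame:
    """Screening table of analytes with a notable paired change.

    Per analyte: percent change (of the cohort mean by default, or the
    mean of per-subject percent changes with ``change_on="subject_means"``)
    and the paired signed-rank p-value.  Rows are retained iff
    |percent change| > ``abs_change_threshold`` (strict) and
    p < ``p_threshold`` (strict), sorted by p.

    Analytes missing a visit or with fewer than 5 complete pairs are
    excluded with a warning rather than silently dropped.
    """
    if change_on not in ("group_means", "subject_means"):
        raise CoinflamError("change_on must be 'group_means' or 'subject_means'")
    rows = []
    for analyte in panel.analytes():
        wide = panel.paired_values(analyte)
        if len(wide) < 5:
            warnings.warn(
                f"analyte {analyte!r}: fewer than 5 complete pre/post pairs; "
                "excluded from the change table",
                stacklevel=2,
            )
            continue
        pre = wide["pre"].to_numpy()
        post = wide["post"].to_numpy()
        if np.allclose(post - pre, 0):
            continue  # identical pre/post: 0% change, never passes the filter
        if change_on == "group_means":
            pct = percent_change_of_means(pre.mean(), post.mean())
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                per = 100.0 * (post - pre) / pre
            pct = float(np.nanmean(per[np.isfinite(per)]))
        _, p = paired_signed_rank(pre, post)
        rows.append(
            {"analyte": analyte, "percent_change": pct, "p_value": p,
             "n_pairs": len(wide)}
        )
    table = pd.DataFrame(rows, columns=["analyte", "percent_change", "p_value", "n_pairs"])
    keep = (table["percent_change"].abs() > abs_change_threshold) & (
        table["p_value"] < p_threshold
    )
    return table[keep].sort_values("p_value").reset_index(drop=True)


@dataclass
class SubgroupExclusion:
    """Filtered records plus the ids that were removed."""

    retained: list
    removed_subject_ids: list


def exclude_subgroup(records, predicate=None) -> SubgroupExclusion:
    """Drop records whose subject matches ``predicate``.

    The default predicate flags subjects with >= 2 autoantibodies (the
    seroconverted subgroup).  Records are returned unaltered; this is a
    pure filter.
    """
    if predicate is None:
        predicate = lambda r: r.autoantibody_count >= 2  # noqa: E731
    retained, removed = [], []
    for r in records:
        if predicate(r):
            removed.append(r.subject_id)
        else:
            retained.append(r)
    if not retained:
        warnings.warn("subgroup exclusion removed every record", stacklevel=2)
    return SubgroupExclusion(retained=retained, removed_subject_ids=removed)


def fiber_percent_of_iom_target(
    fiber_g_per_day: float, kcal_per_day: float
) -> float:
    """Daily fiber intake as a percent of the 14 g / 1000 kcal guideline."""
    if kcal_per_day <= 0:
        raise CoinflamError("kcal_per_day must be positive")
    if fiber_g_per_day < 0:
        raise CoinflamError("fiber must be >= 0")
    target_g = IOM_FIBER_G_PER_1000_KCAL * kcal_per_day / 1000.0
    return 100.0 * fiber_g_per_day / target_g


def memory_naive_ratio(pct_memory: float, pct_naive: float) -> float:
    """CD4+CD45RO+ (memory) : CD4+CD45RA+ (naive) percentage ratio."""
    if pct_naive <= 0:
        raise CoinflamError("naive percentage must be positive")
    if not (0 <= pct_memory <= 100 and 0 < pct_naive <= 100):
        raise CoinflamError("percentages must lie in [0, 100]")
    return pct_memory / pct_naive


def pearson_with_p(x, y):
    """Pearson correlation with the two-sided p from the t transform.

    p is computed from t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of
    freedom.

    Returns
    -------
    (r, p) : tuple of float
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise CoinflamError("need equal-length 1-D arrays with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CoinflamError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
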