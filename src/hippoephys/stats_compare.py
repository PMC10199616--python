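"""Group-comparison layer: two-way ANOVA, small-sample pairwise tests with
Holm-Šídák adjustment, and learning-curve slope comparison.

Input is a long-format table (subject, factor1, factor2, value). Two-way
ANOVA uses Type-II sums of squares by default (appropriate for the mildly
unbalanced cell counts typical of these experiments; Type-III available).
Mann–Whitney and Wilcoxon use exact null distributions for n ≤ 12 per group
and the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

__all__ = [
    "TestResult",
    "two_way_anova",
    "pairwise_tests",
    "holm_sidak",
    "slope_compare",
    "per_subject_slopes",
]

EXACT_N_MAX = 12


@dataclasses.dataclass
class TestResult:
    name: str
    statistic: float
    df: tuple | float | None
    p: float
    adjusted_p: float | None = None
    direction: str | None = None
    flags: list[str] = dataclasses.field(default_factory=list)


def two_way_anova(
    tbl: pd.DataFrame,
    value: str = "value",
    factors: tuple[str, str] = ("factor1", "factor2"),
    ss_type: int = 2,
) -> list[TestResult]:
    """Two-way ANOVA with interaction on a long-format table.

    Returns one :class:`TestResult` per effect (factor1, factor2,
    interaction). Requires ≥ 2 levels per factor and ≥ 1 observation in
    every cell; an empty cell raises a ``ValueError`` naming it.
    """
    f1, f2 = factors
    for f in factors:
        if tbl[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    counts = tbl.groupby([f1, f2], observed=True)[value].count()
    full = pd.MultiIndex.from_product([tbl[f1].unique(), tbl[f2].unique()])
    for cell in full:
        if cell not in counts.index or counts[cell] == 0:
            raise ValueError(f"empty cell {f1}={cell[0]!r}, {f2}={cell[1]!r}")

    data = tbl.rename(columns={value: "_y", f1: "_f1", f2: "_f2"})
    model = ols("_y ~ C(_f1) * C(_f2)", data=data).fit()
    table = anova_lm(model, typ=ss_type)
    names = {"C(_f1)": f1, "C(_f2)": f2, "C(_f1):C(_f2)": f"{f1}:{f2}"}
    results = []
    resid_df = float(table.loc["Residual", "df"])
    for key, label in names.items():
        results.append(
            TestResult(
                name=f"anova[{label}]",
                statistic=float(table.loc[key, "F"]),
                df=(float(table.loc[key, "df"]), resid_df),
                p=float(table.loc[key, "PR(>F)"]),
            )
        )
    return results


def holm_sidak(pvals: np.ndarray) -> np.ndarray:
    """Holm-Šídák step-down adjustment.

    Sorted ascending, ``adj_(i) = 1 − (1 − p_(i))^(m − i + 1)`` with a
    running maximum enforcing monotonicity; returned in the input order.
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def _one_pair(
    name: str, x: np.ndarray, y: np.ndarray, method: str
) -> TestResult:
    flags: list[str] = []
    if method == "mann_whitney":
        mode = "exact" if (
            min(len(x), len(y)) <= EXACT_N_MAX
            and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
        ) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=mode)
        stat, p, df = float(res.statistic), float(res.pvalue), None
    elif method == "t_unpaired":
        res = stats.ttest_ind(x, y)
        stat, p, df = float(res.statistic), float(res.pvalue), len(x) + len(y) - 2
    elif method == "t_paired":
        if len(x) != len(y):
            raise ValueError(f"{name}: paired test requires matched subjects")
        res = stats.ttest_rel(x, y)
        stat, p, df = float(res.statistic), float(res.pvalue), len(x) - 1
    elif method == "wilcoxon":
        if len(x) != len(y):
            raise ValueError(f"{name}: paired test requires matched subjects")
        diffs = np.asarray(x) - np.asarray(y)
        if np.all(diffs == 0):
            flags.append("degenerate: all paired differences are zero")
            stat, p, df = 0.0, 1.0, None
        else:
            mode = "exact" if (len(diffs) <= EXACT_N_MAX
                               and len(np.unique(np.abs(diffs[diffs != 0])))
                               == np.count_nonzero(diffs)) else "approx"
            res = stats.wilcoxon(x, y, method=mode)
            stat, p, df = float(res.statistic), float(res.pvalue), None
    else:
        raise ValueError(f"unknown method {method!r}")
    if np.isnan(p):
        flags.append("degenerate: test statistic undefined; p set to 1")
        p = 1.0
    direction = "A>B" if np.mean(x) > np.mean(y) else "A<B" if np.mean(x) < np.mean(y) else "A=B"
    return TestResult(name=name, statistic=stat, df=df, p=p, direction=direction, flags=flags)


def pairwise_tests(
    pairs: list[tuple[str, np.ndarray, np.ndarray]],
    method: str = "mann_whitney",
    adjust: str = "holm_sidak",
) -> list[TestResult]:
    """Run a family of two-sample tests with optional Holm-Šídák adjustment.

    ``pairs`` is a list of ``(label, sample_a, sample_b)``; paired methods
    (``t_paired``, ``wilcoxon``) require samples matched by position. Exact
    null distributions are used for small tie-free samples.
    """
    results = [
        _one_pair(name, np.asarray(x, dtype=float), np.asarray(y, dtype=float), method)
        for name, x, y in pairs
    ]
    if adjust == "holm_sidak":
        adj = holm_sidak(np.array([r.p for r in results]))
        for r, a in zip(results, adj):
            r.adjusted_p = float(max(a, r.p))
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}")
    return results


def per_subject_slopes(
    series: pd.DataFrame,
    subject: str = "subject",
    trial: str = "trial",
    value: str = "value",
    trial_range: tuple[int, int] | None = None,
) -> pd.Series:
    """Least-squares slope per subject over the designated trials.

    Subjects with fewer than two usable trials are excluded with a warning.
    """
    sel = series
    if trial_range is not None:
        sel = series[(series[trial] >= trial_range[0]) & (series[trial] <= trial_range[1])]
    slopes = {}
    for subj, sub in sel.groupby(subject):
        sub = sub.dropna(subset=[value])
        if len(sub) < 2:
            warnings.warn(f"subject {subj!r} has < 2 trials; excluded", stacklevel=2)
            continue
        slopes[subj] = float(np.polyfit(sub[trial].astype(float), sub[value].astype(float), 1)[0])
    return pd.Series(slopes, name="slope")


def slope_compare(
    series_a: pd.DataFrame,
    series_b: pd.DataFrame,
    trial_range: tuple[int, int] | None = None,
    subject: str = "subject",
    trial: str = "trial",
    value: str = "value",
) -> TestResult:
    """Unpaired two-tailed t test on per-subject learning-curve slopes.

    Mirrors a relearning-phase comparison: each subject's slope over the
    designated trial window is computed by least squares and the two slope
    sets are compared with an unpaired t test.
    """
    sa = per_subject_slopes(series_a, subject, trial, value, trial_range)
    sb = per_subject_slopes(series_b, subject, trial, value, trial_range)
    res = _one_pair("slope_compare", sa.to_numpy(), sb.to_numpy(), "t_unpaired")
    return res
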