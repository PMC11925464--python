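"""Group comparisons and summary tables.

Per-animal readouts are compared between a control genotype and each
mutant with either the unpaired two-tailed Student's t test
(pooled variance — Welch's correction is available behind a flag) or the
two-sided Mann-Whitney U test (exact by enumeration for small untied
samples, normal approximation with tie and continuity correction
otherwise).  No multiple-testing correction is applied: each contrast is
reported raw, as is conventional for this assay family; interpret families
of contrasts accordingly.  Significance stars follow the usual
0.05 / 0.01 / 0.001 convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "students_t_two_tailed",
    "mann_whitney",
    "significance_stars",
    "summarize_groups",
]

#: two-sided p-value thresholds for *, **, ***.
STAR_THRESHOLDS = (0.05, 0.01, 0.001)


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    group_means_or_medians: tuple
    degenerate: bool = False


def _check(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    return x, y


def students_t_two_tailed(x, y, welch: bool = False) -> GroupComparison:
    """Unpaired two-tailed t test (pooled variance unless ``welch``).

    Degenerate zero-variance samples are handled explicitly: equal means
    give p = 1, unequal means give p = 0 with the ``degenerate`` flag set.
    """
    x, y = _check(x, y)
    n1, n2 = x.size, y.size
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        equal = x.mean() == y.mean()
        return GroupComparison(
            "students_t", 0.0 if equal else np.inf, 1.0 if equal else 0.0,
            n1, n2, (float(x.mean()), float(y.mean())), degenerate=not equal,
        )
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return GroupComparison(
        "students_t", float(res.statistic), float(res.pvalue),
        n1, n2, (float(x.mean()), float(y.mean())),
    )


def mann_whitney(x, y, mode: str = "auto") -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    ``mode``: ``"exact"`` enumerates the permutation null (valid only
    without ties), ``"approx"`` uses the normal approximation with tie and
    continuity correction, ``"auto"`` picks exact when n1 + n2 <= 16 and no
    ties are present.  Two identical samples give p = 1.
    """
    x, y = _check(x, y)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (n1 + n2 <= 16 and not has_ties) else "approx"
    if mode not in ("exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    if np.ptp(pooled) == 0:
        return GroupComparison(
            "mann_whitney", float(n1 * n2 / 2.0), 1.0, n1, n2,
            (float(np.median(x)), float(np.median(y))),
        )
    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode is invalid with ties; use approx")
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
    return GroupComparison(
        "mann_whitney", float(res.statistic), float(min(res.pvalue, 1.0)),
        n1, n2, (float(np.median(x)), float(np.median(y))),
    )


def significance_stars(p: float) -> str:
    if p < STAR_THRESHOLDS[2]:
        return "***"
    if p < STAR_THRESHOLDS[1]:
        return "**"
    if p < STAR_THRESHOLDS[0]:
        return "*"
    return "ns"


def summarize_groups(
    values: Sequence[float],
    grouping: Sequence[str],
    control: Optional[str] = None,
    test: str = "students_t",
) -> pd.DataFrame:
    """Per-group summary with pairwise comparison against a control group.

    Returns a DataFrame with one row per group: n, mean, sd, median, and —
    for non-control groups — the configured test's statistic, two-sided p
    and significance stars versus the control.  Groups with n < 2 are
    excluded with a warning.  ``test`` is ``"students_t"`` or
    ``"mann_whitney"`` (per-contrast choice is a config decision, never
    auto-selected from the data).
    """
    import warnings

    values = np.asarray(values, dtype=float)
    grouping = np.asarray(grouping)
    if values.shape != grouping.shape:
        raise ValueError("values and grouping must align")
    groups = {}
    for g in pd.unique(grouping):
        v = values[grouping == g]
        if v.size < 2:
            warnings.warn(f"group {g!r} has n={v.size} < 2; excluded")
            continue
        groups[g] = v
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with n >= 2")
    if control is None:
        control = next(iter(groups))
    if control not in groups:
        raise ValueError(f"control group {control!r} not present")
    testers = {"students_t": students_t_two_tailed, "mann_whitney": mann_whitney}
    if test not in testers:
        raise ValueError(f"unknown test {test!r}")

    rows = []
    for g, v in groups.items():
        row = {
            "group": g,
            "n": int(v.size),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)),
            "median": float(np.median(v)),
            "test": "",
            "statistic": np.nan,
            "p_value": np.nan,
            "stars": "",
        }
        if g != control:
            cmp = testers[test](groups[control], v)
            row.update(test=cmp.test, statistic=cmp.statistic,
                       p_value=cmp.p_value, stars=significance_stars(cmp.p_value))
        rows.append(row)
    return pd.DataFrame(rows)
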