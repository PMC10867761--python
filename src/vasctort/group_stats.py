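"""Group summaries and significance testing with star annotations.

Two groups are compared with the classical two-tailed unpaired Student t
test (pooled variance; Welch available via ``welch=True``); three or more
groups with a one-way ANOVA F test.  No multiple-testing correction is
applied.  Significance stars use strict thresholds:
``**** p < 1e-4, *** p < 1e-3, ** p < 0.01, * p < 0.05``, else ``ns``
(so p exactly 0.05 is ``ns``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "GroupSummary",
    "GroupComparison",
    "summarize_groups",
    "compare",
    "assign_stars",
]


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float
    sem: float
    singleton: bool = False  # n == 1: sd/sem reported as 0 and flagged


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    groups: tuple[GroupSummary, ...]
    test: str  # "t_unpaired" or "anova_oneway"
    statistic: float
    p_value: float
    stars: str


def summarize_groups(groups: dict[str, list[float]]) -> list[GroupSummary]:
    """Mean, sample SD (n-1 denominator) and SEM per group.

    A singleton group has undefined SD; it is reported as 0 with the
    ``singleton`` flag set.
    """
    out = []
    for label, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValidationError(f"group {label!r} is empty")
        singleton = arr.size == 1
        sd = 0.0 if singleton else float(arr.std(ddof=1))
        sem = 0.0 if singleton else sd / np.sqrt(arr.size)
        out.append(
            GroupSummary(
                label=label,
                n=int(arr.size),
                mean=float(arr.mean()),
                sd=sd,
                sem=sem,
                singleton=singleton,
            )
        )
    return out


def assign_stars(p: float) -> str:
    """Map a p-value to the star annotation (strict inequalities)."""
    if not (0.0 <= p <= 1.0) or np.isnan(p):
        raise ValidationError(f"p-value must be in [0, 1], got {p}")
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare(
    groups: dict[str, list[float]], metric: str = "value", welch: bool = False
) -> GroupComparison:
    """Test for a group difference: unpaired t for 2 groups, one-way ANOVA
    for 3 or more.  Every group needs n >= 2."""
    if len(groups) < 2:
        raise ValidationError("compare needs at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    small = [k for k, v in arrays.items() if v.size < 2]
    if small:
        raise ValidationError(f"groups with n < 2 cannot be tested: {small}")
    summaries = tuple(summarize_groups(groups))
    vals = list(arrays.values())
    if len(vals) == 2:
        stat, p = stats.ttest_ind(vals[0], vals[1], equal_var=not welch)
        test = "t_welch" if welch else "t_unpaired"
    else:
        stat, p = stats.f_oneway(*vals)
        test = "anova_oneway"
    # identical groups give 0/0 inside the test; that is "no difference"
    if np.isnan(p):
        stat, p = 0.0, 1.0
    return GroupComparison(
        metric=metric,
        groups=summaries,
        test=test,
        statistic=float(stat),
        p_value=float(p),
        stars=assign_stars(float(p)),
    )
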