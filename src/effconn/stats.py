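"""Group statistics: one-way ANOVA with Dunnett's many-to-one post hoc tests.

Each network parameter is compared across treatment groups against a named
control group: an omnibus one-way ANOVA (F, degrees of freedom, p) followed
by two-sided Dunnett tests of every non-control group against the control,
with significance stars at 0.05 (*), 0.01 (**), and 0.001 (***).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import NetworkMetrics

__all__ = ["GroupComparison", "compare_groups", "summarize_cohort", "r_squared"]

_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for level, stars in _STAR_LEVELS:
        if p < level:
            return stars
    return ""


@dataclass
class GroupComparison:
    """ANOVA + Dunnett results for one metric across named groups."""

    metric: str
    groups: dict[str, np.ndarray]
    control: str
    group_mean: dict[str, float]
    group_sem: dict[str, float]
    anova_f: float
    anova_df: tuple[int, int]
    anova_p: float
    dunnett_p: dict[str, float]
    dunnett_stars: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.dunnett_stars:
            self.dunnett_stars = {g: significance_stars(p) for g, p in self.dunnett_p.items()}

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "control": self.control,
            "group_mean": self.group_mean,
            "group_sem": self.group_sem,
            "anova_F": self.anova_f,
            "anova_df": list(self.anova_df),
            "anova_p": self.anova_p,
            "dunnett_p": self.dunnett_p,
            "dunnett_stars": self.dunnett_stars,
        }


def compare_groups(
    samples: Mapping[str, Sequence[float]],
    control: str,
    metric: str = "",
    random_state: int | None = 0,
) -> GroupComparison:
    """One-way ANOVA plus two-sided Dunnett tests against the control group.

    ``anova_df`` is ``(k - 1, n_total - k)``.  The Dunnett p-values are
    adjusted for the many-to-one comparisons through the multivariate-t
    distribution of the contrast vector (equal-variance model).
    """
    if control not in samples:
        raise ValueError(f"control group {control!r} not among the samples")
    if len(samples) < 2:
        raise ValueError("at least two groups are required")
    arrays = {g: np.asarray(v, dtype=float) for g, v in samples.items()}
    for g, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than two values")
    if all(np.ptp(v) == 0 for v in arrays.values()):
        raise ValueError("zero within-group variance in every group: F undefined")
    k = len(arrays)
    n_total = sum(v.size for v in arrays.values())
    f_stat, p_val = sps.f_oneway(*arrays.values())
    treatment_names = [g for g in arrays if g != control]
    res = sps.dunnett(
        *(arrays[g] for g in treatment_names),
        control=arrays[control],
        alternative="two-sided",
        random_state=random_state,
    )
    dunnett_p = {g: float(p) for g, p in zip(treatment_names, res.pvalue)}
    return GroupComparison(
        metric=metric,
        groups=arrays,
        control=control,
        group_mean={g: float(v.mean()) for g, v in arrays.items()},
        group_sem={g: float(sps.sem(v)) for g, v in arrays.items()},
        anova_f=float(f_stat),
        anova_df=(k - 1, n_total - k),
        anova_p=float(p_val),
        dunnett_p=dunnett_p,
    )


def summarize_cohort(
    metrics_by_group: Mapping[str, Sequence[NetworkMetrics]],
    control: str,
    fields: Sequence[str] | None = None,
) -> list[GroupComparison]:
    """Run :func:`compare_groups` for every scalar network parameter.

    Metrics whose values are non-finite in some network (e.g. modularity of
    an edgeless network) drop those networks from the comparison; a metric
    left with fewer than two values in any group is skipped.
    """
    if not metrics_by_group:
        raise ValueError("empty cohort")
    fields = tuple(fields) if fields is not None else NetworkMetrics.SCALAR_FIELDS
    comparisons = []
    for name in fields:
        samples = {}
        ok = True
        for g, records in metrics_by_group.items():
            vals = np.array([getattr(m, name) for m in records], dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size < 2:
                ok = False
                break
            samples[g] = vals
        if not ok:
            continue
        try:
            comparisons.append(compare_groups(samples, control, metric=name))
        except ValueError:
            continue  # e.g. zero variance everywhere
    return comparisons


def comparison_table(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Flat machine-readable table, one row per (metric, group)."""
    rows = []
    for c in comparisons:
        for g in c.groups:
            rows.append(
                {
                    "metric": c.metric,
                    "group": g,
                    "n": c.groups[g].size,
                    "mean": c.group_mean[g],
                    "sem": c.group_sem[g],
                    "anova_F": c.anova_f,
                    "anova_df1": c.anova_df[0],
                    "anova_df2": c.anova_df[1],
                    "anova_p": c.anova_p,
                    "dunnett_p": c.dunnett_p.get(g, np.nan),
                    "stars": c.dunnett_stars.get(g, ""),
                }
            )
    return pd.DataFrame(rows)


def r_squared(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation between two network-level quantities."""
    r = np.corrcoef(np.asarray(x, float), np.asarray(y, float))[0, 1]
    return float(r**2)
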