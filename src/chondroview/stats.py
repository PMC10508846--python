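"""Group-comparison statistics for the experiment reports.

Deliberately thin: paired and unpaired two-sided Student's t-tests for
two groups and one-way ANOVA for more, at α = 0.05, with no
multiple-testing correction — matching the study design the pipelines
serve. Test dispatch follows the design: a pairing key selects the
paired t-test, more than two groups select ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class GroupSummary:
    name: str
    n: int
    mean: float
    sd: float


@dataclass
class ComparisonReport:
    """Outcome of one group comparison.

    ``degenerate`` flags a paired difference vector with zero variance,
    where the t statistic is undefined: the p-value is reported as 1.0
    when the differences are identically zero and 0.0 when they share a
    nonzero value (the difference is then exact, not sampled), instead
    of emitting an infinite statistic.
    """

    groups: list[GroupSummary]
    test: str                      # "paired t" | "unpaired t" | "one-way ANOVA"
    statistic: float | None
    df: float | tuple[float, float] | None
    p_value: float
    alpha: float = 0.05
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "groups": [g.__dict__ for g in self.groups],
            "test": self.test,
            "statistic": self.statistic,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "significant": self.significant,
            "degenerate": self.degenerate,
        }


def compare_groups(
    groups: dict[str, np.ndarray],
    paired: bool = False,
    alpha: float = 0.05,
) -> ComparisonReport:
    """Dispatch the appropriate test for a set of per-group value vectors.

    Two groups: Student's t (paired when ``paired``, which requires
    aligned, equal-length vectors). More than two: one-way ANOVA
    (``paired`` is rejected there — no repeated-measures model is
    offered). All p-values are two-sided.
    """
    names = list(groups)
    vals = [np.asarray(groups[k], dtype=float) for k in names]
    if len(vals) < 2:
        raise ValueError("need at least two groups")
    for name, v in zip(names, vals):
        if v.size < 2:
            raise ValueError(f"group {name!r} needs >= 2 values")
    summaries = [
        GroupSummary(name=k, n=v.size, mean=float(v.mean()), sd=float(v.std(ddof=1)))
        for k, v in zip(names, vals)
    ]

    if len(vals) > 2:
        if paired:
            raise ValueError("paired comparison is defined for exactly two groups")
        stat, p = sps.f_oneway(*vals)
        k, n = len(vals), sum(v.size for v in vals)
        return ComparisonReport(summaries, "one-way ANOVA", float(stat),
                                (float(k - 1), float(n - k)), float(p), alpha)

    a, b = vals
    if paired:
        if a.size != b.size:
            raise ValueError("paired design requires equal group sizes")
        d = a - b
        if np.all(d == d[0]):  # zero-variance differences: t undefined
            p = 1.0 if d[0] == 0 else 0.0
            return ComparisonReport(summaries, "paired t", None, float(a.size - 1),
                                    p, alpha, degenerate=True)
        stat, p = sps.ttest_rel(a, b)
        return ComparisonReport(summaries, "paired t", float(stat),
                                float(a.size - 1), float(p), alpha)

    stat, p = sps.ttest_ind(a, b)
    return ComparisonReport(summaries, "unpaired t", float(stat),
                            float(a.size + b.size - 2), float(p), alpha)
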