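"""Replicate-level analysis: summaries, pooled t-tests, effect sizes.

Replicate fitness values are compared between the modular network (PMN)
and each non-modular network (FCNMN, SNMN) within a design cell with the
equal-variance two-sample t-test,

    t = (mean_a - mean_b) / (s_p sqrt(1/n_a + 1/n_b)),   df = n_a + n_b - 2,

where s_p is the pooled standard deviation, and with the standardized mean
difference d (Cohen's d on the pooled SD; the Hedges small-sample
correction is available as an option and off by default).

Sign conventions, chosen to match the standard presentation of these
comparisons and documented in the report columns: the reported t statistic
is (non-modular minus modular), while the effect size d is (modular minus
non-modular), so positive d means the modular network performs better.

No multiple-testing correction is applied; the report carries the total
comparison count so readers can apply their own, and marginal p-values
near 0.05 deserve scepticism.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .networks import ArchitectureKind

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "summarize",
    "pooled_t_test",
    "effect_size_d",
    "significance_stars",
    "build_comparison_report",
    "plot_effect_sizes",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupSummary:
    """Mean with a symmetric 95% t-interval: mean +/- t(0.975, n-1) * sd / sqrt(n)."""

    n: int
    mean: float
    sd: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sample comparison; ``direction`` names the sign convention of t and d."""

    t_statistic: float
    df: int
    p_value: float
    effect_size_d: float
    direction: str = "a_minus_b"


def summarize(values: Sequence[float]) -> GroupSummary:
    values = np.asarray(values, dtype=np.float64)
    n = len(values)
    if n < 2:
        raise ValueError(f"need at least 2 values to summarize, got {n}")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    half = float(scipy.stats.t.ppf(0.975, n - 1)) * sd / math.sqrt(n)
    return GroupSummary(n=n, mean=mean, sd=sd, ci95=(mean - half, mean + half))


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    df = len(a) + len(b) - 2
    return math.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df)


def pooled_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> ComparisonResult:
    """Equal-variance two-sample t-test; t and d are signed (a minus b).

    A degenerate zero pooled variance is signalled explicitly: equal means
    give t = 0, p = 1; unequal means give t = +/-inf, p = 0.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    df = len(a) + len(b) - 2
    s_p = _pooled_sd(a, b)
    if s_p == 0.0:
        delta = a.mean() - b.mean()
        if delta == 0.0:
            return ComparisonResult(0.0, df, 1.0, 0.0)
        t = math.copysign(math.inf, delta)
        return ComparisonResult(t, df, 0.0, t)
    res = scipy.stats.ttest_ind(a, b, equal_var=True)
    d = float(a.mean() - b.mean()) / s_p
    return ComparisonResult(float(res.statistic), df, float(res.pvalue), d)


def effect_size_d(
    group_mod: Sequence[float],
    group_other: Sequence[float],
    hedges: bool = False,
) -> float:
    """Standardized mean difference (modular minus other) on the pooled SD.

    Positive d means the modular group scores higher.  ``hedges=True``
    applies the small-sample correction 1 - 3/(4 df - 1).
    """
    a = np.asarray(group_mod, dtype=np.float64)
    b = np.asarray(group_other, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    s_p = _pooled_sd(a, b)
    if s_p == 0.0:
        if a.mean() == b.mean():
            return 0.0
        raise ZeroDivisionError("effect size undefined: zero pooled SD with unequal means")
    d = float(a.mean() - b.mean()) / s_p
    if hedges:
        df = len(a) + len(b) - 2
        d *= 1.0 - 3.0 / (4.0 * df - 1.0)
    return d


def significance_stars(p_value: float) -> str:
    """'**' for p < 0.01, '*' for 0.01 <= p < 0.05, '' otherwise."""
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def build_comparison_report(
    table: pd.DataFrame,
    value_column: str = "best_fitness",
    hedges: bool = False,
) -> pd.DataFrame:
    """Modular-vs-non-modular comparisons for every design cell of a results table.

    For each (state, n_modules, generation) cell the PMN replicates are
    compared with each available non-modular architecture.  Columns document
    the sign conventions: ``t_nonmod_minus_mod`` (matching "FCNMN versus
    PMN" statistics) and ``d_mod_minus_nonmod`` (positive when the modular
    network performs better).  Cells missing an architecture are skipped
    with a logged warning.  ``n_comparisons`` carries the total comparison
    count of the whole report (no multiplicity correction is applied).
    """
    required = {"state", "architecture", "n_modules", "replicate", "generation", value_column}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"results table lacks columns: {sorted(missing)}")
    rows = []
    for (state, m, gen), cell in table.groupby(["state", "n_modules", "generation"]):
        groups = {
            arch: sub[value_column].to_numpy()
            for arch, sub in cell.groupby("architecture")
        }
        if ArchitectureKind.PMN.value not in groups:
            logger.warning("no PMN replicates for state=%s m=%s gen=%s; cell skipped", state, m, gen)
            continue
        pmn = groups[ArchitectureKind.PMN.value]
        for other_kind in (ArchitectureKind.FCNMN, ArchitectureKind.SNMN):
            other = groups.get(other_kind.value)
            if other is None:
                logger.warning(
                    "no %s replicates for state=%s m=%s gen=%s; comparison skipped",
                    other_kind.value, state, m, gen,
                )
                continue
            test = pooled_t_test(other, pmn)
            s_pmn, s_other = summarize(pmn), summarize(other)
            rows.append(
                {
                    "state": state,
                    "n_modules": m,
                    "generation": gen,
                    "comparison": f"{other_kind.value}_vs_PMN",
                    "n_mod": s_pmn.n,
                    "n_nonmod": s_other.n,
                    "mean_mod": s_pmn.mean,
                    "mean_nonmod": s_other.mean,
                    "ci95_mod_low": s_pmn.ci95[0],
                    "ci95_mod_high": s_pmn.ci95[1],
                    "ci95_nonmod_low": s_other.ci95[0],
                    "ci95_nonmod_high": s_other.ci95[1],
                    "t_nonmod_minus_mod": test.t_statistic,
                    "df": test.df,
                    "p_value": test.p_value,
                    "d_mod_minus_nonmod": effect_size_d(pmn, other, hedges=hedges),
                    "stars": significance_stars(test.p_value),
                }
            )
    report = pd.DataFrame(rows)
    if len(report):
        report["n_comparisons"] = len(report)
    return report


def plot_effect_sizes(report: pd.DataFrame, path=None):
    """Bar chart of effect sizes d per design cell, starred by significance.

    Bars above zero mean the modular network performs better.  One panel
    per system state; bars grouped by (size, checkpoint, comparator).
    Returns the matplotlib figure; writes it to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    states = sorted(report["state"].unique())
    fig, axes = plt.subplots(1, len(states), figsize=(4 * len(states), 3.2), squeeze=False)
    for ax, state in zip(axes[0], states):
        sub = report[report["state"] == state].sort_values(
            ["n_modules", "generation", "comparison"]
        )
        labels = [
            f"m={r.n_modules}\ng{r.generation}\n{r.comparison.split('_')[0]}"
            for r in sub.itertuples()
        ]
        bars = ax.bar(range(len(sub)), sub["d_mod_minus_nonmod"], color="steelblue")
        for rect, (_, row) in zip(bars, sub.iterrows()):
            if row["stars"]:
                y = rect.get_height()
                ax.text(rect.get_x() + rect.get_width() / 2, y, row["stars"],
                        ha="center", va="bottom" if y >= 0 else "top", fontsize=9)
        ax.axhline(0.0, color="black", lw=0.8)
        ax.set_xticks(range(len(sub)))
        ax.set_xticklabels(labels, fontsize=6)
        ax.set_title(f"state {state}")
        ax.set_ylabel("effect size d (modular - non-modular)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
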