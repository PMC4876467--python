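"""Descriptive and comparative cohort statistics.

Crude incidence arithmetic and baseline-table group comparisons: Pearson
chi-square (no continuity correction) when every expected cell count is at
least 5, Fisher's exact test otherwise; Welch's t-test for continuous
variables.  All tests two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import frame_from_records_or_frame


@dataclass(frozen=True)
class ContingencyTable:
    """2 x k table of non-negative integer counts with labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
            raise ValueError("contingency table must be at least 2 x 2")
        if np.any(c < 0):
            raise ValueError("negative count in contingency table")
        if np.any(c.sum(axis=0) == 0) or np.any(c.sum(axis=1) == 0):
            raise ValueError("degenerate margin (all-zero row or column)")
        object.__setattr__(self, "counts", c)


def crude_rate(n_events: int, n_total: int) -> float:
    """Crude percentage 100 * events / total, to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_events <= n_total:
        raise ValueError("n_events must be in [0, n_total]")
    return round(100.0 * n_events / n_total, 1)


def compare_categorical(table: ContingencyTable) -> tuple[str, float, float]:
    """Group comparison of a contingency table.

    Pearson chi-square without continuity correction when all expected counts
    are >= 5; otherwise Fisher's exact (two-sided) for 2x2 tables.  Returns
    (method, statistic, P); Fisher's statistic is the odds ratio.
    """
    counts = table.counts
    expected = sps.contingency.expected_freq(counts)
    if np.all(expected >= 5.0):
        chi2, p, _, _ = sps.chi2_contingency(counts, correction=False)
        return "pearson_chi2", float(chi2), float(p)
    if counts.shape == (2, 2):
        oddsratio, p = sps.fisher_exact(counts, alternative="two-sided")
        return "fisher_exact", float(oddsratio), float(p)
    # 2 x k with sparse cells: chi-square is the only closed-form option
    chi2, p, _, _ = sps.chi2_contingency(counts, correction=False)
    return "pearson_chi2_small_expected", float(chi2), float(p)


def compare_continuous(x_a, x_b, equal_var: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test (Welch by default). Returns (t, P)."""
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.size < 2 or x_b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(x_a) == 0 and np.var(x_b) == 0:
        if np.mean(x_a) == np.mean(x_b):
            return 0.0, 1.0
        raise ValueError("zero variance in both groups")
    res = sps.ttest_ind(x_a, x_b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def rank_sum(x_a, x_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum alternative for skewed variables."""
    res = sps.mannwhitneyu(x_a, x_b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def baseline_table(lobes) -> pd.DataFrame:
    """Patient-level baseline comparison of injured vs uninjured patients.

    One row per characteristic: counts (or medians) per group, the test used
    and its two-sided P.  Mirrors the conventional 'Table 1' of a toxicity
    cohort report.
    """
    df = frame_from_records_or_frame(lobes)
    pat = df.groupby("patient_id").agg(
        injured=("event", "max"), age=("age", "first"), sex=("sex", "first"),
        t_stage=("t_stage", "first"), chemo=("chemo", "first"))
    with_tli = pat[pat["injured"] == 1]
    without = pat[pat["injured"] == 0]
    rows = []

    t_stat, p = compare_continuous(without["age"], with_tli["age"])
    rows.append({"characteristic": "age", "group_without": f"median {without['age'].median():.0f}",
                 "group_with": f"median {with_tli['age'].median():.0f}",
                 "method": "welch_t", "statistic": t_stat, "p": p})

    for name, levels in (("sex", ("male", "female")),
                         ("t_stage", ("T1-2", "T3-4")),
                         ("chemo", ("yes", "no"))):
        counts = np.array([
            [int((without[name] == lv).sum()) for lv in levels],
            [int((with_tli[name] == lv).sum()) for lv in levels],
        ])
        method, stat, p = compare_categorical(
            ContingencyTable(counts, ("without_tli", "with_tli"), levels))
        rows.append({"characteristic": name,
                     "group_without": "/".join(str(c) for c in counts[0]),
                     "group_with": "/".join(str(c) for c in counts[1]),
                     "method": method, "statistic": stat, "p": p})
    return pd.DataFrame(rows)
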