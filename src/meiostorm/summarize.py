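"""Per-nucleus / per-stage aggregation and group-comparison tests.

Configuration fractions are computed per nucleus (each nucleus one
vote) and aggregated as mean +/- SD across the nuclei of a stage.
Group comparisons run the standard two-sided tests at a declared unit
of analysis (nucleus, ROI or nanofocus), which is recorded in the
output; no multiple-testing correction is applied and raw p-values are
reported with the test name.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .nanofoci import Configuration

__all__ = ["summarize_configurations", "compare_groups", "GroupComparison"]

MAIN_LABELS = ["D1R1", "D2R1", "D1R2"]


def summarize_configurations(
    configs: Sequence[Configuration],
    metadata: Mapping[str, Mapping[str, str]],
    labels: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-nucleus configuration fractions and stage-level aggregation.

    ``metadata`` maps nucleus_id -> {"genotype": ..., "stage": ...};
    nuclei without a stage are excluded with a warning. ``labels``
    fixes the configuration universe (default: labels present); any
    other label is pooled into "other". Returns (per-nucleus table,
    stage-level mean +/- SD table).
    """
    rows = []
    for cfg in configs:
        meta = metadata.get(cfg.nucleus_id)
        if meta is None or not meta.get("stage"):
            warnings.warn(f"nucleus {cfg.nucleus_id!r} lacks stage metadata; excluded")
            continue
        rows.append(
            (cfg.nucleus_id, meta.get("genotype", "other"), str(meta["stage"]), cfg.label)
        )
    if not rows:
        return pd.DataFrame(), pd.DataFrame()
    df = pd.DataFrame(rows, columns=["nucleus_id", "genotype", "stage", "label"])
    if labels is None:
        labels = sorted(df["label"].unique())
    df["label"] = np.where(df["label"].isin(labels), df["label"], "other")
    universe = list(labels) + (["other"] if (df["label"] == "other").any() else [])
    counts = (
        df.groupby(["genotype", "stage", "nucleus_id"])["label"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=universe, fill_value=0)
    )
    fractions = counts.div(counts.sum(axis=1), axis=0)
    stage_stats = fractions.groupby(["genotype", "stage"]).agg(["mean", "std", "count"])
    return fractions.reset_index(), stage_stats


@dataclass
class GroupComparison:
    test: str
    unit: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]


def compare_groups(
    values,
    grouping=None,
    test: str = "t_two_sided",
    unit: str = "nucleus",
) -> GroupComparison:
    """Two-sided comparison of two groups at a declared unit of analysis.

    ``values``/``grouping`` are parallel sequences (or ``values`` is a
    2x2 count table for ``fisher_exact``). Tests: ``t_two_sided``,
    ``wilcoxon_rank_sum`` (unpaired), ``wilcoxon_signed_rank`` (paired;
    ``wilcoxon`` aliases to the unpaired rank-sum, see docs), and
    ``fisher_exact``.
    """
    if test == "fisher_exact":
        table = np.asarray(values, int)
        if table.shape != (2, 2):
            raise ValueError("fisher_exact expects a 2x2 count table")
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return GroupComparison(test, unit, float(odds), float(p),
                               tuple(int(n) for n in table.sum(axis=1)))

    values = np.asarray(values, float)
    groups = np.asarray(grouping)
    names = np.unique(groups)
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(names)}")
    a = values[groups == names[0]]
    b = values[groups == names[1]]
    if test in ("t_two_sided", "wilcoxon_rank_sum", "wilcoxon"):
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need >= 2 units per group")
        if test == "t_two_sided":
            res = stats.ttest_ind(a, b)
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return GroupComparison(test, unit, float(res.statistic), float(res.pvalue),
                               (len(a), len(b)))
    if test == "wilcoxon_signed_rank":
        if len(a) != len(b):
            raise ValueError("signed-rank test needs paired samples of equal size")
        if len(a) < 2:
            raise ValueError("need >= 2 pairs")
        res = stats.wilcoxon(a, b)
        return GroupComparison(test, unit, float(res.statistic), float(res.pvalue),
                               (len(a), len(b)))
    raise ValueError(f"unknown test {test!r}")
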