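"""Aggregation and inference over the Monte-Carlo results.

Produces per-(scenario, timepoint, policy) summary statistics (means,
SDs, boxplot quartiles with 1.5*IQR whiskers) for both mortality metrics
and, per (scenario, timepoint), a one-way fixed-effects ANOVA across the
policy groups of per-run mortalities followed by Tukey's honestly
significant difference post-hoc test on all 45 policy pairs at a 5%
significance level.
"""

from __future__ import annotations

import itertools
import math
import os
from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ConfigurationError

_GROUP = ["scenario", "t", "policy"]

#: p-values below this are displayed as the floor label in reports.
P_FLOOR = 1e-16


@dataclass
class SummaryTable:
    """Group statistics for the realized and predicted mortality metrics."""

    realized: pd.DataFrame
    predicted: pd.DataFrame


@dataclass
class StatsResult:
    """Inference for one (scenario, timepoint) cell."""

    scenario: int
    t: int
    f_stat: float
    p_value: float
    alpha: float
    pairs: pd.DataFrame  # policy_a, policy_b, mean_diff, p_adj, significant


def _summarize_metric(results: pd.DataFrame, value: str) -> pd.DataFrame:
    def stats_of(g: pd.Series) -> pd.Series:
        q1, med, q3 = g.quantile([0.25, 0.5, 0.75])
        iqr = q3 - q1
        inside = g[(g >= q1 - 1.5 * iqr) & (g <= q3 + 1.5 * iqr)]
        return pd.Series(
            {
                "mean": g.mean(),
                "sd": g.std(ddof=1) if len(g) > 1 else 0.0,
                "min": g.min(),
                "q1": q1,
                "median": med,
                "q3": q3,
                "max": g.max(),
                "whisker_low": inside.min(),
                "whisker_high": inside.max(),
                "n": len(g),
            }
        )

    out = results.groupby(_GROUP)[value].apply(stats_of).unstack().reset_index()
    out["n"] = out["n"].astype(int)
    return out


def summarize(results: pd.DataFrame) -> SummaryTable:
    """Deterministic group statistics for both metrics."""
    if results.empty:
        empty = pd.DataFrame(
            columns=_GROUP
            + ["mean", "sd", "min", "q1", "median", "q3", "max",
               "whisker_low", "whisker_high", "n"]
        )
        return SummaryTable(realized=empty, predicted=empty.copy())
    return SummaryTable(
        realized=_summarize_metric(results, "realized_mortality"),
        predicted=_summarize_metric(results, "predicted_mortality"),
    )


def anova_tukey(
    results: pd.DataFrame,
    scenario: int,
    t: int,
    alpha: float = 0.05,
    value: str = "realized_mortality",
) -> StatsResult:
    """One-way ANOVA + Tukey HSD across policies within one (scenario, t).

    Zero within-group variance everywhere is reported as the exact-tie
    case (F=0/no pairs if all means agree, F=inf/differing pairs flagged
    otherwise) rather than crashing.
    """
    cell = results[(results["scenario"] == scenario) & (results["t"] == t)]
    policies = sorted(cell["policy"].unique())
    if len(policies) < 2:
        raise ConfigurationError("ANOVA needs at least two policy groups")
    groups = [cell.loc[cell["policy"] == p, value].to_numpy() for p in policies]
    if any(len(g) < 2 for g in groups):
        raise ConfigurationError("ANOVA needs at least two runs per policy")

    means = [g.mean() for g in groups]
    if all(np.ptp(g) == 0.0 for g in groups):  # degenerate: exact ties
        distinct = np.ptp(means) > 0.0
        pairs = pd.DataFrame(
            [
                (a, b, means[j] - means[i], 0.0 if means[i] != means[j] else 1.0)
                for (i, a), (j, b) in itertools.combinations(enumerate(policies), 2)
            ],
            columns=["policy_a", "policy_b", "mean_diff", "p_adj"],
        )
        pairs["significant"] = pairs["p_adj"] < alpha
        return StatsResult(
            scenario=scenario,
            t=t,
            f_stat=math.inf if distinct else 0.0,
            p_value=0.0 if distinct else 1.0,
            alpha=alpha,
            pairs=pairs,
        )

    f_stat, p_value = sps.f_oneway(*groups)
    tukey = pairwise_tukeyhsd(
        endog=cell[value].to_numpy(), groups=cell["policy"].to_numpy(), alpha=alpha
    )
    pair_labels = list(itertools.combinations(tukey.groupsunique.tolist(), 2))
    pairs = pd.DataFrame(
        {
            "policy_a": [a for a, _ in pair_labels],
            "policy_b": [b for _, b in pair_labels],
            "mean_diff": tukey.meandiffs,
            "p_adj": tukey.pvalues,
            "significant": tukey.reject,
        }
    )
    return StatsResult(
        scenario=scenario,
        t=t,
        f_stat=float(f_stat),
        p_value=float(p_value),
        alpha=alpha,
        pairs=pairs,
    )


def anova_tukey_all(results: pd.DataFrame, alpha: float = 0.05) -> List[StatsResult]:
    cells = results[["scenario", "t"]].drop_duplicates().sort_values(["scenario", "t"])
    return [
        anova_tukey(results, int(row.scenario), int(row.t), alpha=alpha)
        for row in cells.itertuples(index=False)
    ]


def _format_p(p: float) -> str:
    return f"<{P_FLOOR:g}" if 0.0 < p < P_FLOOR else format(p, ".6g")


def _stats_frame(stats: List[StatsResult]) -> pd.DataFrame:
    rows = []
    for res in stats:
        row = {
            "scenario": res.scenario,
            "t": res.t,
            "f_stat": format(res.f_stat, ".6g"),
            "p_value": _format_p(res.p_value),
        }
        for pair in res.pairs.itertuples(index=False):
            row[f"p_{int(pair.policy_a)}_{int(pair.policy_b)}"] = _format_p(pair.p_adj)
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["scenario", "t", "f_stat", "p_value"])
    return pd.DataFrame(rows)


def export_reports(summary: SummaryTable, stats: List[StatsResult], outdir) -> dict:
    """Write the plot-ready report CSVs; returns {name: path}.

    ``summary.csv`` / ``summary_predicted.csv`` carry the group means and
    SDs per metric, ``stats.csv`` one row per (scenario, t) with the F
    statistic, its p-value and all pairwise Tukey-adjusted p-values, and
    ``boxplot_data.csv`` the quartile/whisker data behind the boxplots.
    Output is bitwise-stable for identical inputs.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    box_cols = _GROUP + ["mean", "q1", "median", "q3", "whisker_low", "whisker_high"]
    tables = {
        "summary.csv": summary.realized,
        "summary_predicted.csv": summary.predicted,
        "stats.csv": _stats_frame(stats),
        "boxplot_data.csv": summary.realized[box_cols]
        if not summary.realized.empty
        else pd.DataFrame(columns=box_cols),
    }
    for name, frame in tables.items():
        path = os.path.join(outdir, name)
        frame.to_csv(path, index=False, float_format="%.10g")
        paths[name] = path
    return paths
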