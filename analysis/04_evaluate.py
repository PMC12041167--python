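#!/usr/bin/env python
"""Step 4 - summary tables and inference.

Aggregates the per-run results into policy x scenario x timepoint
summary tables (realized and Le Gall-predicted mortality, boxplot data)
and runs one-way ANOVA with Tukey HSD per (scenario, timepoint).
Prints the headline comparisons of the policy classes.
"""

import argparse
import os

import pandas as pd

import triage_sim as ts
from triage_sim.triage_engine import (
    CRITERION_POLICIES,
    NON_CRITERION_POLICIES,
    SCORE_POLICIES,
    Policy,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", default="results")
    args = parser.parse_args()

    results = pd.read_csv(os.path.join(args.outdir, "simulation_runs.csv"))
    summary = ts.summarize(results)
    stats = ts.anova_tukey_all(results)
    reports = os.path.join(args.outdir, "reports")
    ts.export_reports(summary, stats, reports)
    print(f"wrote summary/stats/boxplot tables -> {reports}/")

    means = results.groupby(["scenario", "t", "policy"]).realized_mortality.mean()
    p4 = means.xs(int(Policy.SAPS), level="policy")
    print(f"\nSAPS II policy (4) mean ICU mortality: "
          f"{100 * p4.max():.1f}% (scenario {p4.idxmax()[0]}, t={p4.idxmax()[1]}) "
          f"down to {100 * p4.min():.1f}% (scenario {p4.idxmin()[0]}, t={p4.idxmin()[1]})")
    baseline = means.xs(0, level="policy").mean()
    print(f"no-triage baseline average: {100 * baseline:.1f}%")
    print(f"largest reduction vs baseline: "
          f"{100 * (means.xs(0, level='policy') - p4).max():.1f} percentage points")

    def class_mean(policies):
        return means[means.index.get_level_values("policy").isin(list(map(int, policies)))].mean()

    print("\npolicy-class averages over all scenarios and timepoints:")
    print(f"  score-based {{4,5,8,9}}:     {100 * class_mean(SCORE_POLICIES):.1f}%")
    print(f"  criterion-based {{3,6,7}}:   {100 * class_mean(CRITERION_POLICIES):.1f}%")
    print(f"  non-criterion {{0,1,2}}:     "
          f"{100 * class_mean(NON_CRITERION_POLICIES | {Policy.NO_TRIAGE}):.1f}%")

    n_sig_4 = sum(
        res.pairs.set_index(["policy_a", "policy_b"]).loc[(0, 4)].significant
        for res in stats
    )
    n_sig_1 = sum(
        res.pairs.set_index(["policy_a", "policy_b"]).loc[(0, 1)].significant
        for res in stats
    )
    print(f"\nTukey HSD across the {len(stats)} (scenario, t) cells: "
          f"policy 4 vs 0 significant in {n_sig_4}, policy 1 vs 0 in {n_sig_1}")


if __name__ == "__main__":
    main()
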