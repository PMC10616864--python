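#!/usr/bin/env python
"""Bandpass, Pearson connectivity, and whole-network strength/density.

Each session is filtered to 0.009-0.1 Hz and correlated region-by-region;
the per-session strength (sum over all unique pairs) and weighted density
(mean connectivity) trace the whole-brain trajectory: a transient rise at
1 wpi followed by a decline below baseline by 14 wpi.
"""

import numpy as np
import pandas as pd
from common import RESULTS, get_cohort

from hubshift import graph_metrics as gm


def main() -> None:
    c = get_cohort()
    cms, panel = c["cms"], c["panel"]

    rows = [{"subject": cm.subject_id, "timepoint": cm.timepoint,
             "strength": gm.strength(cm),
             "weighted_density": gm.weighted_density(cm),
             "binary_density": gm.binary_density(gm.binarize(cm, panel.threshold))}
            for cm in cms]
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "strength_density_per_session.csv", index=False)

    summary = (df.groupby("timepoint", sort=False)
                 .agg(mean_strength=("strength", "mean"),
                      sem_strength=("strength", lambda x: x.std(ddof=1) / np.sqrt(len(x))),
                      mean_weighted_density=("weighted_density", "mean"),
                      mean_binary_density=("binary_density", "mean"))
                 .reindex(list(panel.timepoints)))
    summary.to_csv(RESULTS / "strength_density_summary.csv")

    print(f"{len(cms)} connectivity matrices, each with "
          f"{cms[0].n_pairs} unique pairs; all entries in "
          f"[{min(cm.offdiag().min() for cm in cms):.3f}, "
          f"{max(cm.offdiag().max() for cm in cms):.3f}]")
    print("\nwhole-network trajectory (cross-subject mean):")
    print(summary.round(3).to_string())
    up = summary.loc["1wpi", "mean_strength"] > summary.loc["pre", "mean_strength"]
    down = summary.loc["14wpi", "mean_strength"] < summary.loc["pre", "mean_strength"]
    print(f"\nstrength rises at 1wpi: {up}; falls below pre by 14wpi: {down}")


if __name__ == "__main__":
    main()
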