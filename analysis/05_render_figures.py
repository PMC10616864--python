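#!/usr/bin/env python
"""Figure-style exports: heatmaps and 3-D node scenes.

Renders the per-timepoint mean connectivity matrices and baseline-vs-final
change matrix as heatmaps, and exports 3-D node scatters colored by
absolute degree centrality (blue 0 -> red n-1) and by centrality ratio
(0.6 -> 1.5). Images land in scratch/figures; each scene's authoritative
CSV twin (node_id, x, y, z, value, RGB) lands in results/node_scenes.
"""

import numpy as np
from common import RESULTS, SCRATCH, BASELINE, FINAL, get_cohort

from hubshift import hub_analysis as ha
from hubshift import longitudinal_stats as ls
from hubshift.reporting import ColorMap, export_node_scene, render_matrix


def main() -> None:
    c = get_cohort()
    panel, atlas, cms = c["panel"], c["atlas"], c["cms"]
    fig_dir = SCRATCH / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    scene_dir = RESULTS / "node_scenes"   # CSV twins (text)
    scene_dir.mkdir(exist_ok=True)

    mean_cms = {tp: ls.mean_connectivity([m for m in cms if m.timepoint == tp])
                for tp in panel.timepoints}
    for tp, cm in mean_cms.items():
        render_matrix(cm, fig_dir / f"connectivity_{tp}.png",
                      f"mean connectivity, {tp}")
    delta = ls.change_matrix(mean_cms[FINAL], mean_cms[BASELINE])
    render_matrix(delta, fig_dir / f"delta_{FINAL}_vs_{BASELINE}.png",
                  f"change, {FINAL} vs {BASELINE}")

    mean_deg = np.nanmean(panel.degree, axis=1)
    abs_map = ColorMap.absolute(panel.n_nodes)
    for ti, tp in enumerate(panel.timepoints):
        csv = export_node_scene(atlas, mean_deg[:, ti], abs_map,
                                fig_dir / f"centrality_{tp}.png",
                                f"degree centrality, {tp}")
        csv.rename(scene_dir / csv.name)
    ratio = np.nanmean(ha.centrality_ratio(panel, BASELINE), axis=1)
    fi = panel.timepoint_index(FINAL)
    csv = export_node_scene(atlas, ratio[:, fi], ColorMap.ratio(),
                            fig_dir / f"ratio_{FINAL}.png",
                            f"centrality ratio vs {BASELINE}, {FINAL}")
    csv.rename(scene_dir / csv.name)

    n_png = len(list(fig_dir.glob("*.png")))
    n_csv = len(list(scene_dir.glob("*.csv")))
    print(f"wrote {n_png} images to {fig_dir} "
          f"and {n_csv} node-scene CSV twins to {scene_dir}")


if __name__ == "__main__":
    main()
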