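"""Shared setup for the analysis drivers.

All drivers operate on the same deterministic scaled cohort (60 nodes x
300 volumes, 10 subjects, 5 timepoints, seed 42) so each script can be run
independently and in any order; regenerating the cohort takes well under a
second. Tables go to ``results/``; bulky artifacts (per-session CSVs,
figures) go to ``scratch/``.
"""

from __future__ import annotations

from functools import lru_cache
from pathlib import Path

from hubshift import graph_metrics
from hubshift.connectivity import cohort_connectivity
from hubshift.synthetic import desk_scenario, simulate_cohort, synthetic_atlas

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

COHORT_SEED = 42
THRESHOLD = 0.10
BASELINE, FINAL = "pre", "14wpi"
ALPHA = 0.05


@lru_cache(maxsize=1)
def get_cohort():
    scenario = desk_scenario(seed=COHORT_SEED)
    sessions, truth = simulate_cohort(scenario)
    cms = cohort_connectivity(sessions)
    panel = graph_metrics.build_centrality_panel(cms, THRESHOLD)
    atlas = synthetic_atlas(scenario.n_nodes, scenario)
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    return {"scenario": scenario, "sessions": sessions, "truth": truth,
            "cms": cms, "panel": panel, "atlas": atlas}
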