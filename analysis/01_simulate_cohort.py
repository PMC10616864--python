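#!/usr/bin/env python
"""Simulate the longitudinal cohort and record what was planted.

Generates the scaled synthetic cohort (10 subjects x 5 timepoints of
60-region, 300-volume BOLD sessions) with a motor hub set whose coupling
to the network declines after the injury timepoint and a subcortical set
whose coupling rises, plus a transient global connectivity burst at 1 wpi.
Writes the atlas and the planted ground truth; per-session signal matrices
go to scratch/ (they are bulky and fully reproducible from the seed).
"""

import json

from common import RESULTS, SCRATCH, get_cohort

from hubshift.atlas_io import write_atlas, write_session


def main() -> None:
    c = get_cohort()
    scenario, truth = c["scenario"], c["truth"]

    write_atlas(c["atlas"], RESULTS / "atlas.csv")
    truth.to_json(SCRATCH / "ground_truth.json")  # full target matrices: bulky
    (RESULTS / "planted_structure.json").write_text(json.dumps({
        "motor_hub_ids": list(truth.motor_hub_ids),
        "subcortical_hub_ids": list(truth.subcortical_hub_ids),
        "strength_direction_vs_pre": truth.strength_direction,
    }, indent=2))
    session_dir = SCRATCH / "sessions"
    session_dir.mkdir(parents=True, exist_ok=True)
    for s in c["sessions"]:
        write_session(s, session_dir / f"{s.subject_id}_{s.timepoint}.csv")

    print(f"cohort: {scenario.n_subjects} subjects x {len(scenario.timepoints)} "
          f"timepoints, {scenario.n_nodes} regions x {scenario.n_volumes} volumes "
          f"(TR {scenario.sampling_interval:g} s), seed {scenario.seed}")
    print(f"planted motor hubs:       {truth.motor_hub_ids}")
    print(f"planted subcortical hubs: {truth.subcortical_hub_ids}")
    print(f"planted strength direction vs pre: {truth.strength_direction}")
    print(f"wrote atlas + planted summary to {RESULTS}/, ground truth to {SCRATCH}/, "
          f"{len(c['sessions'])} session matrices to {session_dir}/")


if __name__ == "__main__":
    main()
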