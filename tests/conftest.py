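import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hubshift import graph_metrics
from hubshift.connectivity import cohort_connectivity
from hubshift.synthetic import desk_scenario, simulate_cohort, synthetic_atlas
from hubshift.types import RegionAtlas

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def toy_atlas() -> RegionAtlas:
    return RegionAtlas(
        node_ids=np.arange(4),
        names=("M1_L", "M1_R", "CPu_L", "CPu_R"),
        hemispheres=("left", "right", "left", "right"),
        coords=np.array([[1.0, 2.0, 3.0], [-1.0, 2.0, 3.0],
                         [2.0, 0.0, -1.0], [-2.0, 0.0, -1.0]]),
    )


@pytest.fixture(scope="session")
def desk_cohort():
    """One scaled cohort (60 nodes x 300 volumes, 10 subjects, 5 timepoints)
    run through filtering, connectivity and the centrality panel."""
    scenario = desk_scenario(seed=7)
    sessions, truth = simulate_cohort(scenario)
    cms = cohort_connectivity(sessions)
    panel = graph_metrics.build_centrality_panel(cms, threshold=0.10)
    return {"scenario": scenario, "sessions": sessions, "truth": truth,
            "cms": cms, "panel": panel,
            "atlas": synthetic_atlas(scenario.n_nodes, scenario)}
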