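# hubshift

Longitudinal resting-state functional-connectivity network analysis:
from region-wise BOLD time series to thresholded graphs, degree-centrality
hub maps, change matrices, and hub-shift statistics.

The scientific question this package serves: after a spinal cord injury,
how do the *hubs* of the brain's resting-state network reorganize over
weeks? In a typical design, 10 subjects are scanned at pre-injury and 1,
3, 7 and 14 weeks post-injury (600 volumes at TR = 1 s per session), the
brain is parcellated into 244 functional areas (122 per hemisphere), and
each scan becomes a graph:

- **edge weight** r_ij — Pearson correlation of the 0.009–0.1 Hz
  bandpassed BOLD series of regions i and j, in [−1, 1];
- **strength** S = Σ_{i<j} r_ij over all n(n−1)/2 unique pairs
  (29,646 pairs at n = 244); **weighted density** = S / (n(n−1)/2);
- **binary graph** — keep pairs with r_ij ≥ θ (θ = 0.10);
- **degree centrality** k_i — number of edges at node i (0…n−1, so
  0…243 here), the index of hub function;
- **hubs** — nodes whose cross-subject mean degree exceeds the cross-node
  mean by > 2 SD.

Longitudinal statistics are paired t-tests across subjects against the
pre-injury scan (per node, on whole-brain mean centrality, and on hub-set
means), and a two-way mixed ANOVA (group × time) for comparisons between
injury models. Because raw animal rs-fMRI of this kind is generally not
deposited, the package ships a synthetic-cohort generator with a planted,
time-shifting hub structure (declining "motor" hubs, rising "subcortical"
hubs, a transient global burst at 1 wpi), so the entire pipeline is
testable against known ground truth. See `docs/methods.md` for the model
and all defaults.

## Layout

```
src/hubshift/        the library
  atlas_io           atlas / session / connectivity CSV + NIfTI extraction
  connectivity       bandpass filtering, Pearson connectivity
  graph_metrics      strength, density, binarize, degree centrality, panels
  longitudinal_stats change matrices, paired tests, mixed ANOVA
  hub_analysis       motor-node masks, centrality ratios, hub sets, report
  synthetic          scenario definition and cohort simulation
  reporting          colormaps, heatmaps, 3-D node scenes, run_pipeline
analysis/            numbered drivers, 01_simulate_cohort ... 05_render_figures
scripts/acceptance.py  recomputes the headline numbers (below)
```

## Worked example

`analysis/` scripts run the whole study on a scaled deterministic cohort
(60 regions × 300 volumes, 10 subjects, 5 timepoints, seed 42); each is
independent and takes seconds. Tables land in `results/`, bulky artifacts
in `scratch/`.

```bash
cd analysis
python 01_simulate_cohort.py
python 02_connectivity_metrics.py
python 04_hub_shift.py
```

`02_connectivity_metrics.py` prints the whole-network trajectory:

```
whole-network trajectory (cross-subject mean):
           mean_strength  sem_strength  mean_weighted_density  mean_binary_density
timepoint
pre              238.446        21.983                  0.135                0.572
1wpi             368.001        23.883                  0.208                0.747
3wpi             303.400        16.729                  0.171                0.660
7wpi             235.746        16.642                  0.133                0.572
14wpi            236.039        17.249                  0.133                0.567

strength rises at 1wpi: True; falls below pre by 14wpi: True
```

— the transient post-injury hyperconnectivity (strength 238 → 368 at
1 wpi) that settles back below baseline by 14 wpi. `04_hub_shift.py`
prints the hub shift itself:

```
baseline (pre) hubs: [0, 1, 2, 3, 4, 5] ['M1_L', 'M1_R', 'M2_L', 'M2_R', 'S1_L', 'S1_R']
planted motor hubs:      [0, 1, 2, 3, 4, 5]
final (14wpi) hubs:    [6, 7, 8, 9, 10, 11] ['CPu_L', 'CPu_R', 'cc-ec_L', 'cc-ec_R', 'Tu_L', 'Tu_R']
planted subcortical hubs: [6, 7, 8, 9, 10, 11]
...
baseline hubs decline significantly by 14wpi: True
final hubs decline significantly by 14wpi:    False
```

The mean + 2 SD rule recovers the planted motor hub set exactly at
baseline, that set's mean centrality declines significantly by 14 wpi
(48.7 → 36.4, p ≈ 0.001), while the subcortical set takes over the
high-centrality role without declining — the cortical-to-subcortical hub
shift the pipeline is built to detect.

The same chain can be driven from a single YAML config via
`hubshift.reporting.run_pipeline(config)`, which writes connectivity
matrices, the centrality panel, statistics tables, the hub-shift report
and a provenance manifest to one output directory.

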