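"""Figure-style outputs and the end-to-end pipeline driver.

Node coloring follows the HSV convention of the source figures: hue runs
linearly from 240 deg (blue) at the low end of the domain to 0 deg (red)
at the high end, with full saturation and value; out-of-range values are
clamped. Absolute mode spans the attainable degree range (0..n-1, i.e.
0-243 for the whole-brain atlas); ratio mode spans 0.6-1.5 around the
pre-injury value of 1. Every image has a machine-readable CSV/JSON twin —
images are never the only record.

``run_pipeline`` wires the whole analysis together from a single YAML
config (sections: io, filter, graph, stats, hubs, simulate, report) and is
deterministic given the config and its seed.
"""

from __future__ import annotations

import colorsys
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import graph_metrics, hub_analysis, longitudinal_stats
from .atlas_io import write_atlas, write_connectivity
from .connectivity import FilterSpec, cohort_connectivity
from .errors import ConfigError, ShapeError
from .longitudinal_stats import ChangeMatrix
from .types import ConnectivityMatrix, RegionAtlas

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColorMap:
    """Linear blue-to-red HSV map over a fixed domain, clamping outside."""

    mode: str = "absolute_hsv"          # or "ratio"
    lo: float = 0.0
    hi: float = 243.0

    @classmethod
    def absolute(cls, n_nodes: int = 244) -> "ColorMap":
        return cls(mode="absolute_hsv", lo=0.0, hi=float(n_nodes - 1))

    @classmethod
    def ratio(cls) -> "ColorMap":
        return cls(mode="ratio", lo=0.6, hi=1.5)


def color_of(value: float, cmap: ColorMap) -> tuple[int, int, int]:
    """RGB triple (0-255) for a value: 240 deg hue at lo down to 0 at hi."""
    if cmap.hi <= cmap.lo:
        raise ConfigError("colormap domain must have lo < hi")
    frac = (np.clip(value, cmap.lo, cmap.hi) - cmap.lo) / (cmap.hi - cmap.lo)
    hue = 240.0 * (1.0 - frac)
    r, g, b = colorsys.hsv_to_rgb(hue / 360.0, 1.0, 1.0)
    return int(round(r * 255)), int(round(g * 255)), int(round(b * 255))


def render_matrix(m: ConnectivityMatrix | ChangeMatrix, out_path: str | Path,
                  title: str = "") -> Path:
    """Heatmap: fixed [-1, 1] scale for connectivity, symmetric diverging
    scale for change matrices (blue = decreased, red = increased)."""
    out_path = Path(out_path)
    values = m.values
    if isinstance(m, ChangeMatrix):
        vmax = float(np.nanmax(np.abs(values))) or 1.0
        vmin = -vmax
    else:
        vmin, vmax = -1.0, 1.0
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(values, cmap="RdBu_r", vmin=vmin, vmax=vmax,
                   interpolation="nearest")
    ax.set_xlabel("node")
    ax.set_ylabel("node")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="connectivity" if vmax == 1 else "delta r")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path


def export_node_scene(atlas: RegionAtlas, values: np.ndarray, cmap: ColorMap,
                      out_path: str | Path, title: str = "") -> Path:
    """3-D node scatter colored through ``cmap``.

    Writes ``<out>.csv`` (node_id, x, y, z, value, r, g, b — the
    authoritative, bit-stable artifact) and ``<out>.png`` (a convenience
    rendering). Returns the CSV path.
    """
    values = np.asarray(values, dtype=float)
    if values.size != atlas.n_nodes:
        raise ShapeError(f"{values.size} values for {atlas.n_nodes} nodes")
    out_path = Path(out_path)
    rgb = np.array([color_of(v, cmap) for v in values], dtype=int)
    df = pd.DataFrame({
        "node_id": atlas.node_ids,
        "x": atlas.coords[:, 0], "y": atlas.coords[:, 1], "z": atlas.coords[:, 2],
        "value": values,
        "r": rgb[:, 0], "g": rgb[:, 1], "b": rgb[:, 2],
    })
    csv_path = out_path.with_suffix(".csv")
    df.to_csv(csv_path, index=False, float_format="%.17g")
    fig = plt.figure(figsize=(5.5, 4.5))
    ax = fig.add_subplot(projection="3d")
    ax.scatter(df.x, df.y, df.z, c=rgb / 255.0, s=28, depthshade=False)
    ax.set_xlabel("x (mm)"); ax.set_ylabel("y (mm)"); ax.set_zlabel("z (mm)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path.with_suffix(".png"), dpi=110)
    plt.close(fig)
    return csv_path


# ---------------------------------------------------------------- pipeline

_REQUIRED_KEYS = {
    "io": ["out_dir"],
    "graph": ["threshold"],
    "stats": ["alpha", "baseline"],
    "hubs": ["k", "final"],
    "simulate": ["seed"],
}


def _check_config(cfg: dict) -> None:
    for section, keys in _REQUIRED_KEYS.items():
        if section not in cfg:
            raise ConfigError(f"config missing section {section!r}")
        for key in keys:
            if key not in cfg[section]:
                raise ConfigError(f"config missing key {section}.{key}")


def run_pipeline(config_path: str | Path) -> Path:
    """Simulate -> filter -> connectivity -> metrics -> stats -> hubs -> reports.

    Returns the output directory. Every stage failure aborts with a
    stage-named error; the manifest records all parameters and outputs.
    """
    from .synthetic import desk_scenario, m1_seed_ids, simulate_cohort, synthetic_atlas

    cfg = yaml.safe_load(Path(config_path).read_text())
    _check_config(cfg)
    out_dir = Path(cfg["io"]["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    sim, fl = cfg["simulate"], cfg.get("filter", {})
    spec = FilterSpec(low_cutoff=fl.get("low_hz", 0.009),
                      high_cutoff=fl.get("high_hz", 0.1),
                      design=fl.get("design", "butterworth_zero_phase"),
                      order=fl.get("order", 2))
    threshold = float(cfg["graph"]["threshold"])
    alpha = float(cfg["stats"]["alpha"])
    baseline = cfg["stats"]["baseline"]
    final = cfg["hubs"]["final"]
    k = float(cfg["hubs"]["k"])

    scenario = desk_scenario(
        seed=int(sim["seed"]),
        n_nodes=int(sim.get("n_nodes", 60)),
        n_volumes=int(sim.get("n_volumes", 300)),
    )
    if "n_subjects" in sim:
        from dataclasses import replace
        scenario = replace(scenario, n_subjects=int(sim["n_subjects"]))
    sessions, truth = simulate_cohort(scenario)
    atlas = synthetic_atlas(scenario.n_nodes, scenario)
    write_atlas(atlas, out_dir / "atlas.csv")
    truth.to_json(out_dir / "ground_truth.json")

    cms = cohort_connectivity(sessions, spec)
    conn_dir = out_dir / "connectivity"
    conn_dir.mkdir(exist_ok=True)
    for cm in cms:
        write_connectivity(cm, conn_dir / f"{cm.subject_id}_{cm.timepoint}.csv")

    panel = graph_metrics.build_centrality_panel(cms, threshold)
    strengths = pd.DataFrame(
        {"subject": [c.subject_id for c in cms],
         "timepoint": [c.timepoint for c in cms],
         "strength": [graph_metrics.strength(c) for c in cms],
         "weighted_density": [graph_metrics.weighted_density(c) for c in cms]})
    strengths.to_csv(out_dir / "strength_density.csv", index=False)
    wide = strengths.pivot(index="subject", columns="timepoint",
                           values="strength")[list(panel.timepoints)]
    longitudinal_stats.strength_delta_series(wide, "vs_baseline", baseline).to_csv(
        out_dir / "strength_delta_vs_baseline.csv", index=False)

    long_rows = []
    for ni in range(panel.n_nodes):
        for si, s in enumerate(panel.subjects):
            for ti, t in enumerate(panel.timepoints):
                long_rows.append((ni, s, t, panel.degree[ni, si, ti]))
    pd.DataFrame(long_rows, columns=["node_id", "subject", "timepoint", "degree"]
                 ).to_csv(out_dir / "centrality_panel.csv", index=False)

    longitudinal_stats.mean_centrality_comparison(panel, baseline, alpha).to_csv(
        out_dir / "mean_centrality.csv", index=False)
    summaries = []
    for tp in panel.timepoints:
        if tp == baseline:
            continue
        _, summary = longitudinal_stats.nodewise_paired_test(
            panel, tp, baseline, alpha, fdr=bool(cfg["stats"].get("fdr", False)))
        summaries.append(summary)
    (out_dir / "nodewise_summary.json").write_text(
        json.dumps(summaries, indent=2, sort_keys=True))

    pre_cms = {cm.subject_id: cm for cm in cms if cm.timepoint == baseline}
    seeds = m1_seed_ids(scenario)
    mask = hub_analysis.extract_motor_nodes(pre_cms, seeds, threshold)
    report = hub_analysis.hub_shift_report(panel, baseline, final, k, alpha)
    report.to_json(out_dir / "hub_shift_report.json")
    (out_dir / "motor_mask.json").write_text(json.dumps({
        "seed_ids": list(mask.seed_ids),
        "threshold": mask.threshold,
        "group_union_size": int(mask.group_union.sum()),
    }, indent=2))

    if cfg.get("report", {}).get("figures", True):
        fig_dir = out_dir / "figures"
        fig_dir.mkdir(exist_ok=True)
        for tp in panel.timepoints:
            mean_cm = longitudinal_stats.mean_connectivity(
                [c for c in cms if c.timepoint == tp], tp)
            render_matrix(mean_cm, fig_dir / f"connectivity_{tp}.png",
                          f"mean connectivity, {tp}")
        mean_deg = np.nanmean(panel.degree, axis=1)
        cmap = ColorMap.absolute(panel.n_nodes)
        for ti, tp in enumerate(panel.timepoints):
            export_node_scene(atlas, mean_deg[:, ti], cmap,
                              fig_dir / f"centrality_{tp}.png",
                              f"degree centrality, {tp}")

    manifest = {
        "scenario": {"n_nodes": scenario.n_nodes, "n_subjects": scenario.n_subjects,
                     "n_volumes": scenario.n_volumes, "seed": scenario.seed,
                     "timepoints": list(scenario.timepoints)},
        "filter": spec.as_meta(),
        "threshold": threshold, "alpha": alpha, "k": k,
        "baseline": baseline, "final": final,
        "outputs": sorted(str(p.relative_to(out_dir))
                          for p in out_dir.rglob("*") if p.is_file()),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline complete: %s", out_dir)
    return out_dir
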