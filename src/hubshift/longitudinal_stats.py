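"""Longitudinal statistics: change matrices, node-wise paired tests,
mean-centrality trajectories, and the between-cohort mixed ANOVA.

Within-cohort comparisons against the pre-injury baseline use two-sided
paired t-tests across subjects (per node, or on per-subject means), as is
conventional for repeated scans of the same animals. Between two injury
models the comparison is a two-way mixed ANOVA (between factor: group;
within factor: time) on per-subject node-set mean centrality.

Node-wise tests are reported uncorrected by default — hub screens in this
literature report raw per-node significance counts — with an optional
Benjamini-Hochberg flag. Error bars are SEM throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ShapeError, ValidationError
from .types import CentralityPanel, ConnectivityMatrix

DEFAULT_ALPHA = 0.05

Reference = Literal["vs_baseline", "vs_previous"]


@dataclass(frozen=True)
class ChangeMatrix:
    """Entrywise connectivity difference between two (mean) matrices."""

    values: np.ndarray
    reference: Reference
    timepoint: str
    reference_timepoint: str

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class NodeTestResult:
    node_id: int
    statistic: float
    p_value: float
    direction: Literal["increase", "decrease", "none"]
    n_pairs: int
    mean_difference: float


def change_matrix(
    cm_t: ConnectivityMatrix,
    cm_ref: ConnectivityMatrix,
    reference: Reference = "vs_baseline",
) -> ChangeMatrix:
    """Difference matrix cm_t - cm_ref (red = increased, blue = decreased)."""
    if cm_t.n != cm_ref.n:
        raise ShapeError(f"shape mismatch: {cm_t.n} vs {cm_ref.n}")
    return ChangeMatrix(
        values=cm_t.values - cm_ref.values,
        reference=reference,
        timepoint=cm_t.timepoint,
        reference_timepoint=cm_ref.timepoint,
    )


def mean_connectivity(cms: list[ConnectivityMatrix], timepoint: str = "") -> ConnectivityMatrix:
    """Cross-subject mean of per-subject connectivity matrices."""
    if not cms:
        raise ValidationError("empty matrix list")
    stack = np.stack([cm.values for cm in cms])
    return ConnectivityMatrix(values=stack.mean(axis=0),
                              timepoint=timepoint or cms[0].timepoint,
                              meta={"n_subjects": len(cms)})


def strength_delta_series(
    strengths: pd.DataFrame,
    reference: Reference = "vs_baseline",
    baseline: str = "pre",
) -> pd.DataFrame:
    """Per-timepoint mean +/- SEM of per-subject strength differences.

    ``strengths`` is a subject x timepoint table (index: subject, columns:
    timepoints in temporal order). The per-subject difference is computed
    first, then the cross-subject mean and SEM; subjects with a missing
    cell at a timepoint are masked from that timepoint with a warning.
    """
    cols = list(strengths.columns)
    if baseline not in cols:
        raise ValidationError(f"baseline {baseline!r} not among timepoints {cols}")
    rows = []
    for j, tp in enumerate(cols):
        if reference == "vs_baseline":
            ref_tp = baseline
            if tp == baseline:
                continue
        else:
            if j == 0:
                continue
            ref_tp = cols[j - 1]
        delta = (strengths[tp] - strengths[ref_tp]).dropna()
        if len(delta) < len(strengths):
            import logging
            logging.getLogger(__name__).warning(
                "strength delta %s vs %s: %d/%d subjects present",
                tp, ref_tp, len(delta), len(strengths))
        sem = float(delta.std(ddof=1) / np.sqrt(len(delta))) if len(delta) > 1 else np.nan
        rows.append({
            "timepoint": tp, "reference": ref_tp, "n": len(delta),
            "mean_delta": float(delta.mean()), "sem": sem,
        })
    return pd.DataFrame(rows)


def nodewise_paired_test(
    panel: CentralityPanel,
    timepoint: str,
    baseline: str = "pre",
    alpha: float = DEFAULT_ALPHA,
    fdr: bool = False,
) -> tuple[list[NodeTestResult], dict]:
    """Two-sided paired t per node: degree at ``timepoint`` vs ``baseline``.

    Returns the per-node results plus a summary dict with the significant
    increase/decrease counts. With ``fdr=True`` the p-values are
    Benjamini-Hochberg adjusted before thresholding at alpha.
    """
    ti, bi = panel.timepoint_index(timepoint), panel.timepoint_index(baseline)
    a = panel.degree[:, :, ti]
    b = panel.degree[:, :, bi]
    results: list[NodeTestResult] = []
    raw_p = np.full(panel.n_nodes, np.nan)
    tstat = np.full(panel.n_nodes, np.nan)
    md = np.full(panel.n_nodes, np.nan)
    n_used = np.zeros(panel.n_nodes, dtype=int)
    for node in range(panel.n_nodes):
        ok = np.isfinite(a[node]) & np.isfinite(b[node])
        n = int(ok.sum())
        n_used[node] = n
        if n < 3:
            raise InsufficientDataError(
                f"node {node}: only {n} subjects with both timepoints (need >= 3)"
            )
        d = a[node, ok] - b[node, ok]
        md[node] = d.mean()
        if np.allclose(d.std(ddof=1), 0.0):
            continue  # statistic undefined; direction stays "none"
        t, p = stats.ttest_rel(a[node, ok], b[node, ok])
        tstat[node], raw_p[node] = float(t), float(p)
    p_eval = raw_p.copy()
    if fdr:
        defined = np.isfinite(raw_p)
        p_eval[defined] = stats.false_discovery_control(raw_p[defined], method="bh")
    n_inc = n_dec = 0
    for node in range(panel.n_nodes):
        direction: Literal["increase", "decrease", "none"] = "none"
        if np.isfinite(p_eval[node]) and p_eval[node] < alpha:
            direction = "increase" if md[node] > 0 else "decrease"
            n_inc += direction == "increase"
            n_dec += direction == "decrease"
        results.append(NodeTestResult(
            node_id=node, statistic=tstat[node], p_value=p_eval[node],
            direction=direction, n_pairs=n_used[node], mean_difference=md[node],
        ))
    summary = {
        "timepoint": timepoint, "baseline": baseline, "alpha": alpha, "fdr": fdr,
        "n_significant_increase": int(n_inc), "n_significant_decrease": int(n_dec),
        "n_tested": int(np.isfinite(p_eval).sum()),
    }
    return results, summary


def mean_centrality_comparison(
    panel: CentralityPanel, baseline: str = "pre", alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Whole-brain mean centrality per timepoint, paired-tested vs baseline.

    The per-subject mean over nodes is computed first; the paired t across
    subjects then compares each timepoint with the baseline.
    """
    if not panel.is_complete:
        raise InsufficientDataError("mean_centrality_comparison needs a complete panel")
    if len(panel.subjects) < 2:
        raise InsufficientDataError("need >= 2 subjects")
    per_subject = panel.degree.mean(axis=0)  # (n_subjects, n_timepoints)
    bi = panel.timepoint_index(baseline)
    rows = []
    for j, tp in enumerate(panel.timepoints):
        vals = per_subject[:, j]
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals)))
        if j == bi:
            t = p = np.nan
            sig = False
        else:
            d = vals - per_subject[:, bi]
            if np.allclose(d.std(ddof=1), 0.0):
                t, p, sig = np.nan, np.nan, False
            else:
                t, p = stats.ttest_rel(vals, per_subject[:, bi])
                sig = bool(p < alpha)
        rows.append({
            "timepoint": tp, "mean_centrality": float(vals.mean()), "sem": sem,
            "t_vs_baseline": float(t) if np.isfinite(t) else np.nan,
            "p_vs_baseline": float(p) if np.isfinite(p) else np.nan,
            "significant": sig,
        })
    return pd.DataFrame(rows)


def nodeset_mean_table(panel: CentralityPanel, node_ids: np.ndarray,
                       group: str) -> pd.DataFrame:
    """Long-format per-subject mean centrality over a node set (ANOVA input)."""
    node_ids = np.asarray(node_ids, dtype=int)
    if node_ids.size == 0:
        raise ValidationError("empty node set")
    sub = panel.degree[node_ids].mean(axis=0)  # (n_subjects, n_timepoints)
    rows = []
    for i, s in enumerate(panel.subjects):
        for j, t in enumerate(panel.timepoints):
            rows.append({"group": group, "subject": f"{group}:{s}",
                         "timepoint": t, "centrality": sub[i, j]})
    return pd.DataFrame(rows)


def group_rm_comparison(
    panel_a: CentralityPanel,
    panel_b: CentralityPanel,
    node_ids_a: np.ndarray,
    node_ids_b: np.ndarray,
    labels: tuple[str, str] = ("contusion", "transection"),
) -> pd.DataFrame:
    """Two-way mixed ANOVA between two cohorts over shared timepoints.

    Between factor: group (injury model); within factor: timepoint. The
    dependent variable is each subject's mean centrality over the supplied
    node set. Returns a table with F and p for group, time, interaction.
    """
    if panel_a.timepoints != panel_b.timepoints:
        raise ValidationError(
            f"timepoint labels differ: {panel_a.timepoints} vs {panel_b.timepoints}"
        )
    if len(panel_a.timepoints) < 2:
        raise InsufficientDataError("mixed ANOVA needs >= 2 timepoints")
    if not (panel_a.is_complete and panel_b.is_complete):
        raise InsufficientDataError("mixed ANOVA needs complete (balanced) panels")
    import pingouin as pg

    df = pd.concat([
        nodeset_mean_table(panel_a, node_ids_a, labels[0]),
        nodeset_mean_table(panel_b, node_ids_b, labels[1]),
    ], ignore_index=True)
    aov = pg.mixed_anova(data=df, dv="centrality", within="timepoint",
                         between="group", subject="subject")
    out = aov.rename(columns={"p-unc": "p", "p_unc": "p"})[
        ["Source", "DF1", "DF2", "F", "p"]]
    out["Source"] = out["Source"].replace({"group": "group", "timepoint": "time",
                                           "Interaction": "interaction"})
    return out
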