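"""Motor-subnetwork extraction and hub identification.

The motor subnetwork is anchored on the left and right primary motor
cortex (M1): a node belongs to a subject's motor set when its pre-injury
connectivity to either M1 seed withstands the edge threshold in that
subject; the group set is the union over subjects (a node is excluded only
when it is sub-threshold to both seeds in every subject). Hubs are nodes
whose cross-subject mean degree lies more than k standard deviations
(default k = 2, "approximately 2 SD") above the cross-node mean at a given
timepoint. The hub-shift report contrasts the baseline hub set (expected
to decline after injury) with the final-timepoint hub set (expected not to
decline), quantifying the cortical-to-subcortical handover of hub function.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import ValidationError
from .graph_metrics import degree_centrality
from .types import BinaryNetwork, CentralityPanel, ConnectivityMatrix

log = logging.getLogger(__name__)

DEFAULT_K = 2.0


@dataclass(frozen=True)
class MotorNodeMask:
    """Per-subject node inclusion against the M1 seeds, plus the group union."""

    subject_masks: dict[str, np.ndarray]  # subject -> (n,) bool
    seed_ids: tuple[int, int]
    threshold: float

    @property
    def group_union(self) -> np.ndarray:
        return np.logical_or.reduce(list(self.subject_masks.values()))


@dataclass(frozen=True)
class HubSet:
    """Nodes selected by the mean + k*SD centrality rule at one timepoint."""

    node_ids: tuple[int, ...]
    rule: str                       # "baseline_high" or "final_high"
    timepoint: str
    k: float
    cutoff: float
    node_means: np.ndarray = field(repr=False, default=None)

    def jaccard(self, other_ids) -> float:
        a, b = set(self.node_ids), set(other_ids)
        if not a and not b:
            return 1.0
        return len(a & b) / len(a | b)


def extract_motor_nodes(
    pre_cms: dict[str, ConnectivityMatrix],
    seed_ids: tuple[int, int],
    threshold: float = 0.10,
) -> MotorNodeMask:
    """Per-subject motor-related node masks from pre-injury connectivity.

    Node j is included for a subject iff max(r(j, seedL), r(j, seedR)) >=
    threshold in that subject's pre-injury matrix; seeds are always
    included in their own mask.
    """
    if not pre_cms:
        raise ValidationError("no pre-injury matrices supplied")
    n = next(iter(pre_cms.values())).n
    for sid in seed_ids:
        if not 0 <= sid < n:
            raise ValidationError(f"seed id {sid} out of range 0..{n - 1}")
    masks: dict[str, np.ndarray] = {}
    for subject, cm in pre_cms.items():
        if cm.n != n:
            raise ValidationError(f"matrix for {subject} has n={cm.n}, expected {n}")
        seed_r = cm.values[list(seed_ids)]          # (2, n), NaN at the seeds' own diag
        with np.errstate(invalid="ignore"):
            best = np.nanmax(seed_r, axis=0)
        mask = best >= threshold
        mask[list(seed_ids)] = True
        masks[subject] = mask
    return MotorNodeMask(subject_masks=masks, seed_ids=tuple(seed_ids),
                         threshold=float(threshold))


def masked_degree_centrality(bn: BinaryNetwork, mask: np.ndarray) -> np.ndarray:
    """Degree on the subgraph induced by masked-in nodes; NaN where masked out."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size != bn.n:
        raise ValidationError(f"mask length {mask.size} != n {bn.n}")
    if not mask.any():
        raise ValidationError("all-false mask: empty subgraph")
    sub = bn.adjacency & mask[:, None] & mask[None, :]
    deg = sub.sum(axis=1).astype(float)
    deg[~mask] = np.nan
    return deg


def centrality_ratio(panel: CentralityPanel, baseline: str = "pre") -> np.ndarray:
    """degree(t) / degree(baseline) per node per subject; NaN where undefined.

    The baseline column is identically 1 where defined; cells with baseline
    degree 0 are flagged NaN and excluded from any summary.
    """
    bi = panel.timepoint_index(baseline)
    base = panel.degree[:, :, bi:bi + 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = panel.degree / base
    ratio[np.broadcast_to(base == 0, ratio.shape)] = np.nan
    n_zero = int((base == 0).sum())
    if n_zero:
        log.warning("centrality_ratio: %d node x subject cells with zero "
                    "baseline degree flagged undefined", n_zero)
    return ratio


def high_centrality_nodes(
    panel: CentralityPanel, timepoint: str, k: float = DEFAULT_K,
    rule: str = "baseline_high",
) -> HubSet:
    """Nodes whose mean degree exceeds the cross-node mean by > k SD."""
    if k <= 0:
        raise ValidationError("k must be positive")
    ti = panel.timepoint_index(timepoint)
    node_means = np.nanmean(panel.degree[:, :, ti], axis=1)
    grand_mean = node_means.mean()
    sd = node_means.std(ddof=1)
    if np.allclose(sd, 0.0):
        warnings.warn("degenerate node-mean SD: no hubs identifiable", stacklevel=2)
        return HubSet(node_ids=(), rule=rule, timepoint=timepoint, k=k,
                      cutoff=float(grand_mean), node_means=node_means)
    cutoff = grand_mean + k * sd
    ids = tuple(int(i) for i in np.flatnonzero(node_means > cutoff))
    return HubSet(node_ids=ids, rule=rule, timepoint=timepoint, k=float(k),
                  cutoff=float(cutoff), node_means=node_means)


def _set_trajectory(panel: CentralityPanel, node_ids, baseline: str,
                    alpha: float) -> list[dict]:
    """Per-timepoint mean/SEM of the node-set mean centrality + paired t."""
    ids = np.asarray(node_ids, dtype=int)
    per_subject = panel.degree[ids].mean(axis=0)       # (n_subjects, n_timepoints)
    bi = panel.timepoint_index(baseline)
    out = []
    for j, tp in enumerate(panel.timepoints):
        vals = per_subject[:, j]
        entry = {
            "timepoint": tp,
            "mean": float(np.nanmean(vals)),
            "sem": float(np.nanstd(vals, ddof=1) / np.sqrt(np.isfinite(vals).sum())),
        }
        if j != bi:
            d = vals - per_subject[:, bi]
            if np.allclose(np.nanstd(d, ddof=1), 0.0):
                t = p = float("nan")
            else:
                t, p = stats.ttest_rel(vals, per_subject[:, bi])
            entry.update(
                t_vs_baseline=float(t), p_vs_baseline=float(p),
                significant_decline=bool(np.isfinite(p) and p < alpha
                                         and float(np.nanmean(d)) < 0),
            )
        out.append(entry)
    return out


@dataclass(frozen=True)
class HubShiftReport:
    """Baseline vs final hub sets with their centrality trajectories."""

    baseline_hubs: tuple[int, ...]
    final_hubs: tuple[int, ...]
    overlap: tuple[int, ...]
    baseline_timepoint: str
    final_timepoint: str
    k: float
    alpha: float
    baseline_trajectory: list[dict]
    final_trajectory: list[dict]

    @property
    def baseline_declines(self) -> bool:
        """True when the baseline hub set declines significantly at the end."""
        last = self.baseline_trajectory[-1]
        return bool(last.get("significant_decline", False))

    @property
    def final_declines(self) -> bool:
        last = self.final_trajectory[-1]
        return bool(last.get("significant_decline", False))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "baseline_hubs": list(self.baseline_hubs),
            "final_hubs": list(self.final_hubs),
            "overlap": list(self.overlap),
            "baseline_timepoint": self.baseline_timepoint,
            "final_timepoint": self.final_timepoint,
            "k": self.k,
            "alpha": self.alpha,
            "baseline_trajectory": self.baseline_trajectory,
            "final_trajectory": self.final_trajectory,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "HubShiftReport":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            baseline_hubs=tuple(d["baseline_hubs"]),
            final_hubs=tuple(d["final_hubs"]),
            overlap=tuple(d["overlap"]),
            baseline_timepoint=d["baseline_timepoint"],
            final_timepoint=d["final_timepoint"],
            k=d["k"],
            alpha=d["alpha"],
            baseline_trajectory=d["baseline_trajectory"],
            final_trajectory=d["final_trajectory"],
        )


def hub_shift_report(
    panel: CentralityPanel,
    baseline: str = "pre",
    final: str = "14wpi",
    k: float = DEFAULT_K,
    alpha: float = 0.05,
) -> HubShiftReport:
    """Contrast baseline-defined and final-defined hub sets over time."""
    base_set = high_centrality_nodes(panel, baseline, k, rule="baseline_high")
    final_set = high_centrality_nodes(panel, final, k, rule="final_high")
    overlap = tuple(sorted(set(base_set.node_ids) & set(final_set.node_ids)))
    return HubShiftReport(
        baseline_hubs=base_set.node_ids,
        final_hubs=final_set.node_ids,
        overlap=overlap,
        baseline_timepoint=baseline,
        final_timepoint=final,
        k=float(k),
        alpha=float(alpha),
        baseline_trajectory=_set_trajectory(panel, base_set.node_ids, baseline, alpha)
        if base_set.node_ids else [],
        final_trajectory=_set_trajectory(panel, final_set.node_ids, baseline, alpha)
        if final_set.node_ids else [],
    )
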