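"""Graph measures on connectivity matrices and thresholded networks.

Strength is the sum of all unique inter-node connectivities — n(n-1)/2
terms, each pair counted once (29,646 for a 244-node atlas). Weighted
density is that sum divided by the pair count, i.e. the mean connectivity.
Binarization keeps the signed correlations that withstand the threshold
(r >= theta, inclusive; negative correlations never become edges at the
conventional theta = 0.10). Degree centrality of a node is the number of
edges incident to it in the binary graph; the maximal attainable value is
n - 1 (243 here), and it is the index of hub function used throughout.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import ShapeError, ValidationError
from .types import BinaryNetwork, CentralityPanel, ConnectivityMatrix, as_timepoint_order

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.10


def strength(cm: ConnectivityMatrix) -> float:
    """Sum of the n(n-1)/2 unique off-diagonal connectivities."""
    return float(cm.offdiag().sum())


def weighted_density(cm: ConnectivityMatrix) -> float:
    """Mean connectivity: strength divided by the unique pair count."""
    return strength(cm) / cm.n_pairs


def binarize(cm: ConnectivityMatrix, threshold: float = DEFAULT_THRESHOLD) -> BinaryNetwork:
    """Threshold the signed correlations into an undirected binary graph."""
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    with np.errstate(invalid="ignore"):
        adj = cm.values >= threshold
    np.fill_diagonal(adj, False)
    return BinaryNetwork(adjacency=adj, threshold=float(threshold),
                         subject_id=cm.subject_id, timepoint=cm.timepoint)


def binary_density(bn: BinaryNetwork) -> float:
    """Fraction of possible edges present, in [0, 1]."""
    return bn.n_edges / (bn.n * (bn.n - 1) / 2)


def degree_centrality(bn: BinaryNetwork) -> np.ndarray:
    """Edges incident to each node; integer vector in [0, n-1]."""
    return bn.adjacency.sum(axis=1).astype(int)


def threshold_sweep(cm: ConnectivityMatrix, thresholds: np.ndarray) -> np.ndarray:
    """Diagnostic: binary density at each threshold (monotone non-increasing)."""
    return np.array([binary_density(binarize(cm, t)) for t in np.asarray(thresholds)])


def build_centrality_panel(
    cms: list[ConnectivityMatrix],
    threshold: float = DEFAULT_THRESHOLD,
    *,
    subjects: list[str] | None = None,
    timepoints: list[str] | None = None,
) -> CentralityPanel:
    """Degree centrality of every (subject, timepoint) matrix, as one panel.

    Axis labels default to the sorted distinct labels found on the
    matrices; cells without a matrix are NaN-masked and logged.
    """
    if not cms:
        raise ValidationError("no connectivity matrices supplied")
    n = cms[0].n
    seen: set[tuple[str, str]] = set()
    for cm in cms:
        if cm.n != n:
            raise ShapeError(f"matrix for {cm.subject_id}/{cm.timepoint} has "
                             f"n={cm.n}, expected {n}")
        key = (cm.subject_id, cm.timepoint)
        if key in seen:
            raise ValidationError(f"duplicate (subject, timepoint) input {key}")
        seen.add(key)
    if subjects is None:
        subjects = sorted({cm.subject_id for cm in cms})
    if timepoints is None:
        timepoints = list(as_timepoint_order({cm.timepoint for cm in cms}))
    degree = np.full((n, len(subjects), len(timepoints)), np.nan)
    sub_ix = {s: i for i, s in enumerate(subjects)}
    tp_ix = {t: i for i, t in enumerate(timepoints)}
    for cm in cms:
        if cm.subject_id not in sub_ix or cm.timepoint not in tp_ix:
            raise ValidationError(
                f"matrix label {(cm.subject_id, cm.timepoint)} outside panel axes"
            )
        degree[:, sub_ix[cm.subject_id], tp_ix[cm.timepoint]] = degree_centrality(
            binarize(cm, threshold)
        )
    missing = int(np.isnan(degree[0]).sum())
    if missing:
        log.warning("centrality panel has %d missing (subject, timepoint) cells", missing)
    return CentralityPanel(degree=degree, subjects=tuple(subjects),
                           timepoints=tuple(timepoints), threshold=float(threshold))
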