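"""Core in-memory containers shared across the pipeline.

The pipeline moves through four representations:

``RegionAtlas``
    the node universe (one row per brain region, with 3-D coordinates),
``BOLDSession``
    one subject x timepoint region-by-volume signal matrix,
``ConnectivityMatrix``
    the symmetric Pearson correlation matrix of a session (diagonal
    excluded from every downstream measure),
``BinaryNetwork`` / ``CentralityPanel``
    the thresholded graph and the node x subject x timepoint degree
    table that all longitudinal statistics operate on.

All containers validate their invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataError, ShapeError, ValidationError

HEMISPHERES = ("left", "right", "midline")

#: canonical timepoint order used throughout: pre-injury then weeks post-injury
DEFAULT_TIMEPOINTS = ("pre", "1wpi", "3wpi", "7wpi", "14wpi")


@dataclass(frozen=True)
class RegionAtlas:
    """Node table: contiguous 0-based ids, names, hemispheres, coordinates (mm)."""

    node_ids: np.ndarray          # (n,) int
    names: tuple[str, ...]        # (n,)
    hemispheres: tuple[str, ...]  # (n,) each in HEMISPHERES
    coords: np.ndarray            # (n, 3) float, atlas space, mm

    def __post_init__(self) -> None:
        ids = np.asarray(self.node_ids)
        n = ids.size
        if n < 2:
            raise ValidationError(f"atlas needs >= 2 nodes, got {n}")
        if len(np.unique(ids)) != n:
            raise ValidationError("duplicate node_id in atlas")
        if not np.array_equal(np.sort(ids), np.arange(n)):
            raise ValidationError("node_ids must be contiguous 0..n-1")
        if not np.array_equal(ids, np.arange(n)):
            raise ValidationError("atlas rows must be ordered by node_id")
        if len(self.names) != n or len(self.hemispheres) != n:
            raise ShapeError("names/hemispheres length mismatch")
        if any(not str(name).strip() for name in self.names):
            raise ValidationError("every region name must be nonempty")
        bad = set(self.hemispheres) - set(HEMISPHERES)
        if bad:
            raise ValidationError(f"unknown hemisphere label(s): {sorted(bad)}")
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (n, 3):
            raise ShapeError(f"coords must be (n, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise DataError("non-finite atlas coordinates")

    @property
    def n_nodes(self) -> int:
        return int(np.asarray(self.node_ids).size)

    def hemisphere_counts(self) -> dict[str, int]:
        """Number of nodes per hemisphere (the 244-area atlas has 122/122)."""
        return {h: sum(1 for x in self.hemispheres if x == h) for h in HEMISPHERES}


@dataclass(frozen=True)
class BOLDSession:
    """One subject x timepoint signal matrix: n_regions rows, n_volumes columns."""

    subject_id: str
    timepoint: str
    signals: np.ndarray           # (n_regions, n_volumes) float
    sampling_interval: float      # seconds per volume (TR)

    def __post_init__(self) -> None:
        sig = np.asarray(self.signals, dtype=float)
        if sig.ndim != 2:
            raise ShapeError(f"signals must be 2-D, got {sig.ndim}-D")
        if sig.shape[1] < 3:
            raise ShapeError(f"need >= 3 volumes, got {sig.shape[1]}")
        if not np.all(np.isfinite(sig)):
            raise DataError(
                f"non-finite signal values in session {self.subject_id}/{self.timepoint}"
            )
        if not self.sampling_interval > 0:
            raise ValidationError("sampling_interval must be positive")
        object.__setattr__(self, "signals", sig)

    @property
    def n_regions(self) -> int:
        return self.signals.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.signals.shape[1]

    @property
    def nyquist(self) -> float:
        return 0.5 / self.sampling_interval


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric node x node Pearson matrix; diagonal excluded (stored NaN)."""

    values: np.ndarray            # (n, n) float, NaN diagonal
    subject_id: str = ""
    timepoint: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).copy()
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ShapeError(f"connectivity must be square, got {v.shape}")
        if v.shape[0] < 2:
            raise ShapeError("connectivity needs n >= 2")
        np.fill_diagonal(v, np.nan)
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if not np.all(np.isfinite(off)):
            raise DataError("non-finite off-diagonal connectivity")
        if not np.allclose(v, v.T, equal_nan=True, atol=1e-12):
            raise ValidationError("connectivity matrix must be symmetric")
        if off.min() < -1 - 1e-9 or off.max() > 1 + 1e-9:
            raise ValidationError("connectivities must lie in [-1, 1]")
        v[~np.eye(v.shape[0], dtype=bool)] = np.clip(off, -1.0, 1.0)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_pairs(self) -> int:
        """Number of unique inter-node connectivities, n(n-1)/2."""
        return self.n * (self.n - 1) // 2

    def offdiag(self) -> np.ndarray:
        """Unique off-diagonal entries (upper triangle, row-major)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass(frozen=True)
class BinaryNetwork:
    """Thresholded adjacency together with the threshold that produced it."""

    adjacency: np.ndarray         # (n, n) bool, symmetric, no self-edges
    threshold: float
    subject_id: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool).copy()
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ShapeError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValidationError("adjacency must be symmetric")
        np.fill_diagonal(a, False)
        object.__setattr__(self, "adjacency", a)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, k=1).sum())


@dataclass(frozen=True)
class CentralityPanel:
    """Degree centrality per node x subject x timepoint.

    Degrees are stored as float64 so missing cells can be NaN-masked; every
    present value is a non-negative integer in [0, n_nodes - 1].
    """

    degree: np.ndarray            # (n_nodes, n_subjects, n_timepoints)
    subjects: tuple[str, ...]
    timepoints: tuple[str, ...]
    threshold: float

    def __post_init__(self) -> None:
        d = np.asarray(self.degree, dtype=float)
        if d.ndim != 3:
            raise ShapeError("panel must be (n_nodes, n_subjects, n_timepoints)")
        if d.shape[1] != len(self.subjects) or d.shape[2] != len(self.timepoints):
            raise ShapeError("panel axes disagree with subject/timepoint labels")
        present = d[np.isfinite(d)]
        if present.size:
            if present.min() < 0 or present.max() > d.shape[0] - 1:
                raise ValidationError("degree outside [0, n_nodes - 1]")
            if not np.all(present == np.round(present)):
                raise ValidationError("degrees must be integral where present")
        object.__setattr__(self, "degree", d)

    @property
    def n_nodes(self) -> int:
        return self.degree.shape[0]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is missing."""
        return ~np.isfinite(self.degree)

    @property
    def is_complete(self) -> bool:
        return not self.mask.any()

    def timepoint_index(self, label: str) -> int:
        try:
            return self.timepoints.index(label)
        except ValueError:
            raise ValidationError(f"timepoint {label!r} not in panel") from None


def as_timepoint_order(labels: Sequence[str]) -> tuple[str, ...]:
    """Return labels sorted into canonical order where known, stable otherwise."""
    known = {t: i for i, t in enumerate(DEFAULT_TIMEPOINTS)}
    return tuple(sorted(labels, key=lambda t: (known.get(t, len(known)), t)))
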