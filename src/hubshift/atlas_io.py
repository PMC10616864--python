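"""Reading and writing the pipeline's tabular artifacts.

Dialect: UTF-8 CSV, one header row. Atlas columns are
``node_id,name,hemisphere,x,y,z``; session files are one row per region with
a header of volume indices; connectivity files are full square matrices with
a NaN diagonal (self-describing and symmetry-checked on load). Floats are
written with ``%.17g`` so a write/read round-trip is bit-exact for float64.

NIfTI extraction averages the 4-D volume over the voxels of each integer
label, where label ``node_id + 1`` encodes atlas node ``node_id`` (0 is
background) — the usual label-image convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CoverageError, DataError, FormatError, ShapeError, ValidationError
from .types import BOLDSession, ConnectivityMatrix, RegionAtlas

_FLOAT_FMT = "%.17g"
_ATLAS_COLUMNS = ["node_id", "name", "hemisphere", "x", "y", "z"]


# ---------------------------------------------------------------- atlas

def load_atlas(path: str | Path) -> RegionAtlas:
    """Read a region atlas CSV and validate it into a :class:`RegionAtlas`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _ATLAS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"atlas file {path} missing column(s) {missing}")
    ids = df["node_id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise ValidationError(f"duplicate node_id in {path}")
    df = df.sort_values("node_id").reset_index(drop=True)
    return RegionAtlas(
        node_ids=df["node_id"].to_numpy(dtype=int),
        names=tuple(str(x) for x in df["name"]),
        hemispheres=tuple(str(x) for x in df["hemisphere"]),
        coords=df[["x", "y", "z"]].to_numpy(dtype=float),
    )


def write_atlas(atlas: RegionAtlas, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "node_id": atlas.node_ids,
            "name": atlas.names,
            "hemisphere": atlas.hemispheres,
            "x": atlas.coords[:, 0],
            "y": atlas.coords[:, 1],
            "z": atlas.coords[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


# ---------------------------------------------------------------- sessions

def load_session(
    path: str | Path,
    atlas: RegionAtlas,
    *,
    subject_id: str = "",
    timepoint: str = "",
    sampling_interval: float = 1.0,
) -> BOLDSession:
    """Read a region x volume signal matrix, checking it against the atlas.

    Row ``i`` of the file is the series of atlas node ``i``; loading never
    reorders nodes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    sig = df.to_numpy(dtype=float)
    if sig.shape[0] != atlas.n_nodes:
        raise ShapeError(
            f"{path}: {sig.shape[0]} rows but atlas has {atlas.n_nodes} nodes"
        )
    if not np.all(np.isfinite(sig)):
        raise DataError(f"{path}: non-finite signal cells")
    return BOLDSession(
        subject_id=subject_id,
        timepoint=timepoint,
        signals=sig,
        sampling_interval=sampling_interval,
    )


def write_session(session: BOLDSession, path: str | Path) -> Path:
    path = Path(path)
    header = ",".join(f"v{t}" for t in range(session.n_volumes))
    np.savetxt(
        path, session.signals, fmt=_FLOAT_FMT, delimiter=",",
        header=header, comments="",
    )
    return path


# ---------------------------------------------------------------- connectivity

def write_connectivity(cm: ConnectivityMatrix, path: str | Path,
                       sidecar: bool = True) -> Path:
    """Write a connectivity matrix (NaN diagonal) plus a JSON meta sidecar."""
    path = Path(path)
    header = ",".join(f"n{i}" for i in range(cm.n))
    np.savetxt(path, cm.values, fmt=_FLOAT_FMT, delimiter=",",
               header=header, comments="")
    if sidecar:
        meta = {"subject_id": cm.subject_id, "timepoint": cm.timepoint, **cm.meta}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2, sort_keys=True)
        )
    return path


def load_connectivity(path: str | Path, *, subject_id: str = "",
                      timepoint: str = "") -> ConnectivityMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    values = pd.read_csv(path, float_precision="round_trip").to_numpy(dtype=float)
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        subject_id = subject_id or meta.pop("subject_id", "")
        timepoint = timepoint or meta.pop("timepoint", "")
    return ConnectivityMatrix(values=values, subject_id=subject_id,
                              timepoint=timepoint, meta=meta)


# ---------------------------------------------------------------- NIfTI

def extract_from_nifti(
    volume_path: str | Path,
    label_path: str | Path,
    atlas: RegionAtlas,
    *,
    subject_id: str = "",
    timepoint: str = "",
) -> BOLDSession:
    """Label-wise mean extraction of region time series from a 4-D volume.

    Stands in for the usual toolbox ROI extraction: the series of node ``i``
    is the mean of the 4-D signal over voxels carrying label ``i + 1``.
    """
    import nibabel as nib

    vol_img = nib.load(str(volume_path))
    lab_img = nib.load(str(label_path))
    vol = np.asarray(vol_img.dataobj, dtype=float)
    lab = np.asarray(lab_img.dataobj)
    if vol.ndim != 4:
        raise ShapeError(f"{volume_path}: expected 4-D volume, got {vol.ndim}-D")
    if lab.ndim != 3:
        raise ShapeError(f"{label_path}: expected 3-D label image, got {lab.ndim}-D")
    if vol.shape[:3] != lab.shape:
        raise ShapeError(
            f"grid mismatch: volume {vol.shape[:3]} vs labels {lab.shape}"
        )
    if not np.allclose(lab, np.round(lab)):
        raise DataError(f"{label_path}: label image is not integer-valued")
    lab = np.round(lab).astype(int)

    tr = float(vol_img.header.get_zooms()[3]) if len(vol_img.header.get_zooms()) > 3 else 1.0
    if tr <= 0:
        tr = 1.0
    n_vol = vol.shape[3]
    signals = np.empty((atlas.n_nodes, n_vol))
    flat = vol.reshape(-1, n_vol)
    flat_lab = lab.reshape(-1)
    for node_id in atlas.node_ids:
        sel = flat_lab == node_id + 1
        if not sel.any():
            raise CoverageError(f"label {node_id + 1} (node {node_id}) absent")
        signals[node_id] = flat[sel].mean(axis=0)
    return BOLDSession(subject_id=subject_id, timepoint=timepoint,
                       signals=signals, sampling_interval=tr)
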