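"""File-format plumbing: orientation files, echo-time sidecars, study loading.

Volumes travel as NIfTI-1.  B0 directions travel as a JSON orientation file,
a list of ``{"id": ..., "b0": [x, y, z], "angle_deg": ...}`` records where
``angle_deg`` is optional provenance (the registered rotation angle to the
reference axis).  Echo times come from a JSON sidecar
``{"echo_times_ms": [...]}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .grids import B0Direction, VolumeGrid
from .inversion import MultiOrientationStudy, OrientationSet

__all__ = [
    "read_orientations",
    "write_orientations",
    "read_echo_times",
    "write_echo_times",
    "load_study",
]


def read_orientations(path: str | Path) -> OrientationSet:
    records = json.loads(Path(path).read_text())
    if not isinstance(records, list) or not records:
        raise ValueError(f"{path}: expected a non-empty list of orientation records")
    b0s, angles = [], []
    for rec in records:
        b0s.append(B0Direction(np.asarray(rec["b0"], dtype=float)))
        angles.append(float(rec.get("angle_deg", np.nan)))
    angles_arr = np.asarray(angles)
    return OrientationSet(b0s, angles_deg=None if np.all(np.isnan(angles_arr)) else angles_arr)


def write_orientations(path: str | Path, orientations: OrientationSet) -> None:
    records = []
    for i, b0 in enumerate(orientations):
        rec = {"id": i, "b0": [float(v) for v in b0.vector]}
        if orientations.angles_deg is not None:
            rec["angle_deg"] = float(orientations.angles_deg[i])
        records.append(rec)
    Path(path).write_text(json.dumps(records, indent=2) + "\n")


def read_echo_times(path: str | Path) -> np.ndarray:
    payload = json.loads(Path(path).read_text())
    te = np.asarray(payload["echo_times_ms"], dtype=float)
    if te.ndim != 1 or len(te) < 2:
        raise ValueError(f"{path}: need >= 2 echo times")
    return te


def write_echo_times(path: str | Path, echo_times_ms) -> None:
    Path(path).write_text(
        json.dumps({"echo_times_ms": [float(t) for t in echo_times_ms]}, indent=2) + "\n"
    )


def load_study(field_paths, orientations_path, mask_path) -> MultiOrientationStudy:
    """Assemble a multi-orientation study from NIfTI fields + orientation JSON."""
    fields = [VolumeGrid.from_nifti(p) for p in field_paths]
    b0s = read_orientations(orientations_path)
    mask = VolumeGrid.from_nifti(mask_path)
    return MultiOrientationStudy(fields=fields, b0s=b0s, mask=mask)
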