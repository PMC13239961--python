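"""Plain-text interchange formats: JSON headers + CSV payloads.

A dose volume is stored as ``<prefix>.json`` (shape, spacing, origin,
isocenter, prescription) plus ``<prefix>.csv`` holding the flat values
in C order; a structure mask reuses the same layout with 0/1 values.  A
dose plane is a CSV matrix with a JSON sidecar (spacing, mode).  Feature
and metric tables are ordinary CSV via pandas.  Round trips are lossless
to 1e-9 Gy (values are written with 17 significant digits).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import DosePlane, DoseVolume, StructureMask, ValidationError

__all__ = [
    "write_volume",
    "read_volume",
    "write_mask",
    "read_mask",
    "write_plane",
    "read_plane",
    "write_feature_table",
    "read_feature_table",
]

_FMT = "%.17g"


def _read_json(path: Path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValidationError(f"malformed JSON header {path}: {e}") from e


def write_volume(volume: DoseVolume, prefix) -> None:
    prefix = Path(prefix)
    header = {
        "shape": list(volume.shape),
        "spacing_mm": volume.spacing.tolist(),
        "origin_mm": volume.origin.tolist(),
        "isocenter_mm": volume.isocenter.tolist(),
        "prescription_dose_gy": volume.prescription_dose,
    }
    prefix.with_suffix(".json").write_text(json.dumps(header, indent=1))
    np.savetxt(prefix.with_suffix(".csv"), volume.grid.reshape(-1, 1), fmt=_FMT)


def read_volume(prefix) -> DoseVolume:
    prefix = Path(prefix)
    header = _read_json(prefix.with_suffix(".json"))
    for key in ("shape", "spacing_mm", "origin_mm", "isocenter_mm"):
        if key not in header:
            raise ValidationError(f"volume header missing field {key!r}")
    values = np.loadtxt(prefix.with_suffix(".csv"))
    shape = tuple(header["shape"])
    if values.size != int(np.prod(shape)):
        raise ValidationError(
            f"volume payload has {values.size} values, header shape {shape} needs {int(np.prod(shape))}"
        )
    return DoseVolume(
        values.reshape(shape),
        header["spacing_mm"],
        header["origin_mm"],
        header["isocenter_mm"],
        prescription_dose=float(header.get("prescription_dose_gy", 0.0)),
    )


def write_mask(mask: StructureMask, prefix) -> None:
    prefix = Path(prefix)
    header = {"shape": list(mask.grid.shape), "label": mask.label}
    prefix.with_suffix(".json").write_text(json.dumps(header, indent=1))
    np.savetxt(prefix.with_suffix(".csv"), mask.grid.astype(int).reshape(-1, 1), fmt="%d")


def read_mask(prefix) -> StructureMask:
    prefix = Path(prefix)
    header = _read_json(prefix.with_suffix(".json"))
    values = np.loadtxt(prefix.with_suffix(".csv"))
    shape = tuple(header["shape"])
    if values.size != int(np.prod(shape)):
        raise ValidationError("mask payload size does not match header shape")
    return StructureMask(values.reshape(shape) > 0.5, label=header.get("label", "target"))


def write_plane(plane: DosePlane, csv_path) -> None:
    csv_path = Path(csv_path)
    np.savetxt(csv_path, plane.matrix, fmt=_FMT, delimiter=",")
    sidecar = {"spacing_mm": plane.spacing_mm, "mode": plane.mode}
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_plane(csv_path) -> DosePlane:
    csv_path = Path(csv_path)
    matrix = np.loadtxt(csv_path, delimiter=",")
    if matrix.ndim != 2:
        raise ValidationError(f"plane CSV {csv_path} is not a 2D matrix")
    sidecar_path = csv_path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = _read_json(sidecar_path)
        if "spacing_mm" not in sidecar:
            raise ValidationError(f"plane sidecar {sidecar_path} missing spacing_mm")
        return DosePlane(matrix, float(sidecar["spacing_mm"]), sidecar.get("mode", "absolute"))
    return DosePlane(matrix, spacing_mm=1.0, mode="absolute")


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
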