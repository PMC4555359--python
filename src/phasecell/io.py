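"""Phase-map, contour, mesh and report I/O.

Phase and thickness maps are stored as 32-bit float single-page TIFF or as
plain-text matrices, with a JSON sidecar carrying the physical metadata
(plane, pixel size, wavelength, wrapped flag, origin).  Contours go to CSV
(plane, label, x, y in μm), reports to CSV/JSON, meshes to PLY/OBJ.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .boundary_extraction import BoundaryContour
from .phase_forward import PhaseMap, ThicknessMap
from .reconstruct3d import NucleusReport

__all__ = [
    "save_phase_map",
    "load_phase_map",
    "save_thickness_map",
    "save_contours",
    "load_contours",
    "save_report",
    "save_mesh",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_phase_map(pm: PhaseMap, path) -> None:
    path = Path(path)
    meta = {
        "plane": pm.plane,
        "pixel_size": pm.pixel_size,
        "origin": [float(v) for v in pm.origin],
        "wavelength": pm.wavelength,
        "wrapped": bool(pm.wrapped),
    }
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, pm.values.astype(np.float32))
    else:
        np.savetxt(path, pm.values)
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_phase_map(path) -> PhaseMap:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    if path.suffix.lower() in {".tif", ".tiff"}:
        values = tifffile.imread(path).astype(float)
    else:
        values = np.loadtxt(path)
    return PhaseMap(
        values=values,
        plane=meta["plane"],
        pixel_size=meta["pixel_size"],
        origin=np.asarray(meta["origin"]),
        wavelength=meta["wavelength"],
        wrapped=meta["wrapped"],
    )


def save_thickness_map(tm: ThicknessMap, path) -> None:
    path = Path(path)
    meta = {
        "plane": tm.plane,
        "pixel_size": tm.pixel_size,
        "origin": [float(v) for v in tm.origin],
        "compartment": tm.compartment,
    }
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, tm.values.astype(np.float32))
    else:
        np.savetxt(path, tm.values)
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def save_contours(contours: list[BoundaryContour], path) -> None:
    rows = []
    for c in contours:
        for x, y in c.points:
            rows.append(
                {"plane": c.plane, "label": c.label, "method": c.method, "u": x, "v": y}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_contours(path) -> list[BoundaryContour]:
    df = pd.read_csv(path)
    out = []
    for (plane, label, method), grp in df.groupby(
        ["plane", "label", "method"], sort=False
    ):
        out.append(
            BoundaryContour(
                plane=plane,
                points=grp[["u", "v"]].to_numpy(),
                label=label,
                method=method,
            )
        )
    return out


def save_report(report: NucleusReport, path) -> None:
    path = Path(path)
    d = report.as_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=1))
    else:
        pd.DataFrame([d]).to_csv(path, index=False)


def save_mesh(mesh, path) -> None:
    mesh.export(str(path))
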