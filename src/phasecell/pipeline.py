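"""End-to-end characterization of a nucleated cell from orthogonal phase maps.

The pipeline chains the method's stages: forward projection (or user-supplied
unwrapped maps) on the x-y and x-z planes → inflexion-curve boundary
extraction on each plane → phase-centre detection (centroid rule, with the
extremum rule reported alongside) → cross-view centre reconciliation →
two-view surface reconstruction → axis-aligned ellipsoid fit → outer-surface
thickness by phase subtraction and membrane/nucleus assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from . import boundary_extraction as be
from . import reconstruct3d as r3
from .cell_models import RefractiveIndexScene
from .phase_forward import PhaseMap, project_phase
from .phase_unwrap import unwrap2d

__all__ = ["CellReconstruction", "characterize_nucleus"]


@dataclass
class CellReconstruction:
    """Full output of the orthogonal-phase reconstruction pipeline."""

    report: r3.NucleusReport
    center_centroid: np.ndarray  # (3,) from the contour-centroid rule
    center_extremum: np.ndarray | None  # (3,) from the in-contour extremum rule
    contours_xy: list
    contours_xz: list
    nucleus_mesh: trimesh.Trimesh
    membrane_mesh: trimesh.Trimesh | None = None
    maps: dict = field(default_factory=dict)


def _nucleus_and_cell(contours):
    nuclei = [c for c in contours if c.label == "nucleus"]
    cells = [c for c in contours if c.label == "cell"]
    if not nuclei:
        raise be.NoNucleusError("no nucleus contour on plane")
    return min(nuclei, key=lambda c: c.area), (max(cells, key=lambda c: c.area) if cells else None)


def characterize_nucleus(
    source: RefractiveIndexScene | tuple[PhaseMap, PhaseMap],
    pixel_size: float = 0.0625,
    field_width: float = 16.0,
    wavelength: float = 0.488,
    smoothing_sigma: float | None = None,
    rel_threshold: float = 0.02,
    reconcile_tol: float = 0.2,
    method: str = "merge",
    assemble: bool = False,
    refractive_indices: tuple[float, float, float] | None = None,
) -> CellReconstruction:
    """Run the full reconstruction and return quantitative nucleus descriptors.

    ``source`` is either a scene (simulated forward) or a pair of *unwrapped*
    phase maps on planes 'xy' and 'xz'.  ``method`` selects the surface
    builder: "merge" (both views, default) or "rotate" (literal 180°
    revolution of the x-y outline about the shared axis).  With
    ``assemble=True`` the membrane surface is reconstructed as well, the
    outer-surface thickness is computed by phase subtraction
    (``refractive_indices`` = (n1, n2, nm) required for scenes it cannot be
    inferred from) and nucleus containment is verified.
    """
    if isinstance(source, RefractiveIndexScene):
        pm_xy = project_phase(source, "xy", pixel_size, wavelength, field_width)
        pm_xz = project_phase(source, "xz", pixel_size, wavelength, field_width)
        if refractive_indices is None:
            prios = sorted({p.priority for p in source.parts})
            if len(prios) >= 2:
                n1 = next(p.refractive_index for p in source.parts if p.priority == prios[0])
                n2 = next(p.refractive_index for p in source.parts if p.priority == prios[-1])
                refractive_indices = (n1, n2, source.medium_index)
    else:
        pm_xy, pm_xz = source
        if pm_xy.plane != "xy" or pm_xz.plane != "xz":
            raise ValueError("expected phase maps on planes 'xy' and 'xz'")
        if pm_xy.wrapped:
            pm_xy = unwrap2d(pm_xy)
        if pm_xz.wrapped:
            pm_xz = unwrap2d(pm_xz)

    contours = {}
    centers_centroid = {}
    centers_extremum = {}
    for pm in (pm_xy, pm_xz):
        resp = be.inflexion_field(pm, smoothing_sigma)
        cs = be.extract_contours(resp, pm, rel_threshold=rel_threshold)
        nucleus, _cell = _nucleus_and_cell(cs)
        contours[pm.plane] = cs
        centers_centroid[pm.plane] = be.phase_center_centroid(nucleus)
        centers_extremum[pm.plane] = be.phase_center_extremum(pm, cs)

    center = be.reconcile_centers(
        centers_centroid["xy"], centers_centroid["xz"], tol=reconcile_tol
    )
    try:
        center_ext = be.reconcile_centers(
            centers_extremum["xy"], centers_extremum["xz"], tol=np.inf
        )
    except be.NoNucleusError:  # pragma: no cover - tol is inf
        center_ext = None

    nuc_xy, cell_xy = _nucleus_and_cell(contours["xy"])
    nuc_xz, cell_xz = _nucleus_and_cell(contours["xz"])
    if method == "merge":
        mesh = r3.merge_orthogonal(nuc_xy, nuc_xz)
    elif method == "rotate":
        mesh = r3.rotate_outline(nuc_xy, axis_offset=center[1])
        # revolution of the x-y outline: swept coordinate is z about y=center
        mesh.vertices[:, 2] += center[2]
    else:
        raise ValueError(f"unknown reconstruction method {method!r}")

    report = r3.fit_ellipsoid(mesh=mesh, center=center)

    membrane = None
    maps = {"phase_xy": pm_xy, "phase_xz": pm_xz}
    if assemble:
        if cell_xy is None or cell_xz is None:
            raise be.NoNucleusError("cell outline missing; cannot assemble")
        membrane = r3.merge_orthogonal(cell_xy, cell_xz)
        r3.assemble_cell(membrane, mesh, center)
        if refractive_indices is not None:
            n1, n2, nm = refractive_indices
            h2 = r3.nucleus_thickness_from_mesh(
                mesh, "xy", pm_xy.pixel_size, field=field_width
            )
            maps["h2_xy"] = h2
            maps["h1_xy"] = r3.outer_surface_thickness(pm_xy, h2, n1, n2, nm)

    return CellReconstruction(
        report=report,
        center_centroid=center,
        center_extremum=center_ext,
        contours_xy=contours["xy"],
        contours_xz=contours["xz"],
        nucleus_mesh=mesh,
        membrane_mesh=membrane,
        maps=maps,
    )
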