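"""Mesh-based measurement utilities.

Reconstruction accuracy is quantified with a gauge-block protocol: two
certified blocks of different heights are scanned side by side and the step
between their top planes is measured as the difference of the mean vertical
vertex coordinates.  Closed-mesh surface area and volume (divergence
theorem) and the longest body axis support morphometric work on specimen
meshes.  All coordinates are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from .errors import InvalidInputError, NotWatertightError

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class RegionSpec:
    """Axis-aligned bounding box selecting a vertex subset (mm)."""

    min_corner: tuple[float, float, float]
    max_corner: tuple[float, float, float]
    label: str = ""

    def __post_init__(self) -> None:
        if any(lo > hi for lo, hi in zip(self.min_corner, self.max_corner)):
            raise InvalidInputError(f"region {self.label!r}: min > max")

    def select(self, vertices: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.min_corner)
        hi = np.asarray(self.max_corner)
        return np.all((vertices >= lo) & (vertices <= hi), axis=1)


def load_mesh(path: str | Path) -> trimesh.Trimesh:
    """Load a PLY/OBJ triangle mesh and drop degenerate faces."""
    mesh = trimesh.load_mesh(Path(path), process=False)
    if not isinstance(mesh, trimesh.Trimesh):
        raise InvalidInputError(f"{path} did not contain a single triangle mesh")
    mesh.update_faces(mesh.nondegenerate_faces())
    return mesh


def step_height(
    mesh: trimesh.Trimesh,
    top: RegionSpec,
    reference: RegionSpec,
    up_axis: str = "z",
) -> tuple[float, float, int, int]:
    """Mean vertical distance between two vertex regions.

    Returns ``(mean, sd, n_top, n_ref)`` where ``mean`` is the difference of
    the mean up-coordinates (top minus reference) and ``sd`` combines the
    two regions' up-coordinate standard deviations in quadrature — the
    spread of a single top/reference vertex pair, not of the mean.
    """
    if up_axis not in _AXES:
        raise InvalidInputError(f"up_axis must be one of {sorted(_AXES)}")
    axis = _AXES[up_axis]
    vertices = np.asarray(mesh.vertices, dtype=np.float64)
    sel_top = top.select(vertices)
    sel_ref = reference.select(vertices)
    if not sel_top.any():
        raise InvalidInputError(f"region {top.label or 'top'} selects no vertices")
    if not sel_ref.any():
        raise InvalidInputError(
            f"region {reference.label or 'reference'} selects no vertices"
        )
    up_top = vertices[sel_top, axis]
    up_ref = vertices[sel_ref, axis]
    mean = float(up_top.mean() - up_ref.mean())
    sd = float(np.hypot(up_top.std(ddof=1) if up_top.size > 1 else 0.0,
                        up_ref.std(ddof=1) if up_ref.size > 1 else 0.0))
    return mean, sd, int(sel_top.sum()), int(sel_ref.sum())


def surface_area(mesh: trimesh.Trimesh) -> float:
    """Total triangle area (mm^2)."""
    return float(mesh.area)


def enclosed_volume(mesh: trimesh.Trimesh) -> float:
    """Enclosed volume (mm^3) of a watertight, consistently oriented mesh.

    Computed as the magnitude of the signed-tetrahedron sum (divergence
    theorem).  A mesh that does not bound a solid is refused.
    """
    if not (mesh.is_watertight and mesh.is_winding_consistent):
        raise NotWatertightError(
            "mesh is not watertight with consistent winding; volume undefined",
            surface_area=float(mesh.area),
        )
    return float(abs(mesh.volume))


def surface_and_volume(mesh: trimesh.Trimesh) -> tuple[float, float]:
    """(area mm^2, volume mm^3); raises for non-watertight meshes.

    The raised :class:`NotWatertightError` still carries the surface area in
    its ``surface_area`` attribute.
    """
    return surface_area(mesh), enclosed_volume(mesh)


def longest_axis(mesh: trimesh.Trimesh, exact_below: int = 500) -> float:
    """Maximum pairwise vertex distance (mm).

    Exact brute force for small vertex counts; for larger meshes the
    diameter is computed on the convex-hull vertices, which contains the
    farthest pair.
    """
    vertices = np.asarray(mesh.vertices, dtype=np.float64)
    if len(vertices) < 2:
        raise InvalidInputError("longest_axis needs at least 2 vertices")
    pts = vertices
    if len(vertices) > exact_below:
        from scipy.spatial import ConvexHull

        try:
            pts = vertices[ConvexHull(vertices).vertices]
        except Exception:  # degenerate (coplanar/collinear) clouds
            pts = vertices
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))
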