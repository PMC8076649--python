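"""Spatially accurate 3D corridor models: spline base ring, cone mesh, export.

The corridor model is a cone from the apex to the ring of translated
extrema, with the base boundary smoothed by a closed periodic cubic spline
through the extrema so the rendered corridor resembles the anatomy rather
than a faceted polygon.  Note the smoothing is *visual only*: the numeric
volume of surgical freedom is always computed from straight segments
between the extrema (the shoelace polygon), never from the mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.interpolate import CubicSpline

from .errors import DegenerateMeshError, UnsupportedFormatError
from .geometry import as_point, as_points, fit_plane_tls
from .polygon import build_plane_basis, to_plane_coords

__all__ = [
    "CorridorMesh",
    "base_spline_ring",
    "build_cone_mesh",
    "mesh_volume",
    "export_mesh",
    "MESH_FORMATS",
]

#: Supported export formats and the trimesh exporter arguments behind them.
MESH_FORMATS = ("stl", "stl-ascii", "obj", "ply")


@dataclass(frozen=True)
class CorridorMesh:
    """Triangle mesh of a corridor cone.

    ``vertices`` is ``(n, 3)`` float (mm), ``faces`` ``(k, 3)`` integer
    indices with consistent outward winding.  ``provenance`` records the
    measurement id, normalization height, and ring sample count used.
    """

    vertices: np.ndarray
    faces: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        v = as_points(self.vertices)
        f = np.asarray(self.faces, dtype=int)
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError(f"faces must be (k, 3) index triples, got {f.shape}")
        if f.min(initial=0) < 0 or (len(f) and f.max() >= len(v)):
            raise ValueError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @property
    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)


def _segment_sample_params(knots: np.ndarray, samples: int) -> np.ndarray:
    """Sample parameters covering each spline segment, always including knots.

    ``samples`` points are allocated to the ``n`` segments by largest
    remainder of chord length, each segment contributing its start knot plus
    evenly spaced interior parameters.  With ``samples == n`` this returns
    exactly the knots, so the extrema are always ring vertices.
    """
    n = len(knots) - 1
    chord = np.diff(knots)
    share = chord / chord.sum() * (samples - n)
    counts = np.floor(share).astype(int)
    remainder = share - counts
    for idx in np.argsort(-remainder)[: samples - n - counts.sum()]:
        counts[idx] += 1
    params = []
    for i in range(n):
        c = counts[i] + 1  # include the start knot
        params.extend(knots[i] + (knots[i + 1] - knots[i]) * np.arange(c) / c)
    return np.asarray(params)


def base_spline_ring(translated_extrema, samples: int = 64) -> np.ndarray:
    """Closed periodic cubic spline through the extrema, sampled on the base plane.

    The extrema (already translated onto the base plane) are charted in 2D,
    interpolated by a periodic cubic spline parameterized by cumulative
    chord length, sampled at ``samples`` parameters that always include the
    knots, and mapped back to 3D.  The returned ring therefore lies exactly
    on the base plane and passes through every extremum.
    """
    pts = as_points(translated_extrema)
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 extrema for a spline ring")
    if samples < n:
        raise ValueError(f"samples ({samples}) must be >= number of extrema ({n})")
    basis = build_plane_basis(pts)  # validates coplanarity, rejects collinear rings
    xy = to_plane_coords(pts, basis)
    closed = np.vstack([xy, xy[:1]])
    chord = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    if np.any(chord < 1e-12):
        raise ValueError("consecutive extrema coincide; spline knots must be distinct")
    knots = np.concatenate([[0.0], np.cumsum(chord)])
    spline = CubicSpline(knots, closed, bc_type="periodic", axis=0)
    params = _segment_sample_params(knots, samples)
    ring2d = spline(params)
    return basis.to_3d(ring2d)


def build_cone_mesh(apex, ring, cap_base: bool = True, provenance=None) -> CorridorMesh:
    """Triangle mesh of the cone from ``apex`` to the closed base ``ring``.

    Side faces fan from the apex over consecutive ring points; with
    ``cap_base`` the base is closed by a fan from the ring centroid, making
    the mesh watertight (``m`` ring points give ``m + 2`` vertices and
    ``2m`` faces).  Winding is consistent so the signed divergence-theorem
    volume is meaningful.
    """
    apex = as_point(apex)
    ring = as_points(ring)
    m = len(ring)
    if m < 3:
        raise DegenerateMeshError("ring needs at least 3 points")
    plane, _ = fit_plane_tls(ring)
    if abs(plane.signed_distance(apex)) < 1e-9:
        raise DegenerateMeshError("apex lies on the base-ring plane")

    vertices = [apex, *ring]
    faces = [(0, 1 + i, 1 + (i + 1) % m) for i in range(m)]
    if cap_base:
        centroid_index = m + 1
        vertices.append(ring.mean(axis=0))
        faces += [(centroid_index, 1 + (i + 1) % m, 1 + i) for i in range(m)]
    return CorridorMesh(
        vertices=np.asarray(vertices),
        faces=np.asarray(faces, dtype=int),
        provenance=dict(provenance or {}),
    )


def mesh_volume(mesh: CorridorMesh) -> float:
    """Unsigned enclosed volume (mm³) by the divergence theorem.

    Sums signed tetrahedron volumes ``det(v0, v1, v2) / 6`` over faces;
    exact for watertight meshes with consistent winding.
    """
    v = mesh.vertices
    f = mesh.faces
    signed = np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])) / 6.0
    return float(abs(signed.sum()))


_TRIMESH_EXPORT = {
    "stl": {"file_type": "stl"},
    "stl-ascii": {"file_type": "stl_ascii"},
    "obj": {"file_type": "obj"},
    "ply": {"file_type": "ply", "encoding": "ascii"},
}


def export_mesh(mesh: CorridorMesh, path, file_format: str | None = None) -> None:
    """Write the mesh to ``path`` as STL (binary or ascii), OBJ, or PLY.

    ``file_format`` defaults to the path suffix (``.stl`` means binary STL;
    pass ``"stl-ascii"`` explicitly for the text variant).  OBJ and ascii
    PLY round-trip coordinates exactly; STL stores float32.
    """
    path = str(path)
    if file_format is None:
        suffix = path.rsplit(".", 1)[-1].lower() if "." in path else ""
        file_format = {"stl": "stl", "obj": "obj", "ply": "ply"}.get(suffix)
        if file_format is None:
            raise UnsupportedFormatError(
                f"cannot infer mesh format from path {path!r}; pass file_format"
            )
    key = file_format.lower().replace("_", "-")
    if key not in _TRIMESH_EXPORT:
        raise UnsupportedFormatError(
            f"unsupported mesh format {file_format!r}; choose from {MESH_FORMATS}"
        )
    try:
        mesh.to_trimesh().export(path, **_TRIMESH_EXPORT[key])
    except OSError as exc:
        raise OSError(f"failed to write mesh to {path!r}: {exc}") from exc
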