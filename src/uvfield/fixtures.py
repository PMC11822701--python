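"""Synthetic inputs: convex fixture meshes and synthetic dose-response data.

Real irradiated objects (food items scanned to convex-hull meshes) are
site-specific; these generators provide convex, watertight stand-ins with
known analytic properties (a box and an icosphere) and seeded synthetic
dose-response observations from a chosen inactivation model, for tests,
examples and end-to-end runs.
"""

from __future__ import annotations

import numpy as np
import trimesh

from .errors import ValidationError
from .geometry import TriangleMesh, _winding_normals
from .inactivation import InactivationModel, log_reduction


def _from_trimesh(tm: trimesh.Trimesh) -> TriangleMesh:
    vertices = np.asarray(tm.vertices, float)
    facets = np.asarray(tm.faces, int)
    normals, _ = _winding_normals(vertices, facets)
    return TriangleMesh(vertices=vertices, facets=facets, facet_normals=normals)


def generate_fixture_mesh(shape: str, **params) -> TriangleMesh:
    """A convex, watertight fixture mesh with outward normals.

    ``shape='box'`` takes ``extents`` (3 side lengths, m; default 0.1 cube);
    ``shape='icosphere'`` takes ``radius`` (m, default 0.03) and
    ``subdivisions`` (default 3).
    """
    if shape == "box":
        extents = np.asarray(params.get("extents", (0.1, 0.1, 0.1)), float)
        if np.any(extents <= 0):
            raise ValidationError("box extents must be > 0")
        return _from_trimesh(trimesh.creation.box(extents=extents))
    if shape == "icosphere":
        radius = float(params.get("radius", 0.03))
        if radius <= 0:
            raise ValidationError("icosphere radius must be > 0")
        subdivisions = int(params.get("subdivisions", 3))
        return _from_trimesh(trimesh.creation.icosphere(
            subdivisions=subdivisions, radius=radius))
    raise ValidationError(f"unknown fixture shape {shape!r} (box | icosphere)")


def save_mesh_stl(mesh: TriangleMesh, path, ascii_format: bool = True) -> None:
    """Write a fixture mesh to STL (ASCII by default, for text fixtures)."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.facets, process=False)
    file_type = "stl_ascii" if ascii_format else "stl"
    tm.export(path, file_type=file_type)


def synthetic_dose_response(model: InactivationModel, fluences,
                            noise_sigma: float = 0.0,
                            rng: np.random.Generator | None = None) -> np.ndarray:
    """(fluence, log10 reduction) observations from a known model.

    Gaussian noise of standard deviation ``noise_sigma`` (log10 units) is
    added to the reductions when requested; pass a seeded ``rng`` for
    reproducibility.
    """
    f = np.asarray(fluences, float).reshape(-1)
    if np.any(f < 0):
        raise ValidationError("fluences must be >= 0")
    y = np.asarray(log_reduction(model, f), float)
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        y = y + rng.normal(0.0, noise_sigma, size=f.shape)
    return np.column_stack([f, y])
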