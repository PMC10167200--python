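"""Tetrahedral meshes of the computational domain.

The flow domain is a circular cylinder of radius ``max l_ro`` aligned with
the valve axis, locally refined around the valve.  Meshes are built by
extrusion: a Delaunay triangulation of a ring-structured point set on the
cross-section disk is extruded through graded z-layers (fine inside the
refinement band around the valve, coarse elsewhere) and every prism is cut
into three tetrahedra with an index-ordering rule that keeps shared faces
conforming.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from .params import ParameterError


@dataclass
class CylinderSpec:
    """Geometry and size field of the cylindrical flow domain (mm)."""

    radius: float
    z_min: float
    z_max: float
    h_fine: float = 0.5
    h_coarse: float = 0.75
    refine_band: tuple[float, float] | None = None  # default: [0, valve top] +/- margin

    def __post_init__(self):
        if self.radius <= 0.0:
            raise ParameterError("cylinder radius must be positive")
        if not self.z_min < 0.0 < self.z_max:
            raise ParameterError("the cylinder must contain the annulus plane z=0")
        if not 0.0 < self.h_fine <= self.h_coarse:
            raise ParameterError("0 < h_fine <= h_coarse required")
        if self.refine_band is None:
            self.refine_band = (-2.0 * self.h_coarse, 0.0)

    @classmethod
    def for_valve(cls, valve_params, h_fine: float = 0.5, h_coarse: float = 0.75,
                  upstream: float = 2.0, downstream: float = 6.0) -> "CylinderSpec":
        """Spec sized from the valve: radius max l_ro, length in leaflet heights."""
        l_h = valve_params.max_l_h
        band = (-2.0 * h_coarse, l_h + 2.0 * h_coarse)
        return cls(radius=valve_params.max_l_ro,
                   z_min=-upstream * l_h, z_max=downstream * l_h,
                   h_fine=h_fine, h_coarse=h_coarse, refine_band=band)


@dataclass
class VolumeMesh:
    """Tetrahedral mesh with tagged boundary facets (all lengths in mm)."""

    nodes: np.ndarray                     # (N, 3)
    cells: np.ndarray                     # (M, 4)
    h_max: float
    boundary_tags: dict                   # tag -> (F, 3) facet node triples
    z_layers: np.ndarray | None = None    # extrusion layers, if structured
    n_per_layer: int | None = None
    disk_node_areas: np.ndarray | None = None  # nodal area weights on the cross-section

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_volumes(self) -> np.ndarray:
        p = self.nodes[self.cells]
        return np.einsum("ij,ij->i", p[:, 1] - p[:, 0],
                         np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0])) / 6.0


# ---------------------------------------------------------------------------
# cross-section
# ---------------------------------------------------------------------------

def _disk_points(radius: float, h: float) -> np.ndarray:
    """Ring-structured point set on the disk with target spacing ~h."""
    n_rings = max(2, round(radius / h))
    pts = [np.zeros((1, 2))]
    for k in range(1, n_rings + 1):
        r = radius * k / n_rings
        n = max(6, round(2.0 * math.pi * r / (radius / n_rings)))
        ang = 2.0 * math.pi * np.arange(n) / n + (0.5 * math.pi * (k % 2)) / max(n, 1)
        pts.append(np.stack([r * np.cos(ang), r * np.sin(ang)], axis=1))
    return np.concatenate(pts, axis=0)


def _triangulate_disk(points2d: np.ndarray) -> np.ndarray:
    tri = Delaunay(points2d)
    simplices = tri.simplices
    # drop near-degenerate slivers on the boundary circle
    p = points2d[simplices]
    area = 0.5 * np.abs((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    return simplices[area > 1e-12 * np.max(area)]


def _graded_layers(z_min: float, z_max: float, band: tuple[float, float],
                   h_fine: float, h_coarse: float) -> np.ndarray:
    lo = max(z_min, min(band[0], z_max))
    hi = max(z_min, min(band[1], z_max))
    zs = [np.array([z_min])]
    for a, b, h in ((z_min, lo, h_coarse), (lo, hi, h_fine), (hi, z_max, h_coarse)):
        if b - a > 1e-12:
            n = max(1, round((b - a) / h))
            zs.append(np.linspace(a, b, n + 1)[1:])
    return np.unique(np.concatenate(zs))


def _extrude_to_tets(points2d: np.ndarray, tris: np.ndarray,
                     z_layers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    np_layer = len(points2d)
    n_layers = len(z_layers)
    nodes = np.empty((np_layer * n_layers, 3))
    for l, z in enumerate(z_layers):
        nodes[l * np_layer:(l + 1) * np_layer, :2] = points2d
        nodes[l * np_layer:(l + 1) * np_layer, 2] = z

    # rotate triangles so the smallest index is first (cyclic, keeps orientation)
    t = tris.copy()
    for _ in range(2):
        roll = (t[:, 1] < t[:, 0]) | (t[:, 2] < t[:, 0])
        t[roll] = np.roll(t[roll], -1, axis=1)

    cells = []
    for l in range(n_layers - 1):
        b = t + l * np_layer
        tt = t + (l + 1) * np_layer
        b0, b1, b2 = b[:, 0], b[:, 1], b[:, 2]
        t0, t1, t2 = tt[:, 0], tt[:, 1], tt[:, 2]
        case = b1 < b2
        # b1 < b2: diagonals through b1; else through b2 (conforming across prisms)
        ca = np.stack([np.stack([b0, b1, b2, t2], 1),
                       np.stack([b0, b1, t2, t1], 1),
                       np.stack([b0, t1, t2, t0], 1)], axis=1)
        cb = np.stack([np.stack([b0, b1, b2, t1], 1),
                       np.stack([b0, t1, b2, t2], 1),
                       np.stack([b0, t1, t2, t0], 1)], axis=1)
        cells.append(np.where(case[:, None, None], ca, cb).reshape(-1, 4))
    cells = np.concatenate(cells, axis=0)

    # enforce positive orientation
    p = nodes[cells]
    vol = np.einsum("ij,ij->i", p[:, 1] - p[:, 0],
                    np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]))
    flip = vol < 0.0
    cells[flip, 2], cells[flip, 3] = cells[flip, 3], cells[flip, 2].copy()
    return nodes, cells


def _boundary_facets(cells: np.ndarray) -> np.ndarray:
    faces = np.concatenate([cells[:, [0, 1, 2]], cells[:, [0, 1, 3]],
                            cells[:, [0, 2, 3]], cells[:, [1, 2, 3]]], axis=0)
    key = np.sort(faces, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return faces[idx[counts == 1]]


def _tag_boundary(nodes: np.ndarray, facets: np.ndarray,
                  z_min: float, z_max: float) -> dict:
    z = nodes[facets, 2]
    tol = 1e-9 * max(1.0, abs(z_max - z_min))
    on_in = np.all(np.abs(z - z_min) < tol, axis=1)
    on_out = np.all(np.abs(z - z_max) < tol, axis=1)
    return {"inlet": facets[on_in], "outlet": facets[on_out],
            "wall": facets[~(on_in | on_out)]}


def _disk_node_areas(points2d: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = points2d[tris]
    area = 0.5 * np.abs((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    w = np.zeros(len(points2d))
    for k in range(3):
        np.add.at(w, tris[:, k], area / 3.0)
    return w


def generate_cylinder_mesh(spec: CylinderSpec) -> VolumeMesh:
    """Generate the graded tetrahedral cylinder mesh with tagged boundaries.

    The cross-section is triangulated at spacing ``h_fine`` and extruded
    through z-layers of height ``h_fine`` inside ``refine_band`` and
    ``h_coarse`` outside, so the average edge length inside the band is
    bounded by ~``h_fine`` and nowhere exceeds ~``h_coarse``.  Boundary
    facets are tagged ``inlet`` (z = z_min), ``outlet`` (z = z_max) and
    ``wall`` (lateral surface).
    """
    pts2d = _disk_points(spec.radius, spec.h_fine)
    tris = _triangulate_disk(pts2d)
    z_layers = _graded_layers(spec.z_min, spec.z_max, spec.refine_band,
                              spec.h_fine, spec.h_coarse)
    nodes, cells = _extrude_to_tets(pts2d, tris, z_layers)
    if np.any(np.abs(np.einsum("ij,ij->i", nodes[cells][:, 1] - nodes[cells][:, 0],
                               np.cross(nodes[cells][:, 2] - nodes[cells][:, 0],
                                        nodes[cells][:, 3] - nodes[cells][:, 0]))) <= 0.0):
        raise RuntimeError(f"cylinder mesher produced degenerate cells "
                           f"(size field h_fine={spec.h_fine}, h_coarse={spec.h_coarse})")
    facets = _boundary_facets(cells)
    tags = _tag_boundary(nodes, facets, spec.z_min, spec.z_max)
    # h_max is the nominal maximum mesh size (coarse target), the quantity
    # the resistive-layer epsilon rule is stated on
    return VolumeMesh(nodes=nodes, cells=cells, h_max=spec.h_coarse,
                      boundary_tags=tags, z_layers=z_layers, n_per_layer=len(pts2d),
                      disk_node_areas=_disk_node_areas(pts2d, tris))


def generate_box_mesh(bounds, h: float) -> VolumeMesh:
    """Structured tetrahedral box mesh; boundary tags inlet/outlet are the
    z-extremes and wall everything lateral (mirrors the cylinder contract)."""
    (x0, x1), (y0, y1), (z0, z1) = bounds
    nx = max(1, round((x1 - x0) / h))
    ny = max(1, round((y1 - y0) / h))
    xs = np.linspace(x0, x1, nx + 1)
    ys = np.linspace(y0, y1, ny + 1)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    pts2d = np.stack([xx.ravel(), yy.ravel()], axis=1)
    tris = _triangulate_disk(pts2d)
    nz = max(1, round((z1 - z0) / h))
    z_layers = np.linspace(z0, z1, nz + 1)
    nodes, cells = _extrude_to_tets(pts2d, tris, z_layers)
    facets = _boundary_facets(cells)
    tags = _tag_boundary(nodes, facets, z0, z1)
    return VolumeMesh(nodes=nodes, cells=cells, h_max=h,
                      boundary_tags=tags, z_layers=z_layers, n_per_layer=len(pts2d),
                      disk_node_areas=_disk_node_areas(pts2d, tris))


def max_edge_length(nodes: np.ndarray, cells: np.ndarray) -> float:
    p = nodes[cells]
    m = 0.0
    for a in range(4):
        for b in range(a + 1, 4):
            m = max(m, float(np.linalg.norm(p[:, a] - p[:, b], axis=1).max()))
    return m


def average_edge_length(nodes: np.ndarray, cells: np.ndarray,
                        mask: np.ndarray | None = None) -> float:
    p = nodes[cells if mask is None else cells[mask]]
    lengths = [np.linalg.norm(p[:, a] - p[:, b], axis=1)
               for a in range(4) for b in range(a + 1, 4)]
    return float(np.mean(np.concatenate(lengths)))


def facet_areas(nodes: np.ndarray, facets: np.ndarray) -> np.ndarray:
    p = nodes[facets]
    return 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
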