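"""Distance from points to the valve surface and the resistive gamma field.

The valve enters the flow solver as a resistive immersed implicit surface:
every mesh node closer than a half-thickness ``epsilon`` to the parametric
surface receives a large penalty coefficient ``C`` (default 1e8), all other
nodes 0.  The nodewise distance is the minimum over the patch functions of

    min_{u,v in [0,1]^2} || h_i(u, v) - x ||

solved with Powell's method started from the best point of a coarse
parameter grid per patch; the mirrored leaflet halves are handled by also
querying the point reflected across each leaflet's symmetry plane.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .params import ParameterError
from .surfaces import ValveSurfaceSet, CoonsPatch


@dataclass
class ResistiveConfig:
    """Settings of the resistive (penalty) field.

    ``C`` is the penalization constant added to the momentum equation on
    the valve support; ``h_phys`` a physiological leaflet thickness floor
    (mm) kept under mesh refinement; ``epsilon_override`` bypasses the
    epsilon rule entirely.
    """

    C: float = 1e8
    h_phys: float = 0.0
    epsilon_override: float | None = None

    def __post_init__(self):
        if self.C <= 0.0:
            raise ParameterError("penalization constant C must be positive")
        if self.h_phys < 0.0:
            raise ParameterError("h_phys must be nonnegative")


@dataclass
class GammaField:
    """Nodewise resistive values: every entry is exactly 0 or C."""

    values: np.ndarray
    epsilon_used: float
    C: float

    @property
    def support_count(self) -> int:
        return int(np.count_nonzero(self.values))


def compute_epsilon(h_max: float, h_phys: float = 0.0,
                    override: float | None = None) -> float:
    """Half-thickness of the resistive layer: max(h_phys/2, 0.75*h_max).

    ``h_max`` is the maximum mesh size; the 75% rule keeps the thresholded
    leaflet free of holes, while the ``h_phys/2`` floor keeps the thickness
    physiological under mesh refinement.  ``override`` wins if given.
    """
    if override is not None:
        return float(override)
    if h_max <= 0.0:
        raise ParameterError("h_max must be positive")
    return max(h_phys / 2.0, 0.75 * h_max)


# ---------------------------------------------------------------------------
# distance queries
# ---------------------------------------------------------------------------

class ValveDistance:
    """Reusable distance evaluator for a fixed valve surface set.

    Precomputes, per half-leaflet patch, a coarse (u,v) sample grid used to
    start Powell's method, and a dense surface point cloud (KD-tree) used
    to prefilter bulk queries.
    """

    def __init__(self, valve: ValveSurfaceSet, coarse_n: int = 5,
                 cloud_n: int = 25):
        if not valve.half_patches:
            raise ParameterError("valve has no patches")
        self.valve = valve
        self.coarse_n = coarse_n
        u = np.linspace(0.0, 1.0, coarse_n)
        uu, vv = np.meshgrid(u, u, indexing="ij")
        self._uv = np.stack([uu.ravel(), vv.ravel()], axis=1)
        self._patches: list[tuple[int, CoonsPatch, np.ndarray]] = []
        for i, (top, bottom) in enumerate(valve.half_patches):
            for patch in (top, bottom):
                pts = patch(self._uv[:, 0], self._uv[:, 1])
                self._patches.append((i, patch, pts))
        # coarse-grid resolution bound per patch: max adjacent-sample spacing
        self._coarse_bound = []
        for _, patch, pts in self._patches:
            g = pts.reshape(coarse_n, coarse_n, 3)
            du = np.linalg.norm(np.diff(g, axis=0), axis=-1).max()
            dv = np.linalg.norm(np.diff(g, axis=1), axis=-1).max()
            self._coarse_bound.append(float(np.hypot(du, dv)))
        cloud = valve.sample_points(cloud_n, cloud_n)
        self._tree = cKDTree(cloud)
        self._cloud_bound = self._cloud_spacing_bound(cloud_n)

    def _cloud_spacing_bound(self, n: int) -> float:
        """Max distance from any surface point to the sampled cloud (upper bound)."""
        bound = 0.0
        for _, patch, _ in self._patches:
            g = patch.sample_grid(n, n)
            du = np.linalg.norm(np.diff(g, axis=0), axis=-1).max()
            dv = np.linalg.norm(np.diff(g, axis=1), axis=-1).max()
            bound = max(bound, 0.5 * float(np.hypot(du, dv)))
        return bound

    def _local_points(self, point: np.ndarray) -> list[np.ndarray]:
        """The query point in each leaflet's local frame, plus its mirror."""
        out = []
        for p in self.valve.params.leaflets:
            c, s = math.cos(p.theta), math.sin(p.theta)
            rot_t = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
            loc = rot_t @ point
            out.append((loc, loc * np.array([1.0, -1.0, 1.0])))
        return out

    def __call__(self, point) -> float:
        """Minimum distance (mm) from ``point`` to the valve surface."""
        point = np.asarray(point, dtype=float)
        locals_ = self._local_points(point)
        # coarse pass over every (patch, mirror) combination
        cand = []
        for k, (leaf, patch, pts) in enumerate(self._patches):
            for loc in locals_[leaf]:
                d = np.linalg.norm(pts - loc, axis=1)
                j = int(np.argmin(d))
                cand.append((float(d[j]), k, loc, self._uv[j]))
        best_coarse = min(c[0] for c in cand)
        # refine every candidate whose coarse distance could still win
        best = math.inf
        for d0, k, loc, uv0 in cand:
            if d0 > best_coarse + self._coarse_bound[k]:
                continue
            _, patch, _ = self._patches[k]
            best = min(best, self._refine(patch, loc, uv0, d0))
        return best

    def _refine(self, patch: CoonsPatch, point: np.ndarray,
                uv0: np.ndarray, d0: float) -> float:
        def objective(uv):
            return float(np.linalg.norm(patch(uv[0], uv[1]) - point))

        res = minimize(objective, uv0, method="Powell",
                       bounds=[(0.0, 1.0), (0.0, 1.0)],
                       options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": 200})
        if res.success and np.isfinite(res.fun):
            return min(float(res.fun), d0)
        warnings.warn("Powell distance refinement did not converge; "
                      "falling back to a refined grid search", stacklevel=2)
        u = np.linspace(0.0, 1.0, 64)
        uu, vv = np.meshgrid(u, u, indexing="ij")
        pts = patch(uu.ravel(), vv.ravel())
        return min(float(np.linalg.norm(pts - point, axis=1).min()), d0)

    def approximate(self, points: np.ndarray) -> tuple[np.ndarray, float]:
        """Cloud-based upper bound of the distances plus its slack.

        Returns (d_approx, delta) with d_true <= d_approx <= d_true + delta.
        """
        d, _ = self._tree.query(np.asarray(points, dtype=float), workers=-1)
        return d, self._cloud_bound


def min_distance_to_valve(point, valve: ValveSurfaceSet, coarse_n: int = 5) -> float:
    """Minimum distance (mm) from one point to the valve surface set."""
    return ValveDistance(valve, coarse_n=coarse_n)(point)


# ---------------------------------------------------------------------------
# gamma field
# ---------------------------------------------------------------------------

def build_gamma(mesh, valve: ValveSurfaceSet, config: ResistiveConfig | None = None,
                distance: ValveDistance | None = None,
                max_components: int = 9) -> GammaField:
    """Threshold the nodal valve distance into the two-valued gamma field.

    gamma(N) = C if d(N) <= epsilon (inclusive) else 0.  A surface point
    cloud prefilter classifies nodes that are certainly inside or certainly
    outside the threshold without changing any value; only nodes in the
    uncertainty band get the full Powell distance refinement.
    """
    config = config or ResistiveConfig()
    eps = compute_epsilon(mesh.h_max, config.h_phys, config.epsilon_override)
    dist = distance or ValveDistance(valve)
    nodes = np.asarray(mesh.nodes, dtype=float)
    d_approx, delta = dist.approximate(nodes)
    values = np.zeros(len(nodes))
    inside = d_approx <= eps                   # upper bound below eps -> certainly in
    band = (~inside) & (d_approx - delta <= eps)
    for i in np.flatnonzero(band):
        if dist(nodes[i]) <= eps:
            inside[i] = True
    values[inside] = config.C
    field = GammaField(values=values, epsilon_used=eps, C=config.C)
    if field.support_count == 0:
        warnings.warn("gamma field has empty support: the valve does not "
                      "intersect the mesh", stacklevel=2)
    else:
        n_comp = _support_components(mesh, inside)
        if n_comp > max_components:
            warnings.warn(f"gamma support splits into {n_comp} connected "
                          f"components; the leaflets may have holes", stacklevel=2)
    return field


def _support_components(mesh, inside: np.ndarray) -> int:
    """Connected components of the support in the mesh edge graph."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    idx = np.flatnonzero(inside)
    if idx.size == 0:
        return 0
    remap = -np.ones(len(inside), dtype=np.int64)
    remap[idx] = np.arange(idx.size)
    cells = np.asarray(mesh.cells)
    pairs = []
    for a in range(4):
        for b in range(a + 1, 4):
            i, j = remap[cells[:, a]], remap[cells[:, b]]
            ok = (i >= 0) & (j >= 0)
            pairs.append(np.stack([i[ok], j[ok]], axis=1))
    pairs = np.concatenate(pairs, axis=0)
    adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                     shape=(idx.size, idx.size))
    n, _ = connected_components(adj, directed=False)
    return int(n)


def export_gamma(field: GammaField, mesh, path) -> None:
    """Write the mesh with nodal gamma as legacy ASCII VTK (bitwise round trip)."""
    from . import io as _io

    if len(field.values) != len(mesh.nodes):
        raise ParameterError("gamma field and mesh sizes are inconsistent")
    _io.write_vtk_unstructured(path, mesh.nodes, mesh.cells,
                               point_data={"gamma": field.values})
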