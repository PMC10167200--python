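"""Coons patches and assembly of the full three-leaflet valve surface.

Each half leaflet is covered by two Coons patches joined smoothly at the
bending curve: a *top* patch between the bending and leaflet (free-edge)
planes and a *bottom* patch between the annulus plane and the bending
plane.  A full leaflet is the half plus its mirror image across the
leaflet's own symmetry plane; three leaflets rotated about the valve axis
make the valve.  Inter-leaflet symmetry is *not* assumed: each leaflet may
carry its own parameters and rotation, which is what lets the model shape
stenotic, asymmetric valves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .params import LeafletParameters, ValveParameters, ParameterError
from .curves import (
    ArcCurve3D,
    BezierCurve3D,
    approximate_edge_as_bezier,
    make_bending_curve,
    make_leaflet_curve,
    make_sinus_curve,
    make_symmetry_curve,
    sinus_split_parameter,
    split_bezier,
)


class CornerMismatchError(ValueError):
    """The four boundary curves of a Coons patch do not meet at its corners."""


@dataclass(frozen=True)
class CoonsPatch:
    """Bilinearly blended Coons patch over (u, v) in [0,1]^2.

    ``bending_edge`` is the v=0 boundary, ``leaflet_edge`` the v=1 boundary
    (the names follow the top patch, where these really are the bending and
    free-edge curves; the bottom patch reuses the same container with the
    annulus boundary and the bending curve in those roles).  The side
    curves ``sym_edge`` (u=0) and ``sinus_edge`` (u=1) are oriented with
    parameter 0 on the v=1 boundary and parameter 1 on the v=0 boundary,
    and enter the blend as sym_edge(1-v) / sinus_edge(1-v):

        h(u,v) = (1-v) bending(u) + v leaflet(u)
               + (1-u) sym(1-v) + u sinus(1-v)
               - [ (1-u)(1-v) Q_b_sym + u v Q_l_sin
                 + u (1-v) Q_b_sin + (1-u) v Q_l_sym ]
    """

    bending_edge: object        # curve of u, v=0 boundary
    leaflet_edge: object        # curve of u, v=1 boundary
    sym_edge: object            # curve of s, u=0 boundary, s=0 at v=1
    sinus_edge: object          # curve of s, u=1 boundary, s=0 at v=1
    corners: dict = field(repr=False)

    def __call__(self, u, v):
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        u, v = np.broadcast_arrays(u, v)
        scalar = u.ndim == 0
        u = np.atleast_1d(u)
        v = np.atleast_1d(v)
        uu = u[..., None]
        vv = v[..., None]
        c = self.corners
        out = ((1.0 - vv) * self.bending_edge(u)
               + vv * self.leaflet_edge(u)
               + (1.0 - uu) * self.sym_edge(1.0 - v)
               + uu * self.sinus_edge(1.0 - v)
               - ((1.0 - uu) * (1.0 - vv) * c["Q_b_sym"]
                  + uu * vv * c["Q_l_sin"]
                  + uu * (1.0 - vv) * c["Q_b_sin"]
                  + (1.0 - uu) * vv * c["Q_l_sym"]))
        return out[0] if scalar else out

    def sample_grid(self, nu: int, nv: int) -> np.ndarray:
        """(nu, nv, 3) array of surface points on a uniform parameter grid."""
        u = np.linspace(0.0, 1.0, nu)
        v = np.linspace(0.0, 1.0, nv)
        uu, vv = np.meshgrid(u, v, indexing="ij")
        return self(uu.ravel(), vv.ravel()).reshape(nu, nv, 3)


def make_coons_patch(bending_edge, leaflet_edge, sym_edge, sinus_edge,
                     corners: dict, tol: float = 1e-8) -> CoonsPatch:
    """Build a Coons patch, asserting the four corner-compatibility identities.

    ``corners`` maps ``Q_b_sym``/``Q_b_sin``/``Q_l_sym``/``Q_l_sin`` to 3D
    points.  Each corner must coincide with both adjacent boundary curves'
    evaluations at the shared parameter end within ``tol`` (mm); a violation
    is reported with the offending corner.
    """
    corners = {k: np.asarray(p, dtype=float) for k, p in corners.items()}
    checks = {
        "Q_b_sym": (bending_edge(0.0), sym_edge(1.0)),
        "Q_b_sin": (bending_edge(1.0), sinus_edge(1.0)),
        "Q_l_sym": (leaflet_edge(0.0), sym_edge(0.0)),
        "Q_l_sin": (leaflet_edge(1.0), sinus_edge(0.0)),
    }
    for name, pts in checks.items():
        for p in pts:
            err = float(np.linalg.norm(np.asarray(p) - corners[name]))
            if err > tol:
                raise CornerMismatchError(
                    f"corner {name} mismatch: boundary curve is {err:.3e} mm "
                    f"away from the stated corner {corners[name]}")
    return CoonsPatch(bending_edge, leaflet_edge, sym_edge, sinus_edge, corners)


def build_half_leaflet(params: LeafletParameters,
                       p0_override: np.ndarray | None = None,
                       annulus_boundary: str = "arc",
                       fd_step: float | None = None) -> tuple[CoonsPatch, CoonsPatch]:
    """Construct the (top, bottom) Coons patches of one half leaflet.

    The sinus and symmetry curves are split at s = b_h/l_h (where they cross
    the bending plane) with De Casteljau's algorithm; the upper sub-curves
    bound the top patch, the lower ones the bottom patch, and the two
    patches share the bending curve pointwise.

    ``annulus_boundary`` selects the bottom patch's fourth boundary: a
    circular ``"arc"`` of radius r_r at z=0 from angle 0 to l_a (default),
    or ``"degenerate"`` to collapse it onto the annulus symmetry point
    (useful when P0 is overridden to coincide with Q0).
    """
    params.validate()
    leaflet_ana = make_leaflet_curve(params)
    bending_ana = make_bending_curve(params)
    leaflet_bez = approximate_edge_as_bezier(leaflet_ana, params.t0, params.t3,
                                             fd_step=fd_step,
                                             reference_length=params.l_ro)
    bending_bez = approximate_edge_as_bezier(bending_ana, params.t0, params.t3,
                                             fd_step=fd_step,
                                             reference_length=params.l_ro)
    sinus = make_sinus_curve(params, p0_override)
    sym = make_symmetry_curve(params)
    s = sinus_split_parameter(params)
    sym_lo, sym_hi = split_bezier(sym, s)
    sin_lo, sin_hi = split_bezier(sinus, s)

    q_b_sym = np.array([params.b_ri, 0.0, params.b_h])
    q_b_sin = np.array([params.b_ro * math.cos(params.b_a),
                        params.b_ro * math.sin(params.b_a), params.b_h])
    q_l_sym = np.array([params.l_ri, 0.0, params.l_h])
    q_l_sin = np.array([params.l_ro * math.cos(params.l_a),
                        params.l_ro * math.sin(params.l_a), params.l_h])
    q_a_sym = np.array([params.r_r, 0.0, 0.0])
    p0 = np.asarray(sinus.control_points[0])

    top = make_coons_patch(
        bending_edge=bending_bez,
        leaflet_edge=leaflet_bez,
        sym_edge=sym_hi.reversed(),    # 0 at the leaflet plane, 1 at the bending plane
        sinus_edge=sin_hi.reversed(),
        corners={"Q_b_sym": q_b_sym, "Q_b_sin": q_b_sin,
                 "Q_l_sym": q_l_sym, "Q_l_sin": q_l_sin},
    )

    if annulus_boundary == "arc":
        annulus_edge = ArcCurve3D(params.r_r, 0.0, params.l_a, 0.0)
        q_a_sin = annulus_edge(1.0)
        if np.linalg.norm(q_a_sin - p0) > 1e-8:
            # a P0 override moves the sinus attachment off the arc end
            annulus_edge = _BlendedEndCurve(annulus_edge, q_a_sym, q_a_sin_target=p0)
            q_a_sin = p0
    elif annulus_boundary == "degenerate":
        annulus_edge = _PointCurve(q_a_sym)
        q_a_sin = q_a_sym
    else:
        raise ParameterError(f"unknown annulus_boundary mode {annulus_boundary!r}")

    bottom = make_coons_patch(
        bending_edge=annulus_edge,     # v=0 boundary: annulus-plane attachment
        leaflet_edge=bending_bez,      # v=1 boundary: shared bending curve
        sym_edge=sym_lo.reversed(),    # 0 at the bending plane, 1 at the annulus
        sinus_edge=sin_lo.reversed(),
        corners={"Q_b_sym": q_a_sym, "Q_b_sin": q_a_sin,
                 "Q_l_sym": q_b_sym, "Q_l_sin": q_b_sin},
    )
    return top, bottom


@dataclass(frozen=True)
class _PointCurve:
    point: np.ndarray

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return np.broadcast_to(self.point, t.shape + (3,)).copy()


@dataclass(frozen=True)
class _BlendedEndCurve:
    """Arc linearly blended so its t=1 end lands on an overridden P0."""

    base: ArcCurve3D
    start: np.ndarray
    q_a_sin_target: np.ndarray

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        base = self.base(t)
        shift = self.q_a_sin_target - self.base(1.0)
        return base + t[..., None] * shift


# ---------------------------------------------------------------------------
# valve assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatchInstance:
    """One concrete surface piece: a half-leaflet patch with its placement."""

    patch: CoonsPatch
    leaflet_index: int
    mirrored: bool     # reflected across the leaflet's local y=0 plane
    theta: float       # rotation about the valve (z) axis
    part: str          # "top" | "bottom"

    def __call__(self, u, v):
        pts = np.atleast_2d(self.patch(u, v))
        if self.mirrored:
            pts = pts * np.array([1.0, -1.0, 1.0])
        c, s = math.cos(self.theta), math.sin(self.theta)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        out = pts @ rot.T
        return out[0] if np.asarray(u).ndim == 0 and np.asarray(v).ndim == 0 else out


@dataclass
class ValveSurfaceSet:
    """The complete valve surface: per-leaflet patch pairs plus placements.

    Each leaflet contributes two Coons patches (top/bottom of the half
    leaflet); the mirrored half is realized by reflecting across the
    leaflet's local symmetry plane, so the valve is covered by the six patch
    functions with the mirror folded into evaluation (12 concrete patch
    instances).
    """

    params: ValveParameters
    half_patches: list[tuple[CoonsPatch, CoonsPatch]]  # (top, bottom) per leaflet

    @property
    def patch_instances(self) -> list[PatchInstance]:
        out = []
        for i, (top, bottom) in enumerate(self.half_patches):
            theta = self.params.leaflets[i].theta
            for mirrored in (False, True):
                out.append(PatchInstance(top, i, mirrored, theta, "top"))
                out.append(PatchInstance(bottom, i, mirrored, theta, "bottom"))
        return out

    @property
    def max_l_ro(self) -> float:
        return self.params.max_l_ro

    @property
    def max_l_h(self) -> float:
        return self.params.max_l_h

    def sample_points(self, nu: int = 17, nv: int = 17) -> np.ndarray:
        """Surface point cloud over all patch instances, (n, 3), mm."""
        u = np.linspace(0.0, 1.0, nu)
        v = np.linspace(0.0, 1.0, nv)
        uu, vv = np.meshgrid(u, v, indexing="ij")
        pts = [inst(uu.ravel(), vv.ravel()) for inst in self.patch_instances]
        return np.concatenate(pts, axis=0)

    def commissure_points(self) -> np.ndarray:
        """Global commissure points (one per leaflet half edge), (6, 3)."""
        pts = []
        for i, p in enumerate(self.params.leaflets):
            local = np.array([p.l_ro * math.cos(p.l_a), p.l_ro * math.sin(p.l_a), p.l_h])
            for sign in (+1.0, -1.0):
                q = local * np.array([1.0, sign, 1.0])
                c, s = math.cos(p.theta), math.sin(p.theta)
                rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
                pts.append(rot @ q)
        return np.array(pts)


def assemble_valve(leaflets, thetas=None,
                   angle_sum_tol: float | None = None,
                   commissure_gap_tol: float | None = None,
                   **half_leaflet_kwargs) -> ValveSurfaceSet:
    """Assemble the full valve from three leaflet parameter sets.

    ``leaflets`` is a ``ValveParameters`` or a sequence of three
    ``LeafletParameters``; ``thetas`` optionally overrides each leaflet's
    rotation about the valve axis.  Emits validation *warnings* (never
    errors) if the leaflet half-angles do not tile the circle
    (sum 2*l_a != 2*pi) or adjacent commissures are farther apart than the
    gap tolerance — deliberately gapped pathological fits are allowed.
    """
    if isinstance(leaflets, ValveParameters):
        vp = leaflets
    else:
        leaflets = tuple(leaflets)
        if len(leaflets) != 3:
            raise ParameterError("assemble_valve needs exactly three leaflets")
        vp = ValveParameters(leaflets=leaflets)
    if thetas is not None:
        vp = ValveParameters(
            leaflets=tuple(p.rotated(th) for p, th in zip(vp.leaflets, thetas)),
            angle_sum_tol=vp.angle_sum_tol,
            commissure_gap_tol=vp.commissure_gap_tol)
    if angle_sum_tol is not None:
        vp.angle_sum_tol = angle_sum_tol
    if commissure_gap_tol is not None:
        vp.commissure_gap_tol = commissure_gap_tol

    half_patches = [build_half_leaflet(p, **half_leaflet_kwargs) for p in vp.leaflets]
    valve = ValveSurfaceSet(params=vp, half_patches=half_patches)

    angle_sum = sum(2.0 * p.l_a for p in vp.leaflets)
    if abs(angle_sum - 2.0 * math.pi) > vp.angle_sum_tol:
        warnings.warn(
            f"leaflet half-angles sum to {math.degrees(angle_sum):.1f} deg of arc "
            f"(expected ~360): the leaflets leave a gap or overlap", stacklevel=2)
    gap = max_commissure_gap(valve)
    if gap > vp.commissure_gap_tol:
        warnings.warn(
            f"adjacent commissures are up to {gap:.2f} mm apart "
            f"(tolerance {vp.commissure_gap_tol} mm)", stacklevel=2)
    return valve


def max_commissure_gap(valve: ValveSurfaceSet) -> float:
    """Largest distance between matching commissures of adjacent leaflets."""
    pts = valve.commissure_points()  # 2 per leaflet
    # for each commissure, distance to nearest commissure of a *different* leaflet
    gaps = []
    for i in range(6):
        dists = [float(np.linalg.norm(pts[i] - pts[j]))
                 for j in range(6) if j // 2 != i // 2]
        gaps.append(min(dists))
    return max(gaps)


# ---------------------------------------------------------------------------
# surface export
# ---------------------------------------------------------------------------

def triangulate_patches(valve: ValveSurfaceSet, nu: int, nv: int,
                        merge_tol: float = 1e-8):
    """Triangulate all patch instances into (vertices, faces).

    Each patch grid yields 2*(nu-1)*(nv-1) triangles; vertices shared along
    patch boundaries (bending curve, symmetry plane, grid seams) are merged
    within ``merge_tol`` mm so every leaflet is watertight along its
    internal seams.
    """
    if nu < 2 or nv < 2:
        raise ParameterError("nu and nv must be >= 2")
    all_pts = []
    all_tris = []
    offset = 0
    for inst in valve.patch_instances:
        u = np.linspace(0.0, 1.0, nu)
        v = np.linspace(0.0, 1.0, nv)
        uu, vv = np.meshgrid(u, v, indexing="ij")
        grid = inst(uu.ravel(), vv.ravel()).reshape(nu, nv, 3)
        idx = np.arange(nu * nv).reshape(nu, nv) + offset
        a = idx[:-1, :-1].ravel()
        b = idx[1:, :-1].ravel()
        c = idx[1:, 1:].ravel()
        d = idx[:-1, 1:].ravel()
        tris = np.concatenate([np.stack([a, b, c], axis=1),
                               np.stack([a, c, d], axis=1)], axis=0)
        all_pts.append(grid.reshape(-1, 3))
        all_tris.append(tris)
        offset += nu * nv
    pts = np.concatenate(all_pts, axis=0)
    tris = np.concatenate(all_tris, axis=0)
    # merge duplicate vertices (shared seams)
    key = np.round(pts / merge_tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    verts = pts[first]
    faces = inverse[tris]
    # drop degenerate triangles (possible along a degenerate annulus boundary)
    ok = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 0] != faces[:, 2])
    return verts, faces[ok]


def sample_and_export(valve: ValveSurfaceSet, nu: int, nv: int, path,
                      file_format: str | None = None):
    """Sample the valve on an (nu x nv) grid per patch and write STL or VTK.

    The format is inferred from the extension unless ``file_format`` is
    given ("stl", "stl_ascii" or "vtk").  Returns (vertices, faces).
    """
    from pathlib import Path
    from . import io as _io

    path = Path(path)
    fmt = file_format or path.suffix.lstrip(".").lower()
    verts, faces = triangulate_patches(valve, nu, nv)
    if fmt in ("stl", "stl_ascii"):
        import trimesh

        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        mesh.export(path, file_type="stl_ascii" if fmt == "stl_ascii" else "stl")
    elif fmt == "vtk":
        _io.write_vtk_polydata(path, verts, faces)
    else:
        raise ValueError(f"unsupported surface format {fmt!r}")
    return verts, faces
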