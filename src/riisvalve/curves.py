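"""Analytic power curves and Bezier curves building up a half leaflet.

A half leaflet (the region between a leaflet's symmetry plane y=0 and its
commissure at half-angle ``l_a``) is bounded by four curves:

* the *leaflet curve* — the free edge at height ``l_h``, a power curve
  x = l_ri + alpha*y**l_p joining the opening circle to the aortic wall;
* the *bending curve* — the analogous power curve at height ``b_h``;
* the *symmetry curve* — a planar (y=0) cubic Bezier from the annulus
  (r_r, 0, 0) to the free edge at (l_ri, 0, l_h), forced through the
  bending point (b_ri, 0, b_h);
* the *sinus curve* — a quadratic Bezier standing in for the sinus and
  interleaflet-triangle anatomy, from the annulus attachment up to the
  commissure, forced through the bending curve's wall point.

Both analytic curves are approximated by cubic Beziers whose inner control
points follow finite-difference end tangents, so that all four boundaries
are polynomial and can be split with De Casteljau's algorithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import LeafletParameters, ParameterError


class DegenerateCurveError(ValueError):
    """A curve construction hit a degenerate configuration (e.g. split at 0/1)."""


# ---------------------------------------------------------------------------
# analytic power curves (leaflet and bending curve)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalyticPowerCurve:
    """Planar curve x = r_inner + coeff * y**power at height ``plane_z``.

    ``y`` runs from 0 (symmetry line) to ``y_max`` (intersection with the
    outer circle).  For ``power > 1`` the derivative at y=0 vanishes, which
    makes the mirrored leaflet C1 across its symmetry plane.
    """

    r_inner: float
    coeff: float
    power: float
    plane_z: float
    y_max: float

    def __call__(self, y):
        y = np.asarray(y, dtype=float)
        return self.r_inner + self.coeff * np.abs(y) ** self.power

    def point(self, y):
        """3D point(s) (f(y), y, plane_z) on the curve."""
        y = np.asarray(y, dtype=float)
        x = self(y)
        z = np.full_like(x, self.plane_z)
        return np.stack([x, y, z], axis=-1)


def make_leaflet_curve(params: LeafletParameters) -> AnalyticPowerCurve:
    """Free-edge power curve at z = l_h.

    alpha = (l_ro*cos(l_a) - l_ri) / (l_ro*sin(l_a))**l_p, so that
    f(0) = l_ri, f'(0) = 0 and f(l_ro*sin(l_a)) = l_ro*cos(l_a).
    """
    params.validate()
    y_max = params.l_ro * math.sin(params.l_a)
    if y_max <= 0.0:
        raise ParameterError("l_ro*sin(l_a) must be positive")
    alpha = (params.l_ro * math.cos(params.l_a) - params.l_ri) / y_max ** params.l_p
    return AnalyticPowerCurve(r_inner=params.l_ri, coeff=alpha, power=params.l_p,
                              plane_z=params.l_h, y_max=y_max)


def make_bending_curve(params: LeafletParameters) -> AnalyticPowerCurve:
    """Bending power curve at z = b_h (same construction with b_* parameters)."""
    params.validate()
    y_max = params.b_ro * math.sin(params.b_a)
    if y_max <= 0.0:
        raise ParameterError("b_ro*sin(b_a) must be positive")
    beta = (params.b_ro * math.cos(params.b_a) - params.b_ri) / y_max ** params.b_p
    return AnalyticPowerCurve(r_inner=params.b_ri, coeff=beta, power=params.b_p,
                              plane_z=params.b_h, y_max=y_max)


# ---------------------------------------------------------------------------
# Bezier curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BezierCurve3D:
    """Polynomial Bezier curve in 3D given by its control points (mm)."""

    control_points: np.ndarray  # (degree+1, 3)

    def __post_init__(self):
        cp = np.asarray(self.control_points, dtype=float)
        if cp.ndim != 2 or cp.shape[1] != 3 or cp.shape[0] < 2:
            raise ValueError("control_points must be an (n>=2, 3) array")
        object.__setattr__(self, "control_points", cp)

    @property
    def degree(self) -> int:
        return self.control_points.shape[0] - 1

    def __call__(self, t):
        """Evaluate at parameter(s) t in [0,1] via De Casteljau recursion."""
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)[:, None]
        pts = np.broadcast_to(self.control_points, (t.shape[0],) + self.control_points.shape).copy()
        while pts.shape[1] > 1:
            pts = (1.0 - t[:, None]) * pts[:, :-1, :] + t[:, None] * pts[:, 1:, :]
        out = pts[:, 0, :]
        return out[0] if scalar else out

    def reversed(self) -> "BezierCurve3D":
        return BezierCurve3D(self.control_points[::-1].copy())


@dataclass(frozen=True)
class ArcCurve3D:
    """Circular arc of given radius in the plane z = const, angles in radians.

    Used for the annulus-plane attachment boundary of the bottom patch; it
    is a sampled (non-Bezier) curve that plugs into the Coons formula like
    any other boundary curve.
    """

    radius: float
    angle0: float
    angle1: float
    plane_z: float

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        ang = self.angle0 + (self.angle1 - self.angle0) * t
        out = np.stack([self.radius * np.cos(ang), self.radius * np.sin(ang),
                        np.broadcast_to(self.plane_z, ang.shape)], axis=-1)
        return out

    def reversed(self) -> "ArcCurve3D":
        return ArcCurve3D(self.radius, self.angle1, self.angle0, self.plane_z)


def split_bezier(curve: BezierCurve3D, t_split: float) -> tuple[BezierCurve3D, BezierCurve3D]:
    """Split a Bezier curve at ``t_split`` with De Casteljau's algorithm.

    Returns (lower, upper) with lower(s) = curve(s*t_split) and
    upper(s) = curve(t_split + s*(1 - t_split)).
    """
    if not 0.0 < t_split < 1.0:
        raise DegenerateCurveError(f"t_split must be in (0,1), got {t_split}")
    pts = [curve.control_points.copy()]
    while pts[-1].shape[0] > 1:
        p = pts[-1]
        pts.append((1.0 - t_split) * p[:-1] + t_split * p[1:])
    lower = np.array([level[0] for level in pts])
    upper = np.array([level[-1] for level in pts])[::-1]
    return BezierCurve3D(lower), BezierCurve3D(upper)


# ---------------------------------------------------------------------------
# sinus and symmetry curves
# ---------------------------------------------------------------------------

def sinus_split_parameter(params: LeafletParameters) -> float:
    """s_sin = b_h / l_h, the parameter where the sinus curve meets the bending plane."""
    s = params.b_h / params.l_h
    if not 0.0 < s < 1.0:
        raise DegenerateCurveError("b_h/l_h must lie strictly in (0,1)")
    return s


def make_sinus_curve(params: LeafletParameters, p0: np.ndarray | None = None) -> BezierCurve3D:
    """Quadratic Bezier replacing the sinus/interleaflet anatomy.

    P0 is the annulus-plane attachment (default (r_r cos l_a, r_r sin l_a, 0),
    the annulus point beneath the commissure; overridable), P2 the commissure
    point (l_ro cos l_a, l_ro sin l_a, l_h).  P1 is solved so that the curve
    passes through the bending curve's outer-circle intersection
    (b_ro cos b_a, b_ro sin b_a, b_h) at t = s_sin = b_h/l_h:

        P1 = (B(s_sin) - (1-s_sin)^2 P0 - s_sin^2 P2) / (2 (1-s_sin) s_sin)

    That target is the corner Q_b_sin shared with the bending curve, which
    is what closes the Coons patch at the wall side.
    """
    s = sinus_split_parameter(params)
    if p0 is None:
        p0 = np.array([params.r_r * math.cos(params.l_a),
                       params.r_r * math.sin(params.l_a), 0.0])
    else:
        p0 = np.asarray(p0, dtype=float)
    p2 = np.array([params.l_ro * math.cos(params.l_a),
                   params.l_ro * math.sin(params.l_a), params.l_h])
    target = np.array([params.b_ro * math.cos(params.b_a),
                       params.b_ro * math.sin(params.b_a), params.b_h])
    p1 = (target - (1.0 - s) ** 2 * p0 - s ** 2 * p2) / (2.0 * (1.0 - s) * s)
    return BezierCurve3D(np.array([p0, p1, p2]))


def make_symmetry_curve(params: LeafletParameters) -> BezierCurve3D:
    """Cubic Bezier along the leaflet's symmetry plane y = 0.

    Q0 = (r_r, 0, 0), Q3 = (l_ri, 0, l_h).  Q1 sets the launch tangent:

        Q1 = ((r_r+b_ri)/2 + xQ1_sym*(r_r-b_ri), 0, b_h/2 + zQ1_sym*b_h)

    and Q2 is solved so the curve passes through (b_ri, 0, b_h) at
    t = s_sym = b_h/l_h.
    """
    s = sinus_split_parameter(params)
    q0 = np.array([params.r_r, 0.0, 0.0])
    q3 = np.array([params.l_ri, 0.0, params.l_h])
    q1 = np.array([(params.r_r + params.b_ri) / 2.0
                   + params.xQ1_sym * (params.r_r - params.b_ri),
                   0.0,
                   params.b_h / 2.0 + params.zQ1_sym * params.b_h])
    target = np.array([params.b_ri, 0.0, params.b_h])
    q2 = (target - (1.0 - s) ** 3 * q0 - 3.0 * s * (1.0 - s) ** 2 * q1
          - s ** 3 * q3) / (3.0 * s ** 2 * (1.0 - s))
    return BezierCurve3D(np.array([q0, q1, q2, q3]))


# ---------------------------------------------------------------------------
# Bezier approximation of the analytic curves
# ---------------------------------------------------------------------------

def approximate_edge_as_bezier(curve: AnalyticPowerCurve,
                               t0: float, t3: float,
                               fd_step: float | None = None,
                               reference_length: float | None = None) -> BezierCurve3D:
    """Cubic Bezier approximation of an analytic power curve.

    L0 and L3 are the endpoints at y=0 and y=y_max.  L1 and L2 are placed a
    parameter-weighted step along the finite-difference end tangents:

        L1 = (L0x + t0*(f(L0y + eps) - L0x)/eps,  L0y + t0)
        L2 = (L3x + t3*(f(L3y - eps) - L3x)/eps,  L3y - t3)

    with eps = ``fd_step`` (default 1e-6 of the reference length, itself
    defaulting to y_max so the step is scale-invariant).  All points carry
    z = curve.plane_z.
    """
    if not (0.0 < t0 < 1.0 and 0.0 < t3 < 1.0):
        raise ParameterError("tangent weights t0, t3 must lie in (0,1)")
    ref = reference_length if reference_length is not None else curve.y_max
    eps = fd_step if fd_step is not None else 1e-6 * ref
    if eps <= 0.0:
        raise ParameterError("fd_step must be positive")
    if curve.y_max - eps < 0.0:
        raise ParameterError("fd_step exceeds the curve's parameter range")
    z = curve.plane_z
    l0 = np.array([float(curve(0.0)), 0.0, z])
    l3 = np.array([float(curve(curve.y_max)), curve.y_max, z])
    l1 = np.array([l0[0] + t0 * (float(curve(eps)) - l0[0]) / eps, 0.0 + t0, z])
    l2 = np.array([l3[0] + t3 * (float(curve(curve.y_max - eps)) - l3[0]) / eps,
                   curve.y_max - t3, z])
    return BezierCurve3D(np.array([l0, l1, l2, l3]))


def edge_approximation_error(curve: AnalyticPowerCurve, t0: float, t3: float,
                             n_bezier: int = 101, n_dense: int = 2001) -> float:
    """Max distance (mm) from the cubic edge approximation to the analytic curve.

    Dense-sampling comparison: ``n_bezier`` points on the Bezier against
    ``n_dense`` points on the analytic curve.
    """
    from scipy.spatial import cKDTree

    bez = approximate_edge_as_bezier(curve, t0, t3)
    bp = bez(np.linspace(0.0, 1.0, n_bezier))
    ana = curve.point(np.linspace(0.0, curve.y_max, n_dense))
    d, _ = cKDTree(ana).query(bp)
    return float(d.max())


def calibrate_tangent_weights(curves, grid: int = 10) -> tuple[float, float]:
    """Grid-search the tangent weights minimizing the edge-approximation error.

    The weights are mostly governed by the curve power: low-power (gently
    curved) edges tolerate small weights, high-power stenotic edges need the
    inner control points pushed as far as the parametrization allows.  The
    search is over a fixed deterministic grid in (0,1)^2, jointly over the
    given curves (typically the leaflet and bending curve of one leaflet,
    which share their weights).
    """
    if isinstance(curves, AnalyticPowerCurve):
        curves = [curves]
    ts = (np.arange(grid, dtype=float) + 0.5) / grid
    best = (math.inf, 0.3, 0.3)
    for t0 in ts:
        for t3 in ts:
            e = max(edge_approximation_error(c, t0, t3, n_bezier=51, n_dense=801)
                    for c in curves)
            if e < best[0]:
                best = (e, float(t0), float(t3))
    return best[1], best[2]
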