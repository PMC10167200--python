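"""Synthetic valve-parameter fixtures spanning healthy to severely stenotic.

No measured parameter tables ship with the package, so these cohorts stand
in for imaging-derived values.  The ranges are grounded in normal adult
aortic root dimensions (aortic radius 12-16 mm, annulus 10-14 mm, leaflet
height 8-12 mm) with the valve opening shrinking from ~55% of the aortic
radius (healthy) to ~15% (severe stenosis); they are package choices, not
published measurements.  Generation is deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .params import LeafletParameters, ValveParameters

FIXTURE_NAMES = ("healthy", "mild", "moderate", "severe")

_SEVERITY = {"healthy": 0.0, "mild": 1.0 / 3.0, "moderate": 2.0 / 3.0, "severe": 1.0}


def _leaflet_for(severity: float, l_a: float, theta: float,
                 rng: np.random.Generator, jitter: float) -> LeafletParameters:
    def j(scale=1.0):
        return 1.0 + jitter * scale * rng.normal() if jitter > 0.0 else 1.0

    l_ro = 13.0 * j(0.04)
    r_r = 11.0 * j(0.04)
    l_h = 10.0 * j(0.05)
    b_h = 0.5 * l_h
    ri_ratio = (0.55 - 0.40 * severity) * j(0.08)
    ri_ratio = float(np.clip(ri_ratio, 0.10, 0.60))
    l_ri = ri_ratio * l_ro
    b_ro = 0.92 * l_ro
    b_ri = float(np.clip(0.85 * l_ri * j(0.05), 0.5, b_ro))
    power = float(np.clip((2.0 + 2.5 * severity) * j(0.10), 1.5, 6.0))
    p = LeafletParameters(
        l_ro=l_ro, l_ri=l_ri, l_a=l_a, l_p=power, l_h=l_h, r_r=r_r,
        b_ro=b_ro, b_ri=b_ri, b_a=l_a, b_p=power, b_h=b_h, theta=theta)
    # tangent weights of the cubic edge approximations are power-dependent
    # and calibrated per leaflet against the analytic curves
    from .curves import calibrate_tangent_weights, make_bending_curve, make_leaflet_curve

    t0, t3 = calibrate_tangent_weights([make_leaflet_curve(p), make_bending_curve(p)])
    return replace(p, t0=t0, t3=t3)


def generate_fixture(name: str | None = None, seed: int | None = None,
                     jitter: float = 0.0, severity: float | None = None) -> ValveParameters:
    """Deterministic three-leaflet parameter set for a named severity.

    ``name`` is one of healthy/mild/moderate/severe; alternatively pass
    ``severity`` in [0, 1] directly, or only a ``seed`` to draw a random
    stenotic severity.  ``jitter`` > 0 adds seeded per-leaflet asymmetry
    (relative scale); with jitter 0 the three leaflets are identical and the
    valve reduces to the 3-fold symmetric reference configuration.
    """
    rng = np.random.default_rng(0 if seed is None else seed)
    if severity is None:
        if name is not None:
            if name not in _SEVERITY:
                raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
            severity = _SEVERITY[name]
        elif seed is not None:
            severity = float(rng.uniform(0.3, 1.0))
            if jitter == 0.0:
                jitter = 0.05
        else:
            raise KeyError("provide a fixture name, a severity, or a seed")

    # half-angles tile the circle: sum of 2*l_a == 2*pi (up to jitter)
    base = math.pi / 3.0
    if jitter > 0.0:
        d = rng.normal(scale=jitter * base / 2.0, size=2)
        deltas = np.array([d[0], d[1], -d[0] - d[1]])
    else:
        deltas = np.zeros(3)
    half_angles = np.clip(base + deltas, math.radians(45.0), math.radians(75.0))

    thetas = [0.0,
              half_angles[0] + half_angles[1],
              half_angles[0] + 2.0 * half_angles[1] + half_angles[2]]
    leaflets = tuple(_leaflet_for(severity, float(a), float(t), rng, jitter)
                     for a, t in zip(half_angles, thetas))
    return ValveParameters(leaflets=leaflets)


def stenotic_cohort(n: int = 4, seed: int = 0, jitter: float = 0.05):
    """A cohort of ``n`` stenotic valves emulating a pre-TAVI population.

    Severities span [0.7, 1.0] (transcatheter-intervention candidates are
    severe by definition) with seeded per-leaflet asymmetry jitter, giving
    per-patient variability around the severe end of the spectrum.
    """
    severities = np.linspace(0.7, 1.0, n)
    return [generate_fixture(severity=float(s), seed=seed + i, jitter=jitter)
            for i, s in enumerate(severities)]


def orifice_area(valve_params: ValveParameters, n: int = 200) -> float:
    """Anatomic orifice area (mm^2): the polygon enclosed by the three free
    edges at their leaflet planes, evaluated from the analytic leaflet curves."""
    from shapely.geometry import Polygon

    from .curves import make_leaflet_curve

    pts = []
    for p in valve_params.leaflets:
        curve = make_leaflet_curve(p)
        y = np.linspace(0.0, curve.y_max, n)
        x = curve(y)
        half = np.stack([x, y], axis=1)
        mirrored = half[::-1] * np.array([1.0, -1.0])
        edge = np.concatenate([mirrored, half[1:]], axis=0)
        c, s = math.cos(p.theta), math.sin(p.theta)
        rot = np.array([[c, -s], [s, c]])
        pts.append(edge @ rot.T)
    ring = np.concatenate(pts, axis=0)
    return float(Polygon(ring).buffer(0).area)
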