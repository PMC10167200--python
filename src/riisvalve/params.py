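"""Leaflet and valve parameter containers with validation and file I/O.

All lengths are millimetres and all angles are stored in radians.  Parameter
files (YAML or JSON) accept angles in degrees, which is how they are usually
reported from imaging; they are converted on load and written back in
degrees on save.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml


class ParameterError(ValueError):
    """A leaflet/valve parameter violates its admissibility constraints."""


_ANGLE_FIELDS = ("l_a", "b_a", "theta")


@dataclass(frozen=True)
class LeafletParameters:
    """Scalar parameters of one valve leaflet.

    The free edge of the leaflet at height ``l_h`` is a power curve with
    exponent ``l_p`` joining the inner opening circle (radius ``l_ri``) to
    the aortic wall (radius ``l_ro``) at half-angle ``l_a``.  An analogous
    curve with parameters ``b_*`` at height ``b_h`` describes how the
    leaflet bends between the annulus (radius ``r_r``, plane z=0) and the
    free edge.  ``theta`` places the leaflet around the valve axis; ``t0``
    and ``t3`` weight the end tangents of the cubic Bezier approximations of
    the analytic curves; ``xQ1_sym``/``zQ1_sym`` weight the tangent control
    point of the symmetry curve.
    """

    l_ro: float = 13.0     # outer (aortic) radius at the leaflet plane [mm]
    l_ri: float = 6.0      # inner opening radius at the leaflet plane [mm]
    l_a: float = math.pi / 3.0   # leaflet half-angle [rad]
    l_p: float = 3.0       # leaflet-curve power [-]
    l_h: float = 10.0      # leaflet height [mm]
    r_r: float = 11.0      # annulus radius [mm]
    b_ro: float = 12.0     # outer radius at the bending plane [mm]
    b_ri: float = 5.0      # inner radius at the bending plane [mm]
    b_a: float = math.pi / 3.0   # bending half-angle [rad]
    b_p: float = 3.0       # bending-curve power [-]
    b_h: float = 5.0       # bending height [mm]
    theta: float = 0.0     # rotation about the valve axis [rad]
    t0: float = 0.3        # edge-Bezier tangent weight at the symmetry side
    t3: float = 0.3        # edge-Bezier tangent weight at the commissure side
    xQ1_sym: float = -0.2  # symmetry-curve tangent weight (x)
    zQ1_sym: float = -0.2  # symmetry-curve tangent weight (z)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        p = self
        checks = [
            (0.0 < p.l_ri < p.l_ro, "0 < l_ri < l_ro"),
            (0.0 < p.b_ri <= p.b_ro, "0 < b_ri <= b_ro"),
            (0.0 < p.b_h < p.l_h, "0 < b_h < l_h"),
            (0.0 < p.l_a < math.pi / 2.0, "0 < l_a < pi/2"),
            (0.0 < p.b_a < math.pi / 2.0, "0 < b_a < pi/2"),
            (p.l_p > 1.0, "l_p > 1"),
            (p.b_p > 1.0, "b_p > 1"),
            (p.r_r > 0.0, "r_r > 0"),
            (0.0 < p.t0 < 1.0, "t0 in (0,1)"),
            (0.0 < p.t3 < 1.0, "t3 in (0,1)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ParameterError(f"leaflet parameter constraint violated: {msg} "
                                     f"(got {self})")

    def rotated(self, theta: float) -> "LeafletParameters":
        return replace(self, theta=theta)


@dataclass
class ValveParameters:
    """Three leaflets plus the global geometry settings of one valve."""

    leaflets: tuple[LeafletParameters, LeafletParameters, LeafletParameters]
    angle_sum_tol: float = 0.15      # warn if sum(2*l_a) deviates from 2*pi by more [rad]
    commissure_gap_tol: float = 1.5  # warn if adjacent commissures are farther apart [mm]

    def __post_init__(self) -> None:
        if len(self.leaflets) != 3:
            raise ParameterError("a valve needs exactly three leaflets")
        self.leaflets = tuple(self.leaflets)

    @property
    def max_l_ro(self) -> float:
        return max(p.l_ro for p in self.leaflets)

    @property
    def max_l_h(self) -> float:
        return max(p.l_h for p in self.leaflets)


def _leaflet_to_file_dict(p: LeafletParameters) -> dict:
    d = asdict(p)
    for k in _ANGLE_FIELDS:
        d[k] = math.degrees(d[k])
    return d


def _leaflet_from_file_dict(d: dict) -> LeafletParameters:
    d = dict(d)
    for k in _ANGLE_FIELDS:
        if k in d:
            d[k] = math.radians(float(d[k]))
    return LeafletParameters(**d)


def save_valve_parameters(valve: ValveParameters, path: str | Path) -> None:
    """Write a valve-parameter file (YAML or JSON by extension, angles in degrees)."""
    path = Path(path)
    doc = {
        "leaflets": [_leaflet_to_file_dict(p) for p in valve.leaflets],
        "settings": {
            "angle_sum_tol": valve.angle_sum_tol,
            "commissure_gap_tol": valve.commissure_gap_tol,
        },
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=True))


def load_valve_parameters(path: str | Path) -> ValveParameters:
    """Read a valve-parameter file written by :func:`save_valve_parameters`."""
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    leaflets = tuple(_leaflet_from_file_dict(d) for d in doc["leaflets"])
    settings = doc.get("settings", {})
    return ValveParameters(leaflets=leaflets, **settings)
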