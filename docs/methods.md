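# Methods

This note documents the model implemented by `riisvalve`, its parameter
defaults, the numerical choices, what the synthetic fixtures emulate, and
the limitations a user should know before trusting a number.

## Geometry model

A valve is three leaflets, each intra-symmetric (built as one half plus its
mirror) but mutually independent (no inter-leaflet symmetry), described by
the scalar set `LeafletParameters` (lengths mm, angles rad):

| parameter | meaning | typical |
|---|---|---|
| `l_ro`, `l_ri` | aortic radius / opening radius at the free-edge plane | 12–16 / 2–9 |
| `l_a`, `l_p`, `l_h` | leaflet half-angle, power, height | 45–75°, 2–6, 8–12 |
| `r_r` | annulus radius (plane z = 0) | 10–14 |
| `b_ro`, `b_ri`, `b_a`, `b_p`, `b_h` | the same quantities at the bending plane | — |
| `theta` | rotation about the valve axis | — |
| `t0`, `t3` | edge-Bézier tangent weights ∈ (0,1) | calibrated |
| `xQ1_sym`, `zQ1_sym` | symmetry-curve tangent weights | −0.2 |

The free edge is `f(y) = l_ri + α y^{l_p}` with α fixed by `f(0) = l_ri`,
`f'(0) = 0` (C¹ mirror) and the outer-circle intersection
`f(l_ro sin l_a) = l_ro cos l_a`; the bending curve is analogous. The
quadratic sinus Bézier runs from the annulus attachment
`P0 = (r_r cos l_a, r_r sin l_a, 0)` to the commissure, its middle control
point solved so the curve crosses the bending curve's outer-circle point at
`t = b_h/l_h`; the cubic symmetry Bézier (plane y = 0) runs annulus → free
edge through `(b_ri, 0, b_h)`, with its first inner control point set by
the −0.2 tangent weights. Note the interpolation target of the sinus curve
must be the bending curve's *outer* end `(b_ro cos b_a, b_ro sin b_a, b_h)`
— the shared corner with the bending curve — otherwise the Coons corners
cannot close; the implementation enforces corner compatibility to 1e-8 mm
at construction and the test suite checks boundary reproduction to 1e-9 mm.

Design choices where the construction was open:

* **Edge orientation in the Coons blend.** Side curves are oriented with
  parameter 0 on the free-edge (top) boundary and enter as `sym(1−v)` /
  `sinus(1−v)`; with that orientation all four corner identities hold
  exactly.
* **P0 and the bottom boundary.** `P0` defaults to the annulus point under
  the commissure (override available). The bottom patch's fourth boundary
  is the annulus arc of radius `r_r` from angle 0 to `l_a`; a degenerate
  (single-point) alternative exists for `P0 = Q0` configurations.
* **Tangent weights.** `t0`, `t3` default to 0.3 but are mostly governed by
  the curve power; `calibrate_tangent_weights` grid-searches (0,1)² against
  a dense-sampling error metric and the fixture generator calibrates per
  leaflet. **Limitation:** the scheme anchors the inner control points
  within ~1 mm of the endpoints, so strongly concave severe-stenosis free
  edges (small `l_ri`, high power) retain an irreducible deviation of up to
  ~0.12 `l_ro` from the analytic curve; gently curved healthy/mild edges
  stay within 0.009–0.03 `l_ro`.
* **Patch bookkeeping.** Two Coons patches cover each *half* leaflet; the
  mirror is folded into evaluation (reflect the query point), so the valve
  is the same surface as six whole-leaflet patch functions.
* **Angle sum.** `Σ 2 l_a,i = 2π` and commissure coincidence are validated
  as warnings, not errors, so deliberately gapped pathological fits remain
  representable.
* Coordinates: valve axis +z = flow direction, annulus plane z = 0, lengths
  mm.

## Resistive field

Nodewise distance to the 12 patch instances (3 leaflets × 2 halves × 2
patches) is minimized with Powell's method over the *closed* box [0,1]²
(nearest points frequently sit on patch boundaries), started from the best
of a 5×5 coarse grid per candidate patch; mirrored halves are queried by
reflecting the point into the leaflet frame. Bulk queries are prefiltered
with a sampled surface point cloud (KD-tree): nodes whose cloud distance is
below ε are certainly inside, nodes farther than ε plus the cloud's spacing
bound are certainly outside, and only the uncertainty shell gets the full
Powell refinement — the prefilter never changes a value. Failures of the
local optimizer fall back to a refined grid search with a warning.

`ε = max(h_phys/2, 0.75 h_max)` with `h_max` the nominal coarse mesh size;
the 75% rule keeps the thresholded leaflet hole-free, the `h_phys/2` floor
keeps it physiological under refinement. The field is exactly two-valued
(`0` or `C = 10⁸`), with the threshold inclusive at `d = ε`.

**Penalization constant and units.** The solver assembles in SI (geometry
converted mm → m) and treats `C = 10⁸` as a raw coefficient (kg m⁻³ s⁻¹).
At stenotic loads (∇p ~ 10⁶ Pa/m across the layer) this admits a Darcy-like
leak `u ≈ ∇p / C ≈ 0.02–0.06 m/s` through the leaflet. Penalization
effectiveness is therefore verified in the unloaded regime (a cross-section
slab with zero inflow suppressing an initial parabolic flow below
10⁻³ U_peak in two steps); in loaded valve runs the support velocity is
leak-dominated and scales with the transvalvular gradient. Raising `C`
tightens the seal proportionally.

## Flow solver

Incompressible Navier–Stokes plus `γ u` in momentum; MINI (P1-bubble / P1)
mixed elements on tetrahedra; backward Euler; convection linearized with
the previous-step velocity (optionally a few Picard passes) together with
the Temam term `(ρ/2)(∇·u) u·v`; strong parabolic inflow; no-slip walls;
natural (do-nothing) outlet with backflow stabilization
`ρ c_bf (u·n)_− u·v` (c_bf = 0.5) — the printed-form outlet condition
`∂u/∂t = 0` does not close a weak form, and the stabilized do-nothing
outlet is the condition consistent with the rest of the formulation. All
element integrals of barycentric monomials are closed-form; the bubble
enters the mass, viscous, penalization and pressure/divergence terms and is
statically condensed per element (yielding the familiar pressure-Laplacian
stabilization of the P1/P1 pair); it is omitted from the convective and
Temam trilinear forms, the standard simplified-MINI treatment.

Linear algebra: the momentum block is identical for the three velocity
components, so each step factorizes one N×N momentum matrix (SuperLU) and
solves the pressure Schur complement with GMRES, preconditioned by the
sparse Schur complement built from diag(A) (a γ- and dt-weighted pressure
Laplacian). GMRES tolerance 1e-8 relative; discrete mass balance in the
verification runs is at solver precision (≤ 1e-9 relative).

Defaults (all configurable): ρ = 1060 kg/m³, μ = 3.5 mPa·s (standard blood
values); envelope `sin(π t / T)` over the systolic interval T = 0.4 s,
integrated to peak systole T_end = 0.2 s; inlet Reynolds number
`Re = ρ U_peak (2R)/μ = 1200` defines the peak centreline velocity; dt
2.5 ms (fine preset) or 10 ms (desk preset); pressure planes
`z_up = −l_h`, `z_down = +3 l_h` (snapped to mesh layers, clamped into the
domain), reported in mmHg (133.322 Pa); `v_max` is the max nodal speed, the
CW-Doppler-style peak.

## Domain mesh

The cylinder (radius `max l_ro`; length −2…+6 leaflet heights by default,
−1.5…+4 in the desk preset to fit single-CPU budgets) is meshed by
extruding a ring-structured Delaunay disk triangulation through graded
z-layers — h_fine (default 0.5 mm) inside the refinement band around the
valve (valve extent ± 2 h_coarse), h_coarse (default 0.75 mm) elsewhere —
and cutting each prism into three tetrahedra with a vertex-index rule that
keeps faces conforming. Boundary facets are tagged inlet/outlet/wall; tag
areas match the analytic cylinder to <1%.

## Synthetic fixtures

No measured per-leaflet parameter tables are available, so the cohort
generator emulates them: aortic radius 13 mm, annulus 11 mm, leaflet height
10 mm, bending at half height, opening ratio `l_ri/l_ro` from 0.55
(healthy) to 0.15 (severe), powers rising 2 → 4.5 with severity, half-angles
tiling 360°, optional seeded per-leaflet jitter (the zero-jitter valve
reduces to the 3-fold-symmetric reference configuration). The stenotic
cohort helper draws ≥4 valves with severity in [0.7, 1] plus jitter,
emulating a pre-intervention (severe AS) population. These fixtures carry
realistic adult dimensions and orifice areas (≈ 250 → 50 mm²) but are *not*
patient measurements; passing tests demonstrate the pipeline's mechanics
and qualitative physics, not agreement with any imaging dataset.

## Scaled-down regime and known limitations

The desk preset (mesh 1.5/2.25 mm, dt 10 ms, 20 steps) triples every length
scale of the fine preset, with one important physical consequence:
ε = 0.75 · 2.25 ≈ 1.7 mm, comparable to the severe orifice radius
(~2 mm). The resistive layer plus ~h/2 of P1 smearing then seals the
moderate/severe orifices: flow crosses the valve as a pressure-driven leak
instead of a resolved jet. The transvalvular pressure drop remains strictly
monotone with severity, but the peak velocity is not — it rises while the
jet is resolvable (healthy → mild) and collapses once the orifice seals, so
`ΔP/v_max²` jumps from ≈2 (open, pressure recovery dominating) to O(10²–10³)
(leak-dominated). At fine resolution (ε ≈ 0.56 mm, h ≈ 0.5 mm) the same
geometries resolve severe jets. The acceptance suite asserts the full
monotone-trend expectation and the velocity half fails at desk scale by
construction; the corresponding test failure message states the mechanism.

Other limitations: fixed open configuration (no opening/closing dynamics,
no FSI); no sinuses of Valsalva or interleaflet triangles (replaced by the
sinus curve) and a straight-cylinder aorta; homogeneous leaflet thickness
2ε; no turbulence model — at systolic Reynolds numbers the Galerkin
convection relies on backward-Euler damping and the short simulated
interval; Doppler-style `v_max` is mesh-limited in narrow jets.
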