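"""Penalized incompressible Navier-Stokes solver on tetrahedral meshes.

Discretization: monolithic mixed finite elements with the MINI pair
(P1 + cubic bubble enrichment for velocity, P1 for pressure), backward
Euler in time, semi-implicit (lagged-advection) convection with the Temam
term (rho/2)(div u) u . v restoring skew-symmetry, a directional backflow
stabilization on the outlet, strong Dirichlet inflow and no-slip walls, a
natural (do-nothing) outlet, and the resistive term  int gamma u . v  that
drives the velocity to zero across the immersed valve.

The bubble degrees of freedom enter the time-derivative, viscous,
penalization and pressure/divergence terms and are statically condensed
element by element, which turns the pair into a stabilized P1/P1 system of
4 unknowns per node.  All element integrals of barycentric monomials are
evaluated in closed form.

Geometry comes in millimetres and is converted to metres internally;
velocities are m/s, pressures Pa (reported drops in mmHg).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .params import ParameterError
from .meshing import VolumeMesh, facet_areas

MMHG = 133.322  # Pa per mmHg

# closed-form integrals of the cubic bubble b = 256 l1 l2 l3 l4 over a tet
# of unit volume: int b dV, int b l_i dV, int b^2 dV, and the factor of
# int grad(b).grad(b) dV = K_BB * sum_i |g_i|^2 * V
I_B = 256.0 / 840.0          # int b
I_BL = 256.0 / 3360.0        # int b l_i
I_B2 = 65536.0 * 96.0 / 39916800.0   # int b^2
K_BB = 65536.0 / 15120.0     # bubble stiffness factor
D_B = 256.0 / 840.0          # |int l_i d_k b| = D_B * V * |g_i[k]| (signed: -D_B*V*g_i[k])


@dataclass
class FluidProperties:
    """Blood density [kg/m^3] and dynamic viscosity [Pa s] (standard values)."""

    rho: float = 1060.0
    mu: float = 3.5e-3

    def __post_init__(self):
        if self.rho <= 0.0 or self.mu <= 0.0:
            raise ParameterError("rho and mu must be positive")


@dataclass
class InflowSpec:
    """Pulsatile inflow: parabolic profile with a temporal envelope.

    The envelope is a half sine over the systolic interval ``T`` (so it
    peaks at T/2 = ``T_end`` for the defaults) or ``"constant"`` for steady
    verification runs.  ``Re_max`` fixes the peak inlet Reynolds number
    Re = rho * U_peak * (2R) / mu, from which the peak axial centreline
    velocity U_peak follows.
    """

    T: float = 0.4
    T_end: float = 0.2
    Re_max: float = 1200.0
    envelope: str = "half_sine"

    def __post_init__(self):
        if not 0.0 < self.T_end <= self.T:
            raise ParameterError("0 < T_end <= T required")
        if self.Re_max <= 0.0:
            raise ParameterError("Re_max must be positive")
        if self.envelope not in ("half_sine", "constant"):
            raise ParameterError(f"unknown envelope {self.envelope!r}")

    def env(self, t: float) -> float:
        if self.envelope == "constant":
            return 1.0
        return math.sin(math.pi * t / self.T)

    def u_peak(self, props: FluidProperties, radius_mm: float) -> float:
        """Peak centreline velocity [m/s] realizing Re_max at the envelope peak."""
        d = 2.0 * radius_mm * 1e-3
        return self.Re_max * props.mu / (props.rho * d)


@dataclass
class SolverConfig:
    """Time step, linearization and stabilization settings."""

    dt: float = 2.5e-3
    backflow_coeff: float = 0.5
    linearization: str = "semi_implicit"   # or "picard"
    picard_iterations: int = 2
    linear_tol: float = 1e-8

    def __post_init__(self):
        if self.dt <= 0.0:
            raise ParameterError("dt must be positive")
        if self.linear_tol <= 0.0:
            raise ParameterError("linear_tol must be positive")
        if self.linearization not in ("semi_implicit", "picard"):
            raise ParameterError(f"unknown linearization {self.linearization!r}")


@dataclass
class FlowState:
    """Velocity/pressure fields at time t on the mesh (plus bubble dofs)."""

    mesh: VolumeMesh
    u: np.ndarray          # (N, 3) m/s, P1 nodal
    p: np.ndarray          # (N,) Pa
    bubble: np.ndarray     # (M, 3) m/s, condensed enrichment coefficients
    t: float = 0.0

    @classmethod
    def zero(cls, mesh: VolumeMesh) -> "FlowState":
        return cls(mesh=mesh, u=np.zeros((mesh.n_nodes, 3)),
                   p=np.zeros(mesh.n_nodes), bubble=np.zeros((mesh.n_cells, 3)))

    @property
    def v_max(self) -> float:
        """Max nodal velocity magnitude (the CW-Doppler-style peak) [m/s]."""
        return float(np.linalg.norm(self.u, axis=1).max())


def inlet_profile(position, t: float, spec: InflowSpec, props: FluidProperties,
                  radius_mm: float) -> np.ndarray:
    """Inlet velocity vector(s) [m/s] at mm position(s) on the inlet plane.

    Axial component U_peak * (1 - (r/R)^2) * env(t), zero transverse.
    """
    pos = np.atleast_2d(np.asarray(position, dtype=float))
    r2 = (pos[:, 0] ** 2 + pos[:, 1] ** 2) / radius_mm ** 2
    uz = spec.u_peak(props, radius_mm) * np.clip(1.0 - r2, 0.0, None) * spec.env(t)
    out = np.zeros((len(pos), 3))
    out[:, 2] = uz
    return out[0] if np.asarray(position).ndim == 1 else out


# ---------------------------------------------------------------------------
# finite-element operator
# ---------------------------------------------------------------------------

class RIISOperator:
    """Assembled operator for one mesh + gamma field + fluid configuration."""

    def __init__(self, mesh: VolumeMesh, gamma_values: np.ndarray | None,
                 props: FluidProperties, config: SolverConfig,
                 inflow: InflowSpec | None = None, radius_mm: float | None = None):
        self.mesh = mesh
        self.props = props
        self.config = config
        self.inflow = inflow
        self.radius_mm = radius_mm
        self.N = mesh.n_nodes
        self.Ne = mesh.n_cells
        self.gamma = (np.zeros(self.N) if gamma_values is None
                      else np.asarray(gamma_values, dtype=float))
        self._setup_geometry()
        self._setup_boundary()
        self._setup_constant()

    # -- geometry ---------------------------------------------------------
    def _setup_geometry(self):
        nodes = self.mesh.nodes * 1e-3  # mm -> m
        cells = self.mesh.cells
        self.nodes_m = nodes
        p = nodes[cells]
        A = np.concatenate([np.ones((self.Ne, 4, 1)), p], axis=2)
        Ainv = np.linalg.inv(A)
        self.grads = np.transpose(Ainv[:, 1:4, :], (0, 2, 1))  # (Ne, 4, 3)
        self.vol = np.abs(np.linalg.det(A)) / 6.0              # (Ne,)

    def _setup_boundary(self):
        tags = self.mesh.boundary_tags
        self.inlet_nodes = np.unique(tags["inlet"])
        self.wall_nodes = np.setdiff1d(np.unique(tags["wall"]), self.inlet_nodes)
        self.outlet_facets = tags["outlet"]
        self.outlet_areas = facet_areas(self.nodes_m * 1e3, self.outlet_facets) * 1e-6
        self.inlet_areas = facet_areas(self.nodes_m * 1e3, tags["inlet"]) * 1e-6
        N = self.N
        vfixed = np.zeros(N, dtype=bool)
        vfixed[self.inlet_nodes] = True
        vfixed[self.wall_nodes] = True
        self.vfixed_mask = vfixed
        self.vfree = np.flatnonzero(~vfixed)
        self.vfixed = np.flatnonzero(vfixed)

    # -- constant part of the operator ------------------------------------
    def _setup_constant(self):
        rho, mu, dt = self.props.rho, self.props.mu, self.config.dt
        g, V = self.grads, self.vol
        cells = self.mesh.cells
        N = self.N

        gam = self.gamma[cells]                       # (Ne, 4)
        gam_sum = gam.sum(axis=1)
        gam_bar = gam_sum / 4.0

        # element P1 mass and stiffness
        eye4 = np.eye(4)
        M = V[:, None, None] * (1.0 + eye4) / 20.0
        K = np.einsum("eik,ejk->eij", g, g) * V[:, None, None]
        # P1 interpolation of gamma: int gamma l_i l_j
        G1 = (gam_sum[:, None, None] * (1.0 + eye4)
              + gam[:, :, None] + gam[:, None, :]
              + 2.0 * eye4 * gam[:, :, None]) * V[:, None, None] / 120.0

        # bubble condensation scalars
        self.a_b = ((rho / dt + gam_bar) * I_B2 + mu * K_BB
                    * np.einsum("eik,eik->e", g, g)) * V
        self.c_b = (rho / dt + gam_bar) * I_BL * V    # bubble-P1 mass coupling
        self.d_b = D_B * V[:, None, None] * g         # (Ne, 4, 3): d_ik

        Auu = rho / dt * M + mu * K + G1 \
            - (self.c_b ** 2 / self.a_b)[:, None, None] * np.ones((1, 4, 4))

        rows_b = np.repeat(cells[:, :, None], 4, axis=2).ravel()  # block rows
        cols_b = np.repeat(cells[:, None, :], 4, axis=1).ravel()  # block cols
        self._blk_rows = rows_b
        self._blk_cols = cols_b

        def nn(block):
            return sp.coo_matrix((np.asarray(block).ravel(), (rows_b, cols_b)),
                                 shape=(N, N)).tocsr()

        self._A_const_data = Auu.ravel()
        # pressure gradient (momentum row, pressure col) and divergence
        # (continuity row, velocity col) blocks, one per component; both carry
        # the bubble-condensation coupling and stay constant in time
        self.G_blocks, self.D_blocks = [], []
        for k in range(3):
            gk = g[:, :, k]
            Gk = (-gk[:, :, None] * (V / 4.0)[:, None, None] * np.ones((1, 1, 4))
                  - (self.c_b / self.a_b)[:, None, None]
                  * (D_B * V)[:, None, None] * gk[:, None, :])
            Dk = (gk[:, None, :] * (V / 4.0)[:, None, None] * np.ones((1, 4, 1))
                  + (self.c_b / self.a_b)[:, None, None]
                  * (D_B * V)[:, None, None] * gk[:, :, None])
            self.G_blocks.append(nn(Gk))
            self.D_blocks.append(nn(Dk))
        # pressure-pressure stabilization from the condensed bubble
        self.Kpp = nn((D_B * V[:, None, None]) ** 2 / self.a_b[:, None, None]
                      * np.einsum("eik,ejk->eij", g, g))

        vf, vx = self.vfree, self.vfixed
        self.G_f = [Gk[vf, :] for Gk in self.G_blocks]
        self.D_f = [Dk[:, vf] for Dk in self.D_blocks]
        self.D_x = [Dk[:, vx] for Dk in self.D_blocks]

        # backflow sparsity on outlet facets
        f = self.outlet_facets
        if len(f):
            self._bf_rows = np.repeat(f[:, :, None], 3, axis=2).ravel()
            self._bf_cols = np.repeat(f[:, None, :], 3, axis=1).ravel()
        else:
            self._bf_rows = self._bf_cols = np.zeros(0, dtype=np.int64)

        self._M_block = M

    # -- per-step assembly -------------------------------------------------
    def _step_blocks(self, w: np.ndarray):
        """Convection + Temam blocks for advecting field w (P1, (N,3))."""
        rho, V, g = self.props.rho, self.vol, self.grads
        cells = self.mesh.cells
        we = w[cells]                                  # (Ne, 4, 3)
        wg = np.einsum("emk,ejk->emj", we, g)          # w_m . g_j
        conv = rho * V[:, None, None] / 20.0 * (wg.sum(axis=1)[:, None, :] + wg)
        divw = np.einsum("emk,emk->e", we, g)
        temam = 0.5 * rho * divw[:, None, None] * (1.0 + np.eye(4)) / 20.0 \
            * V[:, None, None]
        return conv + temam

    def _backflow_blocks(self, w: np.ndarray):
        if not len(self.outlet_facets):
            return np.zeros(0)
        un = w[self.outlet_facets, 2].mean(axis=1)     # outlet normal is +z
        neg = np.clip(-un, 0.0, None)
        coef = self.props.rho * self.config.backflow_coeff * neg * self.outlet_areas
        eye3 = np.eye(3)
        return coef[:, None, None] * (1.0 + eye3) / 12.0

    def _rhs(self, u_old: np.ndarray, bubble_old: np.ndarray):
        rho, dt = self.props.rho, self.config.dt
        V = self.vol
        cells = self.mesh.cells
        N = self.N
        ue = u_old[cells]                              # (Ne, 4, 3)
        # bubble forcing f_bk = rho/dt (I_B2 V beta_old + I_BL V sum_i uold_ik)
        f_b = rho / dt * (I_B2 * V[:, None] * bubble_old
                          + I_BL * V[:, None] * ue.sum(axis=1))
        self._f_b = f_b
        rhs = np.zeros(4 * N)
        mom = np.einsum("eij,ejk->eik", self._M_block, ue) * (rho / dt) \
            + (rho / dt * I_BL * V)[:, None, None] * bubble_old[:, None, :] \
            - (self.c_b / self.a_b)[:, None, None] * f_b[:, None, :]
        cont = np.einsum("eik,ek->ei", self.d_b, f_b) / self.a_b[:, None]
        for k in range(3):
            np.add.at(rhs, k * N + cells.ravel(), mom[:, :, k].ravel())
        np.add.at(rhs, 3 * N + cells.ravel(), cont.ravel())
        return rhs

    def recover_bubble(self, u: np.ndarray, p: np.ndarray) -> np.ndarray:
        cells = self.mesh.cells
        ue = u[cells]
        pe = p[cells]
        num = (self._f_b - self.c_b[:, None] * ue.sum(axis=1)
               - np.einsum("eik,ei->ek", self.d_b, pe))
        return num / self.a_b[:, None]

    def dirichlet_values(self, t: float) -> np.ndarray:
        """Fixed-node velocity values at time t, (N, 3): inlet profile + walls."""
        vals = np.zeros((self.N, 3))
        if self.inflow is not None and len(self.inlet_nodes):
            pos = self.mesh.nodes[self.inlet_nodes]
            vals[self.inlet_nodes] = inlet_profile(pos, t, self.inflow,
                                                   self.props, self.radius_mm)
        return vals

    def assemble_momentum(self, w: np.ndarray):
        """Momentum matrix (N x N, shared by all components) for advecting w."""
        blocks = self._step_blocks(w)
        data = [self._A_const_data, blocks.ravel()]
        rows = [self._blk_rows, self._blk_rows]
        cols = [self._blk_cols, self._blk_cols]
        bf = self._backflow_blocks(w)
        if len(self._bf_rows):
            data.append(bf.ravel())
            rows.append(self._bf_rows)
            cols.append(self._bf_cols)
        return sp.coo_matrix((np.concatenate(data),
                              (np.concatenate(rows), np.concatenate(cols))),
                             shape=(self.N, self.N)).tocsr()

    def _solve_linear(self, w: np.ndarray, rhs: np.ndarray, ud: np.ndarray,
                      t_new: float):
        """Solve one linearized saddle-point system via the pressure Schur
        complement.

        The momentum block is identical for the three velocity components,
        so a single N x N factorization serves all of them; the pressure
        equation  S p = (Kpp - sum_k D_k A^-1 G_k) p = g - sum_k D_k A^-1 f_k
        is solved with preconditioned GMRES, the preconditioner being the
        sparse Schur complement with A approximated by its diagonal (a
        weighted pressure Laplacian).
        """
        N, vf, vx = self.N, self.vfree, self.vfixed
        A1 = self.assemble_momentum(w)
        A_ff = A1[vf][:, vf].tocsc()
        A_fx = A1[vf][:, vx]
        lu = spla.splu(A_ff)
        f = [rhs[k * N:(k + 1) * N][vf] - A_fx @ ud[vx, k] for k in range(3)]
        g = rhs[3 * N:].copy()
        for k in range(3):
            g -= self.D_x[k] @ ud[vx, k]

        Ainv_f = [lu.solve(fk) for fk in f]
        rhs_s = g - sum(self.D_f[k] @ Ainv_f[k] for k in range(3))

        def smul(p):
            return self.Kpp @ p - sum(
                self.D_f[k] @ lu.solve(self.G_f[k] @ p) for k in range(3))

        diag_inv = sp.diags(1.0 / A_ff.diagonal())
        P = (self.Kpp - sum(self.D_f[k] @ diag_inv @ self.G_f[k]
                            for k in range(3))).tocsc()
        plu = spla.splu(P)
        S = spla.LinearOperator((N, N), matvec=smul)
        M = spla.LinearOperator((N, N), matvec=plu.solve)
        p, info = spla.gmres(S, rhs_s, M=M, rtol=self.config.linear_tol,
                             atol=0.0, restart=150, maxiter=8)
        if info != 0:
            raise RuntimeError(
                f"pressure GMRES did not converge at t={t_new} (info={info}); "
                f"residual {np.linalg.norm(smul(p) - rhs_s):.3e}, "
                f"rhs norm {np.linalg.norm(rhs_s):.3e}")
        u = ud.copy()
        for k in range(3):
            u[vf, k] = lu.solve(f[k] - self.G_f[k] @ p)
        return u, p

    def step(self, state: FlowState, t_new: float) -> FlowState:
        """One backward-Euler step to time t_new."""
        rhs = self._rhs(state.u, state.bubble)
        ud = self.dirichlet_values(t_new)
        w = state.u
        n_pass = (self.config.picard_iterations
                  if self.config.linearization == "picard" else 1)
        for _ in range(n_pass):
            u, p = self._solve_linear(w, rhs, ud, t_new)
            w = u
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(p))):
            raise RuntimeError(f"non-finite field after step to t={t_new}")
        bubble = self.recover_bubble(u, p)
        return FlowState(mesh=state.mesh, u=u, p=p, bubble=bubble, t=t_new)

    # -- diagnostics --------------------------------------------------------
    def boundary_flux(self, state: FlowState, tag: str) -> float:
        """Signed outward volume flux [m^3/s] through a tagged boundary."""
        facets = self.mesh.boundary_tags[tag]
        if not len(facets):
            return 0.0
        areas = facet_areas(self.mesh.nodes, facets) * 1e-6
        uz = state.u[facets, 2].mean(axis=1)
        sign = {"inlet": -1.0, "outlet": 1.0}.get(tag, 0.0)
        if sign == 0.0:
            # wall: outward normal varies; the wall is no-slip so flux is 0
            return 0.0
        return float(np.sum(sign * uz * areas))


def advance(state: FlowState, dt: float, gamma, config: SolverConfig,
            props: FluidProperties, inflow: InflowSpec | None = None,
            radius_mm: float | None = None,
            operator: RIISOperator | None = None) -> FlowState:
    """One backward-Euler step of the penalized Navier-Stokes system.

    Convenience wrapper building a fresh operator unless one is passed;
    ``gamma`` is a GammaField, a nodal array, or None (plain Navier-Stokes).
    """
    values = getattr(gamma, "values", gamma)
    if operator is None:
        cfg = SolverConfig(dt=dt, backflow_coeff=config.backflow_coeff,
                           linearization=config.linearization,
                           picard_iterations=config.picard_iterations,
                           linear_tol=config.linear_tol)
        operator = RIISOperator(state.mesh, values, props, cfg, inflow, radius_mm)
    return operator.step(state, state.t + dt)


@dataclass
class SimulationResult:
    """Final fields plus the per-step diagnostics series."""

    state: FlowState
    times: np.ndarray
    v_max_series: np.ndarray
    delta_p_series: np.ndarray
    mass_balance_series: np.ndarray   # |Q_in + Q_out_signed| / |Q_in|
    z_up: float
    z_down: float

    @property
    def peak_v_max(self) -> float:
        return float(self.v_max_series.max(initial=0.0))

    @property
    def peak_delta_p(self) -> float:
        return float(self.delta_p_series.max(initial=0.0))


def run_simulation(mesh: VolumeMesh, gamma, inflow: InflowSpec,
                   config: SolverConfig, props: FluidProperties | None = None,
                   radius_mm: float | None = None,
                   z_up: float | None = None, z_down: float | None = None,
                   valve_height_mm: float | None = None,
                   callback=None) -> SimulationResult:
    """Integrate from rest to t = T_end, recording v_max(t) and DeltaP(t).

    ``gamma`` may be a GammaField, nodal array or None.  Pressure-drop
    planes default to z_up = -1 and z_down = +3 leaflet heights around the
    valve (``valve_height_mm``), snapped to mesh layers.
    """
    props = props or FluidProperties()
    if radius_mm is None:
        radius_mm = float(np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1]).max())
    h = valve_height_mm if valve_height_mm is not None else 10.0
    zs = mesh.z_layers
    if z_up is None:
        z_up = -1.0 * h
        if zs is not None:
            z_up = max(z_up, float(zs.min()))
    if z_down is None:
        z_down = 3.0 * h
        if zs is not None:
            z_down = min(z_down, float(zs.max()))
    values = getattr(gamma, "values", gamma)
    op = RIISOperator(mesh, values, props, config, inflow, radius_mm)
    state = FlowState.zero(mesh)
    n_steps = max(1, round(inflow.T_end / config.dt))
    times, vmax, dps, mb = [], [], [], []
    for n in range(1, n_steps + 1):
        t = n * config.dt
        try:
            state = op.step(state, t)
        except RuntimeError as exc:
            raise RuntimeError(f"step {n} (t={t:.4f}s) failed: {exc}") from exc
        q_in = op.boundary_flux(state, "inlet")
        q_out = op.boundary_flux(state, "outlet")
        times.append(t)
        vmax.append(state.v_max)
        dps.append(compute_pressure_drop(state, z_up, z_down))
        mb.append(abs(q_in + q_out) / max(abs(q_in), 1e-30))
        if callback is not None:
            callback(state)
    return SimulationResult(state=state, times=np.array(times),
                            v_max_series=np.array(vmax),
                            delta_p_series=np.array(dps),
                            mass_balance_series=np.array(mb),
                            z_up=z_up, z_down=z_down)


def compute_pressure_drop(state: FlowState, z_up: float, z_down: float) -> float:
    """Area-averaged pressure on plane z_up minus plane z_down, in mmHg.

    Planes (mm) are snapped to the nearest mesh layer of the extruded mesh;
    nodal pressures are averaged with cross-section area weights.
    """
    if not z_up < z_down:
        raise ParameterError("z_up must be below z_down")
    return (_plane_average(state, z_up) - _plane_average(state, z_down)) / MMHG


def _plane_average(state: FlowState, z_plane: float) -> float:
    mesh = state.mesh
    if mesh.z_layers is None or mesh.n_per_layer is None:
        raise ParameterError("pressure planes need a layered (extruded) mesh")
    zs = np.asarray(mesh.z_layers)
    if not zs.min() - 1e-9 <= z_plane <= zs.max() + 1e-9:
        raise ParameterError(f"plane z={z_plane} mm lies outside the domain "
                             f"[{zs.min()}, {zs.max()}] mm")
    layer = int(np.argmin(np.abs(zs - z_plane)))
    npl = mesh.n_per_layer
    pvals = state.p[layer * npl:(layer + 1) * npl]
    w = mesh.disk_node_areas
    if w is None:
        return float(pvals.mean())
    return float(np.sum(w * pvals) / np.sum(w))


@dataclass
class BernoulliComparison:
    """Quadratic fit DeltaP ~ a v^2 + b v + c and per-point ratios DeltaP/v^2."""

    coefficients: tuple[float, float, float] | None
    ratios: np.ndarray
    bernoulli_constant: float = 4.0

    def fitted(self, v) -> np.ndarray:
        if self.coefficients is None:
            raise ValueError("fit was refused (too few or collinear points)")
        a, b, c = self.coefficients
        v = np.asarray(v, dtype=float)
        return a * v ** 2 + b * v + c


def bernoulli_compare(points) -> BernoulliComparison:
    """Compare (v_max [m/s], DeltaP [mmHg]) pairs with DeltaP = 4 v^2.

    With >= 3 points at >= 3 distinct velocities a least-squares quadratic
    is fitted; otherwise the fit is refused (coefficients None) and only the
    per-point ratios DeltaP / v_max^2 are returned.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 2:
        raise ParameterError("points must be (v_max, delta_p) pairs")
    v, dp = pts[:, 0], pts[:, 1]
    if np.any(v == 0.0):
        raise ParameterError("v_max must be nonzero to form DeltaP/v^2 ratios")
    ratios = dp / v ** 2
    coeffs = None
    if len(pts) >= 3 and len(np.unique(v)) >= 3:
        coeffs = tuple(np.polyfit(v, dp, 2))
    elif len(pts) >= 3:
        warnings.warn("degenerate quadratic fit: velocities are not distinct",
                      stacklevel=2)
    return BernoulliComparison(coefficients=coeffs, ratios=ratios)
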