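"""Coupled heat-moisture-airflow model of a grain bulk cross-section.

The grain pile is treated as a continuous, isotropic porous medium in
local thermal and moisture equilibrium with its interstitial air
(incompressible flow, no metabolic heat source).  On a 2-D vertical
cross-section the model couples

* Darcy-Boussinesq natural convection: creeping interstitial flow driven
  by thermal buoyancy, ``u = m (-grad P + rho_0 g beta (T - T0) z_hat)``
  with mobility ``m = K / (phi mu)``, closed by incompressibility via a
  pressure Poisson problem (no-normal-flow cavity boundaries);
* an energy balance: grain-side heat storage, conduction with
  temperature-dependent conductivity, air-side advection, sorption heat,
  and dynamic envelope fluxes on the tagged boundary faces;
* moisture conservation in dry-basis moisture ``Wg``: moisture-gradient
  diffusion, temperature-gradient cross-diffusion and the two convective
  vapor-transport terms, all scaled by the isotherm partials sigma and
  omega over ``Rv T``;
* an equilibrium relative-humidity closure from the sorption isotherm.

Discretization: uniform cell-centered finite volumes.  Conduction is
advanced implicitly (backward Euler, lagged coefficients, refactorized
only when the temperature field drifts), advection by explicit
first-order upwinding in conservative flux form, moisture fully
explicitly in flux form -- its diffusion number at the default
resolution is ~1e-4, and the flux form keeps the closed-domain moisture
budget exact.  The operator-split step order is flow -> energy ->
moisture -> humidity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import material_models as mm
from .boundary_forcing import ForcingScenario, sol_air_temperature

logger = logging.getLogger(__name__)

__all__ = ["Mesh", "FieldState", "SolverConfig", "BoundarySpec",
           "CoupledSimulator", "SolverError",
           "ENVELOPE_BOUNDARIES", "ADIABATIC_BOUNDARIES",
           "solve_darcy_flow", "step_energy", "step_moisture",
           "update_relative_humidity", "advance_coupled"]

DAY_S = 86400.0
KELVIN = 273.15

#: map from mesh boundary side to envelope face tag
DEFAULT_FACE_TAGS = {"left": "south", "right": "north",
                     "top": "grain_surface", "bottom": "floor"}

_SIDES = ("left", "right", "top", "bottom")


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class Mesh:
    """Uniform cell-centered grid over a vertical cross-section.

    ``plane`` is XOZ or YOZ; ``width`` is the horizontal extent and
    ``height`` the grain fill height.  Cells are squares of side
    ``spacing``; cell (k, i) is centered at ((i+0.5) dx, (k+0.5) dx).
    Boundary sides carry envelope face tags (each side exactly once).
    """

    plane: str = "XOZ"
    width: float = 24.0
    height: float = 6.0
    spacing: float = 0.1
    face_tags: dict = field(default_factory=lambda: dict(DEFAULT_FACE_TAGS))

    def __post_init__(self) -> None:
        if self.plane.upper() not in ("XOZ", "YOZ"):
            raise ValueError("plane must be XOZ or YOZ")
        if self.spacing <= 0 or self.width <= 0 or self.height <= 0:
            raise ValueError("mesh dimensions and spacing must be positive")
        if set(self.face_tags) != set(_SIDES):
            raise ValueError("face_tags must cover left/right/top/bottom exactly")

    @property
    def nx(self) -> int:
        return int(round(self.width / self.spacing))

    @property
    def nz(self) -> int:
        return int(round(self.height / self.spacing))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nz, self.nx)

    @property
    def n_cells(self) -> int:
        return self.nx * self.nz

    @property
    def x(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.spacing

    @property
    def z(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.spacing

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.z)


@dataclass
class FieldState:
    """All prognostic and diagnostic fields on the mesh at one time.

    ``M`` (wet-basis %) and ``RH`` are derived from ``Wg`` and ``T``; the
    simulator keeps them synchronized after every step.
    """

    T: np.ndarray                  # degC, shape (nz, nx)
    Wg: np.ndarray                 # dry-basis fraction
    M: np.ndarray                  # wet-basis %, derived
    RH: np.ndarray                 # fraction, derived
    u: np.ndarray                  # cell-centered velocity (2, nz, nx), m/s
    P: np.ndarray                  # pressure deviation, Pa
    time: float = 0.0              # elapsed seconds

    @classmethod
    def uniform(cls, mesh: Mesh, T: float = 18.0, Wg: float = 0.1628,
                params: mm.MaterialParams | None = None) -> "FieldState":
        shape = mesh.shape
        Tf = np.full(shape, float(T))
        Wgf = np.full(shape, float(Wg))
        Mf = np.asarray(mm.wet_from_dry_basis(Wgf))
        RHf = np.asarray(mm.equilibrium_rh(Tf + KELVIN, Wgf, params))
        return cls(T=Tf, Wg=Wgf, M=Mf, RH=RHf,
                   u=np.zeros((2,) + shape), P=np.zeros(shape))

    @classmethod
    def from_temperature(cls, mesh: Mesh, T: np.ndarray, Wg: float = 0.1628,
                         params: mm.MaterialParams | None = None) -> "FieldState":
        T = np.asarray(T, dtype=float)
        if T.shape != mesh.shape:
            raise ValueError(f"temperature shape {T.shape} != mesh {mesh.shape}")
        st = cls.uniform(mesh, 0.0, Wg, params)
        st.T = T.copy()
        st.RH = np.asarray(mm.equilibrium_rh(T + KELVIN, st.Wg, params))
        return st

    def copy(self) -> "FieldState":
        return FieldState(T=self.T.copy(), Wg=self.Wg.copy(), M=self.M.copy(),
                          RH=self.RH.copy(), u=self.u.copy(), P=self.P.copy(),
                          time=self.time)


@dataclass(frozen=True)
class SolverConfig:
    """Numerical controls for the coupled advance."""

    dt: float = 600.0              # s
    flow_tol: float = 1e-10        # divergence tolerance (relative), see solver
    max_substeps: int = 64         # CFL substep cap for advection
    refactor_dT: float = 0.5       # degC drift before conduction refactor
    snapshot_every: float = DAY_S  # snapshot cadence, s
    flow_every: int = 1            # flow re-solve cadence, in steps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("time step must be positive")
        if self.flow_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class BoundarySpec:
    """Thermal boundary condition of one mesh side.

    kind: "adiabatic" | "dirichlet" (fixed temperature ``value``) |
    "envelope" (sol-air flux through the tagged face).
    """

    kind: str = "envelope"
    value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("adiabatic", "dirichlet", "envelope"):
            raise ValueError(f"unknown boundary kind {self.kind!r}")
        if self.kind == "dirichlet" and self.value is None:
            raise ValueError("dirichlet boundary needs a temperature value")


ENVELOPE_BOUNDARIES = {s: BoundarySpec("envelope") for s in _SIDES}
ADIABATIC_BOUNDARIES = {s: BoundarySpec("adiabatic") for s in _SIDES}


class CoupledSimulator:
    """Operator-split integrator for the coupled model on one mesh.

    Caches the sparse factorizations (pressure Poisson, implicit
    conduction) between steps; the conduction operator is reassembled
    when ``max |T - T_at_assembly|`` exceeds ``config.refactor_dT``.
    """

    def __init__(self, mesh: Mesh, params: mm.MaterialParams | None = None,
                 forcing: ForcingScenario | None = None,
                 config: SolverConfig | None = None,
                 boundaries: dict[str, BoundarySpec] | None = None):
        self.mesh = mesh
        self.params = params or mm.MaterialParams()
        self.forcing = forcing or ForcingScenario()
        self.config = config or SolverConfig()
        self.boundaries = dict(boundaries if boundaries is not None
                               else ENVELOPE_BOUNDARIES)
        for side in _SIDES:
            self.boundaries.setdefault(side, BoundarySpec("adiabatic"))
        self._flow_lu = None
        self._energy_lu = None
        self._energy_T_ref = None
        self._energy_dt = None
        self._ux = np.zeros((mesh.nz, mesh.nx + 1))
        self._uz = np.zeros((mesh.nz + 1, mesh.nx))
        self._prev_dWg_dt = np.zeros(mesh.shape)
        self.substep_log: list[tuple[float, int]] = []

    # ---------------------------------------------------------- flow solve

    def _assemble_flow(self):
        nz, nx = self.mesh.shape
        n = nz * nx
        dx = self.mesh.spacing
        # 5-point Laplacian with pure Neumann boundaries, vectorized
        idx = np.arange(n).reshape(nz, nx)
        rows, cols, vals = [], [], []
        diag = np.zeros((nz, nx))

        def couple(sl_a, sl_b):
            ra, rb = idx[sl_a].ravel(), idx[sl_b].ravel()
            ones = np.ones_like(ra, dtype=float)
            rows.extend([ra, rb]); cols.extend([rb, ra])
            vals.extend([-ones, -ones])
            diag[sl_a] += 1.0
            diag[sl_b] += 1.0

        couple(np.s_[:, 1:], np.s_[:, :-1])
        couple(np.s_[1:, :], np.s_[:-1, :])
        rows.append(idx.ravel()); cols.append(idx.ravel())
        vals.append(diag.ravel())
        A = sp.csr_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(n, n)) / dx**2
        A = A.tolil()
        A[0, :] = 0.0
        A[0, 0] = 1.0  # pin the reference cell of the all-Neumann system
        return splu(A.tocsc())

    def solve_darcy_flow(self, state: FieldState) -> FieldState:
        """Steady Darcy velocity for the current temperature field.

        Isothermal fields (T = T0 everywhere) yield u = 0 exactly.
        Raises :class:`SolverError` if the discrete velocity field is not
        divergence-free to tolerance.
        """
        p = self.params
        mesh = self.mesh
        nz, nx = mesh.shape
        dx = mesh.spacing
        if not np.all(np.isfinite(state.T)):
            raise SolverError("temperature field contains non-finite values")
        mob = p.permeability / (p.phi_drag * p.mu)
        # buoyancy b = rho0 g beta (T - T0), acting along +z only
        b = p.rho_0 * p.g * p.beta * (state.T - (p.T0 - KELVIN))
        b_face = np.zeros((nz + 1, nx))
        b_face[1:-1, :] = 0.5 * (b[1:, :] + b[:-1, :])
        # solve lap(P') = d(b)/dz with dP'/dn = b n_z (P' = P / mobility)
        # finite-volume continuity gives (-lap) P = -d(b)/dz with the
        # operator assembled in positive-definite form
        rhs = -(b_face[1:, :] - b_face[:-1, :]) / dx
        rhs_flat = rhs.ravel().copy()
        rhs_flat[0] = 0.0  # pinned reference cell
        if self._flow_lu is None:
            self._flow_lu = self._assemble_flow()
        Pp = self._flow_lu.solve(rhs_flat).reshape(nz, nx)
        ux = np.zeros((nz, nx + 1))
        uz = np.zeros((nz + 1, nx))
        ux[:, 1:-1] = mob * (-(Pp[:, 1:] - Pp[:, :-1]) / dx)
        uz[1:-1, :] = mob * (-(Pp[1:, :] - Pp[:-1, :]) / dx + b_face[1:-1, :])
        div = (ux[:, 1:] - ux[:, :-1] + uz[1:, :] - uz[:-1, :]) / dx
        div[0, 0] = 0.0  # pinned cell: satisfied through global compatibility
        u_scale = max(float(np.max(np.abs(ux))), float(np.max(np.abs(uz))))
        max_div = float(np.max(np.abs(div)))
        if max_div > max(u_scale / dx, 1.0) * 1e-8:
            raise SolverError(f"flow solve not divergence-free: max|div u| = "
                              f"{max_div:.3e} at velocity scale {u_scale:.3e}")
        state.P = Pp * 1.0  # pressure potential (per unit mobility)
        state.u = np.stack([0.5 * (ux[:, 1:] + ux[:, :-1]),
                            0.5 * (uz[1:, :] + uz[:-1, :])])
        self._ux, self._uz = ux, uz
        return state

    # -------------------------------------------------------- energy step

    def _boundary_coeffs(self, T: np.ndarray) -> dict:
        """Per-side effective conductance U (W/(m^2 K)) toward the
        boundary temperature."""
        dx = self.mesh.spacing
        out = {}
        kb = None
        for side in _SIDES:
            spec = self.boundaries[side]
            if spec.kind == "adiabatic":
                continue
            if spec.kind == "dirichlet":
                if kb is None:
                    kb = mm.thermal_conductivity_maize(np.clip(T, -10, 60),
                                                       self.params)
                edge = {"left": kb[:, 0], "right": kb[:, -1],
                        "top": kb[-1, :], "bottom": kb[0, :]}[side]
                U = 2.0 * edge / dx  # half-cell conduction to the fixed value
            else:
                face = self.mesh.face_tags[side]
                U = self.forcing.face_U(face)
                if U == 0.0:
                    continue
            out[side] = (U, spec)
        return out

    def _assemble_energy(self, state: FieldState, dt: float) -> None:
        """Backward-Euler conduction operator at the current coefficients."""
        p = self.params
        nz, nx = self.mesh.shape
        dx = self.mesh.spacing
        n = nz * nx
        T = state.T
        kb = mm.thermal_conductivity_maize(np.clip(T, -10, 60), p)
        C = p.rho_b * mm.specific_heat_maize(np.clip(state.M, 0, 40), p) * 1e3
        idx = np.arange(n).reshape(nz, nx)
        rows, cols, vals = [], [], []
        diag = C / dt

        def couple(kf, sl_a, sl_b):
            g = (kf / dx**2).ravel()
            ra, rb = idx[sl_a].ravel(), idx[sl_b].ravel()
            rows.extend([ra, rb]); cols.extend([rb, ra])
            vals.extend([-g, -g])
            np.add.at(diag, np.unravel_index(ra, (nz, nx)), g)
            np.add.at(diag, np.unravel_index(rb, (nz, nx)), g)

        kfx = 2 * kb[:, 1:] * kb[:, :-1] / (kb[:, 1:] + kb[:, :-1])
        kfz = 2 * kb[1:, :] * kb[:-1, :] / (kb[1:, :] + kb[:-1, :])
        couple(kfx, np.s_[:, 1:], np.s_[:, :-1])
        couple(kfz, np.s_[1:, :], np.s_[:-1, :])

        for side, (U, spec) in self._boundary_coeffs(T).items():
            Uarr = np.asarray(U, dtype=float)
            if side == "left":
                diag[:, 0] += Uarr / dx
            elif side == "right":
                diag[:, -1] += Uarr / dx
            elif side == "top":
                diag[-1, :] += Uarr / dx
            else:
                diag[0, :] += Uarr / dx

        rows.append(idx.ravel()); cols.append(idx.ravel())
        vals.append(diag.ravel())
        A = sp.csr_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(n, n))
        self._energy_lu = splu(A.tocsc())
        self._energy_T_ref = T.copy()
        self._energy_C = C
        self._energy_dt = dt

    def _advection_rhs(self, state: FieldState) -> np.ndarray:
        """Explicit upwind heat advection, conservative flux form, W/m^3."""
        p = self.params
        dx = self.mesh.spacing
        T = state.T
        ux, uz = self._ux, self._uz
        rhoCa = p.rho_a * p.air_specific_heat(float(T.mean())) * 1e3
        Tfx = np.where(ux[:, 1:-1] > 0, T[:, :-1], T[:, 1:])
        Tfz = np.where(uz[1:-1, :] > 0, T[:-1, :], T[1:, :])
        Fx = np.zeros_like(ux)
        Fz = np.zeros_like(uz)
        Fx[:, 1:-1] = rhoCa * ux[:, 1:-1] * Tfx
        Fz[1:-1, :] = rhoCa * uz[1:-1, :] * Tfz
        return -(Fx[:, 1:] - Fx[:, :-1] + Fz[1:, :] - Fz[:-1, :]) / dx

    def step_energy(self, state: FieldState, dt: float | None = None,
                    dWg_dt: np.ndarray | None = None) -> FieldState:
        """Advance temperature one step.

        Implicit conduction with kb(T); explicit upwind advection scaled
        by the air/grain heat-capacity ratio; sorption heat
        ``h_fg rho_b dWg/dt`` (lagged from the previous moisture step
        unless supplied); envelope or Dirichlet fluxes on tagged sides.
        CFL violations of the explicit advection trigger automatic,
        logged substepping.
        """
        dt = dt or self.config.dt
        mesh = self.mesh
        dx = mesh.spacing
        p = self.params

        u_eff = max(float(np.max(np.abs(self._ux))),
                    float(np.max(np.abs(self._uz)))) \
            * p.rho_a * p.air_specific_heat(float(state.T.mean())) * 1e3
        C_min = p.rho_b * p.cb_coeffs[0] * 1e3
        n_sub = 1
        cfl = u_eff * dt / (C_min * dx)
        if cfl > 0.5:
            n_sub = min(int(np.ceil(cfl / 0.5)), self.config.max_substeps)
            logger.info("advection CFL %.2f at dt=%.0f s: %d substeps",
                        cfl, dt, n_sub)
            self.substep_log.append((state.time, n_sub))
        sub_dt = dt / n_sub

        if (self._energy_lu is None or self._energy_dt != sub_dt
                or np.max(np.abs(state.T - self._energy_T_ref))
                > self.config.refactor_dT):
            self._assemble_energy(state, sub_dt)
        C = self._energy_C
        if dWg_dt is None:
            dWg_dt = self._prev_dWg_dt
        for _ in range(n_sub):
            rhs = C * state.T / sub_dt
            rhs = rhs + self._advection_rhs(state)
            rhs = rhs + p.h_fg * p.rho_b * dWg_dt
            for side, (U, spec) in self._boundary_coeffs(state.T).items():
                if spec.kind == "dirichlet":
                    T_bc = spec.value
                else:
                    face = self.mesh.face_tags[side]
                    T_bc = sol_air_temperature(self.forcing, state.time, face)
                Uarr = np.asarray(U, dtype=float)
                if side == "left":
                    rhs[:, 0] += Uarr / dx * T_bc
                elif side == "right":
                    rhs[:, -1] += Uarr / dx * T_bc
                elif side == "top":
                    rhs[-1, :] += Uarr / dx * T_bc
                else:
                    rhs[0, :] += Uarr / dx * T_bc
            T_new = self._energy_lu.solve(rhs.ravel()).reshape(mesh.shape)
            if not np.all(np.isfinite(T_new)):
                raise SolverError("NaN in energy step")
            state.T = T_new
            state.time += sub_dt
        return state

    # ------------------------------------------------------ moisture step

    def step_moisture(self, state: FieldState, dt: float | None = None) -> FieldState:
        """Advance dry-basis moisture one explicit flux-form step.

        The flux (positive toward increasing coordinate) is::

            q = -DM/(RvT) grad Wg - DT/(RvT) grad T
                + u (sigma/(RvT) Wg + omega/(RvT) T)

        with coefficients averaged to faces and the transported scalars
        upwinded; then ``rho_b dWg/dt = -div q``.  Zero-flux boundaries
        (hermetic bulk); the wet-basis field is resynchronized and Wg is
        clipped to the isotherm validity range [0.05, 0.35] with a logged
        warning.
        """
        dt = dt or self.config.dt
        p = self.params
        nz, nx = self.mesh.shape
        dx = self.mesh.spacing
        T_K = state.T + KELVIN
        coeffs = mm.diffusion_coeffs(np.clip(T_K, 233.16, 329.99),
                                     np.clip(state.Wg, 0.05, 0.35), p)
        RvT = p.rv * T_K
        DW = coeffs.DM / RvT
        DTh = coeffs.DT / RvT
        s_conv = coeffs.sigma / RvT
        w_conv = coeffs.omega / RvT
        ux, uz = self._ux, self._uz

        ax = lambda f: 0.5 * (f[:, 1:] + f[:, :-1])
        az = lambda f: 0.5 * (f[1:, :] + f[:-1, :])

        qx = np.zeros((nz, nx + 1))
        qz = np.zeros((nz + 1, nx))
        qx[:, 1:-1] = -ax(DW) * (state.Wg[:, 1:] - state.Wg[:, :-1]) / dx \
                      - ax(DTh) * (state.T[:, 1:] - state.T[:, :-1]) / dx
        qz[1:-1, :] = -az(DW) * (state.Wg[1:, :] - state.Wg[:-1, :]) / dx \
                      - az(DTh) * (state.T[1:, :] - state.T[:-1, :]) / dx
        Wg_up_x = np.where(ux[:, 1:-1] > 0, state.Wg[:, :-1], state.Wg[:, 1:])
        Wg_up_z = np.where(uz[1:-1, :] > 0, state.Wg[:-1, :], state.Wg[1:, :])
        T_up_x = np.where(ux[:, 1:-1] > 0, state.T[:, :-1], state.T[:, 1:])
        T_up_z = np.where(uz[1:-1, :] > 0, state.T[:-1, :], state.T[1:, :])
        qx[:, 1:-1] += ux[:, 1:-1] * (ax(s_conv) * Wg_up_x + ax(w_conv) * T_up_x)
        qz[1:-1, :] += uz[1:-1, :] * (az(s_conv) * Wg_up_z + az(w_conv) * T_up_z)

        div_q = (qx[:, 1:] - qx[:, :-1] + qz[1:, :] - qz[:-1, :]) / dx
        Wg_new = state.Wg - dt * div_q / p.rho_b
        if np.any(Wg_new < 0.05) or np.any(Wg_new > 0.35):
            logger.warning("moisture left isotherm validity range at t=%.0f s; "
                           "clipping to [0.05, 0.35]", state.time)
            Wg_new = np.clip(Wg_new, 0.05, 0.35)
        self._prev_dWg_dt = (Wg_new - state.Wg) / dt
        state.Wg = Wg_new
        state.M = np.asarray(mm.wet_from_dry_basis(Wg_new))
        return state

    # -------------------------------------------------------- RH closure

    def update_relative_humidity(self, state: FieldState) -> FieldState:
        """Equilibrium RH at every node from the sorption isotherm
        (local-equilibrium assumption)."""
        T_K = np.clip(state.T + KELVIN, 233.16, 329.99)
        state.RH = np.asarray(mm.equilibrium_rh(
            T_K, np.clip(state.Wg, 0.05, 0.35), self.params))
        return state

    # ----------------------------------------------------------- advance

    def advance(self, state: FieldState, horizon_s: float,
                snapshot_every: float | None = None) -> Iterator[FieldState]:
        """Run the operator-split loop and yield snapshot copies.

        Per step: flow solve -> energy -> moisture -> RH.  The initial
        state is yielded first; snapshots then follow at the configured
        cadence (default daily).  Deterministic given the configuration.
        """
        cadence = snapshot_every or self.config.snapshot_every
        dt = self.config.dt
        n_steps = int(round(horizon_s / dt))
        self.update_relative_humidity(state)
        yield state.copy()
        next_snap = cadence
        stage = "init"
        try:
            for step in range(n_steps):
                if step % self.config.flow_every == 0:
                    stage = "flow"
                    self.solve_darcy_flow(state)
                stage = "energy"
                self.step_energy(state, dt)
                stage = "moisture"
                self.step_moisture(state, dt)
                stage = "humidity"
                self.update_relative_humidity(state)
                if state.time >= next_snap - 1e-6:
                    yield state.copy()
                    next_snap += cadence
        except SolverError as exc:
            raise SolverError(f"stage {stage!r} failed at step {step} "
                              f"(t={state.time:.0f} s): {exc}") from exc


# ----------------------------------------------------------------------
# module-level operation surface (one-shot convenience wrappers)

def solve_darcy_flow(state: FieldState, params: mm.MaterialParams,
                     mesh: Mesh) -> FieldState:
    """One-shot steady Darcy flow solve for the state's temperature."""
    sim = CoupledSimulator(mesh, params, boundaries=ADIABATIC_BOUNDARIES)
    return sim.solve_darcy_flow(state)


def step_energy(state: FieldState, params: mm.MaterialParams,
                mesh: Mesh, dt: float,
                forcing: ForcingScenario | None = None,
                boundaries: dict[str, BoundarySpec] | None = None,
                use_flow: bool = False) -> FieldState:
    """One-shot energy step (no flow unless requested)."""
    sim = CoupledSimulator(mesh, params, forcing,
                           boundaries=boundaries or ADIABATIC_BOUNDARIES)
    if use_flow:
        sim.solve_darcy_flow(state)
    return sim.step_energy(state, dt)


def step_moisture(state: FieldState, params: mm.MaterialParams,
                  mesh: Mesh, dt: float, use_flow: bool = False) -> FieldState:
    """One-shot moisture step (no flow unless requested)."""
    sim = CoupledSimulator(mesh, params, boundaries=ADIABATIC_BOUNDARIES)
    if use_flow:
        sim.solve_darcy_flow(state)
    return sim.step_moisture(state, dt)


def update_relative_humidity(state: FieldState,
                             params: mm.MaterialParams) -> FieldState:
    """One-shot equilibrium RH update."""
    mesh = Mesh(width=state.T.shape[1] * 0.1, height=state.T.shape[0] * 0.1)
    sim = CoupledSimulator(mesh, params, boundaries=ADIABATIC_BOUNDARIES)
    return sim.update_relative_humidity(state)


def advance_coupled(state: FieldState, config: SolverConfig,
                    params: mm.MaterialParams, forcing: ForcingScenario,
                    mesh: Mesh, horizon_s: float,
                    boundaries: dict[str, BoundarySpec] | None = None
                    ) -> list[FieldState]:
    """Run the coupled loop over a horizon; returns the snapshot list
    (initial state first, then one per cadence interval)."""
    sim = CoupledSimulator(mesh, params, forcing, config, boundaries)
    return list(sim.advance(state, horizon_s))
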