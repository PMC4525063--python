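"""1D axial osmo-poroelastic intervertebral-disk column.

The disk is reduced to a confined axial column of three layers — cartilage
endplate, nucleus pulposus core, cartilage endplate (CEP-NP-CEP) — of biphasic
(solid + fluid) tissue.  Field variables are the solid axial displacement
``u(z, t)`` and the water chemical potential ``mu(z, t) = p - pi``, where
``p`` is the total fluid pressure and ``pi(z)`` a fixed osmotic pressure
field (the Donnan swelling pressure of the proteoglycan-rich tissue):
``pi = delta_pi`` in the NP, zero at the outer boundaries, linear across the
endplates.  Governing equations (small strain, incompressible constituents):

    d/dz [ H_A du/dz - (mu + pi) ] = 0          (equilibrium)
    d(eps)/dt = d/dz [ k(e) d(mu)/dz ]          (fluid continuity, Darcy)

with ``H_A = K + 4G/3`` the aggregate modulus and ``k(e)`` the
void-ratio-dependent permeability.  Outer boundaries are drained
(``mu = 0``, i.e. total fluid pressure equals the nil external pore
pressure).  A fresh column starts at ``p = 0`` everywhere (``mu = -pi``):
the osmotic imbalance then draws water in until ``p -> pi``, which is the
overnight swelling scenario; mechanical loading enters through the top
boundary as either a prescribed traction or a prescribed displacement.

Discretization: linear finite elements, monolithic backward-Euler steps,
Picard iteration on the strain-dependent permeability with a 1e-10 residual
tolerance.  Units: N - mm - MPa - s; permeability mm^4/(N s) == mm^2/(MPa s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ConvergenceError

__all__ = [
    "DiskTissueParams",
    "DiskColumn",
    "ColumnState",
    "ColumnStepper",
    "DEFAULT_DISK_MATERIALS",
    "load_disk_materials",
    "permeability",
    "build_column",
    "solve_consolidation",
    "intradiscal_pressure",
    "axial_tangent_stiffness",
]


@dataclass(frozen=True)
class DiskTissueParams:
    """Biphasic parameters of one disk subtissue."""

    G: float      # shear modulus, MPa
    K: float      # bulk modulus, MPa
    e0: float     # initial void ratio (fluid/solid volume)
    k0: float     # initial permeability, mm^4/(N s)
    M: float      # permeability exponent
    tissue: str   # "AF" | "NP" | "CEP"

    def __post_init__(self):
        if min(self.G, self.K, self.e0, self.k0) <= 0 or self.M < 0:
            raise ValueError("disk tissue parameters must be positive")

    @property
    def aggregate_modulus(self) -> float:
        """Confined-compression (aggregate) modulus H_A = K + 4G/3, MPa."""
        return self.K + 4.0 * self.G / 3.0


def load_disk_materials(path: str | Path | None = None) -> dict[str, DiskTissueParams]:
    """Read the shipped (or a user) disk-material CSV."""
    if path is None:
        src = resources.files("spinewell.data") / "disk_materials.csv"
        with resources.as_file(src) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    return {str(r.tissue): DiskTissueParams(G=float(r.G), K=float(r.K),
                                            e0=float(r.e0), k0=float(r.k0),
                                            M=float(r.M), tissue=str(r.tissue))
            for r in df.itertuples(index=False)}


DEFAULT_DISK_MATERIALS: dict[str, DiskTissueParams] = load_disk_materials()


def permeability(e: float, params: DiskTissueParams) -> float:
    """Strain-dependent permeability (mm^4/(N s)).

    k = k0 [e (1+e0) / (e0 (1+e))]^2 exp(M ((1+e)/(1+e0) - 1)),
    normalized so k(e0) = k0 exactly; strictly increasing in e.
    """
    if e <= 0:
        raise ValueError("void ratio must be positive")
    ratio = e * (1.0 + params.e0) / (params.e0 * (1.0 + e))
    return params.k0 * ratio * ratio * math.exp(
        params.M * ((1.0 + e) / (1.0 + params.e0) - 1.0))


@dataclass(frozen=True)
class DiskColumn:
    """Assembled CEP-NP-CEP column: grid, tissue assignment, osmotic field."""

    z: np.ndarray                 # nodal coordinates, 0 (bottom) .. H (top)
    element_tissue: tuple         # tissue label per element
    materials: dict               # label -> DiskTissueParams
    area: float                   # effective axial cross-section, mm^2
    pi: np.ndarray                # nodal osmotic pressure field, MPa
    np_center_node: int
    delta_pi: float

    @property
    def n_nodes(self) -> int:
        return self.z.size

    @property
    def height(self) -> float:
        return float(self.z[-1])

    @property
    def element_lengths(self) -> np.ndarray:
        return np.diff(self.z)

    def element_params(self):
        return [self.materials[t] for t in self.element_tissue]

    def drained_axial_stiffness(self) -> float:
        """Series stiffness A / sum(l_e / H_A_e), N/mm (drained limit)."""
        comp = sum(l / p.aggregate_modulus
                   for l, p in zip(self.element_lengths, self.element_params()))
        return self.area / comp


@dataclass
class ColumnState:
    """Nodal state of the column at one instant."""

    time: float
    u: np.ndarray            # nodal axial displacement, mm
    mu: np.ndarray           # nodal water chemical potential p - pi, MPa
    pi: np.ndarray           # nodal osmotic field (fixed), MPa
    e_nodes: np.ndarray      # nodal void ratio
    applied_force: float     # external axial force, N (compression positive)
    top_displacement: float  # prescribed top displacement, mm (NaN if force-driven)
    reaction: float          # axial force at top, N (tension positive)

    @property
    def p(self) -> np.ndarray:
        """Total fluid pressure p = mu + pi, MPa."""
        return self.mu + self.pi

    def copy(self) -> "ColumnState":
        return ColumnState(self.time, self.u.copy(), self.mu.copy(), self.pi,
                           self.e_nodes.copy(), self.applied_force,
                           self.top_displacement, self.reaction)


def build_column(np_height: float = 8.0, cep_height: float = 0.8,
                 area: float = 1800.0,
                 materials: dict | None = None,
                 delta_pi: float = 0.15,
                 n_nodes: int = 11) -> DiskColumn:
    """Assemble a CEP-NP-CEP column with ``n_nodes`` nodes per layer.

    The osmotic field is ``delta_pi`` throughout the NP, zero at the outer
    boundaries and linear across each endplate; the column is mirror-symmetric
    about mid-height.
    """
    if np_height <= 0 or cep_height <= 0 or area <= 0:
        raise ConfigError("column dimensions must be positive")
    if n_nodes < 5:
        raise ConfigError("at least 5 nodes per layer are required")
    if delta_pi < 0:
        raise ConfigError("osmotic gradient must be non-negative")
    mats = dict(materials or DEFAULT_DISK_MATERIALS)
    for lab in ("NP", "CEP"):
        if lab not in mats:
            raise ConfigError(f"missing disk material {lab!r}")

    z_bot = np.linspace(0.0, cep_height, n_nodes)
    z_np = np.linspace(cep_height, cep_height + np_height, n_nodes)
    z_top = np.linspace(cep_height + np_height, 2 * cep_height + np_height,
                        n_nodes)
    z = np.concatenate([z_bot, z_np[1:], z_top[1:]])
    tissues = (["CEP"] * (n_nodes - 1) + ["NP"] * (n_nodes - 1)
               + ["CEP"] * (n_nodes - 1))

    pi = np.empty_like(z)
    h1, h2 = cep_height, cep_height + np_height
    for i, zi in enumerate(z):
        if zi <= h1:
            pi[i] = delta_pi * zi / cep_height
        elif zi <= h2:
            pi[i] = delta_pi
        else:
            pi[i] = delta_pi * (z[-1] - zi) / cep_height
    np_center = int(np.argmin(np.abs(z - 0.5 * (h1 + h2))))
    return DiskColumn(z=z, element_tissue=tuple(tissues), materials=mats,
                      area=area, pi=pi, np_center_node=np_center,
                      delta_pi=delta_pi)


def fresh_state(column: DiskColumn) -> ColumnState:
    """Reference state: undeformed, total fluid pressure zero everywhere
    (mu = -pi), mechanically in equilibrium."""
    e0 = np.array([column.materials[t].e0 for t in column.element_tissue])
    e_nodes = _elements_to_nodes(column, e0)
    return ColumnState(time=0.0, u=np.zeros(column.n_nodes),
                       mu=-column.pi.copy(), pi=column.pi,
                       e_nodes=e_nodes, applied_force=0.0,
                       top_displacement=math.nan, reaction=0.0)


def _elements_to_nodes(column: DiskColumn, elem_vals: np.ndarray) -> np.ndarray:
    out = np.empty(column.n_nodes)
    out[0] = elem_vals[0]
    out[-1] = elem_vals[-1]
    out[1:-1] = 0.5 * (elem_vals[:-1] + elem_vals[1:])
    return out


def _element_void_ratios(column: DiskColumn, u: np.ndarray) -> np.ndarray:
    """Void ratio per element from the current strain (small-strain update)."""
    eps = np.diff(u) / column.element_lengths
    e0 = np.array([column.materials[t].e0 for t in column.element_tissue])
    e = e0 + (1.0 + e0) * eps
    return np.maximum(e, 1e-6)


class ColumnStepper:
    """Backward-Euler time stepping of one column, with trial (uncommitted)
    steps for the coupled solver's staggered linearization."""

    def __init__(self, column: DiskColumn, state: ColumnState | None = None,
                 strain_dependent_permeability: bool = True,
                 newton_tol: float = 1e-10, max_picard: int = 60):
        self.column = column
        self.state = state or fresh_state(column)
        self.strain_dependent = strain_dependent_permeability
        self.newton_tol = newton_tol
        self.max_picard = max_picard

    # -- assembly -------------------------------------------------------
    def _assemble(self, k_elem: np.ndarray):
        col = self.column
        n = col.n_nodes
        lengths = col.element_lengths
        H_A = np.array([p.aggregate_modulus for p in col.element_params()])
        Kuu = np.zeros((n, n))
        Q = np.zeros((n, n))
        H = np.zeros((n, n))
        for e in range(n - 1):
            i, j = e, e + 1
            l = lengths[e]
            ke = H_A[e] / l
            Kuu[i, i] += ke; Kuu[j, j] += ke
            Kuu[i, j] -= ke; Kuu[j, i] -= ke
            # int N'_i N_j over the element
            Q[i, i] += -0.5; Q[i, j] += -0.5
            Q[j, i] += 0.5; Q[j, j] += 0.5
            he = k_elem[e] / l
            H[i, i] += he; H[j, j] += he
            H[i, j] -= he; H[j, i] -= he
        return Kuu, Q, H

    def _solve_step(self, dt: float, *, top_disp: float | None,
                    force: float | None, u_prev: np.ndarray):
        """One backward-Euler step with Picard iteration on k(e)."""
        col = self.column
        n = col.n_nodes
        u = u_prev.copy()
        mu = self.state.mu.copy()
        traction = 0.0 if force is None else -force / col.area
        history = []
        for it in range(self.max_picard):
            if self.strain_dependent:
                e_elem = _element_void_ratios(col, u)
                k_elem = np.array([permeability(e, p) for e, p in
                                   zip(e_elem, col.element_params())])
            else:
                k_elem = np.array([p.k0 for p in col.element_params()])
            Kuu, Q, H = self._assemble(k_elem)

            A = np.zeros((2 * n, 2 * n))
            b = np.zeros(2 * n)
            # equilibrium rows: Kuu u - Q mu = f + Q pi
            A[:n, :n] = Kuu
            A[:n, n:] = -Q
            b[:n] = Q @ col.pi
            b[n - 1] += traction
            # continuity rows: Q^T u + dt H mu = Q^T u_prev
            A[n:, :n] = Q.T
            A[n:, n:] = dt * H
            b[n:] = Q.T @ u_prev

            # Dirichlet: u bottom (and top, if prescribed); mu at both ends
            fixed = {0: 0.0, n: 0.0, 2 * n - 1: 0.0}
            if top_disp is not None:
                fixed[n - 1] = top_disp
            for dof, val in fixed.items():
                A[dof, :] = 0.0
                A[dof, dof] = 1.0
                b[dof] = val

            x = np.linalg.solve(A, b)
            du = np.max(np.abs(x[:n] - u))
            dmu = np.max(np.abs(x[n:] - mu))
            u, mu = x[:n], x[n:]
            scale = max(1.0, np.max(np.abs(mu)), np.max(np.abs(u)))
            history.append(max(du, dmu) / scale)
            if history[-1] < self.newton_tol or not self.strain_dependent:
                break
        else:
            raise ConvergenceError("column Picard loop did not converge",
                                   residual=history[-1], history=history)

        # reaction at the top node from the equilibrium residual (tension +)
        r_top = float((Kuu @ u - Q @ (mu + col.pi))[n - 1])
        reaction = r_top * col.area
        if force is not None:
            reaction = -force
        e_elem = _element_void_ratios(col, u)
        new = ColumnState(
            time=self.state.time + dt, u=u, mu=mu, pi=col.pi,
            e_nodes=_elements_to_nodes(col, e_elem),
            applied_force=(force if force is not None else -reaction),
            top_displacement=(top_disp if top_disp is not None else float(u[-1])),
            reaction=reaction)
        return new

    # -- public API -----------------------------------------------------
    def trial_displacement(self, top_disp: float, dt: float) -> ColumnState:
        """Advance one step with a prescribed top displacement, without
        committing the state."""
        return self._solve_step(dt, top_disp=top_disp, force=None,
                                u_prev=self.state.u)

    def trial_force(self, force: float, dt: float) -> ColumnState:
        """Advance one step under a prescribed axial force (compression
        positive), without committing."""
        return self._solve_step(dt, top_disp=None, force=force,
                                u_prev=self.state.u)

    def linearize(self, top_disp: float, dt: float, h: float = 1e-6):
        """Reaction and finite-difference tangent dR/d(top_disp) for the
        staggered coupling: returns (R0, K_t, trial_state_at_top_disp)."""
        s0 = self.trial_displacement(top_disp, dt)
        s1 = self.trial_displacement(top_disp + h, dt)
        K_t = (s1.reaction - s0.reaction) / h
        return s0.reaction, K_t, s0

    def commit(self, state: ColumnState) -> None:
        self.state = state


def solve_consolidation(column: DiskColumn, load_history, duration: float,
                        dt: float, *, dt_max: float | None = None,
                        growth: float = 1.2,
                        strain_dependent_permeability: bool = True,
                        record_every: int = 1) -> list[ColumnState]:
    """March the column under a force history ``load_history(t) -> N``
    (compression positive) from the fresh state to ``duration`` seconds.

    ``dt`` is the initial step; if ``dt_max`` is given the step grows
    geometrically by ``growth`` up to that cap (adaptive creep stepping).
    Returns the recorded states, starting with the initial one.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    stepper = ColumnStepper(
        column, strain_dependent_permeability=strain_dependent_permeability)
    states = [stepper.state.copy()]
    t, step, i = 0.0, dt, 0
    while t < duration - 1e-9:
        step = min(step, duration - t)
        new = stepper.trial_force(float(load_history(t + step)), step)
        stepper.commit(new)
        t += step
        i += 1
        if i % record_every == 0 or t >= duration - 1e-9:
            states.append(new.copy())
        if dt_max is not None:
            step = min(step * growth, dt_max)
    return states


def intradiscal_pressure(state: ColumnState, column: DiskColumn) -> float:
    """Total fluid pressure at the NP mid-node (MPa): pore (chemical
    potential) part plus the local osmotic contribution.

    Equal-order u-p elements carry a spurious node-to-node pressure zigzag at
    small time steps (the mean is correct); the readout applies the standard
    (1/4, 1/2, 1/4) nodal filter, which removes the checkerboard mode exactly
    and is the identity on smooth fields.
    """
    c = column.np_center_node
    p = state.p
    return float(0.25 * p[c - 1] + 0.5 * p[c] + 0.25 * p[c + 1])


def axial_tangent_stiffness(stepper: ColumnStepper, dt: float,
                            h: float = 1e-6) -> float:
    """Finite-difference tangent of the top reaction force with respect to
    the imposed top displacement over one step of size ``dt`` (N/mm)."""
    base = stepper.state.top_displacement
    if math.isnan(base):
        base = float(stepper.state.u[-1])
    _, K_t, _ = stepper.linearize(base, dt, h=h)
    return K_t
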