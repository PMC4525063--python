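"""Quasi-static scenario engine coupling vertebrae, disks and muscles.

The osteoligamentous L3-S1 segment is reduced to its sagittal plane: rigid
vertebrae L3, L4, L5 with three degrees of freedom each (anteroposterior
translation, axial translation, sagittal rotation about the vertebral
center); S1, the pelvic/sacral muscle insertions and the femoral node are
fixed.  The thoracic rod node rides rigidly on L3 (the thorax rests on the
uppermost modeled vertebra), so rod-inserted fascicles load L3.

Each intervertebral level carries four parallel load paths:

* the osmo-poroelastic disk column (axial, time-dependent; see
  :mod:`spinewell.disk`), driven by the relative axial approach of the
  endplate centers,
* a lumped posterior axial element (supraspinous/interspinous ligaments and
  facets) posterior to the disk,
* lumped rotational and shear springs for the remaining passive resistance,
* the muscle fascicles crossing or inserting at the level.

Muscle activation is stretch-driven: each solver step re-evaluates the
fascicle engineering strain, maps it to the contractile strain
``zeta = C_CE * eps`` and evaluates the uniaxial element force.  Time enters
only through the history of ``eps``; there is no explicit force-velocity
curve.

Time integration is a staggered quasi-static scheme: each disk column is
advanced by backward Euler and linearized (reaction + tangent) about the
current relative displacement, the rigid-body equilibrium is re-solved by
damped Newton with a finite-difference Jacobian, and the loop repeats until
the interface displacements settle; the disk states are then committed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import anatomy
from .anatomy import (FREE_BODIES, LEVELS, FascicleNetwork, GeometryConfig,
                      SpineGeometry, build_geometry, build_network)
from .disk import (DEFAULT_DISK_MATERIALS, ColumnStepper, build_column,
                   intradiscal_pressure)
from .errors import ConfigError, ConvergenceError
from .loads import (DEFAULT_BODY_MASS_KG, STANDARD_GRAVITY, LoadSet,
                    distribute_gravity_loads)
from .muscle import DEFAULT_MATERIALS, contractile_strain, fascicle_axial_force

__all__ = [
    "LevelSprings",
    "SpineModel",
    "ScenarioResult",
    "build_model",
    "solve_quasi_static_step",
    "run_night_rest",
    "run_standing",
    "summarize",
    "compare_scenarios",
]

#: level -> (caudal body, cranial body); "ground" is the fixed sacrum
_LEVEL_BODIES = {"L5/S1": ("ground", "L5"),
                 "L4/L5": ("L5", "L4"),
                 "L3/L4": ("L4", "L3")}

_VERTEBRA_OF_LEVEL = {"L3/L4": "L3", "L4/L5": "L4", "L5/S1": "L5"}


@dataclass(frozen=True)
class LevelSprings:
    """Lumped passive resistance of one intervertebral level.

    The ligaments are represented by two tension-only axial bands: a
    posterior one (interspinous/supraspinous ligaments, ligamentum flavum,
    facet capsules) and an anterior one (anterior longitudinal ligament).
    Both engage under axial distraction (so overnight swelling meets a pure
    axial resistance with no net couple), while sagittal flexion loads only
    the posterior band — the classic source of flexion-induced disk
    compression.  The rotational spring carries the remaining (annulus)
    bending stiffness and the shear spring the anteroposterior coupling.

    Defaults are explicit calibration, not prediction: they are in the
    physiological small-displacement range and keep standing rotations below
    2 degrees.
    """

    k_rot: float = 6.5e4        # N*mm/rad (annulus bending, ~1.1 N*m/deg)
    k_shear: float = 300.0      # N/mm
    k_post: float = 100.0       # N/mm, tension-only posterior band
    post_offset_x: float = -30.0  # mm (posterior of the disk center)
    k_ant: float = 100.0        # N/mm, tension-only anterior band
    ant_offset_x: float = 30.0  # mm (anterior of the disk center)


@dataclass
class SpineModel:
    """Assembled coupled model plus its mutable solver state."""

    geometry: SpineGeometry
    network: FascicleNetwork
    materials: dict
    steppers: dict                       # level -> ColumnStepper
    springs: dict                        # level -> LevelSprings
    load_set: LoadSet | None
    include_muscles: bool = True
    free_bodies: tuple = FREE_BODIES
    q: np.ndarray = None                 # (3 * n_free,) tx, tz, theta per body
    time: float = 0.0
    newton_tol: float = 1e-8
    max_newton: int = 60
    last_rotations: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.q is None:
            self.q = np.zeros(3 * len(self.free_bodies))
        for level in self.steppers:
            lo, up = _LEVEL_BODIES[level]
            if up not in self.free_bodies:
                raise ConfigError(f"disk {level} attached to a fixed vertebra")

    # -- kinematics ------------------------------------------------------
    def body_dofs(self, body: str) -> np.ndarray:
        i = self.free_bodies.index(body)
        return self.q[3 * i:3 * i + 3]

    def poses(self, q: np.ndarray | None = None) -> dict:
        """Rigid transforms (R, t) per attachment label; x -> R x + t.

        Rotation is about the vertebral center.  The thoracic rod node
        follows the translation of L3 (the thorax rides on the uppermost
        modeled vertebra) but not its sagittal tilt: the thorax orientation
        is stabilized by the whole trunk, not slaved to one vertebra.
        """
        q = self.q if q is None else q
        poses = {}
        for i, body in enumerate(self.free_bodies):
            tx, tz, th = q[3 * i:3 * i + 3]
            R = anatomy._roty(th)
            C = self.geometry.frames[body].center
            t = C - R @ C + np.array([tx, 0.0, tz])
            poses[body] = (R, t)
        if "L3" in poses:
            i = self.free_bodies.index("L3")
            tx, tz, _ = q[3 * i:3 * i + 3]
            poses["rod"] = (np.eye(3), np.array([tx, 0.0, tz]))
        return poses

    @property
    def load_scale_reference(self) -> float:
        return self.load_set.total if self.load_set is not None else 0.0


def build_model(body_mass: float = DEFAULT_BODY_MASS_KG,
                include_muscles: bool = True,
                geometry_config: GeometryConfig | None = None,
                muscle_materials: dict | None = None,
                disk_materials: dict | None = None,
                springs: LevelSprings | dict | None = None,
                delta_pi: float = 0.15,
                n_nodes: int = 9,
                g: float = STANDARD_GRAVITY,
                free_bodies: tuple = FREE_BODIES,
                with_gravity: bool = True) -> SpineModel:
    """Assemble the default coupled model (three levels, 46 fascicles)."""
    cfg = geometry_config or GeometryConfig()
    network = build_network(cfg)
    geom = network.geometry
    mats = dict(muscle_materials or DEFAULT_MATERIALS)
    dmats = dict(disk_materials or DEFAULT_DISK_MATERIALS)
    if springs is None:
        springs = LevelSprings()
    if isinstance(springs, LevelSprings):
        springs = {lvl: springs for lvl in LEVELS}

    steppers = {}
    for level in LEVELS:
        lo, up = _LEVEL_BODIES[level]
        if up not in free_bodies:
            continue
        column = build_column(np_height=cfg.np_height,
                              cep_height=cfg.cep_height,
                              area=cfg.disk_area, materials=dmats,
                              delta_pi=delta_pi, n_nodes=n_nodes)
        steppers[level] = ColumnStepper(column)

    load_set = distribute_gravity_loads(body_mass, g=g) if with_gravity else None
    return SpineModel(geometry=geom, network=network, materials=mats,
                      steppers=steppers, springs={l: springs[l] for l in steppers},
                      load_set=load_set, include_muscles=include_muscles,
                      free_bodies=tuple(free_bodies))


# ----------------------------------------------------------------------
# force assembly
# ----------------------------------------------------------------------

def _world(point: np.ndarray, pose) -> np.ndarray:
    if pose is None:
        return point
    R, t = pose
    return R @ point + t


def _disk_elongation(model: SpineModel, level: str, poses: dict) -> float:
    lo, up = _LEVEL_BODIES[level]
    A0, B0 = model.geometry.disk_endpoints[level]
    axis = (B0 - A0) / np.linalg.norm(B0 - A0)
    A = _world(A0, poses.get(lo))
    B = _world(B0, poses.get(up))
    return float((B - A) @ axis - (B0 - A0) @ axis)


def _fascicle_forces(model: SpineModel, poses: dict) -> dict:
    """Per-fascicle mechanical evaluation at the given poses.

    Returns id -> dict(eps, zeta, branch, total, passive, active, matrix,
    unit vector caudal->cranial, endpoint world positions)."""
    if not model.include_muscles:
        return {}
    return {f.id: _fascicle_forces_single(model, f, poses)
            for f in model.network}


def _residual(model: SpineModel, q: np.ndarray, disk_lin: dict,
              load_scale: float) -> np.ndarray:
    """Out-of-balance generalized force per free body (fx, fz, my)."""
    poses = model.poses(q)
    nb = len(model.free_bodies)
    R = np.zeros(3 * nb)
    centers = {}
    for i, b in enumerate(model.free_bodies):
        C = model.geometry.frames[b].center
        tx, tz, _ = q[3 * i:3 * i + 3]
        centers[b] = C + np.array([tx, 0.0, tz])

    def add(body, point, force):
        if body not in centers:
            return
        i = model.free_bodies.index(body)
        r = point - centers[body]
        R[3 * i] += force[0]
        R[3 * i + 1] += force[2]
        R[3 * i + 2] += r[2] * force[0] - r[0] * force[2]

    def add_moment(body, m):
        if body in centers:
            R[3 * model.free_bodies.index(body) + 2] += m

    # gravity loads (ride with the loaded vertebra)
    if model.load_set is not None and load_scale != 0.0:
        for entry in model.load_set.entries:
            body = _VERTEBRA_OF_LEVEL[entry.level]
            if body not in centers:
                continue
            C = model.geometry.frames[body].center
            p_ref = C + np.array([entry.eccentricity, 0.0, 0.0])
            p = _world(p_ref, poses.get(body))
            add(body, p, np.array([0.0, 0.0, -entry.magnitude * load_scale]))

    # disks (linearized about the current step) + lumped level springs
    for level, stepper in model.steppers.items():
        lo, up = _LEVEL_BODIES[level]
        A0, B0 = model.geometry.disk_endpoints[level]
        axis = (B0 - A0) / np.linalg.norm(B0 - A0)
        e_d = _disk_elongation(model, level, poses)
        R0, K_t, e_ref = disk_lin[level]
        tension = R0 + K_t * (e_d - e_ref)
        A = _world(A0, poses.get(lo))
        B = _world(B0, poses.get(up))
        add(up, B, -tension * axis)
        add(lo, A, +tension * axis)

        spr = model.springs[level]
        # tension-only anterior / posterior ligament bands
        for offset, k_band in ((spr.post_offset_x, spr.k_post),
                               (spr.ant_offset_x, spr.k_ant)):
            Pl0 = A0 + np.array([offset, 0.0, 0.0])
            Pu0 = B0 + np.array([offset, 0.0, 0.0])
            Pl = _world(Pl0, poses.get(lo))
            Pu = _world(Pu0, poses.get(up))
            elong = float((Pu - Pl) @ axis - (Pu0 - Pl0) @ axis)
            t_band = k_band * max(elong, 0.0)  # slack under approach
            add(up, Pu, -t_band * axis)
            add(lo, Pl, +t_band * axis)
        # shear spring (anteroposterior relative translation at the disk)
        dx = float(((B - A) - (B0 - A0))[0])
        add(up, B, np.array([-spr.k_shear * dx, 0.0, 0.0]))
        add(lo, A, np.array([+spr.k_shear * dx, 0.0, 0.0]))
        # rotational spring
        th_up = q[3 * model.free_bodies.index(up) + 2] if up in centers else 0.0
        th_lo = q[3 * model.free_bodies.index(lo) + 2] if lo in centers else 0.0
        m = -spr.k_rot * (th_up - th_lo)
        add_moment(up, m)
        add_moment(lo, -m)

    # fascicles
    for f in model.network:
        if not model.include_muscles:
            break
        rec = _fascicle_forces_single(model, f, poses)
        T, u = rec["total"], rec["u"]
        add(_attach_body(model, f.insertion_body), rec["p_i"], -T * u)
        add(_attach_body(model, f.origin_body), rec["p_o"], +T * u)
    return R


def _attach_body(model: SpineModel, label: str) -> str:
    """Rod forces act on L3; fixed labels are absorbed by the ground."""
    if label == "rod":
        return "L3"
    return label


def _fascicle_forces_single(model: SpineModel, f, poses) -> dict:
    p_o = _world(f.origin, poses.get(f.origin_body))
    p_i = _world(f.insertion, poses.get(f.insertion_body))
    d = p_i - p_o
    L = float(np.linalg.norm(d))
    eps = (L - f.L0) / f.L0
    act = contractile_strain(eps, model.materials[f.group])
    total, passive, active, matrix = fascicle_axial_force(
        1.0 + eps, act, model.materials[f.group], f.csa)
    return {"eps": eps, "zeta": act.zeta, "branch": act.branch,
            "total": total, "passive": passive, "active": active,
            "matrix": matrix, "u": d / L, "p_o": p_o, "p_i": p_i}


# ----------------------------------------------------------------------
# quasi-static solve
# ----------------------------------------------------------------------

def _newton(model: SpineModel, q0: np.ndarray, disk_lin: dict,
            load_scale: float) -> np.ndarray:
    """Damped Newton on the rigid-body equilibrium with linearized disks."""
    q = q0.copy()
    scale = max(1.0, model.load_set.total if model.load_set else 1.0)
    tol = model.newton_tol * scale
    hs = np.tile([1e-6, 1e-6, 1e-8], len(model.free_bodies))
    history = []
    r = _residual(model, q, disk_lin, load_scale)
    for it in range(model.max_newton):
        nrm = np.max(np.abs(r))
        history.append(nrm)
        if nrm < tol:
            return q
        J = np.empty((q.size, q.size))
        for j in range(q.size):
            qp = q.copy()
            qp[j] += hs[j]
            J[:, j] = (_residual(model, qp, disk_lin, load_scale) - r) / hs[j]
        try:
            dq = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular equilibrium Jacobian",
                                   residual=nrm, history=history) from exc
        # cap the step to keep the exponential muscle law in range
        cap = np.tile([2.0, 2.0, 0.05], len(model.free_bodies))
        fac = min(1.0, float(np.min(cap / np.maximum(np.abs(dq), 1e-30))))
        for _ in range(12):
            q_try = q + fac * dq
            r_try = _residual(model, q_try, disk_lin, load_scale)
            if np.max(np.abs(r_try)) < nrm or fac < 1e-4:
                q, r = q_try, r_try
                break
            fac *= 0.5
        else:
            q, r = q + fac * dq, _residual(model, q + fac * dq, disk_lin,
                                           load_scale)
    raise ConvergenceError("rigid-body equilibrium did not converge",
                           residual=history[-1], history=history)


def solve_quasi_static_step(model: SpineModel, load_scale: float,
                            dt: float, max_outer: int = 12) -> dict:
    """Advance the coupled model one time step.

    Staggered iteration: linearize every disk column about the current
    relative displacement, re-solve the rigid-body equilibrium, repeat until
    the interface displacements change by < 1e-9 mm, then commit the columns.
    Returns the per-step record used by the scenario result.
    """
    e_ref = {level: _disk_elongation(model, level, model.poses())
             for level in model.steppers}
    q = model.q.copy()
    trial_states = {}
    for outer in range(max_outer):
        disk_lin = {}
        for level, stepper in model.steppers.items():
            R0, K_t, s0 = stepper.linearize(e_ref[level], dt)
            disk_lin[level] = (R0, K_t, e_ref[level])
            trial_states[level] = s0
        q = _newton(model, q, disk_lin, load_scale)
        poses = model.poses(q)
        e_new = {level: _disk_elongation(model, level, poses)
                 for level in model.steppers}
        delta = max(abs(e_new[l] - e_ref[l]) for l in e_new)
        e_ref = e_new
        if delta < 1e-9:
            break
    else:
        raise ConvergenceError("staggered disk/skeleton loop did not settle",
                               residual=delta)

    for level, stepper in model.steppers.items():
        final = stepper.trial_displacement(e_ref[level], dt)
        stepper.commit(final)
        trial_states[level] = final
    model.q = q
    model.time += dt
    model.last_rotations = {b: model.body_dofs(b)[2] for b in model.free_bodies}

    poses = model.poses()
    fasc = _fascicle_forces(model, poses)
    record = {
        "time": model.time,
        "fascicles": fasc,
        "idp": {level: intradiscal_pressure(stepper.state, stepper.column)
                for level, stepper in model.steppers.items()},
        "elongation": dict(e_ref),
        "q": model.q.copy(),
        "load_scale": load_scale,
    }
    record["level_resultant"] = _level_resultants(model, fasc)
    return record


def _level_resultants(model: SpineModel, fasc: dict) -> dict:
    """Vector sum of the fascicle forces applied to each level's vertebra
    (the total intra-level muscle force)."""
    out = {}
    for level in model.steppers:
        vert = _VERTEBRA_OF_LEVEL[level]
        total = np.zeros(3)
        for f in model.network.select(level=level):
            rec = fasc.get(f.id)
            if rec is None:
                continue
            T, u = rec["total"], rec["u"]
            # force applied at the fascicle's own vertebral endpoint
            if f.insertion_body == vert:
                total += -T * u
            elif f.origin_body == vert:
                total += +T * u
        out[level] = {"vector": total, "magnitude": float(np.linalg.norm(total))}
    return out


# ----------------------------------------------------------------------
# scenarios
# ----------------------------------------------------------------------

@dataclass
class ScenarioResult:
    """Recorded time series of one scenario run."""

    scenario: str
    records: list

    @property
    def times(self) -> np.ndarray:
        return np.array([r["time"] for r in self.records])

    def final(self) -> dict:
        return self.records[-1]

    def idp_series(self) -> pd.DataFrame:
        rows = [{"time_s": r["time"], **{f"idp_{l.replace('/', '')}": v
                 for l, v in r["idp"].items()}} for r in self.records]
        return pd.DataFrame(rows)

    def fascicle_table(self, index: int = -1) -> pd.DataFrame:
        r = self.records[index]
        rows = []
        for fid, rec in r["fascicles"].items():
            rows.append({"id": fid, "eps": rec["eps"], "zeta": rec["zeta"],
                         "branch": rec["branch"],
                         "total_N": rec["total"], "active_N": rec["active"],
                         "passive_N": rec["passive"], "matrix_N": rec["matrix"]})
        return pd.DataFrame(rows)

    def level_table(self, index: int = -1) -> pd.DataFrame:
        r = self.records[index]
        rows = []
        for level in r["idp"]:
            res = r["level_resultant"].get(level, {"magnitude": 0.0})
            rows.append({"level": level, "idp_MPa": r["idp"][level],
                         "muscle_resultant_N": res["magnitude"]})
        return pd.DataFrame(rows)


def run_night_rest(model: SpineModel, hours: float = 8.0,
                   dt0: float = 1.0, dt_max: float = 600.0,
                   growth: float = 1.2) -> ScenarioResult:
    """Free overnight swelling: no gravity, the osmotic gradient draws water
    into the disks, distracting the segment and stretching the fascicles."""
    duration = hours * 3600.0
    records = []
    t, dt = 0.0, dt0
    while t < duration - 1e-6:
        dt = min(dt, duration - t)
        records.append(solve_quasi_static_step(model, 0.0, dt))
        t += dt
        dt = min(dt * growth, dt_max)
    return ScenarioResult("night_rest", records)


def run_standing(model: SpineModel, ramp_seconds: float = 60.0,
                 with_prior_rest: bool = False, rest_hours: float = 8.0,
                 n_steps: int = 30) -> ScenarioResult:
    """Standing: the distributed gravity load is ramped linearly over
    ``ramp_seconds``, optionally starting from the overnight-rest state."""
    if model.load_set is None:
        raise ConfigError("standing requires a gravity load set")
    if with_prior_rest:
        run_night_rest(model, hours=rest_hours)
    dt = ramp_seconds / n_steps
    records = []
    for i in range(1, n_steps + 1):
        scale = i / n_steps
        records.append(solve_quasi_static_step(model, scale, dt))
    name = "standing_after_rest" if with_prior_rest else "standing"
    return ScenarioResult(name, records)


def summarize(result: ScenarioResult) -> dict:
    """CSV-ready summary tables: per-fascicle forces at the final state,
    per-level totals, and the IDP time series."""
    if not result.records:
        empty = pd.DataFrame()
        return {"fascicles": empty, "levels": empty, "idp_series": empty}
    return {"fascicles": result.fascicle_table(),
            "levels": result.level_table(),
            "idp_series": result.idp_series()}


def compare_scenarios(a: ScenarioResult, b: ScenarioResult) -> dict:
    """Relative changes of scenario ``b`` with respect to ``a``.

    Reports per-level IDP percentage change, per-group summed active-force
    percentage change, and the per-level muscle-resultant change.
    """
    ra, rb = a.final(), b.final()
    if set(ra["idp"]) != set(rb["idp"]) or set(ra["fascicles"]) != set(rb["fascicles"]):
        raise ConfigError("scenario results have different topology")

    idp_rows = []
    for level in ra["idp"]:
        va, vb = ra["idp"][level], rb["idp"][level]
        pct = math.inf if va == 0 and vb != 0 else (
            0.0 if va == 0 else 100.0 * (vb - va) / abs(va))
        idp_rows.append({"level": level, "idp_a": va, "idp_b": vb,
                         "pct_change": pct})

    groups = sorted({fid.split("-")[0] for fid in ra["fascicles"]})
    grp_rows = []
    for g in groups:
        fa = sum(rec["active"] for fid, rec in ra["fascicles"].items()
                 if fid.startswith(g + "-"))
        fb = sum(rec["active"] for fid, rec in rb["fascicles"].items()
                 if fid.startswith(g + "-"))
        pct = math.inf if fa == 0 and fb != 0 else (
            0.0 if fa == 0 else 100.0 * (fb - fa) / abs(fa))
        grp_rows.append({"group": g, "active_a": fa, "active_b": fb,
                         "pct_change": pct})

    res_rows = []
    for level in ra["level_resultant"]:
        ma = ra["level_resultant"][level]["magnitude"]
        mb = rb["level_resultant"][level]["magnitude"]
        pct = math.inf if ma == 0 and mb != 0 else (
            0.0 if ma == 0 else 100.0 * (mb - ma) / abs(ma))
        res_rows.append({"level": level, "resultant_a": ma, "resultant_b": mb,
                         "pct_change": pct})

    return {"idp": pd.DataFrame(idp_rows),
            "group_active": pd.DataFrame(grp_rows),
            "level_resultant": pd.DataFrame(res_rows)}
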