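"""46-fascicle L3-S1 muscle network on a synthetic lordotic geometry.

Five muscle groups act on the modeled lumbar segment: the multifidus (MF,
8 fascicle pairs, three anteroposterior sub-groups), the lumbar parts of the
longissimus thoracis (LTpL, 3 pairs) and of the iliocostalis lumborum (ILpL,
2 pairs), the thoracic part of the longissimus (LTpTh, 4 pairs, all reaching
a common rostral node on a rigid thoracic rod), and the psoas major (PS,
6 overlapping segmental pairs converging on a common femoral node).  That is
13 local pairs (attached to lumbar vertebrae only) and 10 global pairs
(reaching the ribcage or the femur), 46 fascicles in total, sagittally
mirror-symmetric.  Every fascicle is a straight unidirectional line of
action between two insertion points.

The exact subject-specific 3D insertion coordinates are not published, so
this module generates a SYNTHETIC but anatomically plausible geometry from a
small set of configurable offsets (spinous process, lamina, transverse /
accessory process, anterolateral vertebral body) applied to a lordotic
L3-S1 chain.  Topology, pair counts and the insertion-code id scheme
(SP / LAM / VB with A/B variants) are fixed; all coordinates and
cross-sectional areas are explicit configuration that can be swapped for
subject-specific data.

Coordinate convention (documented once, used everywhere): right-handed,
x anterior, y left, z cranial; origin at the center of the S1 upper
endplate; millimetres.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "GeometryConfig",
    "SpineGeometry",
    "Fascicle",
    "FascicleNetwork",
    "build_geometry",
    "build_network",
    "equivalent_csa",
    "fascicle_strain",
    "line_of_action",
    "LEVELS",
    "FREE_BODIES",
]

LEVELS = ("L3/L4", "L4/L5", "L5/S1")
FREE_BODIES = ("L3", "L4", "L5")
LOCAL_GROUPS = frozenset({"MF", "LTpL", "ILpL"})
GLOBAL_GROUPS = frozenset({"LTpTh", "PS"})


@dataclass(frozen=True)
class GeometryConfig:
    """Parameters of the synthetic lordotic L3-S1 chain.

    Lordosis angles are segmental extension tilts (degrees); the L5/S1 angle
    is proportional to the L4/L5 one through ``lordosis_l5s1_ratio`` (the
    anatomical proportion is configurable, not hard-coded).
    """

    vertebral_body_height: float = 28.0   # mm
    np_height: float = 8.0                # nucleus pulposus height, mm
    cep_height: float = 0.8               # each cartilage endplate, mm
    disk_area: float = 1800.0             # effective axial disk area, mm^2
    lordosis_l4l5_deg: float = 8.0
    lordosis_l5s1_ratio: float = 1.4      # L5/S1 lordosis = ratio * L4/L5
    lordosis_l3l4_deg: float = 6.0
    rod_posterior_offset: float = 80.0    # thoracic rod node, mm posterior of L3
    rod_y: float = 25.0
    #: local insertion-site offsets in the vertebra frame (x ant, y left, z cran)
    site_offsets: dict = field(default_factory=lambda: {
        "SP_A": (-58.0, 6.0, 2.0),
        "SP_B": (-55.0, 9.0, -3.0),
        "LAM": (-28.0, 8.0, 6.0),
        "TP": (-20.0, 34.0, 6.0),
        "ACC": (-22.0, 30.0, 8.0),
        "VB_A": (10.0, 20.0, 6.0),
        "VB_B": (12.0, 22.0, -6.0),
    })
    #: fixed caudal nodes (left side; right is mirrored), model frame
    femoral_node: tuple = (12.0, 42.0, -140.0)
    iliac_node_lt: tuple = (-35.0, 42.0, -15.0)
    iliac_node_il: tuple = (-30.0, 48.0, -18.0)
    sacral_nodes: dict = field(default_factory=lambda: {
        "S-A": (-52.0, 6.0, -18.0),
        "S-B": (-49.0, 8.0, -28.0),
        "S-C": (-43.0, 5.0, -8.0),
        "S-D": (-49.0, 6.0, -25.0),
        "S-E": (-47.0, 8.0, -35.0),
        "S-F": (-41.0, 5.0, -15.0),
        "S-G": (-47.0, 6.0, -30.0),
        "S-H": (-39.0, 5.0, -20.0),
    })
    #: per-fascicle equivalent cross-sectional areas (mm^2), keyed by base id
    csa_table: dict = field(default_factory=lambda: {
        "MF-L3-SP-A": 95.0, "MF-L3-SP-B": 90.0, "MF-L3-LAM": 60.0,
        "MF-L4-SP-A": 100.0, "MF-L4-SP-B": 95.0, "MF-L4-LAM": 65.0,
        "MF-L5-SP": 110.0, "MF-L5-LAM": 70.0,
        "LTpL-L3": 70.0, "LTpL-L4": 90.0, "LTpL-L5": 110.0,
        "ILpL-L3": 100.0, "ILpL-L4": 110.0,
        "LTpTh-L3": 60.0, "LTpTh-L4": 60.0, "LTpTh-L5-A": 55.0,
        "LTpTh-L5-B": 55.0,
        "PS-L3-VB-A": 90.0, "PS-L3-VB-B": 90.0, "PS-L4-VB-A": 90.0,
        "PS-L4-VB-B": 90.0, "PS-L5-VB-A": 90.0, "PS-L5-VB-B": 90.0,
    })
    #: optional per-fascicle insertion-point overrides keyed by full id
    #: (including the -L / -R side suffix); both sides of a pair must be given
    insertion_overrides: dict | None = None
    csa_overrides: dict | None = None

    @property
    def disk_height(self) -> float:
        return self.np_height + 2.0 * self.cep_height


def _roty(theta: float) -> np.ndarray:
    """Rotation about +y (left); positive theta tilts anterior points caudally
    (sagittal flexion)."""
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


@dataclass(frozen=True)
class VertebraFrame:
    label: str
    center: np.ndarray      # vertebral center (VC)
    tilt: float             # reference sagittal tilt, rad (extension negative)

    def point(self, offset) -> np.ndarray:
        return self.center + _roty(self.tilt) @ np.asarray(offset, dtype=float)


@dataclass(frozen=True)
class SpineGeometry:
    """Reference frames, disk endpoints, and fixed nodes of the chain."""

    config: GeometryConfig
    frames: dict            # body label -> VertebraFrame
    disk_endpoints: dict    # level -> (caudal point, cranial point)
    rod_node_left: np.ndarray
    total_lordosis_deg: float


def build_geometry(config: GeometryConfig | None = None) -> SpineGeometry:
    """Stack S1 -> L5 -> L4 -> L3 along a lordotic arc.

    The thoracic rod node is placed at the same cranio-caudal coordinate as
    L3 in the reference standing pose, posterior of its center.
    """
    cfg = config or GeometryConfig()
    if cfg.np_height <= 0 or cfg.cep_height <= 0 or cfg.disk_area <= 0:
        raise ConfigError("disk dimensions must be positive")
    if cfg.vertebral_body_height <= 0:
        raise ConfigError("vertebral body height must be positive")

    ang_l5s1 = math.radians(cfg.lordosis_l5s1_ratio * cfg.lordosis_l4l5_deg)
    ang_l4l5 = math.radians(cfg.lordosis_l4l5_deg)
    ang_l3l4 = math.radians(cfg.lordosis_l3l4_deg)

    frames: dict[str, VertebraFrame] = {}
    disk_endpoints: dict[str, tuple] = {}
    cursor = np.zeros(3)   # S1 upper endplate center
    tilt = 0.0
    for level, body, ang in (("L5/S1", "L5", ang_l5s1),
                             ("L4/L5", "L4", ang_l4l5),
                             ("L3/L4", "L3", ang_l3l4)):
        tilt -= ang  # lordosis: each segment tilts into extension
        axis = _roty(tilt) @ np.array([0.0, 0.0, 1.0])
        caudal = cursor.copy()
        cranial = caudal + cfg.disk_height * axis
        disk_endpoints[level] = (caudal, cranial)
        center = cranial + 0.5 * cfg.vertebral_body_height * axis
        frames[body] = VertebraFrame(body, center, tilt)
        cursor = cranial + cfg.vertebral_body_height * axis

    rod = frames["L3"].center + np.array(
        [-cfg.rod_posterior_offset, cfg.rod_y, 0.0])
    # rod node shares L3's cranio-caudal coordinate in the reference pose
    rod[2] = frames["L3"].center[2]
    total = math.degrees(ang_l5s1 + ang_l4l5 + ang_l3l4)
    return SpineGeometry(cfg, frames, disk_endpoints, rod, total)


@dataclass(frozen=True)
class Fascicle:
    """One straight unidirectional muscle element.

    ``origin`` is the caudal endpoint, ``insertion`` the cranial one; each
    carries the label of the rigid body (or fixed node set) it rides on.
    """

    id: str
    group: str
    side: str               # "left" | "right"
    origin: np.ndarray
    insertion: np.ndarray
    origin_body: str
    insertion_body: str
    L0: float
    csa: float
    level: str              # disk level the fascicle is reported under
    subgroup: str | None = None

    @property
    def scope(self) -> str:
        return "local" if self.group in LOCAL_GROUPS else "global"


class FascicleNetwork:
    """Ordered collection of the 46 fascicles with group/level/side lookup."""

    def __init__(self, fascicles: list[Fascicle], geometry: SpineGeometry):
        self.fascicles = list(fascicles)
        self.geometry = geometry
        self._by_id = {f.id: f for f in self.fascicles}
        if len(self._by_id) != len(self.fascicles):
            raise ConfigError("duplicate fascicle ids")

    def __len__(self):
        return len(self.fascicles)

    def __iter__(self):
        return iter(self.fascicles)

    def __getitem__(self, fid: str) -> Fascicle:
        return self._by_id[fid]

    def select(self, group=None, side=None, level=None, scope=None):
        out = self.fascicles
        if group is not None:
            out = [f for f in out if f.group == group]
        if side is not None:
            out = [f for f in out if f.side == side]
        if level is not None:
            out = [f for f in out if f.level == level]
        if scope is not None:
            out = [f for f in out if f.scope == scope]
        return out

    def pairs(self):
        """Left/right partner pairs, ordered by base id."""
        left = [f for f in self.fascicles if f.side == "left"]
        return [(f, self._by_id[f.id[:-2] + "-R"]) for f in left]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for f in self.fascicles:
            rows.append({
                "id": f.id, "group": f.group, "side": f.side,
                "scope": f.scope, "level": f.level, "subgroup": f.subgroup,
                "ox": f.origin[0], "oy": f.origin[1], "oz": f.origin[2],
                "ix": f.insertion[0], "iy": f.insertion[1], "iz": f.insertion[2],
                "L0": f.L0, "csa": f.csa,
            })
        return pd.DataFrame(rows)

    def to_csv(self, path_or_buf) -> None:
        self.to_dataframe().to_csv(path_or_buf, index=False)


def equivalent_csa(volume: float, length: float) -> float:
    """Equivalent cross-sectional area: fascicle volume / fascicle length."""
    if length <= 0:
        raise ValueError("fascicle length must be positive")
    if volume < 0:
        raise ValueError("fascicle volume must be non-negative")
    return volume / length


def _fascicle_plan(geom: SpineGeometry):
    """Left-side fascicle blueprint: (base id, group, cranial spec,
    caudal spec, subgroup).  A spec is (body_label, site) for vertebral
    attachments or (fixed_label, point) for fixed nodes."""
    cfg = geom.config
    sac = cfg.sacral_nodes
    plan = [
        # -- multifidus: cranial on SP/lamina, caudal on the sacrum ---------
        ("MF-L3-SP-A", "MF", ("L3", "SP_A"), ("sacrum", sac["S-A"]), "superficial"),
        ("MF-L3-SP-B", "MF", ("L3", "SP_B"), ("sacrum", sac["S-B"]), "intermediate"),
        ("MF-L3-LAM", "MF", ("L3", "LAM"), ("sacrum", sac["S-C"]), "deep"),
        ("MF-L4-SP-A", "MF", ("L4", "SP_A"), ("sacrum", sac["S-D"]), "superficial"),
        ("MF-L4-SP-B", "MF", ("L4", "SP_B"), ("sacrum", sac["S-E"]), "intermediate"),
        ("MF-L4-LAM", "MF", ("L4", "LAM"), ("sacrum", sac["S-F"]), "deep"),
        ("MF-L5-SP", "MF", ("L5", "SP_A"), ("sacrum", sac["S-G"]), "intermediate"),
        ("MF-L5-LAM", "MF", ("L5", "LAM"), ("sacrum", sac["S-H"]), "deep"),
        # -- longissimus thoracis pars lumborum: accessory process -> ilium -
        ("LTpL-L3", "LTpL", ("L3", "ACC"), ("ilium", cfg.iliac_node_lt), None),
        ("LTpL-L4", "LTpL", ("L4", "ACC"), ("ilium", cfg.iliac_node_lt), None),
        ("LTpL-L5", "LTpL", ("L5", "ACC"), ("ilium", cfg.iliac_node_lt), None),
        # -- iliocostalis lumborum pars lumborum: transverse proc -> ilium --
        ("ILpL-L3", "ILpL", ("L3", "TP"), ("ilium", cfg.iliac_node_il), None),
        ("ILpL-L4", "ILpL", ("L4", "TP"), ("ilium", cfg.iliac_node_il), None),
        # -- longissimus thoracis pars thoracis: lumbar TP -> thoracic rod --
        ("LTpTh-L3", "LTpTh", ("rod", geom.rod_node_left), ("L3", "TP"), None),
        ("LTpTh-L4", "LTpTh", ("rod", geom.rod_node_left), ("L4", "TP"), None),
        ("LTpTh-L5-A", "LTpTh", ("rod", geom.rod_node_left), ("L5", "TP"), None),
        ("LTpTh-L5-B", "LTpTh", ("rod", geom.rod_node_left), ("L5", "ACC"), None),
        # -- psoas major: anterolateral vertebral body -> femoral node ------
        ("PS-L3-VB-A", "PS", ("L3", "VB_A"), ("femur", cfg.femoral_node), None),
        ("PS-L3-VB-B", "PS", ("L3", "VB_B"), ("femur", cfg.femoral_node), None),
        ("PS-L4-VB-A", "PS", ("L4", "VB_A"), ("femur", cfg.femoral_node), None),
        ("PS-L4-VB-B", "PS", ("L4", "VB_B"), ("femur", cfg.femoral_node), None),
        ("PS-L5-VB-A", "PS", ("L5", "VB_A"), ("femur", cfg.femoral_node), None),
        ("PS-L5-VB-B", "PS", ("L5", "VB_B"), ("femur", cfg.femoral_node), None),
    ]
    return plan


def _resolve(geom: SpineGeometry, spec, mirror: bool):
    """Resolve an endpoint spec to (point, attachment label)."""
    label, what = spec
    if label in FREE_BODIES:
        p = geom.frames[label].point(what if not isinstance(what, str)
                                     else geom.config.site_offsets[what])
        body = label
    else:
        p = np.asarray(what, dtype=float).copy()
        body = label
    if mirror:
        p = p * np.array([1.0, -1.0, 1.0])
    return p, body


def _vertebra_of(plan_entry) -> str:
    """Lumbar vertebra a fascicle is reported under (its level key)."""
    _, group, cranial, caudal, _ = plan_entry
    for spec in (cranial, caudal):
        if spec[0] in FREE_BODIES and group != "LTpTh":
            return spec[0]
    # LTpTh: reported under its lumbar (caudal) insertion
    return caudal[0]


_LEVEL_OF_BODY = {"L3": "L3/L4", "L4": "L4/L5", "L5": "L5/S1"}


def build_network(config: GeometryConfig | None = None) -> FascicleNetwork:
    """Assemble the 46-fascicle network on the synthetic geometry.

    Raises :class:`ConfigError` when an insertion override is missing its
    mirror partner or names an unknown fascicle.
    """
    cfg = config or GeometryConfig()
    geom = build_geometry(cfg)
    plan = _fascicle_plan(geom)

    overrides = dict(cfg.insertion_overrides or {})
    known_ids = {f"{base}-{s}" for base, *_ in plan for s in ("L", "R")}
    unknown = set(overrides) - known_ids
    if unknown:
        raise ConfigError(f"insertion overrides for unknown fascicles: {sorted(unknown)}")
    for fid in overrides:
        partner = fid[:-2] + ("-R" if fid.endswith("-L") else "-L")
        if partner not in overrides:
            raise ConfigError(
                f"insertion override for {fid} has no sagittal partner {partner}")

    csa_table = dict(cfg.csa_table)
    if cfg.csa_overrides:
        bad = set(cfg.csa_overrides) - set(csa_table)
        if bad:
            raise ConfigError(f"csa overrides for unknown fascicles: {sorted(bad)}")
        csa_table.update(cfg.csa_overrides)

    fascicles = []
    for entry in plan:
        base, group, cranial_spec, caudal_spec, subgroup = entry
        vert = _vertebra_of(entry)
        for side, suffix in (("left", "L"), ("right", "R")):
            mirror = side == "right"
            fid = f"{base}-{suffix}"
            cranial, cranial_body = _resolve(geom, cranial_spec, mirror)
            caudal, caudal_body = _resolve(geom, caudal_spec, mirror)
            if fid in overrides:
                ov = overrides[fid]
                if "origin" in ov:
                    caudal = np.asarray(ov["origin"], dtype=float)
                if "insertion" in ov:
                    cranial = np.asarray(ov["insertion"], dtype=float)
            L0 = float(np.linalg.norm(cranial - caudal))
            if L0 <= 0:
                raise ConfigError(f"fascicle {fid} has coincident endpoints")
            csa = csa_table.get(base)
            if csa is None or csa <= 0:
                raise ConfigError(f"missing or non-positive csa for fascicle {base}")
            fascicles.append(Fascicle(
                id=fid, group=group, side=side,
                origin=caudal, insertion=cranial,
                origin_body=caudal_body, insertion_body=cranial_body,
                L0=L0, csa=float(csa),
                level=_LEVEL_OF_BODY[vert], subgroup=subgroup))
    return FascicleNetwork(fascicles, geom)


# ----------------------------------------------------------------------
# kinematic queries
# ----------------------------------------------------------------------

def _transform(point: np.ndarray, pose) -> np.ndarray:
    if pose is None:
        return point
    R, t = pose
    return np.asarray(R, dtype=float) @ point + np.asarray(t, dtype=float)


def fascicle_strain(network: FascicleNetwork, poses: dict) -> dict:
    """Engineering strain eps = (L - L0)/L0 of every fascicle under rigid
    poses of the attachment bodies.

    ``poses`` maps attachment labels ("L3", "L4", "L5", "sacrum", "ilium",
    "femur", "rod") to rigid transforms ``(R, t)`` acting as x -> R x + t;
    missing labels stay at identity.  All strains are zero in the reference
    pose.
    """
    out = {}
    for f in network:
        p_o = _transform(f.origin, poses.get(f.origin_body))
        p_i = _transform(f.insertion, poses.get(f.insertion_body))
        L = float(np.linalg.norm(p_i - p_o))
        out[f.id] = (L - f.L0) / f.L0
    return out


def line_of_action(fascicle: Fascicle, poses: dict, center) -> tuple:
    """Current unit line of action (caudal -> cranial) and the moment arm
    (perpendicular distance, mm) of the line about ``center``."""
    p_o = _transform(fascicle.origin, poses.get(fascicle.origin_body))
    p_i = _transform(fascicle.insertion, poses.get(fascicle.insertion_body))
    d = p_i - p_o
    L = float(np.linalg.norm(d))
    if L < 1e-12:
        raise ConfigError(f"fascicle {fascicle.id} has zero length")
    u = d / L
    r = np.asarray(center, dtype=float) - p_o
    arm = float(np.linalg.norm(np.cross(r, u)))
    return u, arm
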