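"""Distributed eccentric gravity loads for the standing scenario.

The upper-body weight acting on an L3-S1 segment is represented by three
vertical point loads: everything from the head down to L3 is lumped into one
load applied at the L3/L4 level, at an effective anterior eccentricity
R_eff; the L4 and L5 segment masses load their own levels at their local
eccentricities.  Segment masses come from percent-of-body-mass data
(head/cervical from crash-dummy inertial studies, thoracolumbar from
radiographic densitometry); the parallel-axis (Huygens-Steiner) theorem
transfers the segmental sagittal moments of inertia to the L3/L4 axis.

Units: masses kg, inertias kg*cm^2, distances d in cm, eccentricities mm,
forces N, g in m/s^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "BodySegmentRow",
    "LoadSet",
    "load_segment_table",
    "scale_masses",
    "steiner_inertia",
    "effective_inertia_L3",
    "effective_eccentricity",
    "distribute_gravity_loads",
    "STANDARD_GRAVITY",
    "DEFAULT_BODY_MASS_KG",
]

STANDARD_GRAVITY = 9.81          # m/s^2
DEFAULT_BODY_MASS_KG = 70.8      # normal-subject body mass used throughout

#: rows lumped into the L3/L4 load (head and cervical through L3)
_UPPER_LABELS = ("HD", "C1", "C2", "C3", "C4", "C5", "C6", "C7",
                 "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9",
                 "T10", "T11", "T12", "L1", "L2", "L3")
#: rows contributing parallel-axis terms to the effective L3/L4 inertia
#: (head/cervical d^2 is negligible and excluded by construction)
_STEINER_LABELS = ("T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9",
                   "T10", "T11", "T12", "L1", "L2")


@dataclass(frozen=True)
class BodySegmentRow:
    """One body segment: mass percentage, own-axis inertia and (optionally)
    its parallel-axis transfer to L3/L4 and its COM eccentricity."""

    label: str
    bm_percent: float
    iz: float | None = None        # kg*cm^2 about the segment's own COM axis
    iz_L3: float | None = None     # kg*cm^2 about the L3/L4 COM axis
    d: float | None = None         # axis distance, cm
    r: float | None = None         # VC->COM anterior eccentricity, mm

    def __post_init__(self):
        if self.bm_percent < 0:
            raise ValueError("segment mass percentage must be non-negative")


@dataclass(frozen=True)
class LoadEntry:
    level: str          # "L3/L4" | "L4/L5" | "L5/S1"
    magnitude: float    # N, downward
    eccentricity: float  # mm anterior to the segmental vertebral center


@dataclass(frozen=True)
class LoadSet:
    entries: tuple

    @property
    def total(self) -> float:
        return sum(e.magnitude for e in self.entries)

    def by_level(self) -> dict:
        return {e.level: e for e in self.entries}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"level": e.level, "magnitude_N": e.magnitude,
              "eccentricity_mm": e.eccentricity} for e in self.entries])


def load_segment_table(path: str | Path | None = None) -> list[BodySegmentRow]:
    """Read the shipped (or a user) body-segment CSV into rows."""
    if path is None:
        src = resources.files("spinewell.data") / "body_segments.csv"
        with resources.as_file(src) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    rows = []
    for rec in df.itertuples(index=False):
        def opt(v):
            return None if pd.isna(v) else float(v)
        rows.append(BodySegmentRow(
            label=str(rec.label), bm_percent=float(rec.bm_percent),
            iz=opt(rec.iz), iz_L3=opt(rec.iz_l3), d=opt(rec.d_cm),
            r=opt(rec.r_mm)))
    return rows


def scale_masses(total_body_mass: float, table: list[BodySegmentRow]) -> dict:
    """Per-segment masses (kg) scaled from the percentage column.

    The percentages are authoritative; any absolute mass column in the source
    data is ignored.
    """
    if total_body_mass < 0:
        raise ValueError("body mass must be non-negative")
    return {row.label: row.bm_percent / 100.0 * total_body_mass for row in table}


def steiner_inertia(mass: float, d: float) -> float:
    """Parallel-axis transfer term m * d^2 (kg*cm^2)."""
    if mass < 0:
        raise ValueError("mass must be non-negative")
    return mass * d * d


def effective_inertia_L3(table: list[BodySegmentRow],
                         iz_local_L3: float) -> float:
    """Effective sagittal inertia about the L3/L4 COM axis: the sum of the 14
    parallel-axis contributions T1..L2 plus the local L3/L4 term.

    Head/cervical rows are excluded: their axis distances are second-order
    small, so their transfer terms are negligible.
    """
    by_label = {row.label: row for row in table}
    missing = [lab for lab in _STEINER_LABELS
               if lab not in by_label or by_label[lab].iz_L3 is None]
    if missing:
        raise ConfigError(
            f"iz_L3 entries required for rows {missing} are missing")
    return sum(by_label[lab].iz_L3 for lab in _STEINER_LABELS) + iz_local_L3


def effective_eccentricity(table: list[BodySegmentRow],
                           total_body_mass: float = DEFAULT_BODY_MASS_KG,
                           labels: tuple = _UPPER_LABELS) -> float:
    """Mass-weighted mean anterior eccentricity R_eff = sum(m_i r_i)/sum(m_i)
    of the contributing segments (mm).

    With the shipped (calibrated) r-data and the default configuration this
    returns 41.4 mm for the lumped HD..L3 load.
    """
    masses = scale_masses(total_body_mass, table)
    by_label = {row.label: row for row in table}
    contributing = [lab for lab in labels
                    if lab in by_label and by_label[lab].r is not None]
    if not contributing:
        raise ConfigError("no rows with eccentricity data to average over")
    m = np.array([masses[lab] for lab in contributing])
    r = np.array([by_label[lab].r for lab in contributing])
    if m.sum() <= 0:
        raise ConfigError("contributing segment masses sum to zero")
    return float((m * r).sum() / m.sum())


def distribute_gravity_loads(total_body_mass: float = DEFAULT_BODY_MASS_KG,
                             table: list[BodySegmentRow] | None = None,
                             g: float = STANDARD_GRAVITY) -> LoadSet:
    """Three-point distributed gravity load for the standing scenario.

    L3/L4 carries the lumped weight of everything from the head to L3 at the
    effective eccentricity R_eff; L4/L5 and L5/S1 carry their own segment
    weights at their local eccentricities.  With the default 70.8 kg subject
    and g = 9.81 m/s^2 the totals are ~276 N = ~239 N + 18.1 N + 18.1 N.
    """
    if total_body_mass <= 0:
        raise ValueError("body mass must be positive")
    if table is None:
        table = load_segment_table()
    masses = scale_masses(total_body_mass, table)
    by_label = {row.label: row for row in table}

    upper_mass = sum(masses[lab] for lab in _UPPER_LABELS if lab in masses)
    r_eff = effective_eccentricity(table, total_body_mass)

    def local_ecc(lab):
        row = by_label.get(lab)
        if row is None or row.r is None:
            raise ConfigError(f"missing eccentricity for segment {lab}")
        return row.r

    entries = (
        LoadEntry("L3/L4", g * upper_mass, r_eff),
        LoadEntry("L4/L5", g * masses.get("L4", 0.0), local_ecc("L4")),
        LoadEntry("L5/S1", g * masses.get("L5", 0.0), local_ecc("L5")),
    )
    return LoadSet(entries)
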