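"""Lung-segment flow allocation and active-breathing boundary conditions.

Active expiration is simulated by driving the small-airway orifices as
velocity inlets and the large-airway (tracheal) orifice as a zero-pressure
outlet.  The total expiratory flow is distributed over the 18
bronchopulmonary segments according to the classical fixed
function-proportion table; a segment's flow is split among the model
outlets that drain it (the tree is truncated at generation 5-8, so a
segment may own several orifices, or several segments one orifice).

The stenotic model is then driven by the *pressures* computed at those
orifices in the normal-geometry run (the equal-pressure assumption): this
module only exports/imports those boundary tables — the flow solve itself
happens in external CFD software.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# 18-segment lung function proportions (percent of total ventilation).
# Classical fixed-proportion table; the raw values sum to 99.2 %.
SEGMENT_FRACTIONS_RAW: dict[str, float] = {
    # left upper lobe
    "LUL_apical_posterior": 6.0,
    "LUL_anterior": 6.0,
    "LUL_superior_lingular": 4.3,
    "LUL_inferior_lingular": 4.3,
    # left lower lobe
    "LLL_dorsal": 6.1,
    "LLL_anteromedial_basal": 6.1,
    "LLL_lateral_basal": 6.1,
    "LLL_posterior_basal": 6.1,
    # right upper lobe
    "RUL_apical": 6.9,
    "RUL_posterior": 6.9,
    "RUL_anterior": 6.9,
    # right middle lobe
    "RML_lateral": 4.5,
    "RML_medial": 4.5,
    # right lower lobe
    "RLL_dorsal": 4.9,
    "RLL_anterior_basal": 4.9,
    "RLL_medial_basal": 4.9,
    "RLL_lateral_basal": 4.9,
    "RLL_posterior_basal": 4.9,
}

LOBE_OF_SEGMENT = {name: name.split("_", 1)[0] for name in SEGMENT_FRACTIONS_RAW}


@dataclass
class SegmentFractionTable:
    """Per-segment ventilation fractions (as proportions, not percent)."""

    fractions: dict[str, float]
    normalized: bool

    def __post_init__(self):
        if len(self.fractions) != 18:
            raise ValueError(f"expected 18 segments, got {len(self.fractions)}")
        if any(f <= 0 for f in self.fractions.values()):
            raise ValueError("fractions must be > 0")
        if self.normalized and abs(sum(self.fractions.values()) - 1.0) > 1e-12:
            raise ValueError("normalized table must sum to 1")

    def normalize(self) -> "SegmentFractionTable":
        total = sum(self.fractions.values())
        return SegmentFractionTable(
            {k: v / total for k, v in self.fractions.items()}, normalized=True)


def load_segment_fractions(normalize: bool = True) -> SegmentFractionTable:
    """The built-in 18-segment table, as proportions.

    The raw percentages sum to 99.2 %, not 100 %; with ``normalize`` (the
    default) each fraction is divided by the raw sum so that allocated
    flows conserve the total — required for a closed airway tree."""
    raw = SegmentFractionTable(
        {k: v / 100.0 for k, v in SEGMENT_FRACTIONS_RAW.items()},
        normalized=False)
    return raw.normalize() if normalize else raw


@dataclass
class Outlet:
    """One small-airway orifice of the truncated model."""

    outlet_id: str
    segments: list[str]
    area_mm2: float

    def __post_init__(self):
        if self.area_mm2 <= 0:
            raise ValueError(f"outlet {self.outlet_id}: area must be > 0")


@dataclass
class OutletMap:
    """Mapping from model orifices to the lung segments they drain."""

    outlets: list[Outlet]

    def __post_init__(self):
        known = set(SEGMENT_FRACTIONS_RAW)
        for o in self.outlets:
            unknown = set(o.segments) - known
            if unknown:
                raise ValueError(f"outlet {o.outlet_id}: unknown segments {sorted(unknown)}")

    @classmethod
    def from_json(cls, path: str | Path) -> "OutletMap":
        doc = json.loads(Path(path).read_text())
        return cls([Outlet(o["outlet_id"], list(o["segments"]), float(o["area_mm2"]))
                    for o in doc["outlets"]])

    def to_json(self, path: str | Path) -> None:
        doc = {"outlets": [
            {"outlet_id": o.outlet_id, "segments": o.segments, "area_mm2": o.area_mm2}
            for o in self.outlets]}
        Path(path).write_text(json.dumps(doc, indent=1))


@dataclass
class BoundaryCase:
    """Per-outlet velocity-inlet boundary conditions for one total flow."""

    total_flow_L_s: float
    outlet_flows_L_s: dict[str, float]
    outlet_velocities_m_s: dict[str, float]
    outlet_condition: str = "zero-pressure"


def velocity_to_flow(velocity_m_s: float, area_mm2: float) -> float:
    """m/s x mm^2 -> L/s (factor 1e-3: 1 m/s * 1 mm^2 = 1e-6 m^3/s = 1e-3 L/s)."""
    if area_mm2 <= 0:
        raise ValueError(f"area must be > 0, got {area_mm2}")
    return velocity_m_s * area_mm2 * 1e-3


def flow_to_velocity(flow_L_s: float, area_mm2: float) -> float:
    """Inverse of :func:`velocity_to_flow`."""
    if area_mm2 <= 0:
        raise ValueError(f"area must be > 0, got {area_mm2}")
    return flow_L_s / area_mm2 * 1e3


def allocate_flows(total_flow_L_s: float, table: SegmentFractionTable,
                   outlet_map: OutletMap,
                   split: str = "equal") -> BoundaryCase:
    """Distribute the total expiratory flow over the model outlets.

    Each segment receives fraction x total flow; a segment drained by k
    outlets splits its share equally among them (``split='equal'``) or in
    proportion to orifice area (``split='area'``).  An outlet draining
    several segments receives the sum of its shares.  Inlet velocity per
    outlet is flow / area.
    """
    if total_flow_L_s <= 0:
        raise ValueError(f"total flow must be > 0, got {total_flow_L_s}")
    if split not in ("equal", "area"):
        raise ValueError(f"split must be 'equal' or 'area', got {split!r}")
    seg_outlets: dict[str, list[Outlet]] = {s: [] for s in table.fractions}
    for o in outlet_map.outlets:
        for s in o.segments:
            seg_outlets[s].append(o)
    unmapped = [s for s, os_ in seg_outlets.items()
                if not os_ and table.fractions[s] > 0]
    if unmapped:
        raise ValueError(f"segments with no outlet: {sorted(unmapped)}")
    flows = {o.outlet_id: 0.0 for o in outlet_map.outlets}
    for seg, frac in table.fractions.items():
        seg_flow = frac * total_flow_L_s
        outs = seg_outlets[seg]
        if split == "equal":
            weights = np.full(len(outs), 1.0 / len(outs))
        else:
            areas = np.array([o.area_mm2 for o in outs])
            weights = areas / areas.sum()
        for o, w in zip(outs, weights):
            flows[o.outlet_id] += seg_flow * float(w)
    vels = {o.outlet_id: flow_to_velocity(flows[o.outlet_id], o.area_mm2)
            for o in outlet_map.outlets}
    return BoundaryCase(total_flow_L_s, flows, vels)


BC_COLUMNS = ["boundary", "type", "value", "units"]


def export_bc(case: BoundaryCase, path: str | Path,
              stage: str = "normal_velocity_inlets",
              pressures_Pa: dict[str, float] | None = None,
              trachea_name: str = "trachea_outlet") -> None:
    """Write a boundary-condition CSV for the external CFD run.

    ``normal_velocity_inlets``: each orifice as a velocity inlet (m/s).
    ``stenotic_pressure_inlets``: each orifice as a pressure inlet with the
    pressures read back from the normal-geometry run (the equal-pressure
    transfer).  The large-airway outlet is always a 0 Pa pressure outlet.
    """
    rows = []
    if stage == "normal_velocity_inlets":
        for oid, v in case.outlet_velocities_m_s.items():
            rows.append((oid, "velocity-inlet", v, "m/s"))
    elif stage == "stenotic_pressure_inlets":
        if pressures_Pa is None or set(pressures_Pa) != set(case.outlet_flows_L_s):
            missing = (set(case.outlet_flows_L_s) - set(pressures_Pa or {}))
            raise ValueError(f"missing pressures for outlets: {sorted(missing)}")
        for oid, p in pressures_Pa.items():
            rows.append((oid, "pressure-inlet", p, "Pa"))
    else:
        raise ValueError(f"unknown stage {stage!r}")
    rows.append((trachea_name, "pressure-outlet", 0.0, "Pa"))
    pd.DataFrame(rows, columns=BC_COLUMNS).to_csv(path, index=False,
                                                  float_format="%.17g")


def import_bc(path: str | Path) -> pd.DataFrame:
    """Read back a boundary-condition CSV written by :func:`export_bc`."""
    df = pd.read_csv(path)
    missing = set(BC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["value"].isna().any():
        raise ValueError(f"{path}: NaN values in 'value' column")
    return df


def import_simulation_results(path: str | Path) -> pd.DataFrame:
    """Read per-outlet readings from the external CFD run.

    Expected columns: ``boundary``, ``area_mm2``, and at least one of
    ``pressure_Pa`` / ``velocity_m_s``.  Returns a DataFrame indexed by
    boundary name."""
    df = pd.read_csv(path)
    if "boundary" not in df.columns or "area_mm2" not in df.columns:
        raise ValueError(f"{path}: need columns 'boundary' and 'area_mm2'")
    if not ({"pressure_Pa", "velocity_m_s"} & set(df.columns)):
        raise ValueError(f"{path}: need 'pressure_Pa' or 'velocity_m_s'")
    if df[[c for c in ("pressure_Pa", "velocity_m_s") if c in df.columns]].isna().any().any():
        raise ValueError(f"{path}: NaN readings")
    if (df["area_mm2"] <= 0).any():
        raise ValueError(f"{path}: non-positive outlet area")
    return df.set_index("boundary")
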