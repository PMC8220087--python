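"""Bending angle, axial strain, nucleus displacement/strain and the
per-state metrics table of a flexion/extension loading protocol.

Conventions follow the loading experiment the pipeline emulates: bending
angle variation alpha - alpha0 is negative in flexion and positive in
extension; axial strain 100 (h - h0)/h0 is negative under compression;
displacements are mm along the A-P axis with anterior positive; strains
in percent.  The reference mechanical state is the loaded neutral step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import MarkerFrame
from .segmentation import NucleusGeometry, ap_coordinate

__all__ = [
    "MechanicalState",
    "MetricsTable",
    "METRIC_COLUMNS",
    "bending_angle",
    "axial_strain",
    "nucleus_boundary_displacement",
    "nucleus_sagittal_strain",
    "nucleus_global_displacement",
    "state_delta",
    "build_metrics_table",
]


@dataclass(frozen=True)
class MechanicalState:
    """One loading step: name, damage state and applied boundary loads."""

    step_id: int
    name: str  # Neutral / Flexion / Extension
    fissured: bool
    axial_compression: float  # N
    bending_force: float  # N
    bending_moment: float  # N.m
    cumulative_load_time: float = 0.0  # hours

    def __post_init__(self) -> None:
        if self.axial_compression < 0 or self.bending_force < 0:
            raise ValueError("forces must be >= 0")


#: Column order of the exported metrics table.
METRIC_COLUMNS = [
    "step",
    "axial_strain",
    "specimen_angle",
    "angle_variation",
    "nucleus_boundary_displacement",
    "nucleus_global_displacement",
    "nucleus_sagittal_strain",
    "migration",
]


@dataclass
class MetricsTable:
    """Ordered per-state metric rows with a single reference step."""

    data: pd.DataFrame
    reference_step: int

    def __post_init__(self) -> None:
        if list(self.data.columns) != METRIC_COLUMNS:
            raise ValueError(f"metrics table columns must be {METRIC_COLUMNS}")
        if self.reference_step not in set(self.data["step"]):
            raise ValueError("reference step missing from table")

    def row(self, step: int) -> pd.Series:
        sel = self.data[self.data["step"] == step]
        if sel.empty:
            raise KeyError(f"step {step} not in metrics table")
        return sel.iloc[0]


# ---------------------------------------------------------------------------
# marker-based kinematics


def _upper_stick_angle(frame: MarkerFrame) -> float:
    base = frame.position("upper_base")
    tip = frame.position("upper_tip")
    v = tip - base
    return float(np.degrees(np.arctan2(v[1], v[0])))


def bending_angle(frame: MarkerFrame, frame0: MarkerFrame) -> float:
    """Bending angle alpha - alpha0 (deg) from the upper-stick marker pair.

    alpha is the angle of the upper stick with the horizontal; negative
    results indicate flexion, positive extension.
    """
    try:
        a = _upper_stick_angle(frame)
        a0 = _upper_stick_angle(frame0)
    except KeyError as exc:
        raise ValueError(f"missing marker: {exc}") from exc
    return a - a0


def axial_strain(frame: MarkerFrame, frame0: MarkerFrame) -> float:
    """Axial strain 100 (h - h0)/h0 in percent, h the stick-tip distance."""
    try:
        h = float(np.linalg.norm(frame.position("upper_tip") - frame.position("lower_tip")))
        h0 = float(np.linalg.norm(frame0.position("upper_tip") - frame0.position("lower_tip")))
    except KeyError as exc:
        raise ValueError(f"missing marker: {exc}") from exc
    if h0 == 0:
        raise ValueError("reference height h0 is zero")
    return 100.0 * (h - h0) / h0


# ---------------------------------------------------------------------------
# map-based nucleus kinematics


def nucleus_boundary_displacement(geom: NucleusGeometry, geom0: NucleusGeometry) -> float:
    """Change in A-P nucleus extent w - w0 (mm)."""
    return geom.w - geom0.w


def nucleus_sagittal_strain(geom: NucleusGeometry, geom0: NucleusGeometry) -> float:
    """Nucleus sagittal strain 100 (w - w0)/w0 in percent."""
    if geom0.w <= 0:
        raise ValueError("reference nucleus extent w0 must be > 0")
    return 100.0 * (geom.w - geom0.w) / geom0.w


def nucleus_global_displacement(geom: NucleusGeometry, geom0: NucleusGeometry) -> float:
    """Change d - d0 (mm) of the signed A-P nucleus-to-canal centroid distance.

    The spinal-canal centroid anchors the measurement, so a rigid
    translation of the whole image cancels and only relative
    nucleus-canal motion is reported (anterior positive).
    """
    d = ap_coordinate(geom.centroid_np) - ap_coordinate(geom.centroid_canal)
    d0 = ap_coordinate(geom0.centroid_np) - ap_coordinate(geom0.centroid_canal)
    return d - d0


# ---------------------------------------------------------------------------
# table assembly and state deltas


def state_delta(table: MetricsTable, column: str, step_a: int, step_b: int,
                mode: str = "signed") -> float:
    """Difference of one metric between two steps.

    ``signed`` mode returns value(b) - value(a); ``magnitude`` mode
    returns \\|value(b)\\| - \\|value(a)\\|, the appropriate comparison when a
    reported decrease refers to the size of a displacement rather than
    its signed value.
    """
    if column not in METRIC_COLUMNS:
        raise KeyError(f"unknown metric column {column!r}")
    if mode not in ("signed", "magnitude"):
        raise ValueError("mode must be 'signed' or 'magnitude'")
    va = float(table.row(step_a)[column])
    vb = float(table.row(step_b)[column])
    if mode == "magnitude":
        return abs(vb) - abs(va)
    return vb - va


def build_metrics_table(
    states: list[MechanicalState],
    frames: dict[int, MarkerFrame],
    geometries: dict[int, "NucleusGeometry"],
    reference_step: int = 1,
) -> MetricsTable:
    """Compute one metrics row per mechanical state against the reference.

    ``frames``/``geometries`` map step id to the state's marker frame and
    segmented nucleus geometry.  The reference row keeps its specimen
    angle and migration but leaves the variation metrics undefined (NaN),
    mirroring how such tables are reported.
    """
    if reference_step not in frames or reference_step not in geometries:
        raise ValueError("reference step must have a marker frame and geometry")
    f0 = frames[reference_step]
    g0 = geometries[reference_step]
    rows = []
    for st in sorted(states, key=lambda s: s.step_id):
        sid = st.step_id
        if sid not in frames or sid not in geometries:
            raise ValueError(f"state {sid} missing marker frame or geometry")
        f, g = frames[sid], geometries[sid]
        ref = sid == reference_step
        rows.append({
            "step": sid,
            "axial_strain": np.nan if ref else axial_strain(f, f0),
            "specimen_angle": _upper_stick_angle(f),
            "angle_variation": np.nan if ref else bending_angle(f, f0),
            "nucleus_boundary_displacement": np.nan if ref else nucleus_boundary_displacement(g, g0),
            "nucleus_global_displacement": np.nan if ref else nucleus_global_displacement(g, g0),
            "nucleus_sagittal_strain": np.nan if ref else nucleus_sagittal_strain(g, g0),
            "migration": g.migration,
        })
    df = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    return MetricsTable(data=df, reference_step=reference_step)
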