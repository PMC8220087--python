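"""Reference measurement tables of the ex vivo ovine loading experiment
this pipeline emulates, transcribed from the published study report.

Three tables are bundled so reproduction and configuration need no
external data:

* :data:`LOADING_STATES` — the seven mechanical loading steps (axial
  compression, bending force and moment), steps 4-6 after the anterior
  annulus was fissured;
* :data:`MATERIALS` — linear-isotropic elastic properties used for the
  simplified finite-element disc model;
* :func:`measured_metrics_table` — the per-step kinematic metrics the
  experiment reported (reference state: step 1, loaded neutral);
* :data:`REPORTED_DELTAS` — the intact-versus-fissured metric changes
  quoted in the study's results, each pinned to its comparison mode
  (plain signed difference, or difference of magnitudes for the flexion
  comparisons where the reported decrease refers to displacement size).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kinematics import METRIC_COLUMNS, MechanicalState, MetricsTable

__all__ = [
    "LOADING_STATES",
    "MATERIALS",
    "FISSURE_GEOMETRY",
    "measured_metrics_table",
    "REPORTED_DELTAS",
]

#: Mechanical loading protocol (step, name, fissured, axial N, bending N,
#: moment N.m, cumulative hours under axial compression).
LOADING_STATES = [
    MechanicalState(0, "Neutral", False, 0.0, 0.0, 0.0, 0.0),
    MechanicalState(1, "Neutral", False, 59.7, 0.0, 0.0, 1.5),
    MechanicalState(2, "Flexion", False, 59.7, 81.1, 2.1, 3.0),
    MechanicalState(3, "Extension", False, 59.7, 80.9, 2.8, 4.5),
    MechanicalState(4, "Extension", True, 59.7, 80.5, 2.8, 6.5),
    MechanicalState(5, "Flexion", True, 59.7, 81.0, 2.1, 8.5),
    MechanicalState(6, "Neutral", True, 59.7, 0.0, 0.0, 10.0),
]

#: Linear-isotropic material properties: region -> (Young modulus MPa, Poisson ratio).
MATERIALS = {
    "nucleus": (1.0, 0.499),
    "annulus": (8.4, 0.45),
}

#: Induced anterior fissure size relative to disc dimensions:
#: 54 % of total disc height (sagittal), 27 % of transverse diameter.
FISSURE_GEOMETRY = {"height_fraction": 0.54, "radial_fraction": 0.27}

# Per-step measured metrics: axial strain %, specimen angle deg, angle
# variation deg, nucleus boundary sagittal displacement mm, nucleus global
# sagittal displacement mm, nucleus sagittal strain %, migration %.
_MEASURED_ROWS = [
    (1, -4.0, 4.7, np.nan, np.nan, np.nan, np.nan, np.nan),
    (2, -7.3, -8.8, -13.5, -2.2, -3.6, -5.6, 0.0),
    (3, -8.3, 10.4, 5.7, 2.2, -0.9, -6.1, 0.0),
    (4, -8.8, 11.1, 6.4, 5.0, 3.7, 21.1, 100.0),
    (5, -7.5, -8.9, -13.6, -0.6, -1.6, -3.1, 21.0),
    (6, -4.6, 8.7, 4.0, 4.5, 1.5, 20.8, 100.0),
]


def measured_metrics_table() -> MetricsTable:
    """The experiment's measured per-step metrics as a MetricsTable."""
    df = pd.DataFrame(_MEASURED_ROWS, columns=METRIC_COLUMNS)
    return MetricsTable(data=df, reference_step=1)


#: Reported intact-vs-fissured changes: (label, column, step_a, step_b,
#: mode, reported value, absolute tolerance).  Tolerances cover the
#: rounding of the reported numbers (e.g. the extension strain change is
#: quoted as +27 while the table arithmetic gives +27.2).
REPORTED_DELTAS = [
    ("boundary displacement, extension", "nucleus_boundary_displacement", 3, 4, "signed", 2.8, 0.05),
    ("boundary displacement, flexion", "nucleus_boundary_displacement", 2, 5, "magnitude", -1.6, 0.05),
    ("global displacement, extension", "nucleus_global_displacement", 3, 4, "signed", 4.6, 0.05),
    ("global displacement, flexion", "nucleus_global_displacement", 2, 5, "magnitude", -2.0, 0.05),
    ("sagittal strain, extension", "nucleus_sagittal_strain", 3, 4, "signed", 27.0, 0.3),
    ("sagittal strain, flexion", "nucleus_sagittal_strain", 2, 5, "signed", 2.5, 0.05),
    ("angle shift, neutral", "specimen_angle", 1, 6, "signed", 4.0, 0.05),
    ("angle shift, extension", "specimen_angle", 3, 4, "signed", 0.7, 0.05),
    ("angle shift, flexion", "specimen_angle", 2, 5, "signed", -0.1, 0.05),
]
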