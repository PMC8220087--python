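"""Default run configuration for the end-to-end phantom study.

The study emulates the seven-step bench protocol: a loaded-neutral
reference (step 1), intact flexion/extension (steps 2-3), then the same
bending states plus a return to neutral after an anterior radial fissure
(steps 4-6).  Per-step entries impose the ground-truth kinematics the
phantom realises: specimen angle (deg), axial strain versus the
reference (%), anterior-positive nucleus shift (mm) and the fraction of
the fissure breach filled by nucleus tissue.  Specimen angles are the
values measured in the bench experiment; shifts and fills are phantom
choices of realistic magnitude (full infiltration in fissured extension
and neutral, partial in fissured flexion).
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["default_config", "load_config"]


_DEFAULT = {
    "phantom": {
        "grid_shape": [100, 96],
        "pixel_spacing": 0.52,
        "disc_center": [22.0, 25.0],
        "disc_outer_semiaxes": [11.0, 14.0],
        "nucleus_semiaxes": [5.5, 7.0],
        "nucleus_center_offset": [0.0, 0.0],
        "canal_center": [40.0, 25.0],
        "canal_radius": 4.0,
        "noise_sigma": 0.02,
        "compartments": {
            "nucleus": [1200.0, 120.0, 1.0],
            "annulus": [500.0, 50.0, 0.7],
            "canal": [1400.0, 200.0, 0.9],
        },
        "fissure": {
            "angular_position": 0.0,
            "angular_width": 18.0,
            "radial_depth_fraction": 1.0,
            "sagittal_height_fraction": 0.54,
            "transverse_fraction": 0.27,
        },
    },
    "acquisition": {
        "inversion_times": [30, 60, 130, 300, 600, 1300, 3000, 5800],
        "echo_times": [30.0 * k for k in range(1, 33)],
        "ir_signed": False,
    },
    "fit": {
        "t1_bounds": [1.0, 5000.0],
        "t2_bounds": [1.0, 1000.0],
        "min_signal_fraction": 0.15,
        "polarity_restoration": True,
    },
    "segmentation": {
        "t1_threshold": 800.0,
        "t2_threshold": 80.0,
        "min_component_px": 5,
        "opening_radius_px": 4,
        "band_halfwidth_px": 1,
    },
    "markers": {
        "stick_length_mm": 80.0,
        "h0_mm": 100.0,
        "noise_mm": 0.0,
    },
    "states": {
        "reference_step": 1,
        # step: angle deg, axial strain % vs reference, nucleus shift mm
        # (anterior +), fissure fill fraction, fissured flag
        "imposed": {
            1: {"angle": 4.7, "strain": 0.0, "shift": 0.0, "fill": 0.0, "fissured": False},
            2: {"angle": -8.8, "strain": -3.4, "shift": -1.5, "fill": 0.0, "fissured": False},
            3: {"angle": 10.4, "strain": -4.5, "shift": 1.0, "fill": 0.0, "fissured": False},
            4: {"angle": 11.1, "strain": -5.0, "shift": 2.5, "fill": 1.0, "fissured": True},
            5: {"angle": -8.9, "strain": -3.6, "shift": -0.8, "fill": 0.21, "fissured": True},
            6: {"angle": 8.7, "strain": -0.6, "shift": 2.0, "fill": 1.0, "fissured": True},
        },
    },
    "fem": {
        "disc_height_mm": 10.0,
        "target_edge_mm": 0.8,
        "probe_margin_mm": 2.0,
    },
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULT)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ValueError("config file must contain a mapping")
        cfg = _merge(cfg, user)
    return cfg
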