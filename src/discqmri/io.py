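"""File formats: NIfTI / multi-page TIFF image series with JSON timing
sidecars, label maps, metrics CSV, legacy ASCII VTK stress export and
provenance sidecars."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .fem import Mesh, StressField
from .kinematics import METRIC_COLUMNS, MetricsTable
from .phantom import ImageSeries, LABELS, MarkerFrame
from .relaxometry import RelaxationMap
from .segmentation import DiscLabelMap

__all__ = [
    "read_image_series",
    "write_image_series",
    "read_label_map",
    "write_label_map",
    "write_metrics_table",
    "read_metrics_table",
    "write_vtk",
    "save_stress_png",
    "write_provenance",
]

_SIDECAR_KEYS = ("timing_ms", "modality", "pixel_spacing_mm", "signed")


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii", ".tif", ".tiff"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def write_image_series(series: ImageSeries, path: str | Path) -> Path:
    """Write frames as float32 NIfTI (.nii/.nii.gz) or multi-page TIFF plus
    a JSON sidecar holding timing, modality, spacing and signedness."""
    path = Path(path)
    data = series.frames.astype(np.float32)
    if path.name.endswith((".nii", ".nii.gz")):
        # rows x cols x frames volume; spacing in the affine diagonal
        vol = np.moveaxis(data, 0, -1)
        aff = np.diag([series.pixel_spacing, series.pixel_spacing, 1.0, 1.0])
        nib.save(nib.Nifti1Image(vol, aff), str(path))
    elif path.name.endswith((".tif", ".tiff")):
        tifffile.imwrite(str(path), data, photometric="minisblack")
    else:
        raise ValueError(f"unsupported image format: {path.name}")
    sidecar = {
        "timing_ms": [float(t) for t in series.timing],
        "modality": series.modality,
        "pixel_spacing_mm": series.pixel_spacing,
        "signed": bool(series.signed),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_image_series(path: str | Path) -> ImageSeries:
    """Read an image series and its JSON sidecar; validates the metadata."""
    path = Path(path)
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise FileNotFoundError(
            f"missing sidecar {sc_path.name}; required keys: {', '.join(_SIDECAR_KEYS)}"
        )
    meta = json.loads(sc_path.read_text())
    missing = [k for k in _SIDECAR_KEYS if k not in meta]
    if missing:
        raise ValueError(f"sidecar {sc_path.name} lacks keys: {', '.join(missing)}")
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        frames = np.moveaxis(np.asarray(img.dataobj, dtype=np.float32), -1, 0)
    elif path.name.endswith((".tif", ".tiff")):
        frames = tifffile.imread(str(path)).astype(np.float32)
        if frames.ndim == 2:
            frames = frames[None]
    else:
        raise ValueError(f"unsupported image format: {path.name}")
    return ImageSeries(frames=frames.astype(float), timing=meta["timing_ms"],
                       modality=meta["modality"], pixel_spacing=meta["pixel_spacing_mm"],
                       signed=meta["signed"])


def write_label_map(labelmap: DiscLabelMap, path: str | Path) -> Path:
    path = Path(path)
    aff = np.diag([labelmap.pixel_spacing, labelmap.pixel_spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(labelmap.labels[..., None].astype(np.uint8), aff), str(path))
    meta = {"labels": {str(k): v for k, v in labelmap.dictionary.items()},
            "pixel_spacing_mm": labelmap.pixel_spacing}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_label_map(path: str | Path) -> DiscLabelMap:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj, dtype=np.uint8)[..., 0]
    dictionary = {int(k): v for k, v in meta.get("labels", {}).items()} or dict(LABELS)
    return DiscLabelMap(labels=labels, pixel_spacing=float(meta["pixel_spacing_mm"]),
                        dictionary=dictionary)


def write_relaxation_map(rmap: "RelaxationMap", path: str | Path) -> Path:
    """Store values/amplitude/rss/validity as a 4-volume float32 NIfTI."""
    path = Path(path)
    stack = np.stack([rmap.values, rmap.amplitude, rmap.rss,
                      rmap.valid_mask.astype(np.float32)], axis=-1).astype(np.float32)
    aff = np.diag([rmap.pixel_spacing, rmap.pixel_spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(stack, aff), str(path))
    meta = {"kind": rmap.kind, "pixel_spacing_mm": rmap.pixel_spacing,
            "bounds_ms": list(rmap.bounds),
            "volumes": ["values_ms", "amplitude", "rss", "valid"]}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_relaxation_map(path: str | Path) -> "RelaxationMap":
    from .relaxometry import RelaxationMap

    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    stack = np.asarray(nib.load(str(path)).dataobj, dtype=np.float32)
    return RelaxationMap(values=stack[..., 0].astype(float),
                         amplitude=stack[..., 1].astype(float),
                         rss=stack[..., 2].astype(float),
                         valid_mask=stack[..., 3] > 0.5,
                         kind=meta["kind"], pixel_spacing=float(meta["pixel_spacing_mm"]),
                         bounds=tuple(meta.get("bounds_ms", (1.0, 5000.0))))


def write_marker_frames(frames: list[MarkerFrame], path: str | Path) -> Path:
    """Marker coordinates as CSV: state_id, marker_id, x_mm, y_mm."""
    rows = [{"state_id": fr.state_id, "marker_id": mid, "x_mm": x, "y_mm": y}
            for fr in frames for (mid, x, y) in fr.markers]
    pd.DataFrame(rows, columns=["state_id", "marker_id", "x_mm", "y_mm"]).to_csv(
        Path(path), index=False, float_format="%.12g")
    return Path(path)


def read_marker_frames(path: str | Path) -> dict[str, MarkerFrame]:
    df = pd.read_csv(path)
    frames: dict[str, MarkerFrame] = {}
    for sid, grp in df.groupby("state_id", sort=False):
        frames[str(sid)] = MarkerFrame(
            state_id=str(sid),
            markers=[(str(r.marker_id), float(r.x_mm), float(r.y_mm))
                     for r in grp.itertuples()])
    return frames


def write_metrics_table(table: MetricsTable, path: str | Path) -> Path:
    """CSV export in the fixed metric column order."""
    path = Path(path)
    table.data.to_csv(path, index=False, float_format="%.12g")
    return path


def read_metrics_table(path: str | Path, reference_step: int = 1) -> MetricsTable:
    df = pd.read_csv(path)
    if list(df.columns) != METRIC_COLUMNS:
        raise ValueError(f"metrics CSV columns must be {METRIC_COLUMNS}")
    return MetricsTable(data=df, reference_step=reference_step)


def write_vtk(mesh: Mesh, field: StressField, path: str | Path) -> Path:
    """Legacy ASCII VTK unstructured grid with per-cell stress data."""
    path = Path(path)
    lines = ["# vtk DataFile Version 3.0", "discqmri stress field", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {mesh.n_nodes} float"]
    for x, y in mesh.nodes:
        lines.append(f"{x:.8g} {y:.8g} 0")
    m = mesh.elements.shape[0]
    lines.append(f"CELLS {m} {m * 7}")
    for conn in mesh.elements:
        lines.append("6 " + " ".join(str(int(n)) for n in conn))
    lines.append(f"CELL_TYPES {m}")
    lines.extend(["22"] * m)  # VTK_QUADRATIC_TRIANGLE
    lines.append(f"CELL_DATA {m}")
    for name, arr in (("sigma_xx", field.sigma_xx), ("sigma_yy", field.sigma_yy),
                      ("sigma_xy", field.sigma_xy), ("axial_stress", field.axial_stress),
                      ("max_shear_intensity", field.max_shear_intensity)):
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.8g}" for v in arr)
    path.write_text("\n".join(lines) + "\n")
    return path


def save_stress_png(mesh: Mesh, field: StressField, path: str | Path,
                    quantity: str = "axial") -> Path:
    """Heatmap of a stress quantity: symmetric diverging scale for axial
    stress, sequential for shear intensity."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import matplotlib.tri as mtri

    path = Path(path)
    tri = mtri.Triangulation(mesh.nodes[:, 0], mesh.nodes[:, 1], mesh.elements[:, :3])
    fig, ax = plt.subplots(figsize=(5, 4))
    if quantity == "axial":
        v = field.axial_stress
        vmax = float(np.max(np.abs(v))) or 1.0
        tpc = ax.tripcolor(tri, facecolors=v, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        label = "axial stress (MPa)"
    elif quantity == "shear":
        v = field.max_shear_intensity
        tpc = ax.tripcolor(tri, facecolors=v, cmap="viridis", vmin=0)
        label = "max shear intensity (MPa)"
    else:
        raise ValueError("quantity must be 'axial' or 'shear'")
    fig.colorbar(tpc, ax=ax, label=label)
    ax.set_aspect("equal")
    ax.set_xlabel("anterior-posterior (mm)")
    ax.set_ylabel("height (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def write_provenance(path: str | Path, config: dict, seed: int) -> Path:
    """Record config hash, seed and package version next to an artifact."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    meta = {"config_sha256": hashlib.sha256(blob).hexdigest(),
            "seed": int(seed), "version": __version__}
    path = Path(path)
    path.write_text(json.dumps(meta, indent=1))
    return path
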