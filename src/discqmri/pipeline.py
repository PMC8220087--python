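"""End-to-end phantom study: simulate each mechanical state, fit maps,
segment, and assemble the per-state metrics table (plus, on request, the
finite-element stress comparison)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from . import fem, io, phantom, relaxometry, segmentation
from .config import default_config
from .kinematics import MetricsTable, build_metrics_table
from .phantom import FissureSpec, PhantomSpec
from .reference_data import FISSURE_GEOMETRY, LOADING_STATES
from .relaxometry import FitOptions
from .segmentation import SegmentationOptions

__all__ = ["StateResult", "StudyResult", "phantom_spec_from_config",
           "run_state", "run_study", "imposed_ground_truth"]


@dataclass
class StateResult:
    step: int
    truth: phantom.PhantomTruth
    t1_map: relaxometry.RelaxationMap
    t2_map: relaxometry.RelaxationMap
    labelmap: segmentation.DiscLabelMap
    geometry: segmentation.NucleusGeometry
    frame: phantom.MarkerFrame


@dataclass
class StudyResult:
    metrics: MetricsTable
    states: dict[int, StateResult]
    seed: int


def phantom_spec_from_config(cfg: dict, fissured: bool, seed: int) -> PhantomSpec:
    p = cfg["phantom"]
    fis = None
    if fissured:
        f = p["fissure"]
        fis = FissureSpec(
            angular_position=f["angular_position"], angular_width=f["angular_width"],
            radial_depth_fraction=f["radial_depth_fraction"],
            sagittal_height_fraction=f.get("sagittal_height_fraction", FISSURE_GEOMETRY["height_fraction"]),
            transverse_fraction=f.get("transverse_fraction", FISSURE_GEOMETRY["radial_fraction"]),
        )
    comp = {k: tuple(v) for k, v in p["compartments"].items()}
    return PhantomSpec(
        grid_shape=tuple(p["grid_shape"]), pixel_spacing=p["pixel_spacing"],
        disc_center=tuple(p["disc_center"]), disc_outer_semiaxes=tuple(p["disc_outer_semiaxes"]),
        nucleus_semiaxes=tuple(p["nucleus_semiaxes"]),
        nucleus_center_offset=tuple(p["nucleus_center_offset"]),
        canal_center=tuple(p["canal_center"]), canal_radius=p["canal_radius"],
        compartment_props=comp, fissure=fis, noise_sigma=p["noise_sigma"], seed=seed,
    )


def _fit_options(cfg: dict) -> FitOptions:
    f = cfg["fit"]
    return FitOptions(t1_bounds=tuple(f["t1_bounds"]), t2_bounds=tuple(f["t2_bounds"]),
                      min_signal_fraction=f["min_signal_fraction"],
                      polarity_restoration=f["polarity_restoration"])


def _seg_options(cfg: dict) -> SegmentationOptions:
    s = cfg["segmentation"]
    return SegmentationOptions(t1_threshold=s["t1_threshold"], t2_threshold=s["t2_threshold"],
                               min_component_px=s["min_component_px"],
                               opening_radius_px=s["opening_radius_px"],
                               band_halfwidth_px=s["band_halfwidth_px"])


def run_state(cfg: dict, step: int, imposed: dict, seed: int) -> StateResult:
    """Simulate, fit and segment one mechanical state."""
    spec = phantom_spec_from_config(cfg, fissured=bool(imposed["fissured"]), seed=seed)
    truth = phantom.make_phantom(spec, shift_ap=imposed["shift"],
                                 infiltration_fraction=imposed["fill"] if imposed["fissured"] else None)
    acq = cfg["acquisition"]
    opts = _fit_options(cfg)
    ir = phantom.simulate_ir_series(truth, acq["inversion_times"], seed=seed * 4 + 1,
                                    signed=bool(acq.get("ir_signed", False)))
    me = phantom.simulate_me_series(truth, acq["echo_times"], seed=seed * 4 + 2)
    t1_map = relaxometry.fit_t1_map(ir, opts)
    t2_map = relaxometry.fit_t2_map(me, opts)
    labelmap = segmentation.segment_disc(t1_map, t2_map, _seg_options(cfg))
    geom = segmentation.nucleus_geometry(labelmap, _seg_options(cfg), t1_map=t1_map)
    m = cfg["markers"]
    ref = cfg["states"]["imposed"][cfg["states"]["reference_step"]]
    h0 = m["h0_mm"]
    h = h0 * (1.0 + imposed["strain"] / 100.0)
    _, frame = phantom.make_marker_frames(ref["angle"], imposed["angle"], h0, h,
                                          m["stick_length_mm"], m["noise_mm"],
                                          seed=seed * 4 + 3)
    return StateResult(step=step, truth=truth, t1_map=t1_map, t2_map=t2_map,
                       labelmap=labelmap, geometry=geom, frame=frame)


def run_study(cfg: dict | None = None, seed: int = 0, outdir: str | Path | None = None) -> StudyResult:
    """Run the six-state phantom study and assemble the metrics table.

    Per-state seeds are derived deterministically from ``seed``.  When
    ``outdir`` is given, image series, label maps, the metrics CSV and a
    provenance sidecar are written there.
    """
    cfg = default_config() if cfg is None else cfg
    imposed = {int(k): v for k, v in cfg["states"]["imposed"].items()}
    ref_step = int(cfg["states"]["reference_step"])
    states = {}
    for step in sorted(imposed):
        states[step] = run_state(cfg, step, imposed[step], seed=seed * 101 + step)
    frames = {s: r.frame for s, r in states.items()}
    geoms = {s: r.geometry for s, r in states.items()}
    mech = [st for st in LOADING_STATES if st.step_id in imposed]
    table = build_metrics_table(mech, frames, geoms, reference_step=ref_step)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_metrics_table(table, outdir / "metrics.csv")
        for step, r in states.items():
            io.write_label_map(r.labelmap, outdir / f"labels_step{step}.nii.gz")
        io.write_provenance(outdir / "provenance.json", cfg, seed)
    return StudyResult(metrics=table, states=states, seed=seed)


def imposed_ground_truth(cfg: dict | None = None) -> dict[int, dict]:
    """Analytic ground-truth metrics implied by the imposed state parameters.

    For each step: angle variation, axial strain, global A-P nucleus
    displacement (equal to the imposed shift), nucleus extent w (the
    nucleus A-P diameter plus the infiltrated anterior annulus depth
    along the midline), boundary displacement, sagittal strain and
    migration.
    """
    cfg = default_config() if cfg is None else cfg
    p = cfg["phantom"]
    a_disc = p["disc_outer_semiaxes"][0]
    a_nuc = p["nucleus_semiaxes"][0]
    off = p["nucleus_center_offset"][0]
    depth_frac = p["fissure"]["radial_depth_fraction"]
    imposed = {int(k): v for k, v in cfg["states"]["imposed"].items()}
    ref = imposed[int(cfg["states"]["reference_step"])]

    def w_of(state: dict) -> float:
        w = 2.0 * a_nuc
        if state["fissured"] and state["fill"] > 0:
            thickness = a_disc - a_nuc - (off + state["shift"])  # anterior ray
            w += depth_frac * state["fill"] * thickness
        return w

    w0 = w_of(ref)
    out = {}
    for step, st in imposed.items():
        w = w_of(st)
        out[step] = {
            "angle_variation": st["angle"] - ref["angle"],
            "axial_strain": st["strain"],
            "nucleus_global_displacement": st["shift"] - ref["shift"],
            "w": w,
            "nucleus_boundary_displacement": w - w0,
            "nucleus_sagittal_strain": 100.0 * (w - w0) / w0,
            "migration": 100.0 * depth_frac * st["fill"] if st["fissured"] else 0.0,
        }
    return out


def run_fem_comparison(cfg: dict | None = None, labelmap_intact=None, labelmap_fissured=None,
                       moment: float = 2.8, axial_force: float = 59.7) -> dict:
    """Intact-versus-fissured stress comparison on segmentation geometry.

    When label maps are not supplied, noiseless phantoms of the intact
    and fully infiltrated fissured states are segmented to provide them.
    Returns the probe-region summary plus meshes and fields for export.
    """
    cfg = default_config() if cfg is None else cfg
    fcfg = cfg["fem"]
    if labelmap_intact is None or labelmap_fissured is None:
        seg_opts = _seg_options(cfg)
        fit_opts = _fit_options(cfg)
        for fissured in (False, True):
            spec = phantom_spec_from_config(cfg, fissured=fissured, seed=0)
            truth = phantom.make_phantom(spec)
            ir = phantom.simulate_ir_series(truth, cfg["acquisition"]["inversion_times"],
                                            noise_sigma=0.0, signed=True)
            me = phantom.simulate_me_series(truth, cfg["acquisition"]["echo_times"], noise_sigma=0.0)
            lm = segmentation.segment_disc(relaxometry.fit_t1_map(ir, fit_opts),
                                           relaxometry.fit_t2_map(me, fit_opts), seg_opts)
            if fissured:
                labelmap_fissured = labelmap_fissured or lm
            else:
                labelmap_intact = labelmap_intact or lm
    h = fcfg["disc_height_mm"]
    geo_i = fem.geometry_from_labels(labelmap_intact, h, fissure_meta=None)
    meta = {"height_fraction": cfg["phantom"]["fissure"]["sagittal_height_fraction"],
            "radial_fraction": cfg["phantom"]["fissure"]["transverse_fraction"]}
    geo_f = fem.geometry_from_labels(labelmap_fissured, h, fissure_meta=meta)
    mats = fem.default_materials()
    edge = fcfg["target_edge_mm"]
    mesh_i = fem.build_mesh(geo_i, edge)
    mesh_f = fem.build_mesh(geo_f, edge)
    load_i = fem.LoadCase(moment=moment, axial_force=axial_force,
                          out_of_plane_width=geo_i.out_of_plane_width)
    load_f = fem.LoadCase(moment=moment, axial_force=axial_force,
                          out_of_plane_width=geo_f.out_of_plane_width)
    u_i = fem.solve_elasticity(mesh_i, mats, load_i)
    u_f = fem.solve_elasticity(mesh_f, mats, load_f)
    fld_i = fem.stress_fields(mesh_i, u_i, mats)
    fld_f = fem.stress_fields(mesh_f, u_f, mats)
    depth, ylo, yhi = geo_f.notch
    probe = (float(depth), float(depth + fcfg["probe_margin_mm"]), float(ylo), float(yhi))
    summary = fem.compare_intact_fissured(fld_i, fld_f, probe)
    return {"summary": summary, "probe_box": probe,
            "intact": (mesh_i, fld_i), "fissured": (mesh_f, fld_f)}
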