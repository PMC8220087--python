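"""Synthetic intervertebral-disc phantom and MR acquisition simulator.

The phantom is a 2D axial section of a lumbar intervertebral disc: an
elliptical annulus fibrosus (AF) enclosing an elliptical nucleus pulposus
(NP), with the spinal canal as a disjoint circular region posterior to the
disc.  An optional anterior radial fissure relabels a wedge of the annulus
as nucleus-infiltrated tissue, emulating nucleus migration through an
annular tear.  From the compartment-wise ground-truth T1/T2/proton-density
maps the module simulates inversion-recovery (IR) and multi-echo spin-echo
(ME) image series with the mono-exponential signal models

    S_IR(TI) = PD * (1 - 2 * exp(-TI / T1))
    S_ME(TE) = PD * exp(-TE / T2)

plus seeded Gaussian (signed data) or Rician (magnitude data) noise.

Coordinate conventions (used throughout the package)
----------------------------------------------------
* Images are ``(rows, cols)`` arrays; physical position of a pixel centre
  is ``(row + 0.5, col + 0.5) * pixel_spacing`` in mm.
* The anteroposterior (A-P) axis is the row axis; *anterior* is towards
  decreasing row index and anterior displacement is positive.
* Fissure angular position 0 deg points anterior (towards row 0); angles
  increase towards increasing column index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LABELS",
    "FissureSpec",
    "PhantomSpec",
    "PhantomTruth",
    "ImageSeries",
    "MarkerFrame",
    "make_phantom",
    "apply_mechanical_state",
    "simulate_ir_series",
    "simulate_me_series",
    "make_marker_frames",
]

#: Label dictionary shared by phantom truth and segmentation output.
LABELS = {0: "background", 1: "annulus", 2: "nucleus", 3: "canal", 4: "infiltration"}

BACKGROUND, ANNULUS, NUCLEUS, CANAL, INFILTRATION = 0, 1, 2, 3, 4


class InvalidSpecError(ValueError):
    """Raised when a phantom specification violates a geometric invariant."""


@dataclass(frozen=True)
class FissureSpec:
    """Anterior radial fissure of the annulus.

    The fissure is a wedge of the annulus centred on ``angular_position``
    (0 deg = anterior midline).  ``radial_depth_fraction`` is the fraction
    of the local annulus thickness breached by the tear and
    ``infiltration_fraction`` the fraction of that breach filled with
    nucleus-like tissue, so the imposed migration ground truth is
    ``100 * radial_depth_fraction * infiltration_fraction`` percent.

    ``sagittal_height_fraction`` and ``transverse_fraction`` describe the
    through-plane extent of the tear relative to disc height and the
    in-plane depth relative to the disc transverse diameter; they are not
    rasterised in the axial phantom but are carried as metadata for the
    sagittal-section finite-element geometry.  The defaults (0.54 and
    0.27) match the experimentally induced lesion the pipeline emulates.
    """

    angular_position: float = 0.0
    angular_width: float = 18.0
    radial_depth_fraction: float = 1.0
    infiltration_fraction: float = 1.0
    sagittal_height_fraction: float = 0.54
    transverse_fraction: float = 0.27

    def __post_init__(self) -> None:
        if not (0.0 <= self.radial_depth_fraction <= 1.0):
            raise InvalidSpecError("radial_depth_fraction must be in [0, 1]")
        if not (0.0 <= self.infiltration_fraction <= 1.0):
            raise InvalidSpecError("infiltration_fraction must be in [0, 1]")
        if self.angular_width <= 0:
            raise InvalidSpecError("angular_width must be > 0")


#: Compartment magnetic properties: name -> (T1 ms, T2 ms, proton density a.u.)
DEFAULT_COMPARTMENTS = {
    "nucleus": (1200.0, 120.0, 1.0),
    "annulus": (500.0, 50.0, 0.7),
    "canal": (1400.0, 200.0, 0.9),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue properties and noise level of a disc phantom.

    Lengths are mm; the default 0.52 mm pixel spacing matches the in-plane
    resolution of the T1/T2 mapping acquisitions the simulator emulates.
    ``nucleus_center_offset`` and the mechanical shift applied later are
    (A-P, lateral) with anterior positive.
    """

    grid_shape: tuple[int, int] = (100, 96)
    pixel_spacing: float = 0.52
    disc_center: tuple[float, float] = (22.0, 25.0)  # (row mm, col mm)
    disc_outer_semiaxes: tuple[float, float] = (11.0, 14.0)  # (A-P, lateral)
    nucleus_semiaxes: tuple[float, float] = (5.5, 7.0)
    nucleus_center_offset: tuple[float, float] = (0.0, 0.0)  # (A-P+, lateral)
    canal_center: tuple[float, float] = (40.0, 25.0)  # (row mm, col mm)
    canal_radius: float = 4.0
    compartment_props: dict = field(default_factory=lambda: dict(DEFAULT_COMPARTMENTS))
    fissure: FissureSpec | None = None
    noise_sigma: float = 0.02
    seed: int = 0
    #: blend truth T1/T2/PD at compartment boundaries by the sub-pixel area
    #: fraction (partial-volume effect); off by default so truth-recovery
    #: tests see piecewise-constant maps
    partial_volume: bool = False

    def __post_init__(self) -> None:
        if self.pixel_spacing <= 0:
            raise InvalidSpecError("pixel_spacing must be > 0")
        for name, (t1, t2, pd) in self.compartment_props.items():
            if t1 <= 0 or t2 <= 0 or pd <= 0:
                raise InvalidSpecError(f"compartment {name!r}: T1, T2, PD must be > 0")
        _check_geometry(self, shift_ap=0.0)


def _nucleus_center(spec: PhantomSpec, shift_ap: float) -> tuple[float, float]:
    """Nucleus centre in (row, col) mm; anterior-positive offsets map to -row."""
    ap, lat = spec.nucleus_center_offset
    r0, c0 = spec.disc_center
    return (r0 - ap - shift_ap, c0 + lat)


def _check_geometry(spec: PhantomSpec, shift_ap: float) -> None:
    """Verify nucleus-inside-disc and canal-disjoint-from-disc invariants."""
    r0, c0 = spec.disc_center
    ad, bd = spec.disc_outer_semiaxes
    an, bn = spec.nucleus_semiaxes
    rn, cn = _nucleus_center(spec, shift_ap)
    theta = np.linspace(0.0, 2.0 * np.pi, 256, endpoint=False)
    # sample the nucleus boundary and require it strictly inside the disc
    br = rn + an * np.cos(theta)
    bc = cn + bn * np.sin(theta)
    inside = ((br - r0) / ad) ** 2 + ((bc - c0) / bd) ** 2
    if np.any(inside >= 1.0):
        raise InvalidSpecError(
            "nucleus ellipse not strictly inside disc outer ellipse "
            f"(max normalized radius {np.sqrt(inside.max()):.3f})"
        )
    rc, cc = spec.canal_center
    kr = rc + spec.canal_radius * np.cos(theta)
    kc = cc + spec.canal_radius * np.sin(theta)
    overlap = ((kr - r0) / ad) ** 2 + ((kc - c0) / bd) ** 2
    if np.any(overlap <= 1.0):
        raise InvalidSpecError("spinal canal overlaps the disc outer ellipse")


@dataclass
class PhantomTruth:
    """Ground-truth maps and imposed kinematics of one phantom state."""

    labels: np.ndarray  # uint8 label image
    t1: np.ndarray  # ms
    t2: np.ndarray  # ms
    pd: np.ndarray  # a.u.
    spec: PhantomSpec
    imposed_nucleus_shift: float = 0.0  # mm, anterior positive
    imposed_migration: float = 0.0  # percent
    label_names: dict = field(default_factory=lambda: dict(LABELS))

    @property
    def pixel_spacing(self) -> float:
        return self.spec.pixel_spacing


@dataclass
class ImageSeries:
    """Stack of 2D frames with per-frame timing (TI or TE, ms).

    ``signed`` distinguishes real-valued inversion-recovery data from
    magnitude data; ``norms``/``valid`` are filled by
    :func:`discqmri.relaxometry.normalize_series`.
    """

    frames: np.ndarray  # (n_frames, rows, cols)
    timing: np.ndarray  # ms, strictly increasing
    modality: str  # "IR" or "ME"
    pixel_spacing: float
    signed: bool = True
    norms: np.ndarray | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timing = np.asarray(self.timing, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, rows, cols) stack")
        if len(self.timing) != self.frames.shape[0]:
            raise ValueError("timing length must equal frame count")
        if len(self.timing) and np.any(np.diff(self.timing) <= 0):
            raise ValueError("timing must be strictly increasing")
        if self.modality not in ("IR", "ME"):
            raise ValueError("modality must be 'IR' or 'ME'")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")


@dataclass
class MarkerFrame:
    """Sagittal-plane marker coordinates (mm) of one mechanical state."""

    state_id: str
    markers: list[tuple[str, float, float]]

    def position(self, marker_id: str) -> np.ndarray:
        for mid, x, y in self.markers:
            if mid == marker_id:
                return np.array([x, y], dtype=float)
        raise KeyError(f"marker {marker_id!r} not present in frame {self.state_id!r}")


# ---------------------------------------------------------------------------
# rasterization


def _pixel_grid_mm(shape: tuple[int, int], spacing: float):
    rows = (np.arange(shape[0]) + 0.5) * spacing
    cols = (np.arange(shape[1]) + 0.5) * spacing
    return np.meshgrid(rows, cols, indexing="ij")


def _ray_ellipse_exit(origin, direction, center, semiaxes) -> float:
    """Distance from *origin* along *direction* to the far intersection with
    an axis-aligned ellipse; NaN when the ray misses the ellipse."""
    er = origin[0] - center[0]
    ec = origin[1] - center[1]
    a, b = semiaxes
    dr, dc = direction
    A = (dr / a) ** 2 + (dc / b) ** 2
    B = 2.0 * (er * dr / a**2 + ec * dc / b**2)
    C = (er / a) ** 2 + (ec / b) ** 2 - 1.0
    disc = B * B - 4.0 * A * C
    if disc < 0:
        return float("nan")
    return (-B + np.sqrt(disc)) / (2.0 * A)


def _ellipse_area_fraction(shape, spacing, center, semiaxes, n_sub: int = 8) -> np.ndarray:
    """Per-pixel area fraction inside an axis-aligned ellipse (supersampled)."""
    rows_mm, cols_mm = _pixel_grid_mm(shape, spacing)
    offs = ((np.arange(n_sub) + 0.5) / n_sub - 0.5) * spacing
    count = np.zeros(shape)
    a, b = semiaxes
    for dr in offs:
        for dc in offs:
            count += (((rows_mm + dr - center[0]) / a) ** 2
                      + ((cols_mm + dc - center[1]) / b) ** 2) <= 1.0
    return count / n_sub**2


def make_phantom(
    spec: PhantomSpec,
    shift_ap: float = 0.0,
    infiltration_fraction: float | None = None,
) -> PhantomTruth:
    """Rasterize a phantom state into label and ground-truth property maps.

    ``shift_ap`` rigidly translates the nucleus along the A-P axis
    (anterior positive, mm) by analytic re-rasterization, so sub-pixel
    shifts are represented exactly in the geometry.
    ``infiltration_fraction`` overrides the fissure's fill fraction for
    this state (nucleus tissue advancing into or retreating from the tear
    under load).
    """
    _check_geometry(spec, shift_ap)
    rows_mm, cols_mm = _pixel_grid_mm(spec.grid_shape, spec.pixel_spacing)
    r0, c0 = spec.disc_center
    ad, bd = spec.disc_outer_semiaxes
    an, bn = spec.nucleus_semiaxes
    rn, cn = _nucleus_center(spec, shift_ap)

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    in_disc = ((rows_mm - r0) / ad) ** 2 + ((cols_mm - c0) / bd) ** 2 <= 1.0
    in_nucleus = ((rows_mm - rn) / an) ** 2 + ((cols_mm - cn) / bn) ** 2 <= 1.0
    rc, cc = spec.canal_center
    in_canal = (rows_mm - rc) ** 2 + (cols_mm - cc) ** 2 <= spec.canal_radius**2
    labels[in_disc] = ANNULUS
    labels[in_disc & in_nucleus] = NUCLEUS
    labels[in_canal] = CANAL

    migration = 0.0
    fis = spec.fissure
    if fis is not None:
        fill = fis.infiltration_fraction if infiltration_fraction is None else float(infiltration_fraction)
        if not (0.0 <= fill <= 1.0):
            raise InvalidSpecError("infiltration_fraction must be in [0, 1]")
        depth = fis.radial_depth_fraction
        if depth * fill > 0:
            _rasterize_infiltration(labels, spec, shift_ap, depth * fill, rows_mm, cols_mm)
        migration = 100.0 * depth * fill

    t1 = np.ones(spec.grid_shape)
    t2 = np.ones(spec.grid_shape)
    pd = np.zeros(spec.grid_shape)
    region_of = {ANNULUS: "annulus", NUCLEUS: "nucleus", CANAL: "canal", INFILTRATION: "nucleus"}
    for lab, name in region_of.items():
        t1v, t2v, pdv = spec.compartment_props[name]
        mask = labels == lab
        t1[mask], t2[mask], pd[mask] = t1v, t2v, pdv

    if spec.partial_volume:
        f_np = _ellipse_area_fraction(spec.grid_shape, spec.pixel_spacing, (rn, cn), (an, bn))
        f_np = np.maximum(f_np, labels == INFILTRATION)  # infiltration is nucleus-valued
        f_disc = _ellipse_area_fraction(spec.grid_shape, spec.pixel_spacing, (r0, c0), (ad, bd))
        f_canal = _ellipse_area_fraction(spec.grid_shape, spec.pixel_spacing, (rc, cc),
                                         (spec.canal_radius, spec.canal_radius))
        t1n, t2n, pdn = spec.compartment_props["nucleus"]
        t1a, t2a, pda = spec.compartment_props["annulus"]
        t1c, t2c, pdc = spec.compartment_props["canal"]
        in_tissue = (f_disc > 0) | (f_canal > 0)
        t1 = np.where(in_tissue, f_np * t1n + (1 - f_np) * t1a, 1.0)
        t2 = np.where(in_tissue, f_np * t2n + (1 - f_np) * t2a, 1.0)
        t1 = np.where(f_canal > 0.5, t1c, t1)
        t2 = np.where(f_canal > 0.5, t2c, t2)
        pd = f_disc * (f_np * pdn + (1 - f_np) * pda) + f_canal * pdc

    return PhantomTruth(
        labels=labels, t1=t1, t2=t2, pd=pd, spec=spec,
        imposed_nucleus_shift=float(shift_ap), imposed_migration=migration,
    )


def _rasterize_infiltration(labels, spec, shift_ap, fill_fraction, rows_mm, cols_mm) -> None:
    """Relabel the fissure wedge of the annulus as nucleus infiltration.

    Along each ray from the disc centre inside the wedge, annulus pixels
    with relative radial position <= ``fill_fraction`` of the local annulus
    thickness (nucleus boundary to disc outer boundary) are relabelled.
    """
    fis = spec.fissure
    r0, c0 = spec.disc_center
    annulus_idx = np.argwhere(labels == ANNULUS)
    if annulus_idx.size == 0:
        return
    pr = rows_mm[annulus_idx[:, 0], annulus_idx[:, 1]] - r0
    pc = cols_mm[annulus_idx[:, 0], annulus_idx[:, 1]] - c0
    # angle from the anterior direction (-row), increasing towards +col
    theta = np.degrees(np.arctan2(pc, -pr))
    dtheta = (theta - fis.angular_position + 180.0) % 360.0 - 180.0
    in_wedge = np.abs(dtheta) <= fis.angular_width / 2.0
    sel = annulus_idx[in_wedge]
    if sel.size == 0:
        return
    rn, cn = _nucleus_center(spec, shift_ap)
    for (i, j) in sel:
        p = np.array([rows_mm[i, j], cols_mm[i, j]])
        r = np.hypot(p[0] - r0, p[1] - c0)
        d = (p - np.array([r0, c0])) / r
        r_in = _ray_ellipse_exit((r0, c0), d, (rn, cn), spec.nucleus_semiaxes)
        r_out = _ray_ellipse_exit((r0, c0), d, (r0, c0), spec.disc_outer_semiaxes)
        if not np.isfinite(r_in) or r_out <= r_in:
            continue
        rho = (r - r_in) / (r_out - r_in)
        if rho <= fill_fraction:
            labels[i, j] = INFILTRATION


def apply_mechanical_state(
    truth: PhantomTruth,
    shift_ap: float = 0.0,
    infiltration_fraction: float | None = None,
) -> PhantomTruth:
    """Re-rasterize a phantom under a new mechanical state.

    The nucleus is translated by ``shift_ap`` mm along the A-P axis
    (anterior positive) and the fissure fill fraction is re-set, emulating
    the load-dependent advance/retreat of nucleus tissue into the tear.
    Raises :class:`InvalidSpecError` if the shift pushes the nucleus
    against the disc boundary.
    """
    return make_phantom(truth.spec, shift_ap=shift_ap, infiltration_fraction=infiltration_fraction)


# ---------------------------------------------------------------------------
# MR signal simulation


def _noise(rng: np.random.Generator, signal: np.ndarray, sigma: float, signed: bool) -> np.ndarray:
    if sigma <= 0:
        return signal
    if signed:
        return signal + rng.normal(0.0, sigma, signal.shape)
    # Rician: magnitude of a complex Gaussian perturbation of the signal
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(re, im)


def simulate_ir_series(
    truth: PhantomTruth,
    inversion_times: Sequence[float] | None = None,
    noise_sigma: float | None = None,
    seed: int | None = None,
    signed: bool = True,
) -> ImageSeries:
    """Simulate an inversion-recovery series S(TI) = PD (1 - 2 e^{-TI/T1}).

    With ``signed=False`` the magnitude is taken and Rician noise applied;
    signed data receive plain Gaussian noise.  ``noise_sigma`` is relative
    to the maximum proton density; the default comes from the phantom spec.
    """
    if inversion_times is None:
        inversion_times = DEFAULT_INVERSION_TIMES
    ti = np.asarray(inversion_times, dtype=float)
    if ti.size == 0 or np.any(ti <= 0):
        raise ValueError("inversion times must be positive and nonempty")
    if np.any(np.diff(ti) <= 0):
        raise ValueError("inversion times must be strictly increasing")
    sigma = truth.spec.noise_sigma if noise_sigma is None else noise_sigma
    sigma_abs = sigma * truth.pd.max() if truth.pd.max() > 0 else sigma
    rng = np.random.default_rng(truth.spec.seed if seed is None else seed)
    frames = truth.pd[None] * (1.0 - 2.0 * np.exp(-ti[:, None, None] / truth.t1[None]))
    if not signed:
        frames = np.abs(frames)
    frames = _noise(rng, frames, sigma_abs, signed)
    return ImageSeries(frames=frames, timing=ti, modality="IR",
                       pixel_spacing=truth.pixel_spacing, signed=signed)


def simulate_me_series(
    truth: PhantomTruth,
    echo_times: Sequence[float] | None = None,
    noise_sigma: float | None = None,
    seed: int | None = None,
) -> ImageSeries:
    """Simulate a multi-echo spin-echo series S(TE) = PD e^{-TE/T2}.

    Echo data are magnitudes, so Rician noise is applied.
    """
    if echo_times is None:
        echo_times = DEFAULT_ECHO_TIMES
    te = np.asarray(echo_times, dtype=float)
    if te.size == 0 or np.any(te <= 0):
        raise ValueError("echo times must be positive and nonempty")
    if np.any(np.diff(te) <= 0):
        raise ValueError("echo times must be strictly increasing")
    sigma = truth.spec.noise_sigma if noise_sigma is None else noise_sigma
    sigma_abs = sigma * truth.pd.max() if truth.pd.max() > 0 else sigma
    rng = np.random.default_rng(truth.spec.seed if seed is None else seed)
    frames = truth.pd[None] * np.exp(-te[:, None, None] / truth.t2[None])
    frames = _noise(rng, frames, sigma_abs, signed=False)
    return ImageSeries(frames=frames, timing=te, modality="ME",
                       pixel_spacing=truth.pixel_spacing, signed=False)


#: Inversion-time schedule of the emulated T1-mapping protocol (ms).
DEFAULT_INVERSION_TIMES = (30.0, 60.0, 130.0, 300.0, 600.0, 1300.0, 3000.0, 5800.0)

#: 32-echo train, first echo 30 ms, 30 ms spacing (ms).
DEFAULT_ECHO_TIMES = tuple(30.0 * k for k in range(1, 33))


# ---------------------------------------------------------------------------
# marker frames


def make_marker_frames(
    angle0_deg: float,
    angle_deg: float,
    h0_mm: float,
    h_mm: float,
    stick_length_mm: float = 80.0,
    noise_mm: float = 0.0,
    seed: int = 0,
) -> tuple[MarkerFrame, MarkerFrame]:
    """Build reference and loaded marker frames with imposed kinematics.

    Two rigid sticks carry two marks each.  The lower stick stays
    horizontal; the upper stick makes ``angle0_deg`` (reference frame) or
    ``angle_deg`` (loaded frame) with the horizontal, and the distance
    between the two stick tips is ``h0_mm`` / ``h_mm``.  Optional Gaussian
    jitter of ``noise_mm`` is added to every coordinate.
    """
    if stick_length_mm <= 0:
        raise ValueError("stick_length_mm must be > 0")
    if h0_mm <= 0:
        raise ValueError("h0_mm must be > 0")
    rng = np.random.default_rng(seed)

    def frame(state_id: str, alpha_deg: float, h: float) -> MarkerFrame:
        a = np.radians(alpha_deg)
        lower_base = np.array([0.0, 0.0])
        lower_tip = np.array([stick_length_mm, 0.0])
        upper_tip = lower_tip + np.array([0.0, h])
        upper_base = upper_tip - stick_length_mm * np.array([np.cos(a), np.sin(a)])
        pts = {"lower_base": lower_base, "lower_tip": lower_tip,
               "upper_base": upper_base, "upper_tip": upper_tip}
        markers = []
        for mid, p in pts.items():
            q = p + rng.normal(0.0, noise_mm, 2) if noise_mm > 0 else p
            markers.append((mid, float(q[0]), float(q[1])))
        return MarkerFrame(state_id=state_id, markers=markers)

    return frame("reference", angle0_deg, h0_mm), frame("loaded", angle_deg, h_mm)
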