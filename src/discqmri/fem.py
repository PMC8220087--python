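"""Simplified 2D bi-material finite-element stress analysis of the disc.

The midsagittal disc section is modelled as a rectangle (A-P width taken
from the axial segmentation, height a configurable disc height) split
into an anterior annulus block, a nucleus band and a posterior annulus
block, with an optional anterior notch representing the radial fissure
(depth = radial fraction x anterior annulus width, height = height
fraction x disc height).  Materials are linear isotropic and the
analysis is plane strain with 6-node (quadratic) triangles — quadratic
interpolation keeps the nearly incompressible nucleus (nu = 0.499) free
of volumetric locking.

Loading mirrors the bench experiment: the inferior plate is fully fixed
and the superior plate carries a traction statically equivalent to the
applied bending moment (a pure couple as a linearly varying normal
traction) plus a uniform axial compression.  The 3D moment (N.m) is
converted to a 2D line moment by dividing by the out-of-plane disc
width.  Units: mm, N, MPa.

Sign conventions: x runs anterior (0) to posterior (width); a positive
moment (extension) produces tensile axial stress sigma_yy on the
anterior side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .segmentation import ANNULUS, INFILTRATION, NUCLEUS, DiscLabelMap, SegmentationError, centroid

__all__ = [
    "MaterialProps",
    "DiscSectionGeometry",
    "Mesh",
    "LoadCase",
    "StressField",
    "default_materials",
    "geometry_from_labels",
    "build_mesh",
    "solve_elasticity",
    "stress_fields",
    "equilibrium_residual",
    "compare_intact_fissured",
]


@dataclass(frozen=True)
class MaterialProps:
    """Linear-isotropic material: Young modulus (MPa) and Poisson ratio."""

    young_modulus: float
    poisson_ratio: float
    region: str = ""

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError("Young modulus must be > 0")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError("Poisson ratio must be in [0, 0.5)")


def default_materials() -> dict[str, MaterialProps]:
    """Disc tissue elastic properties used by the simplified model."""
    from .reference_data import MATERIALS

    return {name: MaterialProps(E, nu, region=name) for name, (E, nu) in MATERIALS.items()}


@dataclass(frozen=True)
class DiscSectionGeometry:
    """Rectangular midsagittal section with nucleus band and optional notch.

    ``nucleus_x`` is the (anterior, posterior) x-range of the nucleus
    band; ``notch`` is None (intact) or ``(depth, y_lo, y_hi)`` of the
    anterior fissure rectangle.  All mm.
    """

    width: float
    height: float
    nucleus_x: tuple[float, float]
    notch: tuple[float, float, float] | None = None
    out_of_plane_width: float = 28.0

    def __post_init__(self) -> None:
        xa, xp = self.nucleus_x
        if not (0.0 < xa < xp < self.width):
            raise ValueError("nucleus band must lie strictly inside the section")
        if self.notch is not None:
            d, ylo, yhi = self.notch
            if not (0.0 < d <= xa and 0.0 <= ylo < yhi <= self.height):
                raise ValueError("notch must fit inside the anterior annulus block")


@dataclass
class Mesh:
    """Conforming 6-node triangle mesh.

    ``elements`` columns are (n1, n2, n3, m12, m23, m31) with CCW
    corners; ``region_id`` holds 'nucleus' / 'annulus' per element;
    ``node_sets`` tags inferior/superior plate and fissure-face nodes.
    """

    nodes: np.ndarray  # (N, 2) mm
    elements: np.ndarray  # (M, 6) int
    region_id: np.ndarray  # (M,) object/str
    node_sets: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements[:, :3]].mean(axis=1)


@dataclass(frozen=True)
class LoadCase:
    """Bending moment (N.m, positive = extension) and axial force (N)."""

    moment: float = 0.0
    axial_force: float = 0.0
    out_of_plane_width: float = 28.0

    def __post_init__(self) -> None:
        if self.out_of_plane_width <= 0:
            raise ValueError("out_of_plane_width must be > 0")


@dataclass
class StressField:
    """Per-element stresses at centroids (MPa) on a given mesh."""

    centroids: np.ndarray
    region_id: np.ndarray
    sigma_xx: np.ndarray
    sigma_yy: np.ndarray
    sigma_xy: np.ndarray
    sigma_zz: np.ndarray  # out-of-plane, nu (sxx + syy); stored, not headline
    sigma_1: np.ndarray  # in-plane principal, sigma_1 >= sigma_2
    sigma_2: np.ndarray
    max_shear_intensity: np.ndarray  # (sigma_1 - sigma_2) / 2

    @property
    def axial_stress(self) -> np.ndarray:
        return self.sigma_yy


class MeshingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# geometry from segmentation


def geometry_from_labels(
    labelmap: DiscLabelMap,
    disc_height_mm: float = 10.0,
    fissure_meta: dict | None = None,
) -> DiscSectionGeometry:
    """Derive the sagittal-section geometry from an axial label map.

    A-P extents are read on the midsagittal column band through the disc
    centroid; the lateral disc extent provides the out-of-plane width for
    the 3D-to-2D load conversion.  ``fissure_meta`` carries
    ``height_fraction`` and ``radial_fraction`` of the induced tear
    (defaults 0.54 / 0.27); pass None for the intact geometry.
    """
    disc = labelmap.mask(ANNULUS, NUCLEUS, INFILTRATION)
    nuc = labelmap.mask(NUCLEUS)  # NP body only: the notch models the tear
    if not disc.any() or not nuc.any():
        raise SegmentationError("label map lacks disc or nucleus")
    s = labelmap.pixel_spacing
    r_mm, c_mm = centroid(labelmap, NUCLEUS) if nuc.any() else (0, 0)
    jc = int(round(c_mm / s - 0.5))
    band = slice(max(0, jc - 1), jc + 2)
    rows_disc = np.flatnonzero(disc[:, band].any(axis=1))
    rows_nuc = np.flatnonzero(nuc[:, band].any(axis=1))
    if rows_disc.size < 3 or rows_nuc.size < 1:
        raise MeshingError("degenerate A-P extents on the midsagittal band")
    r0 = rows_disc[0]
    width = (rows_disc[-1] - rows_disc[0] + 1) * s
    xa = (rows_nuc[0] - r0) * s
    xp = (rows_nuc[-1] - r0 + 1) * s
    if not (0 < xa < xp < width):
        raise MeshingError("nucleus band does not sit inside the disc extent")
    cols_disc = np.flatnonzero(disc.any(axis=0))
    out_w = (cols_disc[-1] - cols_disc[0] + 1) * s
    notch = None
    if fissure_meta is not None:
        hf = float(fissure_meta.get("height_fraction", 0.54))
        rf = float(fissure_meta.get("radial_fraction", 0.27))
        depth = rf * xa
        half = hf * disc_height_mm / 2.0
        notch = (depth, disc_height_mm / 2.0 - half, disc_height_mm / 2.0 + half)
    return DiscSectionGeometry(width=width, height=disc_height_mm,
                               nucleus_x=(xa, xp), notch=notch,
                               out_of_plane_width=out_w)


# ---------------------------------------------------------------------------
# structured quadratic-triangle meshing


def _segmented_coords(breaks: list[float], target: float) -> np.ndarray:
    """Grid coordinates honouring the breakpoints with ~target spacing."""
    breaks = sorted(set(float(b) for b in breaks))
    out = [breaks[0]]
    for a, b in zip(breaks[:-1], breaks[1:]):
        n = max(1, int(np.ceil((b - a) / target)))
        out.extend(np.linspace(a, b, n + 1)[1:])
    return np.asarray(out)


def build_mesh(geometry: DiscSectionGeometry, target_edge_mm: float = 0.8) -> Mesh:
    """Structured conforming quadratic-triangle mesh of the section.

    Grid lines are snapped to the nucleus-band and notch boundaries so
    material interfaces and the fissure faces are conforming; each grid
    cell is split into two CCW triangles and midside nodes are added for
    quadratic interpolation.  Elements inside the notch are removed.
    """
    if target_edge_mm <= 0:
        raise MeshingError("target edge must be > 0")
    xa, xp = geometry.nucleus_x
    xb = [0.0, xa, xp, geometry.width]
    yb = [0.0, geometry.height]
    if geometry.notch is not None:
        d, ylo, yhi = geometry.notch
        xb.append(d)
        yb.extend([ylo, yhi])
    xs = _segmented_coords(xb, target_edge_mm)
    ys = _segmented_coords(yb, target_edge_mm)
    nx, ny = len(xs), len(ys)
    corner_id = np.arange(nx * ny).reshape(nx, ny)
    corner_xy = np.array([[x, y] for x in xs for y in ys])

    def in_notch(x: float, y: float) -> bool:
        if geometry.notch is None:
            return False
        d, ylo, yhi = geometry.notch
        return x < d - 1e-12 and ylo + 1e-12 < y < yhi - 1e-12

    tris = []
    regions = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            cx = 0.5 * (xs[i] + xs[i + 1])
            cy = 0.5 * (ys[j] + ys[j + 1])
            if in_notch(cx, cy):
                continue
            n00, n10 = corner_id[i, j], corner_id[i + 1, j]
            n01, n11 = corner_id[i, j + 1], corner_id[i + 1, j + 1]
            tris.append((n00, n10, n11))
            tris.append((n00, n11, n01))
            reg = "nucleus" if (xa - 1e-9 < cx < xp + 1e-9) else "annulus"
            regions.extend([reg, reg])

    used = sorted({n for t in tris for n in t})
    remap = {old: new for new, old in enumerate(used)}
    nodes = [corner_xy[old] for old in used]
    tris = [(remap[a], remap[b], remap[c]) for a, b, c in tris]

    midside: dict[tuple[int, int], int] = {}

    def mid(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        if key not in midside:
            midside[key] = len(nodes)
            nodes.append(0.5 * (np.asarray(nodes[a]) + np.asarray(nodes[b])))
        return midside[key]

    elements = []
    for a, b, c in tris:
        elements.append((a, b, c, mid(a, b), mid(b, c), mid(c, a)))
    nodes = np.asarray(nodes, dtype=float)
    elements = np.asarray(elements, dtype=int)
    region_id = np.asarray(regions, dtype=object)

    # positive-Jacobian check (CCW corners)
    p = nodes[elements[:, :3]]
    areas = 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                   - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    if np.any(areas <= 0):
        raise MeshingError("inverted element produced by structured meshing")

    tol = 1e-9
    inferior = np.flatnonzero(np.abs(nodes[:, 1]) < tol)
    superior = np.flatnonzero(np.abs(nodes[:, 1] - geometry.height) < tol)
    fissure = np.array([], dtype=int)
    if geometry.notch is not None:
        d, ylo, yhi = geometry.notch
        on_face = (np.abs(nodes[:, 0] - d) < tol) & (nodes[:, 1] >= ylo - tol) & (nodes[:, 1] <= yhi + tol)
        on_lips = (nodes[:, 0] <= d + tol) & ((np.abs(nodes[:, 1] - ylo) < tol) | (np.abs(nodes[:, 1] - yhi) < tol))
        fissure = np.flatnonzero(on_face | on_lips)
    return Mesh(nodes=nodes, elements=elements, region_id=region_id,
                node_sets={"inferior_plate": inferior, "superior_plate": superior,
                           "fissure_faces": fissure})


# ---------------------------------------------------------------------------
# quadratic-triangle plane-strain elasticity

# 3-point Gauss rule on the reference triangle (exact to degree 2)
_GAUSS_PTS = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
_GAUSS_W = np.array([1 / 6, 1 / 6, 1 / 6])


def _shape_gradients(xi: float, eta: float) -> np.ndarray:
    """d(N_i)/d(xi, eta) for the 6-node triangle, shape (6, 2)."""
    l1 = 1.0 - xi - eta
    l2, l3 = xi, eta
    dl = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])  # dL_i/d(xi,eta)
    g = np.zeros((6, 2))
    for i in range(3):
        g[i] = (4.0 * [l1, l2, l3][i] - 1.0) * dl[i]
    pairs = [(0, 1), (1, 2), (2, 0)]
    for k, (a, b) in enumerate(pairs):
        L = [l1, l2, l3]
        g[3 + k] = 4.0 * (L[a] * dl[b] + L[b] * dl[a])
    return g


def _dmatrix(mat: MaterialProps) -> np.ndarray:
    """Plane-strain constitutive matrix."""
    E, nu = mat.young_modulus, mat.poisson_ratio
    f = E / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return f * np.array([[1.0 - nu, nu, 0.0],
                         [nu, 1.0 - nu, 0.0],
                         [0.0, 0.0, (1.0 - 2.0 * nu) / 2.0]])


def _element_b(coords: np.ndarray, xi: float, eta: float):
    """Strain-displacement matrix B (3 x 12) and |J| at a reference point."""
    g = _shape_gradients(xi, eta)  # (6,2) in reference coords
    J = coords.T @ g  # (2,2); constant for straight-sided elements
    detJ = np.linalg.det(J)
    gx = g @ np.linalg.inv(J)  # (6,2) physical gradients
    B = np.zeros((3, 12))
    B[0, 0::2] = gx[:, 0]
    B[1, 1::2] = gx[:, 1]
    B[2, 0::2] = gx[:, 1]
    B[2, 1::2] = gx[:, 0]
    return B, detJ


def _assemble(mesh: Mesh, materials: dict[str, MaterialProps]) -> sparse.csr_matrix:
    for reg in np.unique(mesh.region_id):
        if reg not in materials:
            raise ValueError(f"no material for region {reg!r}")
    D = {reg: _dmatrix(materials[reg]) for reg in np.unique(mesh.region_id)}
    rows, cols, vals = [], [], []
    for e in range(mesh.elements.shape[0]):
        conn = mesh.elements[e]
        coords = mesh.nodes[conn]
        ke = np.zeros((12, 12))
        for (xi, eta), w in zip(_GAUSS_PTS, _GAUSS_W):
            B, detJ = _element_b(coords, xi, eta)
            ke += w * detJ * (B.T @ D[mesh.region_id[e]] @ B)
        dof = np.empty(12, dtype=int)
        dof[0::2] = 2 * conn
        dof[1::2] = 2 * conn + 1
        rows.append(np.repeat(dof, 12))
        cols.append(np.tile(dof, 12))
        vals.append(ke.ravel())
    n = 2 * mesh.n_nodes
    K = sparse.coo_matrix((np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                          shape=(n, n)).tocsr()
    return K


def _top_edges(mesh: Mesh) -> list[tuple[int, int, int]]:
    """Superior-plate element edges as (corner_a, midside, corner_b)."""
    top = set(mesh.node_sets["superior_plate"].tolist())
    edges = []
    for conn in mesh.elements:
        corner_pairs = [(0, 1, 3), (1, 2, 4), (2, 0, 5)]
        for a, b, m in corner_pairs:
            na, nb, nm = conn[a], conn[b], conn[m]
            if na in top and nb in top and nm in top:
                edges.append((int(na), int(nm), int(nb)))
    return edges


def _load_vector(mesh: Mesh, load: LoadCase) -> np.ndarray:
    """Consistent nodal forces of the superior-plate traction.

    t_y(x) = -sigma_axial - m_line (x - x_c) / I_line with
    m_line = 1000 M / b (N), I_line = W^3 / 12 (mm^3), sigma in MPa;
    a positive moment gives tension on the anterior (x = 0) side.
    """
    f = np.zeros(2 * mesh.n_nodes)
    edges = _top_edges(mesh)
    if not edges:
        return f
    xs = np.concatenate([mesh.nodes[list(e), 0] for e in edges])
    x_min, x_max = xs.min(), xs.max()
    W = x_max - x_min
    xc = 0.5 * (x_min + x_max)
    b = load.out_of_plane_width
    sigma_ax = load.axial_force / (W * b) if load.axial_force else 0.0
    m_line = 1000.0 * load.moment / b  # N.mm per mm
    I_line = W**3 / 12.0

    def ty(x: float) -> float:
        return -sigma_ax - m_line * (x - xc) / I_line

    # quadratic edge shape functions at s = 0, 1/2, 1; Simpson integration
    # (exact for the cubic integrand N_i(s) * t(s))
    for na, nm, nb in edges:
        pa, pb = mesh.nodes[na], mesh.nodes[nb]
        L = float(np.hypot(*(pb - pa)))
        svals = [0.0, 0.5, 1.0]
        xvals = [pa[0], 0.5 * (pa[0] + pb[0]), pb[0]]
        tvals = [ty(x) for x in xvals]
        N = {  # node -> shape values at the three Simpson points
            na: [1.0, 0.0, 0.0],
            nm: [0.0, 1.0, 0.0],
            nb: [0.0, 0.0, 1.0],
        }
        # quadratic shapes: N_a = (1-s)(1-2s), N_m = 4s(1-s), N_b = s(2s-1)
        shp = lambda s: ((1 - s) * (1 - 2 * s), 4 * s * (1 - s), s * (2 * s - 1))
        for node_i, comp in zip((na, nm, nb), range(3)):
            g = [shp(s)[comp] * t for s, t in zip(svals, tvals)]
            f[2 * node_i + 1] += L * (g[0] + 4 * g[1] + g[2]) / 6.0
    return f


def solve_elasticity(
    mesh: Mesh,
    materials: dict[str, MaterialProps],
    load: LoadCase,
) -> np.ndarray:
    """Plane-strain displacement field (n_nodes x 2, mm).

    The inferior plate is fully fixed; the superior plate carries the
    statically equivalent bending + compression traction.  Raises if no
    constraints are present (singular system).
    """
    K = _assemble(mesh, materials)
    f = _load_vector(mesh, load)
    fixed_nodes = mesh.node_sets.get("inferior_plate", np.array([], dtype=int))
    if fixed_nodes.size == 0:
        raise ValueError("no inferior-plate constraint: system is singular")
    fixed = np.concatenate([2 * fixed_nodes, 2 * fixed_nodes + 1])
    free = np.setdiff1d(np.arange(2 * mesh.n_nodes), fixed)
    u = np.zeros(2 * mesh.n_nodes)
    u[free] = spsolve(K[free][:, free].tocsc(), f[free])
    # iterative refinement to push the relative residual below 1e-8
    r = f[free] - K[free][:, free] @ u[free]
    if np.linalg.norm(f[free]) > 0 and np.linalg.norm(r) > 1e-8 * np.linalg.norm(f[free]):
        u[free] += spsolve(K[free][:, free].tocsc(), r)
    return u.reshape(-1, 2)


def equilibrium_residual(mesh: Mesh, materials, load: LoadCase, displacements: np.ndarray) -> float:
    """Relative imbalance between inferior-plate reactions and applied load."""
    K = _assemble(mesh, materials)
    f = _load_vector(mesh, load)
    r = K @ displacements.ravel() - f
    fixed_nodes = mesh.node_sets["inferior_plate"]
    fixed = np.concatenate([2 * fixed_nodes, 2 * fixed_nodes + 1])
    reactions = r[fixed]
    total_applied = np.array([f[0::2].sum(), f[1::2].sum()])
    total_reaction = np.array([r.reshape(-1, 2)[fixed_nodes, 0].sum(),
                               r.reshape(-1, 2)[fixed_nodes, 1].sum()])
    scale = max(np.abs(f).sum(), np.abs(reactions).sum(), 1e-30)
    return float(np.linalg.norm(total_applied + total_reaction) / scale)


def stress_fields(mesh: Mesh, displacements: np.ndarray,
                  materials: dict[str, MaterialProps]) -> StressField:
    """Element-centroid stresses via plane-strain Hooke's law.

    Stresses are evaluated at the element centroid (the average of the
    quadrature-point stresses of a quadratic triangle equals the centroid
    value for straight-sided elements).
    """
    D = {reg: _dmatrix(materials[reg]) for reg in np.unique(mesh.region_id)}
    n_el = mesh.elements.shape[0]
    sxx = np.zeros(n_el)
    syy = np.zeros(n_el)
    sxy = np.zeros(n_el)
    nus = np.array([materials[r].poisson_ratio for r in mesh.region_id])
    u = displacements.ravel()
    for e in range(n_el):
        conn = mesh.elements[e]
        coords = mesh.nodes[conn]
        dof = np.empty(12, dtype=int)
        dof[0::2] = 2 * conn
        dof[1::2] = 2 * conn + 1
        B, _ = _element_b(coords, 1.0 / 3.0, 1.0 / 3.0)
        s = D[mesh.region_id[e]] @ (B @ u[dof])
        sxx[e], syy[e], sxy[e] = s
    szz = nus * (sxx + syy)
    mean = 0.5 * (sxx + syy)
    rad = np.sqrt((0.5 * (sxx - syy)) ** 2 + sxy**2)
    return StressField(
        centroids=mesh.element_centroids(), region_id=mesh.region_id.copy(),
        sigma_xx=sxx, sigma_yy=syy, sigma_xy=sxy, sigma_zz=szz,
        sigma_1=mean + rad, sigma_2=mean - rad, max_shear_intensity=rad,
    )


def compare_intact_fissured(
    intact: StressField,
    fissured: StressField,
    probe_box: tuple[float, float, float, float],
) -> dict:
    """Stress summary in a probe box (x0, x1, y0, y1) for both models.

    Reports max and mean of \\|axial stress\\| and of the maximal-shear
    intensity inside the box, plus fissured/intact ratios — the region of
    interest sits just beyond the fissure tip, where a stress
    concentration is expected in the damaged disc.
    """
    x0, x1, y0, y1 = probe_box

    def summarize(fld: StressField) -> dict:
        c = fld.centroids
        sel = (c[:, 0] >= x0) & (c[:, 0] <= x1) & (c[:, 1] >= y0) & (c[:, 1] <= y1)
        if not sel.any():
            raise ValueError("probe box contains no element centroids")
        return {
            "axial_max": float(np.max(np.abs(fld.axial_stress[sel]))),
            "axial_mean": float(np.mean(np.abs(fld.axial_stress[sel]))),
            "shear_max": float(np.max(fld.max_shear_intensity[sel])),
            "shear_mean": float(np.mean(fld.max_shear_intensity[sel])),
            "n_elements": int(sel.sum()),
        }

    si, sf = summarize(intact), summarize(fissured)
    ratios = {k: (sf[k] / si[k] if si[k] > 0 else float("inf"))
              for k in ("axial_max", "axial_mean", "shear_max", "shear_mean")}
    return {"intact": si, "fissured": sf, "ratio": ratios}
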