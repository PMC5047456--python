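"""Parametric multi-layer head phantoms.

The phantom is a five-layer sphere set (scalp, skull, CSF, gray matter,
white matter) with an axis-aligned ellipsoidal tumor, a peritumoral shell,
parametric skull defects (virtual craniectomy / burr holes), an optional
resection cavity, scalp electrode patches and synthetic per-element
diffusion tensors.  It stands in for MRI-derived patient head models: the
geometry is idealized, but it reproduces the layered volume-conduction
physics that controls how skull defects channel current into the brain.

Virtual surgery is pure relabeling: node coordinates and connectivity are
never touched, so paired scenarios (with/without craniectomy, with/without
resection) share the identical discretization and support element-by-element
difference maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .constants import Tissue
from .mesh import VolumeMesh, face_areas, layered_sphere_mesh

__all__ = [
    "HeadPhantomSpec", "SkullDefectSpec", "DiffusionTensorField",
    "ElectrodePair", "TensorParams",
    "build_head_phantom", "flag_peritumoral", "apply_skull_defect",
    "apply_resection", "generate_diffusion_tensors", "place_electrode_pairs",
    "default_layout",
]


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeadPhantomSpec:
    """Geometry of the layered-sphere head phantom.

    ``layer_radii`` are the outer radii (mm) of scalp, skull, CSF, GM and WM
    in that order, strictly decreasing.  The tumor is an axis-aligned
    ellipsoid that must lie entirely inside the brain (GM ball).
    """

    layer_radii: tuple = (92.0, 85.0, 79.0, 76.0, 60.0)
    tumor_center: tuple = (31.0, 0.0, 0.0)
    tumor_semiaxes: tuple = (25.0, 17.5, 25.5)
    peritumor_margin: float = 10.0
    target_edge_length: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        r = np.asarray(self.layer_radii, dtype=float)
        if len(r) != 5 or np.any(np.diff(r) >= 0) or r[-1] <= 0:
            raise ValueError("layer_radii must be 5 strictly decreasing positive radii")
        if self.peritumor_margin <= 0:
            raise ValueError("peritumor_margin must be > 0")
        if self.target_edge_length <= 0:
            raise ValueError("target_edge_length must be > 0")
        a = np.asarray(self.tumor_semiaxes, dtype=float)
        if np.any(a <= 0):
            raise ValueError("infeasible geometry: tumor semiaxes must be > 0 "
                             f"(got {tuple(self.tumor_semiaxes)})")
        # sample the ellipsoid surface and require it inside the GM ball
        th = np.linspace(0, np.pi, 64)
        ph = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        T, P = np.meshgrid(th, ph, indexing="ij")
        pts = np.stack([a[0] * np.sin(T) * np.cos(P),
                        a[1] * np.sin(T) * np.sin(P),
                        a[2] * np.cos(T)], axis=-1).reshape(-1, 3)
        pts = pts + np.asarray(self.tumor_center, dtype=float)
        if np.max(np.linalg.norm(pts, axis=1)) >= r[3]:
            raise ValueError(
                "infeasible geometry: tumor extends outside the brain "
                f"(GM outer radius {r[3]} mm); spec = {self}")

    @staticmethod
    def superficial(**overrides) -> "HeadPhantomSpec":
        """Default phantom emulating a superficial fronto-parietal tumor
        (50 x 35 x 51 mm ellipsoid, surface ~20 mm below the cortical
        boundary, along +x)."""
        return replace(HeadPhantomSpec(), **overrides)

    @staticmethod
    def deep(**overrides) -> "HeadPhantomSpec":
        """Deep variant: a 32 x 51 x 41 mm tumor at the head centre,
        emulating a thalamic lesion."""
        spec = HeadPhantomSpec(tumor_center=(0.0, 0.0, 0.0),
                               tumor_semiaxes=(16.0, 25.5, 20.5))
        return replace(spec, **overrides)


@dataclass(frozen=True)
class SkullDefectSpec:
    """A skull defect as a (multi-)cylindrical footprint.

    All cylinders run parallel to ``center_direction`` (a unit vector from
    the head centre through the defect centre).  ``circle`` uses
    ``diameter``; ``oval_flap`` uses ``principal_diameters`` along the two
    tangent axes; ``burr_holes`` uses ``hole_diameter`` plus 2-D
    ``hole_centers`` offsets (mm) in the tangent plane.
    """

    kind: str = "circle"
    center_direction: tuple = (1.0, 0.0, 0.0)
    diameter: float = 50.0
    principal_diameters: tuple = (50.0, 67.0)
    hole_diameter: float = 15.0
    hole_centers: tuple = ((-8.75, -12.75), (-8.75, 12.75),
                          (8.75, -12.75), (8.75, 12.75))

    def validate(self) -> None:
        if self.kind not in ("circle", "oval_flap", "burr_holes"):
            raise ValueError(f"unknown defect kind {self.kind!r}")
        if self.kind == "circle" and not (0.0 <= self.diameter <= 100.0):
            raise ValueError("circle diameter must lie in [0, 100] mm")
        if self.kind == "burr_holes" and len(self.hole_centers) < 1:
            raise ValueError("burr_holes needs at least one hole centre")

    def footprint_area(self) -> float:
        """Analytic area (mm^2) of the defect footprint."""
        if self.kind == "circle":
            return np.pi * (self.diameter / 2.0) ** 2
        if self.kind == "oval_flap":
            a, b = self.principal_diameters
            return np.pi * a * b / 4.0
        return len(self.hole_centers) * np.pi * (self.hole_diameter / 2.0) ** 2

    @staticmethod
    def four_burr_holes(tumor_semiaxes=(25.0, 17.5, 25.5),
                        center_direction=(1.0, 0.0, 0.0),
                        hole_diameter: float = 15.0) -> "SkullDefectSpec":
        """Four holes in a rectangle spanning half the tumor's tangent-plane
        projection — 'distributed evenly across the tumor projection'."""
        axis = np.asarray(center_direction, dtype=float)
        axis = axis / np.linalg.norm(axis)
        t1, t2 = _tangent_frame(axis)
        semi = np.asarray(tumor_semiaxes, dtype=float)
        # projected tumor semiaxes onto the two tangent directions
        bu = np.sqrt(np.sum((semi * t1) ** 2))
        bv = np.sqrt(np.sum((semi * t2) ** 2))
        du, dv = 0.5 * bu, 0.5 * bv
        centers = tuple((su * du, sv * dv) for su in (-1, 1) for sv in (-1, 1))
        return SkullDefectSpec(kind="burr_holes",
                               center_direction=tuple(axis),
                               hole_diameter=hole_diameter,
                               hole_centers=centers)


def _tangent_frame(axis: np.ndarray):
    """Deterministic orthonormal tangent frame (t1, t2) for a unit axis."""
    helper = np.array([0.0, 0.0, 1.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(axis, helper)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(axis, t1)
    return t1, t2


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def _radial_nodes(layer_radii, h: float) -> np.ndarray:
    """Shell radii: every layer boundary, plus intermediates so the radial
    spacing stays below ~h, with an innermost shell at ~h (the centre fan)."""
    bounds = np.sort(np.asarray(layer_radii, dtype=float))  # ascending
    radii = []
    r0 = max(1.5 * h, 8.0)
    r0 = min(r0, bounds[0] * 0.45)
    inner = np.arange(r0, bounds[0] - 0.49 * h, h)
    radii.extend(inner)
    prev = 0.0
    for b in bounds:
        if radii:
            prev = radii[-1]
        gap = b - prev
        n_extra = int(np.floor(gap / h))
        for i in range(1, n_extra):
            radii.append(prev + gap * i / n_extra)
        radii.append(b)
    return np.unique(np.round(radii, 9))


def _subdivisions_for(h: float, r_outer: float) -> int:
    """Icosphere level whose edge length at the outer radius is ~h."""
    n = int(np.round(np.log2(1.0515 * r_outer / h)))
    return int(np.clip(n, 2, 6))


def _inside_ellipsoid(points, center, semiaxes) -> np.ndarray:
    u = (points - np.asarray(center)) / np.asarray(semiaxes)
    return np.einsum("ij,ij->i", u, u) < 1.0


def build_head_phantom(spec: HeadPhantomSpec) -> VolumeMesh:
    """Build the labeled 5-layer phantom with tumor.

    Shell nodes are placed exactly on every layer boundary, so compartment
    volumes converge to the analytic sphere-shell values; tumor membership
    is decided per element by its centroid falling inside the ellipsoid.
    """
    spec.validate()
    radii_desc = np.asarray(spec.layer_radii, dtype=float)
    subdiv = _subdivisions_for(spec.target_edge_length, radii_desc[0])
    radial = _radial_nodes(radii_desc, spec.target_edge_length)
    mesh = layered_sphere_mesh(radial, subdiv)

    r = np.linalg.norm(mesh.centroids, axis=1)
    # ascending boundaries: wm, gm, csf, skull, scalp outer radii
    bounds = radii_desc[::-1]
    layer_of = np.searchsorted(bounds, r)  # 0 => inside WM ball
    codes = np.array([Tissue.WM, Tissue.GM, Tissue.CSF, Tissue.SKULL,
                      Tissue.SCALP], dtype=np.int64)
    layer_of = np.clip(layer_of, 0, 4)
    mesh.labels = codes[layer_of]

    in_tumor = _inside_ellipsoid(mesh.centroids, spec.tumor_center,
                                 spec.tumor_semiaxes)
    brain = np.isin(mesh.labels, (Tissue.GM, Tissue.WM))
    mesh.labels[in_tumor & brain] = Tissue.TUMOR
    if not np.any(in_tumor & brain):
        raise ValueError("infeasible geometry: tumor captured no elements; "
                         f"spec = {spec}")

    mesh.metadata.update({
        "spec": spec,
        "seed": spec.seed,
        "layer_radii": tuple(spec.layer_radii),
        "tumor_center": tuple(spec.tumor_center),
        "tumor_semiaxes": tuple(spec.tumor_semiaxes),
    })
    return flag_peritumoral(mesh, spec.peritumor_margin)


# ---------------------------------------------------------------------------
# peritumoral shell
# ---------------------------------------------------------------------------

def _point_triangle_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distances from points[i] to triangles tri[i] (paired, (K,3,3))."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, points - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    def settle(mask, pts):
        m = mask & ~done
        closest[m] = pts[m] if pts.shape == points.shape else pts
        done[m] = True

    settle((d1 <= 0) & (d2 <= 0), a)                       # vertex a
    settle((d3 >= 0) & (d4 <= d3), b)                      # vertex b
    settle((d6 >= 0) & (d5 <= d6), c)                      # vertex c
    vc = d1 * d4 - d3 * d2
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    v = np.divide(d1, d1 - d3, out=np.zeros_like(d1), where=(d1 - d3) != 0)
    settle(m, a + v[:, None] * ab)                          # edge ab
    vb = d5 * d2 - d1 * d6
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    w = np.divide(d2, d2 - d6, out=np.zeros_like(d2), where=(d2 - d6) != 0)
    settle(m, a + w[:, None] * ac)                          # edge ac
    va = d3 * d6 - d5 * d4
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    w = np.divide(d4 - d3, denom, out=np.zeros_like(d4), where=denom != 0)
    settle(m, b + w[:, None] * (c - b))                     # edge bc
    # interior
    denom = va + vb + vc
    v = np.divide(vb, denom, out=np.zeros_like(vb), where=denom != 0)
    w = np.divide(vc, denom, out=np.zeros_like(vc), where=denom != 0)
    settle(np.ones(len(points), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    return np.linalg.norm(points - closest, axis=1)


def distance_to_surface(points: np.ndarray, nodes: np.ndarray,
                        faces: np.ndarray, k: int = 12) -> np.ndarray:
    """Distance from each point to a triangulated surface: KD-tree prefilter
    on triangle centroids, exact point-triangle distance on the k nearest."""
    tri = nodes[faces]
    tree = cKDTree(tri.mean(axis=1))
    k = min(k, len(faces))
    _, idx = tree.query(points, k=k)
    idx = np.atleast_2d(idx.T).T
    best = np.full(len(points), np.inf)
    for j in range(idx.shape[1]):
        d = _point_triangle_distance(points, tri[idx[:, j]])
        best = np.minimum(best, d)
    return best


def flag_peritumoral(mesh: VolumeMesh, margin: float) -> VolumeMesh:
    """Flag non-tumor brain elements whose centroid lies strictly closer
    than ``margin`` (mm) to the triangulated tumor boundary surface."""
    if margin <= 0:
        raise ValueError("peritumoral margin must be > 0")
    tumor = mesh.labels == Tissue.TUMOR
    if not np.any(tumor):
        raise ValueError("mesh has no tumor compartment to flag around")
    faces, _ = mesh.boundary_faces(tumor)
    brain = np.isin(mesh.labels, (Tissue.GM, Tissue.WM))
    # cheap prefilter: bounding sphere of the tumor surface + margin
    surf_pts = mesh.nodes[np.unique(faces)]
    center = surf_pts.mean(axis=0)
    r_max = np.max(np.linalg.norm(surf_pts - center, axis=1))
    cand = brain & (np.linalg.norm(mesh.centroids - center, axis=1)
                    < r_max + margin + 1.0)
    flag = np.zeros(mesh.n_elements, dtype=bool)
    if np.any(cand):
        d = distance_to_surface(mesh.centroids[cand], mesh.nodes, faces)
        flag[np.flatnonzero(cand)[d < margin]] = True
    mesh.flags["peritumoral"] = flag
    return mesh


# ---------------------------------------------------------------------------
# virtual surgery
# ---------------------------------------------------------------------------

def _in_footprint(points: np.ndarray, defect: SkullDefectSpec) -> np.ndarray:
    """Membership of points in the defect's cylindrical footprint (axes
    parallel to center_direction, evaluated in the tangent frame)."""
    axis = np.asarray(defect.center_direction, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t1, t2 = _tangent_frame(axis)
    ax = points @ axis
    u = points @ t1
    v = points @ t2
    side = ax > 0  # only the hemisphere the defect centre is on
    if defect.kind == "circle":
        r = defect.diameter / 2.0
        return side & (u ** 2 + v ** 2 <= r ** 2)
    if defect.kind == "oval_flap":
        ra, rb = (d / 2.0 for d in defect.principal_diameters)
        return side & ((u / ra) ** 2 + (v / rb) ** 2 <= 1.0)
    r = defect.hole_diameter / 2.0
    hit = np.zeros(len(points), dtype=bool)
    for (cu, cv) in defect.hole_centers:
        hit |= (u - cu) ** 2 + (v - cv) ** 2 <= r ** 2
    return side & hit


def apply_skull_defect(mesh: VolumeMesh, defect: SkullDefectSpec) -> VolumeMesh:
    """Virtual craniectomy: relabel skull elements inside the defect
    footprint as scalp (bone flap replaced by skin).  Pure relabeling."""
    defect.validate()
    skull = mesh.labels == Tissue.SKULL
    hit = skull & _in_footprint(mesh.centroids, defect)
    if defect.kind == "circle" and defect.diameter == 0:
        return mesh  # zero-measure footprint: identity
    if not np.any(hit):
        raise ValueError(f"skull defect footprint misses the skull entirely: {defect}")
    mesh.labels[hit] = Tissue.SCALP
    relabeled = mesh.get_flag("defect_relabeled")
    relabeled |= hit
    mesh.flags["defect_relabeled"] = relabeled
    scalp = mesh.labels == Tissue.SCALP
    mesh.flags["over_defect_skin"] = scalp & _in_footprint(mesh.centroids, defect)
    mesh.metadata["defect"] = defect
    return mesh


def defect_patch_area(mesh: VolumeMesh) -> float:
    """Footprint area (mm^2) of the defect on the skull: relabeled volume
    divided by the skull-shell thickness.  The volumetric measure is far
    less sensitive to surface-triangle granularity than summing boundary
    face areas."""
    relabeled = mesh.get_flag("defect_relabeled")
    if not np.any(relabeled):
        return 0.0
    radii = mesh.metadata.get("layer_radii")
    if radii is not None:
        thickness = float(radii[1] - radii[2])      # skull outer - inner
    else:
        nr = np.linalg.norm(mesh.nodes[np.unique(mesh.tets[relabeled])],
                            axis=1)
        thickness = float(nr.max() - nr.min())
    return float(mesh.volumes[relabeled].sum() / thickness)


def apply_resection(mesh: VolumeMesh) -> VolumeMesh:
    """Virtual gross total resection: relabel every tumor element as CSF
    (cavity filled with CSF).  Peritumoral flags — defined against the
    pre-resection tumor boundary — are left untouched."""
    tumor = mesh.labels == Tissue.TUMOR
    if not np.any(tumor):
        warnings.warn("apply_resection: mesh has no tumor compartment; no-op",
                      stacklevel=2)
        return mesh
    mesh.labels[tumor] = Tissue.CSF
    mesh.flags["resected"] = tumor
    mesh.metadata["resected"] = True
    return mesh


# ---------------------------------------------------------------------------
# synthetic diffusion tensors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TensorParams:
    """Per-tissue synthetic DTI parameters.

    ``md`` mean diffusivity (mm^2/s), ``fa`` fractional anisotropy target in
    [0, 1), ``orientation`` the principal-eigenvector rule ('radial' or
    'tangential'), ``noise_sigma`` the log-normal scale of the per-element
    multiplicative dispersion (applied to the whole tensor, preserving FA).

    Defaults emulate brain DTI at body temperature; the dispersion is sized
    so the mapped conductivity interquartile ranges land on the ~0.03-0.06
    S/m scale seen in patient data.
    """

    md: dict = field(default_factory=lambda: {
        Tissue.GM: 0.89e-3, Tissue.WM: 0.69e-3, Tissue.TUMOR: 0.95e-3})
    fa: dict = field(default_factory=lambda: {
        Tissue.GM: 0.15, Tissue.WM: 0.70, Tissue.TUMOR: 0.10})
    orientation: dict = field(default_factory=lambda: {
        Tissue.GM: "tangential", Tissue.WM: "radial", Tissue.TUMOR: "radial"})
    noise_sigma: float = 0.25

    def validate(self) -> None:
        for t, v in self.md.items():
            if v <= 0:
                raise ValueError(f"mean diffusivity for {t} must be > 0")
        for t, v in self.fa.items():
            if not (0.0 <= v < 1.0):
                raise ValueError(f"fractional anisotropy for {t} must be in [0, 1)")


@dataclass
class DiffusionTensorField:
    """Per-element symmetric positive-definite diffusion tensors (mm^2/s).

    ``tensors`` has shape (M, 3, 3); ``covered`` marks the elements (GM, WM,
    tumor) the generator filled — others hold zeros.
    """

    tensors: np.ndarray
    covered: np.ndarray
    params: TensorParams
    seed: int

    def mean_diffusivity(self) -> np.ndarray:
        return np.trace(self.tensors, axis1=1, axis2=2) / 3.0


def _axisymmetric_eigvals(md: float, fa: float):
    """(lam1, lam2) of a prolate axially symmetric tensor with the requested
    mean diffusivity and fractional anisotropy: lam1 = md (1 + 2 d),
    lam2 = lam3 = md (1 - d) with d = fa / sqrt(3 - 2 fa^2)."""
    d = fa / np.sqrt(3.0 - 2.0 * fa ** 2)
    return md * (1.0 + 2.0 * d), md * (1.0 - d)


def generate_diffusion_tensors(mesh: VolumeMesh, params: TensorParams | None = None,
                               seed: int = 0) -> DiffusionTensorField:
    """Synthesize per-element diffusion tensors for GM, WM and tumor.

    WM principal eigenvectors follow the local radial direction (the phantom
    analogue of fiber tracts crossing the layered geometry), GM eigenvectors
    lie tangentially, and each element's tensor is scaled by a log-normal
    factor exp(N(0, noise_sigma)) to emulate biological dispersion without
    perturbing the anisotropy.  Fully reproducible from the seed.
    """
    params = params or TensorParams()
    params.validate()
    rng = np.random.default_rng(seed)

    M = mesh.n_elements
    tensors = np.zeros((M, 3, 3))
    covered = np.zeros(M, dtype=bool)
    cent = mesh.centroids
    rad = cent / np.maximum(np.linalg.norm(cent, axis=1, keepdims=True), 1e-12)

    for tissue in (Tissue.GM, Tissue.WM, Tissue.TUMOR):
        sel = np.flatnonzero(mesh.labels == tissue)
        if len(sel) == 0:
            continue
        lam1, lam2 = _axisymmetric_eigvals(params.md[tissue], params.fa[tissue])
        e1 = rad[sel]
        if params.orientation[tissue] == "tangential":
            helper = np.zeros_like(e1)
            helper[:, 2] = 1.0
            swap = np.abs(e1[:, 2]) > 0.9
            helper[swap] = [0.0, 1.0, 0.0]
            e1 = np.cross(rad[sel], helper)
            e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        # D = lam2 I + (lam1 - lam2) e1 e1^T  (axially symmetric)
        D = lam2 * np.eye(3)[None, :, :] + \
            (lam1 - lam2) * np.einsum("ij,ik->ijk", e1, e1)
        scale = np.exp(rng.normal(0.0, params.noise_sigma, size=len(sel)))
        tensors[sel] = D * scale[:, None, None]
        covered[sel] = True

    return DiffusionTensorField(tensors=tensors, covered=covered,
                                params=params, seed=seed)


# ---------------------------------------------------------------------------
# electrode placement
# ---------------------------------------------------------------------------

@dataclass
class ElectrodePair:
    """One transducer-array pair: two disjoint sets of outer-scalp boundary
    faces and the current (A) injected at waveform peak."""

    name: str
    faces_a: np.ndarray
    faces_b: np.ndarray
    current: float = 0.9

    def __post_init__(self) -> None:
        if self.current < 0:
            raise ValueError("injected current must be non-negative")
        if len(self.faces_a) == 0 or len(self.faces_b) == 0:
            raise ValueError(f"pair {self.name}: empty electrode patch")
        ka = {tuple(sorted(f)) for f in self.faces_a}
        kb = {tuple(sorted(f)) for f in self.faces_b}
        if ka & kb:
            raise ValueError(f"pair {self.name}: electrode patches overlap")

    def patch_areas(self, mesh: VolumeMesh):
        return (float(face_areas(mesh.nodes, self.faces_a).sum()),
                float(face_areas(mesh.nodes, self.faces_b).sum()))


def default_layout(patch_size=(70.0, 50.0)) -> dict:
    """Two orthogonal pairs: L/R along ±x (straddling the superficial tumor
    and skull defect laterally) and A/P along ±y.  ``patch_size`` is the
    (width, height) footprint in mm of each rectangular array patch."""
    return {
        "LR": ((1.0, 0.0, 0.0), (-1.0, 0.0, 0.0)),
        "AP": ((0.0, 1.0, 0.0), (0.0, -1.0, 0.0)),
        "patch_size": tuple(patch_size),
    }


def _select_patch(mesh: VolumeMesh, faces: np.ndarray, owners: np.ndarray,
                  direction, patch_size) -> np.ndarray:
    """Outer-surface faces whose centroids fall inside a geodesic rectangle
    of the given (width, height) centred on ``direction``."""
    w, h = patch_size
    if w <= 0 or h <= 0:
        raise ValueError("electrode patch dimensions must be > 0")
    axis = np.asarray(direction, dtype=float)
    axis /= np.linalg.norm(axis)
    t1, t2 = _tangent_frame(axis)
    fc = mesh.nodes[faces].mean(axis=1)
    R = np.linalg.norm(fc, axis=1)
    d = fc / R[:, None]
    u = R * np.arctan2(d @ t1, d @ axis)
    v = R * np.arctan2(d @ t2, d @ axis)
    front = d @ axis > 0
    sel = front & (np.abs(u) <= w / 2.0) & (np.abs(v) <= h / 2.0)
    return sel


def place_electrode_pairs(mesh: VolumeMesh, layout: dict | None = None,
                          current: float = 0.9):
    """Place the L/R and A/P electrode pairs on the outer scalp surface.

    Returns ``(pair_LR, pair_AP)``.  Patches are geodesic rectangles of the
    layout's ``patch_size``; overlapping patches raise.  Scalp elements
    under any patch are flagged ``under_electrode_skin``.
    """
    if current <= 0:
        raise ValueError("injected current must be > 0")
    layout = layout or default_layout()
    patch_size = layout.get("patch_size", (70.0, 50.0))
    faces, owners = mesh.boundary_faces()

    masks = {}
    for pair_name in ("LR", "AP"):
        dir_a, dir_b = layout[pair_name]
        masks[pair_name + "_a"] = _select_patch(mesh, faces, owners, dir_a, patch_size)
        masks[pair_name + "_b"] = _select_patch(mesh, faces, owners, dir_b, patch_size)

    stacked = np.stack(list(masks.values()))
    if np.any(stacked.sum(axis=0) > 1):
        raise ValueError("electrode patches overlap on the scalp surface")

    pairs = tuple(
        ElectrodePair(name=nm, faces_a=faces[masks[nm + "_a"]],
                      faces_b=faces[masks[nm + "_b"]], current=current)
        for nm in ("LR", "AP"))

    under = np.zeros(mesh.n_elements, dtype=bool)
    scalp = mesh.labels == Tissue.SCALP
    for key, m in masks.items():
        dir_vec = layout[key[:-2]][0 if key.endswith("_a") else 1]
        axis = np.asarray(dir_vec, dtype=float)
        axis /= np.linalg.norm(axis)
        t1, t2 = _tangent_frame(axis)
        c = mesh.centroids
        R = np.linalg.norm(c, axis=1)
        with np.errstate(invalid="ignore"):
            d = c / np.maximum(R[:, None], 1e-12)
        u = R * np.arctan2(d @ t1, d @ axis)
        v = R * np.arctan2(d @ t2, d @ axis)
        w, h = patch_size
        under |= scalp & (d @ axis > 0) & (np.abs(u) <= w / 2) & (np.abs(v) <= h / 2)
    mesh.flags["under_electrode_skin"] = under
    return pairs
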