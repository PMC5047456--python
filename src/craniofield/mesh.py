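"""Tetrahedral volume meshes with per-element tissue labels and region flags.

The mesh is a plain container (nodes in mm, 4-node tets, integer labels)
plus the geometric queries the rest of the pipeline needs: element volumes
and centroids, boundary-face extraction, compartment surfaces, and a
geometry hash used to guarantee that paired scenarios share the identical
discretization.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .constants import Tissue

__all__ = ["VolumeMesh", "box_mesh", "icosphere", "tet_volumes", "face_areas"]


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes (mm^3) of tetrahedra; positive for right-handed order."""
    p = nodes[tets]
    a, b, c = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def face_areas(nodes: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Areas (mm^2) of triangles given as (K, 3) node-index rows."""
    p = nodes[faces]
    return 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)


# the four faces of a tet, each opposite the omitted local vertex;
# ordering gives outward normals for a positively oriented tet
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


@dataclass
class VolumeMesh:
    """Labeled conforming tetrahedral mesh.

    Attributes
    ----------
    nodes : (N, 3) float array, mm
    tets : (M, 4) int array of node indices, positively oriented
    labels : (M,) int array of :class:`~craniofield.constants.Tissue` codes
    flags : dict of named per-element boolean masks (``peritumoral``,
        ``defect_relabeled``, ``resected``, ``under_electrode_skin``,
        ``over_defect_skin``, ...)
    metadata : free-form provenance (spec echo, seed, ...)
    """

    nodes: np.ndarray
    tets: np.ndarray
    labels: np.ndarray
    flags: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise ValueError("tets must be an (M, 4) index array")
        if len(self.labels) != len(self.tets):
            raise ValueError("labels must have one entry per element")
        self._volumes: np.ndarray | None = None
        self._centroids: np.ndarray | None = None

    # ---- cached geometry -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    @property
    def volumes(self) -> np.ndarray:
        """Element volumes in mm^3 (all positive for a valid mesh)."""
        if self._volumes is None:
            self._volumes = tet_volumes(self.nodes, self.tets)
        return self._volumes

    @property
    def centroids(self) -> np.ndarray:
        if self._centroids is None:
            self._centroids = self.nodes[self.tets].mean(axis=1)
        return self._centroids

    def total_volume(self) -> float:
        return float(self.volumes.sum())

    def compartment_volume(self, tissue: int) -> float:
        return float(self.volumes[self.labels == tissue].sum())

    def geometry_hash(self) -> str:
        """Hash of node coordinates and connectivity only — invariant under
        relabeling operations (virtual surgery)."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.nodes).tobytes())
        h.update(np.ascontiguousarray(self.tets).tobytes())
        return h.hexdigest()

    def get_flag(self, name: str) -> np.ndarray:
        """Named boolean mask, defaulting to all-False if never set."""
        if name in self.flags:
            return self.flags[name]
        return np.zeros(self.n_elements, dtype=bool)

    # ---- topology --------------------------------------------------------
    def _all_faces(self, element_mask: np.ndarray | None = None):
        tets = self.tets if element_mask is None else self.tets[element_mask]
        owners = np.repeat(
            np.arange(self.n_elements) if element_mask is None
            else np.flatnonzero(element_mask), 4)
        faces = tets[:, _TET_FACES].reshape(-1, 3)
        return faces, owners

    def boundary_faces(self, element_mask: np.ndarray | None = None):
        """Triangles occurring exactly once among the faces of the selected
        elements (the surface of that sub-volume), with owning element ids.

        Returns ``(faces, owners)`` where faces preserve the outward
        orientation of the owning tet.
        """
        faces, owners = self._all_faces(element_mask)
        key = np.sort(faces, axis=1)
        order = np.lexsort(key.T)
        key_sorted = key[order]
        boundary = np.ones(len(key), dtype=bool)
        dup = np.all(key_sorted[1:] == key_sorted[:-1], axis=1)
        flat = np.zeros(len(key), dtype=bool)
        flat[1:] = dup
        flat[:-1] |= dup
        boundary[order] = ~flat
        return faces[boundary], owners[boundary]

    def compartment_surface(self, tissue: int):
        """Closed triangulated surface of one labeled compartment."""
        return self.boundary_faces(self.labels == tissue)

    def is_conforming(self) -> bool:
        """Every interior face must be shared by exactly two tets."""
        faces, _ = self._all_faces()
        key = np.sort(faces, axis=1)
        _, counts = np.unique(key, axis=0, return_counts=True)
        return bool(np.all(counts <= 2))

    def copy(self) -> "VolumeMesh":
        return VolumeMesh(
            self.nodes.copy(), self.tets.copy(), self.labels.copy(),
            {k: v.copy() for k, v in self.flags.items()},
            dict(self.metadata),
        )


def _fix_orientation(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Swap two vertices of negatively oriented tets (volume sign flip)."""
    v = tet_volumes(nodes, tets)
    bad = v < 0
    tets = tets.copy()
    tets[bad, 2], tets[bad, 3] = tets[bad, 3], tets[bad, 2].copy()
    return tets


# ---------------------------------------------------------------------------
# primitive meshers used for phantoms and validation problems
# ---------------------------------------------------------------------------

# Kuhn subdivision of the unit cube into 6 tets sharing the main diagonal;
# neighbouring cubes produce matching triangles on shared faces.
_KUHN = np.array([
    [0, 1, 3, 7], [0, 1, 7, 5], [0, 5, 7, 4],
    [0, 3, 2, 7], [0, 2, 6, 7], [0, 6, 4, 7],
])


def box_mesh(shape: tuple[int, int, int], size: tuple[float, float, float],
             label: int = int(Tissue.WM)) -> VolumeMesh:
    """Structured tet mesh of a box: ``shape`` cells per axis, ``size`` in mm."""
    nx, ny, nz = shape
    xs = [np.linspace(0.0, size[i], n + 1) for i, n in enumerate(shape)]
    grid = np.stack(np.meshgrid(*xs, indexing="ij"), axis=-1).reshape(-1, 3)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    # cube corner ids in (x, y, z) bit order matching _KUHN
    corners = np.stack([nid(i + (c >> 2 & 1), j + (c >> 1 & 1), k + (c & 1))
                        for c in range(8)], axis=1)
    tets = corners[:, _KUHN].reshape(-1, 4)
    tets = _fix_orientation(grid, tets)
    labels = np.full(len(tets), label, dtype=np.int64)
    return VolumeMesh(grid, tets, labels, metadata={"generator": "box_mesh"})


_ICO_T = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array([
    [-1, _ICO_T, 0], [1, _ICO_T, 0], [-1, -_ICO_T, 0], [1, -_ICO_T, 0],
    [0, -1, _ICO_T], [0, 1, _ICO_T], [0, -1, -_ICO_T], [0, 1, -_ICO_T],
    [_ICO_T, 0, -1], [_ICO_T, 0, 1], [-_ICO_T, 0, -1], [-_ICO_T, 0, 1],
], dtype=float)
_ICO_FACES = np.array([
    [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
    [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
    [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
    [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
])


def icosphere(subdivisions: int):
    """Geodesic triangulation of the unit sphere (20 * 4**n faces).

    Returns ``(verts, faces)`` with outward-oriented faces.
    """
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS[0])
    faces = _ICO_FACES.copy()
    for _ in range(subdivisions):
        edge_mid: dict[tuple[int, int], int] = {}
        verts_list = list(verts)
        new_faces = []

        def midpoint(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key not in edge_mid:
                m = verts_list[a] + verts_list[b]
                verts_list.append(m / np.linalg.norm(m))
                edge_mid[key] = len(verts_list) - 1
            return edge_mid[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(verts_list)
        faces = np.array(new_faces)
    return verts, faces


def _split_prism(bot: np.ndarray, top: np.ndarray) -> np.ndarray:
    """Split triangular prisms into 3 tets each with diagonals chosen by the
    smallest-global-index rule, so adjacent prisms triangulate shared quad
    faces identically (conforming by construction).

    bot, top: (P, 3) node-index arrays; vertex i of top sits above vertex i
    of bot.  Returns (P * 3, 4) tets.
    """
    prisms = np.concatenate([bot, top], axis=1)  # local order 0,1,2 | 3,4,5
    out = np.empty((len(prisms), 3, 4), dtype=np.int64)
    rot = np.array([[0, 1, 2, 3, 4, 5], [1, 2, 0, 4, 5, 3], [2, 0, 1, 5, 3, 4]])
    # rotate each prism so its smallest global index is at local vertex 0 or 3
    amin = np.argmin(prisms, axis=1) % 3
    p = np.take_along_axis(prisms, rot[amin], axis=1)
    # Dompierre et al. indirection: compare the two candidate diagonals of the
    # quad face opposite vertex 0
    use_first = np.minimum(p[:, 1], p[:, 5]) < np.minimum(p[:, 2], p[:, 4])
    t1 = np.stack([p[:, [0, 1, 2, 5]], p[:, [0, 1, 5, 4]], p[:, [0, 4, 5, 3]]], axis=1)
    t2 = np.stack([p[:, [0, 1, 2, 4]], p[:, [0, 4, 2, 5]], p[:, [0, 4, 5, 3]]], axis=1)
    out[use_first] = t1[use_first]
    out[~use_first] = t2[~use_first]
    return out.reshape(-1, 4)


def layered_sphere_mesh(radial_nodes: np.ndarray, subdivisions: int) -> VolumeMesh:
    """Onion mesh: concentric geodesic shells joined by prisms (split into
    tets), with a tet fan from the centre node to the innermost shell.

    ``radial_nodes`` are the shell radii in mm, ascending; labels are not
    assigned here (all zero) — callers classify elements afterwards.
    """
    radial_nodes = np.asarray(radial_nodes, dtype=float)
    if radial_nodes.ndim != 1 or len(radial_nodes) < 1:
        raise ValueError("need at least one shell radius")
    if np.any(np.diff(radial_nodes) <= 0) or radial_nodes[0] <= 0:
        raise ValueError("radial_nodes must be positive and ascending")
    sv, sf = icosphere(subdivisions)
    n_sv = len(sv)
    nodes = [np.zeros((1, 3))]
    for r in radial_nodes:
        nodes.append(sv * r)
    nodes = np.concatenate(nodes, axis=0)

    tets = [np.concatenate(
        [np.zeros((len(sf), 1), dtype=np.int64), 1 + sf], axis=1)]
    for k in range(len(radial_nodes) - 1):
        bot = 1 + k * n_sv + sf
        top = bot + n_sv
        tets.append(_split_prism(bot, top))
    tets = np.concatenate(tets, axis=0)
    tets = _fix_orientation(nodes, tets)
    labels = np.zeros(len(tets), dtype=np.int64)
    return VolumeMesh(nodes, tets, labels,
                      metadata={"generator": "layered_sphere_mesh",
                                "subdivisions": subdivisions,
                                "radial_nodes": radial_nodes.tolist()})
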