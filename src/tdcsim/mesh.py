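"""Tagged simplicial meshes for multi-tissue head phantoms.

The spatial discretization used throughout the package is a conforming
simplicial mesh (triangles in 2D, tetrahedra in 3D) in which every element
carries one of five tissue labels: skin, skull, cerebrospinal fluid (CSF),
grey matter (GM) and white matter (WM).  The union of GM and WM elements is
the brain region ``Omega_B`` where the bidomain equations live; everything
else is a passive volume conductor.

All coordinates are stored in meters and all physics downstream is SI.
Two-dimensional problems are interpreted as unit-depth (1 m) slabs, so an
electrode current of "1 mA" means 1 mA per meter of depth.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "Tissue",
    "ElectrodeKind",
    "SimplicialMesh",
    "ElectrodePatch",
    "build_annulus_phantom",
    "place_electrode",
    "read_mesh",
    "write_mesh",
]


class Tissue(enum.IntEnum):
    """The five head tissues, ordered from outermost to innermost."""

    SKIN = 1
    SKULL = 2
    CSF = 3
    GM = 4
    WM = 5


#: Tissues that make up the brain region Omega_B (where neurons live).
BRAIN_TISSUES = frozenset({Tissue.GM, Tissue.WM})


class ElectrodeKind(enum.Enum):
    ANODE = "anode"
    CATHODE = "cathode"


class MeshError(ValueError):
    """Raised for invalid mesh construction or I/O requests."""


def _boundary_facets_of(elements: np.ndarray) -> np.ndarray:
    """Facets (edges/faces) that belong to exactly one element.

    Returned with node indices sorted within each facet and facets sorted
    lexicographically, so the result is a deterministic function of the
    element array alone.
    """
    elements = np.asarray(elements)
    d = elements.shape[1] - 1  # simplex dimension
    # all facets: drop one vertex at a time
    facets = []
    for drop in range(d + 1):
        keep = [k for k in range(d + 1) if k != drop]
        facets.append(elements[:, keep])
    allf = np.sort(np.concatenate(facets, axis=0), axis=1)
    uniq, counts = np.unique(allf, axis=0, return_counts=True)
    bnd = uniq[counts == 1]
    return np.ascontiguousarray(bnd)


@dataclass
class SimplicialMesh:
    """A conforming simplicial mesh with per-element tissue tags.

    Parameters
    ----------
    nodes : (n_nodes, d) float array
        Node coordinates in meters, d in {2, 3}.
    elements : (n_elements, d+1) int array
        Node index tuples of each d-simplex.
    tissue_tag : (n_elements,) int array
        One :class:`Tissue` value per element.
    boundary_facets : (n_facets, d) int array, optional
        Facets on the outer surface.  Recomputed from the elements when not
        supplied.
    boundary_tag : (n_facets,) int array, optional
        Integer label per boundary facet (0 = untagged scalp).
    """

    nodes: np.ndarray
    elements: np.ndarray
    tissue_tag: np.ndarray
    boundary_facets: np.ndarray | None = None
    boundary_tag: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.elements = np.ascontiguousarray(self.elements, dtype=np.int64)
        self.tissue_tag = np.ascontiguousarray(self.tissue_tag, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] not in (2, 3):
            raise MeshError("nodes must be (n, 2) or (n, 3)")
        d = self.nodes.shape[1]
        if self.elements.shape[1] != d + 1:
            raise MeshError(
                f"{d}-dimensional mesh requires {d + 1}-node simplices, "
                f"got {self.elements.shape[1]}-node elements"
            )
        if self.tissue_tag.shape != (self.elements.shape[0],):
            raise MeshError("tissue_tag must have one entry per element")
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= len(self.nodes)
        ):
            raise MeshError("element references node index out of range")
        meas = self.element_measures()
        if np.any(meas <= 0.0):
            bad = int(np.argmin(meas))
            raise MeshError(f"degenerate element {bad} (measure {meas[bad]:g})")
        if self.boundary_facets is None:
            self.boundary_facets = _boundary_facets_of(self.elements)
        else:
            self.boundary_facets = np.ascontiguousarray(
                self.boundary_facets, dtype=np.int64
            )
        if self.boundary_tag is None:
            self.boundary_tag = np.zeros(len(self.boundary_facets), dtype=np.int64)

    # -- geometry -----------------------------------------------------------

    @property
    def dim(self) -> int:
        return self.nodes.shape[1]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_measures(self) -> np.ndarray:
        """Signed-free measures (areas in 2D, volumes in 3D) per element."""
        if "measures" in self._cache:
            return self._cache["measures"]
        p = self.nodes[self.elements]  # (m, d+1, d)
        v = p[:, 1:, :] - p[:, :1, :]  # (m, d, d)
        det = np.linalg.det(v)
        meas = np.abs(det) / (2.0 if self.dim == 2 else 6.0)
        self._cache["measures"] = meas
        return meas

    def element_centroids(self) -> np.ndarray:
        if "centroids" not in self._cache:
            self._cache["centroids"] = self.nodes[self.elements].mean(axis=1)
        return self._cache["centroids"]

    # -- tissue queries -----------------------------------------------------

    def brain_element_mask(self) -> np.ndarray:
        return np.isin(self.tissue_tag, [int(t) for t in BRAIN_TISSUES])

    def brain_nodes(self) -> np.ndarray:
        """Sorted global indices of nodes belonging to any brain element."""
        if "brain_nodes" not in self._cache:
            be = self.elements[self.brain_element_mask()]
            self._cache["brain_nodes"] = np.unique(be)
        return self._cache["brain_nodes"]

    def tissue_areas(self) -> dict[Tissue, float]:
        meas = self.element_measures()
        return {
            t: float(meas[self.tissue_tag == int(t)].sum())
            for t in Tissue
            if np.any(self.tissue_tag == int(t))
        }

    # -- boundary geometry (2D) ---------------------------------------------

    def boundary_facet_midpoints(self) -> np.ndarray:
        return self.nodes[self.boundary_facets].mean(axis=1)

    def boundary_facet_measures(self) -> np.ndarray:
        p = self.nodes[self.boundary_facets]
        if self.dim == 2:
            return np.linalg.norm(p[:, 1, :] - p[:, 0, :], axis=1)
        a = p[:, 1, :] - p[:, 0, :]
        b = p[:, 2, :] - p[:, 0, :]
        return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


@dataclass
class ElectrodePatch:
    """A contiguous set of scalp boundary facets acting as one electrode.

    ``total_current`` is the net injected current in amperes (per meter of
    depth in 2D); it is meaningful for the anode only — the cathode is a
    grounded (Dirichlet) reference.
    """

    kind: ElectrodeKind
    facet_indices: np.ndarray
    total_current: float = 0.0

    def __post_init__(self) -> None:
        self.facet_indices = np.ascontiguousarray(self.facet_indices, dtype=np.int64)

    def nodes(self, mesh: SimplicialMesh) -> np.ndarray:
        return np.unique(mesh.boundary_facets[self.facet_indices])


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------

#: Tissue of each concentric band, innermost disc first.
_BAND_TISSUES = (Tissue.WM, Tissue.GM, Tissue.CSF, Tissue.SKULL, Tissue.SKIN)


def _ring_points(radii_bands: list[tuple[float, float]], h: float) -> np.ndarray:
    """Concentric-ring node cloud honouring the band interfaces.

    Rings are snapped so that every tissue interface radius carries a ring,
    per-ring node counts are kept even and ring phases alternate by half a
    step; both choices preserve mirror symmetry about the x and y axes,
    which the axisymmetric physics of the phantom otherwise has no way to
    recover on an unstructured mesh.
    """
    ring_radii: list[float] = []
    r_prev = 0.0
    for (r0, r1) in radii_bands:
        nsub = max(1, int(round((r1 - r0) / h)))
        for k in range(1, nsub + 1):
            ring_radii.append(r0 + (r1 - r0) * k / nsub)
        r_prev = r1
    del r_prev

    pts = [np.zeros((1, 2))]
    for iring, r in enumerate(ring_radii):
        n_theta = int(round(np.pi * r / h)) * 2
        n_theta = max(n_theta, 8)
        offset = 0.5 if (iring % 2) else 0.0
        theta = 2.0 * np.pi * (np.arange(n_theta) + offset) / n_theta
        pts.append(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
    return np.concatenate(pts, axis=0)


def build_annulus_phantom(
    radii: tuple[float, float, float, float, float] = (0.040, 0.050, 0.070, 0.090, 0.100),
    csf_strip_width: float = 0.010,
    target_element_count: int = 10_000,
    strip_max_radius: float | None = None,
) -> SimplicialMesh:
    """Build the 2D five-tissue concentric-annulus head phantom.

    The innermost disc (radius ``radii[0]``) is white matter; the four
    surrounding annuli out to ``radii[1:]`` are grey matter, CSF, skull and
    skin.  A horizontal CSF strip of the given width crosses the brain,
    emulating CSF interwoven with the cortex: every element whose centroid
    satisfies ``|y| <= csf_strip_width/2`` and lies inside
    ``strip_max_radius`` (default: the GM outer radius, confining the strip
    to the cerebral region) is retagged CSF.

    Parameters are in meters.  ``target_element_count`` is met to within
    roughly 20%.
    """
    radii = tuple(float(r) for r in radii)
    if len(radii) != 5:
        raise MeshError("exactly five radii required (WM, GM, CSF, skull, skin)")
    if not all(r1 > r0 for r0, r1 in zip(radii, radii[1:])) or radii[0] <= 0:
        raise MeshError(f"radii must be strictly increasing and positive: {radii}")
    if csf_strip_width < 0 or csf_strip_width >= 2 * radii[0]:
        raise MeshError("csf_strip_width must lie in [0, 2*innermost radius)")
    if strip_max_radius is None:
        strip_max_radius = radii[1]

    R = radii[-1]
    thinnest = min(r1 - r0 for r0, r1 in zip((0.0,) + radii, radii))
    # two triangles per h x h cell is a decent first guess for ring meshes
    h = float(np.sqrt(2.0 * np.pi * R * R / max(target_element_count, 1)))
    if target_element_count < 500 or h > 1.5 * thinnest:
        raise MeshError(
            f"target_element_count={target_element_count} too small to resolve "
            f"the thinnest annulus ({thinnest * 1e3:.1f} mm)"
        )

    bands = list(zip((0.0,) + radii[:-1], radii))
    mesh = None
    for _ in range(6):
        pts = _ring_points(bands, h)
        tri = Delaunay(pts)
        elems = tri.simplices
        # orient counter-clockwise and drop slivers (degenerate co-circular cases)
        p = pts[elems]
        det = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
            p[:, 1, 1] - p[:, 0, 1]
        ) * (p[:, 2, 0] - p[:, 0, 0])
        flip = det < 0
        elems[flip, 0], elems[flip, 1] = elems[flip, 1], elems[flip, 0].copy()
        area = 0.5 * np.abs(det)
        elems = elems[area > 1e-9 * R * R]

        count = len(elems)
        if abs(count - target_element_count) <= 0.15 * target_element_count:
            break
        h *= float(np.sqrt(count / target_element_count))
    else:
        elems = elems  # keep last attempt; validated below

    centroids = pts[elems].mean(axis=1)
    rc = np.linalg.norm(centroids, axis=1)
    band_idx = np.searchsorted(np.asarray(radii), rc)
    band_idx = np.clip(band_idx, 0, 4)
    tags = np.array([int(_BAND_TISSUES[b]) for b in band_idx], dtype=np.int64)

    if csf_strip_width > 0:
        in_strip = (np.abs(centroids[:, 1]) <= csf_strip_width / 2.0) & (
            rc <= strip_max_radius
        )
        tags[in_strip] = int(Tissue.CSF)

    mesh = SimplicialMesh(nodes=pts, elements=elems, tissue_tag=tags)
    n = mesh.n_elements
    if abs(n - target_element_count) > 0.20 * target_element_count:
        raise MeshError(
            f"could not meet target element count {target_element_count} "
            f"(achieved {n})"
        )
    return mesh


# ---------------------------------------------------------------------------
# Electrodes
# ---------------------------------------------------------------------------


def place_electrode(
    mesh: SimplicialMesh,
    kind: ElectrodeKind | str,
    center_angle: float,
    arc_length: float,
    total_current: float = 0.0,
) -> ElectrodePatch:
    """Select scalp boundary facets for an electrode on the circular phantom.

    ``center_angle`` is the polar angle (radians) of the electrode center on
    the outer circle; ``arc_length`` (meters) is the electrode size measured
    along the circle.  All boundary facets whose midpoint lies within
    ``arc_length/2`` of the center along the circumference are selected.
    """
    kind = ElectrodeKind(kind)
    mids = mesh.boundary_facet_midpoints()
    if len(mids) == 0:
        raise MeshError("mesh has no boundary facets")
    r_mid = np.linalg.norm(mids[:, :2], axis=1)
    R = r_mid.max()
    theta = np.arctan2(mids[:, 1], mids[:, 0])
    dtheta = np.angle(np.exp(1j * (theta - center_angle)))
    sel = np.flatnonzero(np.abs(dtheta) * R <= arc_length / 2.0)
    if sel.size == 0:
        raise MeshError(
            f"no boundary facets within {arc_length * 1e3:.1f} mm arc at "
            f"angle {center_angle:.3f} rad — arc too small for mesh resolution"
        )
    return ElectrodePatch(kind=kind, facet_indices=sel, total_current=total_current)


# ---------------------------------------------------------------------------
# Gmsh-dialect text I/O (MSH 2.2 ASCII)
# ---------------------------------------------------------------------------

_GMSH_TRI = 2
_GMSH_LINE = 1
_GMSH_TET = 4


def write_mesh(mesh: SimplicialMesh, path) -> None:
    """Write a tagged mesh as Gmsh MSH 2.2 ASCII.

    Each tissue becomes a physical group whose id is the :class:`Tissue`
    enum value; boundary facets are emitted as lower-dimensional elements
    with physical id ``100 + boundary_tag``.
    """
    etype = _GMSH_TRI if mesh.dim == 2 else _GMSH_TET
    ftype = _GMSH_LINE if mesh.dim == 2 else _GMSH_TRI
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    lines.append("$PhysicalNames")
    names = [(mesh.dim, int(t), t.name) for t in Tissue]
    lines.append(str(len(names)))
    for d, pid, nm in names:
        lines.append(f'{d} {pid} "{nm}"')
    lines.append("$EndPhysicalNames")
    lines.append("$Nodes")
    lines.append(str(mesh.n_nodes))
    for i, xy in enumerate(mesh.nodes, start=1):
        x, y = float(xy[0]), float(xy[1])
        z = float(xy[2]) if mesh.dim == 3 else 0.0
        lines.append(f"{i} {x!r} {y!r} {z!r}")
    lines.append("$EndNodes")
    lines.append("$Elements")
    lines.append(str(mesh.n_elements + len(mesh.boundary_facets)))
    eid = 1
    for el, tag in zip(mesh.elements, mesh.tissue_tag):
        conn = " ".join(str(v + 1) for v in el)
        lines.append(f"{eid} {etype} 2 {int(tag)} {int(tag)} {conn}")
        eid += 1
    for fc, btag in zip(mesh.boundary_facets, mesh.boundary_tag):
        conn = " ".join(str(v + 1) for v in fc)
        lines.append(f"{eid} {ftype} 2 {100 + int(btag)} {100 + int(btag)} {conn}")
        eid += 1
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_mesh(path, tag_map: dict[int, Tissue] | None = None) -> SimplicialMesh:
    """Read a Gmsh MSH 2.2 ASCII mesh with tissue physical groups.

    ``tag_map`` maps physical-group ids to :class:`Tissue` values; by
    default ids are interpreted directly as Tissue enum values.  An element
    whose physical group has no mapping is an error (naming the group).
    Boundary facets are recomputed from element adjacency, so meshes written
    by :func:`write_mesh` round-trip exactly.
    """
    with open(path) as fh:
        txt = fh.read()
    sections: dict[str, list[str]] = {}
    cur = None
    for ln in txt.splitlines():
        ln = ln.strip()
        if ln.startswith("$End"):
            cur = None
        elif ln.startswith("$"):
            cur = ln[1:]
            sections[cur] = []
        elif cur is not None:
            sections[cur].append(ln)
    if "Nodes" not in sections or "Elements" not in sections:
        raise MeshError(f"{path}: not a MSH 2.2 file (missing Nodes/Elements)")

    node_lines = sections["Nodes"][1:]
    coords = np.array([[float(t) for t in ln.split()[1:4]] for ln in node_lines])
    elem_lines = sections["Elements"][1:]

    tris, tri_tags = [], []
    tets, tet_tags = [], []
    for ln in elem_lines:
        parts = ln.split()
        etype = int(parts[1])
        ntags = int(parts[2])
        phys = int(parts[3]) if ntags >= 1 else 0
        conn = [int(v) - 1 for v in parts[3 + ntags :]]
        if etype == _GMSH_TRI:
            tris.append(conn)
            tri_tags.append(phys)
        elif etype == _GMSH_TET:
            tets.append(conn)
            tet_tags.append(phys)
        elif etype in (_GMSH_LINE, 15):  # boundary lines / points: recomputed
            continue
        else:
            raise MeshError(f"{path}: unsupported element type {etype}")

    if tets and tris:
        # a 3D mesh may carry surface triangles; treat triangles as facets
        elems, phys = np.array(tets), tet_tags
        dim = 3
    elif tets:
        elems, phys = np.array(tets), tet_tags
        dim = 3
    elif tris:
        elems, phys = np.array(tris), tri_tags
        dim = 2
    else:
        raise MeshError(f"{path}: no volume elements found")

    if tag_map is None:
        tag_map = {int(t): t for t in Tissue}
    tags = np.empty(len(elems), dtype=np.int64)
    for i, pid in enumerate(phys):
        if pid not in tag_map:
            raise MeshError(
                f"{path}: physical group {pid} has no tissue mapping "
                f"(known: {sorted(tag_map)})"
            )
        tags[i] = int(tag_map[pid])

    nodes = coords[:, :dim]
    return SimplicialMesh(nodes=nodes, elements=elems, tissue_tag=tags)
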