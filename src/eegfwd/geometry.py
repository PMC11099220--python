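"""Layered spherical head meshes and dipole placement.

The volume meshes used throughout the package are nested-shell tetrahedral
meshes built from a single spherical surface triangulation that is extruded
radially: every tissue interface (brain/skull, skull/scalp, scalp/air, ...)
is triangulated by the *same* angular mesh scaled to the shell radius, the
gaps between consecutive radial layers are filled with triangular prisms,
and each prism is split into three tetrahedra with a globally consistent
diagonal rule.  The construction guarantees that

* every interface sphere is exactly a set of tetrahedron faces (so boundary
  surfaces extracted for the BEM / hybrid coupling conform to the FE mesh),
* each tetrahedron lies entirely inside one tissue shell,
* the mesh is deterministic for a fixed density and seed.

All coordinates are SI (meters).  Shell radii enter in centimeters only at
the model-specification boundary, mirroring how head-model parameters are
usually quoted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull, cKDTree
from scipy.spatial.transform import Rotation


# --------------------------------------------------------------------------
# model specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MeshDensity:
    """Mesh-size control for :func:`build_sphere_mesh`.

    n_surface
        Number of vertices of the angular triangulation shared by all
        shells; the triangulation has ``2 * n_surface - 4`` triangles.
    inner_layers
        Number of radial element layers across the innermost region
        (center to first shell).
    outer_layers
        Radial element layers for each remaining region (one entry per
        region beyond the first; missing entries default to 1).
    """

    n_surface: int = 519
    inner_layers: int = 4
    outer_layers: tuple[int, ...] = ()
    inner_grading: float = 1.0   # <1 concentrates radial layers near the
    #                              innermost shell, where eccentric sources sit
    cap_fraction: float = 0.0    # fraction of surface points packed into a
    cap_angle_deg: float = 25.0  # polar cap around +z (the source axis of the
    #                              validation setup); sharpens the scalp peak
    #                              over eccentric dipoles at fixed budget

    def scaled(self, factor: float) -> "MeshDensity":
        """Return a density with the surface point count scaled by ``factor``
        (element counts scale roughly linearly with ``factor``)."""
        return MeshDensity(
            n_surface=max(12, int(round(self.n_surface * factor))),
            inner_layers=max(1, int(round(self.inner_layers * np.sqrt(factor)))),
            outer_layers=self.outer_layers,
        )


@dataclass(frozen=True)
class SphereModelSpec:
    """Concentric multi-shell head model.

    radii_cm are the outer radii of each shell, innermost first.  Each layer
    carries a conductivity interval [S/m] from which Monte-Carlo draws are
    taken; ``skull_anisotropy`` optionally fixes a radial:tangential
    conductivity pair for the skull layer (used instead of the interval).
    """

    radii_cm: tuple[float, ...]
    conductivity_intervals: tuple[tuple[float, float], ...]
    layer_names: tuple[str, ...]
    skull_layer: int | None = None            # 1-based region label of the skull
    skull_anisotropy: tuple[float, float] | None = None   # (sigma_r, sigma_t) S/m
    density: MeshDensity = field(default_factory=MeshDensity)

    def __post_init__(self):
        r = np.asarray(self.radii_cm, float)
        if not np.all(np.diff(r) > 0):
            raise ValueError("shell radii must be strictly increasing")
        if len(self.conductivity_intervals) != len(self.radii_cm):
            raise ValueError("one conductivity interval per layer required")
        for lo, hi in self.conductivity_intervals:
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid conductivity interval [{lo}, {hi}]")

    @property
    def radii_m(self) -> np.ndarray:
        return np.asarray(self.radii_cm, float) * 1e-2

    @property
    def n_layers(self) -> int:
        return len(self.radii_cm)

    def midpoint_conductivities(self) -> np.ndarray:
        return np.array([(lo + hi) / 2 for lo, hi in self.conductivity_intervals])


def three_layer_model(density: MeshDensity | None = None) -> SphereModelSpec:
    """Brain / skull / scalp shells (outer radii 8.0 / 8.6 / 9.2 cm)."""
    return SphereModelSpec(
        radii_cm=(8.0, 8.6, 9.2),
        conductivity_intervals=((0.2200, 0.6700), (0.0016, 0.0330), (0.2800, 0.8700)),
        layer_names=("brain", "skull", "scalp"),
        skull_layer=2,
        skull_anisotropy=(0.0093, 0.015),
        density=density or MeshDensity(
            n_surface=1050, inner_layers=5, outer_layers=(1, 1),
            inner_grading=0.8, cap_fraction=0.25),
    )


def four_layer_model(density: MeshDensity | None = None) -> SphereModelSpec:
    """Brain / CSF / skull / scalp shells (outer radii 7.6 / 8.0 / 8.6 / 9.2 cm)."""
    return SphereModelSpec(
        radii_cm=(7.6, 8.0, 8.6, 9.2),
        conductivity_intervals=(
            (0.2200, 0.6700), (1.7696, 1.8104), (0.0016, 0.0330), (0.2800, 0.8700)),
        layer_names=("brain", "csf", "skull", "scalp"),
        skull_layer=3,
        skull_anisotropy=(0.0093, 0.015),
        density=density or MeshDensity(
            n_surface=1777, inner_layers=5, outer_layers=(1, 1, 1),
            inner_grading=0.8, cap_fraction=0.25),
    )


# --------------------------------------------------------------------------
# core mesh containers
# --------------------------------------------------------------------------

@dataclass
class LabeledTetMesh:
    """Tetrahedral volume mesh with per-element tissue labels.

    nodes: (n, 3) float array [m]; tets: (m, 4) int array (0-based);
    region_label: (m,) int array, 1 = innermost tissue, increasing outward.
    """

    nodes: np.ndarray
    tets: np.ndarray
    region_label: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, float)
        self.tets = np.ascontiguousarray(self.tets, np.int64)
        self.region_label = np.ascontiguousarray(self.region_label, np.int64)
        if self.tets.shape[0] != self.region_label.shape[0]:
            raise ValueError("one region label per tetrahedron required")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_tets(self) -> int:
        return self.tets.shape[0]

    @property
    def labels_present(self) -> np.ndarray:
        return np.unique(self.region_label)

    def tet_volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        return np.einsum(
            "ij,ij->i",
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
            p[:, 3] - p[:, 0],
        ) / 6.0

    def tet_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def orient_positive(self) -> None:
        """Swap node order of inverted tets so all signed volumes are > 0."""
        neg = self.tet_volumes() < 0
        self.tets[neg, 2], self.tets[neg, 3] = (
            self.tets[neg, 3].copy(), self.tets[neg, 2].copy())

    def restricted(self, labels: Sequence[int]) -> tuple["LabeledTetMesh", np.ndarray]:
        """Submesh of the given region labels.

        Returns the submesh (nodes renumbered) and the array mapping submesh
        node index -> parent node index.
        """
        keep = np.isin(self.region_label, np.asarray(labels))
        tets = self.tets[keep]
        used = np.unique(tets)
        remap = -np.ones(self.n_nodes, np.int64)
        remap[used] = np.arange(used.size)
        sub = LabeledTetMesh(
            nodes=self.nodes[used],
            tets=remap[tets],
            region_label=self.region_label[keep],
            provenance={**self.provenance, "restricted_to": tuple(labels)},
        )
        return sub, used


@dataclass
class InterfaceSurface:
    """Closed triangulated surface between two tissue regions.

    Triangle node indices refer to the parent mesh; triangles are oriented
    so their normals point from ``inner_region`` toward ``outer_region``
    (``outer_region`` = 0 denotes the exterior / air).
    """

    nodes: np.ndarray          # parent mesh node coordinates (shared array)
    triangles: np.ndarray      # (t, 3) node indices, outward-oriented
    inner_region: int
    outer_region: int

    def __post_init__(self):
        self.triangles = np.ascontiguousarray(self.triangles, np.int64)

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    @property
    def vertices(self) -> np.ndarray:
        return self.nodes[self.triangles]   # (t, 3, 3)

    def centroids(self) -> np.ndarray:
        return self.vertices.mean(axis=1)

    def areas(self) -> np.ndarray:
        v = self.vertices
        return 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)

    def normals(self) -> np.ndarray:
        v = self.vertices
        n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def total_area(self) -> float:
        return float(self.areas().sum())

    def solid_angle(self, point: np.ndarray) -> float:
        """Summed signed solid angle of all triangles seen from ``point``.

        4*pi for interior points of a closed outward-oriented surface
        (Gauss), 0 for exterior points.
        """
        from .bem import triangle_solid_angles
        return float(triangle_solid_angles(self.vertices, np.asarray(point, float)).sum())


@dataclass(frozen=True)
class Dipole:
    """Point current dipole: position [m], unit direction, strength [A*m].

    ``monopole_separation`` selects the equivalent source/sink pair
    representation r0 +- (d/2) * direction carrying current I = strength/d.
    """

    position: np.ndarray
    direction: np.ndarray
    strength: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, float))
        d = np.asarray(self.direction, float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("dipole direction must be nonzero")
        object.__setattr__(self, "direction", d / n)

    @property
    def moment(self) -> np.ndarray:
        return self.strength * self.direction

    def monopoles(self, separation: float) -> tuple[np.ndarray, np.ndarray, float]:
        """(sink position r1, source position r2, current I) with I*d = strength."""
        if separation <= 0:
            raise ValueError("separation must be positive")
        half = 0.5 * separation * self.direction
        return self.position - half, self.position + half, self.strength / separation


# --------------------------------------------------------------------------
# sphere triangulation and radial extrusion
# --------------------------------------------------------------------------

def fibonacci_sphere(n: int, seed: int = 0) -> np.ndarray:
    """n approximately uniform unit vectors (Fibonacci lattice, then a
    seed-dependent random rotation so meshes differ across seeds)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    s = np.sqrt(1.0 - z * z)
    pts = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    rot = Rotation.random(random_state=np.random.default_rng(seed)).as_matrix()
    return pts @ rot.T


def sphere_points(n: int, seed: int = 0, cap_fraction: float = 0.0,
                  cap_angle_deg: float = 25.0) -> np.ndarray:
    """Unit-sphere point set, optionally graded toward the +z polar cap.

    With ``cap_fraction`` > 0, that fraction of the points is distributed
    over the spherical cap of half-angle ``cap_angle_deg`` around +z (a
    golden-angle spiral, uniform per area within the cap) and global
    lattice points falling inside the cap are removed.  The cap is pinned
    to +z regardless of the seed rotation because the validation sources
    sit on the z-axis.
    """
    if not 0 <= cap_fraction < 1:
        raise ValueError("cap_fraction must be in [0, 1)")
    if cap_fraction == 0.0:
        return fibonacci_sphere(n, seed)
    n_cap = max(3, int(round(n * cap_fraction)))
    n_glob = n - n_cap
    pts = fibonacci_sphere(n_glob, seed)
    zc = np.cos(np.radians(cap_angle_deg))
    pts = pts[pts[:, 2] < zc]
    j = np.arange(n_cap)
    zj = 1.0 - (1.0 - zc) * (2.0 * j + 1.0) / (2.0 * n_cap)
    sj = np.sqrt(1.0 - zj * zj)
    pj = np.pi * (3.0 - np.sqrt(5.0)) * j + 0.7
    cap = np.column_stack([sj * np.cos(pj), sj * np.sin(pj), zj])
    return np.vstack([pts, cap])


def sphere_triangulation(
    n: int, seed: int = 0, cap_fraction: float = 0.0,
    cap_angle_deg: float = 25.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate the unit sphere with about n vertices.

    Returns (directions, triangles) with triangles oriented outward
    (counter-clockwise seen from outside); the triangle count is
    2 * n_points - 4.
    """
    if n < 12:
        raise ValueError("need at least 12 surface points")
    pts = sphere_points(n, seed, cap_fraction, cap_angle_deg)
    hull = ConvexHull(pts)
    tris = hull.simplices.copy()
    # orient outward: normal . centroid > 0
    v = pts[tris]
    nrm = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    flip = np.einsum("ij,ij->i", nrm, v.mean(axis=1)) < 0
    tris[flip, 1], tris[flip, 2] = tris[flip, 2].copy(), tris[flip, 1].copy()
    return pts, tris


def _split_prism(tris: np.ndarray, bottom: np.ndarray, top: np.ndarray) -> np.ndarray:
    """Split prisms (same angular triangle on two radial layers) into 3 tets.

    ``tris`` are angular-vertex triples; ``bottom``/``top`` map angular vertex
    index -> global node id on the two layers.  The quad-face diagonal always
    emanates from the bottom node of the smaller angular index, which makes
    splits of adjacent prisms face-compatible.
    """
    out = np.empty((len(tris) * 3, 4), np.int64)
    k = 0
    for tri in tris:
        # rotate so the smallest angular index comes first (keeps orientation)
        r = int(np.argmin(tri))
        v = np.roll(tri, -r)
        b0, b1, b2 = bottom[v]
        t0, t1, t2 = top[v]
        if v[1] < v[2]:      # diagonal b1-t2 on the (v1,v2) quad
            out[k] = (b0, b1, b2, t2)
            out[k + 1] = (b0, b1, t2, t1)
            out[k + 2] = (b0, t1, t2, t0)
        else:                # diagonal b2-t1
            out[k] = (b0, b1, b2, t1)
            out[k + 1] = (b0, b2, t2, t1)
            out[k + 2] = (b0, t1, t2, t0)
        k += 3
    return out


def build_sphere_mesh(
    spec: SphereModelSpec,
    density: MeshDensity | None = None,
    seed: int = 0,
) -> LabeledTetMesh:
    """Build a labeled tetrahedral mesh of nested concentric shells.

    All interface spheres are exact faces of the tetrahedralization; region
    labels are 1 (innermost) .. L (outermost), assigned per radial gap.
    """
    density = density or spec.density
    radii = spec.radii_m
    L = len(radii)
    n_inner = max(1, density.inner_layers)
    outer_layers = list(density.outer_layers) + [1] * (L - 1 - len(density.outer_layers))

    # radial layer positions (excluding the center) and region of each gap
    layer_r: list[float] = []
    gap_region: list[int] = []
    for k in range(1, n_inner + 1):
        layer_r.append(radii[0] * (k / n_inner) ** density.inner_grading)
        gap_region.append(1)
    for j in range(1, L):
        nsub = max(1, outer_layers[j - 1])
        for k in range(1, nsub + 1):
            layer_r.append(radii[j - 1] + (radii[j] - radii[j - 1]) * k / nsub)
            gap_region.append(j + 1)
    layer_r_arr = np.asarray(layer_r)

    dirs, tris = sphere_triangulation(
        density.n_surface, seed,
        cap_fraction=density.cap_fraction,
        cap_angle_deg=density.cap_angle_deg)
    n_ang = dirs.shape[0]
    n_layers = len(layer_r)

    nodes = np.empty((1 + n_ang * n_layers, 3))
    nodes[0] = 0.0
    for li, r in enumerate(layer_r):
        nodes[1 + li * n_ang: 1 + (li + 1) * n_ang] = dirs * r

    tet_blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []

    # center cap: center node + innermost layer triangles
    first = 1 + np.arange(n_ang)
    cap = np.column_stack([
        np.zeros(len(tris), np.int64), first[tris[:, 0]], first[tris[:, 1]],
        first[tris[:, 2]]])
    tet_blocks.append(cap)
    labels.append(np.full(len(cap), gap_region[0], np.int64))

    for li in range(n_layers - 1):
        bottom = 1 + li * n_ang + np.arange(n_ang)
        top = 1 + (li + 1) * n_ang + np.arange(n_ang)
        block = _split_prism(tris, bottom, top)
        tet_blocks.append(block)
        labels.append(np.full(len(block), gap_region[li + 1], np.int64))

    mesh = LabeledTetMesh(
        nodes=nodes,
        tets=np.vstack(tet_blocks),
        region_label=np.concatenate(labels),
        provenance={
            "generator": "nested_sphere",
            "radii_m": tuple(radii),
            "n_surface": density.n_surface,
            "layer_radii_m": tuple(layer_r_arr),
            "seed": int(seed),
        },
    )
    mesh.orient_positive()
    vol = mesh.tet_volumes()
    if np.any(vol <= 0):
        raise RuntimeError(
            f"degenerate mesh: {int((vol <= 0).sum())} non-positive tetrahedra "
            f"at density {density}")
    return mesh


def refine_mesh(mesh: LabeledTetMesh, snap_spheres: Sequence[float] = ()) -> LabeledTetMesh:
    """Uniform 1->8 red refinement via edge midpoints.

    ``snap_spheres``: radii; midpoints of edges whose endpoints both lie on
    one of these spheres are projected back onto it (keeps spherical
    interfaces spherical under refinement of generated head meshes).
    """
    nodes, tets = mesh.nodes, mesh.tets
    edges = np.vstack([
        tets[:, [0, 1]], tets[:, [0, 2]], tets[:, [0, 3]],
        tets[:, [1, 2]], tets[:, [1, 3]], tets[:, [2, 3]]])
    edges = np.sort(edges, axis=1)
    uniq, inv = np.unique(edges, axis=0, return_inverse=True)
    mid = 0.5 * (nodes[uniq[:, 0]] + nodes[uniq[:, 1]])

    if len(snap_spheres):
        r0 = np.linalg.norm(nodes[uniq[:, 0]], axis=1)
        r1 = np.linalg.norm(nodes[uniq[:, 1]], axis=1)
        for rs in snap_spheres:
            on = (np.abs(r0 - rs) < 1e-9) & (np.abs(r1 - rs) < 1e-9)
            if on.any():
                m = mid[on]
                mid[on] = m * (rs / np.linalg.norm(m, axis=1))[:, None]

    mid_ids = mesh.n_nodes + np.arange(len(uniq))
    m = inv.reshape(6, -1).T           # per-tet edge midpoint ids (01,02,03,12,13,23)
    e01, e02, e03, e12, e13, e23 = (mid_ids[m[:, k]] for k in range(6))
    v0, v1, v2, v3 = tets.T
    children = np.stack([
        np.column_stack([v0, e01, e02, e03]),
        np.column_stack([v1, e01, e12, e13]),
        np.column_stack([v2, e02, e12, e23]),
        np.column_stack([v3, e03, e13, e23]),
        np.column_stack([e01, e02, e03, e13]),
        np.column_stack([e01, e02, e12, e13]),
        np.column_stack([e02, e03, e13, e23]),
        np.column_stack([e02, e12, e13, e23]),
    ], axis=1).reshape(-1, 4)
    out = LabeledTetMesh(
        nodes=np.vstack([nodes, mid]),
        tets=children,
        region_label=np.repeat(mesh.region_label, 8),
        provenance={**mesh.provenance, "refined": mesh.provenance.get("refined", 0) + 1},
    )
    out.orient_positive()
    return out


# --------------------------------------------------------------------------
# interface extraction
# --------------------------------------------------------------------------

def extract_interfaces(mesh: LabeledTetMesh) -> list[InterfaceSurface]:
    """Extract the closed triangulated surfaces separating tissue regions.

    Triangles are exactly the tetrahedron faces shared by two tets of
    different labels (plus outer boundary faces, reported with
    ``outer_region = 0``).  Orientation points from the lower-label (inner)
    region outward.  A face shared by more than two tets is a hard error.
    """
    tets = mesh.tets
    faces = np.vstack([
        tets[:, [1, 2, 3]], tets[:, [0, 3, 2]],
        tets[:, [0, 1, 3]], tets[:, [0, 2, 1]]])
    # stored face orientation is outward of the owning tet (positive volumes)
    owner = np.tile(np.arange(mesh.n_tets), 4)
    key = np.sort(faces, axis=1)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    key_s, faces_s, owner_s = key[order], faces[order], owner[order]

    groups: dict[tuple[int, int], list[tuple[np.ndarray, int]]] = {}
    i = 0
    nfaces = len(key_s)
    labels = mesh.region_label
    while i < nfaces:
        j = i + 1
        while j < nfaces and np.array_equal(key_s[j], key_s[i]):
            j += 1
        count = j - i
        if count > 2:
            raise ValueError(
                f"non-manifold face {tuple(key_s[i])} shared by {count} tetrahedra")
        if count == 1:
            t = owner_s[i]
            groups.setdefault((int(labels[t]), 0), []).append((faces_s[i], t))
        else:
            t1, t2 = owner_s[i], owner_s[j - 1]
            l1, l2 = int(labels[t1]), int(labels[t2])
            if l1 != l2:
                # orient from the inner (smaller-label) side
                if l1 < l2:
                    groups.setdefault((l1, l2), []).append((faces_s[i], t1))
                else:
                    groups.setdefault((l2, l1), []).append((faces_s[j - 1], t2))
        i = j

    surfaces = []
    for (inner, outer), items in sorted(groups.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        tri = np.array([f for f, _ in items], np.int64)
        surfaces.append(InterfaceSurface(
            nodes=mesh.nodes, triangles=tri, inner_region=inner, outer_region=outer))
    # report scalp/air last, internal interfaces by inner label
    surfaces.sort(key=lambda s: (s.outer_region == 0, s.inner_region))
    for s in surfaces:
        _check_closed(s)
    return surfaces


def _check_closed(surface: InterfaceSurface) -> None:
    tri = surface.triangles
    edges = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    _, counts = np.unique(key, axis=0, return_counts=True)
    if not np.all(counts == 2):
        raise ValueError(
            f"interface {surface.inner_region}/{surface.outer_region} is not closed: "
            f"{int((counts != 2).sum())} edges not shared by exactly 2 triangles")


# --------------------------------------------------------------------------
# dipole placement and point location
# --------------------------------------------------------------------------

MAX_ECCENTRICITY_PCT = 98.0


def place_dipole(
    spec: SphereModelSpec,
    eccentricity_pct: float,
    orientation: str,
    strength: float = 1.0,
) -> Dipole:
    """Place a dipole on the +z axis at the given eccentricity.

    Eccentricity is the distance from the sphere center in percent of the
    innermost shell radius.  ``radial`` orients the moment along z (away
    from the center), ``tangential`` along x.
    """
    if not 0 <= eccentricity_pct <= MAX_ECCENTRICITY_PCT:
        raise ValueError(
            f"eccentricity {eccentricity_pct}% outside [0, {MAX_ECCENTRICITY_PCT}]")
    r1 = spec.radii_m[0]
    z = eccentricity_pct / 100.0 * r1
    if orientation == "radial":
        direction = np.array([0.0, 0.0, 1.0])
    elif orientation == "tangential":
        direction = np.array([1.0, 0.0, 0.0])
    else:
        raise ValueError("orientation must be 'radial' or 'tangential'")
    return Dipole(position=np.array([0.0, 0.0, z]), direction=direction,
                  strength=strength)


class TetLocator:
    """Point-in-tetrahedron queries via a centroid kd-tree candidate search."""

    def __init__(self, mesh: LabeledTetMesh):
        self.mesh = mesh
        self.tree = cKDTree(mesh.tet_centroids())

    def barycentric(self, tet_idx: int, point: np.ndarray) -> np.ndarray:
        p = self.mesh.nodes[self.mesh.tets[tet_idx]]
        T = np.column_stack([p[1] - p[0], p[2] - p[0], p[3] - p[0]])
        lam = np.linalg.solve(T, np.asarray(point, float) - p[0])
        return np.concatenate([[1.0 - lam.sum()], lam])

    def find(self, point: np.ndarray, tol: float = 1e-10) -> tuple[int, np.ndarray]:
        """Return (tet index, barycentric coords) of the tet containing point."""
        point = np.asarray(point, float)
        k = min(64, self.mesh.n_tets)
        _, cand = self.tree.query(point, k=k)
        cand = np.atleast_1d(cand)
        best, best_lam, best_viol = -1, None, np.inf
        for t in cand:
            lam = self.barycentric(int(t), point)
            viol = -lam.min()
            if viol < best_viol:
                best, best_lam, best_viol = int(t), lam, viol
            if viol <= tol:
                return int(t), lam
        if best_viol < 1e-6:       # on a face/edge: accept the closest tet
            return best, best_lam
        raise ValueError(f"point {point} lies outside the mesh "
                         f"(barycentric violation {best_viol:.3g})")
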