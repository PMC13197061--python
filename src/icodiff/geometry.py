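"""Hierarchical icosahedral sphere meshes and their index structures.

The cortical surface, once inflated and mapped to a sphere, is resampled to a
subdivided icosahedron so that every subject lives on the same vertex set.  An
order-``k`` icosphere has ``10 * 4**k + 2`` vertices; order 6 (40962 vertices)
is the resolution used for full cortical work, while orders 1-4 suffice for
synthetic experiments.

Vertex ordering is hierarchical: the first ``10 * 4**(k-1) + 2`` vertices of an
order-``k`` sphere are exactly the vertices of the order-``(k-1)`` sphere (the
*prefix property*).  Pooling a per-vertex signal down one order is then simply
keeping the prefix, and up-pooling is zero-padding the newly inserted vertices
— no averaging, which avoids grid artifacts in generated samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

__all__ = [
    "IcoSphere",
    "Parcellation",
    "build_icosphere",
    "icosphere_hierarchy",
    "neighbor_ordering",
    "pool",
    "unpool",
    "resample_to_icosphere",
    "make_parcellation",
    "n_vertices_at_order",
    "icosahedral_symmetries",
]

MAX_ORDER = 8


def n_vertices_at_order(order: int) -> int:
    """Vertex count of the order-``order`` icosphere, ``10 * 4**order + 2``."""
    return 10 * 4**order + 2


@dataclass
class IcoSphere:
    """A subdivided icosahedron projected onto the unit sphere.

    Attributes
    ----------
    order : int
        Number of 4-to-1 subdivision rounds applied to the base icosahedron.
    vertices : (V, 3) float64 array
        Unit vectors.
    faces : (F, 3) int array
        Counter-clockwise vertex triples.
    neighbors : (V, 6) int array
        Ordered 1-ring neighbor indices per vertex.  The 12 valence-5 base
        vertices carry a pad slot in column 5 equal to the vertex's own index.
    valence : (V,) int array
        5 for the 12 base vertices, 6 elsewhere.
    vertex_counts_per_order : list of int
        Prefix vertex count for every order up to ``order``.
    """

    order: int
    vertices: np.ndarray
    faces: np.ndarray
    neighbors: np.ndarray = field(repr=False)
    valence: np.ndarray = field(repr=False)
    vertex_counts_per_order: list[int] = field(default_factory=list)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    @property
    def n_edges(self) -> int:
        return self.n_vertices + self.n_faces - 2  # Euler: V - E + F = 2

    def gather_indices(self) -> np.ndarray:
        """(V, 7) tap indices per vertex: [self, ordered 1-ring (pad=self)]."""
        return np.concatenate(
            [np.arange(self.n_vertices)[:, None], self.neighbors], axis=1
        )


@dataclass
class Parcellation:
    """Per-vertex ROI labels on an icosphere (e.g. a Desikan-Killiany-like atlas)."""

    labels: np.ndarray
    n_rois: int
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D integer array")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.n_rois):
            raise ValueError("labels must lie in [0, n_rois)")


def _base_icosahedron() -> tuple[np.ndarray, np.ndarray]:
    """Icosahedron with poles on the z-axis: vertex 0 = +z, vertex 11 = -z.

    Rings of five vertices sit at latitude arctan(1/2); the lower ring is
    rotated by pi/5 relative to the upper one.  This fixed orientation makes
    every derived mesh bit-reproducible.
    """
    z = 1.0 / np.sqrt(5.0)
    r = 2.0 / np.sqrt(5.0)
    verts = [np.array([0.0, 0.0, 1.0])]
    for k in range(5):
        a = 2.0 * np.pi * k / 5.0
        verts.append(np.array([r * np.cos(a), r * np.sin(a), z]))
    for k in range(5):
        a = 2.0 * np.pi * k / 5.0 + np.pi / 5.0
        verts.append(np.array([r * np.cos(a), r * np.sin(a), -z]))
    verts.append(np.array([0.0, 0.0, -1.0]))
    vertices = np.array(verts)

    faces = []
    for k in range(5):
        u, u1 = 1 + k, 1 + (k + 1) % 5
        l, l1 = 6 + k, 6 + (k + 1) % 5
        faces.append([0, u, u1])          # north cap
        faces.append([u, l, u1])          # upper band
        faces.append([u1, l, l1])         # lower band
        faces.append([11, l1, l])         # south cap
    return vertices, np.array(faces, dtype=np.int64)


def _subdivide(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One 4-to-1 subdivision round.

    Parent vertices keep their indices; edge midpoints are appended in
    lexicographically sorted edge order, so the prefix property holds by
    construction.
    """
    e01 = faces[:, [0, 1]]
    e12 = faces[:, [1, 2]]
    e20 = faces[:, [2, 0]]
    edges = np.sort(np.concatenate([e01, e12, e20], axis=0), axis=1)
    uniq, inv = np.unique(edges, axis=0, return_inverse=True)
    mids = vertices[uniq[:, 0]] + vertices[uniq[:, 1]]
    mids /= np.linalg.norm(mids, axis=1, keepdims=True)
    new_vertices = np.concatenate([vertices, mids], axis=0)

    nf = faces.shape[0]
    m01 = vertices.shape[0] + inv[:nf]
    m12 = vertices.shape[0] + inv[nf : 2 * nf]
    m20 = vertices.shape[0] + inv[2 * nf :]
    a, b, c = faces[:, 0], faces[:, 1], faces[:, 2]
    new_faces = np.concatenate(
        [
            np.stack([a, m01, m20], axis=1),
            np.stack([b, m12, m01], axis=1),
            np.stack([c, m20, m12], axis=1),
            np.stack([m01, m12, m20], axis=1),
        ],
        axis=0,
    )
    return new_vertices, new_faces


def _adjacency_from_faces(n_vertices: int, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unordered 1-ring adjacency: (V, 6) index table (pad = self) + valence."""
    src = faces[:, [0, 1, 1, 2, 2, 0]].ravel()
    dst = faces[:, [1, 0, 2, 1, 0, 2]].ravel()
    pairs = np.unique(np.stack([src, dst], axis=1), axis=0)
    valence = np.bincount(pairs[:, 0], minlength=n_vertices)
    if valence.min() < 3:
        raise ValueError("mesh is not a closed manifold triangulation")
    table = np.repeat(np.arange(n_vertices)[:, None], 6, axis=1)
    col = np.concatenate([np.arange(v) for v in valence])
    table[pairs[:, 0], col] = pairs[:, 1]
    return table, valence


def _azimuth_in_tangent_frame(centers: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Azimuth of ``points[i, j]`` after rotating ``centers[i]`` to the north pole.

    The rotation is the minimal one about ``center x z``; at the poles it
    degenerates and is replaced by the identity (+z) or a half-turn about x (-z).
    """
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(centers, z)
    sin_t = np.linalg.norm(axis, axis=1)
    cos_t = centers @ z
    safe = sin_t > 1e-12
    axis_n = np.where(safe[:, None], axis / np.where(safe, sin_t, 1.0)[:, None], 0.0)

    # Rodrigues rotation of each point about its row's axis
    k = axis_n[:, None, :]
    ct = cos_t[:, None, None]
    st = sin_t[:, None, None]
    kxp = np.cross(np.broadcast_to(k, points.shape), points)
    kdp = np.sum(k * points, axis=2, keepdims=True)
    rot = points * ct + kxp * st + k * kdp * (1.0 - ct)

    # degenerate rows: +z pole -> identity; -z pole -> pi about x-axis
    north = (~safe) & (cos_t > 0)
    south = (~safe) & (cos_t <= 0)
    rot[north] = points[north]
    flipped = points[south].copy()
    flipped[:, :, 1] *= -1.0
    flipped[:, :, 2] *= -1.0
    rot[south] = flipped

    az = np.arctan2(rot[:, :, 1], rot[:, :, 0])
    return np.mod(az, 2.0 * np.pi)


def neighbor_ordering(
    vertices: np.ndarray, faces: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Canonically ordered 1-ring table.

    Neighbors are sorted by increasing azimuth in the local tangent frame
    obtained by rotating the center vertex to the north pole; exact azimuth
    ties break toward the smaller vertex index.  Valence-5 vertices repeat
    their own index in the pad column.

    Returns ``(neighbors, valence)`` with shapes ``(V, 6)`` and ``(V,)``.
    """
    n = vertices.shape[0]
    table, valence = _adjacency_from_faces(n, faces)
    pts = vertices[table]  # (V, 6, 3); pad rows point at the center itself
    az = _azimuth_in_tangent_frame(vertices, pts)
    az[table == np.arange(n)[:, None]] = np.inf  # pads sort last
    order = np.lexsort((table, az), axis=1)
    ordered = np.take_along_axis(table, order, axis=1)
    return ordered, valence


def build_icosphere(order: int) -> IcoSphere:
    """Construct the order-``order`` icosphere with its canonical index tables.

    Deterministic: fixed base orientation (poles at +-z) and sorted-edge
    midpoint insertion, so repeated calls are bit-identical and the vertex
    prefix property holds across orders.
    """
    if order < 0:
        raise ValueError("order must be non-negative")
    if order > MAX_ORDER:
        raise ValueError(f"order {order} exceeds the supported maximum {MAX_ORDER}")
    vertices, faces = _base_icosahedron()
    counts = [12]
    for _ in range(order):
        vertices, faces = _subdivide(vertices, faces)
        counts.append(vertices.shape[0])
    neighbors, valence = neighbor_ordering(vertices, faces)
    return IcoSphere(
        order=order,
        vertices=vertices,
        faces=faces,
        neighbors=neighbors,
        valence=valence,
        vertex_counts_per_order=counts,
    )


def icosphere_hierarchy(max_order: int) -> list[IcoSphere]:
    """Icospheres for every order ``0..max_order`` (prefix-compatible)."""
    return [build_icosphere(k) for k in range(max_order + 1)]


def _infer_order(n_verts: int) -> int:
    k = 0
    while n_vertices_at_order(k) < n_verts and k <= MAX_ORDER:
        k += 1
    if n_vertices_at_order(k) != n_verts:
        raise ValueError(f"{n_verts} is not an icosphere vertex count")
    return k


def pool(values: np.ndarray, ico: IcoSphere | None = None, axis: int = -2) -> np.ndarray:
    """Down-pool one icosphere order by keeping the coarse-vertex prefix.

    ``values`` has the vertex dimension on ``axis`` (default: second to last,
    the (batch, vertex, channel) layout).  No averaging is performed.
    """
    n = values.shape[axis]
    k = _infer_order(n)
    if k == 0:
        raise ValueError("cannot pool below order 0")
    keep = n_vertices_at_order(k - 1)
    index = [slice(None)] * values.ndim
    index[axis] = slice(0, keep)
    return values[tuple(index)]


def unpool(values: np.ndarray, ico: IcoSphere | None = None, axis: int = -2) -> np.ndarray:
    """Up-pool one icosphere order by zero-padding the newly added vertices."""
    n = values.shape[axis]
    k = _infer_order(n)
    if ico is not None and k + 1 > ico.order:
        raise ValueError("cannot unpool beyond the sphere's order")
    target = n_vertices_at_order(k + 1)
    pad = [(0, 0)] * values.ndim
    pad[axis % values.ndim] = (0, target - n)
    return np.pad(values, pad)


def _barycentric_weights(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Solve p ~ w0*a + w1*b + w2*c (least squares on the 3x3 system), normalized."""
    # tri: (3, 3) rows a, b, c
    A = tri.T  # columns are the triangle vertices
    w, *_ = np.linalg.lstsq(A, p, rcond=None)
    s = w.sum()
    if abs(s) < 1e-12:
        return np.full(3, np.inf)
    return w / s


def resample_to_icosphere(
    values: np.ndarray,
    src_vertices: np.ndarray,
    src_faces: np.ndarray,
    dst: IcoSphere,
    method: str = "barycentric",
) -> np.ndarray:
    """Resample a per-vertex signal from an arbitrary spherical mesh onto ``dst``.

    ``barycentric`` locates each destination vertex inside a source triangle
    (gnomonic/central projection) and interpolates linearly; ``nearest`` copies
    the closest source vertex and is appropriate for label maps.
    """
    src_vertices = np.asarray(src_vertices, dtype=np.float64)
    src_vertices = src_vertices / np.linalg.norm(src_vertices, axis=1, keepdims=True)
    values = np.asarray(values)
    if values.shape[0] != src_vertices.shape[0]:
        raise ValueError("values and src_vertices disagree on vertex count")

    tree = cKDTree(src_vertices)
    if method == "nearest":
        _, idx = tree.query(dst.vertices)
        return values[idx]
    if method != "barycentric":
        raise ValueError(f"unknown method {method!r}")

    # candidate triangles per destination vertex: faces incident to near vertices
    n_src = src_vertices.shape[0]
    incident: list[list[int]] = [[] for _ in range(n_src)]
    for fi, f in enumerate(src_faces):
        for v in f:
            incident[v].append(fi)

    out_shape = (dst.n_vertices,) + values.shape[1:]
    out = np.zeros(out_shape, dtype=np.float64)
    for di, p in enumerate(dst.vertices):
        found = False
        for tol, k_near in ((1e-10, 1), (1e-6, 4), (1e-3, 12)):
            _, near = tree.query(p, k=k_near)
            near = np.atleast_1d(near)
            cand = sorted({fi for v in near for fi in incident[v]})
            best_w, best_f, best_def = None, None, np.inf
            for fi in cand:
                tri = src_vertices[src_faces[fi]]
                w = _barycentric_weights(p, tri)
                deficit = -min(w.min(), 0.0)
                if deficit < best_def:
                    best_def, best_w, best_f = deficit, w, fi
            if best_w is not None and best_def <= tol:
                w = np.clip(best_w, 0.0, None)
                w = w / w.sum()
                out[di] = np.tensordot(w, values[src_faces[best_f]], axes=1)
                found = True
                break
        if not found:
            raise ValueError(
                f"destination vertex {di} could not be located in any source triangle"
            )
    return out


def make_parcellation(ico: IcoSphere, n_rois: int, seed: int = 0) -> Parcellation:
    """Geodesic-Voronoi parcellation from farthest-point-sampled seed vertices.

    A synthetic stand-in for an anatomical atlas: deterministic given
    ``seed``, every ROI non-empty, labels ``0..n_rois-1``.
    """
    if not 1 <= n_rois <= ico.n_vertices:
        raise ValueError("n_rois out of range")
    rng = np.random.default_rng(seed)

    f = ico.faces
    i = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    j = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    w = np.linalg.norm(ico.vertices[i] - ico.vertices[j], axis=1)
    graph = csr_matrix(
        (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(ico.n_vertices, ico.n_vertices),
    )

    seeds = [int(rng.integers(ico.n_vertices))]
    dist = dijkstra(graph, indices=seeds[0])
    for _ in range(n_rois - 1):
        nxt = int(np.argmax(dist))
        seeds.append(nxt)
        dist = np.minimum(dist, dijkstra(graph, indices=nxt))

    all_d = dijkstra(graph, indices=seeds)
    labels = np.argmin(all_d, axis=0).astype(np.int64)
    return Parcellation(labels=labels, n_rois=n_rois)


def icosahedral_symmetries(ico: IcoSphere) -> np.ndarray:
    """Vertex permutations of the 60 rotational symmetries of the icosphere.

    The rotation group of the icosahedron maps the subdivided vertex set onto
    itself; each rotation therefore acts on per-vertex data as a permutation.
    Returns an ``(60, V)`` integer array ``perms`` with
    ``rotated_values = values[perms[k]]``.  Useful as exact, distribution-
    preserving data augmentation for isotropic fields on the sphere.
    """
    v = ico.vertices

    def rot(axis, angle):
        axis = axis / np.linalg.norm(axis)
        k = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)

    # group closure from two generators: 2pi/5 about the vertex-0 axis and
    # pi about the midpoint of the edge between vertices 0 and 1
    g1 = rot(v[0], 2 * np.pi / 5)
    g2 = rot(v[0] + v[1], np.pi)
    mats = [np.eye(3)]
    frontier = [np.eye(3)]
    while frontier:
        new = []
        for m in frontier:
            for g in (g1, g2):
                cand = g @ m
                if not any(np.abs(cand - e).max() < 1e-8 for e in mats):
                    mats.append(cand)
                    new.append(cand)
        frontier = new
    if len(mats) != 60:
        raise RuntimeError(f"icosahedral group closure found {len(mats)} != 60 elements")

    tree = cKDTree(v)
    perms = np.empty((60, ico.n_vertices), dtype=np.int64)
    for i, m in enumerate(mats):
        dist, idx = tree.query(v @ m.T)
        if dist.max() > 1e-9 or len(np.unique(idx)) != ico.n_vertices:
            raise RuntimeError("symmetry does not permute the vertex set exactly")
        perms[i] = idx
    return perms
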