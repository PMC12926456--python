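"""Triangular cortical surface meshes and their vertex graphs.

The pial surface of one hemisphere is represented as a closed triangular
mesh.  The mesh's edge structure — not its geometry — defines the unweighted
graph on which the node classifiers operate; vertex coordinates are carried
along only because they enter the per-vertex feature vector.

Synthetic hemispheres are icospheres: recursively subdivided icosahedra
projected to a sphere.  Subdivision order 3 yields 642 vertices, the
resolution of the fsaverage3 template on which vertex-wise structural
connectivity is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SurfaceMesh", "VertexGraph", "build_icosphere", "mesh_to_graph"]


@dataclass
class SurfaceMesh:
    """A triangular surface mesh.

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex coordinates in mm (RAS convention).
    faces : (F, 3) int array
        Vertex-index triples, 0-based.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        v = len(self.vertices)
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= v:
                raise ValueError(f"face indices must lie in [0, {v})")
            degenerate = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if degenerate.any():
                raise ValueError("degenerate face repeats a vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def unique_edges(self) -> np.ndarray:
        """Sorted (E, 2) array of unique undirected edges."""
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.unique_edges()) + self.n_faces


@dataclass
class VertexGraph:
    """Simple undirected graph on mesh vertices.

    ``edges`` holds each undirected edge once as (i, j) with i < j; no
    self-loops are stored.
    """

    node_count: int
    edges: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.edges.size:
            if (self.edges[:, 0] == self.edges[:, 1]).any():
                raise ValueError("self-loops are not stored")
            self.edges = np.unique(np.sort(self.edges, axis=1), axis=0)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.node_count, dtype=np.int64)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg

    def adjacency(self, sparse: bool = True):
        """Binary adjacency matrix (scipy CSR by default)."""
        from scipy import sparse as sp

        i, j = self.edges[:, 0], self.edges[:, 1]
        rows = np.concatenate([i, j])
        cols = np.concatenate([j, i])
        data = np.ones(len(rows))
        a = sp.coo_matrix((data, (rows, cols)), shape=(self.node_count, self.node_count)).tocsr()
        return a if sparse else a.toarray()


# Regular icosahedron on the unit sphere.
_PHI = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        [-1, _PHI, 0], [1, _PHI, 0], [-1, -_PHI, 0], [1, -_PHI, 0],
        [0, -1, _PHI], [0, 1, _PHI], [0, -1, -_PHI], [0, 1, -_PHI],
        [_PHI, 0, -1], [_PHI, 0, 1], [-_PHI, 0, -1], [-_PHI, 0, 1],
    ],
    dtype=np.float64,
)
_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=np.int64,
)


def build_icosphere(subdivisions: int, radius: float = 50.0) -> SurfaceMesh:
    """Build an icosphere by recursive triangle subdivision.

    Each subdivision splits every triangle into four through deduplicated
    edge midpoints projected back to the sphere, so V = 10·4^s + 2 and
    F = 20·4^s.  Midpoints are deduplicated by exact vertex-index pair, not
    by coordinate hashing.

    Parameters
    ----------
    subdivisions : int
        Subdivision order s ≥ 0 (order 3 gives the 642-vertex hemisphere
        resolution).  Capped at 7 to guard against memory blowup.
    radius : float
        Sphere radius in mm; default 50 mm approximates brain scale.
    """
    if subdivisions < 0:
        raise ValueError(f"subdivisions must be >= 0, got {subdivisions}")
    if subdivisions > 7:
        raise ValueError(f"subdivisions must be <= 7, got {subdivisions}")

    verts = [v / np.linalg.norm(v) for v in _ICO_VERTS]
    faces = _ICO_FACES.copy()

    for _ in range(subdivisions):
        midpoint_cache: dict[tuple[int, int], int] = {}

        def midpoint(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            idx = midpoint_cache.get(key)
            if idx is None:
                m = verts[i] + verts[j]
                m /= np.linalg.norm(m)
                verts.append(m)
                idx = len(verts) - 1
                midpoint_cache[key] = idx
            return idx

        new_faces = np.empty((4 * len(faces), 3), dtype=np.int64)
        for k, (a, b, c) in enumerate(faces):
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces[4 * k:4 * k + 4] = [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        faces = new_faces

    return SurfaceMesh(vertices=np.asarray(verts) * radius, faces=faces)


def mesh_to_graph(mesh: SurfaceMesh) -> VertexGraph:
    """Convert a mesh to its unweighted vertex graph.

    One undirected edge per unique triangle edge; for a closed mesh
    E = 3F/2.  Invariant to face ordering and winding.
    """
    if mesh.n_faces == 0:
        return VertexGraph(node_count=mesh.n_vertices)
    return VertexGraph(node_count=mesh.n_vertices, edges=mesh.unique_edges())
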