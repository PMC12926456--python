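"""Independent brute-force oracles used by the tests.

Everything here is written against the mathematical definitions with plain
loops and dense matrices, independently of the package's vectorized /
sparse implementations.
"""

from __future__ import annotations

import numpy as np


def dense_gcn_layer(h: np.ndarray, edges: np.ndarray, n: int, w: np.ndarray,
                    b: np.ndarray) -> np.ndarray:
    """S H W + b with S = D̂^{-1/2}(A+I)D̂^{-1/2} built densely."""
    a = np.zeros((n, n))
    for i, j in edges:
        a[i, j] = a[j, i] = 1.0
    a_hat = a + np.eye(n)
    d = a_hat.sum(axis=1)
    s = a_hat / np.sqrt(np.outer(d, d))
    return s @ h @ w + b


def dense_gat_head(h: np.ndarray, edges: np.ndarray, n: int, w: np.ndarray,
                   a_src: np.ndarray, a_dst: np.ndarray,
                   slope: float = 0.2) -> np.ndarray:
    """Single-head attention computed with per-node python loops and an
    explicit softmax over N(i) ∪ {i}."""
    wh = h @ w
    neighbors = {i: {i} for i in range(n)}
    for i, j in edges:
        neighbors[i].add(j)
        neighbors[j].add(i)
    out = np.zeros((n, w.shape[1]))
    for i in range(n):
        js = sorted(neighbors[i])
        logits = []
        for j in js:
            e = float(a_src.ravel() @ wh[j] + a_dst.ravel() @ wh[i])
            logits.append(e if e > 0 else slope * e)
        logits = np.asarray(logits)
        alpha = np.exp(logits - logits.max())
        alpha /= alpha.sum()
        for a_ij, j in zip(alpha, js):
            out[i] += a_ij * wh[j]
    return out


def bfs_hop_distances(edges: np.ndarray, n: int, source: int) -> np.ndarray:
    """Plain breadth-first hop distances from one source."""
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    dist = np.full(n, np.inf)
    dist[source] = 0
    frontier = [source]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if dist[v] == np.inf:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def voronoi_assignment(edges: np.ndarray, n: int, seeds: np.ndarray) -> np.ndarray:
    """Exhaustive nearest-seed assignment, ties to the lower seed index."""
    dists = np.stack([bfs_hop_distances(edges, n, s) for s in seeds])
    out = np.empty(n, dtype=np.int64)
    for v in range(n):
        best = 0
        for k in range(1, len(seeds)):
            if dists[k, v] < dists[best, v]:
                best = k
        out[v] = best
    return out


def subdivide_count(vertices: np.ndarray, faces: np.ndarray,
                    rounds: int) -> tuple[int, int]:
    """Brute-force unique-vertex and face count after midpoint subdivision,
    deduplicating midpoints by rounded coordinate tuples."""
    verts = [tuple(np.round(v / np.linalg.norm(v), 9)) for v in vertices]
    index = {v: i for i, v in enumerate(verts)}
    faces = [tuple(f) for f in faces]
    for _ in range(rounds):
        new_faces = []
        for a, b, c in faces:
            mids = []
            for i, j in ((a, b), (b, c), (c, a)):
                m = np.asarray(verts[i]) + np.asarray(verts[j])
                m = tuple(np.round(m / np.linalg.norm(m), 9))
                if m not in index:
                    index[m] = len(verts)
                    verts.append(m)
                mids.append(index[m])
            ab, bc, ca = mids
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    return len(verts), len(faces)
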