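"""Curve-graph skeleton of the fibre phase.

The skeletonization protocol is designed for robustness on discretized
fibre networks:

1. thin the volume and its three 90° rotations about the wall-normal (z)
   axis, rotate the results back and take the voxelwise union, then thin the
   union once more (``robust_medial_axis``) — overlaying rotated medial axes
   cancels most of the scan-order anisotropy of the thinning pass;
2. convert skeleton voxels to a graph with an edge for every 26-neighbour
   pair (``to_graph``);
3. at junctions (degree > 2) repeatedly drop the incident edge least aligned
   with any other, keeping the best through-path (``prune_junctions``);
4. Laplacian-smooth the polylines (``smooth``), drop components shorter than
   20 edges, and smooth again (``extract_skeleton``).

Vertex coordinates are in µm; after smoothing they move off-lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import networkx as nx
import numpy as np
import pandas as pd
from skimage.morphology import skeletonize

from .volumes import BinaryVolume

__all__ = [
    "SkeletonGraph",
    "robust_medial_axis",
    "to_graph",
    "prune_junctions",
    "smooth",
    "filter_components",
    "extract_skeleton",
]


@dataclass
class SkeletonGraph:
    """Undirected curve graph with continuous vertex coordinates in µm.

    ``graph`` nodes carry a ``pos`` attribute (length-3 float array);
    ``component`` ids are assigned by :meth:`assign_components`.
    """

    graph: nx.Graph
    voxel_size: float
    components: dict[int, int] = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def positions(self) -> dict[int, np.ndarray]:
        return {n: d["pos"] for n, d in self.graph.nodes(data=True)}

    def assign_components(self) -> None:
        comps = sorted(nx.connected_components(self.graph), key=lambda c: min(c))
        self.components = {}
        for cid, comp in enumerate(comps):
            for n in comp:
                self.components[n] = cid

    def edge_table(self) -> pd.DataFrame:
        """One row per edge: endpoint coordinates (µm) and component id."""
        if not self.components:
            self.assign_components()
        rows = []
        for u, v in self.graph.edges():
            pu = self.graph.nodes[u]["pos"]
            pv = self.graph.nodes[v]["pos"]
            rows.append(
                dict(
                    v1=u, v2=v,
                    x1=pu[0], y1=pu[1], z1=pu[2],
                    x2=pv[0], y2=pv[1], z2=pv[2],
                    component=self.components[u],
                )
            )
        return pd.DataFrame(
            rows, columns=["v1", "v2", "x1", "y1", "z1", "x2", "y2", "z2", "component"]
        )

    def vertex_table(self) -> pd.DataFrame:
        if not self.components:
            self.assign_components()
        rows = [
            dict(id=n, x_um=p[0], y_um=p[1], z_um=p[2], component=self.components[n])
            for n, p in sorted(self.positions().items())
        ]
        return pd.DataFrame(rows, columns=["id", "x_um", "y_um", "z_um", "component"])


def robust_medial_axis(volume: BinaryVolume) -> BinaryVolume:
    """1-voxel-wide skeleton mask via the rotation-overlay protocol.

    The fibre mask and its three 90° rotations about z are thinned
    independently; the back-rotated skeletons are unioned and the union is
    thinned once more.  Non-square XY extents are zero-padded to a square for
    the rotations and cropped back.
    """
    mask = volume.fibre_mask
    if not mask.any():
        return volume.with_grid(np.zeros_like(volume.grid))
    nx_, ny_ = mask.shape[:2]
    n = max(nx_, ny_)
    padded = np.zeros((n, n, mask.shape[2]), dtype=bool)
    padded[:nx_, :ny_] = mask

    union = np.zeros_like(padded)
    for k in range(4):
        rot = np.rot90(padded, k, axes=(0, 1))
        skel = skeletonize(rot).astype(bool)
        union |= np.rot90(skel, -k, axes=(0, 1))
    final = skeletonize(union).astype(bool)
    # thinning of a perfectly even-symmetric structure can annihilate it
    # entirely (no unique centre plane); fall back to the overlay, which is
    # already at most two voxels wide and is cleaned up by junction pruning
    if not final.any() and union.any():
        final = union
    return volume.with_grid(final[:nx_, :ny_].astype(np.uint8))


_NEIGHBOUR_OFFSETS = [
    off for off in product((-1, 0, 1), repeat=3) if off > (0, 0, 0)
]  # 13 lexicographically positive offsets: each 26-neighbour pair once


def to_graph(skel_mask: BinaryVolume) -> SkeletonGraph:
    """Vertex per skeleton voxel (centre, µm), edge per 26-neighbour pair."""
    coords = np.argwhere(skel_mask.grid > 0)
    s = skel_mask.voxel_size
    index = {tuple(c): i for i, c in enumerate(map(tuple, coords))}
    g = nx.Graph()
    for i, c in enumerate(map(tuple, coords)):
        g.add_node(i, pos=np.asarray(c, dtype=float) * s)
    for c, i in index.items():
        for off in _NEIGHBOUR_OFFSETS:
            j = index.get((c[0] + off[0], c[1] + off[1], c[2] + off[2]))
            if j is not None:
                g.add_edge(i, j)
    return SkeletonGraph(graph=g, voxel_size=s)


def _edge_key(g: nx.Graph, u: int, v: int) -> tuple:
    pu = tuple(g.nodes[u]["pos"])
    pv = tuple(g.nodes[v]["pos"])
    return (min(pu, pv), max(pu, pv))


def prune_junctions(sg: SkeletonGraph) -> SkeletonGraph:
    """Reduce every junction to a through-path by the incidence-angle rule.

    At a vertex of degree > 2, each incident edge is scored by the largest
    angle it makes with any other incident edge (180° = a perfectly straight
    continuation exists).  The edge with the smallest score — the one least
    alignable into a through-path — is removed; this repeats until the degree
    drops to 2.  Ties break on the lexicographic order of edge endpoint
    coordinates, making the result deterministic.
    """
    g = sg.graph.copy()

    def best_angle(v: int, nbrs: list[int]) -> dict[int, float]:
        pos_v = g.nodes[v]["pos"]
        dirs = {}
        for n in nbrs:
            d = g.nodes[n]["pos"] - pos_v
            norm = np.linalg.norm(d)
            dirs[n] = d / norm if norm > 0 else d
        scores = {}
        for n in nbrs:
            angles = [
                np.degrees(np.arccos(np.clip(np.dot(dirs[n], dirs[m]), -1.0, 1.0)))
                for m in nbrs
                if m != n
            ]
            scores[n] = max(angles)
        return scores

    queue = sorted((v for v in g.nodes if g.degree(v) > 2), key=lambda v: tuple(g.nodes[v]["pos"]))
    pending = set(queue)
    while queue:
        v = queue.pop(0)
        pending.discard(v)
        while g.degree(v) > 2:
            nbrs = list(g.neighbors(v))
            scores = best_angle(v, nbrs)
            worst = min(nbrs, key=lambda n: (scores[n], _edge_key(g, v, n)))
            g.remove_edge(v, worst)
            if g.degree(worst) > 2 and worst not in pending:
                queue.append(worst)
                pending.add(worst)
    out = SkeletonGraph(graph=g, voxel_size=sg.voxel_size)
    return out


def smooth(sg: SkeletonGraph, rounds: int = 10, lam: float = 0.5) -> SkeletonGraph:
    """Laplacian smoothing of the polylines.

    Per round every degree-2 vertex moves to ``(1-lam)·p + lam·mean(nbrs)``
    (synchronous update); degree-1 endpoints stay anchored so open fibres do
    not shrink.  The edge set never changes.
    """
    g = sg.graph.copy()
    pos = {n: np.array(d["pos"], dtype=float) for n, d in g.nodes(data=True)}
    movable = [n for n in g.nodes if g.degree(n) == 2]
    for _ in range(rounds):
        new = {}
        for n in movable:
            nbrs = list(g.neighbors(n))
            mean = (pos[nbrs[0]] + pos[nbrs[1]]) / 2.0
            new[n] = (1.0 - lam) * pos[n] + lam * mean
        pos.update(new)
    for n, p in pos.items():
        g.nodes[n]["pos"] = p
    return SkeletonGraph(graph=g, voxel_size=sg.voxel_size)


def filter_components(sg: SkeletonGraph, min_edges: int = 20) -> SkeletonGraph:
    """Remove connected components with fewer than ``min_edges`` edges."""
    g = sg.graph.copy()
    for comp in list(nx.connected_components(g)):
        sub = g.subgraph(comp)
        if sub.number_of_edges() < min_edges:
            g.remove_nodes_from(comp)
    out = SkeletonGraph(graph=g, voxel_size=sg.voxel_size)
    out.assign_components()
    return out


def extract_skeleton(
    volume: BinaryVolume,
    rounds: int = 10,
    lam: float = 0.5,
    min_edges: int = 20,
) -> SkeletonGraph:
    """Full skeleton pipeline: medial axis → graph → prune → smooth →
    component filter → smooth."""
    mask = robust_medial_axis(volume)
    sg = to_graph(mask)
    sg = prune_junctions(sg)
    sg = smooth(sg, rounds=rounds, lam=lam)
    sg = filter_components(sg, min_edges=min_edges)
    sg = smooth(sg, rounds=rounds, lam=lam)
    sg.assign_components()
    return sg
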