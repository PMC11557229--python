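"""Persistent homology of the sublevel filtration of a distance volume.

The cubical complex uses the V-construction: voxels are vertices, and edges,
squares and cubes span axis-adjacent voxels; every cell takes the maximum of
its vertices' values, so a cell enters the filtration exactly when its last
vertex does.  Cells are totally ordered by ``(value, dimension, lexicographic
cell coordinate)``, which makes births, deaths and birth locations
reproducible run to run.

``compute_persistence`` pairs dimension-0 features by union-find with the
elder rule (at a merge the older component survives and the younger bar dies)
and dimension-1 features by boundary-matrix reduction over GF(2) with the
clearing optimisation.  ``brute_force_persistence`` reduces the boundary
matrix of the *entire* complex in one pass and serves as the independent
oracle in tests.

Raw diagrams retain zero-persistence pairs (death equal to birth); use
:func:`simplify` to strip features up to a persistence threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sedt import DistanceVolume

__all__ = [
    "CubicalFiltration",
    "PersistenceDiagram",
    "build_filtration",
    "compute_persistence",
    "simplify",
    "brute_force_persistence",
]

POINT_COLUMNS = ["dim", "birth", "death", "bx", "by", "bz"]


@dataclass(frozen=True)
class PersistenceDiagram:
    """Multiset of (dim, birth, death) points with birth-cell locations.

    ``points`` has columns ``dim, birth, death, bx, by, bz``; ``death`` is
    ``inf`` for essential features.  ``bx, by, bz`` are voxel coordinates of
    the even corner of the creating cell (the creating vertex for dim 0), on
    the grid the diagram was computed on.
    """

    points: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def of_dim(self, dim: int) -> pd.DataFrame:
        return self.points[self.points["dim"] == dim]

    @property
    def n_essential(self) -> int:
        return int(np.isinf(self.points["death"]).sum())

    def to_csv(self, path: str) -> None:
        self.points.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, **provenance) -> "PersistenceDiagram":
        return cls(points=pd.read_csv(path), provenance=provenance)


def simplify(diagram: PersistenceDiagram, threshold: float) -> PersistenceDiagram:
    """Drop finite points with persistence (death − birth) <= ``threshold``.

    Essential (infinite-death) points are always retained.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    p = diagram.points
    keep = np.isinf(p["death"]) | (p["death"] - p["birth"] > threshold)
    prov = dict(diagram.provenance, simplify_threshold=threshold)
    return PersistenceDiagram(points=p[keep].reset_index(drop=True), provenance=prov)


# ---------------------------------------------------------------------------
# filtration
# ---------------------------------------------------------------------------


def _doubled_values(values: np.ndarray) -> np.ndarray:
    """Cell values on the doubled lattice (vertex at 2i, edge at odd coords...).

    Entry at doubled coordinate ``c`` is the max over the vertices of the cell
    anchored there; the cell's dimension is the number of odd components.
    """
    out = np.asarray(values, dtype=float)
    for ax in range(3):
        n = out.shape[ax]
        shape = list(out.shape)
        shape[ax] = 2 * n - 1
        nw = np.empty(shape, dtype=float)
        even = [slice(None)] * 3
        even[ax] = slice(0, 2 * n - 1, 2)
        nw[tuple(even)] = out
        if n > 1:
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[ax] = slice(0, n - 1)
            hi[ax] = slice(1, n)
            odd = [slice(None)] * 3
            odd[ax] = slice(1, 2 * n - 1, 2)
            nw[tuple(odd)] = np.maximum(out[tuple(lo)], out[tuple(hi)])
        out = nw
    return out


@dataclass(frozen=True)
class CubicalFiltration:
    """Lower-star (V-construction) filtration of a distance volume."""

    values: np.ndarray
    doubled: np.ndarray = field(repr=False)
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def cells_of_dim(self, dim: int) -> tuple[np.ndarray, np.ndarray]:
        """(doubled flat indices, values) of all cells of ``dim``, sorted by
        the total order (value, lex doubled coordinate)."""
        D = self.doubled
        parity = [np.arange(s) % 2 for s in D.shape]
        px, py, pz = np.ix_(*parity)
        mask = (px + py + pz) == dim
        flat = np.flatnonzero(mask.ravel())
        vals = D.ravel()[flat]
        order = np.lexsort((flat, vals))
        return flat[order], vals[order]


def build_filtration(d: DistanceVolume) -> CubicalFiltration:
    values = np.asarray(d.grid, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("distance volume contains non-finite values")
    prov = {
        "foreground": d.foreground,
        "subdivision": d.subdivision,
        "voxel_size": d.voxel_size,
    }
    return CubicalFiltration(
        values=values, doubled=_doubled_values(values), provenance=prov
    )


# ---------------------------------------------------------------------------
# dimension 0: union-find with the elder rule
# ---------------------------------------------------------------------------


def _sorted_edges(f: CubicalFiltration):
    """Edges sorted by (value, lex); returns endpoint flat-vertex ids, values
    and doubled flat indices."""
    nx, ny, nz = f.shape
    vals = f.values
    idx = np.arange(nx * ny * nz).reshape(nx, ny, nz)
    dshape = f.doubled.shape
    ea, eb, ev, ed = [], [], [], []
    for ax in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, f.shape[ax] - 1)
        hi[ax] = slice(1, f.shape[ax])
        a = idx[tuple(lo)].ravel()
        b = idx[tuple(hi)].ravel()
        v = np.maximum(vals[tuple(lo)], vals[tuple(hi)]).ravel()
        # doubled coordinate of the edge anchored at its lower vertex
        coords = [np.unravel_index(a, f.shape)[i] * 2 for i in range(3)]
        coords[ax] = coords[ax] + 1
        d = np.ravel_multi_index(coords, dshape)
        ea.append(a)
        eb.append(b)
        ev.append(v)
        ed.append(d)
    ea = np.concatenate(ea)
    eb = np.concatenate(eb)
    ev = np.concatenate(ev)
    ed = np.concatenate(ed)
    order = np.lexsort((ed, ev))
    return ea[order], eb[order], ev[order], ed[order]


def compute_persistence(
    f: CubicalFiltration, max_dim: int = 1
) -> PersistenceDiagram:
    """Persistence diagram of the sublevel filtration, dimensions 0..max_dim.

    Dimension 0 uses union-find with the elder rule; dimension 1 uses GF(2)
    boundary-matrix reduction with clearing.  ``max_dim`` must be 0 or 1
    (cavities are outside the analysis path).
    """
    if max_dim not in (0, 1):
        raise ValueError("max_dim must be 0 or 1")
    nx, ny, nz = f.shape
    nvox = nx * ny * nz
    vflat = f.values.ravel()
    ea, eb, ev, ed = _sorted_edges(f)

    parent = list(range(nvox))
    birth_vertex = list(range(nvox))  # birth vertex of the component rooted here
    val_list = vflat.tolist()
    ea_l, eb_l, ev_l = ea.tolist(), eb.tolist(), ev.tolist()

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    dead_vertices: list[int] = []
    death_values: list[float] = []
    for k in range(len(ev_l)):
        ra, rb = find(ea_l[k]), find(eb_l[k])
        if ra == rb:
            continue  # positive edge: creates a 1-cycle
        bva, bvb = birth_vertex[ra], birth_vertex[rb]
        # younger component = later-born creating vertex in the total order
        if (val_list[bva], bva) < (val_list[bvb], bvb):
            parent[rb] = ra
            young = bvb
        else:
            parent[ra] = rb
            young = bva
        dead_vertices.append(young)
        death_values.append(ev_l[k])

    rows: list[tuple] = []
    xs, ys, zs = np.unravel_index(np.asarray(dead_vertices, dtype=int), f.shape)
    for young, death, x, y, z in zip(dead_vertices, death_values, xs, ys, zs):
        rows.append((0, val_list[young], death, int(x), int(y), int(z)))
    # essential components (one per connected component of the grid: 1 for a box)
    roots = {find(i) for i in range(nvox)}
    for r in sorted(roots):
        bv = birth_vertex[r]
        x, y, z = np.unravel_index(bv, f.shape)
        rows.append((0, val_list[bv], np.inf, int(x), int(y), int(z)))

    if max_dim >= 1:
        rows.extend(_dim1_pairs(f, ev, ed))

    points = pd.DataFrame(rows, columns=POINT_COLUMNS)
    points = points.sort_values(["dim", "birth", "death"], kind="mergesort").reset_index(
        drop=True
    )
    return PersistenceDiagram(points=points, provenance=dict(f.provenance))


def _dim1_pairs(f: CubicalFiltration, ev: np.ndarray, ed: np.ndarray) -> list[tuple]:
    """(birth, death) pairs of 1-cycles via ∂₂ reduction with clearing."""
    dshape = f.doubled.shape
    strides = (dshape[1] * dshape[2], dshape[2], 1)
    edge_rank = {int(d): i for i, d in enumerate(ed)}

    sq_flat, sq_vals = f.cells_of_dim(2)
    cu_flat, cu_vals = f.cells_of_dim(3)
    sq_rank = {int(d): i for i, d in enumerate(sq_flat)}

    def odd_axes(flat: int) -> list[int]:
        c = np.unravel_index(flat, dshape)
        return [a for a in range(3) if c[a] % 2 == 1]

    # --- clearing pass: reduce cube columns over squares; pivot squares are
    # creators of 2-cycles, whose ∂₂ columns reduce to zero.
    cleared = set()
    pivot_sq: dict[int, int] = {}
    cu_cols: list[int] = []
    for j, flat in enumerate(cu_flat):
        col = 0
        for a in range(3):
            for s in (-strides[a], strides[a]):
                col ^= 1 << sq_rank[int(flat) + s]
        while col:
            low = col.bit_length() - 1
            if low in pivot_sq:
                col ^= cu_cols[pivot_sq[low]]
            else:
                pivot_sq[low] = j
                cleared.add(low)
                break
        cu_cols.append(col)

    # --- ∂₂ reduction
    pairs: list[tuple] = []
    pivot_e: dict[int, int] = {}
    sq_cols: list[int] = []
    for j, flat in enumerate(sq_flat):
        if j in cleared:
            sq_cols.append(0)
            continue
        col = 0
        for a in odd_axes(int(flat)):
            for s in (-strides[a], strides[a]):
                col ^= 1 << edge_rank[int(flat) + s]
        while col:
            low = col.bit_length() - 1
            if low in pivot_e:
                col ^= sq_cols[pivot_e[low]]
            else:
                pivot_e[low] = j
                ec = np.unravel_index(int(ed[low]), dshape)
                pairs.append(
                    (1, ev[low], sq_vals[j], ec[0] // 2, ec[1] // 2, ec[2] // 2)
                )
                break
        sq_cols.append(col)
    return pairs


# ---------------------------------------------------------------------------
# brute-force oracle: full boundary-matrix reduction, dimensions 0-2
# ---------------------------------------------------------------------------


def brute_force_persistence(d: DistanceVolume) -> PersistenceDiagram:
    """Reduce the boundary matrix of the whole complex (test oracle).

    Guarded to grids of at most 1000 voxels.  Emits dimensions 0-2 with the
    same total order and tie-breaking as :func:`compute_persistence`.
    """
    values = np.asarray(d.grid, dtype=float)
    if values.size > 1000:
        raise ValueError("brute-force oracle is limited to grids of <= 1000 voxels")
    D = _doubled_values(values)
    dshape = D.shape
    strides = (dshape[1] * dshape[2], dshape[2], 1)

    flat_all = np.arange(D.size)
    coords = np.unravel_index(flat_all, dshape)
    dims = (coords[0] % 2) + (coords[1] % 2) + (coords[2] % 2)
    vals = D.ravel()
    order = np.lexsort((flat_all, dims, vals))
    rank = {int(flat_all[i]): r for r, i in enumerate(order)}
    sorted_flat = flat_all[order]
    sorted_vals = vals[order]
    sorted_dims = dims[order]

    columns: list[int] = []
    pivot: dict[int, int] = {}
    pair_of: dict[int, int] = {}  # birth rank -> death rank
    for j in range(len(sorted_flat)):
        flat = int(sorted_flat[j])
        c = np.unravel_index(flat, dshape)
        col = 0
        for a in range(3):
            if c[a] % 2 == 1:
                col ^= 1 << rank[flat - strides[a]]
                col ^= 1 << rank[flat + strides[a]]
        while col:
            low = col.bit_length() - 1
            if low in pivot:
                col ^= columns[pivot[low]]
            else:
                pivot[low] = j
                pair_of[low] = j
                break
        columns.append(col)

    paired = set(pair_of) | set(pair_of.values())
    rows = []
    for i, j in pair_of.items():
        dim = int(sorted_dims[i])
        if dim > 2:
            continue
        ec = np.unravel_index(int(sorted_flat[i]), dshape)
        rows.append(
            (dim, sorted_vals[i], sorted_vals[j], ec[0] // 2, ec[1] // 2, ec[2] // 2)
        )
    for i in range(len(sorted_flat)):
        if i in paired:
            continue
        dim = int(sorted_dims[i])
        if dim > 2:
            continue
        ec = np.unravel_index(int(sorted_flat[i]), dshape)
        rows.append((dim, sorted_vals[i], np.inf, ec[0] // 2, ec[1] // 2, ec[2] // 2))

    points = pd.DataFrame(rows, columns=POINT_COLUMNS)
    points = points.sort_values(["dim", "birth", "death"], kind="mergesort").reset_index(
        drop=True
    )
    prov = {"foreground": d.foreground, "subdivision": d.subdivision, "oracle": True}
    return PersistenceDiagram(points=points, provenance=prov)
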