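"""Conductance graphs over raster cells: least-cost and resistance
distances, and explicit least-cost corridors.

A conductance raster becomes a sparse symmetric *transition graph* in which
every cell is connected to its 8 neighbours with transition value
t_ij = mean(c_i, c_j) (arithmetic mean by default, geometric optionally);
cells of conductance 0 are isolated. Because the grid lives in lon/lat
degrees, raw transitions carry two geometric distortions — diagonal
neighbours are farther apart than orthogonal ones, and east-west spacing
shrinks towards the poles — corrected by :func:`geo_correct`:

* ``lcp``  — divide each transition by the great-circle distance (m)
  between the two cell centres. Least-cost distances then accumulate edge
  costs 1/t_ij along Dijkstra shortest paths (units: metres / conductance).
* ``ibr``  — weight transitions by the surface area reached in a random
  walk: north-south transitions are multiplied by the cosine of the mean
  latitude of the two centres. Diagonal transitions receive the same
  cosine factor (an implementation convention; the correction's source
  only specifies the north-south case), east-west transitions are
  unchanged. Resistance (commute) distances then come from the graph
  Laplacian: C(i,j) = vol(G) * R_eff(i,j), the expected number of random
  walk steps to commute between the cells.

A ``planar`` correction (divide by Euclidean centre distance in cell
units, no sphere) is provided for unit-grid work and tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import splu

from .geo import haversine
from .raster import LandscapeRaster

__all__ = [
    "TransitionGraph", "CellPath", "build_transition", "geo_correct",
    "least_cost_distance", "commute_distance", "shortest_path",
    "UnreachableError",
]


class GraphError(ValueError):
    pass


class UnreachableError(GraphError):
    """A requested pair of cells is not connected in the graph."""


@dataclass
class TransitionGraph:
    """Sparse symmetric transition matrix over raster cells.

    ``matrix`` is (N, N) with N = nrows * ncols in row-major cell order;
    nonzeros occur only between 8-neighbour cells with positive transition
    value. ``correction`` tags the geodesic correction applied: ``raw``,
    ``lcp``, ``ibr``, or ``planar``.
    """

    matrix: sparse.csr_matrix
    shape: tuple[int, int]
    raster: LandscapeRaster | None = None
    correction: str = "raw"

    @property
    def n_cells(self) -> int:
        return self.shape[0] * self.shape[1]

    @classmethod
    def from_matrix(cls, weights, shape=None, correction="raw"):
        """Wrap an explicit symmetric weight matrix (toy graphs, tests)."""
        W = sparse.csr_matrix(np.asarray(weights, dtype=float)
                              if not sparse.issparse(weights) else weights)
        if shape is None:
            shape = (W.shape[0], 1)
        return cls(W, shape, None, correction)


_OFFSETS = [(0, 1), (1, 0), (1, 1), (1, -1)]  # E, S, SE, SW (undirected)


def _neighbour_pairs(nrows: int, ncols: int):
    """Yield (i_idx, j_idx, drow, dcol) flat-index arrays per direction."""
    rows, cols = np.mgrid[0:nrows, 0:ncols]
    for drow, dcol in _OFFSETS:
        r2, c2 = rows + drow, cols + dcol
        ok = (r2 >= 0) & (r2 < nrows) & (c2 >= 0) & (c2 < ncols)
        i = (rows[ok] * ncols + cols[ok]).ravel()
        j = (r2[ok] * ncols + c2[ok]).ravel()
        yield i, j, drow, dcol


def build_transition(raster: LandscapeRaster,
                     mean: str = "arithmetic") -> TransitionGraph:
    """8-neighbour transition graph from a conductance raster.

    t_ij = (c_i + c_j)/2 (or sqrt(c_i c_j) with ``mean="geometric"``) for
    neighbouring cells with both conductances > 0; zero-conductance cells
    stay isolated.
    """
    if raster.semantics != "conductance":
        raise GraphError("build_transition expects a conductance raster "
                         "(use apply_conductance first)")
    c = raster.values.ravel().astype(float)
    rows_i, rows_j, vals = [], [], []
    for i, j, _, _ in _neighbour_pairs(raster.nrows, raster.ncols):
        ok = (c[i] > 0) & (c[j] > 0)
        i, j = i[ok], j[ok]
        if mean == "arithmetic":
            t = 0.5 * (c[i] + c[j])
        elif mean == "geometric":
            t = np.sqrt(c[i] * c[j])
        else:
            raise GraphError(f"unknown mean {mean!r}")
        rows_i.append(i)
        rows_j.append(j)
        vals.append(t)
    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    t = np.concatenate(vals)
    n = raster.nrows * raster.ncols
    W = sparse.coo_matrix((np.concatenate([t, t]),
                           (np.concatenate([i, j]), np.concatenate([j, i]))),
                          shape=(n, n)).tocsr()
    return TransitionGraph(W, (raster.nrows, raster.ncols), raster, "raw")


def geo_correct(graph: TransitionGraph, mode: str) -> TransitionGraph:
    """Apply the geodesic correction for least-cost (``lcp``), random-walk
    (``ibr``), or unit-grid (``planar``) work. Refuses to correct twice."""
    if graph.correction != "raw":
        raise GraphError(f"graph already carries the {graph.correction!r} "
                         "correction; corrections do not compose")
    if mode not in ("lcp", "ibr", "planar"):
        raise GraphError(f"unknown correction mode {mode!r}")
    if graph.raster is None:
        raise GraphError("geo_correct needs the graph's source raster")
    r = graph.raster
    W = graph.matrix.tocoo(copy=True)
    ri, ci = np.divmod(W.row, r.ncols)
    rj, cj = np.divmod(W.col, r.ncols)
    if mode == "planar":
        d = np.hypot((ci - cj) * r.dx, (ri - rj) * r.dy)
        W.data = W.data / d
    elif mode == "lcp":
        lon_i, lat_i = r.cell_center(ri, ci)
        lon_j, lat_j = r.cell_center(rj, cj)
        W.data = W.data / haversine(lon_i, lat_i, lon_j, lat_j)
    else:  # ibr
        _, lat_i = r.cell_center(ri, ci)
        _, lat_j = r.cell_center(rj, cj)
        ns = ri != rj  # north-south and diagonal transitions
        factor = np.where(ns, np.cos(np.radians(0.5 * (lat_i + lat_j))), 1.0)
        W.data = W.data * factor
    return TransitionGraph(W.tocsr(), graph.shape, r, mode)


def _cost_graph(W: sparse.csr_matrix) -> sparse.csr_matrix:
    cost = W.tocsr(copy=True)
    cost.data = 1.0 / cost.data
    return cost


def _check_reachable(D: np.ndarray, cells, strict: bool, what: str):
    if np.isinf(D).any():
        bad = [(cells[a], cells[b]) for a, b in zip(*np.nonzero(np.isinf(D)))
               if a < b]
        if strict:
            raise UnreachableError(f"{what}: unreachable cell pairs {bad}")
        warnings.warn(f"{what}: unreachable cell pairs {bad} set to inf",
                      stacklevel=3)


def least_cost_distance(graph: TransitionGraph, cells,
                        strict: bool = True) -> np.ndarray:
    """Pairwise least-cost distances between flat cell indices.

    Edge cost is the reciprocal of the transition value; shortest paths by
    Dijkstra. Returns a symmetric zero-diagonal matrix; unreachable pairs
    raise in strict mode, else come back as inf.
    """
    cells = np.asarray(cells, dtype=int)
    D = csgraph.dijkstra(_cost_graph(graph.matrix), directed=False,
                         indices=cells)[:, cells]
    D = 0.5 * (D + D.T)  # symmetrize away float round-off
    np.fill_diagonal(D, 0.0)
    _check_reachable(D, cells, strict, "least-cost")
    return D


def commute_distance(graph: TransitionGraph, cells,
                     strict: bool = True) -> np.ndarray:
    """Expected random-walk commute steps between cells.

    C(i,j) = vol(G) * R_eff(i,j) with R_eff the effective resistance of
    the transition-weighted graph (grounded-Laplacian sparse solves) and
    vol(G) the sum of weighted degrees. Cells in different components give
    inf (or raise in strict mode).
    """
    cells = np.asarray(cells, dtype=int)
    W = graph.matrix.tocsr()
    n_comp, comp = csgraph.connected_components(W, directed=False)
    out = np.full((len(cells), len(cells)), np.inf)
    np.fill_diagonal(out, 0.0)
    for label in np.unique(comp[cells]):
        members = np.flatnonzero(comp == label)
        in_comp = np.flatnonzero(comp[cells] == label)
        if len(in_comp) < 2:
            continue
        sub = W[members][:, members]
        vol = sub.sum()
        deg = np.asarray(sub.sum(axis=1)).ravel()
        L = sparse.diags(deg) - sub
        # ground the last node of the component and factorize once
        Lg = L[:-1, :-1].tocsc()
        solve = splu(Lg).solve
        pos = {c: np.searchsorted(members, c) for c in cells[in_comp]}
        ncomp = len(members)
        pots = {}
        for c in cells[in_comp]:
            e = np.zeros(ncomp - 1)
            if pos[c] < ncomp - 1:
                e[pos[c]] = 1.0
            pots[c] = np.append(solve(e), 0.0) if pos[c] < ncomp - 1 \
                else np.zeros(ncomp)
        for ai in range(len(in_comp)):
            for bi in range(ai + 1, len(in_comp)):
                ca, cb = cells[in_comp[ai]], cells[in_comp[bi]]
                xa, xb = pots[ca], pots[cb]
                r_eff = (xa[pos[ca]] - xa[pos[cb]]
                         - xb[pos[ca]] + xb[pos[cb]])
                val = vol * r_eff
                a, b = in_comp[ai], in_comp[bi]
                out[a, b] = out[b, a] = val
    _check_reachable(out, cells, strict, "commute")
    return out


@dataclass
class CellPath:
    """An explicit least-cost corridor between two cells."""

    cells: list[int]                      # flat indices, origin..destination
    cost: float
    class_composition: dict = field(default_factory=dict)  # class -> fraction

    def __len__(self) -> int:
        return len(self.cells)


def shortest_path(graph: TransitionGraph, origin: int, dest: int,
                  class_raster: LandscapeRaster | None = None) -> CellPath:
    """One optimal path between two cells, with land-use composition.

    Ties between equal-cost paths are broken deterministically by the
    Dijkstra predecessor order (last relaxation wins, scan order fixed by
    the CSR layout). ``class_raster`` (the pre-conductance class grid)
    yields the fraction of path cells per land-use class — the corridor
    product.
    """
    if origin == dest:
        path = [int(origin)]
        cost = 0.0
    else:
        dist, pred = csgraph.dijkstra(_cost_graph(graph.matrix),
                                      directed=False, indices=origin,
                                      return_predecessors=True)
        if np.isinf(dist[dest]):
            raise UnreachableError(f"cell {dest} unreachable from {origin}")
        path = [int(dest)]
        while path[-1] != origin:
            path.append(int(pred[path[-1]]))
        path.reverse()
        cost = float(dist[dest])
    comp: dict = {}
    if class_raster is not None:
        rc = np.divmod(np.asarray(path), class_raster.ncols)
        codes = class_raster.values[rc[0], rc[1]]
        uniq, counts = np.unique(codes, return_counts=True)
        comp = {int(u): float(c) / len(path) for u, c in zip(uniq, counts)}
    return CellPath(path, cost, comp)


def distance_frame(matrix: np.ndarray, labels, units: str) -> pd.DataFrame:
    """Label a square distance matrix; records its units in ``attrs``."""
    df = pd.DataFrame(matrix, index=labels, columns=labels)
    df.attrs["units"] = units
    return df
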