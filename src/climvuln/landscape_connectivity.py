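"""Resistance surfaces, circuit-theory connectivity and distance matrices.

A cost surface assigns every raster cell a movement resistance in
[1, 100] (sea cells get a configurable higher cost, 200 by default, 120 as
the sensitivity alternative).  The landscape becomes an electrical
network: cells are nodes on an 8-neighbour lattice, each edge's resistance
is the arithmetic mean of the two cell costs (diagonal edges scaled by
sqrt(2)), and conductance is its reciprocal.  Effective resistance between
population cells and per-cell cumulative current over all population pairs
are computed from sparse Laplacian solves with one grounded node per
connected component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csc_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .matrix import DistanceMatrix
from .raster import Grid

SEA_COST_DEFAULT = 200.0
SEA_COST_ALTERNATIVE = 120.0


# ----------------------------------------------------------------------
# Cost surfaces
# ----------------------------------------------------------------------

@dataclass
class CostSurface:
    """Per-cell movement resistance; NaN = no-data (impassable, off-grid)."""

    grid: Grid
    sea_mask: np.ndarray | None = None
    sea_cost: float = SEA_COST_DEFAULT

    @property
    def cost(self) -> np.ndarray:
        return self.grid.data

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


def build_cost_surface(raster: Grid, cost_rule="suitability",
                       sea_mask: np.ndarray | None = None,
                       sea_cost: float = SEA_COST_DEFAULT) -> CostSurface:
    """Convert a landscape raster into a resistance cost surface.

    cost_rule:
      * "suitability": cost = 1 + 99 * (1 - s) for suitability s in [0, 1];
      * dict {category: cost} for categorical rasters (unmapped values are
        an error, reported explicitly);
      * (xs, costs) tuple: piecewise-linear interpolation;
      * any callable array -> array.

    Sea cells override everything with `sea_cost`; no-data stays no-data.
    """
    data = raster.data
    if cost_rule == "suitability":
        with np.errstate(invalid="ignore"):
            if np.nanmin(data) < -1e-9 or np.nanmax(data) > 1 + 1e-9:
                raise ValueError("suitability rule expects values in [0, 1]")
        cost = 1.0 + 99.0 * (1.0 - data)
    elif isinstance(cost_rule, dict):
        cost = np.full(data.shape, np.nan)
        present = set(np.unique(data[~np.isnan(data)]))
        unmapped = sorted(present - set(cost_rule))
        if unmapped:
            raise ValueError(f"unmapped raster categories: {unmapped}")
        for value, c in cost_rule.items():
            cost[data == value] = c
    elif isinstance(cost_rule, tuple):
        xs, cs = (np.asarray(v, float) for v in cost_rule)
        cost = np.where(np.isnan(data), np.nan, np.interp(data, xs, cs))
    elif callable(cost_rule):
        cost = np.where(np.isnan(data), np.nan, cost_rule(data))
    else:
        raise TypeError(f"unsupported cost_rule: {cost_rule!r}")

    land = ~np.isnan(cost)
    if sea_mask is not None:
        land &= ~sea_mask
    if land.any():
        lo, hi = np.nanmin(cost[land]), np.nanmax(cost[land])
        if lo < 1.0 - 1e-9 or hi > 100.0 + 1e-9:
            raise ValueError(f"land costs must lie in [1, 100]; got [{lo}, {hi}]")
    if sea_mask is not None:
        # sea is passable, at high cost; it overrides the land rule
        cost = np.where(sea_mask, sea_cost, cost)
    return CostSurface(raster.copy_with(cost), sea_mask, sea_cost)


# ----------------------------------------------------------------------
# Lattice network
# ----------------------------------------------------------------------

_ORTHO = [(-1, 0), (0, -1)]
_DIAG = [(-1, -1), (-1, 1)]


@dataclass
class _Network:
    node_of_cell: np.ndarray     # (nrows, ncols) int, -1 for no-data
    cells: np.ndarray            # (n_nodes, 2) row/col of each node
    edges: np.ndarray            # (n_edges, 2) node indices
    conductance: np.ndarray      # (n_edges,)
    laplacian: csc_matrix
    component: np.ndarray        # (n_nodes,) component label


def build_network(surface: CostSurface, neighbors: int = 8,
                  edge_cost: str = "mean") -> _Network:
    """Build the conductance network for a cost surface.

    `edge_cost="mean"` takes edge resistance as the arithmetic mean of the
    two cell costs (the convention used throughout); "harmonic" uses the
    harmonic mean instead.  Diagonal edges (8-neighbour mode) have their
    resistance scaled by sqrt(2) for the longer step.
    """
    if neighbors not in (4, 8):
        raise ValueError("neighbors must be 4 or 8")
    cost = surface.cost
    nrows, ncols = cost.shape
    valid = ~np.isnan(cost)
    node_of_cell = np.full((nrows, ncols), -1, dtype=int)
    cells = np.argwhere(valid)
    node_of_cell[valid] = np.arange(len(cells))

    offsets = list(_ORTHO) + (list(_DIAG) if neighbors == 8 else [])
    edge_list, cond_list = [], []
    for dr, dc in offsets:
        r_lo, r_hi = max(0, -dr), nrows - max(0, dr)
        c_lo, c_hi = max(0, -dc), ncols - max(0, dc)
        a = node_of_cell[r_lo:r_hi, c_lo:c_hi].ravel()
        b = node_of_cell[r_lo + dr:r_hi + dr, c_lo + dc:c_hi + dc].ravel()
        ok = (a >= 0) & (b >= 0)
        a, b = a[ok], b[ok]
        ca = cost[cells[a, 0], cells[a, 1]]
        cb = cost[cells[b, 0], cells[b, 1]]
        if edge_cost == "mean":
            resistance = 0.5 * (ca + cb)
        elif edge_cost == "harmonic":
            resistance = 2.0 * ca * cb / (ca + cb)
        else:
            raise ValueError("edge_cost must be 'mean' or 'harmonic'")
        if (dr, dc) in _DIAG:
            resistance = resistance * np.sqrt(2.0)
        edge_list.append(np.column_stack([a, b]))
        cond_list.append(1.0 / resistance)

    edges = np.concatenate(edge_list) if edge_list else np.empty((0, 2), int)
    cond = np.concatenate(cond_list) if cond_list else np.empty(0)

    n = len(cells)
    i = np.concatenate([edges[:, 0], edges[:, 1], edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0], edges[:, 0], edges[:, 1]])
    v = np.concatenate([-cond, -cond, cond, cond])
    lap = csc_matrix((v, (i, j)), shape=(n, n))

    adj = csc_matrix((np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n))
    _, comp = connected_components(adj, directed=False)
    return _Network(node_of_cell, cells, edges, cond, lap, comp)


class _ComponentSolver:
    """Grounded-Laplacian solver for one connected component."""

    def __init__(self, net: _Network, comp_id: int):
        self.nodes = np.flatnonzero(net.component == comp_id)
        self.index = {int(nd): k for k, nd in enumerate(self.nodes)}
        sub = net.laplacian[np.ix_(self.nodes, self.nodes)].tocsc()
        self.n = len(self.nodes)
        self.ground = self.n - 1
        keep = np.arange(self.n - 1)
        self.lu = splu(sub[np.ix_(keep, keep)].tocsc()) if self.n > 1 else None

    def potentials(self, source: int, sink: int) -> np.ndarray:
        """Node potentials (full component vector) for unit current a->b."""
        rhs = np.zeros(self.n - 1)
        s, t = self.index[source], self.index[sink]
        if s != self.ground:
            rhs[s] += 1.0
        if t != self.ground:
            rhs[t] -= 1.0
        v = self.lu.solve(rhs)
        return np.append(v, 0.0)


def _focal_nodes(net: _Network, surface: CostSurface,
                 focal_cells: list[tuple[int, int]]) -> list[int]:
    nodes = []
    for r, c in focal_cells:
        node = int(net.node_of_cell[r, c])
        if node < 0:
            raise ValueError(f"focal cell ({r}, {c}) lies on no-data")
        nodes.append(node)
    return nodes


def resistance_distance(surface: CostSurface,
                        focal_cells: list[tuple[int, int]],
                        labels: list[str] | None = None,
                        neighbors: int = 8,
                        edge_cost: str = "mean") -> DistanceMatrix:
    """Pairwise effective resistance between focal cells.

    R_ab = (e_a - e_b)^T L^+ (e_a - e_b) via sparse solves with one node
    grounded per component; pairs in different components get inf.
    """
    net = build_network(surface, neighbors, edge_cost)
    nodes = _focal_nodes(net, surface, focal_cells)
    labels = labels or [f"N{k + 1}" for k in range(len(nodes))]

    solvers: dict[int, _ComponentSolver] = {}
    pot: dict[int, np.ndarray] = {}
    for node in set(nodes):
        cid = int(net.component[node])
        if cid not in solvers:
            solvers[cid] = _ComponentSolver(net, cid)
        sol = solvers[cid]
        rhs = np.zeros(sol.n - 1)
        k = sol.index[node]
        if k != sol.ground:
            rhs[k] = 1.0
        pot[node] = np.append(sol.lu.solve(rhs), 0.0) if sol.lu is not None else \
            np.zeros(1)

    n = len(nodes)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = nodes[i], nodes[j]
            if net.component[a] != net.component[b]:
                vals[i, j] = vals[j, i] = np.inf
                continue
            sol = solvers[int(net.component[a])]
            va, vb = pot[a], pot[b]
            ka, kb = sol.index[a], sol.index[b]
            r = va[ka] - va[kb] - vb[ka] + vb[kb]
            vals[i, j] = vals[j, i] = max(r, 0.0)
    return DistanceMatrix(labels, vals, "resistance")


def cumulative_current(surface: CostSurface,
                       focal_cells: list[tuple[int, int]],
                       neighbors: int = 8,
                       edge_cost: str = "mean") -> Grid:
    """Cumulative current map over all focal pairs.

    For each unordered pair, unit current is injected/extracted and each
    cell receives half the sum of absolute branch currents incident to it;
    maps are summed over pairs.  No-data cells stay NaN.
    """
    net = build_network(surface, neighbors, edge_cost)
    nodes = _focal_nodes(net, surface, focal_cells)
    solvers: dict[int, _ComponentSolver] = {}

    total = np.zeros(len(net.cells))
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            a, b = nodes[i], nodes[j]
            ca, cb = int(net.component[a]), int(net.component[b])
            if ca != cb:
                continue
            if ca not in solvers:
                solvers[ca] = _ComponentSolver(net, ca)
            sol = solvers[ca]
            v_local = sol.potentials(a, b)
            v = np.zeros(len(net.cells))
            v[sol.nodes] = v_local
            i_edge = (v[net.edges[:, 0]] - v[net.edges[:, 1]]) * net.conductance
            node_cur = np.zeros(len(net.cells))
            np.add.at(node_cur, net.edges[:, 0], np.abs(i_edge))
            np.add.at(node_cur, net.edges[:, 1], np.abs(i_edge))
            total += 0.5 * node_cur

    out = np.full(surface.shape, np.nan)
    out[net.cells[:, 0], net.cells[:, 1]] = total
    return surface.grid.copy_with(out)


# ----------------------------------------------------------------------
# Geographic distance
# ----------------------------------------------------------------------

_EARTH_RADIUS_KM = 6371.0


def euclidean_matrix(pops: pd.DataFrame, mode: str = "planar",
                     x: str = "x", y: str = "y") -> DistanceMatrix:
    """Pairwise geographic distances (planar Euclidean or great-circle).

    In "greatcircle" mode the x/y columns are interpreted as lon/lat in
    degrees and distances are returned in kilometres.
    """
    for col in (x, y, "pop"):
        if col not in pops.columns:
            raise ValueError(f"population table lacks column {col!r}")
    if pops[[x, y]].isna().any().any():
        raise ValueError("missing coordinates")
    labels = pops["pop"].tolist()
    xs = pops[x].to_numpy(float)
    ys = pops[y].to_numpy(float)
    if mode == "planar":
        d = np.hypot(xs[:, None] - xs[None, :], ys[:, None] - ys[None, :])
    elif mode == "greatcircle":
        lon = np.radians(xs)
        lat = np.radians(ys)
        dlon = lon[:, None] - lon[None, :]
        dlat = lat[:, None] - lat[None, :]
        h = (np.sin(dlat / 2) ** 2
             + np.cos(lat[:, None]) * np.cos(lat[None, :]) * np.sin(dlon / 2) ** 2)
        h = np.clip(h, 0.0, 1.0)
        d = 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))
    else:
        raise ValueError("mode must be 'planar' or 'greatcircle'")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d, "geographic")


# ----------------------------------------------------------------------
# Range-shift flags from current-map change
# ----------------------------------------------------------------------

def connectivity_change(current_now: Grid, current_future: Grid,
                        pops: pd.DataFrame, buffer_radius: int = 3,
                        tau: float = 0.5,
                        resistance_now: DistanceMatrix | None = None,
                        resistance_future: DistanceMatrix | None = None,
                        corridor_factor: float = 2.0) -> pd.DataFrame:
    """Per-population range-shift potential flag ('+' or '-').

    The connectivity score of a population is the mean cumulative current
    within `buffer_radius` cells of its cell.  A population is flagged '-'
    (low range-shift potential) if its future/present score ratio falls
    below `tau`, or — when future resistance matrices and future
    suitability flags are available — if every remaining corridor (future
    effective resistance within `corridor_factor` of the present median)
    terminates in a future-unsuitable population.
    """
    if current_now.shape != current_future.shape:
        raise ValueError("current maps must be aligned")
    nrows, ncols = current_now.shape

    def score(grid: Grid, r0: int, c0: int) -> float:
        rr = slice(max(0, r0 - buffer_radius), min(nrows, r0 + buffer_radius + 1))
        cc = slice(max(0, c0 - buffer_radius), min(ncols, c0 + buffer_radius + 1))
        window = grid.data[rr, cc]
        return float(np.nanmean(window))

    corridor_ok = None
    if resistance_now is not None and resistance_future is not None \
            and "suitable_future" in pops.columns:
        rn = resistance_now.align(pops["pop"].tolist())
        rf = resistance_future.align(pops["pop"].tolist())
        finite = rn.lower_triangle()[np.isfinite(rn.lower_triangle())]
        threshold = np.median(finite) * corridor_factor
        corridor_ok = np.isfinite(rf.values) & (rf.values <= threshold)
        np.fill_diagonal(corridor_ok, False)

    rows = []
    suit_future = pops.get("suitable_future")
    for k, rec in enumerate(pops.itertuples()):
        s_now = score(current_now, rec.row, rec.col)
        s_fut = score(current_future, rec.row, rec.col)
        ratio = s_fut / s_now if s_now > 0 else np.nan
        flag, reason = "+", "connectivity maintained"
        if not np.isfinite(ratio) or ratio < tau:
            flag, reason = "-", f"future/present current ratio {ratio:.3g} < {tau}"
        elif corridor_ok is not None:
            nbrs = np.flatnonzero(corridor_ok[k])
            if len(nbrs) == 0:
                flag, reason = "-", "no remaining corridors"
            elif not any(bool(suit_future.iloc[m]) for m in nbrs):
                flag, reason = "-", "all corridors end in unsuitable populations"
        rows.append({"pop": rec.pop, "score_now": s_now, "score_future": s_fut,
                     "ratio": ratio, "range_shift": flag, "reason": reason})
    return pd.DataFrame(rows)
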