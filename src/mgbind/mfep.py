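"""Zero-temperature string method for minimum free energy paths.

A chain of nodes between two fixed endpoints is relaxed on a 2D FES by
alternating (i) a gradient-descent move of the interior nodes on the
bilinearly interpolated surface and (ii) reparameterisation to equal
arclength, until the maximum node displacement falls below tolerance.
"""
from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator, interp1d

from .fes import FESGrid


@dataclass
class MFEPPath:
    nodes: np.ndarray           # (n_nodes, 2) CV points
    energies: np.ndarray        # kJ/mol per node
    converged: bool
    n_iterations: int


def _interpolators(fes: FESGrid, fill_value: float):
    centers = fes.grid.centers()
    f = fes.free_energy.copy()
    nan = ~np.isfinite(f)
    if nan.any():
        f[nan] = fill_value
    interp = RegularGridInterpolator(centers, f, bounds_error=False,
                                     fill_value=fill_value)
    gx, gy = np.gradient(f, centers[0], centers[1], edge_order=1)
    gix = RegularGridInterpolator(centers, gx, bounds_error=False, fill_value=0.0)
    giy = RegularGridInterpolator(centers, gy, bounds_error=False, fill_value=0.0)
    return interp, gix, giy


def _clamp(nodes: np.ndarray, fes: FESGrid) -> np.ndarray:
    centers = fes.grid.centers()
    lo = np.array([c[0] for c in centers])
    hi = np.array([c[-1] for c in centers])
    return np.clip(nodes, lo, hi)


def _reparameterize(nodes: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return nodes
    target = np.linspace(0.0, s[-1], len(nodes))
    out = np.column_stack([interp1d(s, nodes[:, k])(target) for k in range(2)])
    out[0], out[-1] = nodes[0], nodes[-1]
    return out


def _initial_path(fes: FESGrid, a: np.ndarray, b: np.ndarray, n_nodes: int):
    """Straight line unless it crosses missing cells, then a lowest-cost
    grid path (uniform-cost search over finite cells) seeds the string."""
    line = np.linspace(a, b, n_nodes)
    f = fes.free_energy
    if not np.isnan(f).any():
        return line
    centers = fes.grid.centers()

    def cell_of(p):
        return tuple(int(np.clip(np.round((p[k] - c[0]) / (c[1] - c[0])),
                                 0, len(c) - 1))
                     for k, c in enumerate(centers))

    ok = np.isfinite(f)
    if all(ok[cell_of(p)] for p in line):
        return line
    start, goal = cell_of(a), cell_of(b)
    if not (ok[start] and ok[goal]):
        raise ValueError("an endpoint lies in an unvisited FES cell")
    # Dijkstra with cost = FES value of the entered cell (shifted positive)
    shift = np.nanmin(f) - 1.0
    dist = {start: 0.0}
    prev = {}
    heap = [(0.0, start)]
    moves = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    while heap:
        d, cur = heapq.heappop(heap)
        if cur == goal:
            break
        if d > dist.get(cur, np.inf):
            continue
        for dx, dy in moves:
            nxt = (cur[0] + dx, cur[1] + dy)
            if not (0 <= nxt[0] < f.shape[0] and 0 <= nxt[1] < f.shape[1]):
                continue
            if not ok[nxt]:
                continue
            nd = d + (f[nxt] - shift)
            if nd < dist.get(nxt, np.inf):
                dist[nxt] = nd
                prev[nxt] = cur
                heapq.heappush(heap, (nd, nxt))
    if goal not in prev and goal != start:
        raise ValueError("no finite-cell path connects the endpoints")
    cells = [goal]
    while cells[-1] != start:
        cells.append(prev[cells[-1]])
    cells.reverse()
    pts = np.array([[centers[0][i], centers[1][j]] for i, j in cells])
    pts[0], pts[-1] = a, b
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0, s[-1], n_nodes)
    return np.column_stack([interp1d(s, pts[:, k])(target) for k in range(2)])


def string_minimize(fes: FESGrid, endpoint_a, endpoint_b, n_nodes: int = 100,
                    step_size: float = 0.01, tol: float = 1e-4,
                    max_iter: int = 5000) -> MFEPPath:
    """Relax a string between two CV-space endpoints on a 2D FES.

    ``step_size`` multiplies the interpolated downhill gradient (in grid
    units of energy per CV unit); convergence is declared when the
    maximum node displacement in one iteration drops below ``tol``.
    Endpoints stay fixed; nodes leaving the grid are clamped.
    """
    if fes.grid.ndim != 2:
        raise ValueError("string_minimize requires a 2D FES")
    a = np.asarray(endpoint_a, float)
    b = np.asarray(endpoint_b, float)
    centers = fes.grid.centers()
    for p in (a, b):
        for k in range(2):
            if not (centers[k][0] <= p[k] <= centers[k][-1]):
                raise ValueError(f"endpoint {p} lies outside the FES grid")
    fill = np.nanmax(fes.free_energy[np.isfinite(fes.free_energy)]) + 50.0
    interp, gix, giy = _interpolators(fes, fill)
    nodes = _initial_path(fes, a, b, n_nodes)

    converged = False
    it = 0
    # cap per-iteration node moves at half a grid cell: keeps the descent
    # stable against the steep artificial wall filling unvisited cells
    move_cap = 0.5 * float(np.min(fes.grid.spacing()))
    for it in range(1, max_iter + 1):
        grad = np.column_stack([gix(nodes), giy(nodes)])
        move = step_size * grad[1:-1]
        norm = np.linalg.norm(move, axis=1, keepdims=True)
        move = move * np.minimum(1.0, move_cap / np.maximum(norm, 1e-300))
        new = nodes.copy()
        new[1:-1] = nodes[1:-1] - move
        new = _clamp(new, fes)
        new = _reparameterize(new)
        disp = np.max(np.linalg.norm(new - nodes, axis=1))
        nodes = new
        if disp < tol:
            converged = True
            break
    energies = np.asarray(interp(nodes), float)
    return MFEPPath(nodes=nodes, energies=energies, converged=converged,
                    n_iterations=it)


def path_energy_profile(fes: FESGrid, path) -> np.ndarray:
    """(arclength, energy) pairs along a path on the FES.

    Energies are bilinear interpolations of the FES; a node falling in a
    missing (NaN) cell raises an error naming the node.
    """
    nodes = path.nodes if isinstance(path, MFEPPath) else np.asarray(path, float)
    centers = fes.grid.centers()
    f = fes.free_energy

    def cell_of(p):
        return tuple(int(np.clip(np.round((p[k] - c[0]) / (c[1] - c[0])),
                                 0, len(c) - 1))
                     for k, c in enumerate(centers))

    for i, p in enumerate(nodes):
        if not np.isfinite(f[cell_of(p)]):
            raise ValueError(f"path node {i} at {tuple(p)} lies in a missing cell")
    interp = RegularGridInterpolator(centers, np.nan_to_num(f, nan=0.0),
                                     bounds_error=False, fill_value=None)
    energies = np.asarray(interp(nodes), float)
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    arclength = np.concatenate([[0.0], np.cumsum(seg)])
    return np.column_stack([arclength, energies])
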