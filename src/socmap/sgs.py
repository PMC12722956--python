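"""Sequential Gaussian simulation of conditional field realizations.

Each realization visits the grid nodes along an independent random path.
At every node a simple-kriging system (mean 0 in normal-score space) is
solved over a moving neighborhood of conditioning data plus previously
simulated nodes, and a Gaussian value is drawn from the local kriging
distribution. The full normal-score grid is back-transformed through the
data's normal-score map with linear tail extrapolation.

Simple kriging (not OK) is used inside the simulation because SGS requires
the globally stationary mean for the sequential decomposition to reproduce
the target covariance; ordinary kriging is reserved for prediction maps.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import FieldGrid, GridSpec
from .kriging import Neighborhood
from .nscore import NormalScoreTransform
from .variogram import VariogramModel


@dataclasses.dataclass
class SimulationEnsemble:
    """Stack of equiprobable grid realizations with per-pixel statistics."""

    realizations: np.ndarray  # (n_real, ny, nx)
    spec: GridSpec

    def __post_init__(self):
        self.realizations = np.asarray(self.realizations, dtype=float)
        if self.realizations.ndim != 3:
            raise ValueError("realization stack must be (n_real, ny, nx)")
        if self.realizations.shape[1:] != self.spec.shape:
            raise ValueError("realization shape does not match grid spec")

    @property
    def n_real(self) -> int:
        return self.realizations.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.realizations.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.realizations.std(axis=0, ddof=1) if self.n_real > 1 \
            else np.zeros(self.spec.shape)

    @property
    def cv(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.sd / self.mean

    def mean_grid(self) -> FieldGrid:
        return FieldGrid(self.spec, self.mean)

    def sd_grid(self) -> FieldGrid:
        return FieldGrid(self.spec, self.sd)


def _sk_weights(C, c0):
    return np.linalg.solve(C, c0)


def sequential_gaussian_simulation(
        coords, values, vg: VariogramModel, grid: GridSpec,
        n_real: int, seed: int,
        neighborhood: Neighborhood | None = None,
        nscore: NormalScoreTransform | None = None) -> SimulationEnsemble:
    """Simulate ``n_real`` conditional realizations on ``grid``.

    Parameters
    ----------
    coords, values : conditioning data (data units)
    vg : variogram model **in normal-score space** (unit sill expected)
    nscore : optional pre-fitted normal-score map; fitted from ``values``
        when omitted
    seed : master seed; realization r uses ``SeedSequence([seed, r])``

    Grid nodes coincident with a conditioning point take its (normal-score)
    value exactly; two conditioning points on one node is an error.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if n_real < 1:
        raise ValueError("n_real must be >= 1")
    nb = neighborhood or Neighborhood()
    ns = nscore or NormalScoreTransform.fit(values)
    z_data = ns.forward(values)

    targets = grid.cell_centers_flat()
    n_nodes = len(targets)
    tol = 1e-9 * max(grid.dx, grid.dy)

    # map conditioning data onto coincident grid nodes
    node_of_datum = np.full(len(coords), -1)
    cell_value = {}
    for i, (x, y) in enumerate(coords):
        col = round((x - grid.x0) / grid.dx)
        row_from_s = round((y - grid.y0) / grid.dy)
        if 0 <= col < grid.nx and 0 <= row_from_s < grid.ny:
            node = (grid.ny - 1 - row_from_s) * grid.nx + col
            if (abs(targets[node, 0] - x) < tol
                    and abs(targets[node, 1] - y) < tol):
                if node in cell_value:
                    raise ValueError(
                        f"two conditioning data fall on grid node {node}")
                cell_value[node] = z_data[i]
                node_of_datum[i] = node

    sill = vg.sill
    exact = vg.nugget == 0.0
    free_nodes = np.array([i for i in range(n_nodes) if i not in cell_value])

    fixed_nodes = np.array(sorted(cell_value), dtype=int)
    # data coincident with a grid node enter via that node, not twice
    loose = node_of_datum < 0
    coords_l, z_l = coords[loose], z_data[loose]
    n_base = len(coords_l) + len(fixed_nodes)
    cap = n_base + len(free_nodes)

    stack = np.empty((n_real, n_nodes))
    for r in range(n_real):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), r]))
        path = rng.permutation(free_nodes)
        # conditioned points so far: data, then data-coincident nodes,
        # then simulated nodes in path order
        xy = np.empty((cap, 2))
        zz = np.empty(cap)
        xy[: len(coords_l)] = coords_l
        zz[: len(coords_l)] = z_l
        if len(fixed_nodes):
            xy[len(coords_l): n_base] = targets[fixed_nodes]
            zz[len(coords_l): n_base] = [cell_value[n] for n in fixed_nodes]
        m = n_base
        field = np.full(n_nodes, np.nan)
        for node in fixed_nodes:
            field[node] = cell_value[node]
        radius = nb.radius_factor * vg.range_
        for node in path:
            t = targets[node]
            d2 = (xy[:m, 0] - t[0]) ** 2 + (xy[:m, 1] - t[1]) ** 2
            k = min(nb.max_points, m)
            near = np.argpartition(d2, k - 1)[:k] if k < m else np.arange(m)
            dist = np.sqrt(d2[near])
            inside = dist <= radius
            if inside.sum() < nb.min_points:
                keep = np.argsort(dist)[: min(nb.min_points, len(dist))]
            else:
                keep = np.flatnonzero(inside)
            hood = near[keep]
            hx = xy[hood]
            hz = zz[hood]
            d0 = np.sqrt((hx[:, 0] - t[0]) ** 2 + (hx[:, 1] - t[1]) ** 2)
            if exact and len(d0) and d0.min() < tol:
                mean_, var_ = float(hz[np.argmin(d0)]), 0.0
            else:
                c0 = vg.covariance(d0)
                dd = np.sqrt((hx[:, 0, None] - hx[None, :, 0]) ** 2
                             + (hx[:, 1, None] - hx[None, :, 1]) ** 2)
                C = vg.covariance(dd)
                try:
                    w = _sk_weights(C, c0)
                except np.linalg.LinAlgError:
                    w = np.linalg.lstsq(C, c0, rcond=None)[0]
                mean_ = float(w @ hz)
                var_ = float(max(sill - w @ c0, 0.0))
            zsim = mean_ + np.sqrt(var_) * rng.standard_normal()
            field[node] = zsim
            xy[m] = t
            zz[m] = zsim
            m += 1
        stack[r] = field
    back = ns.inverse(stack.ravel()).reshape(n_real, grid.ny, grid.nx)
    return SimulationEnsemble(back, grid)
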