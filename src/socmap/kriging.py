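"""Ordinary and simple kriging with a moving neighborhood.

Ordinary kriging solves, per target location, the augmented system

    [ C   1 ] [ w ]   [ c0 ]
    [ 1^T 0 ] [ mu] = [ 1  ]

where C is the covariance matrix among the neighborhood data, c0 the
covariance between data and target, and mu the Lagrange multiplier that
enforces sum(w) = 1. The kriging variance is sill - w.c0 - mu.

The default moving neighborhood takes the nearest 16 points within
1.5 x range; if fewer than 4 fall inside the radius the nearest 4 are used
regardless of distance.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import FieldGrid, GridSpec
from .variogram import VariogramModel


@dataclasses.dataclass(frozen=True)
class Neighborhood:
    max_points: int = 16
    min_points: int = 4
    radius_factor: float = 1.5  # search radius = factor * variogram range


@dataclasses.dataclass
class KrigingResult:
    prediction: FieldGrid
    variance: FieldGrid
    loo_table: pd.DataFrame | None = None

    @property
    def loo_rmse(self) -> float:
        if self.loo_table is None:
            raise ValueError("LOO table not computed")
        return float(np.sqrt(np.mean(self.loo_table["error"] ** 2)))


def _check_duplicates(coords):
    coords = np.asarray(coords, float)
    _, idx, counts = np.unique(coords.round(9), axis=0,
                               return_index=True, return_counts=True)
    if (counts > 1).any():
        where = idx[counts > 1][0]
        raise ValueError(
            f"duplicate sample locations (e.g. point index {int(where)}); "
            "the kriging matrix would be singular"
        )


def _neighbors(tree: cKDTree, coords, targets, vg: VariogramModel,
               nb: Neighborhood):
    """Per target: indices of neighborhood points (variable length)."""
    radius = nb.radius_factor * vg.range_
    k = min(nb.max_points, tree.n)
    dist, idx = tree.query(targets, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    out = []
    for d_row, i_row in zip(dist, idx):
        inside = i_row[d_row <= radius]
        if len(inside) < nb.min_points:  # expand: nearest min_points overall
            inside = i_row[: min(nb.min_points, len(i_row))]
        out.append(inside)
    return out


def _ok_solve_one(coords, values, target, vg: VariogramModel):
    """OK weights/prediction/variance for one target from given data."""
    n = len(values)
    d = np.linalg.norm(coords - target, axis=1)
    c0 = vg.covariance(d)
    dd = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    C = vg.covariance(dd)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = C
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    A[n, n] = 0.0
    b = np.append(c0, 1.0)
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular kriging matrix at target {target}") from exc
    w, mu = sol[:n], sol[n]
    pred = float(w @ values)
    var = float(max(vg.sill - w @ c0 - mu, 0.0))
    return w, pred, var


def ordinary_kriging(coords, values, vg: VariogramModel, grid: GridSpec,
                     neighborhood: Neighborhood | None = None,
                     compute_loo: bool = False) -> KrigingResult:
    """Ordinary-kriging prediction and variance surfaces on a grid."""
    coords = np.asarray(coords, float)
    values = np.asarray(values, float)
    if len(values) < 2:
        raise ValueError("need at least two samples for kriging")
    _check_duplicates(coords)
    nb = neighborhood or Neighborhood()
    tree = cKDTree(coords)
    targets = grid.cell_centers_flat()
    hoods = _neighbors(tree, coords, targets, vg, nb)
    pred = np.empty(len(targets))
    var = np.empty(len(targets))
    for i, (target, hood) in enumerate(zip(targets, hoods)):
        _, pred[i], var[i] = _ok_solve_one(coords[hood], values[hood],
                                           target, vg)
    result = KrigingResult(
        FieldGrid(grid, pred.reshape(grid.shape)),
        FieldGrid(grid, var.reshape(grid.shape)),
    )
    if compute_loo:
        result.loo_table = loo_cv(coords, values, vg, nb)
    return result


def loo_cv(coords, values, vg: VariogramModel,
           neighborhood: Neighborhood | None = None) -> pd.DataFrame:
    """Leave-one-out ordinary-kriging cross-validation table."""
    coords = np.asarray(coords, float)
    values = np.asarray(values, float)
    _check_duplicates(coords)
    nb = neighborhood or Neighborhood()
    tree = cKDTree(coords)
    radius = nb.radius_factor * vg.range_
    k = min(nb.max_points + 1, len(values))
    dist, idx = tree.query(coords, k=k)
    preds = np.empty(len(values))
    for i in range(len(values)):
        others = idx[i][idx[i] != i]
        d_others = dist[i][idx[i] != i]
        hood = others[d_others <= radius]
        if len(hood) < nb.min_points:
            hood = others[: min(nb.min_points, len(others))]
        _, preds[i], _ = _ok_solve_one(coords[hood], values[hood],
                                       coords[i], vg)
    return pd.DataFrame({"observed": values, "predicted": preds,
                         "error": preds - values})


def simple_kriging(coords, values, target, vg: VariogramModel,
                   mean: float = 0.0):
    """Simple-kriging mean and variance at one target (known mean).

    Used by sequential Gaussian simulation in normal-score space, where the
    stationary mean is 0 by construction.
    """
    n = len(values)
    if n == 0:
        return mean, vg.sill
    d = np.linalg.norm(coords - target, axis=1)
    c0 = vg.covariance(d)
    dd = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    C = vg.covariance(dd)
    try:
        w = np.linalg.solve(C, c0)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular SK matrix at target {target}") from exc
    est = mean + w @ (values - mean)
    var = max(vg.sill - w @ c0, 0.0)
    return float(est), float(var)
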