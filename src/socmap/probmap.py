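"""Paired-ensemble difference maps and interval-probability surfaces.

Two SGS ensembles on co-registered grids are differenced realization-by-
realization (same realization index), giving an ensemble of difference
maps. Per pixel, the probability of each interval of a partition of the
real line is the fraction of difference realizations falling inside it;
intervals are left-closed half-open [a, b), with open-ended extremes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import statsmodels.api as sm

from .io import FieldGrid
from .sgs import SimulationEnsemble

#: default interval edge sets for the two regional viewpoints
JIAODONG_EDGES = (-20.0, -10.0, -6.0, 0.0)
SOUTHWEST_EDGES = (-6.0, 0.0, 6.0, 10.0, 20.0)


@dataclasses.dataclass
class DeltaProbabilityMap:
    edges: np.ndarray          # strictly increasing interior edges
    probabilities: np.ndarray  # (n_intervals, ny, nx)

    @property
    def n_intervals(self) -> int:
        return len(self.edges) + 1

    def interval_labels(self) -> list[str]:
        e = self.edges
        labels = [f"(-inf, {e[0]:g})"]
        labels += [f"[{a:g}, {b:g})" for a, b in zip(e[:-1], e[1:])]
        labels.append(f"[{e[-1]:g}, inf)")
        return labels


@dataclasses.dataclass
class MeanSdFit:
    slope: float
    intercept: float
    adj_r2: float
    p_value: float
    n_pixels: int

    def summary(self) -> str:
        return (
            "Ensemble mean-SD regression\n"
            f"  SD = {self.intercept:.4g} + {self.slope:.4g} * mean\n"
            f"  adj R2 = {self.adj_r2:.3f}, p = {self.p_value:.3g}, "
            f"n = {self.n_pixels}"
        )


def delta_ensemble(ens_a: SimulationEnsemble, ens_b: SimulationEnsemble,
                   align: str = "index") -> SimulationEnsemble:
    """Difference ensemble B - A, pairing realizations by index.

    ``align`` controls how pixels of the two (equally sized) grids are
    paired: ``'index'`` (default) differences co-registered pixels;
    ``'rank'`` permutes B's pixels so that pixels of equal ensemble-mean
    rank are paired — a distributional comparison for grids that are not
    geographically co-registered.
    """
    if ens_a.n_real != ens_b.n_real:
        raise ValueError(
            f"ensembles have {ens_a.n_real} vs {ens_b.n_real} realizations")
    if ens_a.spec.shape != ens_b.spec.shape:
        raise ValueError("ensembles live on grids of different dimensions")
    b = ens_b.realizations
    if align == "rank":
        n = ens_a.spec.n_cells
        order_a = np.argsort(ens_a.mean.ravel(), kind="stable")
        order_b = np.argsort(ens_b.mean.ravel(), kind="stable")
        perm = np.empty(n, dtype=int)
        perm[order_a] = order_b
        b = b.reshape(ens_b.n_real, n)[:, perm].reshape(b.shape)
    elif align != "index":
        raise ValueError("align must be 'index' or 'rank'")
    return SimulationEnsemble(b - ens_a.realizations, ens_a.spec)


def interval_probability(delta: SimulationEnsemble,
                         edges) -> DeltaProbabilityMap:
    """Per-pixel probabilities over the partition defined by ``edges``.

    A value exactly on an edge counts in the upper interval.
    """
    edges = np.atleast_1d(np.asarray(edges, dtype=float))
    if len(edges) < 1 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    reals = delta.realizations
    # bin index per value: 0 -> (-inf, e1), k -> [e_k, e_{k+1}), ...
    idx = np.searchsorted(edges, reals, side="right")
    n_int = len(edges) + 1
    probs = np.empty((n_int, *delta.spec.shape))
    for k in range(n_int):
        probs[k] = (idx == k).mean(axis=0)
    return DeltaProbabilityMap(edges, probs)


def mean_sd_regression(ens: SimulationEnsemble):
    """OLS of per-pixel ensemble SD on per-pixel mean, plus the CV map."""
    mean = ens.mean.ravel()
    sd = ens.sd.ravel()
    if len(mean) < 3:
        raise ValueError("need >= 3 pixels")
    if np.ptp(mean) == 0:
        raise ValueError("per-pixel means are constant; regression undefined")
    model = sm.OLS(sd, sm.add_constant(mean)).fit()
    fit = MeanSdFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        adj_r2=float(model.rsquared_adj),
        p_value=float(model.pvalues[1]),
        n_pixels=len(mean),
    )
    cv_map = FieldGrid(ens.spec, ens.cv)
    return fit, cv_map
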