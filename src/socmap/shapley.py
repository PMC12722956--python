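"""Exact interventional Shapley values and pairwise interaction values.

For each explained row x, the value of a feature coalition S is

    v(S) = mean over background rows b of f(x_S, b_{not S}),

i.e. features outside S are marginalised against a background sample.
With p features all 2^p coalition values are evaluated in one batched
model call, and

    phi_i      = sum_{S not containing i} w(|S|)   [v(S+i) - v(S)],
                 w(s) = s! (p-s-1)! / p!
    Phi_{ij}   = sum_{S w/o i,j}        u(|S|)     [v(S+ij) - v(S+i)
                                                    - v(S+j) + v(S)],
                 u(s) = s! (p-s-2)! / (2 (p-1)!)        (i != j)
    Phi_{ii}   = phi_i - sum_{j != i} Phi_{ij}

so the interaction matrix is symmetric, its rows sum to phi, and
base + sum_i phi_i reproduces f(x) exactly (the sum telescopes to
v(full) - v(empty)). Cost is O(2^p) model rows per (sample, background)
pair, practical for the low-dimensional predictor sets used here (a guard
rejects p > 14).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np


@dataclasses.dataclass
class ShapDecomposition:
    base_value: float
    values: np.ndarray               # (n_samples, p) contributions phi
    interactions: np.ndarray | None  # (n_samples, p, p) or None
    feature_names: list[str]
    X: np.ndarray                    # the explained rows

    def dependence(self, feature: str):
        """(x, phi) pairs for one feature, for SHAP dependence plots."""
        j = self.feature_names.index(feature)
        return self.X[:, j], self.values[:, j]


def _coalition_masks(p: int) -> np.ndarray:
    codes = np.arange(2 ** p, dtype=np.uint32)
    return (codes[:, None] >> np.arange(p)[None, :]) & 1  # (2^p, p) in {0,1}


def shapley_values(predict, X, background, interactions: bool = False,
                   batch_rows: int = 200_000) -> ShapDecomposition:
    """Exact interventional Shapley decomposition of ``predict`` on ``X``.

    Parameters
    ----------
    predict : callable mapping (n, p) arrays to (n,) predictions
    X : rows to explain
    background : background rows for marginalisation
    interactions : also compute the pairwise interaction matrices
    """
    X = np.asarray(X, dtype=float)
    B = np.asarray(background, dtype=float)
    n, p = X.shape
    if p > 14:
        raise ValueError(f"exact Shapley enumeration limited to p <= 14 "
                         f"(got {p})")
    nb = len(B)
    masks = _coalition_masks(p).astype(bool)          # (2^p, p)
    n_coal = len(masks)

    # v[s, k] = coalition value of mask k for sample s
    v = np.empty((n, n_coal))
    rows_per_sample = n_coal * nb
    chunk = max(1, batch_rows // rows_per_sample)
    tile_B = np.tile(B, (n_coal, 1))                  # (n_coal*nb, p)
    mask_rep = np.repeat(masks, nb, axis=0)           # (n_coal*nb, p)
    for start in range(0, n, chunk):
        xs = X[start:start + chunk]
        m = len(xs)
        data = np.where(mask_rep[None, :, :], xs[:, None, :],
                        tile_B[None, :, :]).reshape(m * n_coal * nb, p)
        preds = np.asarray(predict(data), dtype=float)
        v[start:start + m] = preds.reshape(m, n_coal, nb).mean(axis=2)

    sizes = masks.sum(axis=1)
    base_per_sample = v[:, 0]  # v(empty): identical for every sample
    fw = np.array([math.factorial(s) * math.factorial(p - s - 1)
                   / math.factorial(p) for s in range(p)])

    phi = np.zeros((n, p))
    codes = np.arange(n_coal, dtype=np.uint32)
    for i in range(p):
        bit = np.uint32(1 << i)
        without = (codes & bit) == 0
        s = sizes[without]
        w = fw[s]
        idx_wo = codes[without]
        idx_wi = idx_wo | bit
        phi[:, i] = ((v[:, idx_wi] - v[:, idx_wo]) * w[None, :]).sum(axis=1)

    inter = None
    if interactions:
        uw = np.array([math.factorial(s) * math.factorial(max(p - s - 2, 0))
                       / (2.0 * math.factorial(p - 1)) for s in range(p)])
        inter = np.zeros((n, p, p))
        for i in range(p):
            for j in range(i + 1, p):
                bi, bj = np.uint32(1 << i), np.uint32(1 << j)
                wo = (codes & bi) == 0
                wo &= (codes & bj) == 0
                idx = codes[wo]
                s = sizes[wo]
                w = uw[s]
                delta = (v[:, idx | bi | bj] - v[:, idx | bi]
                         - v[:, idx | bj] + v[:, idx])
                val = (delta * w[None, :]).sum(axis=1)
                inter[:, i, j] = val
                inter[:, j, i] = val
        for i in range(p):
            off_diag = inter[:, i, :].sum(axis=1) - inter[:, i, i]
            inter[:, i, i] = phi[:, i] - off_diag

    return ShapDecomposition(
        base_value=float(base_per_sample.mean()),
        values=phi,
        interactions=inter,
        feature_names=[f"x{i}" for i in range(p)],
        X=X,
    )
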