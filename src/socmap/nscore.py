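"""Normal-score transform and its back-transform.

Data values are ranked and mapped to standard-normal quantiles through the
plotting positions (r - 0.5)/n. The inverse interpolates monotonically
between the data quantiles and extrapolates linearly into configurable
tails (default [min - 0.5 IQR, max + 0.5 IQR]), which bounds back-
transformed simulation values.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import norm


@dataclasses.dataclass
class NormalScoreTransform:
    values: np.ndarray   # sorted original values (deduplicated)
    scores: np.ndarray   # matching standard-normal scores
    lower: float         # tail extrapolation bound (data units)
    upper: float

    @classmethod
    def fit(cls, data, tail_iqr_factor: float = 0.5,
            bounds: tuple[float, float] | None = None) -> "NormalScoreTransform":
        data = np.asarray(data, dtype=float)
        if len(data) < 2 or np.ptp(data) == 0:
            raise ValueError("need >= 2 distinct values for normal scores")
        order = np.argsort(data, kind="stable")
        ranks = np.empty(len(data))
        ranks[order] = np.arange(1, len(data) + 1)
        # average ranks for ties so the map stays strictly monotone
        uniq, inv = np.unique(data, return_inverse=True)
        mean_rank = np.zeros(len(uniq))
        np.add.at(mean_rank, inv, ranks)
        mean_rank /= np.bincount(inv)
        scores = norm.ppf((mean_rank - 0.5) / len(data))
        if bounds is None:
            q1, q3 = np.percentile(data, [25, 75])
            iqr = q3 - q1
            bounds = (float(data.min() - tail_iqr_factor * iqr),
                      float(data.max() + tail_iqr_factor * iqr))
        return cls(uniq, scores, bounds[0], bounds[1])

    def forward(self, data) -> np.ndarray:
        """Map data values to normal scores (monotone interpolation)."""
        data = np.asarray(data, dtype=float)
        return np.interp(data, self.values, self.scores)

    def inverse(self, scores) -> np.ndarray:
        """Map normal scores back to data units with linear tail extrapolation."""
        scores = np.asarray(scores, dtype=float)
        out = np.interp(scores, self.scores, self.values)
        # linear extrapolation from the last data quantile to the tail bound,
        # reaching it at +-3.5 sigma; clipped to the bound beyond that
        lo_s, hi_s = self.scores[0], self.scores[-1]
        lo_v, hi_v = self.values[0], self.values[-1]
        smax = 3.5
        below = scores < lo_s
        if below.any():
            frac = np.clip((lo_s - scores[below]) / (smax + lo_s), 0.0, 1.0)
            out[below] = lo_v - frac * (lo_v - self.lower)
        above = scores > hi_s
        if above.any():
            frac = np.clip((scores[above] - hi_s) / (smax - hi_s), 0.0, 1.0)
            out[above] = hi_v + frac * (self.upper - hi_v)
        return out


def normal_score(data, **kwargs):
    """Fit the transform and return (transform, transformed values)."""
    ns = NormalScoreTransform.fit(data, **kwargs)
    return ns, ns.forward(np.asarray(data, dtype=float))


def inverse_normal_score(ns: NormalScoreTransform, scores):
    return ns.inverse(scores)
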