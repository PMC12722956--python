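"""Two-stage threshold identification and dual-threshold interaction domains.

Stage 1 locates candidate breakpoints on a predictor from the model's
marginal behaviour: local extrema and curvature changes of the (LOESS-
smoothed) partial-dependence curve, and sign shifts of the smoothed SHAP
dependence. Stage 2 tests the candidates by continuous piecewise-linear
(segmented) least squares, searching each breakpoint on a fine grid inside
a window around its candidate; a segmented fit is accepted when it
improves adjusted R^2 over the straight-line fit by at least 0.01.

The reported *primary* threshold distinguishes the two response shapes the
procedure encounters:

* a narrow steep middle segment (< 15% of the x-range) is a smoothed
  *step*, whose scientifically meaningful location is the knot midpoint;
* otherwise the fit is a *ramp/saturation* shape and the knot with the
  larger |slope change| (ties -> the lower knot, the onset) is reported.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .ml import PDPCurve, partial_dependence, shap_decomposition
from .shapley import ShapDecomposition


def loess_smooth(x, y, span: float = 0.3) -> np.ndarray:
    """LOESS (local linear, tricube weights) smoothing of y over x.

    Deterministic; returns smoothed values aligned with the input order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("need >= 5 points for LOESS")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if span * len(x) < 2:
        raise ValueError(f"span {span} covers fewer than 2 of {len(x)} points")
    out = lowess(y, x, frac=span, it=0, return_sorted=False)
    return np.asarray(out, dtype=float)


@dataclasses.dataclass
class CandidateSet:
    predictor: str
    breakpoints: np.ndarray
    provenance: list[str]  # 'pdp-extremum' | 'pdp-curvature' | 'shap-sign-shift'

    def __len__(self) -> int:
        return len(self.breakpoints)


def candidate_breakpoints(pdp: PDPCurve, shap_dependence=None,
                          span: float = 0.15,
                          curvature_mads: float = 3.0) -> CandidateSet:
    """Stage-1 candidate breakpoints for one predictor.

    Candidates, merged within one grid step:
      (i)  local extrema of the LOESS-smoothed PDP,
      (ii) curvature changes: local maxima of |second difference| exceeding
           ``curvature_mads`` x MAD of all second differences (with an
           absolute floor of 1e-3 of the PDP's range, so a straight or flat
           curve yields nothing),
      (iii) zero crossings of the LOESS-smoothed SHAP dependence.
    A flat PDP returns an empty set.
    """
    g, r = pdp.grid, pdp.response
    if len(g) < 10:
        raise ValueError("PDP needs >= 10 grid points")
    rng_y = float(np.ptp(r))
    cands: list[float] = []
    prov: list[str] = []
    if rng_y > 0:
        sm = loess_smooth(g, r, span=span)
        d1 = np.diff(sm)
        sign = np.sign(d1)
        for i in range(1, len(sign)):
            if sign[i] != 0 and sign[i - 1] != 0 and sign[i] != sign[i - 1]:
                cands.append(float(g[i]))
                prov.append("pdp-extremum")
        d2 = np.abs(np.diff(sm, 2))
        mad = float(np.median(np.abs(d2 - np.median(d2))))
        thresh = max(curvature_mads * mad, 1e-3 * rng_y)
        hot = d2 > thresh
        # per contiguous run of curvature exceedances: the |curvature| peak
        # (a kink/shoulder) plus the steepest point inside the run (the
        # inflection centre of a smoothed step)
        slopes = np.abs(d1)
        i = 0
        while i < len(hot):
            if hot[i]:
                j = i
                while j + 1 < len(hot) and hot[j + 1]:
                    j += 1
                k = i + int(np.argmax(d2[i:j + 1]))
                cands.append(float(g[k + 1]))
                prov.append("pdp-curvature")
                m = i + int(np.argmax(slopes[i:j + 2]))
                cands.append(float(0.5 * (g[m] + g[m + 1])))
                prov.append("pdp-curvature")
                i = j + 1
            else:
                i += 1
    if shap_dependence is not None:
        xs, phi = shap_dependence
        xs = np.asarray(xs, dtype=float)
        phi = np.asarray(phi, dtype=float)
        order = np.argsort(xs)
        xs, phi = xs[order], phi[order]
        if len(xs) >= 5 and np.ptp(phi) > 0:
            sm_phi = loess_smooth(xs, phi, span=0.3)
            s = np.sign(sm_phi)
            for i in range(1, len(s)):
                if s[i] != 0 and s[i - 1] != 0 and s[i] != s[i - 1]:
                    # linear interpolation to the crossing
                    x0, x1 = xs[i - 1], xs[i]
                    y0, y1 = sm_phi[i - 1], sm_phi[i]
                    xc = x0 - y0 * (x1 - x0) / (y1 - y0) if y1 != y0 else x0
                    if g[0] <= xc <= g[-1]:
                        cands.append(float(xc))
                        prov.append("shap-sign-shift")
    if not cands:
        return CandidateSet(pdp.predictor, np.empty(0), [])
    step = float(np.median(np.diff(g)))
    order = np.argsort(cands)
    merged, mprov = [], []
    for k in order:
        if merged and abs(cands[k] - merged[-1]) <= step:
            continue
        merged.append(cands[k])
        mprov.append(prov[k])
    return CandidateSet(pdp.predictor, np.asarray(merged), mprov)


# -- segmented (breakpoint) regression ------------------------------------

def _hinge_design(x, knots):
    cols = [np.ones_like(x), x]
    for b in knots:
        cols.append(np.maximum(x - b, 0.0))
    return np.column_stack(cols)


def _fit_rss(x, y, knots):
    A = _hinge_design(x, knots)
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(resid @ resid), coef


def _adj_r2(rss, tss, n, p):
    if n - p - 1 <= 0 or tss == 0:
        return float("nan")
    return 1.0 - (rss / tss) * (n - 1) / (n - p - 1)


@dataclasses.dataclass
class SegmentedFitResults:
    """Continuous piecewise-linear fit with data-driven knots."""

    predictor: str
    breakpoints: np.ndarray       # selected knots (possibly empty)
    coef: np.ndarray              # intercept, slope, hinge coefficients
    segment_slopes: np.ndarray    # slope within each segment
    rss_segmented: float
    rss_unsegmented: float
    adj_r2_gain: float
    accepted: bool
    x_range: tuple[float, float]
    x_fit: np.ndarray = None  # the x data the segments were fitted to

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return _hinge_design(x, self.breakpoints) @ self.coef

    @property
    def knot_levels(self) -> np.ndarray:
        return self.predict(self.breakpoints)

    def step_size(self, x=None) -> float | None:
        """Plateau-to-plateau response change across a 2-knot rise/drop.

        Each plateau level is the fit evaluated at the median of that outer
        segment's data, which is robust against knots that sit slightly
        inside the rise and would otherwise clip the measured step.
        """
        if len(self.breakpoints) != 2:
            return None
        x = self.x_fit if x is None else np.asarray(x, dtype=float)
        b1, b2 = self.breakpoints
        seg1, seg3 = x[x < b1], x[x >= b2]
        x_lo = float(np.median(seg1)) if len(seg1) else float(b1)
        x_hi = float(np.median(seg3)) if len(seg3) else float(b2)
        lo, hi = self.predict([x_lo, x_hi])
        return float(hi - lo)

    @property
    def primary_threshold(self) -> float | None:
        """The single threshold this fit reports (see module docstring)."""
        if not self.accepted or len(self.breakpoints) == 0:
            return None
        if len(self.breakpoints) == 1:
            return float(self.breakpoints[0])
        b1, b2 = self.breakpoints
        span = self.x_range[1] - self.x_range[0]
        s1, s2, s3 = self.segment_slopes
        if abs(s2) > max(abs(s1), abs(s3)):
            # plateau-(rise|drop)-plateau: a narrow middle segment is a
            # smoothed step (report its centre); a wide one is a ramp whose
            # threshold is the onset knot
            if (b2 - b1) < 0.15 * span:
                return float(0.5 * (b1 + b2))
            return float(b1)
        d1 = abs(s2 - s1)
        d2 = abs(s3 - s2)
        return float(b1 if d1 >= d2 else b2)

    def summary(self) -> str:
        bp = ", ".join(f"{b:.4g}" for b in self.breakpoints) or "none"
        return (
            f"Segmented regression for '{self.predictor}'\n"
            f"  breakpoints : {bp}\n"
            f"  primary     : {self.primary_threshold}\n"
            f"  slopes      : "
            + ", ".join(f"{s:.4g}" for s in self.segment_slopes) + "\n"
            f"  RSS         : {self.rss_segmented:.4g} "
            f"(line: {self.rss_unsegmented:.4g})\n"
            f"  adj-R2 gain : {self.adj_r2_gain:.4g}  "
            f"accepted: {self.accepted}"
        )


class SegmentedRegression:
    """Least-squares continuous piecewise-linear model with 0-2 knots.

    Knots are searched on a fine grid (x-range/``grid_resolution``) inside
    windows of half-width ``window_frac`` x x-range around each candidate.
    A knot (or a second knot) is kept only when it raises adjusted R^2 by
    ``accept_gain`` over the simpler fit.
    """

    def __init__(self, x, y, candidates=None, max_breaks: int = 2,
                 window_frac: float = 0.10, grid_resolution: int = 200,
                 accept_gain: float = 0.01):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if len(self.x) < 10:
            raise ValueError("need >= 10 points for segmented regression")
        if candidates is None or (hasattr(candidates, "__len__")
                                  and len(candidates) == 0):
            self.candidates = None
        elif isinstance(candidates, CandidateSet):
            self.candidates = np.asarray(candidates.breakpoints, dtype=float)
        else:
            self.candidates = np.asarray(candidates, dtype=float)
        self.max_breaks = max_breaks
        self.window_frac = window_frac
        self.grid_resolution = grid_resolution
        self.accept_gain = accept_gain

    def _windows(self):
        lo, hi = self.x.min(), self.x.max()
        span = hi - lo
        res = span / self.grid_resolution
        half = self.window_frac * span
        cands = self.candidates
        if cands is None:  # explicit max_breaks, no candidates: search all x
            cands = np.array([0.5 * (lo + hi)])
            half = 0.5 * span
        wins = []
        for c in cands:
            a = max(lo + res, c - half)
            b = min(hi - res, c + half)
            if a >= b:
                continue
            wins.append(np.arange(a, b + 0.5 * res, res))
        if not wins:
            raise ValueError("all candidate windows fall outside the data range")
        return wins

    def fit(self, predictor: str = "x") -> SegmentedFitResults:
        x, y = self.x, self.y
        n = len(x)
        tss = float(((y - y.mean()) ** 2).sum())
        rss0, coef0 = _fit_rss(x, y, [])
        adj0 = _adj_r2(rss0, tss, n, 1)
        wins = self._windows()

        best1 = None  # (rss, knots, coef)
        for w in wins:
            for b in w:
                rss, coef = _fit_rss(x, y, [b])
                if best1 is None or rss < best1[0]:
                    best1 = (rss, np.array([b]), coef)
        adj1 = _adj_r2(best1[0], tss, n, 2)

        best2 = None
        if self.max_breaks >= 2 and len(wins) >= 2:
            # coarse pair search over distinct windows, then refine
            for i in range(len(wins)):
                for j in range(i + 1, len(wins)):
                    for b1 in wins[i][::4]:
                        for b2 in wins[j][::4]:
                            lo_b, hi_b = sorted((b1, b2))
                            if hi_b - lo_b < 1e-12:
                                continue
                            rss, coef = _fit_rss(x, y, [lo_b, hi_b])
                            if best2 is None or rss < best2[0]:
                                best2 = (rss, np.array([lo_b, hi_b]), coef)
            if best2 is not None:
                span = x.max() - x.min()
                res = span / self.grid_resolution
                b1c, b2c = best2[1]
                g1 = np.arange(b1c - 4 * res, b1c + 4 * res + 0.5 * res, res)
                g2 = np.arange(b2c - 4 * res, b2c + 4 * res + 0.5 * res, res)
                for b1 in g1:
                    for b2 in g2:
                        if b2 - b1 < res:
                            continue
                        rss, coef = _fit_rss(x, y, [b1, b2])
                        if rss < best2[0]:
                            best2 = (rss, np.array([b1, b2]), coef)
        adj2 = _adj_r2(best2[0], tss, n, 3) if best2 is not None else -np.inf

        # pick the knot count by adjusted R^2 (a one-knot continuous fit
        # cannot represent a level step, so the two-knot model must be able
        # to win on its own), then apply the acceptance gain vs the line
        if best2 is not None and adj2 > adj1:
            rss, knots, coef = best2
            gain = adj2 - adj0
        else:
            rss, knots, coef = best1
            gain = adj1 - adj0
        accepted = gain >= self.accept_gain
        slopes = np.cumsum(coef[1:])
        return SegmentedFitResults(
            predictor=predictor,
            breakpoints=knots,
            coef=coef,
            segment_slopes=slopes,
            rss_segmented=float(rss),
            rss_unsegmented=float(rss0),
            adj_r2_gain=float(gain),
            accepted=bool(accepted),
            x_range=(float(x.min()), float(x.max())),
            x_fit=x,
        )


def segmented_fit(x, y, candidates=None, max_breaks: int = 2,
                  **kwargs) -> SegmentedFitResults:
    """Functional wrapper over :class:`SegmentedRegression`."""
    return SegmentedRegression(x, y, candidates, max_breaks, **kwargs).fit()


# -- orchestration ---------------------------------------------------------

@dataclasses.dataclass
class ThresholdResult:
    predictor: str
    candidates: CandidateSet
    fit: SegmentedFitResults | None
    pdp: PDPCurve

    @property
    def accepted(self) -> bool:
        return self.fit is not None and self.fit.accepted

    @property
    def threshold(self) -> float | None:
        return self.fit.primary_threshold if self.fit is not None else None


def _oof_predictions(model, X, y, cv_folds, seed):
    from sklearn.base import clone
    from sklearn.model_selection import KFold, cross_val_predict
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    return cross_val_predict(clone(model), X, np.asarray(y, float), cv=cv)


def two_stage_thresholds(model, X, feature_names, predictor: str,
                         shap: ShapDecomposition | None = None,
                         mode: str = "partial", y=None, oof=None,
                         cv_folds: int = 10, seed: int = 0, n_grid: int = 50,
                         max_breaks: int = 2) -> ThresholdResult:
    """Run the full two-stage threshold procedure for one predictor.

    Stage 1: PDP + SHAP dependence -> candidate breakpoints.
    Stage 2: segmented regression on one of three targets built from
    10-fold cross-validated (out-of-fold) model predictions:

    * ``mode='partial'`` (default): per-sample partial residuals
      ``y - y_oof + PDP(x_j)``. Subtracting the out-of-fold prediction
      removes the other covariates' variance *and* the model's own
      (smoothed) rendering of this predictor; adding the PDP back restores
      the marginal effect, so the profile is unbiased for the predictor's
      true response shape with only residual-scale noise around it.
    * ``mode='oof'``: raw per-sample out-of-fold predictions.
    * ``mode='pdp'``: the quantile-spaced PDP curve itself (no ``y``
      needed; inherits the model's smoothing bias).

    ``oof`` may be supplied to reuse precomputed out-of-fold predictions.
    """
    X = np.asarray(X, dtype=float)
    pdp = partial_dependence(model, X, feature_names, predictor,
                             n_grid=n_grid)
    if shap is None:
        shap = shap_decomposition(model, X, feature_names,
                                  interactions=False, seed=seed)
    cands = candidate_breakpoints(pdp, shap.dependence(predictor))
    if len(cands) == 0:
        return ThresholdResult(predictor, cands, None, pdp)
    j = list(feature_names).index(predictor)
    if mode == "pdp":
        x2, y2 = pdp.grid, pdp.response
    elif mode in ("oof", "partial"):
        if y is None:
            raise ValueError(f"mode='{mode}' requires y")
        if oof is None:
            oof = _oof_predictions(model, X, y, cv_folds, seed)
        x2 = X[:, j]
        if mode == "oof":
            y2 = np.asarray(oof, dtype=float)
        else:
            y2 = (np.asarray(y, dtype=float) - np.asarray(oof, dtype=float)
                  + np.interp(x2, pdp.grid, pdp.response))
    else:
        raise ValueError("mode must be 'partial', 'oof' or 'pdp'")
    fit = SegmentedRegression(x2, y2, cands, max_breaks=max_breaks) \
        .fit(predictor=predictor)
    return ThresholdResult(predictor, cands, fit, pdp)


# -- dual-threshold interaction domains ------------------------------------

@dataclasses.dataclass
class InteractionDomain:
    pair: tuple[str, str]
    thresholds: tuple[float, float]
    quadrant_means: np.ndarray   # 2x2: [x1 side][x2 side], side 0 = below
    quadrant_counts: np.ndarray
    sign_pattern: dict[str, int]
    objective: float
    flagged: bool

    def summary(self) -> str:
        f1, f2 = self.pair
        t1, t2 = self.thresholds
        lines = [f"Dual-threshold domain ({f1}, {f2})",
                 f"  thresholds: {f1} = {t1:.4g}, {f2} = {t2:.4g}",
                 f"  objective (between-quadrant variance): {self.objective:.4g}"
                 + ("  [flagged]" if self.flagged else "")]
        for a, la in ((0, f"{f1}<t"), (1, f"{f1}>=t")):
            for b, lb in ((0, f"{f2}<t"), (1, f"{f2}>=t")):
                lines.append(f"  {la:>10} & {lb:<10}: mean interaction "
                             f"{self.quadrant_means[a, b]:+.4g} "
                             f"(n={int(self.quadrant_counts[a, b])})")
        return "\n".join(lines)


def dual_threshold_domain(shap: ShapDecomposition,
                          pair: tuple[str, str],
                          min_quadrant: int = 5) -> InteractionDomain:
    """Decile-grid search for the threshold pair maximising quadrant contrast.

    Candidate thresholds are the 1st-9th deciles of each feature; the
    objective is the count-weighted between-quadrant variance (the ANOVA
    between-group sum of squares / n) of the pair's SHAP interaction
    values, i.e. the interaction heterogeneity explained by the 2x2 split.
    Weighting by quadrant size keeps noisy few-sample quadrants from
    dominating. Degenerate optima (an empty quadrant, or a near-zero
    objective) are flagged, not fatal.
    """
    if shap.interactions is None:
        raise ValueError("ShapDecomposition lacks interaction values")
    f1, f2 = pair
    i = shap.feature_names.index(f1)
    j = shap.feature_names.index(f2)
    x1 = shap.X[:, i]
    x2 = shap.X[:, j]
    inter = shap.interactions[:, i, j]
    dec1 = np.quantile(x1, np.arange(1, 10) / 10.0)
    dec2 = np.quantile(x2, np.arange(1, 10) / 10.0)
    best = None
    for t1 in dec1:
        side1 = x1 >= t1
        for t2 in dec2:
            side2 = x2 >= t2
            means = np.empty((2, 2))
            counts = np.empty((2, 2))
            ok = True
            for a in (0, 1):
                for b in (0, 1):
                    m = (side1 == bool(a)) & (side2 == bool(b))
                    counts[a, b] = m.sum()
                    if counts[a, b] == 0:
                        ok = False
                        break
                    means[a, b] = inter[m].mean()
                if not ok:
                    break
            if not ok:
                continue
            grand = inter.mean()
            obj = float((counts * (means - grand) ** 2).sum() / counts.sum())
            if best is None or obj > best[0]:
                best = (obj, (float(t1), float(t2)), means.copy(),
                        counts.copy())
    if best is None:
        raise ValueError("no decile pair leaves all four quadrants populated")
    obj, ts, means, counts = best
    scale = float(np.mean(np.abs(inter))) or 1.0
    flagged = (counts < min_quadrant).any() or obj < (1e-4 * scale) ** 2
    pattern = {
        "low1_low2": int(np.sign(means[0, 0])),
        "low1_high2": int(np.sign(means[0, 1])),
        "high1_low2": int(np.sign(means[1, 0])),
        "high1_high2": int(np.sign(means[1, 1])),
    }
    return InteractionDomain(pair, ts, means, counts, pattern, obj, flagged)


def threshold_report(results: list[ThresholdResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "predictor": r.predictor,
            "accepted": r.accepted,
            "threshold": r.threshold,
            "breakpoints": list(r.fit.breakpoints) if r.fit is not None else [],
            "adj_r2_gain": r.fit.adj_r2_gain if r.fit is not None else 0.0,
        })
    return pd.DataFrame(rows)
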