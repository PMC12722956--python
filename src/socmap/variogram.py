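"""Semivariogram estimation and variogram-model fitting.

The empirical semivariogram uses the Matheron estimator

    gamma(h) = (1 / 2 N(h)) * sum_{|si-sj| in bin(h)} (z_i - z_j)^2

and parametric models (spherical, exponential, Gaussian) are fitted by
weighted least squares with Cressie weights N(h)/gamma_model(h)^2. The
winning family is selected by leave-one-out ordinary-kriging RMSE on the
samples, mirroring common digital-soil-mapping practice.

Exponential and Gaussian families use the *practical range* convention
(gamma reaches ~95% of the sill at h = a), so the fitted range parameter is
comparable across families.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist
from scipy.stats import boxcox, skew

FAMILIES = ("spherical", "exponential", "gaussian")


@dataclasses.dataclass(frozen=True)
class VariogramModel:
    """Isotropic variogram model: nugget + partial sill + range (km)."""

    family: str
    nugget: float
    psill: float
    range_: float

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unsupported variogram family '{self.family}'")
        if self.nugget < 0 or self.psill < 0 or self.range_ <= 0:
            raise ValueError("require nugget >= 0, psill >= 0, range > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.psill

    @property
    def nugget_fraction(self) -> float:
        return self.nugget / self.sill if self.sill > 0 else 0.0

    def gamma(self, h) -> np.ndarray:
        """Semivariance at lag h (same units as the data, squared)."""
        h = np.asarray(h, dtype=float)
        t = h / self.range_
        if self.family == "spherical":
            g = np.where(t < 1.0, 1.5 * t - 0.5 * t ** 3, 1.0)
        elif self.family == "exponential":
            g = 1.0 - np.exp(-3.0 * t)
        else:  # gaussian
            g = 1.0 - np.exp(-3.0 * t ** 2)
        out = self.nugget + self.psill * g
        return np.where(h > 0, out, 0.0)

    def covariance(self, h) -> np.ndarray:
        """Stationary covariance C(h) = sill - gamma(h); C(0) = sill."""
        h = np.asarray(h, dtype=float)
        return np.where(h > 0, self.sill - self.gamma(h), self.sill)


@dataclasses.dataclass
class EmpiricalVariogram:
    lags: np.ndarray          # bin centres (km)
    gamma: np.ndarray         # semivariance per bin
    counts: np.ndarray        # pair counts per bin
    max_lag: float

    def nonempty(self) -> "EmpiricalVariogram":
        m = self.counts > 0
        return EmpiricalVariogram(self.lags[m], self.gamma[m],
                                  self.counts[m], self.max_lag)


def empirical_semivariogram(coords, values, n_lags: int = 12,
                            max_lag: float | None = None) -> EmpiricalVariogram:
    """Matheron semivariogram on equal-width distance bins.

    ``max_lag`` defaults to half the maximum pairwise distance. Bins with no
    pairs are kept with count 0 and NaN semivariance.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two samples for a semivariogram")
    d = pdist(coords)
    sq = pdist(values[:, None], metric="sqeuclidean")
    if max_lag is None:
        max_lag = 0.5 * d.max()
    if max_lag <= 0:
        raise ValueError("max_lag must be positive")
    inside = d <= max_lag
    if not inside.any():
        raise ValueError("all point pairs lie beyond max_lag")
    edges = np.linspace(0.0, max_lag, n_lags + 1)
    idx = np.clip(np.searchsorted(edges, d[inside], side="right") - 1,
                  0, n_lags - 1)
    counts = np.bincount(idx, minlength=n_lags).astype(float)
    sums = np.bincount(idx, weights=sq[inside], minlength=n_lags)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = sums / (2.0 * counts)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalVariogram(centres, gamma, counts, float(max_lag))


def _wls_fit_family(emp: EmpiricalVariogram, family: str,
                    sample_var: float) -> tuple[VariogramModel, float]:
    """Cressie-weighted least squares for one family; returns (model, cost)."""
    emp = emp.nonempty()
    lags, gam, cnt = emp.lags, emp.gamma, emp.counts
    if len(lags) < 3:
        raise ValueError("need >= 3 non-empty lag bins to fit a variogram")
    sill0 = sample_var if sample_var > 0 else float(np.nanmean(gam))
    sill0 = max(sill0, 1e-12)

    def resid(theta):
        c0, c, a = theta
        model = VariogramModel(family, max(c0, 0.0), max(c, 1e-12), max(a, 1e-9))
        gm = model.gamma(lags)
        w = np.sqrt(cnt) / np.maximum(gm, 1e-12)
        return w * (gam - gm)

    best = None
    # multi-start over plausible ranges and nugget shares
    for a0 in (emp.max_lag / 4, emp.max_lag / 2, emp.max_lag):
        for f0 in (0.0, 0.3, 0.7):
            x0 = np.array([f0 * sill0, (1 - f0) * sill0, a0])
            try:
                sol = least_squares(
                    resid, x0,
                    bounds=([0.0, 1e-12, 1e-6],
                            [5 * sill0, 10 * sill0, 4 * emp.max_lag]),
                    max_nfev=200)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError(f"WLS fit failed to converge for family '{family}'")
    c0, c, a = best.x
    return VariogramModel(family, float(c0), float(c), float(a)), float(best.cost)


@dataclasses.dataclass
class VariogramFitResults:
    """Fitted variogram with per-family diagnostics.

    ``model`` is the winning family (minimum LOO ordinary-kriging RMSE; ties
    broken by WLS cost, then spherical > exponential > gaussian).
    """

    model: VariogramModel
    empirical: EmpiricalVariogram
    per_family: dict[str, VariogramModel]
    wls_cost: dict[str, float]
    loo_rmse: dict[str, float]
    transform: str = "none"
    nugget_fraction_raw: float | None = None

    def summary(self) -> str:
        m = self.model
        lines = [
            "Variogram fit",
            "=" * 50,
            f"selected family : {m.family}",
            f"nugget          : {m.nugget:.4g}",
            f"partial sill    : {m.psill:.4g}",
            f"range (km)      : {m.range_:.4g}",
            f"nugget effect   : {100 * m.nugget_fraction:.2f}%"
            + (" (fitted scale)" if self.transform != "none" else ""),
        ]
        if self.transform != "none" and self.nugget_fraction_raw is not None:
            lines.append(
                f"nugget effect (raw scale): {100 * self.nugget_fraction_raw:.2f}%"
            )
            lines.append(f"transform       : {self.transform}")
        lines.append("-" * 50)
        lines.append(f"{'family':<12}{'WLS cost':>12}{'LOO RMSE':>12}")
        for fam in FAMILIES:
            if fam in self.per_family:
                lines.append(f"{fam:<12}{self.wls_cost[fam]:>12.4g}"
                             f"{self.loo_rmse[fam]:>12.4g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Empirical semivariogram with the fitted model curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        emp = self.empirical.nonempty()
        ax.plot(emp.lags, emp.gamma, "o", label="empirical")
        h = np.linspace(0, emp.max_lag, 200)
        ax.plot(h, self.model.gamma(h), "-",
                label=f"{self.model.family} fit")
        ax.set_xlabel("lag h (km)")
        ax.set_ylabel("semivariance")
        ax.legend()
        return ax


class Variogram:
    """Spatial-structure model for a point-sampled field (statsmodels style).

    Parameters
    ----------
    coords : (n, 2) array of planar km coordinates
    values : (n,) field values
    n_lags, max_lag : empirical-semivariogram binning (default 12 bins to
        half the maximum pairwise distance)
    """

    def __init__(self, coords, values, n_lags: int = 12,
                 max_lag: float | None = None, loo_rel_tol: float = 0.01):
        self.coords = np.asarray(coords, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.n_lags = n_lags
        self.max_lag = max_lag
        self.loo_rel_tol = loo_rel_tol

    def fit(self, families=FAMILIES, select: str = "loo") -> VariogramFitResults:
        """Fit each family by WLS; select by LOO kriging RMSE ('loo') or
        WLS cost ('wls')."""
        from .kriging import loo_cv  # local import avoids a cycle

        emp = empirical_semivariogram(self.coords, self.values,
                                      self.n_lags, self.max_lag)
        svar = float(np.var(self.values, ddof=1))
        fits: dict[str, VariogramModel] = {}
        cost: dict[str, float] = {}
        rmse: dict[str, float] = {}
        errors = {}
        for fam in families:
            try:
                fits[fam], cost[fam] = _wls_fit_family(emp, fam, svar)
            except Exception as exc:  # keep diagnostics, try other families
                errors[fam] = exc
                continue
            if select == "loo":
                table = loo_cv(self.coords, self.values, fits[fam])
                rmse[fam] = float(np.sqrt(np.mean(table["error"] ** 2)))
            else:
                rmse[fam] = cost[fam]
        if not fits:
            raise RuntimeError(f"no variogram family converged: {errors}")
        order = {f: i for i, f in enumerate(FAMILIES)}
        best = min(rmse.values())
        # LOO RMSEs within 1% of the best are ties: differences that small
        # sit below the LOO estimate's own Monte-Carlo noise. Ties fall back
        # to the WLS fit quality, then to the fixed family order.
        tied = [f for f in fits if rmse[f] <= best * (1.0 + self.loo_rel_tol)]
        win = min(tied, key=lambda f: (round(cost[f], 12), order[f]))
        return VariogramFitResults(fits[win], emp, fits, cost, rmse)


def fit_variogram(emp_or_coords, values=None, families=FAMILIES,
                  **kwargs) -> VariogramFitResults:
    """Functional wrapper: ``fit_variogram(coords, values)``."""
    return Variogram(emp_or_coords, values, **kwargs).fit(families=families)


def transform_if_skewed(values, threshold: float = 1.0):
    """Log- or Box-Cox-transform values whose |skewness| exceeds threshold.

    Returns (transformed, name, params). Log is preferred when it already
    brings the skewness inside the threshold; otherwise Box-Cox with
    maximum-likelihood lambda.
    """
    values = np.asarray(values, dtype=float)
    if abs(skew(values)) <= threshold:
        return values, "none", {}
    if (values <= 0).any():
        warnings.warn("non-positive values: skipping log/Box-Cox transform")
        return values, "none", {}
    logged = np.log(values)
    if abs(skew(logged)) <= threshold:
        return logged, "log", {}
    bc, lam = boxcox(values)
    return bc, "boxcox", {"lmbda": float(lam)}
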