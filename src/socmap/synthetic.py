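"""Synthetic soil-landscape generator.

Generates spatially structured covariate fields and a soil-organic-carbon
(SOC) response with planted nonlinear thresholds, so that every stage of
the pipeline (variography, kriging, simulation, ML interpretation,
threshold detection) can be exercised and scored against known truth.

Construction, per scenario:

1. Each covariate is a Gaussian random field with the regional variogram
   (circulant-embedding synthesis, exact covariance on the embedding
   torus), pushed through a monotone marginal transform that fixes its
   median and interquartile range (lognormal for concentrations, Gaussian
   for pH).
2. SOC = base + structural term(s) + centered modifier terms + centered
   interaction terms + homoscedastic Gaussian noise. Threshold terms are
   logistic-smoothed piecewise-linear segments; modifier/interaction terms
   are centered by their analytic expectation under the generating
   marginal (Gauss-Hermite quadrature), so the partial-dependence plateaus
   of the focal predictors sit at the configured absolute levels.
3. Sites are distinct grid cells drawn uniformly without replacement.

Two scenarios ship as defaults: "jiaodong" (short-range, high-nugget
spatial structure; nitrate step at 10 mg/kg with plateaus 13.5 -> 16.0
g/kg; biphasic iron effect; a nitrate x iron dual-threshold interaction at
(10, 12)) and "southwest" (long-range, near-zero nugget; total-nitrogen
ramp at 3.25 g/kg rising 2.0 g/kg at slope 1.54; nitrate drop above
27 mg/kg; sequential phosphorus and CEC steps; a TN x CEC interaction
flipping sign at TN = 4).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .io import FieldGrid, GridSpec, SampleTable, load_config
from .variogram import VariogramModel

_Z75 = 0.6744897501960817  # standard-normal upper quartile
_Z99 = 2.3263478740408408


# -- marginal transforms ---------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Marginal:
    """Target marginal for one covariate: median and IQR, exact by design."""

    median: float
    iqr: float
    dist: str = "lognormal"  # or "normal"

    def __post_init__(self):
        if self.iqr <= 0:
            raise ValueError("marginal spread (IQR) must be positive")
        if self.median <= 0 and self.dist == "lognormal":
            raise ValueError("lognormal marginal needs a positive median")

    @property
    def _s(self) -> float:
        # lognormal log-sd from median/IQR: med*2*sinh(z75*s) = iqr
        return float(np.arcsinh(self.iqr / (2.0 * self.median)) / _Z75)

    def transform(self, z) -> np.ndarray:
        """Monotone map from standard-normal scores to the target marginal."""
        z = np.asarray(z, dtype=float)
        if self.dist == "lognormal":
            return self.median * np.exp(self._s * z)
        return self.median + (self.iqr / (2.0 * _Z75)) * z

    def quantile_span(self, lo: float = 0.01, hi: float = 0.99) -> float:
        from scipy.stats import norm
        return float(self.transform(norm.ppf(hi)) - self.transform(norm.ppf(lo)))

    def expect(self, func, n_nodes: int = 96) -> float:
        """Gauss-Hermite expectation of func(X) under this marginal."""
        t, w = np.polynomial.hermite.hermgauss(n_nodes)
        z = np.sqrt(2.0) * t
        return float(np.sum(w * func(self.transform(z))) / np.sqrt(np.pi))


# -- response terms --------------------------------------------------------

def _sigmoid(u):
    return 1.0 / (1.0 + np.exp(-np.clip(u, -60, 60)))


def _softplus(u):
    return np.logaddexp(0.0, np.clip(u, -60, 60))


@dataclasses.dataclass(frozen=True)
class StepTerm:
    """Logistic step: amplitude * sigma((x - threshold)/width)."""

    covariate: str
    threshold: float
    amplitude: float
    width: float
    centered: bool = True

    def raw(self, x):
        return self.amplitude * _sigmoid((x - self.threshold) / self.width)


@dataclasses.dataclass(frozen=True)
class RampTerm:
    """Smoothed ramp: slope 0 below onset, ``slope`` up to a cap, 0 above.

    The cap knot sits at onset + rise/slope, so the total rise is ``rise``.
    Structural (never centered): it carries the response's absolute level.
    """

    covariate: str
    onset: float
    slope: float
    rise: float
    width: float
    centered: bool = False

    @property
    def cap_knot(self) -> float:
        return self.onset + self.rise / self.slope

    def raw(self, x):
        w = self.width
        return self.slope * w * (_softplus((x - self.onset) / w)
                                 - _softplus((x - self.cap_knot) / w))


@dataclasses.dataclass(frozen=True)
class SlopeChangeTerm:
    """Biphasic effect: slope1 below the break, slope2 above; zero at ref."""

    covariate: str
    ref: float
    break_: float
    slope1: float
    slope2: float
    width: float
    centered: bool = True

    def raw(self, x):
        w,d = self.width, self.slope2 - self.slope1
        return (self.slope1 * (x - self.ref)
                + d * w * (_softplus((x - self.break_) / w)
                           - _softplus((self.ref - self.break_) / w)))


@dataclasses.dataclass(frozen=True)
class GateInteraction:
    """f2's step effect whose sign/magnitude is gated by f1's threshold.

    term = [low + (high-low) * sigma((x1-t1)/w1)] * (sigma((x2-t2)/w2) - k2)

    with k2 the analytic expectation of the second factor, so the term
    contributes nothing to the partial dependence on f1.
    """

    f1: str
    f2: str
    t1: float
    t2: float
    w1: float
    w2: float
    low_amp: float
    high_amp: float

    def value(self, x1, x2, k2: float):
        a = self.low_amp + (self.high_amp - self.low_amp) \
            * _sigmoid((x1 - self.t1) / self.w1)
        return a * (_sigmoid((x2 - self.t2) / self.w2) - k2)


@dataclasses.dataclass(frozen=True)
class QuadrantInteraction:
    """Sign-flip interaction: amplitude * sgn-like(f1 - t1) * centered f2.

    term = amplitude * (2 sigma((x1-t1)/w1) - 1) * (tanh((x2-c2)/s2) - k2)
    """

    f1: str
    f2: str
    t1: float
    w1: float
    c2: float
    s2: float
    amplitude: float

    def value(self, x1, x2, k2: float):
        return (self.amplitude * (2.0 * _sigmoid((x1 - self.t1) / self.w1) - 1.0)
                * (np.tanh((x2 - self.c2) / self.s2) - k2))


@dataclasses.dataclass
class ResponseSpec:
    """Additive SOC response: base + terms + interactions (g/kg)."""

    base: float
    terms: list
    interactions: list

    def evaluate(self, covariates: dict[str, np.ndarray],
                 marginals: dict[str, Marginal]) -> np.ndarray:
        needed = {t.covariate for t in self.terms}
        for it in self.interactions:
            needed |= {it.f1, it.f2}
        missing = needed - set(covariates)
        if missing:
            raise KeyError(f"missing covariate(s) {sorted(missing)} "
                           "required by the response")
        shape = next(iter(covariates.values())).shape
        out = np.full(shape, float(self.base))
        for term in self.terms:
            x = covariates[term.covariate]
            v = term.raw(x)
            if term.centered:
                v = v - marginals[term.covariate].expect(term.raw)
            out = out + v
        for it in self.interactions:
            x1, x2 = covariates[it.f1], covariates[it.f2]
            if isinstance(it, GateInteraction):
                k2 = marginals[it.f2].expect(
                    lambda v: _sigmoid((v - it.t2) / it.w2))
            else:
                k2 = marginals[it.f2].expect(
                    lambda v: np.tanh((v - it.c2) / it.s2))
            out = out + it.value(x1, x2, k2)
        return out


# -- scenario configuration ------------------------------------------------

@dataclasses.dataclass
class ScenarioConfig:
    name: str
    grid: GridSpec
    field_variograms: dict[str, VariogramModel]
    marginals: dict[str, Marginal]
    response: ResponseSpec
    noise_sd: float
    n_sites: int
    seed: int
    soc_envelope: tuple[float, float]
    cluster_replicates: int = 1  # >1 averages composite noise draws per site

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_sites > self.grid.n_cells:
            raise ValueError("n_sites exceeds the number of grid cells")
        # every planted threshold must sit well inside its covariate's
        # generated range, or downstream recovery tests are meaningless
        from scipy.stats import norm
        lo_z, hi_z = norm.ppf(0.001), norm.ppf(0.999)
        for term in self.response.terms:
            marg = self.marginals.get(term.covariate)
            if marg is None:
                continue
            lo, hi = marg.transform(lo_z), marg.transform(hi_z)
            for attr in ("threshold", "onset", "break_"):
                t = getattr(term, attr, None)
                if t is not None and not lo < t < hi:
                    raise ValueError(
                        f"breakpoint {t} of term on '{term.covariate}' "
                        f"lies outside the generated range ({lo:.3g}, "
                        f"{hi:.3g})")


def _default_width(marginal: Marginal, frac: float = 0.02) -> float:
    """Default logistic smoothness: 2% of the 1st-99th percentile span."""
    return frac * marginal.quantile_span()


def jiaodong_scenario(n_sites: int = 144, seed: int = 1,
                      nx: int = 100, ny: int = 100,
                      cell_km: float = 2.0) -> ScenarioConfig:
    """Maritime-monsoon scenario: short range, high nugget, NO3 x Fe gates."""
    grid = GridSpec(0.0, 0.0, cell_km, cell_km, nx, ny)
    marg = {
        "no3n": Marginal(10.0, 6.0),
        "fe": Marginal(11.0, 4.0),
        "cec": Marginal(10.5, 3.0),
        "nh4n": Marginal(8.0, 4.0),
        "ph": Marginal(6.5, 1.0, dist="normal"),
    }
    vg = {c: VariogramModel("spherical", 0.3914, 1.0 - 0.3914, 42.6)
          for c in marg}
    w_fe = _default_width(marg["fe"])
    response = ResponseSpec(
        base=13.5,
        terms=[
            # sharp nitrate step: plateaus 13.5 -> 16.0 at 10 mg/kg
            StepTerm("no3n", 10.0, 2.5, width=0.2, centered=False),
            # biphasic iron effect, turning at 11.5 mg/kg
            SlopeChangeTerm("fe", ref=8.0, break_=11.5,
                            slope1=0.10, slope2=-0.15, width=w_fe),
        ],
        interactions=[
            # Fe > 12 is inhibitory (-1.5) under nitrate limitation,
            # mildly positive (+0.4) above the nitrate threshold
            GateInteraction("no3n", "fe", t1=10.0, t2=12.0,
                            w1=0.2, w2=w_fe, low_amp=-1.5, high_amp=0.4),
        ],
    )
    return ScenarioConfig("jiaodong", grid, vg, marg, response,
                          noise_sd=0.5, n_sites=n_sites, seed=seed,
                          soc_envelope=(8.0, 22.0))


def southwest_scenario(n_sites: int = 123, seed: int = 1,
                       nx: int = 100, ny: int = 100,
                       cell_km: float = 2.0) -> ScenarioConfig:
    """Continental scenario: long range, near-zero nugget, TN-dominated."""
    grid = GridSpec(0.0, 0.0, cell_km, cell_km, nx, ny)
    marg = {
        "tn": Marginal(3.67, 1.2),
        "no3n": Marginal(14.94, 12.0),
        "tp": Marginal(0.71, 0.14),
        "cec": Marginal(11.5, 2.5),
        "nh4n": Marginal(8.0, 4.0),
        "ph": Marginal(7.5, 0.8, dist="normal"),
    }
    vg = {c: VariogramModel("spherical", 0.0112, 1.0 - 0.0112, 68.0)
          for c in marg}
    base = 17.5
    response = ResponseSpec(
        base=base,
        terms=[
            # TN ramp: flat at 17.5 below 3.25, slope 1.54 to a 2.0 rise
            RampTerm("tn", onset=3.25, slope=1.54, rise=2.0,
                     width=_default_width(marg["tn"])),
            # nitrate drop above 27 mg/kg: -3.1% of the base level
            StepTerm("no3n", 27.0, -0.031 * base,
                     width=_default_width(marg["no3n"])),
            # sequential phosphorus suppression steps
            StepTerm("tp", 0.71, -2.0, width=_default_width(marg["tp"])),
            StepTerm("tp", 0.81, -2.0, width=_default_width(marg["tp"])),
            # CEC rises: +6.7% of base at 10.8, +2.2 g/kg at 12.1
            StepTerm("cec", 10.8, 0.067 * base,
                     width=_default_width(marg["cec"])),
            StepTerm("cec", 12.1, 2.2, width=_default_width(marg["cec"])),
        ],
        interactions=[
            # TN x CEC co-limitation flipping sign at TN = 4.0
            QuadrantInteraction("tn", "cec", t1=4.0,
                                w1=_default_width(marg["tn"]),
                                c2=11.5, s2=2.0, amplitude=1.2),
        ],
    )
    return ScenarioConfig("southwest", grid, vg, marg, response,
                          noise_sd=0.5, n_sites=n_sites, seed=seed,
                          soc_envelope=(8.0, 30.0))


_BUILDERS = {"jiaodong": jiaodong_scenario, "southwest": southwest_scenario}


def scenario(name: str, **overrides) -> ScenarioConfig:
    """Build a named default scenario, optionally overriding n_sites/seed/..."""
    if name not in _BUILDERS:
        raise KeyError(f"unknown scenario '{name}'; have {sorted(_BUILDERS)}")
    return _BUILDERS[name](**overrides)


def scenario_from_file(path) -> ScenarioConfig:
    """Load a scenario YAML: a named default plus keyword overrides."""
    cfg = load_config(path)
    name = cfg.pop("scenario")
    return scenario(name, **cfg)


# -- Gaussian random fields ------------------------------------------------

def gaussian_random_field(spec: GridSpec, vg: VariogramModel,
                          seed: int) -> FieldGrid:
    """Zero-mean, unit-sill Gaussian field with variogram ``vg``.

    The continuous component is synthesised by circulant embedding (exact
    torus covariance, FFT); the nugget component is added as independent
    white noise. ``vg`` is rescaled to unit sill; small negative embedding
    eigenvalues are clipped (warning if they carry > 0.1% of the energy).
    Falls back to dense Cholesky for grids of <= 4000 cells where the
    embedding is strongly non-positive.
    """
    if spec.n_cells > 10 ** 6:
        raise ValueError("grid too large (> 1e6 cells)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6F5]))
    fnug = vg.nugget_fraction
    csill = 1.0 - fnug
    out = np.zeros(spec.shape)
    if csill > 0:
        cont = VariogramModel(vg.family, 0.0, csill, vg.range_)
        M, N = 2 * spec.ny, 2 * spec.nx
        iy = np.minimum(np.arange(M), M - np.arange(M)) * spec.dy
        ix = np.minimum(np.arange(N), N - np.arange(N)) * spec.dx
        H = np.hypot(iy[:, None], ix[None, :])
        C = cont.covariance(H)
        e = np.fft.fft2(C).real
        neg = -e[e < 0].sum()
        if neg > 1e-3 * e[e > 0].sum():
            if spec.n_cells <= 4000:
                return _grf_cholesky(spec, vg, rng)
            warnings.warn(
                f"circulant embedding clipped {neg:.3g} negative spectral "
                "mass; field covariance is approximate")
        e = np.maximum(e, 0.0)
        zeta = rng.standard_normal((M, N)) + 1j * rng.standard_normal((M, N))
        F = np.fft.ifft2(np.sqrt(e) * zeta) * np.sqrt(M * N)
        out = F.real[: spec.ny, : spec.nx].copy()
    if fnug > 0:
        out += np.sqrt(fnug) * rng.standard_normal(spec.shape)
    return FieldGrid(spec, out)


def _grf_cholesky(spec: GridSpec, vg: VariogramModel, rng) -> FieldGrid:
    pts = spec.cell_centers_flat()
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    C = vg.covariance(d) + 1e-10 * np.eye(len(pts))
    L = np.linalg.cholesky(C)
    vals = L @ rng.standard_normal(len(pts))
    return FieldGrid(spec, vals.reshape(spec.shape))


# -- scenario realisation --------------------------------------------------

def _rank_standardize(values: np.ndarray) -> np.ndarray:
    """Map a field to an exact standard-normal sample marginal.

    Rank-based Gaussian anamorphosis: monotone in the original values, so
    the spatial rank structure is untouched, while the ergodic fluctuation
    of a single finite-domain realization (its mean and variance drifting
    from 0/1) is removed. This pins every covariate's sample median and
    IQR to the configured marginal exactly.
    """
    from scipy.stats import norm
    flat = values.ravel()
    order = np.argsort(flat, kind="stable")
    ranks = np.empty(len(flat))
    ranks[order] = np.arange(1, len(flat) + 1)
    return norm.ppf((ranks - 0.5) / len(flat)).reshape(values.shape)


def generate_covariates(cfg: ScenarioConfig) -> dict[str, FieldGrid]:
    """Independent covariate fields with the scenario's spatial structure."""
    fields = {}
    for k, name in enumerate(sorted(cfg.marginals)):
        grf = gaussian_random_field(cfg.grid, cfg.field_variograms[name],
                                    seed=_stream(cfg.seed, 1000 + k))
        z = _rank_standardize(grf.values)
        vals = cfg.marginals[name].transform(z)
        fields[name] = FieldGrid(cfg.grid, vals)
    return fields


def response_soc(covariates: dict[str, FieldGrid], resp: ResponseSpec,
                 marginals: dict[str, Marginal], noise_sd: float,
                 seed: int) -> FieldGrid:
    """Deterministic response plus homoscedastic Gaussian noise."""
    arrays = {k: f.values for k, f in covariates.items()}
    spec = next(iter(covariates.values())).spec
    soc = resp.evaluate(arrays, marginals)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x501]))
        soc = soc + noise_sd * rng.standard_normal(spec.shape)
    return FieldGrid(spec, soc)


def _stream(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([int(seed), k])
               .generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def sample_scenario(cfg: ScenarioConfig):
    """Draw the scenario's site sample.

    Returns ``(table, truth)`` where ``truth`` is a dict with the covariate
    grids, the noise-free SOC grid and the sampled SOC grid.
    """
    cov = generate_covariates(cfg)
    soc_clean = response_soc(cov, cfg.response, cfg.marginals, 0.0, cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x517E]))
    cells = rng.choice(cfg.grid.n_cells, size=cfg.n_sites, replace=False)
    xy = cfg.grid.cell_centers_flat()[cells]
    rows, cols = np.divmod(cells, cfg.grid.nx)
    if cfg.cluster_replicates > 1:
        noise = cfg.noise_sd * rng.standard_normal(
            (cfg.n_sites, cfg.cluster_replicates)).mean(axis=1)
    else:
        noise = cfg.noise_sd * rng.standard_normal(cfg.n_sites)
    soc_obs = soc_clean.values[rows, cols] + noise
    data = {"x": xy[:, 0], "y": xy[:, 1], "region": cfg.name,
            "soc": soc_obs}
    for name, field in cov.items():
        data[name] = field.values[rows, cols]
    table = SampleTable(pd.DataFrame(data))
    truth = {"covariates": cov, "soc_clean": soc_clean,
             "cells": cells}
    return table, truth
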