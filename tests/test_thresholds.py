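import numpy as np
import pytest

from socmap import (SegmentedRegression, candidate_breakpoints,
                    dual_threshold_domain, loess_smooth, segmented_fit)
from socmap.ml import PDPCurve
from socmap.shapley import ShapDecomposition


class TestLoess:
    def test_reproduces_exact_line(self):
        x = np.linspace(0, 10, 60)
        y = 3.0 * x - 2.0
        np.testing.assert_allclose(loess_smooth(x, y, span=0.3), y,
                                   atol=1e-9)

    def test_span_one_on_symmetric_noise_matches_ols(self, rng):
        x = np.linspace(0, 1, 80)
        noise = rng.normal(0, 0.3, 40)
        y = 2 * x + np.concatenate([noise, -noise[::-1]])  # symmetric
        sm = loess_smooth(x, y, span=1.0)
        ols = np.polyval(np.polyfit(x, y, 1), x)
        np.testing.assert_allclose(sm, ols, atol=0.15)

    def test_step_midpoint_located(self):
        x = np.linspace(0, 10, 100)
        y = np.where(x < 5.0, 0.0, 1.0)
        sm = loess_smooth(x, y, span=0.3)
        crossing = x[np.argmin(np.abs(sm - 0.5))]
        assert abs(crossing - 5.0) <= x[1] - x[0] + 1e-9

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            loess_smooth([1, 2, 3], [1, 2, 3], span=0.3)
        x = np.linspace(0, 1, 50)
        with pytest.raises(ValueError):
            loess_smooth(x, x, span=0.01)
        with pytest.raises(ValueError):
            loess_smooth(x, x, span=1.5)


def make_pdp(x, y, name="x"):
    return PDPCurve(name, np.asarray(x, float), np.asarray(y, float))


class TestCandidateBreakpoints:
    def test_kink_of_absolute_value_found(self):
        g = np.linspace(0, 20, 50)
        pdp = make_pdp(g, np.abs(g - 10.0))
        cands = candidate_breakpoints(pdp)
        step = g[1] - g[0]
        assert any(abs(c - 10.0) <= 1.5 * step for c in cands.breakpoints)

    def test_strictly_linear_pdp_yields_nothing(self):
        g = np.linspace(0, 20, 50)
        cands = candidate_breakpoints(make_pdp(g, 0.5 * g + 1))
        assert len(cands) == 0

    def test_flat_pdp_yields_empty_set_without_error(self):
        g = np.linspace(0, 20, 50)
        cands = candidate_breakpoints(make_pdp(g, np.full(50, 3.0)))
        assert len(cands) == 0

    def test_logistic_step_located_precisely(self):
        g = np.linspace(2.0, 6.0, 60)
        y = 17.5 + 2.0 / (1 + np.exp(-(g - 3.25) / 0.07))
        cands = candidate_breakpoints(make_pdp(g, y))
        assert len(cands) >= 1
        assert min(abs(cands.breakpoints - 3.25)) <= 0.1

    def test_shap_sign_shift_contributes_candidate(self, rng):
        g = np.linspace(0, 20, 50)
        pdp = make_pdp(g, np.zeros(50))  # flat: only SHAP can contribute
        xs = rng.uniform(0, 20, 200)
        phi = np.where(xs < 12.0, -0.5, 0.5) + rng.normal(0, 0.05, 200)
        cands = candidate_breakpoints(pdp, (xs, phi))
        assert any(abs(c - 12.0) < 1.0 for c in cands.breakpoints)
        assert "shap-sign-shift" in cands.provenance

    def test_too_few_grid_points_rejected(self):
        with pytest.raises(ValueError):
            candidate_breakpoints(make_pdp(np.arange(5), np.arange(5)))


class TestSegmentedRegression:
    def test_noiseless_two_piece_line_recovered(self):
        x = np.linspace(0, 8, 200)
        y = np.where(x < 3.25, 1.0, 1.0 + 1.54 * (x - 3.25))
        fit = segmented_fit(x, y, candidates=[3.0])
        assert fit.accepted
        # exact up to the knot-search grid resolution (x-range / 200)
        assert fit.breakpoints[0] == pytest.approx(3.25, abs=8 / 200)
        assert fit.rss_segmented < 0.01

    def test_pure_line_with_noise_not_accepted(self, rng):
        x = np.linspace(0, 10, 150)
        y = 2 * x + rng.normal(0, 0.5, 150)
        fit = segmented_fit(x, y, candidates=[5.0])
        assert not fit.accepted

    def test_noisy_step_recovered_within_half_unit(self):
        results = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.uniform(0, 20, 200)
            y = np.where(x < 10, 0.0, 2.0) + r.normal(0, 0.3, 200)
            fit = segmented_fit(x, y, candidates=[9.5, 10.5])
            assert fit.accepted
            results.append(fit.primary_threshold)
        assert abs(np.median(results) - 10.0) <= 0.5

    def test_matches_exhaustive_grid_oracle(self, rng):
        # single-knot selection agrees with a brute-force scan over the
        # same knot grid on small instances
        x = np.sort(rng.uniform(0, 10, 120))
        y = np.where(x < 6, 1.0, 1.0 + 0.8 * (x - 6)) \
            + rng.normal(0, 0.2, 120)
        model = SegmentedRegression(x, y, candidates=[6.0], max_breaks=1)
        fit = model.fit()
        from socmap.thresholds import _fit_rss
        span = x.max() - x.min()
        res = span / model.grid_resolution
        grid = np.arange(max(x.min() + res, 6.0 - 0.1 * span),
                         min(x.max() - res, 6.0 + 0.1 * span) + 0.5 * res,
                         res)
        oracle_rss, oracle_b = min((_fit_rss(x, y, [b])[0], b) for b in grid)
        assert fit.breakpoints[0] == pytest.approx(oracle_b, abs=1e-9)
        assert fit.rss_segmented == pytest.approx(oracle_rss, rel=1e-9)

    def test_noise_never_beats_noiseless_rss(self, rng):
        x = np.linspace(0, 20, 150)
        clean = np.where(x < 10, 0.0, 2.0)
        base = segmented_fit(x, clean, candidates=[9.8, 10.2])
        noisy = segmented_fit(x, clean + rng.normal(0, 0.4, 150),
                              candidates=[9.8, 10.2])
        assert noisy.rss_segmented >= base.rss_segmented

    def test_rescaling_predictor_rescales_breakpoint(self, rng):
        x = rng.uniform(0, 10, 200)
        y = np.where(x < 4.0, 0.0, 1.5) + rng.normal(0, 0.2, 200)
        fit1 = segmented_fit(x, y, candidates=[3.8, 4.2])
        fit2 = segmented_fit(10 * x, y, candidates=[38.0, 42.0])
        assert fit2.primary_threshold == pytest.approx(
            10 * fit1.primary_threshold, rel=0.02)

    def test_step_size_measures_plateau_difference(self, rng):
        x = rng.uniform(0, 20, 400)
        y = np.where(x < 10, 1.0, 3.0) + rng.normal(0, 0.2, 400)
        fit = segmented_fit(x, y, candidates=[9.5, 10.5])
        assert len(fit.breakpoints) == 2
        assert fit.step_size() == pytest.approx(2.0, abs=0.2)

    def test_candidate_windows_outside_range_rejected(self):
        x = np.linspace(0, 1, 30)
        with pytest.raises(ValueError, match="outside"):
            segmented_fit(x, x, candidates=[5.0])

    def test_primary_rule_step_vs_ramp(self):
        x = np.linspace(0, 100, 400)
        # narrow steep middle -> step: report midpoint
        y_step = np.interp(x, [0, 49, 51, 100], [0, 0, 5, 5])
        f1 = segmented_fit(x, y_step, candidates=[48.0, 52.0])
        assert f1.primary_threshold == pytest.approx(50.0, abs=1.5)
        # wide ramp -> onset: report the lower knot
        y_ramp = np.interp(x, [0, 30, 70, 100], [0, 0, 5, 5])
        f2 = segmented_fit(x, y_ramp, candidates=[30.0, 70.0])
        assert f2.primary_threshold == pytest.approx(30.0, abs=2.0)


class TestDualThresholdDomain:
    @staticmethod
    def make_dec(x1, x2, inter, names=("a", "b", "c")):
        n, p = len(x1), len(names)
        X = np.column_stack([x1, x2, np.zeros(n)])
        interactions = np.zeros((n, p, p))
        interactions[:, 0, 1] = interactions[:, 1, 0] = inter
        return ShapDecomposition(0.0, np.zeros((n, p)), interactions,
                                 list(names), X)

    def test_planted_sign_product_recovered(self, rng):
        x1 = rng.uniform(0, 20, 400)
        x2 = rng.uniform(0, 24, 400)
        inter = np.sign(x1 - 10) * np.sign(x2 - 12) \
            + rng.normal(0, 0.15, 400)
        dec = self.make_dec(x1, x2, inter)
        dom = dual_threshold_domain(dec, ("a", "b"))
        d1 = np.diff(np.quantile(x1, np.arange(1, 10) / 10)).max()
        d2 = np.diff(np.quantile(x2, np.arange(1, 10) / 10)).max()
        assert abs(dom.thresholds[0] - 10.0) <= d1 + 1e-9
        assert abs(dom.thresholds[1] - 12.0) <= d2 + 1e-9
        assert dom.sign_pattern["high1_high2"] > 0
        assert dom.sign_pattern["low1_high2"] < 0
        assert not dom.flagged

    def test_constant_interaction_flagged(self, rng):
        x1 = rng.uniform(0, 10, 100)
        x2 = rng.uniform(0, 10, 100)
        dec = self.make_dec(x1, x2, np.full(100, 0.2))
        dom = dual_threshold_domain(dec, ("a", "b"))
        assert dom.flagged

    def test_missing_interactions_rejected(self, rng):
        dec = ShapDecomposition(0.0, np.zeros((5, 2)), None, ["a", "b"],
                                np.zeros((5, 2)))
        with pytest.raises(ValueError):
            dual_threshold_domain(dec, ("a", "b"))
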