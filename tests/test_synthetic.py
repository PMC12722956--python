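import numpy as np
import pytest

from socmap import (GridSpec, Marginal, VariogramModel,
                    empirical_semivariogram, gaussian_random_field,
                    generate_covariates, response_soc, sample_scenario,
                    scenario)
from socmap.synthetic import _sigmoid


class TestMarginal:
    def test_lognormal_median_and_iqr_exact(self):
        m = Marginal(14.94, 12.0)
        z = np.random.default_rng(0).standard_normal(200_000)
        x = m.transform(z)
        assert np.median(x) == pytest.approx(14.94, rel=0.01)
        q1, q3 = np.percentile(x, [25, 75])
        assert q3 - q1 == pytest.approx(12.0, rel=0.02)

    def test_normal_marginal(self):
        m = Marginal(6.5, 1.0, dist="normal")
        z = np.array([-0.6744897501960817, 0.0, 0.6744897501960817])
        np.testing.assert_allclose(m.transform(z), [6.0, 6.5, 7.0])

    def test_nonpositive_spread_rejected(self):
        with pytest.raises(ValueError):
            Marginal(3.0, 0.0)

    def test_expectation_by_quadrature(self):
        m = Marginal(6.5, 2.0, dist="normal")
        assert m.expect(lambda x: x) == pytest.approx(6.5, rel=1e-6)
        var = m.expect(lambda x: (x - 6.5) ** 2)
        assert var == pytest.approx((2.0 / 1.3489795) ** 2, rel=1e-6)


class TestGaussianRandomField:
    def test_deterministic_given_seed(self, small_grid):
        vg = VariogramModel("spherical", 0.1, 0.9, 8.0)
        a = gaussian_random_field(small_grid, vg, seed=5)
        b = gaussian_random_field(small_grid, vg, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_pure_nugget_is_white_noise(self):
        spec = GridSpec(0, 0, 1, 1, 100, 100)
        vg = VariogramModel("spherical", 1.0, 0.0, 10.0)
        f = gaussian_random_field(spec, vg, seed=1).values
        r = np.corrcoef(f[:, :-1].ravel(), f[:, 1:].ravel())[0, 1]
        assert abs(r) < 0.05
        assert f.var() == pytest.approx(1.0, rel=0.05)

    def test_variogram_reaches_sill_beyond_range(self):
        # 10-seed average of the generator's own empirical variogram; a
        # 20-km range on the 200-km domain gives each field enough
        # independent range-blocks for a stable tail estimate
        spec = GridSpec(0, 0, 2, 2, 100, 100)
        vg = VariogramModel("spherical", 0.0, 1.0, 20.0)
        xy = spec.cell_centers_flat()
        rng = np.random.default_rng(4)
        tails = []
        for seed in range(10):
            f = gaussian_random_field(spec, vg, seed=seed).values.ravel()
            idx = rng.choice(len(f), 400, replace=False)
            emp = empirical_semivariogram(xy[idx], f[idx], n_lags=12)
            tails.append(np.nanmean(emp.gamma[emp.lags > 30]))
        assert np.mean(tails) == pytest.approx(1.0, rel=0.10)

    def test_grid_size_guard(self):
        vg = VariogramModel("spherical", 0.0, 1.0, 10.0)
        with pytest.raises(ValueError, match="large"):
            gaussian_random_field(GridSpec(0, 0, 1, 1, 2000, 2000), vg, 0)


class TestGenerateCovariates:
    def test_southwest_medians_match_configured_marginals(self):
        cfg = scenario("southwest", seed=3)
        fields = generate_covariates(cfg)
        assert np.median(fields["tn"].values) == pytest.approx(3.67,
                                                               rel=0.05)
        assert np.median(fields["no3n"].values) == pytest.approx(14.94,
                                                                 rel=0.05)
        assert np.median(fields["tp"].values) == pytest.approx(0.71,
                                                               rel=0.05)

    def test_fields_positive_for_lognormal_marginals(self):
        cfg = scenario("jiaodong", seed=2)
        fields = generate_covariates(cfg)
        for name in ("no3n", "fe", "cec", "nh4n"):
            assert (fields[name].values > 0).all()


class TestResponseSoc:
    def test_no_terms_reduces_to_base(self, small_grid):
        from socmap.synthetic import ResponseSpec
        resp = ResponseSpec(base=13.5, terms=[], interactions=[])
        cov = {"no3n": gaussian_random_field(
            small_grid, VariogramModel("spherical", 0, 1, 5.0), 0)}
        soc = response_soc(cov, resp, {}, noise_sd=0.0, seed=0)
        np.testing.assert_allclose(soc.values, 13.5)

    def test_missing_covariate_named_in_error(self):
        cfg = scenario("jiaodong")
        cov = generate_covariates(cfg)
        cov.pop("fe")
        with pytest.raises(KeyError, match="fe"):
            response_soc(cov, cfg.response, cfg.marginals, 0.0, 0)

    def test_noise_free_map_is_deterministic_function(self):
        cfg = scenario("jiaodong", seed=9)
        cov = generate_covariates(cfg)
        a = response_soc(cov, cfg.response, cfg.marginals, 0.0, 1)
        b = response_soc(cov, cfg.response, cfg.marginals, 0.0, 2)
        np.testing.assert_array_equal(a.values, b.values)

    def test_jiaodong_nitrate_step_plateaus(self):
        # conditional means of the noise-free response reproduce the
        # planted nitrate plateaus (13.5 -> 16.0) once averaged over the
        # other covariates
        cfg = scenario("jiaodong", seed=5)
        cov = generate_covariates(cfg)
        soc = response_soc(cov, cfg.response, cfg.marginals, 0.0, 0).values
        no3 = cov["no3n"].values
        low = soc[no3 < 8.0].mean()
        high = soc[no3 > 12.0].mean()
        assert low == pytest.approx(13.5, abs=0.15)
        assert high == pytest.approx(16.0, abs=0.15)


class TestSampleScenario:
    def test_default_sample_sizes(self):
        table_j, _ = sample_scenario(scenario("jiaodong", seed=1))
        table_s, _ = sample_scenario(scenario("southwest", seed=1))
        assert len(table_j) == 144
        assert len(table_s) == 123

    def test_exhaustive_sampling_covers_every_cell(self):
        cfg = scenario("jiaodong", n_sites=400, seed=2, nx=20, ny=20)
        table, truth = sample_scenario(cfg)
        assert len(table) == 400
        assert len(np.unique(truth["cells"])) == 400

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            scenario("jiaodong", n_sites=401, nx=20, ny=20)

    def test_determinism_byte_identical(self):
        t1, _ = sample_scenario(scenario("southwest", seed=7))
        t2, _ = sample_scenario(scenario("southwest", seed=7))
        assert t1.frame.equals(t2.frame)

    def test_soc_within_configured_envelope(self):
        for name in ("jiaodong", "southwest"):
            cfg = scenario(name, seed=3)
            table, truth = sample_scenario(cfg)
            lo, hi = cfg.soc_envelope
            assert table.soc.min() >= lo
            assert table.soc.max() <= hi
            vals = truth["soc_clean"].values
            assert vals.min() >= lo and vals.max() <= hi

    def test_scenario_files_load(self):
        from importlib.resources import files
        from socmap.synthetic import scenario_from_file
        for name in ("jiaodong", "southwest"):
            path = files("socmap") / "scenarios" / f"{name}.yaml"
            cfg = scenario_from_file(str(path))
            assert cfg.name == name


def test_planted_variogram_recoverable_from_dense_sample():
    # the geostat layer recovers the field generator's range within 20%
    cfg = scenario("jiaodong", seed=1)
    from socmap import Variogram
    ranges = []
    xy = cfg.grid.cell_centers_flat()
    rng = np.random.default_rng(0)
    for seed in range(10):
        f = gaussian_random_field(cfg.grid, cfg.field_variograms["no3n"],
                                  seed=seed).values.ravel()
        idx = rng.choice(len(f), 400, replace=False)
        fit = Variogram(xy[idx], f[idx]).fit(select="wls")
        ranges.append(fit.model.range_)
    assert np.median(ranges) == pytest.approx(42.6, rel=0.20)


def test_sigmoid_clipping_stable():
    assert _sigmoid(1e6) >= 1 - 1e-15
    assert _sigmoid(-1e6) < 1e-20
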