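import json

import numpy as np
import pytest

from tado2i import (
    CalibrationDataset,
    DegenerateDataError,
    ParameterError,
    ParseError,
    bootstrap_coefficients,
    fit_quadratic,
    fit_with_bootstrap,
    generate_dataset,
    read_calibration_csv,
    write_fit_json,
    SyntheticSpec,
)

from conftest import CANONICAL, TABLE1, exact_quadratic_ols


class TestDatasetValidation:
    def test_length_mismatch(self):
        with pytest.raises(ParameterError):
            CalibrationDataset([24, 25], [100])

    def test_temperature_bounds(self):
        with pytest.raises(ParameterError):
            CalibrationDataset([19.0, 25, 30, 35], [100, 120, 150, 200])

    def test_positive_do2i(self):
        with pytest.raises(ParameterError):
            CalibrationDataset([24, 25, 30, 35], [100, -5, 150, 200])

    def test_provenance(self):
        with pytest.raises(ParameterError):
            CalibrationDataset([24, 30, 35, 37], [1, 2, 3, 4], provenance="magic")


class TestFitQuadratic:
    def test_noise_free_self_fit(self, canonical_dataset):
        fit = fit_quadratic(canonical_dataset)
        for got, want in zip(fit.coeffs.as_tuple(), CANONICAL):
            assert got == pytest.approx(want, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.see == pytest.approx(0.0, abs=1e-9)

    def test_table_q10_points_fit_closely(self):
        temps = sorted(TABLE1)
        q10_vals = [TABLE1[t][1] for t in temps]
        data = CalibrationDataset(temps, q10_vals)
        fit = fit_quadratic(data)
        assert fit.r_squared > 0.99
        # independent exact normal-equations oracle
        a, b, c = exact_quadratic_ols(temps, q10_vals)
        assert fit.coeffs.a == pytest.approx(a, rel=1e-8)
        assert fit.coeffs.b == pytest.approx(b, rel=1e-8)
        assert fit.coeffs.c == pytest.approx(c, rel=1e-8)

    def test_single_temperature_degenerate(self):
        data = CalibrationDataset([30, 30, 30, 30], [150, 151, 152, 153])
        with pytest.raises(DegenerateDataError):
            fit_quadratic(data)

    def test_two_distinct_temperatures_degenerate(self):
        data = CalibrationDataset([30, 30, 35, 35], [150, 151, 250, 251])
        with pytest.raises(DegenerateDataError):
            fit_quadratic(data)

    def test_too_few_points(self):
        with pytest.raises(DegenerateDataError):
            fit_quadratic(CalibrationDataset([25, 30, 35], [100, 150, 250]))

    def test_see_uses_n_minus_3(self):
        rng = np.random.default_rng(5)
        temps = np.linspace(24, 37, 10)
        y = 2.0 * temps + 50 + rng.normal(0, 2, 10)
        data = CalibrationDataset(temps, y)
        fit = fit_quadratic(data)
        a, b, c = exact_quadratic_ols(temps, y)
        resid = y - (a * temps**2 + b * temps + c)
        assert fit.see == pytest.approx(np.sqrt(resid @ resid / (10 - 3)), rel=1e-7)

    def test_oracle_equivalence_on_noisy_data(self):
        rng = np.random.default_rng(11)
        temps = np.repeat(np.linspace(24, 37, 14), 2)
        y = np.maximum(1.0, 150 + 10 * (temps - 30) + rng.normal(0, 5, temps.size))
        fit = fit_quadratic(CalibrationDataset(temps, y))
        oracle = exact_quadratic_ols(temps, y)
        for got, want in zip((fit.coeffs.a, fit.coeffs.b, fit.coeffs.c), oracle):
            assert got == pytest.approx(want, rel=1e-8)

    def test_r_squared_invariant_under_y_scaling(self, canonical_dataset):
        d = generate_dataset(SyntheticSpec(seed=3))
        scaled = CalibrationDataset(d.temp_c, d.do2i_per_m2 * 0.5)
        assert fit_quadratic(scaled).r_squared == pytest.approx(
            fit_quadratic(d).r_squared, abs=1e-12
        )


class TestBootstrap:
    def test_noise_free_intervals_degenerate(self, canonical_dataset):
        ci, _ = bootstrap_coefficients(canonical_dataset, n_resamples=200, seed=0)
        for name, want in zip("abc", CANONICAL):
            lo, hi = ci[name]
            assert hi - lo < 1e-6
            assert lo - 1e-6 <= want <= hi + 1e-6

    def test_seed_reproducibility(self):
        data = generate_dataset(SyntheticSpec(seed=42))
        ci1, n1 = bootstrap_coefficients(data, n_resamples=1000, seed=7)
        ci2, n2 = bootstrap_coefficients(data, n_resamples=1000, seed=7)
        assert ci1 == ci2
        assert n1 == n2

    def test_containment_of_point_estimates(self):
        data = generate_dataset(SyntheticSpec(seed=42))
        fit = fit_with_bootstrap(data, n_resamples=1000, seed=7)
        point = {"a": fit.coeffs.a, "b": fit.coeffs.b, "c": fit.coeffs.c}
        for name, (lo, hi) in fit.ci.items():
            assert lo <= point[name] <= hi

    def test_different_seeds_differ_but_overlap(self):
        data = generate_dataset(SyntheticSpec(seed=42))
        fit = fit_quadratic(data)
        ci1, _ = bootstrap_coefficients(data, n_resamples=500, seed=1)
        ci2, _ = bootstrap_coefficients(data, n_resamples=500, seed=2)
        assert ci1 != ci2
        point = dict(zip("abc", fit.coeffs.as_tuple()))
        for ci in (ci1, ci2):
            for name, (lo, hi) in ci.items():
                assert lo <= point[name] <= hi

    def test_minimum_sizes(self):
        small = CalibrationDataset([24, 27, 30, 33, 36], [100, 130, 170, 220, 280])
        with pytest.raises(ParameterError):
            bootstrap_coefficients(small, n_resamples=200, seed=0)
        data = generate_dataset(SyntheticSpec(seed=0))
        with pytest.raises(ParameterError):
            bootstrap_coefficients(data, n_resamples=50, seed=0)

    def test_parameter_recovery_within_bootstrap_se(self):
        # canonical quadratic + sd-3 noise on the 27-point grid: each
        # coefficient recovered within 3 bootstrap SEs for >= 90% of replicates
        hits = np.zeros(3)
        n_rep = 25
        for seed in range(n_rep):
            data = generate_dataset(SyntheticSpec(generator_model="quadratic", seed=seed))
            fit = fit_with_bootstrap(data, n_resamples=400, seed=seed + 1000)
            for i, name in enumerate("abc"):
                lo, hi = fit.ci[name]
                se = (hi - lo) / (2 * 1.96)
                point = dict(zip("abc", fit.coeffs.as_tuple()))[name]
                hits[i] += abs(point - CANONICAL[i]) <= 3 * se
        assert np.all(hits / n_rep >= 0.9)


class TestIO:
    def test_csv_roundtrip(self, tmp_path):
        path = tmp_path / "cal.csv"
        path.write_text("temp_c,do2i_per_m2\n24,100.5\n30,180.25\n35,250\n37,281.7\n")
        data = read_calibration_csv(path)
        assert len(data) == 4
        assert data.temp_c[0] == 24.0
        assert data.do2i_per_m2[1] == 180.25

    def test_comment_lines_skipped(self, tmp_path):
        path = tmp_path / "cal.csv"
        path.write_text("# provenance\ntemp_c,do2i_per_m2\n24,100\n30,180\n35,250\n37,281\n")
        assert len(read_calibration_csv(path)) == 4

    def test_missing_column(self, tmp_path):
        path = tmp_path / "cal.csv"
        path.write_text("temperature,do2i\n24,100\n")
        with pytest.raises(ParseError, match="missing required column"):
            read_calibration_csv(path)

    def test_bad_value_names_line(self, tmp_path):
        path = tmp_path / "cal.csv"
        path.write_text("temp_c,do2i_per_m2\n24,100\n30,oops\n35,250\n37,281\n")
        with pytest.raises(ParseError, match="line 3"):
            read_calibration_csv(path)

    def test_fit_json_report(self, tmp_path):
        data = generate_dataset(SyntheticSpec(seed=9))
        fit = fit_with_bootstrap(data, n_resamples=200, seed=4)
        out = tmp_path / "fit.json"
        write_fit_json(fit, out)
        loaded = json.loads(out.read_text())
        assert set(loaded) >= {"coefficients", "r_squared", "see", "n", "ci", "seed"}
        assert loaded["n"] == 27
        assert loaded["n_resamples"] == 200
        assert loaded["coefficients"]["a"] == fit.coeffs.a
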