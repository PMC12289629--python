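"""Calibration workflow: MLR/PLSR fitting, screening, evaluation."""

from __future__ import annotations

import numpy as np
import pytest

from chloroleaf import (
    FEATURE_NAMES,
    CalibrationDataset,
    CalibrationRow,
    SensorReading,
    compare_single_index,
    default_models,
    evaluate,
    extract_features,
    fit_mlr,
    fit_plsr,
    predict,
    select_significant,
)
from chloroleaf.calibration import read_fit_report, write_fit_report
from chloroleaf.errors import (
    CollinearityError,
    EmptyInputError,
    ParameterError,
    SampleSizeError,
)
from chloroleaf.models import LinearModel
from chloroleaf.synthetic import GeneratorConfig, generate_calibration_dataset

FIVE = ["b", "b_raw", "h", "s", "v"]

TRUE_CLA = {"b": 1.143, "b_raw": -0.225, "h": 0.008, "s": 85.096, "v": -170.899}
TRUE_CLB = {"b": 0.467, "b_raw": -0.052, "h": 0.005, "s": 35.536, "v": -72.08}


@pytest.fixture(scope="module")
def noiseless_data() -> CalibrationDataset:
    return generate_calibration_dataset(GeneratorConfig(n_samples=60, noise_sd=0.0, seed=3))


@pytest.fixture(scope="module")
def noisy_data() -> CalibrationDataset:
    return generate_calibration_dataset(GeneratorConfig(n_samples=80, noise_sd=0.05, seed=7))


def _dataset_from_xy(x: np.ndarray, y: np.ndarray, feature: str = "h") -> CalibrationDataset:
    """Tiny dataset whose chosen feature carries x and target tcl carries y."""
    rows = []
    for i, (xi, yi) in enumerate(zip(x, y)):
        reading = SensorReading(25.0 + 0.01 * i, 24.0, 18.0, 80.0)
        feats = extract_features(reading).as_dict()
        feats[feature] = float(xi)
        from chloroleaf.colorspace import ColorFeatures

        rows.append(
            CalibrationRow(
                sample_id=f"s{i}",
                features=ColorFeatures(**feats),
                cla=max(float(yi), 1e-6) / 2,
                clb=max(float(yi), 1e-6) / 2,
                tcl=max(float(yi), 1e-6),
                crop="wheat",
            )
        )
    return CalibrationDataset(tuple(rows))


class TestFitMLR:
    def test_exact_recovery_of_planted_model(self, noiseless_data):
        """Noiseless data generated from the production chlorophyll-a
        equation returns its coefficients to 1e-6."""
        result = fit_mlr(noiseless_data, "chlorophyll_a", FIVE)
        assert result.model.intercept == pytest.approx(-30.623, abs=1e-6)
        for name, want in TRUE_CLA.items():
            assert result.model.coefficients[name] == pytest.approx(want, abs=1e-6)
        assert result.rmse == pytest.approx(0.0, abs=1e-8)
        assert result.r2 == pytest.approx(1.0, abs=1e-10)

    def test_constant_target(self):
        x = np.linspace(0.0, 10.0, 12)
        y = np.full(12, 2.5)
        data = _dataset_from_xy(x, y)
        result = fit_mlr(data, "total_chlorophyll", ["h"])
        assert result.model.intercept == pytest.approx(2.5, abs=1e-9)
        assert result.model.coefficients["h"] == pytest.approx(0.0, abs=1e-10)
        assert result.rmse == pytest.approx(0.0, abs=1e-9)

    def test_duplicated_feature_raises_collinearity(self, noisy_data):
        with pytest.raises(CollinearityError):
            fit_mlr(noisy_data, "chlorophyll_a", ["b", "b", "h"])

    def test_insufficient_samples(self, noisy_data):
        tiny = CalibrationDataset(noisy_data.rows[:4])
        with pytest.raises(SampleSizeError):
            fit_mlr(tiny, "chlorophyll_a", FIVE)

    def test_mae_not_above_rmse(self, noisy_data):
        result = fit_mlr(noisy_data, "chlorophyll_b", FIVE)
        assert result.mae <= result.rmse + 1e-12
        assert all(0.0 <= p <= 1.0 for p in result.pvalues.values())

    def test_parameter_recovery_within_three_se(self):
        """Planted chlorophyll-b coefficients are recovered within 3
        standard errors in at least 95% of 100 seeded replications
        (200 samples, N(0, 0.05) noise)."""
        import statsmodels.api as sm

        true = dict(TRUE_CLB, intercept=-13.164)
        ok = 0
        for seed in range(100):
            data = generate_calibration_dataset(
                GeneratorConfig(n_samples=200, noise_sd=0.05, seed=1000 + seed)
            )
            X = sm.add_constant(data.feature_matrix(FIVE))
            y = data.target_vector("chlorophyll_b")
            fit = sm.OLS(y, X).fit()
            names = ["intercept"] + FIVE
            truth = [true["intercept"]] + [TRUE_CLB[f] for f in FIVE]
            within = all(
                abs(est - t) <= 3 * se
                for est, t, se in zip(fit.params, truth, fit.bse)
            )
            ok += within
        assert ok >= 95


class TestFitPLSR:
    def test_full_components_match_mlr_predictions(self, noisy_data):
        """Classical PLS/OLS equivalence at the full component count."""
        mlr = fit_mlr(noisy_data, "chlorophyll_a", FIVE)
        pls = fit_plsr(noisy_data, "chlorophyll_a", FIVE, n_components=5)
        X = noisy_data.feature_matrix(FIVE)
        pred_mlr = X @ np.array([mlr.model.coefficients[f] for f in FIVE]) + mlr.model.intercept
        pred_pls = X @ np.array([pls.model.coefficients[f] for f in FIVE]) + pls.model.intercept
        assert np.max(np.abs(pred_mlr - pred_pls)) < 1e-8

    def test_single_component_on_proportional_target(self):
        x = np.linspace(1.0, 20.0, 15)
        data = _dataset_from_xy(x, 0.2 * x)
        result = fit_plsr(data, "total_chlorophyll", ["h"], n_components=1)
        assert result.rmse == pytest.approx(0.0, abs=1e-9)

    def test_fitting_rmse_nonincreasing_in_components(self, noisy_data):
        rmses = [
            fit_plsr(noisy_data, "total_chlorophyll", FIVE, n_components=k).rmse
            for k in range(1, 6)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(rmses, rmses[1:]))

    def test_out_of_range_components(self, noisy_data):
        with pytest.raises(ParameterError):
            fit_plsr(noisy_data, "chlorophyll_a", FIVE, n_components=6)

    def test_auto_component_selection_reported(self, noisy_data):
        result = fit_plsr(noisy_data, "chlorophyll_a", FIVE)
        assert result.n_components is not None
        assert 1 <= result.n_components <= 5


class TestSelectSignificant:
    def test_published_significance_row(self):
        """The chlorophyll-a coefficient screen keeps the two blue terms
        and hue at alpha = 0.05."""
        pvalues = {"b": 0.0005, "b_raw": 0.004, "h": 0.012, "s": 0.060, "v": 0.087}
        kept = select_significant(pvalues, alpha=0.05)
        assert set(kept) == {"b", "b_raw", "h"}
        # canonical feature order: raw channels before normalized indices
        assert kept == ["b_raw", "b", "h"]

    def test_nothing_significant(self):
        assert select_significant(dict.fromkeys(FIVE, 0.5), alpha=0.05) == []

    def test_alpha_one_keeps_all_in_canonical_order(self):
        pvalues = {"v": 0.9, "b": 0.9, "h": 0.9}
        kept = select_significant(pvalues, alpha=0.999999)
        assert kept == ["b", "h", "v"]  # canonical feature order

    def test_bad_alpha(self):
        with pytest.raises(ParameterError):
            select_significant({"b": 0.01}, alpha=0.0)


class TestEvaluate:
    def test_perfect_model_on_its_own_data(self, noiseless_data):
        cla = default_models()[0]
        metrics = evaluate(cla, noiseless_data, "chlorophyll_a")
        assert metrics["rmse"] == pytest.approx(0.0, abs=1e-9)
        assert metrics["r2"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_bias_gives_rmse_equal_mae(self, noiseless_data):
        cla = default_models()[0]
        shifted = LinearModel(
            "chlorophyll_a",
            cla.intercept + 0.25,
            dict(cla.coefficients),
            cla.feature_order,
        )
        metrics = evaluate(shifted, noiseless_data, "chlorophyll_a")
        assert metrics["rmse"] == pytest.approx(0.25, abs=1e-9)
        assert metrics["mae"] == pytest.approx(0.25, abs=1e-9)

    def test_agrees_with_two_pass_oracle_on_small_fixture(self, noisy_data):
        """Hand-coded two-pass mean/SSE computation, 5 rows, 1e-12."""
        small = CalibrationDataset(noisy_data.rows[:5])
        model = default_models()[2]
        metrics = evaluate(model, small, "total_chlorophyll")
        y = [row.tcl for row in small.rows]
        yhat = [predict(model, row.features) for row in small.rows]
        mean_y = sum(y) / len(y)
        sse = sum((a - b) ** 2 for a, b in zip(y, yhat))
        sst = sum((a - mean_y) ** 2 for a in y)
        assert metrics["rmse"] == pytest.approx((sse / len(y)) ** 0.5, abs=1e-12)
        assert metrics["mae"] == pytest.approx(
            sum(abs(a - b) for a, b in zip(y, yhat)) / len(y), abs=1e-12
        )
        assert metrics["r2"] == pytest.approx(1 - sse / sst, abs=1e-12)

    def test_rmse_converges_to_noise_sd_at_large_n(self):
        """On data with planted N(0, sigma) content noise, the production
        model's RMSE estimates sigma within 5% at n = 10^4."""
        sigma = 0.05
        data = generate_calibration_dataset(
            GeneratorConfig(n_samples=10_000, noise_sd=sigma, seed=11)
        )
        metrics = evaluate(default_models()[0], data, "chlorophyll_a")
        assert metrics["rmse"] == pytest.approx(sigma, rel=0.05)

    def test_empty_dataset_rejected(self):
        with pytest.raises(EmptyInputError):
            evaluate(default_models()[0], CalibrationDataset(()), "chlorophyll_a")


class TestNestedModels:
    def test_five_feature_rmse_not_below_twenty_feature(self, noisy_data):
        """Adding features can only lower fitting-set RMSE (and raise R2)."""
        for target in ("chlorophyll_a", "chlorophyll_b", "total_chlorophyll"):
            five = fit_mlr(noisy_data, target, FIVE)
            full = fit_mlr(noisy_data, target, list(FEATURE_NAMES))
            assert five.rmse >= full.rmse - 1e-12
            assert five.r2 <= full.r2 + 1e-12


class TestCompareSingleIndex:
    def test_exact_line(self):
        x = np.linspace(0.0, 10.0, 12)
        data = _dataset_from_xy(x, 2.0 * x + 1.0)
        result = compare_single_index(data, "h", "total_chlorophyll")
        assert result.model.coefficients["h"] == pytest.approx(2.0, abs=1e-9)
        assert result.model.intercept == pytest.approx(1.0, abs=1e-9)
        assert result.rmse == pytest.approx(0.0, abs=1e-9)

    def test_single_index_never_beats_five_feature_fit(self, noisy_data):
        single = compare_single_index(noisy_data, "b", "total_chlorophyll")
        five = fit_mlr(noisy_data, "total_chlorophyll", FIVE)
        assert single.rmse >= five.rmse - 1e-12

    def test_planted_slope_recovered_within_three_se(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(0.0, 50.0, 100)
        y = 0.05 * x + 1.0 + rng.normal(0.0, 0.1, 100)
        data = _dataset_from_xy(x, y)
        result = compare_single_index(data, "h", "total_chlorophyll")
        import statsmodels.api as sm

        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert abs(result.model.coefficients["h"] - 0.05) <= 3 * fit.bse[1]

    def test_spad_style_baseline_column(self, noisy_data):
        """A SPAD-like auxiliary column regresses through the same path."""
        rows = tuple(
            CalibrationRow(
                sample_id=r.sample_id,
                features=r.features,
                cla=r.cla,
                clb=r.clb,
                tcl=r.tcl,
                crop=r.crop,
                spad=10.0 + 15.0 * r.tcl,
            )
            for r in noisy_data.rows
        )
        data = CalibrationDataset(rows)
        result = compare_single_index(data, "spad", "total_chlorophyll")
        assert result.rmse == pytest.approx(0.0, abs=1e-9)


class TestFitReportRoundTrip:
    def test_report_round_trips(self, tmp_path, noisy_data):
        result = fit_mlr(noisy_data, "chlorophyll_a", FIVE)
        path = tmp_path / "report.json"
        write_fit_report(result, path)
        back = read_fit_report(path)
        assert back.model.intercept == result.model.intercept
        assert dict(back.model.coefficients) == dict(result.model.coefficients)
        assert back.pvalues == dict(result.pvalues)
        assert back.r2 == result.r2 and back.rmse == result.rmse
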