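"""Parametric sweeps, the empirical-rule benchmark and pore-array geometry."""

import math

import numpy as np
import pandas as pd
import pytest

from anodpore import dataset_io
from anodpore.regressors import fit_mlr, predict
from anodpore.structure_analysis import (HEX_POROSITY_LIMIT, empirical_rule,
                                         hexagonal_porosity, loading_capacity,
                                         pore_interpore_regression,
                                         predict_conditions, rule_benchmark,
                                         temperature_sensitivity,
                                         voltage_response)
from anodpore.synthetic_data import GeneratorConfig, generate


@pytest.fixture(scope="module")
def oxalic_model():
    """MLR fitted on noise-free data with the 1.29 nm/V oxalic slope."""
    cfg = GeneratorConfig(
        n_records=150, noise_sd=0.0, interpore_noise_sd=0.0,
        missing_rate_T=0.0, missing_rate_t=0.0,
        voltage_slope={"H2SO4": 1.29, "H2C2O4": 1.29, "H3PO4": 1.29},
        intercept={"H2SO4": 10.0, "H2C2O4": 10.0, "H3PO4": 10.0},
        time_range=(10.0, 600.0), seed=21)
    fm = dataset_io.encode(generate(cfg).frame)
    return fit_mlr(fm), fm, cfg


class TestSweeps:
    def test_voltage_slope_recovers_generator(self, oxalic_model):
        model, fm, cfg = oxalic_model
        result = voltage_response(model, fm, "H2C2O4",
                                  np.arange(30.0, 81.0, 5.0))
        assert result.slope == pytest.approx(1.29, abs=1e-8)

    def test_mlr_sweep_is_exactly_affine(self, oxalic_model):
        model, fm, _ = oxalic_model
        result = voltage_response(model, fm, "H2C2O4",
                                  np.arange(30.0, 81.0, 5.0))
        diffs = np.diff(result.predictions) / np.diff(result.grid)
        assert np.ptp(diffs) < 1e-9

    def test_temperature_slope_recovers_generator(self, oxalic_model):
        model, fm, cfg = oxalic_model
        result = temperature_sensitivity(model, fm, "H2C2O4",
                                         np.arange(0.0, 31.0, 1.0),
                                         voltage=40.0)
        assert result.slope == pytest.approx(cfg.temperature_slope, abs=1e-8)

    def test_cooling_by_20C_grows_pores_6_to_10_nm(self, oxalic_model):
        # slope −0.4 nm/°C over a 20 °C drop: +8 nm, inside the 6–10 nm band
        model, fm, _ = oxalic_model
        result = temperature_sensitivity(model, fm, "H2C2O4",
                                         np.array([0.0, 20.0]), voltage=40.0)
        growth = result.predictions[0] - result.predictions[1]
        assert 6.0 <= growth <= 10.0

    def test_zero_temperature_effect_gives_zero_slope(self):
        cfg = GeneratorConfig(n_records=100, noise_sd=0.0,
                              temperature_slope=0.0, missing_rate_T=0.0,
                              missing_rate_t=0.0, time_range=(10.0, 600.0),
                              voltage_slope={"H2SO4": 1.29, "H2C2O4": 1.29,
                                             "H3PO4": 1.29}, seed=3)
        fm = dataset_io.encode(generate(cfg).frame)
        result = temperature_sensitivity(fit_mlr(fm), fm, "H2C2O4",
                                         np.arange(0.0, 31.0, 5.0),
                                         voltage=40.0)
        assert result.slope == pytest.approx(0.0, abs=1e-8)

    def test_default_calibration_slope_in_literature_band(self):
        cfg = GeneratorConfig(seed=8)
        df = generate(cfg).frame
        fm = dataset_io.encode(dataset_io.complete_cases(df))
        result = voltage_response(fit_mlr(fm), fm, "H2C2O4",
                                  np.arange(30.0, 81.0, 5.0))
        assert 1.0 <= result.slope <= 1.5

    def test_extrapolation_warns(self, oxalic_model):
        model, fm, _ = oxalic_model
        with pytest.warns(UserWarning, match="support"):
            voltage_response(model, fm, "H2C2O4",
                             np.array([300.0, 400.0]))

    def test_non_increasing_grid_rejected(self, oxalic_model):
        model, fm, _ = oxalic_model
        with pytest.raises(ValueError, match="increasing"):
            voltage_response(model, fm, "H2C2O4", np.array([40.0, 40.0]))


class TestEmpiricalRule:
    @pytest.mark.parametrize("V,expected", [(0.0, 0.0), (40.0, 51.6),
                                            (100.0, 129.0)])
    def test_proportionality(self, V, expected):
        assert empirical_rule(V) == pytest.approx(expected)

    def test_negative_voltage_rejected(self):
        with pytest.raises(ValueError):
            empirical_rule(-1.0)


class TestRuleBenchmark:
    def test_rule_is_truth_when_generator_matches(self, oxalic_model):
        # slope exactly 1.29 but nonzero intercept/temperature term, so the
        # rule is close; with intercept 10 − 0.4·T the model must win
        model, fm, _ = oxalic_model
        df = fm.raw_frame()
        oxalic = df[df["electrolyte"] == "H2C2O4"]
        out = rule_benchmark(model, fm, oxalic)
        assert out["rmse_model"] <= out["rmse_rule"]
        assert out["rmse_model"] == pytest.approx(0.0, abs=1e-8)

    def test_pure_rule_data_gives_zero_rmse(self):
        cfg = GeneratorConfig(
            n_records=60, noise_sd=0.0, temperature_slope=0.0,
            time_slope=0.0, missing_rate_T=0.0, missing_rate_t=0.0,
            voltage_slope={"H2SO4": 1.29, "H2C2O4": 1.29, "H3PO4": 1.29},
            intercept={"H2SO4": 0.0, "H2C2O4": 0.0, "H3PO4": 0.0},
            time_range=(10.0, 600.0), seed=4)
        fm = dataset_io.encode(generate(cfg).frame)
        model = fit_mlr(fm)
        df = fm.raw_frame()
        out = rule_benchmark(model, fm, df[df["electrolyte"] == "H2C2O4"])
        assert out["rmse_rule"] == pytest.approx(0.0, abs=1e-9)
        assert out["rmse_model"] == pytest.approx(0.0, abs=1e-6)

    def test_model_beats_rule_with_temperature_effect(self):
        cfg = GeneratorConfig(n_records=200, noise_sd=5.0,
                              missing_rate_T=0.0, missing_rate_t=0.0,
                              time_range=(10.0, 600.0), seed=6)
        fm = dataset_io.encode(generate(cfg).frame)
        model = fit_mlr(fm)
        df = fm.raw_frame()
        out = rule_benchmark(model, fm, df[df["electrolyte"] == "H2C2O4"])
        assert out["rmse_model"] <= out["rmse_rule"]

    def test_empty_subset_errors(self, oxalic_model):
        model, fm, _ = oxalic_model
        with pytest.raises(ValueError, match="empty"):
            rule_benchmark(model, fm, fm.raw_frame().iloc[:0])


class TestPoreInterporeRegression:
    def test_exact_line(self):
        D = np.array([50.0, 100.0, 200.0, 400.0])
        df = pd.DataFrame({"interpore_distance_nm": D,
                           "pore_diameter_nm": 0.35 * D})
        out = pore_interpore_regression(df)
        assert out["slope"] == pytest.approx(0.35)
        assert out["r2"] == pytest.approx(1.0)

    def test_generator_default_ratio_recovered(self, default_dataset):
        out = pore_interpore_regression(default_dataset.frame)
        assert out["slope"] == pytest.approx(0.35, abs=0.03)
        assert out["r2"] > 0.8

    def test_uncorrelated_noise_near_zero_r2(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"interpore_distance_nm": rng.uniform(50, 500, 400),
                           "pore_diameter_nm": rng.uniform(10, 300, 400)})
        assert pore_interpore_regression(df)["r2"] < 0.05

    def test_too_few_pairs(self):
        df = pd.DataFrame({"interpore_distance_nm": [100.0, 200.0],
                           "pore_diameter_nm": [35.0, 70.0]})
        with pytest.raises(ValueError):
            pore_interpore_regression(df)


class TestGeometry:
    def test_close_packing_limit(self):
        assert hexagonal_porosity(99.999999, 100.0) == pytest.approx(
            HEX_POROSITY_LIMIT, rel=1e-6)
        assert HEX_POROSITY_LIMIT == pytest.approx(0.9069, abs=5e-5)

    def test_zero_diameter(self):
        assert hexagonal_porosity(0.0, 100.0) == 0.0

    def test_typical_ratio(self):
        # d/D = 0.35 -> 0.9069 * 0.1225 = 0.1111
        assert hexagonal_porosity(35.0, 100.0) == pytest.approx(0.1111,
                                                                abs=5e-5)

    def test_strictly_increasing_in_ratio(self):
        ratios = np.linspace(0.01, 0.9, 50)
        values = [hexagonal_porosity(r * 100.0, 100.0) for r in ratios]
        assert np.all(np.diff(values) > 0)
        assert values[-1] < HEX_POROSITY_LIMIT

    def test_merged_pores_rejected(self):
        with pytest.raises(ValueError, match="merge"):
            hexagonal_porosity(100.0, 100.0)

    def test_loading_hand_value(self):
        # porosity 0.1, 10 um depth, 100 mg/mL -> 10 ug/cm2
        d, D = 35.0, 100.0
        eps = hexagonal_porosity(d, D)
        load = loading_capacity(d, D, 10.0, 100.0)
        assert load == pytest.approx(eps * 10e-4 * 100 * 1000)
        assert loading_capacity(33.2055, 100.0, 10.0, 100.0) == pytest.approx(
            10.0, abs=0.01)  # ratio giving eps = 0.1

    def test_loading_linear_in_depth(self):
        one = loading_capacity(35.0, 100.0, 5.0, 100.0)
        two = loading_capacity(35.0, 100.0, 10.0, 100.0)
        assert two == pytest.approx(2 * one)
        assert loading_capacity(35.0, 100.0, 0.0, 100.0) == 0.0


def test_predict_conditions_matches_manual_encoding(oxalic_model):
    model, fm, cfg = oxalic_model
    pred = predict_conditions(model, fm, "H2C2O4", 40.0, 10.0, 60.0)
    expected = (10.0 + 1.29 * 40.0 + cfg.temperature_slope * 10.0)
    assert pred[0] == pytest.approx(expected, abs=1e-8)
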