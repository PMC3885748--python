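"""Stepwise fitting, prediction, and model comparison."""

import json
import math

import numpy as np
import pytest

from pbtransfer.bcf_core import BCFRecord
from pbtransfer.soil_data import SoilDataError, SoilProfile
from pbtransfer.synthetic_data import gen_bcf_records, gen_soils, SyntheticConfig
from pbtransfer.transfer_model import (
    TransferModel,
    compare_models,
    fit_forced,
    fit_stepwise,
    load_model,
    model_from_dict,
    model_to_dict,
    predict_log_bcf,
    save_model,
)


def _records_from(panel, truth, seed=0, noise_sd=0.0):
    records, _ = gen_bcf_records(
        panel, truth, species_offsets={}, noise_sd=noise_sd, seed=seed, levels=("low",)
    )
    return records


def _ols_oracle(records, panel, predictors):
    """Textbook normal-equations least squares on a fixed predictor set."""
    by_id = {s.soil_id: s for s in panel}
    value = {
        "pH": lambda s: s.ph,
        "logOM": lambda s: math.log10(s.om),
        "logCEC": lambda s: math.log10(s.cec),
    }
    x = np.column_stack(
        [np.ones(len(records))]
        + [[value[p](by_id[r.soil_id]) for r in records] for p in predictors]
    )
    y = np.array([r.log_bcf for r in records])
    beta = np.linalg.solve(x.T @ x, x.T @ y)
    return beta  # [intercept, *slopes]


class TestStepwise:
    def test_noiseless_recovery_of_low_dose_model(self, panel, model1, noiseless_bcf):
        """Exact data from the published low-dose equation over the 17-soil
        panel must be recovered coefficient-for-coefficient."""
        fit = fit_stepwise(noiseless_bcf, panel, level_label="low")
        assert fit.selected == ("pH", "logOM")
        assert fit.a == pytest.approx(-0.098, abs=1e-8)
        assert fit.b == pytest.approx(-0.150, abs=1e-8)
        assert fit.c == 0.0
        assert fit.k == pytest.approx(-1.894, abs=1e-8)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)
        assert fit.p_value < 1e-6

    def test_noiseless_cec_only_model_selects_cec_only(self, panel):
        truth = TransferModel(c=-0.5, k=-2.0, selected=("logCEC",))
        fit = fit_stepwise(_records_from(panel, truth), panel)
        assert fit.selected == ("logCEC",)
        assert fit.c == pytest.approx(-0.5, abs=1e-8)
        assert fit.a == 0.0 and fit.b == 0.0

    def test_matches_normal_equations_on_true_set(self, panel, model1):
        """With noise, the stepwise end point on the true predictors equals
        the closed-form least-squares solution."""
        records = _records_from(panel, model1, seed=3, noise_sd=0.05)
        fit = fit_forced(records, panel, ("pH", "logOM"))
        beta = _ols_oracle(records, panel, ("pH", "logOM"))
        assert fit.k == pytest.approx(beta[0], abs=1e-8)
        assert fit.a == pytest.approx(beta[1], abs=1e-8)
        assert fit.b == pytest.approx(beta[2], abs=1e-8)

    def test_r2_never_decreases_with_added_predictor(self, panel, model1):
        records = _records_from(panel, model1, seed=5, noise_sd=0.1)
        r2 = [
            fit_forced(records, panel, preds).r2
            for preds in [("pH",), ("pH", "logOM"), ("pH", "logOM", "logCEC")]
        ]
        assert r2[0] <= r2[1] + 1e-12 and r2[1] <= r2[2] + 1e-12

    def test_selected_predictors_respect_alpha_thresholds(self, panel, model1):
        """Every retained predictor is significant at the removal threshold
        in the final model."""
        from scipy import stats as sps
        import statsmodels.api as sm

        records = _records_from(panel, model1, seed=9, noise_sd=0.1)
        fit = fit_stepwise(records, panel, alpha_enter=0.05, alpha_remove=0.10)
        assert fit.selected  # pH signal is strong at this noise level
        refit = fit_forced(records, panel, fit.selected)
        beta = _ols_oracle(records, panel, fit.selected)
        y = np.array([r.log_bcf for r in records])
        by_id = {s.soil_id: s for s in panel}
        value = {"pH": lambda s: s.ph, "logOM": lambda s: math.log10(s.om),
                 "logCEC": lambda s: math.log10(s.cec)}
        x = sm.add_constant(np.column_stack(
            [[value[p](by_id[r.soil_id]) for r in records] for p in fit.selected]
        ))
        res = sm.OLS(y, x).fit()
        assert all(p <= 0.10 + 1e-12 for p in res.pvalues[1:])
        assert refit.k == pytest.approx(beta[0], abs=1e-8)

    def test_pure_noise_gives_intercept_only(self, panel):
        rng = np.random.default_rng(1)
        records = [
            BCFRecord(s.soil_id, "Zhengdan 958", "low", 10.0 ** v, v)
            for s, v in zip(panel, rng.normal(-2.5, 0.3, len(panel)))
        ]
        fit = fit_stepwise(records, panel)
        assert fit.selected == ()
        assert fit.a == fit.b == fit.c == 0.0
        assert fit.k == pytest.approx(np.mean([r.log_bcf for r in records]), abs=1e-10)

    def test_too_few_records_rejected(self, panel, model1):
        records = _records_from(panel, model1)[:4]
        with pytest.raises(SoilDataError, match="at least 5"):
            fit_stepwise(records, panel)

    def test_alpha_ordering_enforced(self, panel, noiseless_bcf):
        with pytest.raises(SoilDataError, match="alpha"):
            fit_stepwise(noiseless_bcf, panel, alpha_enter=0.2, alpha_remove=0.1)


class TestPredict:
    def test_literature_soil_predictions(self, model1):
        """The low-dose equation evaluated at the two literature soils."""
        soil1 = SoilProfile(soil_id="Lit1", ph=6.3, om=17.6, cec=22.6)
        soil2 = SoilProfile(soil_id="Lit2", ph=5.9, om=38.6)
        lb1 = predict_log_bcf(model1, soil1)
        lb2 = predict_log_bcf(model1, soil2)
        assert lb1 == pytest.approx(-2.6982269, abs=1e-6)
        assert 10.0 ** lb1 == pytest.approx(0.0020034, abs=1e-6)
        assert lb2 == pytest.approx(-2.7101881, abs=1e-6)
        assert 10.0 ** lb2 == pytest.approx(0.0019490, abs=1e-6)

    def test_negative_ph_slope_orders_predictions(self, model1):
        acid = SoilProfile(soil_id="A", ph=5.0, om=20.0, cec=20.0)
        alkaline = SoilProfile(soil_id="B", ph=8.0, om=20.0, cec=20.0)
        assert predict_log_bcf(model1, acid) > predict_log_bcf(model1, alkaline)

    def test_missing_required_property_rejected(self):
        model = TransferModel(c=-0.5, k=-2.0, selected=("logCEC",))
        with pytest.raises(SoilDataError, match="CEC"):
            predict_log_bcf(model, SoilProfile(soil_id="X", ph=7.0, om=20.0))


class TestCompareModels:
    def test_identical_models_differ_nowhere(self, panel, model1):
        cmp = compare_models(model1, model1, panel)
        assert all(d == 0.0 for d in cmp.differences)
        assert cmp.mean_abs_diff == 0.0

    def test_published_dose_models_agree_closely(self, panel, model1, model2):
        """The low- and high-dose equations predict nearly the same log BCF
        across the full panel."""
        cmp = compare_models(model1, model2, panel)
        assert cmp.mean_abs_diff < 0.15

    def test_intercept_shift_gives_constant_difference(self, panel, model1):
        shifted = TransferModel(
            a=model1.a, b=model1.b, k=model1.k + 0.25, selected=model1.selected
        )
        cmp = compare_models(model1, shifted, panel)
        assert all(d == pytest.approx(-0.25, abs=1e-12) for d in cmp.differences)


class TestSerialization:
    def test_json_round_trip(self, tmp_path, panel, model1, noiseless_bcf):
        fit = fit_stepwise(noiseless_bcf, panel, level_label="low")
        path = tmp_path / "model.json"
        save_model(fit, path)
        again = load_model(path)
        assert again == fit
        data = json.loads(path.read_text())
        assert set(data) == {
            "level_label", "a", "b", "c", "k", "selected", "r2", "p_value", "n",
        }

    def test_unselected_nonzero_coefficient_rejected(self):
        with pytest.raises(SoilDataError):
            model_from_dict({"k": -2.0, "a": -0.1, "selected": []})

    def test_dict_round_trip(self, model1):
        assert model_from_dict(model_to_dict(model1)) == model1
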