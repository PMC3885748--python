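"""Intercept-only cross-species extrapolation and fold agreement."""

import math

import numpy as np
import pytest

from pbtransfer.bcf_core import BCFRecord
from pbtransfer.cross_species import (
    evaluate_fold_agreement,
    fit_species_intercept,
)
from pbtransfer.datasets import literature_validation_records
from pbtransfer.soil_data import SoilDataError
from pbtransfer.synthetic_data import gen_bcf_records
from pbtransfer.transfer_model import TransferModel, predict_log_bcf


def _species_records(panel, model, offset, species="Nongda 84", noise_sd=0.0, seed=0):
    shifted = TransferModel(
        a=model.a, b=model.b, c=model.c, k=model.k + offset, selected=model.selected
    )
    records, _ = gen_bcf_records(
        panel, shifted, species_offsets={}, noise_sd=noise_sd, seed=seed, levels=("low",)
    )
    return [
        BCFRecord(r.soil_id, species, r.level, r.bcf, r.log_bcf) for r in records
    ]


class TestFitSpeciesIntercept:
    @pytest.mark.parametrize("space", ["log", "linear"])
    def test_noiseless_recovery_of_shifted_intercept(self, panel, model1, space):
        """Records generated with intrinsic sensitivity -2.152 recover it in
        either objective space."""
        records = _species_records(panel, model1, offset=-2.152 - model1.k)
        out = fit_species_intercept(model1, records, panel, space=space)
        assert out.k == pytest.approx(-2.152, abs=1e-4 if space == "linear" else 1e-10)
        assert out.objective == pytest.approx(0.0, abs=1e-8)
        assert out.n == 17

    def test_k_is_mean_of_log_residuals(self, panel, model1):
        base = [predict_log_bcf(model1, s) for s in panel[:2]]
        records = [
            BCFRecord(panel[0].soil_id, "X", "low", 10.0 ** (base[0] + 0.1), base[0] + 0.1),
            BCFRecord(panel[1].soil_id, "X", "low", 10.0 ** (base[1] - 0.1), base[1] - 0.1),
        ]
        out = fit_species_intercept(model1, records, panel, space="log")
        assert out.k == pytest.approx(model1.k, abs=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_closed_form_matches_grid_search_oracle(self, panel, model1, seed):
        """The log-space closed form agrees with an exhaustive grid search
        over k centred on a robust (median-based) start."""
        records = _species_records(panel, model1, offset=-0.3, noise_sd=0.2, seed=seed)
        out = fit_species_intercept(model1, records, panel, space="log")
        terms = np.array(
            [predict_log_bcf(model1, s) - model1.k for s in panel]
        )
        log_meas = np.array([r.log_bcf for r in records])
        center = float(np.median(log_meas - terms))
        grid = np.arange(center - 0.5, center + 0.5, 1e-6)
        sse = ((log_meas[:, None] - (terms[:, None] + grid[None, :])) ** 2).sum(axis=0)
        k_grid = grid[int(np.argmin(sse))]
        assert out.k == pytest.approx(k_grid, abs=1e-5)

    def test_log_objective_convex_in_k(self, panel, model1):
        records = _species_records(panel, model1, offset=-0.2, noise_sd=0.1, seed=6)
        out = fit_species_intercept(model1, records, panel, space="log")
        log_meas = np.array([r.log_bcf for r in records])
        terms = np.array([predict_log_bcf(model1, s) - model1.k for s in panel])

        def sse(k):
            return float(((log_meas - terms - k) ** 2).sum())

        for eps in (1e-3, 1e-2, 0.1):
            assert sse(out.k + eps) > out.objective
            assert sse(out.k - eps) > out.objective

    def test_shifting_measurements_shifts_k(self, panel, model1):
        records = _species_records(panel, model1, offset=-0.1, noise_sd=0.1, seed=7)
        delta = 0.37
        shifted = [
            BCFRecord(r.soil_id, r.species, r.level, r.bcf * 10**delta, r.log_bcf + delta)
            for r in records
        ]
        k0 = fit_species_intercept(model1, records, panel).k
        k1 = fit_species_intercept(model1, shifted, panel).k
        assert k1 - k0 == pytest.approx(delta, abs=1e-10)

    def test_single_record_rejected(self, panel, model1):
        records = _species_records(panel, model1, offset=0.0)[:1]
        with pytest.raises(SoilDataError, match="at least 2"):
            fit_species_intercept(model1, records, panel)


class TestFoldAgreement:
    def test_exact_predictions_cover_fully(self, panel, model1, noiseless_bcf):
        out = evaluate_fold_agreement(model1, noiseless_bcf, panel)
        assert all(d == pytest.approx(1.0, abs=1e-9) for d in out.fold_deviations)
        assert out.coverage == 1.0

    def test_twofold_boundary_counts_as_inside(self, panel, model1):
        soil = panel[0]
        predicted = 10.0 ** predict_log_bcf(model1, soil)
        measured = predicted / 2.0
        record = BCFRecord(soil.soil_id, "X", "low", measured, math.log10(measured))
        out = evaluate_fold_agreement(model1, [record], panel, fold=2.0)
        assert out.fold_deviations[0] == pytest.approx(2.0, rel=1e-12)
        assert out.coverage == 1.0

    def test_literature_soils_within_twofold(self, model1):
        """The two independent literature soils fall inside the 2-fold band
        with deviations 1.00 and 1.23."""
        obs = literature_validation_records()
        soils = [o.soil for o in obs]
        records = [
            BCFRecord(o.soil.soil_id, o.species, "low", o.measured_bcf,
                      math.log10(o.measured_bcf))
            for o in obs
        ]
        out = evaluate_fold_agreement(model1, records, soils, fold=2.0)
        assert out.fold_deviations[0] == pytest.approx(1.00, abs=0.005)
        assert out.fold_deviations[1] == pytest.approx(1.23, abs=0.005)
        assert out.coverage == 1.0

    def test_coverage_nondecreasing_in_threshold(self, panel, model1):
        records = _species_records(panel, model1, offset=-0.3, noise_sd=0.3, seed=8)
        coverages = [
            evaluate_fold_agreement(model1, records, panel, fold=f).coverage
            for f in (1.0, 1.5, 2.0, 3.0, 10.0)
        ]
        assert coverages == sorted(coverages)
        assert all(d >= 1.0 for d in
                   evaluate_fold_agreement(model1, records, panel).fold_deviations)

    def test_k_override_recenters_predictions(self, panel, model1):
        records = _species_records(panel, model1, offset=-0.3)
        biased = evaluate_fold_agreement(model1, records, panel, fold=1.5)
        fixed = evaluate_fold_agreement(
            model1, records, panel, k_override=model1.k - 0.3, fold=1.5
        )
        assert biased.coverage < fixed.coverage == 1.0
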