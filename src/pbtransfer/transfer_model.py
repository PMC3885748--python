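"""Log-linear soil-to-grain transfer model and stepwise fitting.

The model is

    log10 BCF = a*pH + b*log10 OM + c*log10 CEC + k

where the slopes a, b, c carry the soil-property effects on Pb availability
and the intercept k is the cultivar's intrinsic sensitivity — its propensity
to accumulate Pb independent of soil. Candidate predictors are selected by
forward-entry / backward-removal stepwise ordinary least squares on the
partial t-test p-values, the procedure classically used for such
soil-property transfer functions.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .bcf_core import BCFRecord
from .soil_data import SoilDataError, SoilProfile

__all__ = [
    "PREDICTORS",
    "TransferModel",
    "ModelComparison",
    "fit_stepwise",
    "fit_forced",
    "predict_log_bcf",
    "compare_models",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

#: Candidate predictors, in canonical order.
PREDICTORS = ("pH", "logOM", "logCEC")

#: Condition number above which a collinearity warning is emitted.
CONDITION_NUMBER_WARN = 1e8

_SLOPE_FIELD = {"pH": "a", "logOM": "b", "logCEC": "c"}


@dataclass(frozen=True)
class TransferModel:
    """Fitted (or published) coefficients of the log-linear transfer model.

    Slopes of predictors not in ``selected`` are exactly 0. ``r2``,
    ``p_value`` and ``n`` are None for models quoted from the literature
    rather than fitted here.
    """

    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    k: float = 0.0
    selected: tuple[str, ...] = ()
    r2: float | None = None
    p_value: float | None = None
    n: int | None = None
    level_label: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.selected) - set(PREDICTORS)
        if unknown:
            raise SoilDataError(f"unknown predictors {sorted(unknown)}")
        for name in PREDICTORS:
            coef = getattr(self, _SLOPE_FIELD[name])
            if name not in self.selected and coef != 0.0:
                raise SoilDataError(
                    f"coefficient for unselected predictor {name} must be 0"
                )
        if self.r2 is not None and not (-1e-12 <= self.r2 <= 1.0 + 1e-12):
            raise SoilDataError(f"r2 must lie in [0, 1], got {self.r2!r}")

    @property
    def slopes(self) -> dict[str, float]:
        return {name: getattr(self, _SLOPE_FIELD[name]) for name in self.selected}

    def predict(self, soil: SoilProfile) -> float:
        return predict_log_bcf(self, soil)


def _predictor_value(soil: SoilProfile, name: str) -> float:
    if name == "pH":
        return soil.ph
    if name == "logOM":
        if soil.om is None:
            raise SoilDataError(f"soil {soil.soil_id}: OM required but absent")
        return math.log10(soil.om)
    if name == "logCEC":
        if soil.cec is None:
            raise SoilDataError(f"soil {soil.soil_id}: CEC required but absent")
        return math.log10(soil.cec)
    raise SoilDataError(f"unknown predictor {name!r}")


def predict_log_bcf(model: TransferModel, soil: SoilProfile) -> float:
    """Model-implied log10 BCF at a soil's properties."""
    total = model.k
    for name, coef in model.slopes.items():
        total += coef * _predictor_value(soil, name)
    return total


def _design(
    records: Sequence[BCFRecord],
    soils: Sequence[SoilProfile] | Mapping[str, SoilProfile],
    predictors: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    by_id = soils if isinstance(soils, Mapping) else {s.soil_id: s for s in soils}
    y = np.empty(len(records))
    x = np.empty((len(records), len(predictors)))
    for i, record in enumerate(records):
        soil = by_id.get(record.soil_id)
        if soil is None:
            raise SoilDataError(f"record soil_id {record.soil_id!r} not in panel")
        y[i] = record.log_bcf
        for j, name in enumerate(predictors):
            x[i, j] = _predictor_value(soil, name)
    return y, x


def _partial_stats(res, j: int) -> tuple[float, float]:
    """(t, two-sided p) for coefficient j, robust to zero-residual fits."""
    coef = res.params[j]
    se = res.bse[j]
    df = res.df_resid
    if se == 0 or not math.isfinite(se):
        # Perfect fit: a non-null coefficient is infinitely significant,
        # a null one carries no evidence.
        return (math.inf, 0.0) if abs(coef) > 1e-10 else (0.0, 1.0)
    t = coef / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def _ols(y: np.ndarray, x: np.ndarray):
    return sm.OLS(y, sm.add_constant(x, has_constant="add")).fit()


def fit_stepwise(
    bcf_records: Sequence[BCFRecord],
    soils: Sequence[SoilProfile] | Mapping[str, SoilProfile],
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    candidates: Sequence[str] = PREDICTORS,
    level_label: str | None = None,
) -> TransferModel:
    """Forward-entry / backward-removal stepwise OLS of log10 BCF.

    At each round the not-yet-selected candidate with the smallest partial
    t-test p enters if p <= alpha_enter (ties: larger |t|, then predictor
    name); then any selected predictor whose partial p exceeds alpha_remove
    is dropped, worst first. Terminates when a round changes nothing.
    """
    if alpha_enter > alpha_remove:
        raise SoilDataError("alpha_enter must not exceed alpha_remove")
    records = list(bcf_records)
    if len(records) < 5:
        raise SoilDataError(f"need at least 5 records, got {len(records)}")
    candidates = tuple(candidates)
    y, x_all = _design(records, soils, candidates)

    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.linalg.cond(
            (x_all - x_all.mean(axis=0)) / np.where(x_all.std(axis=0) == 0, 1, x_all.std(axis=0))
        )
    if cond > CONDITION_NUMBER_WARN:
        logger.warning("candidate design is near-collinear (cond=%.3g)", cond)

    col = {name: j for j, name in enumerate(candidates)}
    selected: list[str] = []
    while True:
        changed = False
        # forward entry
        entry: list[tuple[float, float, str]] = []
        for name in candidates:
            if name in selected:
                continue
            trial = selected + [name]
            res = _ols(y, x_all[:, [col[c] for c in trial]])
            t, p = _partial_stats(res, len(trial))  # j=0 is the intercept
            entry.append((p, -abs(t), name))
        if entry:
            p, neg_t, name = min(entry)
            if p <= alpha_enter:
                selected.append(name)
                changed = True
                logger.info("stepwise: entered %s (p=%.3g)", name, p)
        # backward removal
        while len(selected) > 0:
            res = _ols(y, x_all[:, [col[c] for c in selected]])
            stats_by_name = {
                nm: _partial_stats(res, j + 1) for j, nm in enumerate(selected)
            }
            worst = max(selected, key=lambda nm: stats_by_name[nm][1])
            if stats_by_name[worst][1] > alpha_remove:
                selected.remove(worst)
                changed = True
                logger.info(
                    "stepwise: removed %s (p=%.3g)", worst, stats_by_name[worst][1]
                )
            else:
                break
        if not changed:
            break

    if not selected:
        logger.warning("stepwise: no predictor passed entry; intercept-only model")
    order = [name for name in candidates if name in selected]
    return _finalize(y, x_all, col, order, len(records), level_label)


def fit_forced(
    bcf_records: Sequence[BCFRecord],
    soils: Sequence[SoilProfile] | Mapping[str, SoilProfile],
    predictors: Sequence[str],
    level_label: str | None = None,
) -> TransferModel:
    """Plain OLS on a fixed predictor set (no selection)."""
    records = list(bcf_records)
    predictors = tuple(predictors)
    y, x = _design(records, soils, predictors)
    col = {name: j for j, name in enumerate(predictors)}
    return _finalize(y, x, col, list(predictors), len(records), level_label)


def _finalize(
    y: np.ndarray,
    x_all: np.ndarray,
    col: Mapping[str, int],
    selected: list[str],
    n: int,
    level_label: str | None,
) -> TransferModel:
    res = _ols(y, x_all[:, [col[c] for c in selected]]) if selected else None
    coeffs = {"a": 0.0, "b": 0.0, "c": 0.0}
    if res is None:
        k = float(np.mean(y))
        r2, p_value = 0.0, None
    else:
        k = float(res.params[0])
        for j, name in enumerate(selected):
            coeffs[_SLOPE_FIELD[name]] = float(res.params[j + 1])
        r2 = float(res.rsquared)
        p_value = _overall_p(res, len(selected))
    return TransferModel(
        **coeffs,
        k=k,
        selected=tuple(selected),
        r2=min(max(r2, 0.0), 1.0),
        p_value=p_value,
        n=n,
        level_label=level_label,
    )


def _overall_p(res, n_pred: int) -> float:
    p = res.f_pvalue
    if p is None or not math.isfinite(p):
        # zero-residual fit: F statistic diverges
        return 0.0 if res.rsquared > 0.5 else 1.0
    return float(p)


@dataclass(frozen=True)
class ModelComparison:
    """Per-soil predicted log-BCF differences between two models (m1 - m2)."""

    soil_ids: tuple[str, ...]
    differences: tuple[float, ...]
    mean_abs_diff: float
    t_statistic: float
    p_value: float


def compare_models(
    m1: TransferModel, m2: TransferModel, soils: Sequence[SoilProfile]
) -> ModelComparison:
    """Compare two fitted models' predictions over a soil panel.

    The paired t-test asks whether the two dose-level models predict
    systematically different log BCFs on the same soils.
    """
    diffs = np.array([m1.predict(s) - m2.predict(s) for s in soils])
    if diffs.size < 2 or np.allclose(diffs, diffs[0]):
        t_stat, p = (0.0, 1.0) if np.allclose(diffs, 0) else (math.inf, 0.0)
    else:
        t_stat, p = stats.ttest_1samp(diffs, 0.0)
    return ModelComparison(
        soil_ids=tuple(s.soil_id for s in soils),
        differences=tuple(float(d) for d in diffs),
        mean_abs_diff=float(np.mean(np.abs(diffs))),
        t_statistic=float(t_stat),
        p_value=float(p),
    )


def model_to_dict(model: TransferModel) -> dict:
    return {
        "level_label": model.level_label,
        "a": model.a,
        "b": model.b,
        "c": model.c,
        "k": model.k,
        "selected": list(model.selected),
        "r2": model.r2,
        "p_value": model.p_value,
        "n": model.n,
    }


def model_from_dict(data: Mapping) -> TransferModel:
    return TransferModel(
        a=data.get("a", 0.0),
        b=data.get("b", 0.0),
        c=data.get("c", 0.0),
        k=data["k"],
        selected=tuple(data.get("selected", ())),
        r2=data.get("r2"),
        p_value=data.get("p_value"),
        n=data.get("n"),
        level_label=data.get("level_label"),
    )


def save_model(model: TransferModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2) + "\n")


def load_model(path: str | Path) -> TransferModel:
    return model_from_dict(json.loads(Path(path).read_text()))
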