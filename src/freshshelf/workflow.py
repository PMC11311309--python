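"""End-to-end shelf-life analysis of a storage trial.

Ties the pipeline together: fit growth curves per treatment, read off the
sensory shelf life, select key quality indicators by correlation with the
bacterial count, fit kinetic models to the selected attributes, anchor
their cut-offs to the sensory day, and invert everything into a
per-treatment shelf-life comparison table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .dataset import StorageDataset
from .fitting import (
    GrowthCurveModel,
    GrowthCurveResults,
    QualityKineticsModel,
    QualityKineticsResults,
    rank_models,
)
from .growth import MODEL_KINDS
from .indicators import CorrelationReport, select_key_indicators
from .shelf import (
    SAFETY_LIMIT_DEFAULT,
    SENSORY_LIMIT_DEFAULT,
    ShelfLifeEstimate,
    derive_attribute_cutoff,
    predict_quality_shelf_life,
    predict_safety_shelf_life,
    sensory_shelf_life,
    shelf_life_report,
)

__all__ = ["TrialAnalysis", "analyze_trial", "fit_growth_all", "fit_quality_all"]


def fit_growth_all(
    dataset: StorageDataset,
    model: str = "all",
    rmse_convention: str = "dof",
) -> dict[str, list[GrowthCurveResults]]:
    """Fit growth model(s) to each treatment's count trajectory.

    Returns, per treatment, a list of results ranked best-first (a single
    element unless ``model="all"``).
    """
    kinds = MODEL_KINDS if model == "all" else (model,)
    out: dict[str, list[GrowthCurveResults]] = {}
    for trt in dataset.treatments:
        fits = [
            GrowthCurveModel.from_dataset(dataset, trt, kind=k).fit(rmse_convention)
            for k in kinds
        ]
        out[trt] = rank_models(fits)
    return out


def fit_quality_all(
    dataset: StorageDataset,
    attributes: list[str],
    order: str = "both",
    rmse_convention: str = "dof",
) -> dict[tuple[str, str], list[QualityKineticsResults]]:
    """Fit kinetic order(s) to each (treatment, attribute) trajectory,
    ranked best-first.  First-order fits are skipped for attributes with
    non-positive values (log undefined)."""
    orders = ("zero", "first") if order == "both" else (order,)
    out: dict[tuple[str, str], list[QualityKineticsResults]] = {}
    for trt in dataset.treatments:
        for attr in attributes:
            fits = []
            for o in orders:
                try:
                    m = QualityKineticsModel.from_dataset(dataset, trt, attr, order=o)
                except ValueError:
                    continue
                fits.append(m.fit(rmse_convention))
            if fits:
                out[(trt, attr)] = rank_models(fits)
    return out


@dataclass
class TrialAnalysis:
    """Everything produced by :func:`analyze_trial`."""

    growth_fits: dict[str, list[GrowthCurveResults]]
    correlation: CorrelationReport | None
    quality_fits: dict[tuple[str, str], list[QualityKineticsResults]]
    estimates: list[ShelfLifeEstimate] = field(default_factory=list)
    report: pd.DataFrame | None = None


def analyze_trial(
    dataset: StorageDataset,
    growth_model: str = "gompertz",
    limit_tbc: float = SAFETY_LIMIT_DEFAULT,
    sensory_limit: float = SENSORY_LIMIT_DEFAULT,
    corr_threshold: float = 0.9,
    order: str = "both",
    rmse_convention: str = "dof",
    sensory_method: str = "discrete",
    corr_method: str = "within_treatment",
) -> TrialAnalysis:
    """Run the full shelf-life pipeline on a storage dataset.

    The safety basis uses the requested growth model (best-ranked of all
    four when ``growth_model="all"``).  Quality bases use the best-fitting
    kinetic order per selected attribute, with cut-offs anchored to each
    treatment's sensory shelf-life day.  Sensory-dependent bases are
    skipped when the dataset has no sensory scores.
    """
    attrs = dataset.attributes
    has_tbc = "tbc_log_cfu_g" in attrs
    has_sensory = "sensory" in attrs

    growth_fits = fit_growth_all(dataset, growth_model, rmse_convention) if has_tbc else {}

    correlation = None
    selected: list[str] = []
    if has_tbc and len(attrs) > 2:
        correlation = select_key_indicators(
            dataset, threshold=corr_threshold, method=corr_method
        )
        selected = correlation.selected

    estimates: list[ShelfLifeEstimate] = []
    sensory_days: dict[str, float] = {}
    for trt in dataset.treatments:
        if has_tbc:
            estimates.append(
                predict_safety_shelf_life(growth_fits[trt][0], limit_tbc, treatment=trt)
            )
        if has_sensory:
            t, s = dataset.trajectory(trt, "sensory")
            est = sensory_shelf_life(
                list(zip(t, s)), sensory_limit, sensory_method, treatment=trt
            )
            estimates.append(est)
            sensory_days[trt] = est.t_pred

    quality_fits = (
        fit_quality_all(dataset, selected, order, rmse_convention) if selected else {}
    )
    for trt in dataset.treatments:
        if trt not in sensory_days:
            continue
        for attr in selected:
            fits = quality_fits.get((trt, attr))
            if not fits:
                continue
            cutoff = derive_attribute_cutoff(dataset, attr, trt, sensory_days[trt])
            estimates.append(predict_quality_shelf_life(fits[0], cutoff, treatment=trt))

    report = shelf_life_report(estimates) if estimates else None
    return TrialAnalysis(growth_fits, correlation, quality_fits, estimates, report)
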