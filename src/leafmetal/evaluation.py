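"""Model evaluation: one-in-four modeling/validation split, RMSE/R2 metrics,
RPD with its five-level interpretation, and paired GA-PLSR vs full-band PLSR
comparison reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SoilTable, SpectraSet
from .ga import GAConfig, SelectionResult, select_bands
from .plsr import (CVResult, cross_validate, default_max_ncomp, fit_plsr,
                   predict)
from .preprocessing import (DEFAULT_SG_POLYORDER, DEFAULT_SG_WINDOW,
                            DEFAULT_TRIM_NM, apply_transform, msc_fit,
                            sg_smooth, trim_low_bands)

__all__ = [
    "EvalReport", "ComparisonRow", "split_one_in_four", "rmse", "r2", "rpd",
    "classify_rpd", "evaluate_combination", "compare_models",
    "reports_to_frame", "comparison_to_frame", "EvaluationError",
    "RPD_CATEGORIES",
]


class EvaluationError(ValueError):
    pass


RPD_CATEGORIES = (
    "poor",                      # rpd <= 1.50
    "distinguishes high/low",    # 1.50 < rpd <= 2.00
    "approximate quantitative",  # 2.00 < rpd <= 2.50
    "good",                      # 2.50 < rpd <= 3.00
    "excellent",                 # rpd > 3.00
)


def split_one_in_four(n: int) -> tuple[np.ndarray, np.ndarray]:
    """One sample in every four held out: validation indices 3, 7, 11, ...

    Samples are assumed already ordered by the split's sort key (ascending
    site id).  Returns (modeling_indices, validation_indices); disjoint and
    exhaustive.
    """
    if n < 4:
        raise EvaluationError("need at least 4 samples for a one-in-four split")
    idx = np.arange(n)
    validation = idx[3::4]
    modeling = np.setdiff1d(idx, validation)
    return modeling, validation


def rmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    observed = np.asarray(observed, float).ravel()
    predicted = np.asarray(predicted, float).ravel()
    if observed.size != predicted.size or observed.size < 2:
        raise EvaluationError("observed/predicted must have equal length >= 2")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination 1 - SSE/SST (not squared correlation)."""
    observed = np.asarray(observed, float).ravel()
    predicted = np.asarray(predicted, float).ravel()
    if observed.size != predicted.size or observed.size < 2:
        raise EvaluationError("observed/predicted must have equal length >= 2")
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst <= 0:
        raise EvaluationError("observed values have zero variance")
    sse = float(np.sum((observed - predicted) ** 2))
    return 1.0 - sse / sst


def rpd(observed_validation: np.ndarray, predicted_validation: np.ndarray) -> float:
    """SD (ddof=1) of observed validation values divided by RMSE of prediction."""
    observed = np.asarray(observed_validation, float).ravel()
    if observed.size < 3:
        raise EvaluationError("RPD needs at least 3 validation samples")
    sd = float(observed.std(ddof=1))
    if sd <= 0:
        raise EvaluationError("validation observations have zero variance")
    return sd / rmse(observed, predicted_validation)


def classify_rpd(value: float) -> str:
    """Five-level interpretation; interior boundaries belong to the lower tier."""
    if not value > 0:
        raise EvaluationError("RPD must be positive")
    if value > 3.00:
        return "excellent"
    if value > 2.50:
        return "good"
    if value > 2.00:
        return "approximate quantitative"
    if value > 1.50:
        return "distinguishes high/low"
    return "poor"


# --------------------------------------------------------------------------
# comparison pipeline
# --------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Metrics for one (metal, transform, method) combination."""

    metal: str
    transform: str
    method: str  # "GA-PLSR" or "PLSR"
    n_bands_selected: int
    ncomp: int
    r2_cv: float
    rmse_cv: float
    r2_ev: float
    rmse_ev: float
    rpd: float
    rpd_category: str
    selected_wavelengths_nm: list[float] | None = None


@dataclass
class ComparisonRow:
    """Paired GA-PLSR vs full-band PLSR reports plus percent changes."""

    ga: EvalReport
    full: EvalReport
    pct_r2_cv_gain: float     # 100*(GA - full)/full
    pct_rmse_cv_drop: float   # 100*(full - GA)/full
    selection: SelectionResult | None = None


def _external_metrics(y_model, X_model, y_valid, X_valid, ncomp):
    model = fit_plsr(X_model, y_model, ncomp)
    pred = predict(model, X_valid)
    value = rpd(y_valid, pred)
    return r2(y_valid, pred), rmse(y_valid, pred), value, classify_rpd(value), model


def evaluate_combination(spectra: SpectraSet, soil: SoilTable, metal: str,
                         transform: str, ga_config: GAConfig,
                         cv_scheme="loo",
                         trim_cutoff_nm: float = DEFAULT_TRIM_NM,
                         sg_window: int = DEFAULT_SG_WINDOW,
                         sg_polyorder: int = DEFAULT_SG_POLYORDER) -> ComparisonRow:
    """Run the full comparison for one (metal, transform) pair.

    Preprocessing references (MSC), autoscaling, GA selection and component
    choice are all derived from the modeling set only; validation samples
    enter only at final external evaluation.
    """
    order = np.argsort(spectra.site_ids)
    y_all = soil.metal(metal)[order]

    base = trim_low_bands(spectra, trim_cutoff_nm)
    base = sg_smooth(base, sg_window, sg_polyorder)
    base = base.replace(reflectance=base.reflectance[order],
                        site_ids=spectra.site_ids[order])

    model_idx, valid_idx = split_one_in_four(base.n_sites)
    modeling = base.replace(reflectance=base.reflectance[model_idx],
                            site_ids=base.site_ids[model_idx])
    validation = base.replace(reflectance=base.reflectance[valid_idx],
                              site_ids=base.site_ids[valid_idx])

    msc_ref = msc_fit(modeling) if transform == "MSC" else None
    X_model = apply_transform(modeling, transform, msc_ref=msc_ref).reflectance
    X_valid = apply_transform(validation, transform, msc_ref=msc_ref).reflectance
    y_model, y_valid = y_all[model_idx], y_all[valid_idx]

    n, p = X_model.shape
    max_ncomp = default_max_ncomp(n, p)
    if ga_config.max_ncomp is not None:
        max_ncomp = min(max_ncomp, ga_config.max_ncomp)

    # full-band PLSR
    cv_full = cross_validate(X_model, y_model, max_ncomp=max_ncomp, scheme=cv_scheme)
    r2_ev, rmse_ev, rpd_v, cat, _ = _external_metrics(
        y_model, X_model, y_valid, X_valid, cv_full.chosen_ncomp)
    full_report = EvalReport(
        metal=metal, transform=transform, method="PLSR",
        n_bands_selected=p, ncomp=cv_full.chosen_ncomp,
        r2_cv=cv_full.r2_cv, rmse_cv=cv_full.rmse_cv,
        r2_ev=r2_ev, rmse_ev=rmse_ev, rpd=rpd_v, rpd_category=cat,
    )

    # GA-PLSR
    selection = select_bands(X_model, y_model, ga_config, cv_scheme=cv_scheme)
    mask = selection.best.included
    cap = default_max_ncomp(n, int(mask.sum()))
    if ga_config.max_ncomp is not None:
        cap = min(cap, ga_config.max_ncomp)
    cv_ga = cross_validate(X_model[:, mask], y_model, max_ncomp=cap, scheme=cv_scheme)
    r2_ev, rmse_ev, rpd_v, cat, _ = _external_metrics(
        y_model, X_model[:, mask], y_valid, X_valid[:, mask], cv_ga.chosen_ncomp)
    ga_report = EvalReport(
        metal=metal, transform=transform, method="GA-PLSR",
        n_bands_selected=int(mask.sum()), ncomp=cv_ga.chosen_ncomp,
        r2_cv=cv_ga.r2_cv, rmse_cv=cv_ga.rmse_cv,
        r2_ev=r2_ev, rmse_ev=rmse_ev, rpd=rpd_v, rpd_category=cat,
        selected_wavelengths_nm=list(base.wavelengths_nm[mask]),
    )

    return ComparisonRow(
        ga=ga_report, full=full_report,
        pct_r2_cv_gain=100.0 * (cv_ga.r2_cv - cv_full.r2_cv) / abs(cv_full.r2_cv)
        if cv_full.r2_cv != 0 else float("nan"),
        pct_rmse_cv_drop=100.0 * (cv_full.rmse_cv - cv_ga.rmse_cv) / cv_full.rmse_cv,
        selection=selection,
    )


def compare_models(spectra: SpectraSet, soil: SoilTable,
                   transforms, metals, ga_config: GAConfig,
                   cv_scheme="loo", **preprocess_kwargs) -> list[ComparisonRow]:
    """Sweep (metal, transform) pairs; each yields a paired report row."""
    rows = []
    for metal in metals:
        for transform in transforms:
            rows.append(evaluate_combination(
                spectra, soil, metal, transform, ga_config,
                cv_scheme=cv_scheme, **preprocess_kwargs))
    return rows


def reports_to_frame(rows: list[ComparisonRow]) -> pd.DataFrame:
    """Long-form table: one line per (metal, transform, method)."""
    records = []
    for row in rows:
        for rep in (row.ga, row.full):
            rec = asdict(rep)
            rec.pop("selected_wavelengths_nm")
            records.append(rec)
    return pd.DataFrame.from_records(records)


def comparison_to_frame(rows: list[ComparisonRow]) -> pd.DataFrame:
    """Wide comparison table: GA-PLSR metrics per pair plus percent changes."""
    records = []
    for row in rows:
        records.append({
            "metal": row.ga.metal,
            "transform": row.ga.transform,
            "n_bands": row.ga.n_bands_selected,
            "pc_ga": row.ga.ncomp,
            "pc_full": row.full.ncomp,
            "r2_cv": row.ga.r2_cv,
            "rmse_cv": row.ga.rmse_cv,
            "r2_ev": row.ga.r2_ev,
            "rmse_ev": row.ga.rmse_ev,
            "rpd": row.ga.rpd,
            "rpd_category": row.ga.rpd_category,
            "r2_cv_full": row.full.r2_cv,
            "rmse_cv_full": row.full.rmse_cv,
            "pct_r2_cv_gain": row.pct_r2_cv_gain,
            "pct_rmse_cv_drop": row.pct_rmse_cv_drop,
        })
    return pd.DataFrame.from_records(records)


def comparison_to_json(rows: list[ComparisonRow], path: str | Path) -> None:
    payload = []
    for row in rows:
        payload.append({
            "ga": asdict(row.ga),
            "full": asdict(row.full),
            "pct_r2_cv_gain": row.pct_r2_cv_gain,
            "pct_rmse_cv_drop": row.pct_rmse_cv_drop,
        })
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
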