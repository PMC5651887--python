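"""End-to-end convenience wrapper: preprocess -> band fit -> screen -> classify."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bandfit, classify, preprocess, stats_screen
from .bandfit import FeatureTable
from .classify import CVResult, ROCCurve
from .errors import MissingBandError
from .io_formats import LabeledCohort, Spectrum
from .stats_screen import ScreenReport


@dataclass
class AnalysisResult:
    processed: LabeledCohort
    preprocess_report: dict
    features: FeatureTable
    screen: ScreenReport
    cv: CVResult
    roc: ROCCurve
    score_source: str


def analyze_cohort(
    cohort: LabeledCohort,
    toluene: Spectrum | None = None,
    water: Spectrum | None = None,
    pre_config: preprocess.PreprocessConfig | None = None,
    regions=bandfit.DEFAULT_REGIONS,
    nominal_centers=bandfit.DEFAULT_NOMINAL_CENTERS,
    ratio_specs=((900.0, 940.0),),
    pca_region=classify.DEFAULT_REGION,
    score_source: str = "band_ratio",
    alpha: float = 0.05,
) -> AnalysisResult:
    """Run the full analysis on an assembled cohort.

    ``score_source`` selects the ROC score: "band_ratio" (the 900/940 area
    ratio, the default) or "qda_posterior" (held-out LOOCV posteriors).
    """
    processed, report = preprocess.run_chain(cohort, toluene, water, pre_config)
    fits = bandfit.fit_cohort(processed, regions=regions, centers=nominal_centers)
    features = bandfit.build_features(
        fits, processed.labels, nominal_centers, ratio_specs
    )
    screen = stats_screen.screen_features(features, alpha=alpha)
    cv = classify.loocv(processed, region=pca_region)

    if score_source == "band_ratio":
        num, den = ratio_specs[0]
        col = f"r{num:g}_{den:g}"
        tab = features.table
        scores = tab[col].to_numpy(float)
        labels = (tab["label"] == "pregnant").to_numpy()
    elif score_source == "qda_posterior":
        scores = cv.posterior_scores
        labels = cv.labels
    else:
        raise MissingBandError(f"unknown score_source {score_source!r}")
    roc = classify.roc_analysis(scores, labels)
    return AnalysisResult(processed, report, features, screen, cv, roc, score_source)


def result_summary(res: AnalysisResult) -> dict:
    """JSON-serializable summary of an analysis run."""
    cm = res.cv.confusion
    return {
        "n_samples": len(res.processed),
        "preprocess": res.preprocess_report,
        "screen": res.screen.to_dict(),
        "loocv": {
            "confusion": {"TP": cm.tp, "FN": cm.fn, "TN": cm.tn, "FP": cm.fp},
            "sensitivity_pct": 100.0 * cm.sensitivity,
            "specificity_pct": 100.0 * cm.specificity,
            "sensitivity_display": classify.format_percent(100.0 * cm.sensitivity),
            "specificity_display": classify.format_percent(100.0 * cm.specificity),
            "accuracy_pct": 100.0 * cm.accuracy,
            "excluded_folds": res.cv.excluded,
            "explained_variance_ratio": (
                None
                if res.cv.explained_variance_ratio is None
                else [float(v) for v in res.cv.explained_variance_ratio]
            ),
        },
        "roc": {
            "score_source": res.score_source,
            "auc": res.roc.auc,
            "optimal_threshold": res.roc.optimal_threshold,
            "optimal_sensitivity_pct": 100.0 * res.roc.optimal_sensitivity,
            "optimal_specificity_pct": 100.0 * res.roc.optimal_specificity,
            "orientation_flipped": res.roc.flipped,
        },
        "excluded_samples": res.features.excluded,
    }
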