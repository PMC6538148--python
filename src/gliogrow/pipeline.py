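"""End-to-end convenience layer: raw series -> detection -> fits -> summary."""

from __future__ import annotations

import logging
from typing import Iterable, List, Optional, Tuple

from .changepoint import ChangePointConfig, detect_growth_online
from .cohort_stats import CaseResult, CohortStats, cohort_summary
from .growth_models import GrowthFit, PooledFit, fit_growth, pooled_fit
from .trajectory import NormalizedCurve, VolumeSeries, find_baseline, normalize_curve

__all__ = ["analyze_case", "analyze_cohort", "classify_cohort_growth"]

logger = logging.getLogger("gliogrow")


def analyze_case(series: VolumeSeries, cfg: ChangePointConfig = ChangePointConfig()) -> CaseResult:
    """Baseline determination followed by the online change-point sweep."""
    baseline = find_baseline(series)
    detection = detect_growth_online(series, baseline, cfg)
    logger.info(
        "case %s: baseline index %d (%.0f px^3), detected=%s ttg=%s",
        series.case_id,
        baseline.baseline_index,
        baseline.baseline_volume,
        detection.detected,
        f"{detection.ttg_months:.1f}" if detection.detected else "-",
    )
    return CaseResult(series=series, baseline=baseline, detection=detection)


def analyze_cohort(
    series_list: Iterable[VolumeSeries], cfg: ChangePointConfig = ChangePointConfig()
) -> List[CaseResult]:
    return [analyze_case(s, cfg) for s in series_list]


def classify_cohort_growth(
    cases: Iterable[CaseResult],
) -> Tuple[List[GrowthFit], Optional[PooledFit]]:
    """Fit growth kinetics for every detected case and pool the exponential ones.

    Returns the per-case fits and the single exp1 fit over the pooled points
    of exponential-classified curves (None when no curve classifies as
    exponential).
    """
    fits: List[GrowthFit] = []
    exp_curves: List[NormalizedCurve] = []
    for c in cases:
        if not c.detection.detected:
            continue
        curve = normalize_curve(c.series, c.baseline)
        fit = fit_growth(curve)
        fits.append(fit)
        if fit.classification == "exponential":
            exp_curves.append(curve)
    pooled = pooled_fit(exp_curves) if exp_curves else None
    return fits, pooled
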