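"""Cohort-level comparative statistics for CAD vs visual-comparison detection.

Summarizes per-case detection results by pathology group: how often the
computer-assisted call preceded the radiology-report call (dG), medians and
interquartile ranges of time to growth (TTG, months) and of the fractional
volume change at detection (dV), and Mann-Whitney-Wilcoxon two-tailed
p-values comparing the CAD and VC distributions.  Three table shapes are
produced, mirroring the three clinical courses: radiological progression
(CAD vs VC columns), clinically stable (CAD-only columns plus follow-up
durations), and imaging abnormality (detection count only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .changepoint import DetectionResult
from .errors import InvalidInputError
from .trajectory import BaselineResult, VolumeSeries, find_baseline, percent_change

__all__ = [
    "CaseResult",
    "ProgressionRow",
    "StableRow",
    "AbnormalityRow",
    "CohortStats",
    "mann_whitney_p",
    "median_iqr",
    "format_p",
    "cohort_summary",
]

# Pathology display order in the summary tables.
_PATHOLOGY_ORDER = ("oligodendroglioma", "astrocytoma", "mixed")

#: Combined sample size up to which the exact Mann-Whitney null is used.
EXACT_MWW_LIMIT = 20


@dataclass(frozen=True)
class CaseResult:
    """One case's series, baseline and online detection outcome."""

    series: VolumeSeries
    baseline: BaselineResult
    detection: DetectionResult

    @property
    def followup_months(self) -> float:
        """Baseline scan to last scan, in months."""
        return float(self.series.times[-1] - self.baseline.baseline_time)

    @property
    def vc_ttg_months(self) -> Optional[float]:
        if self.series.vc_detection_time is None:
            return None
        return float(self.series.vc_detection_time - self.baseline.baseline_time)

    @property
    def vc_delta_v(self) -> Optional[float]:
        """Fractional volume change at the scan nearest the VC call."""
        t_vc = self.series.vc_detection_time
        if t_vc is None:
            return None
        idx = int(np.argmin(np.abs(self.series.times - t_vc)))  # ties -> earlier
        return percent_change(float(self.series.volumes[idx]), self.baseline.baseline_volume)


MedianIqr = Tuple[float, float, float]


@dataclass(frozen=True)
class ProgressionRow:
    pathology: str
    n: int
    delta_g: int
    ttg_cad: Optional[MedianIqr]
    ttg_vc: Optional[MedianIqr]
    p_ttg: Optional[float]
    dv_cad: Optional[MedianIqr]
    dv_vc: Optional[MedianIqr]
    p_dv: Optional[float]


@dataclass(frozen=True)
class StableRow:
    pathology: str
    n: int
    cad_g: int
    ttg_cad: Optional[MedianIqr]
    fu_growth: Optional[MedianIqr]
    fu_stable: Optional[MedianIqr]
    dv_cad: Optional[MedianIqr]


@dataclass(frozen=True)
class AbnormalityRow:
    n: int
    detections: int
    followup: Optional[MedianIqr]


@dataclass(frozen=True)
class CohortStats:
    progression: Tuple[ProgressionRow, ...]
    stable: Tuple[StableRow, ...]
    abnormality: Optional[AbnormalityRow]
    warnings: Tuple[str, ...] = ()


def mann_whitney_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-tailed Mann-Whitney-Wilcoxon p-value.

    Uses the exact null distribution when the combined sample size is at
    most 20 and the pooled values carry no ties, and the tie-corrected
    normal approximation (with continuity correction) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidInputError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (pooled.size <= EXACT_MWW_LIMIT and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def median_iqr(values: Sequence[float]) -> MedianIqr:
    """Median with linearly interpolated quartiles (q1, q3)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InvalidInputError("empty sample")
    q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def format_p(p: float) -> str:
    """Display convention: three decimals with a '<0.001' floor."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def _mi(values: List[float]) -> Optional[MedianIqr]:
    return median_iqr(values) if values else None


def _progression_row(pathology: str, cases: List[CaseResult], warn: List[str]) -> ProgressionRow:
    detected = [c for c in cases if c.detection.detected]
    with_vc: List[CaseResult] = []
    for c in cases:
        if c.series.vc_detection_time is None:
            msg = f"case {c.series.case_id}: progression case without VC annotation; excluded from dG and VC columns"
            warn.append(msg)
            warnings.warn(msg)
        else:
            with_vc.append(c)
    detected_vc = [c for c in with_vc if c.detection.detected]

    delta_g = sum(1 for c in detected_vc if c.detection.ttg_months < c.vc_ttg_months)
    ttg_cad = [c.detection.ttg_months for c in detected]
    ttg_vc = [c.vc_ttg_months for c in with_vc]
    dv_cad = [c.detection.delta_v for c in detected]
    dv_vc = [c.vc_delta_v for c in with_vc]

    p_ttg = mann_whitney_p(ttg_cad, ttg_vc) if ttg_cad and ttg_vc else None
    p_dv = mann_whitney_p(dv_cad, dv_vc) if dv_cad and dv_vc else None
    return ProgressionRow(
        pathology=pathology,
        n=len(cases),
        delta_g=delta_g,
        ttg_cad=_mi(ttg_cad),
        ttg_vc=_mi(ttg_vc),
        p_ttg=p_ttg,
        dv_cad=_mi(dv_cad),
        dv_vc=_mi(dv_vc),
        p_dv=p_dv,
    )


def _stable_row(pathology: str, cases: List[CaseResult]) -> StableRow:
    grown = [c for c in cases if c.detection.detected]
    stable = [c for c in cases if not c.detection.detected]
    return StableRow(
        pathology=pathology,
        n=len(cases),
        cad_g=len(grown),
        ttg_cad=_mi([c.detection.ttg_months for c in grown]),
        fu_growth=_mi([c.followup_months for c in grown]),
        fu_stable=_mi([c.followup_months for c in stable]),
        dv_cad=_mi([c.detection.delta_v for c in grown]),
    )


def cohort_summary(cases: Iterable[CaseResult]) -> CohortStats:
    """Group per-case detection results into the three clinical tables.

    Progression and stable groups get one row per pathology present plus an
    "All" row; empty pathology groups are omitted.  Progression cases
    lacking a VC annotation are counted in n and the CAD columns but
    excluded from dG and the VC columns (with a warning).
    """
    cases = list(cases)
    warn: List[str] = []

    prog = [c for c in cases if c.series.group == "progression"]
    stab = [c for c in cases if c.series.group == "stable"]
    abn = [c for c in cases if c.series.group == "imaging_abnormality"]

    prog_rows: List[ProgressionRow] = []
    if prog:
        for pathology in _PATHOLOGY_ORDER:
            sub = [c for c in prog if c.series.pathology == pathology]
            if sub:
                prog_rows.append(_progression_row(pathology, sub, warn))
        prog_rows.append(_progression_row("All", prog, warn=[]))  # warn once, above

    stable_rows: List[StableRow] = []
    if stab:
        for pathology in _PATHOLOGY_ORDER:
            sub = [c for c in stab if c.series.pathology == pathology]
            if sub:
                stable_rows.append(_stable_row(pathology, sub))
        stable_rows.append(_stable_row("All", stab))

    abnormality = None
    if abn:
        abnormality = AbnormalityRow(
            n=len(abn),
            detections=sum(1 for c in abn if c.detection.detected),
            followup=_mi([c.followup_months for c in abn]),
        )
    return CohortStats(tuple(prog_rows), tuple(stable_rows), abnormality, tuple(warn))
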