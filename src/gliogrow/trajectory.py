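"""Longitudinal volume series: baseline determination and curve normalization.

A case's record is a time-ordered sequence of tumor volumes (pixels^3)
measured at irregular intervals (months from the first scan).  Growth
detection is anchored at a *baseline* scan: for resected tumors this is the
first volume minimum after surgery, chosen to exclude FLAIR signal still
resolving from the operation itself; for never-operated cases (imaging
abnormalities) the first scan serves as baseline.

Curve normalization maps a series onto the unit square so that growth
kinetics can be compared across tumors of very different sizes and
follow-up lengths: volumes have the baseline subtracted and are divided by
the most recent volume, times are offset to the baseline and divided by the
largest interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "PATHOLOGIES",
    "GROUPS",
    "VolumeSeries",
    "BaselineResult",
    "NormalizedCurve",
    "find_baseline",
    "percent_change",
    "normalize_curve",
    "MIN_SCANS_FOR_ANALYSIS",
]

PATHOLOGIES = ("oligodendroglioma", "astrocytoma", "mixed", "imaging_abnormality")
GROUPS = ("progression", "stable", "imaging_abnormality")

#: Inclusion criterion for cohort-level analysis: at least 4 scans per case.
MIN_SCANS_FOR_ANALYSIS = 4


@dataclass(frozen=True)
class VolumeSeries:
    """One case's longitudinal tumor volumes.

    Parameters
    ----------
    case_id : str
        Opaque case identifier.
    times : sequence of float
        Months from the first scan; strictly increasing, first entry >= 0.
    volumes : sequence of float
        Tumor volumes in pixels^3; strictly positive.
    pathology : str
        One of :data:`PATHOLOGIES`.
    group : str
        One of :data:`GROUPS` (radiological-course group).
    had_resection : bool
        Whether the tumor was surgically resected before follow-up; governs
        the baseline rule.
    vc_detection_time : float, optional
        Months at which growth was called by visual comparison of the
        longitudinal images (from radiology reports); absent when no such
        call exists.  This is annotation data, never recomputed.
    earliest_baseline_time : float, optional
        Earliest month admissible as baseline, e.g. the completion of
        chemotherapy; scans before it are excluded from the baseline search.
    """

    case_id: str
    times: np.ndarray
    volumes: np.ndarray
    pathology: str = "astrocytoma"
    group: str = "progression"
    had_resection: bool = True
    vc_detection_time: Optional[float] = None
    earliest_baseline_time: Optional[float] = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        volumes = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "volumes", volumes)
        if times.ndim != 1 or volumes.ndim != 1 or len(times) != len(volumes):
            raise InvalidInputError(
                f"case {self.case_id}: times and volumes must be 1-D and equal length"
            )
        if len(times) < 1:
            raise InvalidInputError(f"case {self.case_id}: empty series")
        if np.any(np.diff(times) <= 0):
            raise InvalidInputError(f"case {self.case_id}: times must be strictly increasing")
        if times[0] < 0:
            raise InvalidInputError(f"case {self.case_id}: negative time offset")
        if np.any(volumes <= 0):
            raise InvalidInputError(f"case {self.case_id}: volumes must be positive")
        if self.pathology not in PATHOLOGIES:
            raise InvalidInputError(f"case {self.case_id}: unknown pathology {self.pathology!r}")
        if self.group not in GROUPS:
            raise InvalidInputError(f"case {self.case_id}: unknown group {self.group!r}")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def meets_inclusion(self) -> bool:
        """True when the case has enough scans for cohort analysis."""
        return len(self) >= MIN_SCANS_FOR_ANALYSIS

    def truncated(self, n: int) -> "VolumeSeries":
        """Return a copy containing only the first ``n`` scans."""
        return VolumeSeries(
            case_id=self.case_id,
            times=self.times[:n],
            volumes=self.volumes[:n],
            pathology=self.pathology,
            group=self.group,
            had_resection=self.had_resection,
            vc_detection_time=self.vc_detection_time,
            earliest_baseline_time=self.earliest_baseline_time,
        )


@dataclass(frozen=True)
class BaselineResult:
    baseline_index: int
    baseline_volume: float
    baseline_time: float


@dataclass(frozen=True)
class NormalizedCurve:
    """Dimensionless growth curve on [0, 1] x (-inf, 1]."""

    times: np.ndarray
    volumes: np.ndarray
    case_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "volumes", np.asarray(self.volumes, dtype=float))

    def __len__(self) -> int:
        return len(self.times)


def find_baseline(series: VolumeSeries) -> BaselineResult:
    """Locate the baseline scan of a series.

    For resected tumors the baseline is the first volume minimum after
    surgery: the earliest scan not exceeded by any earlier scan and followed
    by a strict volume increase.  A plateau at the minimum resolves to the
    last scan of the minimal run before the rise; if the series never rises,
    the last scan is the minimum.  Non-operated cases use the first scan.
    ``earliest_baseline_time`` (e.g. the end of chemotherapy) restricts the
    search window.
    """
    v = series.volumes
    n = len(v)
    start = 0
    if series.earliest_baseline_time is not None:
        eligible = np.nonzero(series.times >= series.earliest_baseline_time)[0]
        if len(eligible) == 0:
            raise InvalidInputError(
                f"case {series.case_id}: no scan at or after earliest_baseline_time"
            )
        start = int(eligible[0])
    if not series.had_resection:
        return BaselineResult(start, float(v[start]), float(series.times[start]))

    prefix_min = np.inf
    for i in range(start, n):
        if v[i] <= prefix_min:
            if i == n - 1 or v[i + 1] > v[i]:
                return BaselineResult(i, float(v[i]), float(series.times[i]))
        prefix_min = min(prefix_min, v[i])
    # Unreachable: the last index always satisfies the condition when it is
    # a prefix minimum, and some prefix minimum always is the last one seen.
    raise AssertionError("baseline search exhausted without a minimum")


def percent_change(v: float, v0: float) -> float:
    """Fractional volume change from baseline: (v - v0) / v0."""
    if v0 <= 0:
        raise InvalidInputError("baseline volume must be positive")
    return (v - v0) / v0


def normalize_curve(series: VolumeSeries, baseline: BaselineResult) -> NormalizedCurve:
    """Map the post-baseline series onto dimensionless coordinates.

    Volumes: subtract the baseline volume and divide by the most recent
    volume, so the baseline maps to 0 and the final point to
    ``1 - V0/v_last`` (shrinking series yield negative values).  Times:
    offset to the baseline and divide by the largest interval, so the last
    scan maps to exactly 1.  Scans before the baseline are dropped.
    """
    i0 = baseline.baseline_index
    t = series.times[i0:]
    v = series.volumes[i0:]
    if len(t) < 2:
        raise InvalidInputError(
            f"case {series.case_id}: need at least 2 scans at/after baseline to normalize"
        )
    span = t[-1] - t[0]
    if span <= 0:
        raise InvalidInputError(f"case {series.case_id}: zero time span after baseline")
    v_last = v[-1]
    if v_last <= 0:
        raise InvalidInputError(f"case {series.case_id}: nonpositive final volume")
    return NormalizedCurve(
        times=(t - t[0]) / span,
        volumes=(v - baseline.baseline_volume) / v_last,
        case_id=series.case_id,
    )
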