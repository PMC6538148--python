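"""Readers and writers for the pipeline's tabular formats.

Canonical on-disk layout is comma-separated text with a header row:

volume table
    ``case_id,time_months,volume_px3`` — one row per scan; times in months
    from the case's first scan, strictly increasing; volumes in pixels^3.
    The deposited spreadsheet layout (same columns, .xlsx) is also accepted.
annotation table
    ``case_id,pathology,group,had_resection,vc_detection_time,earliest_baseline_time``
    — one row per case; the last two columns may be empty.

Writers are deterministic: rows sorted by case id, volumes written as
integers, months and fractions with 2 decimals.  Validation failures are
collected and raised together as :class:`~gliogrow.errors.TableFormatError`
with row provenance.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .changepoint import DetectionResult
from .cohort_stats import CaseResult, CohortStats, format_p
from .errors import TableFormatError
from .growth_models import GrowthFit, PooledFit
from .trajectory import VolumeSeries

__all__ = [
    "read_volume_table",
    "write_volume_table",
    "write_annotations",
    "write_detection_table",
    "write_fit_table",
    "write_pooled_fit",
    "write_cohort_report",
]

logger = logging.getLogger("gliogrow")

VOLUME_COLUMNS = ["case_id", "time_months", "volume_px3"]
ANNOTATION_COLUMNS = [
    "case_id",
    "pathology",
    "group",
    "had_resection",
    "vc_detection_time",
    "earliest_baseline_time",
]

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def _parse_bool(value, issues: List[str], where: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    issues.append(f"{where}: cannot parse boolean {value!r}")
    return False


def _parse_optional_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return float(s) if s else None


def read_volume_table(path, annotation_path) -> List[VolumeSeries]:
    """Load and validate a volume table plus its annotation table.

    Returns one :class:`VolumeSeries` per annotated case, ordered by case
    id.  Any violation — missing columns, non-monotone times, nonpositive
    volumes, volume rows whose case id is absent from the annotations — is
    reported with its row number; all issues are collected before raising.
    """
    issues: List[str] = []
    vol = _read_table(path)
    ann = _read_table(annotation_path)

    missing = [c for c in VOLUME_COLUMNS if c not in vol.columns]
    if missing:
        raise TableFormatError([f"{path}: missing columns {missing}"])
    if "case_id" not in ann.columns:
        raise TableFormatError([f"{annotation_path}: missing column 'case_id'"])

    ann = ann.astype({"case_id": str})
    vol = vol.astype({"case_id": str})
    annotations = {}
    for idx, row in ann.iterrows():
        where = f"{annotation_path}:row {idx + 2}"
        annotations[row["case_id"]] = {
            "pathology": str(row.get("pathology", "astrocytoma")),
            "group": str(row.get("group", "progression")),
            "had_resection": _parse_bool(row.get("had_resection", "false"), issues, where),
            "vc_detection_time": _parse_optional_float(row.get("vc_detection_time")),
            "earliest_baseline_time": _parse_optional_float(row.get("earliest_baseline_time")),
        }

    series: List[VolumeSeries] = []
    for case_id, sub in vol.groupby("case_id", sort=True):
        rows = sub.index.to_numpy() + 2  # header + 1-based
        if case_id not in annotations:
            issues.append(f"{path}:rows {rows[0]}-{rows[-1]}: case {case_id} missing from annotations")
            continue
        times = sub["time_months"].to_numpy(dtype=float)
        volumes = sub["volume_px3"].to_numpy(dtype=float)
        bad_time = np.nonzero(np.diff(times) <= 0)[0]
        for k in bad_time:
            issues.append(f"{path}:row {rows[k + 1]}: case {case_id} times not strictly increasing")
        bad_vol = np.nonzero(volumes <= 0)[0]
        for k in bad_vol:
            issues.append(f"{path}:row {rows[k]}: case {case_id} nonpositive volume")
        if len(bad_time) or len(bad_vol):
            continue
        meta = annotations[case_id]
        try:
            s = VolumeSeries(case_id=case_id, times=times, volumes=volumes, **meta)
        except Exception as exc:
            issues.append(f"{path}:rows {rows[0]}-{rows[-1]}: {exc}")
            continue
        if not s.meets_inclusion:
            logger.warning("case %s has fewer than 4 scans; kept but below inclusion criterion", case_id)
        series.append(s)

    if issues:
        for msg in issues:
            logger.warning(msg)
        raise TableFormatError(issues)
    return series


def _fmt_optional(value: Optional[float], fmt: str = "{:.2f}") -> str:
    return "" if value is None else fmt.format(value)


def write_volume_table(series_list: Sequence[VolumeSeries], path) -> None:
    lines = [",".join(VOLUME_COLUMNS)]
    for s in sorted(series_list, key=lambda s: s.case_id):
        for t, v in zip(s.times, s.volumes):
            lines.append(f"{s.case_id},{t:.2f},{round(v):d}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_annotations(series_list: Sequence[VolumeSeries], path) -> None:
    lines = [",".join(ANNOTATION_COLUMNS)]
    for s in sorted(series_list, key=lambda s: s.case_id):
        lines.append(
            ",".join(
                [
                    s.case_id,
                    s.pathology,
                    s.group,
                    str(s.had_resection).lower(),
                    _fmt_optional(s.vc_detection_time),
                    _fmt_optional(s.earliest_baseline_time),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_detection_table(results: Sequence[CaseResult], path) -> None:
    """One row per case: baseline, alert visit, change point, TTG, dV."""
    header = [
        "case_id",
        "baseline_index",
        "baseline_volume_px3",
        "detected",
        "alert_visit_index",
        "changepoint_index",
        "ttg_months",
        "delta_v",
    ]
    lines = [",".join(header)]
    for c in sorted(results, key=lambda c: c.series.case_id):
        d = c.detection
        lines.append(
            ",".join(
                [
                    c.series.case_id,
                    str(c.baseline.baseline_index),
                    f"{round(c.baseline.baseline_volume):d}",
                    str(d.detected).lower(),
                    "" if d.alert_visit_index is None else str(d.alert_visit_index),
                    "" if d.changepoint_index is None else str(d.changepoint_index),
                    _fmt_optional(d.ttg_months),
                    _fmt_optional(d.delta_v),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fit_table(fits: Sequence[GrowthFit], path) -> None:
    header = ["case_id", "p1", "p2", "a", "b", "sse_lin", "sse_exp", "r2", "classification"]
    lines = [",".join(header)]
    for f in sorted(fits, key=lambda f: f.case_id):
        lines.append(
            f"{f.case_id},{f.p1:.6g},{f.p2:.6g},{f.a:.6g},{f.b:.6g},"
            f"{f.sse_lin:.6g},{f.sse_exp:.6g},{f.r2:.4f},{f.classification}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_pooled_fit(pf: PooledFit, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "a": round(pf.a, 6),
                "b": round(pf.b, 4),
                "sse": round(pf.sse, 4),
                "r2": round(pf.r2, 4),
                "n_points": pf.n_points,
                "n_curves": pf.n_curves,
            },
            indent=2,
        )
        + "\n"
    )


def _mi_str(mi, scale: float = 1.0, unit: str = "") -> str:
    if mi is None:
        return "N.A."
    med, q1, q3 = (x * scale for x in mi)
    return f"{med:.0f}{unit} ({q1:.0f}{unit}–{q3:.0f}{unit})"


def write_cohort_report(stats: CohortStats, directory) -> List[Path]:
    """Write the three tab-separated summary tables into ``directory``.

    Progression: pathology, n, dG, CAD/VC TTG median (IQR) in months with a
    MWW p-value, CAD/VC dV median (IQR) in percent with a p-value.  Stable:
    CAD-only columns plus follow-up durations of grown vs stable cases.
    Imaging abnormality: detection count and follow-up.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    path = directory / "progression_summary.tsv"
    lines = ["pathology\tn\tdelta_g\tttg_cad\tttg_vc\tp_ttg\tdv_cad\tdv_vc\tp_dv"]
    for r in stats.progression:
        lines.append(
            "\t".join(
                [
                    r.pathology,
                    str(r.n),
                    str(r.delta_g),
                    _mi_str(r.ttg_cad),
                    _mi_str(r.ttg_vc),
                    "" if r.p_ttg is None else format_p(r.p_ttg),
                    _mi_str(r.dv_cad, scale=100, unit="%"),
                    _mi_str(r.dv_vc, scale=100, unit="%"),
                    "" if r.p_dv is None else format_p(r.p_dv),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    written.append(path)

    path = directory / "stable_summary.tsv"
    lines = ["pathology\tn\tcad_g\tttg_cad\tfu_growth\tfu_stable\tdv_cad"]
    for r in stats.stable:
        lines.append(
            "\t".join(
                [
                    r.pathology,
                    str(r.n),
                    str(r.cad_g),
                    _mi_str(r.ttg_cad),
                    _mi_str(r.fu_growth),
                    _mi_str(r.fu_stable),
                    _mi_str(r.dv_cad, scale=100, unit="%"),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    written.append(path)

    path = directory / "abnormality_summary.tsv"
    lines = ["n\tdetections\tfollowup_months"]
    if stats.abnormality is not None:
        a = stats.abnormality
        lines.append(f"{a.n}\t{a.detections}\t{_mi_str(a.followup)}")
    path.write_text("\n".join(lines) + "\n")
    written.append(path)
    return written
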