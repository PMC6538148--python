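"""Synthetic longitudinal cohorts and mask phantoms for the detection pipeline.

The generator emulates the structure of MRI-derived glioma volume series:
irregular visit intervals of a few months, multiplicative per-scan
measurement noise (stable series in the source population show per-scan
percent-change mean ~1% with standard deviation ~26.5%), an optional
post-surgical decaying limb preceding the baseline minimum, and growth onset
that is linear (constant px^3/month) or exponential (constant relative rate
per month) after a quiescent interval.

Cohorts come in three radiological-course groups — progression, clinically
stable, imaging abnormality — with a synthetic visual-comparison (VC)
annotation for progression cases: VC "detects" growth at the first visit
whose volume reaches (1 + vc_fold) times baseline, a declared stand-in for
human visual comparison calibrated to the large volume changes (median 174%)
at which growth was historically called from images alone.

Ellipsoid mask phantoms support the volumetric operations, including an
anisotropic mode where the through-plane axis grows faster than the in-plane
axes — growth invisible to single-slice bidimensional measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import InvalidInputError
from .trajectory import VolumeSeries
from .volumetrics import MaskSeries

__all__ = [
    "KINDS",
    "SyntheticConfig",
    "simulate_trajectory",
    "simulate_cohort",
    "simulate_mask_series",
    "anisotropic_growth_axes",
]

KINDS = (
    "stationary",
    "linear_growth",
    "exponential_growth",
    "postop_decay_then_stationary",
    "postop_decay_then_growth",
)

_POSTOP_KINDS = ("postop_decay_then_stationary", "postop_decay_then_growth")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one simulated volume trajectory.

    v0
        Baseline (trend) volume, px^3.  Default 10,000, the rounded median
        baseline volume of the source population.
    noise_mean, noise_sd
        Mean and sd of the per-scan fractional measurement error; each
        volume is the trend times (1 + eps).  Defaults 0.0099 / 0.2654, the
        percent-change statistics of stable series.
    onset_month
        Months after the baseline scan at which growth starts (growth kinds).
    growth_rate
        px^3/month for linear growth; 1/month for exponential growth.
    growth_form
        Trend after onset for ``postop_decay_then_growth``:
        "linear" or "exponential".
    n_decay_scans, decay_fold
        Post-surgical limb: ``n_decay_scans`` scans decaying geometrically
        from ``decay_fold * v0`` down to the baseline trend volume.
    visit_interval_range
        Uniform range (months) for the gap between consecutive scans.
    n_visits
        Scans in the series (>= 4, the analysis inclusion criterion).
    """

    kind: str = "stationary"
    v0: float = 10_000.0
    noise_mean: float = 0.0099
    noise_sd: float = 0.2654
    onset_month: float = 12.0
    growth_rate: float = 0.06
    growth_form: str = "exponential"
    n_decay_scans: int = 2
    decay_fold: float = 1.6
    visit_interval_range: Tuple[float, float] = (2.0, 6.0)
    n_visits: int = 12
    seed: Optional[int] = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise InvalidInputError(f"unknown kind {self.kind!r}")
        if self.v0 <= 0:
            raise InvalidInputError("v0 must be positive")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be nonnegative")
        if self.n_visits < 4:
            raise InvalidInputError("n_visits must be >= 4 (inclusion criterion)")
        lo, hi = self.visit_interval_range
        if not (0 < lo <= hi):
            raise InvalidInputError("visit_interval_range must satisfy 0 < lo <= hi")
        if self.growth_form not in ("linear", "exponential"):
            raise InvalidInputError("growth_form must be 'linear' or 'exponential'")
        if self.kind in _POSTOP_KINDS and self.n_decay_scans < 1:
            raise InvalidInputError("postop kinds need n_decay_scans >= 1")
        if self.kind in _POSTOP_KINDS and self.decay_fold <= 1:
            raise InvalidInputError("decay_fold must exceed 1")


def _trend(cfg: SyntheticConfig, times: np.ndarray) -> np.ndarray:
    """Noise-free volume trend at the given scan times."""
    n_decay = cfg.n_decay_scans if cfg.kind in _POSTOP_KINDS else 0
    t_base = times[n_decay]  # time of the baseline (trend-minimum) scan

    if cfg.kind in ("linear_growth", "exponential_growth"):
        form = "linear" if cfg.kind == "linear_growth" else "exponential"
    elif cfg.kind == "postop_decay_then_growth":
        form = cfg.growth_form
    else:
        form = None  # stationary after baseline

    v = np.full(len(times), cfg.v0, dtype=float)
    if form is not None:
        dt = times - t_base - cfg.onset_month
        grow = dt > 0
        if form == "linear":
            v[grow] = cfg.v0 + cfg.growth_rate * dt[grow]
        else:
            v[grow] = cfg.v0 * np.exp(cfg.growth_rate * dt[grow])

    # post-surgical limb: geometric decay onto the baseline volume
    for j in range(n_decay):
        v[j] = cfg.v0 * cfg.decay_fold ** ((n_decay - j) / n_decay)
    return v


def simulate_trajectory(
    cfg: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
    case_id: str = "synthetic",
    pathology: str = "astrocytoma",
    group: Optional[str] = None,
    vc_detection_time: Optional[float] = None,
) -> VolumeSeries:
    """Draw one volume series: random visit times, deterministic trend,
    multiplicative noise truncated at -0.9 so volumes stay positive.

    The same seed (via ``cfg.seed`` or an explicit ``rng``) reproduces the
    series exactly.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.visit_interval_range
    intervals = rng.uniform(lo, hi, size=cfg.n_visits - 1)
    times = np.concatenate([[0.0], np.cumsum(intervals)])
    trend = _trend(cfg, times)
    eps = np.clip(rng.normal(cfg.noise_mean, cfg.noise_sd, size=cfg.n_visits), -0.9, None)
    volumes = trend * (1.0 + eps)
    if group is None:
        group = "stable" if cfg.kind in ("stationary", "postop_decay_then_stationary") else "progression"
    return VolumeSeries(
        case_id=case_id,
        times=times,
        volumes=volumes,
        pathology=pathology,
        group=group,
        had_resection=cfg.kind in _POSTOP_KINDS,
        vc_detection_time=vc_detection_time,
    )


def _vc_annotation(series: VolumeSeries, baseline_index: int, vc_fold: float) -> Optional[float]:
    """Synthetic visual-comparison call: first visit at/after baseline whose
    volume reaches (1 + vc_fold) times the baseline-scan volume."""
    v0 = series.volumes[baseline_index]
    for i in range(baseline_index, len(series)):
        if series.volumes[i] >= (1.0 + vc_fold) * v0:
            return float(series.times[i])
    return None


# Pathology mix of the source population's progression group (7/18/9 of 34).
_PROGRESSION_PATHOLOGY_P = {"oligodendroglioma": 7 / 34, "astrocytoma": 18 / 34, "mixed": 9 / 34}
# Stable group mix (12/8/2 of 22).
_STABLE_PATHOLOGY_P = {"oligodendroglioma": 12 / 22, "astrocytoma": 8 / 22, "mixed": 2 / 22}


def simulate_cohort(
    n_progression: int = 34,
    n_stable: int = 22,
    n_abnormality: int = 7,
    seed: int = 0,
    vc_fold: float = 1.74,
    exponential_fraction: float = 14 / 47,
    progression_config: SyntheticConfig = SyntheticConfig(kind="postop_decay_then_growth", n_visits=14),
    stable_config: SyntheticConfig = SyntheticConfig(kind="postop_decay_then_stationary"),
    abnormality_config: SyntheticConfig = SyntheticConfig(kind="stationary"),
) -> List[VolumeSeries]:
    """Simulate a three-group cohort with synthetic VC annotations.

    Group sizes default to the source population (34 progression, 22 stable,
    7 imaging abnormality).  Progression cases draw a growth onset uniform
    in 6-24 months and a per-case rate (exponential: 0.04-0.10 /month for a
    fraction ``exponential_fraction`` of cases; otherwise linear 300-1,200
    px^3/month); VC annotations use the fold-change rule at ``vc_fold``
    (default 1.74, the scale of the 174% median volume change at
    image-based detection).
    """
    rng = np.random.default_rng(seed)
    cohort: List[VolumeSeries] = []

    prog_paths = list(_PROGRESSION_PATHOLOGY_P)
    prog_p = list(_PROGRESSION_PATHOLOGY_P.values())
    for i in range(n_progression):
        is_exp = rng.random() < exponential_fraction
        cfg = replace(
            progression_config,
            growth_form="exponential" if is_exp else "linear",
            growth_rate=float(rng.uniform(0.04, 0.10)) if is_exp else float(rng.uniform(300.0, 1200.0)),
            onset_month=float(rng.uniform(6.0, 24.0)),
        )
        s = simulate_trajectory(
            cfg,
            rng=rng,
            case_id=f"prog-{i:03d}",
            pathology=str(rng.choice(prog_paths, p=prog_p)),
            group="progression",
        )
        n_decay = cfg.n_decay_scans if cfg.kind in _POSTOP_KINDS else 0
        vc_time = _vc_annotation(s, baseline_index=n_decay, vc_fold=vc_fold)
        cohort.append(replace(s, vc_detection_time=vc_time))

    stab_paths = list(_STABLE_PATHOLOGY_P)
    stab_p = list(_STABLE_PATHOLOGY_P.values())
    for i in range(n_stable):
        cohort.append(
            simulate_trajectory(
                stable_config,
                rng=rng,
                case_id=f"stab-{i:03d}",
                pathology=str(rng.choice(stab_paths, p=stab_p)),
                group="stable",
            )
        )

    for i in range(n_abnormality):
        cohort.append(
            simulate_trajectory(
                abnormality_config,
                rng=rng,
                case_id=f"abn-{i:03d}",
                pathology="imaging_abnormality",
                group="imaging_abnormality",
            )
        )
    return cohort


def simulate_mask_series(
    axes: Sequence[Tuple[float, float, float]],
    grid_shape: Tuple[int, int, int] = (64, 64, 64),
    slice_distance: float = 1.0,
    pixel_area: float = 1.0,
    seed: Optional[int] = None,
) -> List[MaskSeries]:
    """Rasterized ellipsoid phantoms, one mask stack per time point.

    ``axes`` lists (in-plane row, in-plane col, through-plane) semi-axes in
    pixels for each time point; slices are taken along the through-plane
    axis.  A seed, when given, jitters the common center by up to one voxel.
    An ellipsoid that does not fit inside the grid is an error.
    """
    grid = np.asarray(grid_shape, dtype=int)
    center = (grid - 1) / 2.0
    if seed is not None:
        center = center + np.random.default_rng(seed).uniform(-1.0, 1.0, size=3)
    out: List[MaskSeries] = []
    ii, jj, kk = np.indices(tuple(grid))
    for ax in axes:
        a = np.asarray(ax, dtype=float)
        if np.any(a <= 0):
            raise InvalidInputError("semi-axes must be positive")
        if np.any(center - a < -0.5) or np.any(center + a > grid - 0.5):
            raise InvalidInputError(f"ellipsoid with semi-axes {tuple(a)} exceeds grid {tuple(grid)}")
        mask = (
            ((ii - center[0]) / a[0]) ** 2
            + ((jj - center[1]) / a[1]) ** 2
            + ((kk - center[2]) / a[2]) ** 2
        ) <= 1.0
        slices = tuple(mask[:, :, k] for k in range(grid[2]))
        out.append(MaskSeries(slices, pixel_area=pixel_area, slice_distance=slice_distance))
    return out


def anisotropic_growth_axes(
    base_axes: Tuple[float, float, float],
    n_timepoints: int,
    inplane_rate: float = 0.05,
    throughplane_rate: float = 0.30,
) -> List[Tuple[float, float, float]]:
    """Axes schedule where the through-plane axis grows faster per time point —
    the nonhomogeneous-growth phantom (large volume change, small change on
    the largest axial slice)."""
    a, b, c = base_axes
    return [
        (
            a * (1 + inplane_rate) ** t,
            b * (1 + inplane_rate) ** t,
            c * (1 + throughplane_rate) ** t,
        )
        for t in range(n_timepoints)
    ]
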