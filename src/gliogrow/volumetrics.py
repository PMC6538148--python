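"""Tumor volumetry from segmentation masks, and 2D-vs-3D measurement arithmetic.

Volumes are measured on stacks of axial binary masks: the tumor volume is
the sum of per-slice areas multiplied by the inter-slice distance.  The
canonical unit is pixels^3 (pixel area and slice distance default to 1.0);
physical units are obtained by supplying the scanner's voxel geometry.

The module also provides the bidimensional measurement used in clinical
trials — the product of the two largest perpendicular diameters on the slice
holding the largest tumor component, with progression declared at a >= 25%
product increase — and the arithmetic relating per-dimension growth to
product/volume growth (a 12% increase per dimension is a 25% product
increase in 2D but a 41% volume increase in 3D).  A slice-wise growth
profile flags tumors whose fastest-growing slice is not the largest one:
such nonhomogeneous 3D growth is invisible to the bidimensional rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "Segment",
    "SegmentationLabeling",
    "MaskSeries",
    "BidimConfig",
    "SliceGrowthProfile",
    "combine_segments",
    "compute_volume",
    "volume_from_areas",
    "slice_growth_profile",
    "perpendicular_diameters",
    "bidimensional_product",
    "bidim_progression",
    "homogeneous_scaling",
    "mask_series_from_nifti",
    "mask_series_from_pngs",
]

#: Sentinel fractional change for a slice growing from zero baseline area.
UNDEFINED_RATIO = np.inf


@dataclass(frozen=True)
class Segment:
    """One segmented region of an image with its maximal intensity."""

    mask: np.ndarray
    max_intensity: float

    def __post_init__(self):
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


@dataclass(frozen=True)
class SegmentationLabeling:
    """Automated segmentation output for one image: ranked regions plus the
    gray-matter intensity level used to select tumor regions."""

    segments: Tuple[Segment, ...]
    gray_matter_level: float

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(self.segments))


@dataclass(frozen=True)
class MaskSeries:
    """Ordered axial binary masks with voxel geometry.

    ``pixel_area`` is the in-plane area per pixel and ``slice_distance`` the
    distance between consecutive axial images; both default to 1.0 so that
    volumes come out in pixels^3.
    """

    slices: Tuple[np.ndarray, ...]
    pixel_area: float = 1.0
    slice_distance: float = 1.0

    def __post_init__(self):
        slices = tuple(np.asarray(s, dtype=bool) for s in self.slices)
        object.__setattr__(self, "slices", slices)
        if self.slice_distance <= 0:
            raise InvalidInputError("slice_distance must be positive")
        if self.pixel_area <= 0:
            raise InvalidInputError("pixel_area must be positive")
        if slices:
            shape = slices[0].shape
            if any(s.shape != shape for s in slices):
                raise InvalidInputError("all slices must share in-plane dimensions")

    def __len__(self) -> int:
        return len(self.slices)

    def slice_areas(self) -> np.ndarray:
        """Per-slice tumor area (pixel count times pixel_area)."""
        return np.array([s.sum() * self.pixel_area for s in self.slices], dtype=float)


@dataclass(frozen=True)
class BidimConfig:
    """Bidimensional progression rule: fractional product increase threshold."""

    progression_fraction: float = 0.25

    def __post_init__(self):
        if self.progression_fraction <= 0:
            raise InvalidInputError("progression_fraction must be positive")


@dataclass(frozen=True)
class SliceGrowthProfile:
    """Per-slice fractional area change between two time points."""

    fractional_change: np.ndarray
    max_growth_slice: int
    largest_baseline_slice: int
    nonhomogeneous: bool


def combine_segments(labeling: SegmentationLabeling) -> np.ndarray:
    """Merge the regions whose maximal intensity exceeds the gray-matter level.

    The tumor mask is the union of all segments strictly above the
    gray-matter intensity; a segment at exactly the gray level is excluded
    (conservative reading of "above").  Returns an all-false mask when no
    segment qualifies.
    """
    if not labeling.segments:
        raise InvalidInputError("segment list is empty")
    shape = labeling.segments[0].mask.shape
    out = np.zeros(shape, dtype=bool)
    for seg in labeling.segments:
        if seg.mask.shape != shape:
            raise InvalidInputError("segments must share image dimensions")
        if seg.max_intensity > labeling.gray_matter_level:
            out |= seg.mask
    return out


def compute_volume(masks: MaskSeries) -> float:
    """Tumor volume: sum of per-slice areas times the inter-slice distance."""
    return float(masks.slice_areas().sum() * masks.slice_distance)


def volume_from_areas(areas: Sequence[float], slice_distance: float) -> float:
    """Volume from already-measured per-slice areas (e.g. published values)."""
    if slice_distance <= 0:
        raise InvalidInputError("slice_distance must be positive")
    areas = np.asarray(areas, dtype=float)
    if np.any(areas < 0):
        raise InvalidInputError("areas must be nonnegative")
    return float(areas.sum() * slice_distance)


def _areas_of(obj: Union[MaskSeries, Sequence[float]]) -> np.ndarray:
    if isinstance(obj, MaskSeries):
        return obj.slice_areas()
    return np.asarray(obj, dtype=float)


def slice_growth_profile(
    masks_t0: Union[MaskSeries, Sequence[float]],
    masks_t1: Union[MaskSeries, Sequence[float]],
) -> SliceGrowthProfile:
    """Per-slice fractional area change between baseline and follow-up.

    Accepts mask stacks or already-measured area sequences (matched
    anatomical ordering assumed).  A slice growing from zero baseline area
    is reported with the :data:`UNDEFINED_RATIO` sentinel rather than an
    exception; two empty slices give 0.  The profile is *nonhomogeneous*
    when the max-growth slice is not the largest baseline slice and grows
    strictly faster than it — growth the bidimensional rule, which looks
    only at the largest slice, can miss.
    """
    a0 = _areas_of(masks_t0)
    a1 = _areas_of(masks_t1)
    if len(a0) != len(a1):
        raise InvalidInputError(f"slice counts differ: {len(a0)} vs {len(a1)}")
    if len(a0) == 0:
        raise InvalidInputError("empty mask series")
    change = np.empty(len(a0), dtype=float)
    for i, (b, f) in enumerate(zip(a0, a1)):
        if b > 0:
            change[i] = (f - b) / b
        else:
            change[i] = 0.0 if f == 0 else UNDEFINED_RATIO
    max_growth = int(np.argmax(change))  # ties -> lowest index
    largest_baseline = int(np.argmax(a0))
    nonhomogeneous = (
        max_growth != largest_baseline and change[max_growth] > change[largest_baseline]
    )
    return SliceGrowthProfile(change, max_growth, largest_baseline, bool(nonhomogeneous))


_SIN_1_DEG = np.sin(np.deg2rad(1.0))


def _candidate_points(mask: np.ndarray) -> np.ndarray:
    """Pixel centers relevant for diameter search: boundary pixels, reduced
    to the convex hull when the boundary is large."""
    from scipy import ndimage

    interior = ndimage.binary_erosion(mask)
    pts = np.argwhere(mask & ~interior).astype(float)
    if len(pts) == 0:
        pts = np.argwhere(mask).astype(float)
    if len(pts) > 1500:
        from scipy.spatial import ConvexHull

        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:  # degenerate (collinear) point sets
            pass
    return pts


def perpendicular_diameters(mask: np.ndarray) -> Tuple[float, float]:
    """Largest diameter d1 and largest perpendicular extent d2 of a mask.

    Distances are between pixel centers; a single-pixel mask has diameter 1
    by convention (no zero products).  d2 is the largest perpendicular
    component among pixel pairs whose connecting line is perpendicular to d1
    within 1 degree or within one pixel of shear, whichever is looser — a
    pixel grid cannot resolve 1 degree at chord lengths below ~57 px, so the
    one-pixel allowance keeps the measure rotation-tolerant.  When several
    pairs attain d1, the one admitting the larger d2 wins; masks with no
    perpendicular extent (e.g. 1-px lines) fall back to d2 = 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidInputError("empty mask")
    if mask.sum() == 1:
        return 1.0, 1.0
    pts = _candidate_points(mask)
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    d1 = float(dist.max())
    if d1 == 0.0:
        return 1.0, 1.0

    # all pairs attaining d1 (within float tolerance)
    major_pairs = np.argwhere(dist >= d1 - 1e-9)
    best_d2 = 0.0
    for i, j in major_pairs:
        if i >= j:
            continue
        u = diff[i, j] / dist[i, j]
        par = np.abs(diff @ u)  # component along d1
        perp = np.sqrt(np.maximum(dist**2 - par**2, 0.0))
        ok = (par <= dist * _SIN_1_DEG) | (par <= 1.0)
        best_d2 = max(best_d2, float(perp[ok].max()))
    return d1, max(best_d2, 1.0)


def bidimensional_product(mask: np.ndarray) -> float:
    """Product of the two largest perpendicular diameters of one slice (px^2)."""
    d1, d2 = perpendicular_diameters(mask)
    return d1 * d2


def largest_component_slice(masks: MaskSeries) -> int:
    """Index of the slice with the largest tumor area (ties -> lowest index)."""
    areas = masks.slice_areas()
    if len(areas) == 0 or areas.max() == 0:
        raise InvalidInputError("mask series has no tumor pixels")
    return int(np.argmax(areas))


def bidim_progression(
    product_baseline: float,
    product_current: float,
    cfg: BidimConfig = BidimConfig(),
) -> bool:
    """Clinical 2D progression call: product increase >= the threshold fraction."""
    if product_baseline <= 0:
        raise InvalidInputError("baseline product must be positive")
    if product_current <= 0:
        raise InvalidInputError("current product must be positive")
    return (product_current / product_baseline - 1.0) >= cfg.progression_fraction - 1e-12


def homogeneous_scaling(per_dimension_increase: float, n_dims: int) -> float:
    """Fractional measure increase from equal growth in every dimension.

    A fractional increase d applied per dimension multiplies a
    2D product by (1+d)^2 and a volume by (1+d)^3; the return value is
    (1+d)^n - 1.  E.g. d = 0.12 gives +25% in 2D but +41% in 3D, so the
    bidimensional progression rule tolerates far larger volume growth than
    its 25% suggests.
    """
    if n_dims not in (2, 3):
        raise InvalidInputError("n_dims must be 2 or 3")
    if per_dimension_increase <= -1:
        raise InvalidInputError("per-dimension increase must exceed -1")
    return (1.0 + per_dimension_increase) ** n_dims - 1.0


def mask_series_from_nifti(
    path,
    label: Optional[int] = None,
    slice_axis: int = 2,
    pixel_area: Optional[float] = None,
    slice_distance: Optional[float] = None,
) -> MaskSeries:
    """Load a binary or labeled NIfTI volume as a :class:`MaskSeries`.

    Voxel geometry is read from the header zooms unless overridden; the
    tumor mask is ``data > 0`` for binary input or ``data == label``.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise InvalidInputError(f"expected a 3-D NIfTI volume, got shape {data.shape}")
    mask = (data > 0) if label is None else (data == label)
    zooms = img.header.get_zooms()[:3]
    in_plane = [zooms[a] for a in range(3) if a != slice_axis]
    if pixel_area is None:
        pixel_area = float(in_plane[0] * in_plane[1])
    if slice_distance is None:
        slice_distance = float(zooms[slice_axis])
    slices = tuple(np.take(mask, k, axis=slice_axis) for k in range(mask.shape[slice_axis]))
    return MaskSeries(slices, pixel_area=pixel_area, slice_distance=slice_distance)


def mask_series_from_pngs(
    paths: Sequence, pixel_area: float = 1.0, slice_distance: float = 1.0
) -> MaskSeries:
    """Load an ordered per-slice PNG stack (nonzero pixels = tumor)."""
    import imageio.v3 as iio

    slices = []
    for p in paths:
        arr = np.asarray(iio.imread(str(p)))
        if arr.ndim == 3:  # collapse channels
            arr = arr.max(axis=-1)
        slices.append(arr > 0)
    return MaskSeries(tuple(slices), pixel_area=pixel_area, slice_distance=slice_distance)
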