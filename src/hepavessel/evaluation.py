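"""Segmentation accuracy machinery.

Phantom accuracy uses a theoretical reference-area model that accounts for
the partial volume effect: a perfect circle of a given diameter (in
pixels) is placed on the sampling grid in three canonical positions --
centered on a pixel corner, on the middle of a pixel edge, and on a pixel
center -- and per-pixel coverage fractions are computed.  The *optimal*
vessel area is the number of pixels with at least 50% vessel tissue
(minimized over the placements), the *maximum* vessel area the number of
pixels with any vessel tissue (maximized over placements), and the
*calculated* area the exact circle area pi (d/2)^2.  A segmented per-slice
area inside the [optimal, maximum] band counts as valid; otherwise the
pixels outside the band, divided by the calculated area, give the relative
area error in percent.

Object-level accuracy works on 2D connected components per slice:
hit rate (fraction of reference objects overlapped by the segmentation),
per-object sensitivity, average symmetric surface distance

    ASSD(A, B) = ( sum_a min_b ||a-b|| + sum_b min_a ||a-b|| ) / (N_A + N_B)

and the Hausdorff distance

    H(A, B) = max( max_a min_b ||a-b||, max_b min_a ||a-b|| )

between boundary point sets A, B (centers of border pixels, in mm).
Image-level values are medians over detected objects; case-level values
are means over images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .image_io import Mask, ValidationError, Volume
from .phantom import GroundTruth

logger = logging.getLogger("hepavessel")

_PLACEMENTS = {"corner": (0.0, 0.0), "edge": (0.5, 0.0), "center": (0.5, 0.5)}
_STRUCT_8 = np.ones((3, 3), dtype=bool)
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class ReferenceAreas:
    """Reference pixel counts for a circle at a given pixels-per-diameter."""

    optimal: int
    maximum: int
    calculated: float

    def __post_init__(self) -> None:
        if not (0 <= self.optimal <= self.maximum):
            raise ValidationError(f"need 0 <= optimal <= maximum, got {self}")


@dataclass
class ObjectMetrics:
    """Accuracy of one matched 2D object."""

    sensitivity: float
    assd_px: float
    assd_mm: float
    hausdorff_px: float
    hausdorff_mm: float


@dataclass
class CaseSummary:
    """Image-level medians over detected objects plus the object hit rate."""

    hit_rate: float
    median_sensitivity: float  # percent
    median_assd_px: float
    median_assd_mm: float
    median_hausdorff_px: float
    median_hausdorff_mm: float
    object_count: int


def circle_coverage(
    diameter_px: float,
    placement: str = "corner",
    supersampling: int = 64,
    diameter_y_px: float | None = None,
    offset: tuple[float, float] | None = None,
) -> np.ndarray:
    """Per-pixel coverage fractions of a circle on the unit sampling grid.

    ``placement`` positions the circle center on a pixel corner (a grid
    point), the middle of a pixel edge, or a pixel center.  Coverage is
    estimated by midpoint supersampling with ``supersampling`` subdivisions
    per axis; the total coverage equals the circle area pi (d/2)^2 to well
    under 0.1% at the default setting.

    ``diameter_y_px`` turns the circle into an axis-aligned ellipse (the
    cross-section of a tilted tube); ``offset`` overrides the placement
    with an arbitrary sub-pixel center, the continuous-offset companion of
    the three canonical placements.
    """
    if diameter_px <= 0 or (diameter_y_px is not None and diameter_y_px <= 0):
        raise ValidationError("diameter must be > 0")
    if offset is not None:
        ox, oy = float(offset[0]), float(offset[1])
    else:
        if placement not in _PLACEMENTS:
            raise ValidationError(f"placement must be one of {sorted(_PLACEMENTS)}")
        ox, oy = _PLACEMENTS[placement]
    rx = diameter_px / 2.0
    ry = rx if diameter_y_px is None else diameter_y_px / 2.0
    # pixel [i, i+1) x [j, j+1) on an integer lattice; center at (ox, oy)
    lo = int(np.floor(-max(rx, ry))) - 1
    hi = int(np.ceil(max(rx, ry))) + 2
    n = hi - lo
    s = supersampling
    sub = (np.arange(s) + 0.5) / s
    xs = ((lo + np.arange(n)[:, None] + sub[None, :]).ravel() - ox) / rx
    ys = ((lo + np.arange(n)[:, None] + sub[None, :]).ravel() - oy) / ry
    inside = (xs[:, None] ** 2 + ys[None, :] ** 2) <= 1.0
    cov = inside.reshape(n, s, n, s).mean(axis=(1, 3))
    return cov


def reference_areas(
    diameter_px: float,
    supersampling: int = 64,
    diameter_y_px: float | None = None,
) -> ReferenceAreas:
    """Optimal/maximum/calculated areas over the three canonical placements.

    optimal = min over placements of #{coverage >= 0.5};
    maximum = max over placements of #{coverage > 0};
    calculated = pi (d/2)^2 (pi dx dy / 4 for an ellipse).
    """
    optimal = None
    maximum = None
    for placement in ("corner", "edge", "center"):
        cov = circle_coverage(diameter_px, placement, supersampling, diameter_y_px)
        n_opt = int(np.count_nonzero(cov >= 0.5))
        n_max = int(np.count_nonzero(cov > 0))
        optimal = n_opt if optimal is None else min(optimal, n_opt)
        maximum = n_max if maximum is None else max(maximum, n_max)
    dy = diameter_px if diameter_y_px is None else diameter_y_px
    return ReferenceAreas(
        optimal=optimal, maximum=maximum, calculated=float(np.pi * diameter_px * dy / 4.0)
    )


def tilted_tube_reference(
    diameter_px: float, tilt_deg: float, supersampling: int = 64
) -> ReferenceAreas:
    """Reference band for the elliptical cross-section of a tilted tube.

    A tube tilted ``tilt_deg`` from the slice normal (within the x-z plane)
    intersects each slice in an ellipse with axes d/cos(tilt) by d; the
    band is the three-placement model applied to that ellipse.
    """
    c = np.cos(np.deg2rad(tilt_deg))
    if c <= 0:
        raise ValidationError("tilt must be < 90 degrees")
    return reference_areas(diameter_px / c, supersampling, diameter_y_px=diameter_px)


def relative_area_error(segmented_px: float, ref: ReferenceAreas) -> float:
    """Relative area error in percent under the valid-range rule.

    Zero when the segmented pixel count falls inside [optimal, maximum];
    otherwise the distance outside the band divided by the calculated area.
    """
    if segmented_px < 0:
        raise ValidationError("segmented pixel count must be >= 0")
    if ref.optimal <= segmented_px <= ref.maximum:
        return 0.0
    missed = ref.optimal - segmented_px if segmented_px < ref.optimal else segmented_px - ref.maximum
    return float(missed / ref.calculated * 100.0)


def slice_reference_areas(truth: GroundTruth, calculated_px: float) -> list[ReferenceAreas]:
    """Per-slice reference bands from generated ground-truth coverage.

    Used for tilted tubes, whose elliptical cross-sections have no single
    canonical band; the band per slice is [#{coverage >= 0.5},
    #{coverage > 0}] with the analytic cross-section area as the
    ``calculated`` normalizer.
    """
    cov = truth.coverage
    out = []
    for k in range(cov.shape[2]):
        sl = cov[:, :, k]
        out.append(
            ReferenceAreas(
                optimal=int(np.count_nonzero(sl >= 0.5)),
                maximum=int(np.count_nonzero(sl > 0)),
                calculated=float(calculated_px),
            )
        )
    return out


def phantom_slice_errors(
    segmented: Mask,
    bands,
    exclude_end_slices: int = 2,
) -> np.ndarray:
    """Per-interior-slice relative area errors of a segmented tube phantom.

    ``bands`` is either one :class:`ReferenceAreas` applied to every slice
    (perpendicular tube) or a per-slice sequence.  The first and last
    ``exclude_end_slices`` slices, where the tube enters and leaves the
    volume, are excluded.
    """
    nz = segmented.n_slices
    if isinstance(bands, ReferenceAreas):
        bands = [bands] * nz
    if len(bands) != nz:
        raise ValidationError("need one reference band per slice")
    ks = range(exclude_end_slices, nz - exclude_end_slices)
    areas = segmented.data.sum(axis=(0, 1))
    return np.array([relative_area_error(float(areas[k]), bands[k]) for k in ks])


@dataclass
class MatchedObject:
    """A reference 2D object and the overlapping segmented pixels, per slice."""

    z: int
    ref_id: int
    ref_pixels: np.ndarray  # 2D bool
    seg_pixels: np.ndarray  # 2D bool (union of overlapping segmented objects)
    detected: bool


def match_objects(segmented: Mask, reference: Mask) -> tuple[list[MatchedObject], float]:
    """Pair per-slice reference objects with overlapping segmented objects.

    A reference object counts as detected when at least one segmented pixel
    overlaps it; the hit rate is the detected fraction in percent.  An
    empty reference yields NaN (flagged in the log).
    """
    if segmented.shape != reference.shape:
        raise ValidationError("segmented/reference shape mismatch")
    matches: list[MatchedObject] = []
    for k in range(reference.n_slices):
        ref_sl = reference.bool[:, :, k]
        if not ref_sl.any():
            continue
        seg_sl = segmented.bool[:, :, k]
        ref_lab, n_ref = ndimage.label(ref_sl, structure=_STRUCT_8)
        seg_lab, _ = ndimage.label(seg_sl, structure=_STRUCT_8)
        for i in range(1, n_ref + 1):
            ref_obj = ref_lab == i
            overlap_ids = np.unique(seg_lab[ref_obj & seg_sl])
            overlap_ids = overlap_ids[overlap_ids > 0]
            seg_obj = np.isin(seg_lab, overlap_ids) if overlap_ids.size else np.zeros_like(ref_obj)
            matches.append(
                MatchedObject(
                    z=k, ref_id=i, ref_pixels=ref_obj, seg_pixels=seg_obj,
                    detected=bool(overlap_ids.size),
                )
            )
    if not matches:
        logger.warning("match_objects: empty reference mask, hit rate undefined")
        return matches, float("nan")
    hit_rate = 100.0 * sum(m.detected for m in matches) / len(matches)
    return matches, hit_rate


def object_sensitivity(seg_obj: np.ndarray, ref_obj: np.ndarray) -> float:
    """True-positive fraction |seg AND ref| / |ref| for one 2D object."""
    ref_obj = np.asarray(ref_obj, dtype=bool)
    if not ref_obj.any():
        raise ValidationError("reference object is empty")
    seg_obj = np.asarray(seg_obj, dtype=bool)
    return float((seg_obj & ref_obj).sum() / ref_obj.sum())


def boundary_points(obj: np.ndarray, spacing: tuple[float, float] = (1.0, 1.0)) -> np.ndarray:
    """Centers of border pixels (pixels with a 4-neighbor outside), in mm."""
    obj = np.asarray(obj, dtype=bool)
    border = obj & ~ndimage.binary_erosion(obj, structure=_STRUCT_4, border_value=0)
    pts = np.argwhere(border).astype(np.float64)
    return pts * np.asarray(spacing, dtype=np.float64)


def _directed_distances(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return cKDTree(B).query(A, k=1)[0]


def assd(A: np.ndarray, B: np.ndarray) -> float:
    """Average symmetric surface distance between two boundary point sets."""
    A, B = np.atleast_2d(np.asarray(A, float)), np.atleast_2d(np.asarray(B, float))
    if A.size == 0 or B.size == 0:
        raise ValidationError("boundary point sets must be nonempty")
    d_ab = _directed_distances(A, B)
    d_ba = _directed_distances(B, A)
    return float((d_ab.sum() + d_ba.sum()) / (len(A) + len(B)))


def hausdorff(A: np.ndarray, B: np.ndarray) -> float:
    """Maximum symmetric surface distance between two boundary point sets."""
    A, B = np.atleast_2d(np.asarray(A, float)), np.atleast_2d(np.asarray(B, float))
    if A.size == 0 or B.size == 0:
        raise ValidationError("boundary point sets must be nonempty")
    return float(max(_directed_distances(A, B).max(), _directed_distances(B, A).max()))


def roc_curve(
    score_volume: Volume,
    reference: Mask,
    mask: Mask,
    max_thresholds: int = 1024,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise ROC of a score map against a reference, inside a mask.

    The threshold sweeps descending over (up to ``max_thresholds``
    quantile-spaced) distinct score values; a voxel is predicted positive
    when its score is >= the threshold.  The returned (FPR, TPR) sequences
    are monotone non-decreasing with endpoints (0, 0) and (1, 1).
    """
    if score_volume.shape != reference.shape or score_volume.shape != mask.shape:
        raise ValidationError("score/reference/mask shape mismatch")
    sel = mask.bool
    scores = np.asarray(score_volume.data, float)[sel]
    labels = reference.bool[sel]
    P = int(labels.sum())
    N = int(labels.size - P)
    if P == 0 or N == 0:
        raise ValidationError("reference must be neither empty nor full inside the mask")

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    tp = np.cumsum(l_sorted)
    fp = np.cumsum(~l_sorted)
    # last index of each distinct score = operating point "score >= t"
    boundaries = np.nonzero(np.diff(s_sorted))[0]
    idx = np.append(boundaries, len(s_sorted) - 1)
    if len(idx) > max_thresholds:
        pick = np.unique(np.linspace(0, len(idx) - 1, max_thresholds).round().astype(int))
        idx = idx[pick]
        if idx[-1] != len(s_sorted) - 1:
            idx = np.append(idx, len(s_sorted) - 1)
    tpr = np.concatenate([[0.0], tp[idx] / P, [1.0]])
    fpr = np.concatenate([[0.0], fp[idx] / N, [1.0]])
    return fpr, tpr


def summarize_case(per_object: list[ObjectMetrics], hit_rate: float) -> CaseSummary:
    """Image-level medians of sensitivity/ASSD/Hausdorff over detected objects."""
    if not per_object:
        raise ValidationError("need at least one detected object to summarize")
    sens = np.median([m.sensitivity for m in per_object])
    return CaseSummary(
        hit_rate=float(hit_rate),
        median_sensitivity=float(100.0 * sens),
        median_assd_px=float(np.median([m.assd_px for m in per_object])),
        median_assd_mm=float(np.median([m.assd_mm for m in per_object])),
        median_hausdorff_px=float(np.median([m.hausdorff_px for m in per_object])),
        median_hausdorff_mm=float(np.median([m.hausdorff_mm for m in per_object])),
        object_count=len(per_object),
    )


def case_metrics(segmented: Mask, reference: Mask) -> CaseSummary:
    """Full object-level evaluation of a segmentation against a reference.

    Objects are 2D connected components per slice; distances use the
    in-plane spacing for mm values.
    """
    matches, hit_rate = match_objects(segmented, reference)
    spacing = reference.spacing[:2]
    per_object: list[ObjectMetrics] = []
    for m in matches:
        if not m.detected:
            continue
        sens = object_sensitivity(m.seg_pixels, m.ref_pixels)
        a_px = boundary_points(m.seg_pixels)
        b_px = boundary_points(m.ref_pixels)
        a_mm = boundary_points(m.seg_pixels, spacing)
        b_mm = boundary_points(m.ref_pixels, spacing)
        per_object.append(
            ObjectMetrics(
                sensitivity=sens,
                assd_px=assd(a_px, b_px),
                assd_mm=assd(a_mm, b_mm),
                hausdorff_px=hausdorff(a_px, b_px),
                hausdorff_mm=hausdorff(a_mm, b_mm),
            )
        )
    return summarize_case(per_object, hit_rate)
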