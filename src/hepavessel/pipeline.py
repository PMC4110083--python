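"""The proposed segmentation method and the global-thresholding baselines.

:func:`run_proposed` executes the full 16-step sequence:

 1. bias removal                        (O1)
 2. windowed-sinc resample of image and liver mask to isotropic voxels
 3. masking                             (O3)
 4. multiscale vesselness filtering     (O4)
 5. resample back to the original grid  (O5)
 6. masking with the liver mask         (O6)
 7. basic vessel model: vesselness > 0.05 * max  (O7)
 8. per-slice removal of objects smaller than a 3 mm circle (O8)
 9. per-slice connected-component labeling (8-connectivity) (O9)
10. ROI construction: dilation of each object by a disc of radius 5 px (O10)
11. masking of the de-biased image      (O11)
12. local variance-minimization thresholding inside each ROI (O12)
13. 27-neighborhood region growing with per-slice median thresholds (O13)
14. liver-mask erosion by a disc of radius 6 px (O14)
15. masking with the eroded mask        (O15)
16. small-object removal again          (O16, the result)

:func:`run_global_baseline` applies slice-global automatic thresholding to
either the de-biased anatomical image (dark-side pixels) or a vesselness
map (bright-side pixels), the two comparison baselines.

Small-object removal is implemented as per-slice connected-component area
filtering with the area of a 3 mm-diameter circle at the in-plane
resolution as cutoff; this preserves thin-but-long vessels that a literal
morphological opening with a 3 mm disc would erase.  Discrete discs
contain the pixels whose center distance from the disc center is <= r.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_io import Mask, PipelineConfig, ValidationError, Volume
from .preprocess import (
    apply_mask,
    remove_bias,
    resample_isotropic,
    resample_mask,
    resample_mask_isotropic,
    resample_to_spacing,
)
from .thresholding import (
    build_histogram,
    otsu_threshold,
    quantize_volume,
    threshold_slicewise,
)
from .vesselness import VesselnessVolume, frangi_multiscale

logger = logging.getLogger("hepavessel")

_STRUCT_8 = np.ones((3, 3), dtype=bool)  # 2D 8-connectivity
_STRUCT_27 = np.ones((3, 3, 3), dtype=bool)  # 3D 27-neighborhood


def disc(radius_px: int) -> np.ndarray:
    """Discrete disc: pixels whose center lies within ``radius_px`` of the center."""
    if radius_px < 1:
        raise ValidationError(f"disc radius must be >= 1, got {radius_px}")
    r = int(radius_px)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (xx**2 + yy**2) <= r**2


def min_object_area_px(min_diameter_mm: float, in_plane_spacing: tuple[float, float]) -> int:
    """Pixel-count cutoff: area of a circle of the given diameter, rounded up."""
    dx, dy = in_plane_spacing
    return int(math.ceil(math.pi * (min_diameter_mm / 2.0) ** 2 / (dx * dy)))


def extract_basic_model(vesselness: VesselnessVolume | Volume, fraction: float = 0.05) -> Mask:
    """High-certainty vessel voxels: vesselness above ``fraction`` of its maximum."""
    if not 0 < fraction < 1:
        raise ValidationError(f"fraction must be in (0,1), got {fraction}")
    data = np.asarray(vesselness.data, dtype=np.float64)
    peak = float(data.max())
    if peak <= 0:
        logger.warning("extract_basic_model: all-zero vesselness, empty basic model")
        return Mask(np.zeros(vesselness.shape, dtype=np.uint8), vesselness.spacing, vesselness.origin)
    return Mask((data > fraction * peak).astype(np.uint8), vesselness.spacing, vesselness.origin)


def remove_small_objects_2d(mask: Mask, min_diameter_mm: float) -> Mask:
    """Delete per-slice 8-connected components smaller than a 3 mm-equivalent circle.

    Components whose pixel count is at least the cutoff are kept (>=
    comparison at the boundary).
    """
    cutoff = min_object_area_px(min_diameter_mm, mask.spacing[:2])
    out = np.zeros_like(mask.data)
    for k in range(mask.n_slices):
        sl = mask.bool[:, :, k]
        if not sl.any():
            continue
        labels, n = ndimage.label(sl, structure=_STRUCT_8)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = sizes[1:] >= cutoff
        out[:, :, k] = keep[labels].astype(np.uint8)
    return mask.copy_with(out)


@dataclass
class BasicVesselModel:
    """Per-slice labeled 2D objects of the basic vessel model."""

    mask: Mask
    labels: np.ndarray  # int array, per-slice labels (0 = background)
    objects: list = field(default_factory=list)  # (z, object id) in raster order


@dataclass
class RoiSet:
    """Per-slice regions of interest: (object id, 2D boolean region)."""

    by_slice: dict  # z -> list of (object id, 2D bool array)
    shape: tuple[int, int, int]


def label_objects_2d(mask: Mask) -> BasicVesselModel:
    """Per-slice 8-connected component labeling.

    Objects are enumerated in raster order of their first pixel within each
    slice, so labeling is deterministic.
    """
    labels = np.zeros(mask.shape, dtype=np.int32)
    objects = []
    for k in range(mask.n_slices):
        sl = mask.bool[:, :, k]
        lab, n = ndimage.label(sl, structure=_STRUCT_8)
        labels[:, :, k] = lab
        objects.extend((k, i) for i in range(1, n + 1))
    return BasicVesselModel(mask=mask, labels=labels, objects=objects)


def build_rois(objects: BasicVesselModel, radius_px: int = 5) -> RoiSet:
    """Dilate each 2D object by a discrete disc to obtain its ROI.

    Regions may overlap; regions at the slice border are clipped to the
    slice bounds.
    """
    se = disc(radius_px)
    by_slice: dict[int, list] = {}
    for z, obj_id in objects.objects:
        region = objects.labels[:, :, z] == obj_id
        roi = ndimage.binary_dilation(region, structure=se)
        by_slice.setdefault(z, []).append((obj_id, roi))
    return RoiSet(by_slice=by_slice, shape=objects.mask.shape)


def local_threshold(
    volume_masked: Volume,
    rois: RoiSet,
    liver_mask: Mask | None = None,
    bits: int = 16,
) -> Mask:
    """Variance-minimization thresholding inside each ROI; union of decisions.

    For every ROI the histogram is built over the ROI's masked pixels and
    the dark-side pixels (vessels hypointense on the de-biased image) are
    marked.  ROIs with degenerate histograms contribute nothing.
    """
    if rois.shape != volume_masked.shape:
        raise ValidationError("ROI set does not match volume shape")
    q = quantize_volume(volume_masked, bits)
    limit = liver_mask.bool if liver_mask is not None else np.ones(volume_masked.shape, bool)
    out = np.zeros(volume_masked.shape, dtype=np.uint8)
    for z, entries in rois.by_slice.items():
        qs = q[:, :, z]
        ms = limit[:, :, z]
        for obj_id, roi in entries:
            sel = roi & ms
            if not sel.any():
                continue
            hist = build_histogram(qs, sel, bits)
            if hist.n_nonzero_bins < 2:
                logger.debug("slice %d ROI %d: constant intensity, skipped", z, obj_id)
                continue
            t = otsu_threshold(hist)
            out[:, :, z] |= ((qs <= t) & sel).astype(np.uint8)
    return Mask(out, volume_masked.spacing, volume_masked.origin)


def region_grow(
    seeds: Mask,
    volume: Volume,
    valid: Mask | None = None,
    dark_vessels: bool = True,
    max_sweeps: int = 10_000,
) -> Mask:
    """Iterative 27-neighborhood region growing with per-slice median thresholds.

    Starting from the seed voxels, each completed wavefront examines every
    unmarked neighbor (26-neighborhood) of the current region: a candidate
    is accepted when its intensity is on the vessel side (<= for dark
    vessels) of the median intensity of the voxels already marked in the
    candidate's slice.  Medians are recomputed after each completed sweep;
    growth stops when a sweep adds nothing.  Growth never leaves ``valid``
    when given (otherwise the zeroed background outside an organ mask
    would satisfy the dark-side criterion).  The output contains the seeds.
    """
    if seeds.shape != volume.shape:
        raise ValidationError("seeds/volume shape mismatch")
    data = np.asarray(volume.data, dtype=np.float64)
    allowed = valid.bool if valid is not None else np.ones(volume.shape, bool)
    marked = seeds.bool & allowed
    if not marked.any():
        return seeds.copy_with(np.zeros(volume.shape, dtype=np.uint8))

    for _ in range(max_sweeps):
        medians = np.full(volume.n_slices, np.nan)
        counts = marked.sum(axis=(0, 1))
        for k in np.nonzero(counts)[0]:
            medians[k] = np.median(data[:, :, k][marked[:, :, k]])
        frontier = ndimage.binary_dilation(marked, structure=_STRUCT_27) & ~marked & allowed
        if not frontier.any():
            break
        thr = medians[np.newaxis, np.newaxis, :]
        with np.errstate(invalid="ignore"):
            accept = frontier & (data <= thr if dark_vessels else data >= thr)
        if not accept.any():
            break
        marked |= accept
    return seeds.copy_with(marked.astype(np.uint8))


def erode_mask(mask: Mask, radius_px: int = 6) -> Mask:
    """Per-slice erosion by a discrete disc."""
    se = disc(radius_px)
    out = np.zeros_like(mask.data)
    for k in range(mask.n_slices):
        out[:, :, k] = ndimage.binary_erosion(mask.bool[:, :, k], structure=se).astype(np.uint8)
    return mask.copy_with(out)


def run_proposed(
    volume: Volume,
    liver_mask: Mask,
    config: PipelineConfig | None = None,
    return_intermediates: bool = False,
):
    """Run the complete 16-step segmentation on a volume and its liver mask.

    Returns the final vessel mask; with ``return_intermediates`` also a
    dict of every intermediate O1-O16 keyed ``"O1"`` ... ``"O16"``.
    """
    config = config or PipelineConfig()
    if volume.shape != liver_mask.shape:
        raise ValidationError("volume/liver mask shape mismatch")
    if not liver_mask.bool.any():
        raise ValidationError("empty liver mask")

    inter: dict[str, object] = {}

    logger.info("step 1: bias removal")
    o1 = remove_bias(volume, liver_mask)
    inter["O1"] = o1

    logger.info("step 2: sinc interpolation to isotropic voxels")
    o2_img = resample_isotropic(o1)
    o2_mask = resample_mask_isotropic(liver_mask)
    inter["O2'"], inter["O2''"] = o2_img, o2_mask

    logger.info("step 3: masking")
    o3 = apply_mask(o2_img, o2_mask)
    inter["O3"] = o3

    logger.info("step 4: vesselness filtering (%d scales)", len(config.sigma_list))
    o4 = frangi_multiscale(o3, config, mask=o2_mask)
    inter["O4"] = o4

    logger.info("step 5: interpolation back to original voxel size")
    o5 = resample_to_spacing(o4, volume.spacing, shape=volume.shape)
    o5 = o5.copy_with(np.clip(o5.data, 0.0, 1.0))  # sinc over/undershoot
    inter["O5"] = o5

    logger.info("step 6: masking")
    o6 = apply_mask(o5, liver_mask)
    inter["O6"] = o6

    logger.info("step 7: basic vessel model (> %.2f * max vesselness)", config.basic_model_fraction)
    o7 = extract_basic_model(VesselnessVolume(o6.data, o6.spacing, o6.origin), config.basic_model_fraction)
    inter["O7"] = o7

    logger.info("step 8: removal of objects < %.1f mm", config.min_vessel_diameter_mm)
    o8 = remove_small_objects_2d(o7, config.min_vessel_diameter_mm)
    inter["O8"] = o8

    logger.info("step 9: connected component analysis")
    o9 = label_objects_2d(o8)
    inter["O9"] = o9

    logger.info("step 10: ROI dilation (disc r=%d)", config.roi_dilation_radius_px)
    o10 = build_rois(o9, config.roi_dilation_radius_px)
    inter["O10"] = o10

    logger.info("step 11: masking of the de-biased image")
    o11 = apply_mask(o1, liver_mask)
    inter["O11"] = o11

    logger.info("step 12: local thresholding (%d ROIs)", sum(len(v) for v in o10.by_slice.values()))
    o12 = local_threshold(o11, o10, liver_mask, config.histogram_bits)
    inter["O12"] = o12

    logger.info("step 13: region growing")
    o13 = region_grow(o12, o11, valid=liver_mask, dark_vessels=config.dark_vessels)
    inter["O13"] = o13

    logger.info("step 14: liver mask erosion (disc r=%d)", config.mask_erosion_radius_px)
    o14 = erode_mask(liver_mask, config.mask_erosion_radius_px)
    inter["O14"] = o14

    logger.info("step 15: masking with eroded mask")
    o15 = Mask((o13.bool & o14.bool).astype(np.uint8), volume.spacing, volume.origin)
    inter["O15"] = o15

    logger.info("step 16: removal of objects < %.1f mm", config.min_vessel_diameter_mm)
    o16 = remove_small_objects_2d(o15, config.min_vessel_diameter_mm)
    inter["O16"] = o16

    if return_intermediates:
        return o16, inter
    return o16


def run_global_baseline(
    volume_or_vesselness: Volume,
    liver_mask: Mask,
    method: str = "variance",
    input_kind: str = "anatomical",
    debias: bool = True,
) -> Mask:
    """Slice-global automatic thresholding baseline.

    ``input_kind="anatomical"`` de-biases the image first (unless
    ``debias=False``), masks it and marks dark-side pixels;
    ``input_kind="vesselness"`` masks the map and marks bright-side pixels.
    """
    if input_kind not in ("anatomical", "vesselness"):
        raise ValidationError(f"input_kind must be 'anatomical' or 'vesselness', got {input_kind!r}")
    if input_kind == "anatomical":
        work = remove_bias(volume_or_vesselness) if debias else volume_or_vesselness
        side = "below"
    else:
        work = volume_or_vesselness
        side = "above"
    work = apply_mask(work, liver_mask)
    return threshold_slicewise(work, liver_mask, method=method, vessel_side=side)
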