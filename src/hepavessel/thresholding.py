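"""Automatic histogram threshold selection on 16-bit histograms.

Two selectors are implemented, both operating on the full 2^16-bin
histogram of a slice or region of interest:

* :func:`otsu_threshold` -- minimizes the weighted intra-class variance
  (equivalently maximizes the between-class variance) of the two classes
  split at ``t``: bins <= t vs bins > t.
* :func:`kapur_threshold` -- maximizes the sum of Shannon entropies of the
  two normalized class distributions (natural log; the base does not
  affect the argmax; 0*log 0 is treated as 0).

Both return the smallest optimal threshold on ties, so selection is
deterministic, and both are invariant to scaling all counts by a positive
factor.  Intensities are mapped to bins by one global affine rescale per
volume from [volume min, volume max] to [0, 2^16 - 1], fixed before any
slicewise work so per-slice thresholds share a consistent intensity axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .image_io import Mask, ValidationError, Volume

logger = logging.getLogger("hepavessel")


class DegenerateHistogramError(ValueError):
    """Histogram has fewer than two occupied bins; no threshold exists."""


@dataclass
class Histogram16:
    """Occurrence counts per intensity bin over the 16-bit range."""

    counts: np.ndarray
    total: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValidationError("histogram counts must be non-negative")
        self.total = int(self.counts.sum())

    @property
    def n_nonzero_bins(self) -> int:
        return int(np.count_nonzero(self.counts))


def quantize_volume(volume: Volume, bits: int = 16) -> np.ndarray:
    """Map intensities affinely from [min, max] to integer bins [0, 2^bits - 1].

    One global mapping per volume.  A constant volume maps to bin 0.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    lo, hi = float(data.min()), float(data.max())
    nbins = 2**bits
    if hi <= lo:
        return np.zeros(volume.shape, dtype=np.int64)
    q = np.rint((data - lo) / (hi - lo) * (nbins - 1)).astype(np.int64)
    return np.clip(q, 0, nbins - 1)


def build_histogram(
    values: np.ndarray, mask: np.ndarray | None = None, bits: int = 16
) -> Histogram16:
    """Histogram of quantized intensities over the masked pixels."""
    values = np.asarray(values)
    if mask is not None:
        values = values[np.asarray(mask, dtype=bool)]
    values = values.ravel()
    if values.size == 0:
        raise ValidationError("no pixels to threshold")
    counts = np.bincount(values.astype(np.int64), minlength=2**bits)
    return Histogram16(counts=counts, total=int(values.size))


def otsu_threshold(hist: Histogram16) -> int:
    """Threshold minimizing intra-class variance (maximum between-class variance).

    Returns the smallest optimal bin index t for the split
    {bins <= t} vs {bins > t}.
    """
    if hist.n_nonzero_bins < 2:
        raise DegenerateHistogramError("degenerate histogram: need >= 2 occupied bins")
    p = hist.counts.astype(np.float64) / hist.total
    w0 = np.cumsum(p)
    m0 = np.cumsum(p * np.arange(p.size))
    mu_total = m0[-1]
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    bcv = np.full(p.size, -np.inf)
    mu0 = m0[valid] / w0[valid]
    mu1 = (mu_total - m0[valid]) / w1[valid]
    bcv[valid] = w0[valid] * w1[valid] * (mu0 - mu1) ** 2
    return int(np.argmax(bcv))  # first maximum = smallest optimal t


def kapur_threshold(hist: Histogram16) -> int:
    """Threshold maximizing the sum of the two class Shannon entropies.

    Empty bins contribute nothing (0 log 0 = 0); natural logarithm; the
    smallest optimal t is returned on ties.
    """
    if hist.n_nonzero_bins < 2:
        raise DegenerateHistogramError("degenerate histogram: need >= 2 occupied bins")
    p = hist.counts.astype(np.float64) / hist.total
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    P0 = np.cumsum(p)
    A = -np.cumsum(plogp)  # -sum_{i<=t} p ln p
    A_total = A[-1]
    P1 = 1.0 - P0
    valid = (P0 > 0) & (P1 > 0)
    obj = np.full(p.size, -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        h0 = A[valid] / P0[valid] + np.log(P0[valid])
        h1 = (A_total - A[valid]) / P1[valid] + np.log(P1[valid])
    obj[valid] = h0 + h1
    return int(np.argmax(obj))


_SELECTORS = {"variance": otsu_threshold, "entropy": kapur_threshold}


def threshold_slicewise(
    volume: Volume,
    mask: Mask,
    method: str = "variance",
    vessel_side: str = "below",
    bits: int = 16,
) -> Mask:
    """Per-slice automatic thresholding inside a mask.

    Each z slice gets its own threshold selected on the 16-bit histogram of
    its masked pixels; pixels on the vessel side (``"below"`` the threshold
    for dark anatomical vessels, ``"above"`` for bright vesselness maps)
    are marked.  Slices with empty masks or degenerate (single-bin)
    histograms yield empty output slices and are logged.  The output is a
    subset of the input mask.
    """
    if method not in _SELECTORS:
        raise ValidationError(f"method must be one of {sorted(_SELECTORS)}, got {method!r}")
    if vessel_side not in ("below", "above"):
        raise ValidationError(f"vessel_side must be 'below' or 'above', got {vessel_side!r}")
    if volume.shape != mask.shape:
        raise ValidationError("volume/mask shape mismatch")
    select = _SELECTORS[method]
    q = quantize_volume(volume, bits)
    out = np.zeros(volume.shape, dtype=np.uint8)
    for k in range(volume.n_slices):
        m = mask.bool[:, :, k]
        if not m.any():
            continue
        hist = build_histogram(q[:, :, k], m, bits)
        if hist.n_nonzero_bins < 2:
            logger.debug("slice %d: degenerate histogram, left empty", k)
            continue
        t = select(hist)
        side = q[:, :, k] <= t if vessel_side == "below" else q[:, :, k] > t
        out[:, :, k] = (side & m).astype(np.uint8)
    return Mask(out, volume.spacing, volume.origin)
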