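"""Pre-processing: intensity de-biasing, masking, isotropic resampling.

De-biasing suppresses the smooth multiplicative intensity inhomogeneity
("bias field") that MRI coil/field nonuniformity imprints on the image.
The corrector models the bias as the exponential of a low-order
polynomial fitted to the log intensity by least squares over the organ
mask (or all nonzero voxels) and divides it out, preserving the mean
log-intensity.  The operation is deliberately defined by its contract --
homogenize intensities, keep local ordering, idempotent -- so an
alternative corrector (e.g. an N4-style iterative scheme) can be
substituted.

Resampling uses a separable Lanczos windowed-sinc interpolator (radius 4
samples, row-normalized so constants are reproduced exactly) for images,
and linear interpolation re-binarized at 0.5 for masks.
"""

from __future__ import annotations

import logging

import numpy as np

from .image_io import Mask, ValidationError, Volume

logger = logging.getLogger("hepavessel")


def _polynomial_basis(coords: np.ndarray, degree: int) -> np.ndarray:
    """Monomials of total degree <= degree in 3 scaled coordinates."""
    x, y, z = coords[:, 0], coords[:, 1], coords[:, 2]
    cols = [
        (x**i) * (y**j) * (z**k)
        for i in range(degree + 1)
        for j in range(degree + 1 - i)
        for k in range(degree + 1 - i - j)
    ]
    return np.stack(cols, axis=1)


def remove_bias(volume: Volume, mask: Mask | None = None, degree: int = 3) -> Volume:
    """Divide out the smooth multiplicative intensity inhomogeneity.

    The bias field is modeled as the exponential of a low-order polynomial
    (total degree ``degree``) fitted to the log-intensity by least squares
    over the estimation support -- the organ mask when one is supplied,
    otherwise all nonzero voxels -- so that background levels do not leak
    across tissue borders into the estimate.  The fitted field is
    evaluated everywhere and divided out of every nonzero voxel; output
    intensities keep the geometric mean of the input over the support.

    Because the estimator is a projection onto the polynomial space, the
    operation is idempotent: de-biasing a de-biased volume changes
    nothing.  An all-zero volume is returned unchanged.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    if np.any(data < 0):
        raise ValidationError("remove_bias expects non-negative intensities")
    nonzero = data > 0
    support = (mask.bool & nonzero) if mask is not None else nonzero
    if not support.any():
        return volume.copy_with(data.copy())

    log_i = np.zeros_like(data)
    log_i[nonzero] = np.log(data[nonzero])

    # coordinates scaled to [-1, 1] per axis for a well-conditioned fit
    axes = [
        np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n) for n in data.shape
    ]
    grid = np.meshgrid(*axes, indexing="ij")
    sup_idx = np.nonzero(support)
    A = _polynomial_basis(
        np.stack([g[sup_idx] for g in grid], axis=1), degree
    )
    coef, *_ = np.linalg.lstsq(A, log_i[sup_idx], rcond=None)

    nz_idx = np.nonzero(nonzero)
    bias_log = _polynomial_basis(
        np.stack([g[nz_idx] for g in grid], axis=1), degree
    ) @ coef
    mean_log = float((A @ coef).mean())

    corrected = np.zeros_like(data)
    corrected[nz_idx] = np.exp(log_i[nz_idx] - bias_log + mean_log)
    return volume.copy_with(corrected)


def apply_mask(volume: Volume, mask: Mask) -> Volume:
    """Zero all voxels outside the mask; inside voxels are unchanged."""
    if volume.shape != mask.shape:
        raise ValidationError(f"shape mismatch: volume {volume.shape} vs mask {mask.shape}")
    return volume.copy_with(np.where(mask.bool, volume.data, 0))


_LANCZOS_RADIUS = 4


def _lanczos4(x: np.ndarray) -> np.ndarray:
    out = np.sinc(x) * np.sinc(x / _LANCZOS_RADIUS)
    return np.where(np.abs(x) < _LANCZOS_RADIUS, out, 0.0)


def _linear_kernel(x: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, 1.0 - np.abs(x))


def _axis_weights(n_in: int, n_out: int, scale: float, kernel, radius: int) -> np.ndarray:
    """Row-normalized interpolation matrix for one axis.

    Output sample j sits at input-index coordinate j*scale; weights come
    from the kernel, edges are handled by index clamping (sample
    replication), and each row is normalized to sum to 1 so constants are
    reproduced exactly.
    """
    t = np.arange(n_out) * scale
    base = np.floor(t).astype(int)
    offs = np.arange(-radius + 1, radius + 1)
    idx = base[:, None] + offs[None, :]
    wts = kernel(t[:, None] - idx)
    idx = np.clip(idx, 0, n_in - 1)
    W = np.zeros((n_out, n_in))
    np.add.at(W, (np.repeat(np.arange(n_out), idx.shape[1]), idx.ravel()), wts.ravel())
    W /= W.sum(axis=1, keepdims=True)
    return W


def _resample(
    volume: Volume,
    spacing: tuple[float, float, float],
    shape: tuple[int, int, int] | None,
    kernel=_lanczos4,
    radius: int = _LANCZOS_RADIUS,
) -> Volume:
    """Separable kernel resampling onto a grid with the given spacing.

    Without an explicit shape the output size is the number of new-spacing
    samples that fit within the input's voxel-center extent.
    """
    if shape is None:
        shape = tuple(
            int(np.floor((n - 1) * s / t + 1e-9)) + 1
            for n, s, t in zip(volume.shape, volume.spacing, spacing)
        )
    data = np.asarray(volume.data, dtype=np.float64)
    for axis in range(3):
        scale = spacing[axis] / volume.spacing[axis]
        n_in, n_out = data.shape[axis], shape[axis]
        if n_in == n_out and abs(scale - 1.0) < 1e-12:
            continue
        W = _axis_weights(n_in, n_out, scale, kernel, radius)
        data = np.moveaxis(np.tensordot(W, np.moveaxis(data, axis, 0), axes=(1, 0)), 0, axis)
    return Volume(data, spacing, volume.origin)


def resample_isotropic(volume: Volume) -> Volume:
    """Windowed-sinc resample to isotropic voxels at the in-plane spacing.

    The target spacing is the finest in-plane spacing (z is typically the
    coarse axis and gets upsampled).  Physical extent is preserved; origin
    is unchanged.  A single-slice volume whose z spacing differs from the
    target cannot be interpolated along z and raises an error.
    """
    dx, dy, dz = volume.spacing
    target = min(dx, dy)
    if max(volume.spacing) - min(volume.spacing) <= 1e-9 * max(volume.spacing):
        return volume.copy_with(np.asarray(volume.data, dtype=np.float64).copy())
    if volume.n_slices == 1 and abs(dz - target) > 1e-9:
        raise ValidationError("cannot resample a single-slice volume along z")
    out = _resample(volume, (target, target, target), None)
    logger.debug("resample_isotropic: %s %s -> %s %s", volume.shape, volume.spacing, out.shape, out.spacing)
    return out


def resample_to_spacing(
    volume: Volume,
    spacing: tuple[float, float, float],
    shape: tuple[int, int, int] | None = None,
) -> Volume:
    """Windowed-sinc resample to the given spacing (optionally a fixed shape).

    The inverse companion of :func:`resample_isotropic`; passing the shape
    of the original volume reproduces its grid exactly.
    """
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValidationError(f"target spacing must be positive, got {spacing}")
    if spacing == volume.spacing and (shape is None or tuple(shape) == volume.shape):
        return volume.copy_with(np.asarray(volume.data, dtype=np.float64).copy())
    if volume.n_slices == 1 and abs(spacing[2] - volume.spacing[2]) > 1e-9:
        raise ValidationError("cannot resample a single-slice volume along z")
    return _resample(volume, spacing, shape)


def resample_mask(
    mask: Mask,
    spacing: tuple[float, float, float],
    shape: tuple[int, int, int] | None = None,
) -> Mask:
    """Resample a binary mask: linear interpolation, re-binarized at 0.5."""
    as_vol = Volume(mask.data.astype(np.float64), mask.spacing, mask.origin)
    if tuple(float(s) for s in spacing) == mask.spacing and (
        shape is None or tuple(shape) == mask.shape
    ):
        return mask.copy_with(mask.data.copy())
    res = _resample(as_vol, tuple(float(s) for s in spacing), shape,
                    kernel=_linear_kernel, radius=1)
    return Mask((res.data >= 0.5).astype(np.uint8), res.spacing, res.origin)


def resample_mask_isotropic(mask: Mask) -> Mask:
    """Mask companion of :func:`resample_isotropic`."""
    dx, dy, dz = mask.spacing
    target = min(dx, dy)
    if max(mask.spacing) - min(mask.spacing) <= 1e-9 * max(mask.spacing):
        return mask.copy_with(mask.data.copy())
    if mask.n_slices == 1 and abs(dz - target) > 1e-9:
        raise ValidationError("cannot resample a single-slice mask along z")
    return resample_mask(mask, (target, target, target))
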