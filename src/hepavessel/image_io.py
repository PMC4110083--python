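"""Volume containers, on-disk I/O and run configuration.

Volumes are stored with axis order ``(x, y, z)`` where ``z`` is the slice
axis; all per-slice operations in this package iterate over ``z``.  Voxel
indexing is 0-based and a voxel's physical position is the position of its
center, so the center of voxel ``(i, j, k)`` lies at
``origin + (i*dx, j*dy, k*dz)``.

Supported on-disk formats are NIfTI-1 (``.nii``/``.nii.gz``, via nibabel)
and MetaImage (``.mha``/``.mhd``, via SimpleITK); both carry voxel spacing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import yaml

logger = logging.getLogger("hepavessel")


class FormatError(RuntimeError):
    """Raised when a volume file cannot be read or lacks spacing metadata."""


class ValidationError(ValueError):
    """Raised when a configuration or specification value is out of range."""


@dataclass
class Volume:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    data:
        3D array, axis order ``(x, y, z)``.
    spacing:
        Voxel edge lengths ``(dx, dy, dz)`` in mm; all positive.
    origin:
        Physical position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"volume data must be 3D, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def slice(self, k: int) -> np.ndarray:
        """The k-th axial (z) slice as a 2D ``(x, y)`` array view."""
        return self.data[:, :, k]

    def copy_with(self, data: np.ndarray) -> "Volume":
        """New volume with the same geometry and different data."""
        return Volume(np.asarray(data), self.spacing, self.origin)


@dataclass
class Mask(Volume):
    """A binary volume aligned to a :class:`Volume` (values 0/1)."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.isin(np.unique(self.data), (0, 1)).all():
            raise ValidationError("mask values must be 0 or 1")
        self.data = self.data.astype(np.uint8)
        super().__post_init__()

    @property
    def bool(self) -> np.ndarray:
        return self.data.astype(np.bool_)

    def copy_with(self, data: np.ndarray) -> "Mask":
        return Mask(np.asarray(data).astype(np.uint8), self.spacing, self.origin)


def _default_sigma_list() -> tuple[float, ...]:
    # scales 1.0, 1.5, ..., 12.0 in voxel units of the isotropic grid
    return tuple(np.arange(1.0, 12.0 + 0.25, 0.5).tolist())


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of the segmentation pipeline.

    Defaults reproduce the reference operating point: vesselness shape
    parameters ``alpha=0.3`` and ``beta=0.7``, Gaussian scales from 1 to 12
    voxels in steps of 0.5, a basic-vessel-model threshold of 5% of the
    maximum vesselness, removal of objects thinner than a 3 mm circle,
    ROI dilation by a disc of radius 5 px and liver-mask erosion by a disc
    of radius 6 px, dark (hypointense) vessels, 16-bit histograms.
    """

    alpha: float = 0.3
    beta: float = 0.7
    sigma_list: tuple[float, ...] = field(default_factory=_default_sigma_list)
    basic_model_fraction: float = 0.05
    min_vessel_diameter_mm: float = 3.0
    roi_dilation_radius_px: int = 5
    mask_erosion_radius_px: int = 6
    dark_vessels: bool = True
    histogram_bits: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if not self.alpha > 0:
            problems.append(f"alpha must be > 0, got {self.alpha}")
        if not self.beta > 0:
            problems.append(f"beta must be > 0, got {self.beta}")
        if not 0 < self.basic_model_fraction < 1:
            problems.append(
                f"basic_model_fraction must be in (0,1), got {self.basic_model_fraction}"
            )
        sig = tuple(float(s) for s in self.sigma_list)
        object.__setattr__(self, "sigma_list", sig)
        if len(sig) == 0:
            problems.append("sigma_list must be nonempty")
        elif any(s <= 0 for s in sig) or list(sig) != sorted(sig):
            problems.append(f"sigma_list must be positive and ascending, got {sig}")
        if self.min_vessel_diameter_mm <= 0:
            problems.append(f"min_vessel_diameter_mm must be > 0, got {self.min_vessel_diameter_mm}")
        if self.roi_dilation_radius_px < 1:
            problems.append(f"roi_dilation_radius_px must be >= 1, got {self.roi_dilation_radius_px}")
        if self.mask_erosion_radius_px < 1:
            problems.append(f"mask_erosion_radius_px must be >= 1, got {self.mask_erosion_radius_px}")
        if self.histogram_bits < 1 or self.histogram_bits > 16:
            problems.append(f"histogram_bits must be in [1,16], got {self.histogram_bits}")
        if problems:
            raise ValidationError("; ".join(problems))

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_META_SUFFIXES = (".mha", ".mhd")


def _endswith_any(name: str, suffixes: Sequence[str]) -> bool:
    return any(name.endswith(s) for s in suffixes)


def read_volume(path) -> Volume:
    """Read a volume from NIfTI or MetaImage, preserving data and spacing."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    name = path.name.lower()
    try:
        if _endswith_any(name, _NIFTI_SUFFIXES):
            img = nib.load(str(path))
            data = np.asarray(img.dataobj)
            if data.ndim != 3:
                raise FormatError(f"expected a 3D volume, got shape {data.shape}")
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
            origin = tuple(float(v) for v in img.affine[:3, 3])
            return Volume(data.astype(np.float64), spacing, origin)
        if _endswith_any(name, _META_SUFFIXES):
            img = sitk.ReadImage(str(path))
            data = sitk.GetArrayFromImage(img)  # (z, y, x)
            return Volume(
                np.ascontiguousarray(data.transpose(2, 1, 0)).astype(np.float64),
                tuple(img.GetSpacing()),
                tuple(img.GetOrigin()),
            )
    except FormatError:
        raise
    except Exception as exc:  # nibabel/SimpleITK raise format-specific errors
        raise FormatError(f"could not read {path}: {exc}") from exc
    raise FormatError(f"unsupported volume format: {path} (use .nii/.nii.gz/.mha/.mhd)")


def write_volume(volume: Volume, path) -> None:
    """Write a volume to NIfTI or MetaImage; format chosen by extension."""
    path = Path(path)
    name = path.name.lower()
    if _endswith_any(name, _NIFTI_SUFFIXES):
        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        # NIfTI-2: header voxel sizes are float64, so spacing survives exactly
        img = nib.Nifti2Image(np.asarray(volume.data), affine)
        img.header.set_zooms(volume.spacing)
        nib.save(img, str(path))
    elif _endswith_any(name, _META_SUFFIXES):
        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
        img.SetSpacing(volume.spacing)
        img.SetOrigin(volume.origin)
        sitk.WriteImage(img, str(path))
    else:
        raise FormatError(f"unsupported volume format: {path} (use .nii/.nii.gz/.mha/.mhd)")


def read_mask(path) -> Mask:
    """Read a binary mask; nonzero voxels become 1."""
    vol = read_volume(path)
    return Mask((np.asarray(vol.data) > 0.5).astype(np.uint8), vol.spacing, vol.origin)


_CONFIG_KEYS = {
    "alpha",
    "beta",
    "sigma_list",
    "basic_model_fraction",
    "min_vessel_diameter_mm",
    "roi_dilation_radius_px",
    "mask_erosion_radius_px",
    "dark_vessels",
    "histogram_bits",
    "seed",
}


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline configuration; unspecified keys take defaults.

    A ``sigma_list`` entry may be a list of scales or a mapping with keys
    ``start``/``stop``/``step``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "sigma_list" in raw and isinstance(raw["sigma_list"], dict):
        r = raw["sigma_list"]
        raw["sigma_list"] = np.arange(
            r["start"], r["stop"] + 0.5 * r.get("step", 1.0), r.get("step", 1.0)
        ).tolist()
    return PipelineConfig(**raw)
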