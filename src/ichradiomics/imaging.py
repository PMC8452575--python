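"""NIfTI volume and label-mask I/O, isotropic resampling, and region volumes.

CT volumes are held as :class:`VolumeGrid` (Hounsfield units, anisotropic
voxel spacing); segmentations as :class:`RegionMask` sharing the same
geometry with labels 0=background, 1=intracerebral haemorrhage (ICH),
2=intraventricular haemorrhage (IVH), 3=perihaematomal oedema (PHE).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

DEFAULT_LABEL_MAP = {
    0: "background",
    1: "intracerebral haemorrhage",
    2: "intraventricular haemorrhage",
    3: "perihaematomal oedema",
}

LABEL_ICH = 1
LABEL_IVH = 2
LABEL_PHE = 3


class ImagingError(ValueError):
    """Raised for invalid volumes, masks, or headers."""


@dataclass
class VolumeGrid:
    """A 3-D scalar field with physical geometry.

    Parameters
    ----------
    data : ndarray
        3-D array of intensities (HU for CT input).
    spacing : tuple of float
        Per-axis voxel size in mm; all components positive and finite.
    origin : tuple of float
        Physical coordinates (mm) of voxel (0, 0, 0).
    axis_orientation : tuple of str
        Anatomical direction codes of the array axes (e.g. ``('R','A','S')``).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_orientation: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ImagingError(f"volume must have exactly 3 axes, got {self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(
            not math.isfinite(s) or s <= 0 for s in self.spacing
        ):
            raise ImagingError(f"spacing must be 3 positive finite values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ImagingError("volume contains non-finite voxels; scan rejected")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class RegionMask:
    """Voxel-aligned integer label field sharing a :class:`VolumeGrid` geometry."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_orientation: tuple[str, str, str] = ("R", "A", "S")
    label_map: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        self.labels = np.asarray(np.rint(self.labels), dtype=np.int32)
        if self.labels.ndim != 3:
            raise ImagingError(f"mask must have exactly 3 axes, got {self.labels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(not math.isfinite(s) or s <= 0 for s in self.spacing):
            raise ImagingError(f"spacing must be positive and finite, got {self.spacing}")
        present = set(np.unique(self.labels).tolist())
        unknown = present - set(self.label_map)
        if unknown:
            raise ImagingError(f"mask contains labels not in label_map: {sorted(unknown)}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def check_geometry(self, vol: VolumeGrid) -> None:
        if self.shape != vol.shape:
            raise ImagingError(f"mask shape {self.shape} != volume shape {vol.shape}")
        if not np.allclose(self.spacing, vol.spacing):
            raise ImagingError(f"mask spacing {self.spacing} != volume spacing {vol.spacing}")


def _squeeze_to_3d(data: np.ndarray, path) -> np.ndarray:
    if data.ndim > 3:
        extra = data.shape[3:]
        if any(n != 1 for n in extra):
            raise ImagingError(
                f"{path}: {data.ndim}-D image with non-singleton trailing dims {extra}"
            )
        data = data.reshape(data.shape[:3])
    if data.ndim != 3:
        raise ImagingError(f"{path}: expected 3 spatial dimensions, got {data.ndim}")
    return data


def _load_nifti(path):
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise ImagingError(f"cannot read NIfTI file {path}: {exc}") from exc
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any((not math.isfinite(z)) or z <= 0 for z in zooms):
        raise ImagingError(f"{path}: header field pixdim has invalid spacing {zooms}")
    # get_fdata applies scl_slope / scl_inter intensity rescaling
    data = _squeeze_to_3d(np.asarray(img.get_fdata(dtype=np.float64)), path)
    orientation = nib.aff2axcodes(img.affine)
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return data, tuple(float(z) for z in zooms), origin, orientation


def read_volume(path) -> VolumeGrid:
    """Read a NIfTI CT volume, applying header intensity rescaling."""
    data, spacing, origin, orientation = _load_nifti(path)
    if not np.all(np.isfinite(data)):
        raise ImagingError(f"{path}: non-finite voxel intensities; scan rejected")
    return VolumeGrid(data, spacing, origin, orientation)


def read_mask(path, label_map: dict | None = None) -> RegionMask:
    """Read a NIfTI integer label mask."""
    data, spacing, origin, orientation = _load_nifti(path)
    if not np.all(np.isfinite(data)):
        raise ImagingError(f"{path}: non-finite voxels in mask")
    return RegionMask(
        data, spacing, origin, orientation,
        label_map=dict(label_map) if label_map else dict(DEFAULT_LABEL_MAP),
    )


def _affine_from(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def write_volume(vol: VolumeGrid, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float64), _affine_from(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_mask(mask: RegionMask, path) -> None:
    img = nib.Nifti1Image(
        mask.labels.astype(np.int16), _affine_from(mask.spacing, mask.origin)
    )
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def _output_geometry(shape, spacing, target_mm):
    # Voxel-centre convention: output grid covers the input physical extent,
    # half-open on the far edge.
    new_shape = tuple(
        max(1, int(math.ceil(n * s / target_mm))) for n, s in zip(shape, spacing)
    )
    scale = tuple(target_mm / s for s in spacing)
    return new_shape, scale


def _interp_grid(data: np.ndarray, new_shape, scale) -> np.ndarray:
    coords = np.meshgrid(
        *[np.arange(n) * sc for n, sc in zip(new_shape, scale)], indexing="ij"
    )
    return ndimage.map_coordinates(
        data, np.stack(coords), order=1, mode="nearest"
    )


def resample_isotropic(vol, target_mm: float = 1.0, mode: str = "intensity"):
    """Resample a volume or mask to isotropic voxels.

    Intensity volumes are trilinearly interpolated. Label masks are resampled
    by trilinear interpolation of each binary label channel, assigning each
    output voxel the label with the largest interpolated weight (equivalent to
    re-binarising at 0.5 wherever a single label dominates).
    """
    if not (math.isfinite(target_mm) and target_mm > 0):
        raise ImagingError(f"target_mm must be positive, got {target_mm}")
    if mode == "intensity":
        if not isinstance(vol, VolumeGrid):
            raise ImagingError("mode='intensity' requires a VolumeGrid")
        new_shape, scale = _output_geometry(vol.shape, vol.spacing, target_mm)
        out = _interp_grid(vol.data, new_shape, scale)
        return VolumeGrid(out, (target_mm,) * 3, vol.origin, vol.axis_orientation)
    if mode == "mask-label":
        if not isinstance(vol, RegionMask):
            raise ImagingError("mode='mask-label' requires a RegionMask")
        new_shape, scale = _output_geometry(vol.shape, vol.spacing, target_mm)
        labels = sorted(vol.label_map)
        weights = np.stack(
            [_interp_grid((vol.labels == lab).astype(np.float64), new_shape, scale)
             for lab in labels]
        )
        out = np.asarray(labels, dtype=np.int32)[np.argmax(weights, axis=0)]
        return RegionMask(
            out, (target_mm,) * 3, vol.origin, vol.axis_orientation,
            label_map=dict(vol.label_map),
        )
    raise ImagingError(f"unknown resampling mode {mode!r}")


def region_volume_ml(mask: RegionMask, label: int) -> float:
    """Volume of one labelled region in millilitres."""
    if label not in mask.label_map:
        raise ImagingError(f"unknown label {label}; known: {sorted(mask.label_map)}")
    count = int(np.count_nonzero(mask.labels == label))
    return count * float(np.prod(mask.spacing)) / 1000.0
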