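"""Volume and segmentation I/O, ROI registry, and per-ROI voxel extraction.

Intensity images and their label maps must live on the same grid; no
resampling is ever performed here because interpolation would corrupt the
texture statistics downstream. The affine is carried through for provenance
but never used in feature computation — voxel coordinates are 0-based array
indices throughout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "IntensityVolume",
    "SegmentationMap",
    "ROISample",
    "DEFAULT_ROI_REGISTRY",
    "read_volume",
    "write_volume",
    "read_segmentation",
    "read_registry",
    "write_registry",
    "extract_roi",
    "roi_volume",
]

#: FreeSurfer aseg / Desikan-Killiany label codes for the 14 bilateral
#: limbic ROIs analysed by the pipeline: hippocampus, amygdala, accumbens
#: area, ventral diencephalon, caudal and rostral anterior cingulate, and
#: parahippocampal gyrus, left and right.
DEFAULT_ROI_REGISTRY: dict[int, str] = {
    17: "Left-Hippocampus",
    53: "Right-Hippocampus",
    18: "Left-Amygdala",
    54: "Right-Amygdala",
    26: "Left-Accumbens-area",
    58: "Right-Accumbens-area",
    28: "Left-VentralDC",
    60: "Right-VentralDC",
    1002: "ctx-lh-caudalanteriorcingulate",
    2002: "ctx-rh-caudalanteriorcingulate",
    1026: "ctx-lh-rostralanteriorcingulate",
    2026: "ctx-rh-rostralanteriorcingulate",
    1016: "ctx-lh-parahippocampal",
    2016: "ctx-rh-parahippocampal",
}


class VolumeLoadError(ValueError):
    """Raised when an image file cannot be interpreted as a clean 3D volume."""


class DegenerateROIError(ValueError):
    """Raised for ROIs that are absent or too small to carry texture."""


@dataclass
class IntensityVolume:
    """A 3D scalar image with voxel dimensions in mm.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities (finite floats).
    voxel_size : tuple of float
        (dx, dy, dz) in mm; all strictly positive.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform, carried for provenance only.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeLoadError(
                f"expected 3D volume, got {self.data.ndim}D shape {self.data.shape}"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel dimensions must be positive, got {self.voxel_size}")
        n_bad = int(np.count_nonzero(~np.isfinite(self.data)))
        if n_bad:
            raise VolumeLoadError(f"volume contains {n_bad} non-finite voxels")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm³."""
        dx, dy, dz = self.voxel_size
        return dx * dy * dz


@dataclass
class SegmentationMap:
    """Integer label map on the same grid as its companion intensity volume."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    registry: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_ROI_REGISTRY))
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise VolumeLoadError(
                f"expected 3D label map, got {self.labels.ndim}D shape {self.labels.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int64)
            if not np.array_equal(as_int, self.labels):
                raise VolumeLoadError("label map contains non-integer values")
            self.labels = as_int
        if self.labels.min() < 0:
            raise VolumeLoadError("label map contains negative labels")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz


@dataclass
class ROISample:
    """The voxels of one ROI: intensities plus their integer grid coordinates."""

    intensities: np.ndarray
    coords: np.ndarray  # (n, 3) int array of 0-based voxel indices
    roi_name: str
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float).ravel()
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.intensities) != len(self.coords):
            raise ValueError("intensities and coords length mismatch")
        if len(self.intensities) == 0:
            raise ValueError("empty ROI sample")

    def __len__(self) -> int:
        return len(self.intensities)


def read_volume(path: str | os.PathLike) -> IntensityVolume:
    """Load a NIfTI-1 intensity volume.

    Header scl slope/intercept are applied (nibabel's default); intensities
    are otherwise unchanged. Non-3D images and non-finite voxels are
    rejected.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if data.ndim != 3:
        raise VolumeLoadError(f"expected 3D volume, got {data.ndim}D shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return IntensityVolume(data=data, voxel_size=tuple(zooms), affine=np.asarray(img.affine))


def write_volume(vol: IntensityVolume, path: str | os.PathLike, dtype=np.float32) -> None:
    """Write an IntensityVolume as NIfTI-1, recording voxel sizes in the header."""
    img = nib.Nifti1Image(vol.data.astype(dtype), vol.affine)
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))


def read_segmentation(
    path: str | os.PathLike, registry: dict[int, str] | None = None
) -> SegmentationMap:
    """Load a NIfTI-1 integer label map."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeLoadError(f"expected 3D label map, got {data.ndim}D shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return SegmentationMap(
        labels=np.asarray(np.rint(data), dtype=np.int64)
        if not np.issubdtype(data.dtype, np.integer)
        else np.asarray(data, dtype=np.int64),
        voxel_size=tuple(zooms),
        registry=dict(registry) if registry is not None else dict(DEFAULT_ROI_REGISTRY),
        affine=np.asarray(img.affine),
    )


def write_segmentation(seg: SegmentationMap, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(seg.labels.astype(np.int32), seg.affine)
    img.header.set_zooms(seg.voxel_size)
    nib.save(img, str(path))


def read_registry(path: str | os.PathLike) -> dict[int, str]:
    """Read a 2-column TSV (label_code, roi_name) into a registry mapping."""
    registry: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            code_s, name = line.split("\t")[:2]
            code = int(code_s)
            if code in registry:
                raise ValueError(f"duplicate label code {code} in registry {path}")
            registry[code] = name
    return registry


def write_registry(registry: dict[int, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for code in sorted(registry):
            fh.write(f"{code}\t{registry[code]}\n")


def _check_aligned(vol: IntensityVolume, seg: SegmentationMap) -> None:
    if vol.data.shape != seg.labels.shape:
        raise ValueError(
            f"intensity/label grids misaligned: {vol.data.shape} vs {seg.labels.shape}; "
            "resampling is not supported"
        )
    if not np.allclose(vol.voxel_size, seg.voxel_size):
        raise ValueError(
            f"voxel sizes differ: {vol.voxel_size} vs {seg.voxel_size}"
        )


def extract_roi(
    vol: IntensityVolume,
    seg: SegmentationMap,
    roi_code: int,
    min_voxels: int = 10,
) -> ROISample:
    """Return exactly the voxels where ``seg.labels == roi_code``.

    Raises
    ------
    KeyError
        If the code is not in the registry.
    DegenerateROIError
        If the ROI is absent from the label map or smaller than
        ``min_voxels`` (a size-zone matrix on a handful of voxels is
        meaningless).
    """
    _check_aligned(vol, seg)
    if roi_code not in seg.registry:
        raise KeyError(f"ROI code {roi_code} not in registry")
    mask = seg.labels == roi_code
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise DegenerateROIError(f"ROI absent: code {roi_code} has no voxels in label map")
    if n < min_voxels:
        raise DegenerateROIError(
            f"degenerate ROI: code {roi_code} has {n} voxels (< {min_voxels})"
        )
    coords = np.argwhere(mask)
    return ROISample(
        intensities=vol.data[mask],
        coords=coords,
        roi_name=seg.registry[roi_code],
        voxel_size=vol.voxel_size,
    )


def roi_volume(seg: SegmentationMap, roi_code: int, min_voxels: int = 10) -> float:
    """Gray-matter volume of one ROI in mm³: voxel count × voxel volume."""
    if roi_code not in seg.registry:
        raise KeyError(f"ROI code {roi_code} not in registry")
    n = int(np.count_nonzero(seg.labels == roi_code))
    if n == 0:
        raise DegenerateROIError(f"ROI absent: code {roi_code} has no voxels in label map")
    if n < min_voxels:
        raise DegenerateROIError(
            f"degenerate ROI: code {roi_code} has {n} voxels (< {min_voxels})"
        )
    return n * seg.voxel_volume
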