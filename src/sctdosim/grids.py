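"""Grid geometry, volume and mask containers, resampling and I/O.

Conventions used throughout the package:

* arrays are indexed ``(i, j, k)`` along ``(x, y, z)``, 0-based;
* ``Grid.origin`` is the world coordinate (mm) of the *center* of voxel
  ``(0, 0, 0)``; the center of voxel ``i`` lies at ``origin + i * spacing``
  per axis (voxel-centered convention);
* the axial (slice) axis is ``z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "Grid",
    "Volume",
    "BinaryMask",
    "resample_to",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "distance_from_mask",
]

HU_MIN = -1024.0
HU_MAX = 3071.0

_KNOWN_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")


@dataclass(frozen=True)
class Grid:
    """Regular 3-D voxel lattice: shape (nx, ny, nz), spacing and origin in mm."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("Grid is three-dimensional")
        if any(int(n) < 1 for n in self.shape):
            raise ValueError("all shape entries must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacings must be > 0")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (..., 3) to world mm coordinates."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def index_coordinates(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world mm coordinates (..., 3) to fractional voxel indices."""
        pts = np.asarray(points_mm, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of all voxel centers, one 1-D array per axis."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )

    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """World bounding box (lo, hi) of the voxel-center lattice."""
        lo = np.asarray(self.origin)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi


@dataclass
class Volume:
    """Scalar field on a :class:`Grid`; ``unit`` is one of HU / MR / density / Gy."""

    grid: Grid
    values: np.ndarray
    unit: str = "HU"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")
        if self.unit == "HU":
            lo, hi = float(self.values.min()), float(self.values.max())
            if lo < HU_MIN or hi > HU_MAX:
                raise ValueError(f"HU values outside [{HU_MIN}, {HU_MAX}]: [{lo}, {hi}]")

    def copy(self) -> "Volume":
        return Volume(self.grid, self.values.copy(), self.unit)


@dataclass
class BinaryMask:
    """Boolean membership field on a :class:`Grid`."""

    grid: Grid
    member: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member, dtype=bool)
        if self.member.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid shape")

    @property
    def voxel_count(self) -> int:
        return int(self.member.sum())

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_mm3 / 1000.0

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.grid, self.member.copy())


def _default_fill(unit: str) -> float:
    return -1000.0 if unit == "HU" else 0.0


def resample_to(
    vol: Volume,
    target: Grid,
    mode: str = "trilinear",
    fill: float | None = None,
) -> Volume:
    """Resample ``vol`` onto ``target`` by nearest or trilinear interpolation.

    Voxels of ``target`` falling outside the extent of ``vol`` receive
    ``fill`` (default −1000 for HU volumes, 0 otherwise). Label maps and
    masks must use ``mode="nearest"`` so no new values are invented.
    """
    if mode not in ("nearest", "trilinear"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    lo_v, hi_v = vol.grid.extent()
    lo_t, hi_t = target.extent()
    if np.any(hi_v < lo_t) or np.any(hi_t < lo_v):
        raise ValueError("no spatial overlap between volume and target grid")
    if fill is None:
        fill = _default_fill(vol.unit)

    xs, ys, zs = (
        vol.grid.index_coordinates(
            np.stack(np.meshgrid(*target.coordinate_arrays(), indexing="ij"), axis=-1)
        )[..., a]
        for a in range(3)
    )
    order = 0 if mode == "nearest" else 1
    out = ndimage.map_coordinates(
        np.asarray(vol.values, dtype=float),
        [xs, ys, zs],
        order=order,
        mode="constant",
        cval=fill,
    )
    return Volume(target, out.astype(vol.values.dtype, copy=False), vol.unit)


def _to_sitk(values: np.ndarray, grid: Grid) -> sitk.Image:
    # SimpleITK array layout is (z, y, x)
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, Grid]:
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    grid = Grid(arr.shape, tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    return arr, grid


def _check_extension(path: str) -> None:
    if not str(path).endswith(_KNOWN_EXTENSIONS):
        raise ValueError(
            f"unsupported volume format for {path!r}; expected one of {_KNOWN_EXTENSIONS}"
        )


def write_volume(vol: Volume, path: str) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd), float32."""
    _check_extension(path)
    sitk.WriteImage(_to_sitk(np.asarray(vol.values, dtype=np.float32), vol.grid), str(path))


def read_volume(path: str, unit: str = "HU") -> Volume:
    """Read a NIfTI or MetaImage volume; geometry is taken from the header."""
    _check_extension(path)
    import os

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    arr, grid = _from_sitk(sitk.ReadImage(str(path)))
    return Volume(grid, arr, unit)


def write_mask(mask: BinaryMask, path: str) -> None:
    _check_extension(path)
    sitk.WriteImage(_to_sitk(mask.member.astype(np.uint8), mask.grid), str(path))


def read_mask(path: str) -> BinaryMask:
    _check_extension(path)
    import os

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    arr, grid = _from_sitk(sitk.ReadImage(str(path)))
    return BinaryMask(grid, arr > 0)


def distance_from_mask(mask: BinaryMask) -> Volume:
    """Euclidean distance (mm) from each voxel center to the nearest mask voxel
    center; zero inside the mask. Anisotropic spacing is respected."""
    if not mask.member.any():
        raise ValueError("distance transform of an empty mask is undefined")
    dist = ndimage.distance_transform_edt(~mask.member, sampling=mask.grid.spacing)
    return Volume(mask.grid, dist, unit="mm")
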