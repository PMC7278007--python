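"""Bone segmentation agreement and HU accuracy between CT and synthetic CT.

Both images are thresholded at 300 HU (strict exceedance) into skull masks;
agreement is summarized by the Dice similarity coefficient
DSC = 2|A∩B| / (|A|+|B|), bone volumes and their relative difference, and the
mean absolute HU error over a body region from the crown down to a
configurable fraction of head height (stand-in for "crown to cranial base").
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np

from .grids import BinaryMask, Volume

__all__ = [
    "BoneReport",
    "bone_mask",
    "dice",
    "bone_volume",
    "relative_volume_difference",
    "mae_hu",
    "head_region",
    "evaluate_bone",
]

BONE_THRESHOLD_HU = 300.0


@dataclass(frozen=True)
class BoneReport:
    v_ct_cm3: float
    v_sct_cm3: float
    dv_pct: float
    dsc: float
    mae_hu: float

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def bone_mask(vol: Volume, threshold_hu: float = BONE_THRESHOLD_HU) -> BinaryMask:
    """Skull mask by strict HU exceedance (value > threshold)."""
    if vol.unit != "HU":
        raise ValueError(f"bone_mask requires an HU volume, got unit {vol.unit!r}")
    return BinaryMask(vol.grid, np.asarray(vol.values) > threshold_hu)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|); 1.0 if both empty."""
    if a.grid != b.grid:
        raise ValueError("dice requires masks on the same grid")
    na, nb = a.voxel_count, b.voxel_count
    if na + nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a.member & b.member))
    return 2.0 * inter / (na + nb)


def bone_volume(mask: BinaryMask) -> tuple[float, np.ndarray]:
    """Total bone volume (cm³) and per-axial-slice voxel counts (along z)."""
    counts = mask.member.sum(axis=(0, 1)).astype(int)
    total_cm3 = float(counts.sum()) * mask.grid.voxel_volume_mm3 / 1000.0
    return total_cm3, counts


def relative_volume_difference(v_sct_cm3: float, v_ct_cm3: float) -> float:
    """Relative bone-volume difference, percent: 100 (V_sCT − V_CT) / V_CT."""
    if v_ct_cm3 <= 0:
        raise ValueError("reference bone volume must be > 0")
    return 100.0 * (v_sct_cm3 - v_ct_cm3) / v_ct_cm3


def mae_hu(ct: Volume, sct: Volume, region: BinaryMask) -> float:
    """Mean absolute HU error over the region voxels."""
    if ct.grid != sct.grid or ct.grid != region.grid:
        raise ValueError("mae_hu requires both volumes and the region on one grid")
    if not region.member.any():
        raise ValueError("mae_hu region is empty")
    diff = np.asarray(ct.values, dtype=float) - np.asarray(sct.values, dtype=float)
    return float(np.abs(diff[region.member]).mean())


def head_region(body: BinaryMask, height_fraction: float = 0.55) -> BinaryMask:
    """Body restricted to axial slices from the crown (superior-most body
    slice, taken as the top of the z axis) down through ``height_fraction`` of
    the head height — the evaluation region for the HU error."""
    if not (0.0 < height_fraction <= 1.0):
        raise ValueError("height_fraction must be in (0, 1]")
    slices = np.nonzero(body.member.any(axis=(0, 1)))[0]
    if slices.size == 0:
        raise ValueError("empty body mask")
    top, bottom = int(slices.max()), int(slices.min())
    height = top - bottom + 1
    cut = top - int(np.ceil(height_fraction * height)) + 1
    member = body.member.copy()
    member[:, :, : max(cut, bottom)] = False
    return BinaryMask(body.grid, member)


def evaluate_bone(
    ct: Volume,
    sct: Volume,
    body: BinaryMask,
    threshold_hu: float = BONE_THRESHOLD_HU,
    mae_height_fraction: float = 0.55,
) -> BoneReport:
    """Full bone evaluation: DSC on whole-scan skull masks, volumes, relative
    volume difference, and MAE within the crown-to-base body region."""
    mask_ct = bone_mask(ct, threshold_hu)
    mask_sct = bone_mask(sct, threshold_hu)
    v_ct, _ = bone_volume(mask_ct)
    v_sct, _ = bone_volume(mask_sct)
    if v_ct > 0:
        dv = relative_volume_difference(v_sct, v_ct)
    else:
        warnings.warn("reference CT has no bone; ΔV undefined, reporting nan")
        dv = float("nan")
    region = head_region(body, mae_height_fraction)
    return BoneReport(
        v_ct_cm3=v_ct,
        v_sct_cm3=v_sct,
        dv_pct=dv,
        dsc=dice(mask_sct, mask_ct),
        mae_hu=mae_hu(ct, sct, region),
    )
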