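"""Simplified 6 MV photon dose engine on CT/sCT attenuation data.

The engine is a divergent exponential-attenuation pencil model: per beam and
voxel, dose ∝ weight × exp(−μ_eff · d_rad) × (SAD/r)² × penumbra, where
d_rad is the water-equivalent radiological depth from the source, μ_eff is an
effective 6 MV attenuation coefficient, r the source–voxel distance and the
penumbra an error-function lateral falloff at the field edge (projected to
the isocenter plane). There is no buildup or scatter modeling — the model is
deliberately minimal but physically monotone, and it is applied *identically*
to CT- and sCT-derived densities, which is what the plan-copy comparison
requires. Total dose is normalized so the CT-based plan delivers the
prescription to the PTV median; the same constant is reused for the sCT
recalculation (true plan-copy semantics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .grids import BinaryMask, Grid, Volume
from .phantom import BeamPlan

__all__ = [
    "DensityCalibration",
    "DEFAULT_CALIBRATION",
    "MU_EFF_PER_MM",
    "SIGMA_PENUMBRA_MM",
    "hu_to_density",
    "radiological_depth",
    "compute_dose",
    "normalization_constant",
    "recalculate_on_sct",
]

#: effective linear attenuation coefficient for 6 MV photons in water, 1/mm
MU_EFF_PER_MM = 0.0049
#: lateral penumbra width at the field edge, mm (isocenter plane)
SIGMA_PENUMBRA_MM = 3.0


@dataclass(frozen=True)
class DensityCalibration:
    """Piecewise-linear HU → relative electron density calibration."""

    knots_hu: tuple[float, ...] = (-1000.0, 0.0, 942.0, 3071.0)
    knots_density: tuple[float, ...] = (0.001, 1.000, 1.512, 2.2)

    def __post_init__(self) -> None:
        hu = np.asarray(self.knots_hu)
        rho = np.asarray(self.knots_density)
        if hu.size != rho.size or hu.size < 2:
            raise ValueError("calibration needs >= 2 matching knots")
        if np.any(np.diff(hu) <= 0):
            raise ValueError("HU knots must be strictly increasing")
        if np.any(rho < 0) or np.any(np.diff(rho) < 0):
            raise ValueError("densities must be non-negative and non-decreasing")

    def __call__(self, hu_values: np.ndarray) -> np.ndarray:
        return np.interp(hu_values, self.knots_hu, self.knots_density)


DEFAULT_CALIBRATION = DensityCalibration()


def hu_to_density(vol: Volume, cal: DensityCalibration = DEFAULT_CALIBRATION) -> Volume:
    """Convert an HU volume to relative electron density (clamped at end knots)."""
    if vol.unit != "HU":
        raise ValueError("hu_to_density requires an HU volume")
    return Volume(vol.grid, cal(np.asarray(vol.values, dtype=float)), unit="density")


def radiological_depth(density: Volume, source_mm, target_mm) -> float:
    """Water-equivalent path length (mm) from source to target: exact Siddon
    voxel traversal of the density line integral. Path outside the grid
    contributes nothing (vacuum)."""
    p0 = np.asarray(source_mm, dtype=float)
    p1 = np.asarray(target_mm, dtype=float)
    if not (np.all(np.isfinite(p0)) and np.all(np.isfinite(p1))):
        raise ValueError("ray endpoints must be finite")
    d = p1 - p0
    length = float(np.linalg.norm(d))
    if length == 0.0:
        return 0.0
    grid = density.grid
    ts = [0.0, 1.0]
    for axis in range(3):
        if d[axis] == 0.0:
            continue
        # voxel boundary planes: origin + (i - 0.5) * spacing, i = 0..n
        bounds = grid.origin[axis] + (np.arange(grid.shape[axis] + 1) - 0.5) * grid.spacing[axis]
        t = (bounds - p0[axis]) / d[axis]
        ts.extend(t[(t > 0.0) & (t < 1.0)])
    ts = np.unique(np.asarray(ts))
    mids = p0 + np.outer((ts[:-1] + ts[1:]) / 2.0, d)
    idx = np.floor(grid.index_coordinates(mids) + 0.5).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
    seg_len = np.diff(ts) * length
    vals = np.zeros(len(seg_len))
    ii = idx[inside]
    vals[inside] = np.asarray(density.values, dtype=float)[ii[:, 0], ii[:, 1], ii[:, 2]]
    return float(np.sum(vals * seg_len))


def _grid_entry_t(grid: Grid, p0: np.ndarray, rel: np.ndarray) -> np.ndarray:
    """Slab-clip parameter at which each ray p0 + t*rel (t in [0,1]) first
    enters the grid bounding box; 0 if the source is inside."""
    lo, hi = grid.extent()
    lo = lo - 0.5 * np.asarray(grid.spacing)
    hi = hi + 0.5 * np.asarray(grid.spacing)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo - p0) / rel
        t2 = (hi - p0) / rel
    tmin = np.where(np.isfinite(t1), np.minimum(t1, t2), -np.inf)
    return np.clip(np.max(tmin, axis=1), 0.0, 1.0)


def _beam_dose(
    density: np.ndarray,
    grid: Grid,
    points: np.ndarray,
    beam,
    mu_eff: float,
    sigma: float,
    n_depth_samples: int,
) -> np.ndarray:
    """Unweighted dose of one beam at the given world points (N, 3)."""
    src = beam.source_mm
    iso = np.asarray(beam.isocenter_mm)
    axis_dir = (iso - src) / np.linalg.norm(iso - src)
    th = np.deg2rad(beam.gantry_deg)
    e1 = np.array([np.cos(th), -np.sin(th), 0.0])  # lateral, axial plane
    e2 = np.array([0.0, 0.0, 1.0])                 # lateral, slice axis

    rel = points - src
    depth_axis = rel @ axis_dir
    out = np.zeros(len(points))
    fwd = depth_axis > 1e-6
    if not fwd.any():
        return out
    relf = rel[fwd]
    da = depth_axis[fwd]
    scale = beam.sad_mm / da
    hw = beam.field_size_mm / 2.0
    lat1 = (relf @ e1) * scale
    lat2 = (relf @ e2) * scale
    s2 = sigma * np.sqrt(2.0)
    pen = (0.5 * (erf((hw - lat1) / s2) + erf((hw + lat1) / s2))
           * 0.5 * (erf((hw - lat2) / s2) + erf((hw + lat2) / s2)))
    infield = pen > 1e-6
    if not infield.any():
        return out
    relk = relf[infield]
    p0 = src[None, :]
    t_entry = _grid_entry_t(grid, src, relk)
    # fixed-count midpoint quadrature over the in-grid part of each ray
    fracs = (np.arange(n_depth_samples) + 0.5) / n_depth_samples
    span = 1.0 - t_entry
    acc = np.zeros(len(relk))
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    for f in fracs:
        pts = p0 + relk * (t_entry + f * span)[:, None]
        idx = ((pts - origin) / spacing).T
        acc += ndimage.map_coordinates(density, idx, order=1, mode="nearest")
    ray_len = np.linalg.norm(relk, axis=1)
    d_rad = acc / n_depth_samples * ray_len * span
    r = ray_len
    dose = np.exp(-mu_eff * d_rad) * (beam.sad_mm / r) ** 2 * pen[infield]
    tmp = np.zeros(int(fwd.sum()))
    tmp[infield] = dose
    out[fwd] = tmp
    return out


def compute_dose(
    density: Volume,
    plan: BeamPlan,
    body: BinaryMask,
    normalization: float | None = None,
    mu_eff: float = MU_EFF_PER_MM,
    sigma_penumbra: float = SIGMA_PENUMBRA_MM,
    n_depth_samples: int | None = None,
) -> Volume:
    """Dose (Gy) on the density grid, zero outside the body.

    With ``normalization=None`` the returned dose is in raw engine units
    (weight-summed beam doses); pass the constant from
    :func:`normalization_constant` to express it in Gy.
    """
    if density.unit != "density":
        raise ValueError("compute_dose requires a relative-density volume")
    if density.grid != body.grid:
        raise ValueError("density and body must share one grid")
    if not plan.beams:
        raise ValueError("plan has no beams")
    if n_depth_samples is None:
        diag = np.linalg.norm(
            (np.asarray(density.grid.shape) - 1) * np.asarray(density.grid.spacing)
        )
        n_depth_samples = int(np.clip(np.ceil(diag / (0.5 * min(density.grid.spacing))), 32, 256))

    idx = np.argwhere(body.member)
    if idx.size == 0:
        raise ValueError("empty body: no voxels to dose")
    points = body.grid.world_coordinates(idx.astype(float))
    dens = np.asarray(density.values, dtype=float)
    total = np.zeros(len(points))
    for beam in plan.beams:
        total += beam.weight * _beam_dose(
            dens, density.grid, points, beam, mu_eff, sigma_penumbra, n_depth_samples
        )
    if not np.any(total > 0):
        raise ValueError("empty field: no voxel received dose")
    out = np.zeros(density.grid.shape)
    out[idx[:, 0], idx[:, 1], idx[:, 2]] = total
    if normalization is not None:
        out *= normalization
    return Volume(density.grid, out, unit="Gy")


def normalization_constant(raw_dose: Volume, ptv: BinaryMask, prescription_gy: float) -> float:
    """Scale factor mapping raw engine dose to Gy such that the PTV median
    equals the prescription."""
    if raw_dose.grid != ptv.grid:
        raise ValueError("dose and PTV must share one grid")
    vals = np.asarray(raw_dose.values)[ptv.member]
    if vals.size == 0:
        raise ValueError("empty PTV")
    med = float(np.median(vals))
    if med <= 0:
        raise ValueError("PTV receives no dose; cannot normalize")
    return prescription_gy / med


def recalculate_on_sct(
    ct: Volume,
    sct: Volume,
    plan: BeamPlan,
    cal: DensityCalibration = DEFAULT_CALIBRATION,
    body: BinaryMask | None = None,
    ptv: BinaryMask | None = None,
    **engine_kwargs,
) -> tuple[Volume, Volume]:
    """Plan-copy recalculation: (D_CT, D_sCT) with identical plan, calibration
    and normalization constant (fixed from the CT run on the PTV median)."""
    if ct.grid != sct.grid:
        raise ValueError("CT and sCT must be on the same reference grid")
    if body is None:
        raise ValueError("a body mask is required")
    d_ct_raw = compute_dose(hu_to_density(ct, cal), plan, body, **engine_kwargs)
    if ptv is not None:
        k = normalization_constant(d_ct_raw, ptv, plan.prescription_gy)
    else:
        k = 1.0
    d_sct_raw = compute_dose(hu_to_density(sct, cal), plan, body, **engine_kwargs)
    d_ct = Volume(ct.grid, np.asarray(d_ct_raw.values) * k, unit="Gy")
    d_sct = Volume(ct.grid, np.asarray(d_sct_raw.values) * k, unit="Gy")
    return d_ct, d_sct
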