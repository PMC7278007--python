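"""Seeded synthetic head-phantom cohort: co-registered CT/MR pairs with six
tissue classes, an enhancing lesion, structures (BODY/GTV/PTV) and a beam plan.

The anatomy is deliberately simple — nested ellipsoidal shells (scalp, skull,
CSF, grey matter, white matter) plus an air sinus and an ellipsoidal lesion —
but it carries the features the downstream analysis is sensitive to: a
six-class partition with known Hounsfield means, a bone shell that thresholds
cleanly at 300 HU, MR intensity contrast between classes, optional noise,
bias-field shading, contrast enhancement of the lesion, a continuous skull HU
gradient and partial-volume blur for a realistic (nonzero-MAE) regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, Grid, Volume

__all__ = [
    "LABELS",
    "CT_CLASS_MEANS_HU",
    "MR_CLASS_MEANS",
    "PhantomConfig",
    "PhantomCase",
    "BeamPlan",
    "Beam",
    "generate_case",
    "generate_cohort",
    "make_plan",
    "GTV_RANGES_CM3",
    "PTV_RANGES_CM3",
]

#: integer label per tissue class
LABELS = {"air": 0, "soft": 1, "bone": 2, "gm": 3, "wm": 4, "csf": 5}

#: class-mean HU used for CT synthesis; identical to the HU lookup the sCT
#: stage assigns, so a noiseless phantom is an exact fixed point of the pipeline
CT_CLASS_MEANS_HU = {
    "air": -1000.0,
    "soft": 40.0,
    "bone": 942.0,
    "gm": 41.0,
    "wm": 25.0,
    "csf": 15.0,
}

#: T1w-like MR intensity means (arbitrary units); well separated so that a
#: noiseless phantom is perfectly classifiable by intensity alone
MR_CLASS_MEANS = {
    "air": 2.0,
    "bone": 30.0,
    "csf": 70.0,
    "gm": 120.0,
    "wm": 170.0,
    "soft": 220.0,
}

#: GTV / PTV volume ranges (cm³) the cohort must respect, per patient group
GTV_RANGES_CM3 = {"glioma": (14.2, 112.3), "metastasis": (0.1, 16.4)}
PTV_RANGES_CM3 = {"glioma": (132.8, 373.3), "metastasis": (0.3, 28.8)}

#: cohort sampling subranges: GTV volumes drawn here keep PTV = GTV ⊕ margin
#: inside PTV_RANGES_CM3 and the lesion resolvable on coarse grids
_GTV_SAMPLING_CM3 = {"glioma": (20.0, 90.0), "metastasis": (1.0, 16.4)}
_PTV_MARGIN_MM = {"glioma": 16.0, "metastasis": 2.5}


@dataclass(frozen=True)
class PhantomConfig:
    """Generator settings for one synthetic case.

    The defaults are the *realistic* regime: CT/MR noise, MR bias-field
    shading, lesion contrast enhancement, a continuous skull HU gradient
    (700–1300 HU) and 0.5-voxel partial-volume blur. Use :meth:`noiseless`
    for the exact fixed-point regime in which CT is the pure class-mean
    lookup of the labels.
    """

    grid: Grid = field(
        default_factory=lambda: Grid((200, 200, 90), (1.0, 1.0, 2.0), (0.0, 0.0, 0.0))
    )
    group: str = "glioma"
    lesion_volume_cm3: float = 50.0
    ptv_margin_mm: float = 16.0
    noise_sd_ct: float = 20.0
    noise_sd_mr: float = 8.0
    bias_field_amplitude: float = 0.10
    contrast_enhancement: float = 1.3
    skull_hu_range: tuple[float, float] | None = (700.0, 1300.0)
    pv_blur_voxels: float = 0.5
    skull_thickness_frac: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in GTV_RANGES_CM3:
            raise ValueError(f"unknown group {self.group!r}")
        lo, hi = GTV_RANGES_CM3[self.group]
        if not (lo <= self.lesion_volume_cm3 <= hi):
            raise ValueError(
                f"lesion volume {self.lesion_volume_cm3} cm³ outside the "
                f"{self.group} GTV range [{lo}, {hi}] cm³"
            )
        if not (0.0 <= self.bias_field_amplitude < 1.0):
            raise ValueError("bias_field_amplitude must lie in [0, 1)")

    @classmethod
    def noiseless(cls, **kwargs) -> "PhantomConfig":
        """Exact fixed-point regime: no noise, no bias, no enhancement, no
        skull gradient, no partial-volume blur."""
        base = dict(
            noise_sd_ct=0.0,
            noise_sd_mr=0.0,
            bias_field_amplitude=0.0,
            contrast_enhancement=1.0,
            skull_hu_range=None,
            pv_blur_voxels=0.0,
        )
        base.update(kwargs)
        return cls(**base)


@dataclass(frozen=True)
class Beam:
    gantry_deg: float
    sad_mm: float
    isocenter_mm: tuple[float, float, float]
    field_size_mm: float
    weight: float

    @property
    def source_mm(self) -> np.ndarray:
        """Source position: gantry rotates in the axial (x–y) plane; at 0° the
        beam enters from +y (anterior) toward the isocenter."""
        th = np.deg2rad(self.gantry_deg)
        iso = np.asarray(self.isocenter_mm)
        return iso + self.sad_mm * np.array([np.sin(th), np.cos(th), 0.0])


@dataclass(frozen=True)
class BeamPlan:
    prescription_gy: float
    beams: tuple[Beam, ...]

    def __post_init__(self) -> None:
        w = sum(b.weight for b in self.beams)
        if self.beams and abs(w - 1.0) > 1e-9:
            raise ValueError(f"beam weights must sum to 1, got {w}")

    def to_dict(self) -> dict:
        return {
            "prescription_gy": self.prescription_gy,
            "beams": [
                {
                    "gantry_deg": b.gantry_deg,
                    "sad_mm": b.sad_mm,
                    "isocenter_mm": list(b.isocenter_mm),
                    "field_size_mm": b.field_size_mm,
                    "weight": b.weight,
                }
                for b in self.beams
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BeamPlan":
        return cls(
            prescription_gy=float(d["prescription_gy"]),
            beams=tuple(
                Beam(
                    float(b["gantry_deg"]),
                    float(b["sad_mm"]),
                    tuple(b["isocenter_mm"]),
                    float(b["field_size_mm"]),
                    float(b["weight"]),
                )
                for b in d["beams"]
            ),
        )


@dataclass
class PhantomCase:
    """One synthetic patient: labels, CT, MR, structures and a default plan."""

    case_id: str
    group: str
    config: PhantomConfig
    labels: Volume  # integer tissue labels, unit "label"
    ct: Volume
    mr: Volume
    structures: dict[str, BinaryMask]  # BODY, GTV, PTV
    plan: BeamPlan


# ----------------------------------------------------------------- anatomy


def _ellipsoid_rho(grid: Grid, center: np.ndarray, semi_axes: np.ndarray) -> np.ndarray:
    """Normalized ellipsoid coordinate: rho < 1 inside."""
    xs, ys, zs = grid.coordinate_arrays()
    dx = (xs - center[0]) / semi_axes[0]
    dy = (ys - center[1]) / semi_axes[1]
    dz = (zs - center[2]) / semi_axes[2]
    return np.sqrt(
        dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
    )


def _smooth_field(shape: tuple[int, int, int], rng: np.random.Generator,
                  sigma_voxels: float = 8.0) -> np.ndarray:
    """Smooth random field normalized to roughly [-1, 1]."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_voxels)
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def _build_labels(config: PhantomConfig, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Return (labels, gtv_mask) on the config grid."""
    grid = config.grid
    lo, hi = grid.extent()
    center = (np.asarray(lo) + np.asarray(hi)) / 2.0
    half = (np.asarray(hi) - np.asarray(lo)) / 2.0
    # head ellipsoid fills ~90% of the grid
    head_axes = 0.90 * half
    rho = _ellipsoid_rho(grid, center, head_axes)

    t = config.skull_thickness_frac
    labels = np.full(grid.shape, LABELS["air"], dtype=np.int8)
    labels[rho <= 1.0] = LABELS["soft"]                     # scalp / soft rim
    labels[rho <= 0.92] = LABELS["bone"]                    # skull shell
    labels[rho <= 0.92 - t] = LABELS["csf"]                 # CSF layer
    labels[rho <= 0.92 - t - 0.05] = LABELS["gm"]           # GM shell
    labels[rho <= 0.92 - t - 0.19] = LABELS["wm"]           # WM core

    # air sinus: small ellipsoid in the anterior-inferior quadrant
    sinus_center = center + np.array([0.0, 0.62 * head_axes[1], -0.45 * head_axes[2]])
    sinus_axes = np.array([10.0, 9.0, 8.0])
    sinus = _ellipsoid_rho(grid, sinus_center, sinus_axes) <= 1.0
    labels[sinus & (rho <= 1.0)] = LABELS["air"]

    # lesion: ellipsoid of the requested volume inside the eroded brain
    brain_core = rho <= (0.92 - t - 0.19) * 0.9
    if not brain_core.any():
        raise ValueError("grid too coarse: no brain-core voxels to host a lesion")
    target_mm3 = config.lesion_volume_cm3 * 1000.0
    r_eq = (3.0 * target_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    ratios = rng.uniform(0.75, 1.3, size=3)
    semi = r_eq * ratios / np.prod(ratios) ** (1.0 / 3.0)
    # center candidates: brain-core voxels that keep the lesion inside the
    # brain and clear of the air sinus
    margin = _ellipsoid_rho(grid, center, head_axes - semi.max()) <= (0.92 - t - 0.19)
    sinus_clear = _ellipsoid_rho(grid, sinus_center, sinus_axes + semi.max()) > 1.0
    candidates = np.argwhere(brain_core & margin & sinus_clear)
    if candidates.size == 0:
        raise ValueError(
            f"lesion of {config.lesion_volume_cm3} cm³ cannot fit inside the brain"
        )
    c_idx = candidates[rng.integers(len(candidates))]
    lesion_center = grid.world_coordinates(c_idx.astype(float))
    lesion_rho = _ellipsoid_rho(grid, lesion_center, semi)
    # exact-count voxelization: take the k smallest rho values
    k = max(1, int(round(target_mm3 / grid.voxel_volume_mm3)))
    flat = lesion_rho.ravel()
    if k >= flat.size:
        raise ValueError("lesion volume exceeds grid volume")
    thresh = np.partition(flat, k - 1)[k - 1]
    gtv = lesion_rho <= thresh
    if not np.all(labels[gtv] != LABELS["air"]):
        # lesion leaked outside the head (should not happen with the margin)
        raise ValueError("lesion placement escaped the body")
    labels[gtv] = LABELS["soft"]  # contrast-enhancing lesion folds into soft tissue
    return labels, gtv


def _class_lookup(labels: np.ndarray, means: dict[str, float]) -> np.ndarray:
    lut = np.zeros(max(LABELS.values()) + 1)
    for name, lab in LABELS.items():
        lut[lab] = means[name]
    return lut[labels]


def _synthesize_ct(labels: np.ndarray, config: PhantomConfig,
                   rng: np.random.Generator) -> np.ndarray:
    ct = _class_lookup(labels, CT_CLASS_MEANS_HU)
    if config.skull_hu_range is not None:
        lo, hi = config.skull_hu_range
        bone = labels == LABELS["bone"]
        if bone.any():
            # continuous HU gradient across the shell: outer table dense,
            # inner table lighter
            dist_out = ndimage.distance_transform_edt(bone, sampling=config.grid.spacing)
            d = dist_out[bone]
            dmax = d.max() if d.max() > 0 else 1.0
            ct[bone] = hi - (hi - lo) * (d / dmax)
    if config.pv_blur_voxels > 0:
        ct = ndimage.gaussian_filter(ct, config.pv_blur_voxels)
    if config.noise_sd_ct > 0:
        ct = ct + rng.normal(0.0, config.noise_sd_ct, size=ct.shape)
    return np.clip(ct, -1000.0, 3071.0)


def _synthesize_mr(labels: np.ndarray, gtv: np.ndarray, config: PhantomConfig,
                   rng: np.random.Generator) -> np.ndarray:
    mr = _class_lookup(labels, MR_CLASS_MEANS)
    mr[gtv] *= config.contrast_enhancement
    if config.bias_field_amplitude > 0:
        bias = 1.0 + config.bias_field_amplitude * _smooth_field(labels.shape, rng)
        mr = mr * bias
    if config.pv_blur_voxels > 0:
        mr = ndimage.gaussian_filter(mr, config.pv_blur_voxels)
    if config.noise_sd_mr > 0:
        mr = mr + rng.normal(0.0, config.noise_sd_mr, size=mr.shape)
    return np.clip(mr, 0.0, None)


def generate_case(config: PhantomConfig, case_id: str = "case") -> PhantomCase:
    """Generate one co-registered CT/MR phantom with structures and a plan.

    Deterministic for a fixed config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    labels, gtv = _build_labels(config, rng)
    ct = _synthesize_ct(labels, config, rng)
    mr = _synthesize_mr(labels, gtv, config, rng)

    body = labels != LABELS["air"]
    gtv_mask = BinaryMask(grid, gtv)
    dist = ndimage.distance_transform_edt(~gtv, sampling=grid.spacing)
    ptv = (dist <= config.ptv_margin_mm) & body
    structures = {
        "BODY": BinaryMask(grid, body),
        "GTV": gtv_mask,
        "PTV": BinaryMask(grid, ptv),
    }

    case = PhantomCase(
        case_id=case_id,
        group=config.group,
        config=config,
        labels=Volume(grid, labels, unit="label"),
        ct=Volume(grid, ct, unit="HU"),
        mr=Volume(grid, mr, unit="MR"),
        structures=structures,
        plan=None,  # type: ignore[arg-type]
    )
    case.plan = make_plan(case, n_beams=4, prescription_gy=30.0)
    return case


def make_plan(case: PhantomCase, n_beams: int = 4,
              prescription_gy: float = 30.0, sad_mm: float = 1000.0) -> BeamPlan:
    """Equally weighted coplanar beams at evenly spaced gantry angles aimed at
    the PTV centroid; square field covers the PTV bounding box plus 5 mm."""
    if n_beams < 1:
        raise ValueError("n_beams must be >= 1")
    ptv = case.structures["PTV"]
    idx = np.argwhere(ptv.member)
    if idx.size == 0:
        raise ValueError("empty PTV: cannot plan")
    grid = ptv.grid
    centroid_idx = idx.mean(axis=0)
    # snap the isocenter to the PTV voxel nearest the centroid so it is
    # guaranteed to lie inside the (possibly non-convex) PTV
    nearest = idx[np.argmin(((idx - centroid_idx) ** 2).sum(axis=1))]
    iso = grid.world_coordinates(nearest.astype(float))

    lo = grid.world_coordinates(idx.min(axis=0).astype(float))
    hi = grid.world_coordinates(idx.max(axis=0).astype(float))
    field_size = float(np.max(hi - lo) + 2 * 5.0)

    angles = np.arange(n_beams) * (360.0 / n_beams)
    beams = tuple(
        Beam(float(a), sad_mm, tuple(iso), field_size, 1.0 / n_beams) for a in angles
    )
    return BeamPlan(prescription_gy=prescription_gy, beams=beams)


def generate_cohort(n_glioma: int, n_metastasis: int, seed: int,
                    grid_glioma: Grid | None = None,
                    grid_metastasis: Grid | None = None,
                    realistic: bool = True,
                    **config_overrides) -> list[PhantomCase]:
    """Generate a cohort of phantoms, ``n_glioma`` + ``n_metastasis`` cases.

    Per-case seeds are split from the master seed as ``seed * 1000 + index``.
    GTV volumes are sampled uniformly within group-specific subranges chosen so
    the resulting PTVs stay inside the reference volume ranges; glioma cases
    use 2 mm slices, metastasis cases 1 mm.
    """
    if n_glioma < 0 or n_metastasis < 0:
        raise ValueError("cohort sizes must be >= 0")
    if grid_glioma is None:
        grid_glioma = Grid((200, 200, 90), (1.0, 1.0, 2.0))
    if grid_metastasis is None:
        grid_metastasis = Grid((200, 200, 180), (1.0, 1.0, 1.0))
    rng = np.random.default_rng(seed)
    cases: list[PhantomCase] = []
    specs = [("glioma", grid_glioma)] * n_glioma + [
        ("metastasis", grid_metastasis)
    ] * n_metastasis
    for i, (group, grid) in enumerate(specs):
        lo, hi = _GTV_SAMPLING_CM3[group]
        vol = float(rng.uniform(lo, hi))
        kwargs = dict(
            grid=grid,
            group=group,
            lesion_volume_cm3=vol,
            ptv_margin_mm=_PTV_MARGIN_MM[group],
            seed=seed * 1000 + i,
        )
        kwargs.update(config_overrides)
        cfg = (
            PhantomConfig(**kwargs)
            if realistic
            else PhantomConfig.noiseless(**kwargs)
        )
        cases.append(generate_case(cfg, case_id=f"{group}-{i:02d}"))
    return cases
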