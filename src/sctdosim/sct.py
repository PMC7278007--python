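"""Six-class tissue segmentation of the MR volume and synthetic-CT assembly.

The sCT is built by (1) detecting the body outline and assigning air,
(2) fitting a Gaussian mixture by expectation–maximization to the body-voxel
intensities after polynomial bias-field flattening, (3) labeling mixture
components by the rank of their means against the expected MR intensity
ordering (or, optionally, by majority overlap with an atlas label map),
(4) hardening posteriors to mutually exclusive masks with a fixed tie-break
priority and small-component cleanup, and (5) a piecewise-constant HU lookup.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.mixture import GaussianMixture

from .grids import BinaryMask, Grid, Volume, resample_to
from .phantom import LABELS, MR_CLASS_MEANS

__all__ = [
    "HUTable",
    "DEFAULT_HU_TABLE",
    "TissuePosteriors",
    "segment_tissues",
    "masks_from_posteriors",
    "assemble_sct",
    "run_sct_pipeline",
]

#: argmax tie-break priority, highest first
TIE_PRIORITY = ("bone", "csf", "gm", "wm", "soft", "air")

#: connected components of bone/air smaller than this are reassigned to soft
MIN_COMPONENT_CM3 = 0.05


@dataclass(frozen=True)
class HUTable:
    """Tissue class → Hounsfield unit lookup for sCT assembly.

    The five literature values are cortical bone 942, air −1000, grey matter
    41, white matter 25 and CSF 15 HU; the sixth ("other soft tissue") class
    defaults to 40 HU and is configurable.
    """

    values: dict[str, float] = field(
        default_factory=lambda: {
            "air": -1000.0,
            "soft": 40.0,
            "bone": 942.0,
            "gm": 41.0,
            "wm": 25.0,
            "csf": 15.0,
        }
    )

    def __post_init__(self) -> None:
        if set(self.values) != set(LABELS):
            raise ValueError(f"HU table must define exactly the classes {set(LABELS)}")
        for name, hu in self.values.items():
            if not (-1000.0 <= hu <= 3071.0):
                raise ValueError(f"HU for {name!r} outside [-1000, 3071]: {hu}")

    def as_lut(self) -> np.ndarray:
        lut = np.zeros(max(LABELS.values()) + 1)
        for name, lab in LABELS.items():
            lut[lab] = self.values[name]
        return lut

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.values, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "HUTable":
        with open(path) as fh:
            return cls(json.load(fh))


DEFAULT_HU_TABLE = HUTable()


@dataclass
class TissuePosteriors:
    """Per-class posterior probability volumes on the MR grid.

    ``probabilities`` has shape grid.shape + (6,), indexed by the class
    integers of :data:`sctdosim.phantom.LABELS`; per voxel the probabilities
    are non-negative and sum to one.
    """

    grid: Grid
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        if self.probabilities.shape != self.grid.shape + (len(LABELS),):
            raise ValueError("posterior array shape mismatch")
        sums = self.probabilities.sum(axis=-1)
        if np.any(self.probabilities < -1e-9) or np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("posteriors must be >= 0 and sum to 1 per voxel")


def _body_outline(mr_values: np.ndarray, threshold: float) -> np.ndarray:
    """Largest above-threshold connected component, holes filled in-plane-3D."""
    fg = mr_values > threshold
    lab, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("no body found: MR has no voxels above the air threshold")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    body = lab == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(body)


def _polynomial_bias_flatten(
    values: np.ndarray,
    body: np.ndarray,
    grid: Grid,
    responsibilities: np.ndarray,
    log_means: np.ndarray,
    degree: int = 2,
) -> np.ndarray:
    """Estimate a smooth multiplicative bias field as a low-order polynomial
    fit to the residual between log-intensity and the posterior-predicted log
    class mean, and divide it out. On a bias-free image the residual is ~0 and
    the correction is the identity."""
    coords = [c / max(abs(c).max(), 1.0) for c in
              (np.asarray(g) - np.asarray(g).mean() for g in grid.coordinate_arrays())]
    xs, ys, zs = np.meshgrid(*coords, indexing="ij")
    x, y, z = xs[body], ys[body], zs[body]
    terms = [np.ones_like(x), x, y, z]
    if degree >= 2:
        terms += [x * y, x * z, y * z, x**2, y**2, z**2]
    A = np.stack(terms, axis=1)
    resid = np.log(np.maximum(values[body], 1e-6)) - responsibilities @ log_means
    coef, *_ = np.linalg.lstsq(A, resid, rcond=None)
    log_bias = A @ coef
    log_bias -= log_bias.mean()
    corrected = values.copy()
    corrected[body] = values[body] / np.exp(np.clip(log_bias, -1.5, 1.5))
    return corrected


def segment_tissues(
    mr: Volume,
    n_classes: int = 6,
    atlas_hint: Volume | None = None,
    seed: int = 0,
    air_threshold_fraction: float = 0.08,
    bias_iterations: int = 2,
    max_em_iter: int = 200,
) -> TissuePosteriors:
    """Segment an MR volume into six tissue-class posteriors.

    Air is assigned by body-outline thresholding (below
    ``air_threshold_fraction`` of the 99th-percentile intensity, or outside
    the body). The remaining five classes are fitted as a 1-D Gaussian
    mixture by EM on body voxels, interleaved with polynomial bias-field
    flattening; components are labeled by matching the rank of their means to
    the expected MR intensity ordering, or by majority overlap with
    ``atlas_hint`` when given. Deterministic for a fixed seed.
    """
    if n_classes != len(LABELS):
        raise ValueError("only six-class segmentation is supported")
    values = np.asarray(mr.values, dtype=float)
    if values.max() <= 0:
        raise ValueError("MR volume has no positive intensities")
    threshold = air_threshold_fraction * np.percentile(values, 99.0)
    body = _body_outline(values, threshold)
    tissue = body & (values > threshold)
    if tissue.sum() < 10 * (n_classes - 1):
        raise ValueError("too few body voxels to fit the tissue mixture")

    x = values[tissue].reshape(-1, 1)
    n_comp = n_classes - 1  # air is handled by thresholding

    def _fit(data: np.ndarray) -> GaussianMixture:
        # k-means initialization separates well-spaced intensity modes that a
        # quantile init can merge when class sizes are very unequal
        gm = GaussianMixture(
            n_components=n_comp,
            covariance_type="full",
            init_params="k-means++",
            n_init=3,
            reg_covar=1e-3,
            max_iter=max_em_iter,
            random_state=seed,
        )
        gm.fit(data)
        if not gm.converged_:
            raise RuntimeError(
                f"EM did not converge within {max_em_iter} iterations "
                f"(lower bound {gm.lower_bound_:.6g})"
            )
        return gm

    gm = _fit(x)
    corrected = values
    for _ in range(bias_iterations):
        resp = gm.predict_proba(corrected[tissue].reshape(-1, 1))
        log_means = np.log(np.maximum(gm.means_.ravel(), 1e-6))
        flat = _polynomial_bias_flatten(corrected, tissue, mr.grid, resp, log_means)
        gm = _fit(flat[tissue].reshape(-1, 1))
        corrected = flat

    # label components: rank of fitted means vs expected intensity ordering
    tissue_names = [n for n in MR_CLASS_MEANS if n != "air"]
    expected_order = sorted(tissue_names, key=lambda n: MR_CLASS_MEANS[n])
    comp_order = np.argsort(gm.means_.ravel())
    comp_to_class = {}
    for rank, comp in enumerate(comp_order):
        comp_to_class[comp] = LABELS[expected_order[rank]]

    if atlas_hint is not None:
        hard = gm.predict(corrected[tissue].reshape(-1, 1))
        atlas = np.asarray(atlas_hint.values)[tissue]
        for comp in range(n_comp):
            sel = atlas[hard == comp]
            sel = sel[sel != LABELS["air"]]
            if sel.size:
                comp_to_class[comp] = int(np.bincount(sel).argmax())

    proba = gm.predict_proba(corrected[tissue].reshape(-1, 1))
    post = np.zeros(mr.grid.shape + (len(LABELS),))
    post[..., LABELS["air"]] = 1.0  # default: air everywhere
    post[tissue, LABELS["air"]] = 0.0
    for comp in range(n_comp):
        cls = comp_to_class[comp]
        post[tissue, cls] += proba[:, comp]
    post /= post.sum(axis=-1, keepdims=True)
    return TissuePosteriors(mr.grid, post)


def masks_from_posteriors(
    post: TissuePosteriors,
    min_component_cm3: float = MIN_COMPONENT_CM3,
) -> dict[str, BinaryMask]:
    """Harden posteriors to six mutually exclusive, jointly exhaustive masks.

    Per-voxel argmax; exact ties go to the class earliest in
    ``bone > csf > gm > wm > soft > air``. Connected components of bone or
    air smaller than ``min_component_cm3`` are reassigned to soft tissue.
    """
    order = [LABELS[name] for name in TIE_PRIORITY]
    # argmax with priority tie-break: scan classes in priority order and keep
    # the first class attaining the per-voxel maximum
    stacked = post.probabilities[..., order]
    winner_pos = np.argmax(
        np.isclose(stacked, stacked.max(axis=-1, keepdims=True), rtol=0, atol=1e-12),
        axis=-1,
    )
    labels = np.asarray(order, dtype=np.int8)[winner_pos]

    voxel_cm3 = post.grid.voxel_volume_mm3 / 1000.0
    min_vox = int(np.ceil(min_component_cm3 / voxel_cm3))
    for name in ("bone", "air"):
        cls = LABELS[name]
        comp, n = ndimage.label(labels == cls)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, np.arange(1, n + 1))
        for ci in np.nonzero(sizes < min_vox)[0]:
            labels[comp == ci + 1] = LABELS["soft"]

    return {
        name: BinaryMask(post.grid, labels == lab) for name, lab in LABELS.items()
    }


def assemble_sct(masks: dict[str, BinaryMask], hu: HUTable = DEFAULT_HU_TABLE) -> Volume:
    """Piecewise-constant HU volume from six exclusive tissue masks."""
    names = list(masks)
    if set(names) != set(LABELS):
        raise ValueError("masks must cover exactly the six tissue classes")
    grid = masks[names[0]].grid
    total = np.zeros(grid.shape, dtype=np.int32)
    out = np.zeros(grid.shape)
    for name, mask in masks.items():
        if mask.grid != grid:
            raise ValueError("all masks must share one grid")
        total += mask.member
        out[mask.member] = hu.values[name]
    if not np.all(total == 1):
        raise ValueError("masks must partition the grid (exclusive and exhaustive)")
    return Volume(grid, out, unit="HU")


def run_sct_pipeline(
    mr: Volume,
    reference: Grid | None = None,
    hu: HUTable = DEFAULT_HU_TABLE,
    seed: int = 0,
    atlas_hint: Volume | None = None,
) -> Volume:
    """MR → posteriors → masks → sCT, resampled onto ``reference`` if given.

    Resolution matching uses nearest-class resampling of the label image
    followed by the HU lookup, so the output remains piecewise-constant in
    the table's values.
    """
    post = segment_tissues(mr, seed=seed, atlas_hint=atlas_hint)
    masks = masks_from_posteriors(post)
    sct = assemble_sct(masks, hu)
    if reference is not None and reference != mr.grid:
        label_img = np.zeros(mr.grid.shape, dtype=np.int8)
        for name, m in masks.items():
            label_img[m.member] = LABELS[name]
        lbl = resample_to(
            Volume(mr.grid, label_img, unit="label"), reference, mode="nearest", fill=0
        )
        sct = Volume(reference, hu.as_lut()[np.asarray(lbl.values, dtype=int)], unit="HU")
    return sct
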