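"""Structure construction (OAR ring), cumulative DVHs, ICRU-83-style DVH
parameters, relative dose differences and the paired/two-sample rank tests.

DVH parameters follow the near-max/near-min convention: D_X% is the minimum
dose received by the hottest X% of the structure volume (interpolated order
statistic), D_0.1cc the minimum dose of the hottest 0.1 cm³, D_max the voxel
maximum and D_mean the arithmetic mean of member-voxel doses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grids import BinaryMask, Volume, distance_from_mask

__all__ = [
    "DVHCurve",
    "DVHParameters",
    "DVH_PARAMETER_NAMES",
    "oar_ring",
    "cumulative_dvh",
    "dvh_parameters",
    "relative_difference",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
]

DVH_PARAMETER_NAMES = ("d_max", "d_0.1cc", "d_2pct", "d_50pct", "d_95pct", "d_98pct", "d_mean")


@dataclass
class DVHCurve:
    """Exact (unbinned) cumulative DVH of one structure."""

    structure: str
    doses_gy: np.ndarray  # sorted ascending
    voxel_volume_cm3: float

    def __post_init__(self) -> None:
        self.doses_gy = np.sort(np.asarray(self.doses_gy, dtype=float))
        if self.doses_gy.size == 0:
            raise ValueError("DVH of an empty structure is undefined")

    @property
    def volume_cm3(self) -> float:
        return self.doses_gy.size * self.voxel_volume_cm3

    def volume_fraction(self, dose_gy) -> np.ndarray:
        """V(D): fraction of the structure receiving at least dose D."""
        d = np.atleast_1d(np.asarray(dose_gy, dtype=float))
        frac = 1.0 - np.searchsorted(self.doses_gy, d, side="left") / self.doses_gy.size
        return frac if np.ndim(dose_gy) else float(frac[0])


@dataclass(frozen=True)
class DVHParameters:
    d_max: float
    d_0_1cc: float
    d_2pct: float
    d_50pct: float
    d_95pct: float
    d_98pct: float
    d_mean: float

    def as_dict(self) -> dict[str, float]:
        return dict(zip(DVH_PARAMETER_NAMES, (
            self.d_max, self.d_0_1cc, self.d_2pct, self.d_50pct,
            self.d_95pct, self.d_98pct, self.d_mean,
        )))


def oar_ring(ptv: BinaryMask, body: BinaryMask, distance_mm: float = 20.0) -> BinaryMask:
    """Ring of tissue within ``distance_mm`` of the PTV outer edge: voxels with
    0 < distance-to-PTV ≤ distance_mm, inside the body, excluding the PTV."""
    if ptv.grid != body.grid:
        raise ValueError("PTV and body must share one grid")
    if not ptv.member.any():
        raise ValueError("empty PTV")
    dist = np.asarray(distance_from_mask(ptv).values)
    member = (dist > 0.0) & (dist <= distance_mm) & body.member & ~ptv.member
    return BinaryMask(ptv.grid, member)


def cumulative_dvh(dose: Volume, mask: BinaryMask, structure: str = "") -> DVHCurve:
    """Exact empirical cumulative DVH from the member-voxel doses."""
    if dose.grid != mask.grid:
        raise ValueError("dose and mask must share one grid")
    if not mask.member.any():
        raise ValueError(f"empty structure {structure!r}")
    return DVHCurve(
        structure=structure,
        doses_gy=np.asarray(dose.values, dtype=float)[mask.member],
        voxel_volume_cm3=dose.grid.voxel_volume_mm3 / 1000.0,
    )


def _d_percent(doses_sorted: np.ndarray, x_pct: float) -> float:
    """Minimum dose of the hottest x% (interpolated order statistic)."""
    return float(np.quantile(doses_sorted, 1.0 - x_pct / 100.0, method="linear"))


def dvh_parameters(curve: DVHCurve) -> DVHParameters:
    """ICRU-83-style parameter set from a DVH curve."""
    d = curve.doses_gy
    d_max = float(d[-1])
    if curve.volume_cm3 < 0.1:
        warnings.warn(
            f"structure {curve.structure!r} smaller than 0.1 cm³; D_0.1cc = D_max"
        )
        d01 = d_max
    else:
        k = int(np.ceil(0.1 / curve.voxel_volume_cm3))
        d01 = float(d[-k])
    return DVHParameters(
        d_max=d_max,
        d_0_1cc=d01,
        d_2pct=_d_percent(d, 2.0),
        d_50pct=_d_percent(d, 50.0),
        d_95pct=_d_percent(d, 95.0),
        d_98pct=_d_percent(d, 98.0),
        d_mean=float(d.mean()),
    )


def relative_difference(d_sct_gy: float, d_ct_gy: float) -> float:
    """Relative dose difference, percent: 100 (D_sCT − D_CT) / D_CT."""
    if d_ct_gy <= 0:
        raise ValueError("reference dose must be > 0")
    return 100.0 * (d_sct_gy - d_ct_gy) / d_ct_gy


def wilcoxon_signed_rank(differences, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired differences.

    Exact null distribution when the non-zero differences are untied and
    n ≤ ``exact_max_n``; otherwise normal approximation with Pratt
    zero handling and tie correction. All-zero input returns p = 1.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("no differences given")
    nonzero = d[d != 0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; p = 1.0")
        return 1.0
    if nonzero.size < 5:
        warnings.warn("fewer than 5 non-zero differences; test has little power")
    ties = np.unique(np.abs(nonzero)).size < nonzero.size
    if nonzero.size <= exact_max_n and not ties and nonzero.size == d.size:
        res = stats.wilcoxon(d, alternative="two-sided", method="exact")
    else:
        res = stats.wilcoxon(
            d, alternative="two-sided", method="approx",
            zero_method="pratt", correction=True,
        )
    return float(min(res.pvalue, 1.0))


def mann_whitney_u(group_a, group_b, exact_max_n: int = 12) -> float:
    """Two-sided Mann–Whitney U p-value between two independent samples.

    Exact enumeration when n_a + n_b ≤ ``exact_max_n`` and there are no
    ties; normal approximation with tie and continuity correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= exact_max_n and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))
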