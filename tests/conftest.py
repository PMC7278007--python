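import numpy as np
import pytest

from sctdosim import Grid, PhantomConfig, generate_case


@pytest.fixture(scope="session")
def coarse_grid():
    """Desk-scale isotropic grid used by most phantom-based tests."""
    return Grid((48, 48, 48), (4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def noiseless_case(coarse_grid):
    """Noiseless glioma phantom: the exact fixed point of the sCT pipeline."""
    cfg = PhantomConfig.noiseless(
        grid=coarse_grid, group="glioma", lesion_volume_cm3=40.0, seed=3
    )
    return generate_case(cfg, case_id="fixedpoint")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def smooth_dose_pair(shape, spacing, seed, perturbation=0.01, shift_voxels=0.0):
    """Correlated smooth random dose pair on a shared grid (helper used by
    gamma tests): reference is a smoothed positive random field, evaluated is
    the reference plus a smooth relative perturbation."""
    from scipy import ndimage

    from sctdosim import Grid, Volume

    g = np.random.default_rng(seed)
    base = ndimage.gaussian_filter(g.random(shape), 2.5)
    base -= base.min()
    base /= base.max()
    ref = base**2  # peaked, with a genuine low-dose region
    pert = ndimage.gaussian_filter(g.standard_normal(shape), 3.0)
    pert /= max(np.abs(pert).max(), 1e-12)
    ev = ref * (1.0 + perturbation * pert)
    if shift_voxels:
        ev = np.roll(ev, int(shift_voxels), axis=0)
    grid = Grid(shape, spacing)
    return Volume(grid, ref, unit="Gy"), Volume(grid, ev, unit="Gy")
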