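"""Shared fixtures: small synthetic geometries and simulated data."""

import numpy as np
import pytest

from nucleofish import NucleusMask, SimulationConfig, simulate_stack


SPACING = (0.15, 0.1, 0.1)  # (z, y, x) um


def make_sphere_mask(radius_um=1.0, spacing=SPACING, pad=4, **kw):
    """Digitized sphere; centre sits exactly on a voxel centre."""
    spacing = np.asarray(spacing)
    half = np.ceil(radius_um / spacing).astype(int) + pad
    shape = 2 * half + 1
    grids = np.meshgrid(*[(np.arange(n) - h) * s
                          for n, h, s in zip(shape, half, spacing)],
                        indexing="ij")
    r2 = sum(g**2 for g in grids)
    mask = r2 <= radius_um**2
    m = NucleusMask(mask, tuple(spacing), **kw)
    return m, half * spacing  # mask, centre (um)


def make_ellipsoid_mask(semiaxes_um=(1.0, 1.5, 2.0), spacing=SPACING, pad=4):
    spacing = np.asarray(spacing)
    semi = np.asarray(semiaxes_um)
    half = np.ceil(semi / spacing).astype(int) + pad
    shape = 2 * half + 1
    grids = np.meshgrid(*[(np.arange(n) - h) * s
                          for n, h, s in zip(shape, half, spacing)],
                        indexing="ij")
    u2 = sum((g / a)**2 for g, a in zip(grids, semi))
    return NucleusMask(u2 <= 1.0, tuple(spacing)), half * spacing


def brute_force_signed_distance(point_um, mask: NucleusMask) -> float:
    """Independent oracle: exhaustive minimum over every voxel on the far
    side of the chromatin interface (all background voxels, including a
    one-voxel virtual layer beyond the array edge, for inside points; all
    mask voxels for outside points)."""
    spacing = np.asarray(mask.spacing)
    local = mask.to_local_um(point_um)
    if mask.contains(point_um):
        padded = np.pad(mask.mask, 1)
        pts = (np.argwhere(~padded) - 1) * spacing
        return float(np.sqrt(((pts - local) ** 2).sum(axis=1)).min())
    pts = np.argwhere(mask.mask) * spacing
    return -float(np.sqrt(((pts - local) ** 2).sum(axis=1)).min())


def random_blob_mask(rng, max_shape=40, spacing=SPACING) -> NucleusMask:
    """Random connected blob for oracle-equivalence sweeps."""
    from scipy import ndimage as ndi

    shape = rng.integers(12, max_shape + 1, size=3)
    n_seeds = rng.integers(1, 4)
    field = np.zeros(tuple(shape))
    for _ in range(n_seeds):
        c = rng.uniform(0.2, 0.8, 3) * shape
        s = rng.uniform(1.5, 5.0, 3)
        grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
        field += np.exp(-0.5 * sum(((g - ci) / si) ** 2
                                   for g, ci, si in zip(grids, c, s)))
    mask = field > np.quantile(field, 0.8)
    lab, n = ndi.label(mask)
    sizes = ndi.sum_labels(mask, lab, index=np.arange(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    return NucleusMask(mask, spacing)


@pytest.fixture(scope="session")
def sim_stack_pair():
    """One simulated stack with ground truth (shared, read-only)."""
    cfg = SimulationConfig(seed=42, true_distances=(1.0, 2.0))
    return simulate_stack(cfg)


@pytest.fixture(scope="session")
def allele_table():
    """A moderate-size simulated allele table (shared, read-only)."""
    from nucleofish import simulate_allele_table

    cfg = SimulationConfig(seed=7, n_cells=150)
    return simulate_allele_table(cfg)
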