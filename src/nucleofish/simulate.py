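"""Synthetic data with ground truth: image stacks and allele tables.

Two generators:

* :func:`simulate_stack` renders one ROI-sized two/three-channel stack —
  a DAPI-like counterstain of an ellipsoidal nucleus with a perturbed
  boundary under Poisson-Gaussian noise, plus DNA-FISH spots placed at
  requested true border distances and an RNA-FISH channel marking the
  alleles simulated as expressed.  Every spot carries a ground-truth
  record so segmentation and geometry can be validated end to end.

* :func:`simulate_allele_table` draws allele-level measurement tables
  with the statistical structure the downstream models assume: per-group
  distance means/SDs, log-normal nuclear volumes, a shared per-cell
  random intercept, and expression states from a logistic model on
  distance.  Parameter-recovery tests for the stats layer run on its
  output.

Both are deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi
from scipy.special import expit, lpmv

from .schema import EXPECTED_ALLELES, GENOTYPES, coerce_allele_table
from .stack import ImageStack, NucleusMask
from .geometry import SPHERE_SHELL_DEPTH_FRACTIONS, voxel_diagonal


class ConfigurationError(ValueError):
    """Invalid or unsatisfiable simulation configuration."""


# Default group means/SDs (um): maternal alleles sit further from the
# border (1.81 +/- 1.00 um) than paternal alleles (1.58 +/- 0.954 um);
# epigenotype-switch lines inherit the localisation of their expressed
# pattern, WT lines mix both.
_DEFAULT_MEANS = {
    "WT": 1.70, "WT2": 1.70,
    "matrepKO": 1.58, "patrepKO": 1.81,
    "Zfp57KO": 1.81, "matIGDMRKO": 1.58,
}
_DEFAULT_SDS = {
    "WT": 1.00, "WT2": 1.00,
    "matrepKO": 0.954, "patrepKO": 1.00,
    "Zfp57KO": 1.00, "matIGDMRKO": 0.954,
}


@dataclass
class SimulationConfig:
    """All generator parameters; ``seed`` is mandatory.

    Spacings, shapes and coordinates follow the package-wide ``(z, y, x)``
    axis order, micrometre units throughout.
    """

    seed: int
    # -- stack geometry ---------------------------------------------------
    voxel_spacing: tuple[float, float, float] = (0.15, 0.1, 0.1)
    stack_shape: tuple[int, int, int] = (64, 96, 96)
    nucleus_semiaxes: tuple[float, float, float] = (2.6, 3.2, 3.6)
    boundary_roughness: float = 0.04
    spot_sigma: float = 0.12
    true_distances: tuple[float, ...] = (1.0, 2.0)
    snr: float = 10.0
    # -- allele-table statistics ------------------------------------------
    n_cells: int = 200
    group_means: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    group_sds: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SDS))
    volume_logmean: float = 6.1    # exp(6.1) ~ 446 um^3, typical ES-cell nucleus
    volume_logsd: float = 0.2
    expr_logit_intercept: float = -0.034
    expr_logit_slope: float = 0.5   # per um; at 1.81 um -> P(expressed) = 0.705
    cell_intercept_sd: float = 0.3
    distance_floor: float = -0.3    # small negative tail of peripheral spots

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        self.seed = int(self.seed)
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        self.stack_shape = tuple(int(s) for s in self.stack_shape)
        self.nucleus_semiaxes = tuple(float(s) for s in self.nucleus_semiaxes)
        self.true_distances = tuple(float(d) for d in self.true_distances)
        if any(s <= 0 for s in self.voxel_spacing):
            raise ConfigurationError("voxel spacings must be positive")
        if any(n < 4 for n in self.stack_shape):
            raise ConfigurationError("stack shape too small")
        if any(a <= self.spot_sigma for a in self.nucleus_semiaxes):
            raise ConfigurationError("nucleus semi-axes must exceed spot sigma")
        if any(d >= min(self.nucleus_semiaxes) for d in self.true_distances):
            raise ConfigurationError(
                "true distances must be below the smallest nucleus semi-axis"
            )
        if self.snr <= 0:
            raise ConfigurationError("snr must be positive")
        if any(sd < 0 for sd in self.group_sds.values()):
            raise ConfigurationError("group SDs must be non-negative")
        if self.cell_intercept_sd < 0 or self.volume_logsd < 0:
            raise ConfigurationError("SD parameters must be non-negative")
        unknown = set(self.group_means) - set(GENOTYPES)
        if unknown:
            raise ConfigurationError(f"unknown genotype groups: {sorted(unknown)}")

    # -- plain-text round trip --------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k in ("voxel_spacing", "stack_shape", "nucleus_semiaxes", "true_distances"):
            d[k] = list(d[k])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "seed" not in d:
            raise ConfigurationError(f"{path}: seed is mandatory")
        return cls(**d)


@dataclass
class GroundTruth:
    """True geometry behind one simulated stack."""

    mask: np.ndarray                 # bool (z, y, x)
    spacing: tuple[float, float, float]
    volume_um3: float
    spots: pd.DataFrame              # spot_id, z/y/x_um, true_distance_um, expressed

    def nucleus_mask(self, nucleus_id: str = "truth") -> NucleusMask:
        return NucleusMask(self.mask, self.spacing, nucleus_id=nucleus_id)


# ---------------------------------------------------------------------------
# Stack generator
# ---------------------------------------------------------------------------

def _boundary_perturbation(theta, phi, rng, roughness):
    """Low-order real-spherical-harmonic radial perturbation field.

    Sums degree-2 and degree-3 terms with random coefficients; the result
    is normalised to peak amplitude ``roughness``.
    """
    if roughness == 0:
        return np.zeros_like(theta)
    cos_t = np.cos(theta)
    f = np.zeros_like(theta)
    for ell in (2, 3):
        for m in range(ell + 1):
            c = rng.normal()
            s = rng.normal() if m > 0 else 0.0
            p = lpmv(m, ell, cos_t)
            f += p * (c * np.cos(m * phi) + s * np.sin(m * phi))
    peak = np.abs(f).max()
    if peak > 0:
        f *= roughness / peak
    return f


def _render_nucleus_mask(config: SimulationConfig, rng) -> np.ndarray:
    dz, dy, dx = config.voxel_spacing
    nz, ny, nx = config.stack_shape
    az, ay, ax = config.nucleus_semiaxes
    centre = np.array([(nz - 1) * dz, (ny - 1) * dy, (nx - 1) * dx]) / 2.0
    z = np.arange(nz) * dz - centre[0]
    y = np.arange(ny) * dy - centre[1]
    x = np.arange(nx) * dx - centre[2]
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    u = np.sqrt((zz / az) ** 2 + (yy / ay) ** 2 + (xx / ax) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.sqrt(zz**2 + yy**2 + xx**2)
        theta = np.arccos(np.clip(np.divide(zz, r, out=np.zeros_like(r), where=r > 0), -1, 1))
        phi = np.arctan2(yy, xx)
    f = _boundary_perturbation(theta, phi, rng, config.boundary_roughness)
    mask = u <= 1.0 + f
    # keep a single connected component
    lab, n = ndi.label(mask)
    if n > 1:
        sizes = ndi.sum_labels(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return mask


def _signed_distance_field(mask: np.ndarray, spacing) -> np.ndarray:
    """Signed EDT (um) at every voxel centre: inside voxels measure to the
    nearest background voxel, outside voxels to the nearest mask voxel."""
    inside = ndi.distance_transform_edt(mask, sampling=spacing)
    outside = ndi.distance_transform_edt(~mask, sampling=spacing)
    return np.where(mask, inside, -outside)


def _add_gaussian_spot(img: np.ndarray, centre_um, sigma_um: float, amplitude: float,
                       spacing) -> None:
    """Add a 3D Gaussian blob (per-axis voxel sigma) in place."""
    spacing = np.asarray(spacing)
    centre_vox = np.asarray(centre_um) / spacing
    sigma_vox = sigma_um / spacing
    lo = np.maximum(np.floor(centre_vox - 4 * sigma_vox).astype(int), 0)
    hi = np.minimum(np.ceil(centre_vox + 4 * sigma_vox).astype(int) + 1, img.shape)
    if np.any(lo >= hi):
        return
    grids = [np.arange(l, h) for l, h in zip(lo, hi)]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij")
    q = ((zz - centre_vox[0]) ** 2 / sigma_vox[0] ** 2
         + (yy - centre_vox[1]) ** 2 / sigma_vox[1] ** 2
         + (xx - centre_vox[2]) ** 2 / sigma_vox[2] ** 2)
    img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * np.exp(-0.5 * q)


_BG_LAMBDA = 30.0     # background photon rate, FISH channels
_READ_SIGMA = 3.0     # additive read noise SD
_DAPI_BG = 20.0


def simulate_stack(config: SimulationConfig,
                   stack_id: str = "sim") -> tuple[ImageStack, GroundTruth]:
    """Render one nucleus with FISH spots at the configured true distances.

    Returns the noisy stack (channels ``dapi``, ``dna_fish``, ``rna_fish``)
    and the ground truth (true mask, volume, spot table).  Spots are placed
    at voxel centres whose signed border distance is closest to each
    requested value; the recorded true distance is the exact signed
    distance of the chosen position, so it deviates from the request by at
    most half a voxel diagonal.  Negative requests place the spot outside
    the mask near the border.
    """
    rng = np.random.default_rng(config.seed)
    spacing = config.voxel_spacing
    mask = _render_nucleus_mask(config, rng)
    sdf = _signed_distance_field(mask, spacing)

    half_diag = 0.5 * voxel_diagonal(spacing)
    spots = []
    taken: list[np.ndarray] = []
    for i, target in enumerate(config.true_distances):
        tol = half_diag
        cand = np.argwhere(np.abs(sdf - target) <= tol)
        while cand.size == 0 and tol < min(config.nucleus_semiaxes):
            tol *= 2.0
            cand = np.argwhere(np.abs(sdf - target) <= tol)
        if cand.size == 0:
            raise ConfigurationError(
                f"true distance {target} um not placeable inside this nucleus"
            )
        # keep spots apart so detection sees distinct components
        if taken:
            sep = np.min(
                np.linalg.norm((cand[:, None, :] - np.array(taken)[None, :, :])
                               * np.asarray(spacing), axis=-1), axis=1)
            far_enough = cand[sep > 6 * config.spot_sigma]
            if far_enough.size:
                cand = far_enough
        pick = cand[rng.integers(len(cand))]
        taken.append(pick)
        pos_um = pick * np.asarray(spacing)
        true_d = float(sdf[tuple(pick)])
        spots.append({"spot_id": i, "z_um": pos_um[0], "y_um": pos_um[1],
                      "x_um": pos_um[2], "true_distance_um": true_d})

    spot_df = pd.DataFrame(spots, columns=["spot_id", "z_um", "y_um", "x_um",
                                           "true_distance_um"])
    if len(spot_df):
        p_expr = expit(config.expr_logit_intercept
                       + config.expr_logit_slope
                       * spot_df["true_distance_um"].to_numpy())
        spot_df["expressed"] = rng.random(len(spot_df)) < p_expr
    else:
        spot_df["expressed"] = pd.Series(dtype=bool)

    # --- render channels --------------------------------------------------
    bg_sd = np.sqrt(_BG_LAMBDA + _READ_SIGMA**2)
    amp = config.snr * bg_sd

    dapi = np.full(mask.shape, _DAPI_BG, dtype=float)
    dapi[mask] += 20.0 * config.snr
    dapi = ndi.gaussian_filter(dapi, sigma=1.0)

    dna = np.full(mask.shape, _BG_LAMBDA, dtype=float)
    rna = np.full(mask.shape, _BG_LAMBDA, dtype=float)
    for _, row in spot_df.iterrows():
        pos = np.array([row.z_um, row.y_um, row.x_um])
        _add_gaussian_spot(dna, pos, config.spot_sigma, amp, spacing)
        if row.expressed:
            _add_gaussian_spot(rna, pos, config.spot_sigma, amp, spacing)

    channels = {}
    for name, ideal in (("dapi", dapi), ("dna_fish", dna), ("rna_fish", rna)):
        noisy = rng.poisson(ideal).astype(float)
        noisy += rng.normal(0.0, _READ_SIGMA, size=ideal.shape)
        channels[name] = noisy

    stack = ImageStack(channels, spacing, stack_id=stack_id)
    voxel_vol = float(np.prod(spacing))
    truth = GroundTruth(mask=mask, spacing=spacing,
                        volume_um3=float(mask.sum()) * voxel_vol, spots=spot_df)
    return stack, truth


# ---------------------------------------------------------------------------
# Allele-table generator
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lower, upper, max_iter: int = 200):
    """Vectorised rejection sampling of N(mean, sd) on [lower, upper]."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), np.shape(mean))
    x = mean + sd * rng.standard_normal(mean.shape) if np.any(sd) else mean.copy()
    x = np.array(x, dtype=float)
    for _ in range(max_iter):
        bad = (x < lower) | (x > upper)
        if not bad.any():
            break
        x[bad] = mean[bad] + sd * rng.standard_normal(int(bad.sum()))
    return np.clip(x, lower, upper)


def simulate_allele_table(config: SimulationConfig,
                          groups: list[str] | None = None) -> pd.DataFrame:
    """Draw an allele table with the configured statistical structure.

    Per cell: a log-normal nuclear volume, an equivalent-sphere local
    radius, a shared N(0, ``cell_intercept_sd``) intercept, and one or two
    allele distances N(group mean + intercept, group SD) truncated to
    ``[distance_floor, local radius]``.  Expression states are Bernoulli
    with logit ``intercept + slope * distance``.  Three replicate lines
    per genotype, cells assigned round-robin.
    """
    if config.n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    groups = list(groups) if groups is not None else list(config.group_means)
    if not groups:
        raise ConfigurationError("need at least one genotype group")
    for g in groups:
        if g not in config.group_means or g not in config.group_sds:
            raise ConfigurationError(f"group {g!r} missing a mean or SD")

    rng = np.random.default_rng(config.seed)
    t1_frac, t2_frac = SPHERE_SHELL_DEPTH_FRACTIONS
    rows = []
    for g in groups:
        n = config.n_cells
        k = EXPECTED_ALLELES[g]
        mean, sd = config.group_means[g], config.group_sds[g]
        vol = np.exp(rng.normal(config.volume_logmean, config.volume_logsd, n))
        r_local = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
        cell_int = (rng.normal(0.0, config.cell_intercept_sd, n)
                    if config.cell_intercept_sd > 0 else np.zeros(n))
        centre = np.repeat((mean + cell_int)[:, None], k, axis=1)
        d = _truncated_normal(rng, centre, sd, config.distance_floor,
                              np.repeat(r_local[:, None], k, axis=1))
        p = expit(config.expr_logit_intercept + config.expr_logit_slope * d)
        expressed = rng.random(d.shape) < p
        for i in range(n):
            cell = f"{g}_c{i:05d}"
            line = f"{g}_r{(i % 3) + 1}"
            order = np.argsort(d[i])
            for j in range(k):
                depth = d[i, j]
                shell = ("outer" if depth <= t1_frac * r_local[i]
                         else "middle" if depth <= t2_frac * r_local[i]
                         else "inner")
                near_far = ("single" if k == 1
                            else "near" if order[0] == j else "far")
                rows.append((cell, line, g, f"a{j + 1}", depth, r_local[i],
                             depth / r_local[i], shell, near_far,
                             bool(expressed[i, j]), False, vol[i]))
    df = pd.DataFrame(rows, columns=["cell_id", "line_id", "genotype",
                                     "allele_id", "distance_um",
                                     "local_radius_um", "relative_distance",
                                     "shell", "near_far", "expressed",
                                     "fallback", "volume_um3"])
    return coerce_allele_table(df)


def simulate_dataset(config: SimulationConfig, n_nuclei: int,
                     genotype: str = "WT",
                     negative_fraction: float = 0.0):
    """Generate a list of (stack, truth) pairs for pipeline-level tests.

    Per nucleus, true distances are drawn from the genotype's distance
    distribution; with probability ``negative_fraction`` a spot is instead
    placed just outside the mask (the peripheral negative-distance case).
    Each nucleus gets its own child seed derived from the config seed.
    """
    rng = np.random.default_rng(config.seed)
    k = EXPECTED_ALLELES[genotype]
    mean = config.group_means[genotype]
    sd = config.group_sds[genotype]
    upper = 0.8 * min(config.nucleus_semiaxes)
    out = []
    for i in range(n_nuclei):
        d = _truncated_normal(rng, np.full(k, mean), sd, 0.15, np.full(k, upper))
        neg = rng.random(k) < negative_fraction
        d[neg] = -rng.uniform(0.05, 0.25, int(neg.sum()))
        sub_seed = int(rng.integers(2**31 - 1))
        sub = SimulationConfig(**{**asdict(config),
                                  "seed": sub_seed,
                                  "true_distances": tuple(d)})
        out.append(simulate_stack(sub, stack_id=f"{genotype}_{i:04d}"))
    return out
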