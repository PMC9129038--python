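"""Nucleus binarisation, FISH spot detection, doublet merging and
expression calls.

The nucleus mask is the chromatin volume seen by the DNA counterstain:
Gaussian-smoothed, Otsu-thresholded within the ROI, hole-filled, largest
connected component.  Because the threshold is relative, low-density
chromatin at the very periphery can be classified as background — exactly
the failure mode that makes peripheral spots fall outside the mask and be
measured as negative distances downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .stack import FishSpot, ImageStack, NucleusMask, SpotGroup


class NoNucleusError(ValueError):
    """Thresholding found no foreground in the ROI."""


class AmbiguousROIError(ValueError):
    """Two similarly sized components: the ROI covers more than one nucleus."""


@dataclass(frozen=True)
class ROI:
    """Axis-aligned bounding box, 0-based half-open voxel coordinates."""

    stack_id: str
    nucleus_id: str
    z0: int
    z1: int
    y0: int
    y1: int
    x0: int
    x1: int

    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(self.z0, self.z1), slice(self.y0, self.y1),
                slice(self.x0, self.x1))

    @classmethod
    def whole(cls, stack: ImageStack, nucleus_id: str = "n0") -> "ROI":
        nz, ny, nx = stack.shape
        return cls(stack.stack_id, nucleus_id, 0, nz, 0, ny, 0, nx)


def binarize_nucleus(stack: ImageStack, roi: ROI | None = None,
                     counterstain: str = "dapi",
                     smooth_sigma: float = 1.0,
                     ambiguity_ratio: float = 0.5) -> NucleusMask:
    """Binarise the DNA counterstain within a single-nucleus ROI.

    Gaussian smoothing (``smooth_sigma`` voxels), Otsu threshold computed
    inside the ROI, 3D hole filling, largest connected component.

    Raises
    ------
    NoNucleusError
        Flat intensity or no foreground voxels.
    AmbiguousROIError
        A second component at least ``ambiguity_ratio`` the size of the
        largest — the ROI should be tightened.
    """
    if roi is None:
        roi = ROI.whole(stack)
    img = stack.channel(counterstain)[roi.slices()].astype(float)
    if img.size == 0:
        raise ValueError(f"ROI {roi.nucleus_id} is empty")
    smooth = ndi.gaussian_filter(img, sigma=smooth_sigma)
    if np.ptp(smooth) < 1e-12:
        raise NoNucleusError(f"{roi.nucleus_id}: constant intensity in ROI")
    thr = threshold_otsu(smooth)
    fg = smooth > thr
    if not fg.any():
        raise NoNucleusError(f"{roi.nucleus_id}: no foreground after threshold")
    fg = ndi.binary_fill_holes(fg)
    lab, n = ndi.label(fg)
    sizes = ndi.sum_labels(fg, lab, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    if n > 1 and sizes[order[1]] >= ambiguity_ratio * sizes[order[0]]:
        raise AmbiguousROIError(
            f"{roi.nucleus_id}: two components of comparable size "
            f"({int(sizes[order[1]])} vs {int(sizes[order[0]])} voxels); "
            "tighten the ROI"
        )
    mask = lab == (1 + int(order[0]))
    return NucleusMask(mask, stack.spacing, nucleus_id=roi.nucleus_id,
                       origin=(roi.z0, roi.y0, roi.x0))


@dataclass
class SpotParams:
    """Spot-detection parameters.

    ``k_sigma``: threshold is background median + k * robust SD (1.4826 x
    MAD), computed over the whole channel (spots occupy a negligible
    voxel fraction).  ``min_voxels``: smallest accepted component.
    """

    k_sigma: float = 5.0
    min_voxels: int = 4

    def __post_init__(self) -> None:
        if self.k_sigma <= 0 or self.min_voxels < 1:
            raise ValueError("k_sigma must be > 0 and min_voxels >= 1")


def detect_spots(stack: ImageStack, channel: str,
                 params: SpotParams | None = None,
                 roi: ROI | None = None) -> list[FishSpot]:
    """Detect FISH signals as thresholded 3D connected components.

    Each component of at least ``min_voxels`` voxels yields one
    :class:`FishSpot` with a background-subtracted intensity-weighted
    centroid in micrometres (parent-stack frame).  An empty list is a
    valid result.
    """
    params = params or SpotParams()
    img = stack.channel(channel).astype(float)
    offset = np.zeros(3)
    if roi is not None:
        img = img[roi.slices()]
        offset = np.array([roi.z0, roi.y0, roi.x0], dtype=float)
    med = float(np.median(img))
    mad = float(np.median(np.abs(img - med)))
    thr = med + params.k_sigma * 1.4826 * mad
    fg = img > thr
    lab, n = ndi.label(fg)
    spots: list[FishSpot] = []
    spacing = np.asarray(stack.spacing)
    for lab_id, comp in enumerate(ndi.find_objects(lab), start=1):
        if comp is None:
            continue
        sel = lab[comp] == lab_id
        if sel.sum() < params.min_voxels:
            continue
        idx = np.argwhere(sel).astype(float)
        idx += np.array([s.start for s in comp], dtype=float)
        w = np.clip(img[comp][sel] - med, 0, None)
        if w.sum() <= 0:
            continue
        centroid_vox = (idx * w[:, None]).sum(axis=0) / w.sum()
        spots.append(FishSpot(
            channel=channel,
            centroid_um=(centroid_vox + offset) * spacing,
            peak_intensity=float(img[comp][sel].max()),
            integrated_intensity=float(w.sum()),
            n_voxels=int(sel.sum()),
        ))
    spots.sort(key=lambda s: -s.integrated_intensity)
    return spots


def merge_replication_doublets(spots: list[FishSpot], expected_alleles: int,
                               pairing_radius: float = 1.5) -> list[SpotGroup]:
    """Group duplicated FISH signals from replicated loci into alleles.

    When more signals are found than probe targets exist, signals within
    ``pairing_radius`` (um) of each other are paired as one replicated
    allele; the pairing minimising the total within-pair distance is
    chosen by exhaustive enumeration.  Downstream measurements of a
    doublet use the mean of its members.  Groups still in excess of
    ``expected_alleles`` after merging are flagged ``excess`` (keeping the
    brightest groups) and are excluded from the allele table by the
    pipeline, with a logged reason.
    """
    if expected_alleles not in (1, 2):
        raise ValueError("expected_alleles must be 1 or 2")
    if pairing_radius <= 0:
        raise ValueError("pairing_radius must be positive")
    if len(spots) <= expected_alleles:
        return [SpotGroup([s]) for s in spots]

    n_merges = len(spots) - expected_alleles
    near = [
        (i, j, float(np.linalg.norm(spots[i].centroid_um - spots[j].centroid_um)))
        for i, j in itertools.combinations(range(len(spots)), 2)
        if np.linalg.norm(spots[i].centroid_um - spots[j].centroid_um) <= pairing_radius
    ]
    # as many merges as needed and possible; among those, minimum total
    # within-pair distance (exhaustive, spot counts are tiny)
    pairs: list[tuple[int, int]] = []
    for m in range(min(n_merges, len(near)), 0, -1):
        best_cost = None
        for combo in itertools.combinations(near, m):
            used = [i for p in combo for i in p[:2]]
            if len(set(used)) != 2 * m:
                continue
            cost = sum(p[2] for p in combo)
            if best_cost is None or cost < best_cost:
                best_cost = cost
                pairs = [(p[0], p[1]) for p in combo]
        if pairs:
            break
    paired = {i for p in pairs for i in p}
    groups = [SpotGroup([spots[i], spots[j]], doublet=True) for i, j in pairs]
    groups.extend(SpotGroup([s]) for k, s in enumerate(spots) if k not in paired)
    groups.sort(key=lambda g: -g.integrated_intensity)
    for g in groups[expected_alleles:]:
        g.excess = True
    return groups


def classify_expression(stack: ImageStack, rna_channel: str, position_um,
                        nucleus: NucleusMask, radius_um: float = 0.5,
                        k_sigma: float = 3.0,
                        smooth_sigma: float = 1.0) -> bool:
    """Call an allele expressed or non-expressed from nascent-RNA signal.

    The RNA channel is matched-filtered (Gaussian, ``smooth_sigma``
    voxels) so that the maximum of pure shot noise over the neighbourhood
    stays below the threshold while a diffraction-limited transcription
    focus survives.  Expressed iff the maximum filtered intensity within
    ``radius_um`` of the allele position exceeds the filtered nuclear
    background mean + ``k_sigma`` x SD (background statistics over the
    nucleus mask, excluding the neighbourhood itself).
    """
    img = stack.channel(rna_channel).astype(float)
    if smooth_sigma > 0:
        img = ndi.gaussian_filter(img, sigma=smooth_sigma)
    spacing = np.asarray(stack.spacing)
    pos = np.asarray(position_um, dtype=float)
    pos_vox = pos / spacing
    if np.any(pos_vox < -0.5) or np.any(pos_vox > np.asarray(img.shape) - 0.5):
        raise ValueError(f"allele position {pos} outside stack bounds")

    grids = np.meshgrid(*[np.arange(n) for n in img.shape], indexing="ij")
    sq = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, pos_vox, spacing))
    neigh = sq <= radius_um**2
    if not neigh.any():
        neigh[tuple(np.round(pos_vox).astype(int))] = True

    bg_sel = np.zeros_like(neigh)
    bg_sel[tuple(slice(o, o + n) for o, n in zip(nucleus.origin, nucleus.mask.shape))] \
        |= nucleus.mask
    bg_sel &= ~neigh
    bg = img[bg_sel] if bg_sel.any() else img[~neigh]
    thr = float(bg.mean() + k_sigma * bg.std())
    return bool(img[neigh].max() > thr)
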