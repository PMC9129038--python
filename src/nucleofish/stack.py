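"""Core containers: image stacks, nucleus masks and FISH spots.

Axis convention
---------------
All 3D arrays are indexed ``(z, y, x)`` and all physical coordinates and
voxel spacings follow the same axis order, in micrometres.  Coordinates are
voxel-centre based: the centre of voxel ``(i, j, k)`` sits at physical
position ``(i*dz, j*dy, k*dx)`` relative to the array origin.  Bounding
boxes are 0-based and half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from scipy.spatial import cKDTree


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"voxel spacing must be 3 positive values, got {spacing}")
    return spacing


@dataclass
class ImageStack:
    """A multi-channel 3D intensity grid with physical voxel spacing.

    Parameters
    ----------
    channels
        Mapping of channel label to a 3D ``(z, y, x)`` intensity array.
        All channels must share one shape.
    spacing
        Voxel spacing ``(dz, dy, dx)`` in micrometres.
    stack_id
        Identifier used in output tables and file names.
    """

    channels: dict[str, np.ndarray]
    spacing: tuple[float, float, float]
    stack_id: str = "stack"

    def __post_init__(self) -> None:
        self.spacing = _check_spacing(self.spacing)
        if not self.channels:
            raise ValueError("stack needs at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        self.channels = {k: np.asarray(v) for k, v in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, label: str) -> np.ndarray:
        if label not in self.channels:
            raise KeyError(
                f"channel {label!r} not in stack (have {sorted(self.channels)})"
            )
        return self.channels[label]

    # -- TIFF round trip ---------------------------------------------------
    def write_tiff(self, path: str | Path) -> None:
        """Write as a multi-page TIFF, channels stacked on the first axis.

        Spacing and channel labels are stored in the ImageJ-style metadata
        so that :meth:`read_tiff` round-trips losslessly.
        """
        arr = np.stack([self.channels[c] for c in sorted(self.channels)])
        tifffile.imwrite(
            path,
            arr.astype(np.float32),
            metadata={
                "axes": "CZYX",
                "spacing_um": list(self.spacing),
                "channel_labels": sorted(self.channels),
                "stack_id": self.stack_id,
            },
        )

    @classmethod
    def read_tiff(cls, path: str | Path) -> "ImageStack":
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        labels = meta.get("channel_labels")
        spacing = meta.get("spacing_um")
        if arr.ndim == 3:
            arr = arr[None]
        if labels is None:
            labels = [f"ch{i}" for i in range(arr.shape[0])]
        if spacing is None:
            raise ValueError(f"{path}: no voxel spacing recorded in metadata")
        channels = {lab: arr[i] for i, lab in enumerate(labels)}
        return cls(channels, tuple(spacing), stack_id=str(meta.get("stack_id", Path(path).stem)))


class NucleusMask:
    """Binary 3D representation of one nucleus.

    The mask may live in a cropped region of a larger stack; ``origin`` is
    the voxel offset of the crop so that all physical outputs (centroid,
    spot coordinates) refer to the parent stack's frame.

    ``provenance`` is ``"raw"`` for a thresholded mask and
    ``"ellipsoid-fallback"`` when the moment-matched ellipsoid replaced it.
    """

    def __init__(
        self,
        mask: np.ndarray,
        spacing,
        nucleus_id: str = "nucleus",
        origin: tuple[int, int, int] = (0, 0, 0),
        provenance: str = "raw",
    ) -> None:
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if not mask.any():
            raise ValueError("mask is empty: no nucleus voxels")
        self.mask = mask
        self.spacing = _check_spacing(spacing)
        self.nucleus_id = str(nucleus_id)
        self.origin = tuple(int(o) for o in origin)
        if provenance not in ("raw", "ellipsoid-fallback"):
            raise ValueError(f"unknown provenance {provenance!r}")
        self.provenance = provenance

    # -- geometry scalars --------------------------------------------------
    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @cached_property
    def volume_um3(self) -> float:
        """Nuclear volume: voxel count times voxel volume."""
        return float(self.mask.sum()) * self.voxel_volume

    @cached_property
    def centroid_um(self) -> np.ndarray:
        """Mask centroid in the parent stack's physical frame (z, y, x)."""
        idx = np.argwhere(self.mask)
        local = idx.mean(axis=0) * np.asarray(self.spacing)
        return local + self.origin_um

    @property
    def origin_um(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float) * np.asarray(self.spacing)

    @cached_property
    def solidity(self) -> float:
        """Voxel count over convex-hull voxel count (1 for convex shapes)."""
        from skimage import morphology

        hull = morphology.convex_hull_image(self.mask)
        return float(self.mask.sum()) / float(hull.sum())

    @cached_property
    def equivalent_radius_um(self) -> float:
        """Radius of the equal-volume sphere, (3V / 4 pi)^(1/3)."""
        return float((3.0 * self.volume_um3 / (4.0 * np.pi)) ** (1.0 / 3.0))

    # -- border machinery --------------------------------------------------
    @cached_property
    def border_voxels(self) -> np.ndarray:
        """Indices of mask voxels with a 6-connected background neighbour.

        Voxels touching the array edge count as border (background is
        assumed beyond the crop).
        """
        struct = ndi.generate_binary_structure(3, 1)
        interior = ndi.binary_erosion(self.mask, structure=struct, border_value=0)
        return np.argwhere(self.mask & ~interior)

    @cached_property
    def outer_border_voxels(self) -> np.ndarray:
        """Background voxels (6-connected) touching the mask, including the
        virtual background layer just beyond the array edge."""
        struct = ndi.generate_binary_structure(3, 1)
        padded = np.pad(self.mask, 1)
        outer = ndi.binary_dilation(padded, structure=struct) & ~padded
        return np.argwhere(outer) - 1

    @cached_property
    def _inner_border_tree(self) -> cKDTree:
        return cKDTree(self.border_voxels * np.asarray(self.spacing))

    @cached_property
    def _outer_border_tree(self) -> cKDTree:
        return cKDTree(self.outer_border_voxels * np.asarray(self.spacing))

    @cached_property
    def depth_map(self) -> np.ndarray:
        """Interior depth: anisotropic Euclidean distance to background
        (the array edge counts as background)."""
        padded = np.pad(self.mask, 1)
        d = ndi.distance_transform_edt(padded, sampling=self.spacing)
        return d[1:-1, 1:-1, 1:-1]

    # -- point queries -----------------------------------------------------
    def to_local_um(self, point_um) -> np.ndarray:
        return np.asarray(point_um, dtype=float) - self.origin_um

    def voxel_of(self, point_um) -> tuple[int, int, int]:
        """Index of the voxel containing a physical point (local frame)."""
        local = self.to_local_um(point_um)
        return tuple(int(round(c / s)) for c, s in zip(local, self.spacing))

    def in_bounds(self, point_um, margin_voxels: float = 0.5) -> bool:
        local = self.to_local_um(point_um)
        for c, s, n in zip(local, self.spacing, self.mask.shape):
            if c < -margin_voxels * s or c > (n - 1 + margin_voxels) * s:
                return False
        return True

    def contains(self, point_um) -> bool:
        """True if the voxel containing the point belongs to the mask."""
        idx = self.voxel_of(point_um)
        if any(i < 0 or i >= n for i, n in zip(idx, self.mask.shape)):
            return False
        return bool(self.mask[idx])


@dataclass
class FishSpot:
    """One detected FISH signal.

    ``centroid_um`` is the intensity-weighted centre of the thresholded
    component, in the parent stack's physical frame.
    """

    channel: str
    centroid_um: np.ndarray
    peak_intensity: float
    integrated_intensity: float
    n_voxels: int
    doublet: bool = False

    def __post_init__(self) -> None:
        self.centroid_um = np.asarray(self.centroid_um, dtype=float)
        if self.centroid_um.shape != (3,):
            raise ValueError("centroid must be a (z, y, x) triple")


@dataclass
class SpotGroup:
    """An allele-level group of spots after replication-doublet merging."""

    spots: list[FishSpot]
    doublet: bool = False
    excess: bool = False

    @property
    def centroid_um(self) -> np.ndarray:
        return np.mean([s.centroid_um for s in self.spots], axis=0)

    @property
    def integrated_intensity(self) -> float:
        return float(sum(s.integrated_intensity for s in self.spots))
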