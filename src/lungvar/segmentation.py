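"""Automatic lung air-volume segmentation from a 3D voxel grid.

Pipeline (per the threshold → label → 3D-cluster approach):

1. For every image plane along the declared slice axis, an adaptive
   threshold is chosen from the plane's intensity histogram by two-class
   between-variance maximisation (Otsu); voxels *below* the threshold are
   marked foreground, since air is dark on T2-weighted MRI.
2. Per-plane connected components are labelled; components touching the
   plane border (background air) or below a minimum-area floor (noise
   specks) are removed.
3. The filtered planes are stacked and clustered in 3D under 26-connectivity;
   the largest air clusters (up to two — the lungs, or one if they merge at
   the hila) are retained.
4. Volume = retained voxel count × voxel volume, converted mm³ → litres.

All retained air clusters count toward "lung volume" (no airway exclusion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import clear_border

__all__ = [
    "DegeneratePlaneError",
    "SegmentationError",
    "VoxelGrid",
    "LungMask",
    "adaptive_threshold_plane",
    "label_and_filter",
    "cluster_3d",
    "compute_volume",
    "fractional_volume_series",
    "segment_lungs",
]

_ANATOMICAL_AXES = {"RL", "AP", "CC"}


class DegeneratePlaneError(ValueError):
    """Plane has (near-)constant intensity; no threshold can be chosen."""


class SegmentationError(RuntimeError):
    """No air cluster was found."""


@dataclass
class VoxelGrid:
    """3D intensity array with spacing, origin and anatomical axis order.

    ``axes[i]`` names the anatomical direction of array axis ``i`` (a
    permutation of RL/AP/CC); ``spacing`` is in mm per axis in array order.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: tuple[str, str, str] = ("RL", "CC", "AP")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or min(self.spacing) <= 0:
            raise ValueError("spacing must be three strictly positive values")
        if set(self.axes) != _ANATOMICAL_AXES:
            raise ValueError("axes must be a permutation of RL/AP/CC")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def to_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine)
        img.header.set_zooms(self.spacing)
        img.header["descrip"] = ("axes=" + ",".join(self.axes)).encode()
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path, axes: Sequence[str] | None = None) -> "VoxelGrid":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        if axes is None:
            descrip = img.header["descrip"].tobytes().decode(errors="ignore")
            if "axes=" in descrip:
                axes = tuple(descrip.split("axes=")[1].strip("\x00 ").split(","))
            else:
                axes = ("RL", "CC", "AP")
        return cls(data, spacing, origin, tuple(axes))


@dataclass
class LungMask:
    """Binary lung mask congruent with its source grid."""

    mask: np.ndarray  # bool, same shape as source
    labels: np.ndarray  # int 3D component labels (0 = background)
    kept_labels: tuple[int, ...]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.mask.shape != self.labels.shape:
            raise ValueError("mask and labels must be congruent")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def adaptive_threshold_plane(plane: np.ndarray) -> tuple[float, np.ndarray]:
    """Otsu threshold of one plane; foreground = voxels below it (air).

    Raises :class:`DegeneratePlaneError` on a constant-intensity plane; the
    caller marks such planes empty.
    """
    plane = np.asarray(plane)
    if plane.size == 0:
        raise ValueError("plane must be non-empty")
    if np.ptp(plane) == 0:
        raise DegeneratePlaneError("constant-intensity plane")
    threshold = float(threshold_otsu(plane))
    return threshold, plane < threshold


def label_and_filter(
    binary: np.ndarray,
    min_area: int = 50,
    slice_axis: int = 2,
) -> tuple[np.ndarray, list[dict]]:
    """Per-plane connected components with border and area filtering.

    Components touching the plane border (background air around the body)
    and components smaller than ``min_area`` pixels are removed.  Returns
    the filtered binary stack and a list of per-component region properties
    (plane, label, area, centroid, bbox) for the retained components.
    """
    binary = np.asarray(binary, dtype=bool)
    filtered = np.zeros_like(binary)
    props: list[dict] = []
    for k in range(binary.shape[slice_axis]):
        index = [slice(None)] * 3
        index[slice_axis] = k
        plane = binary[tuple(index)]
        labels = sk_label(plane, connectivity=2)
        labels = clear_border(labels)
        keep = np.zeros_like(plane)
        for region in regionprops(labels):
            if region.area < min_area:
                continue
            keep[labels == region.label] = True
            props.append(
                {
                    "plane": k,
                    "label": int(region.label),
                    "area": int(region.area),
                    "centroid": tuple(float(c) for c in region.centroid),
                    "bbox": tuple(int(b) for b in region.bbox),
                }
            )
        filtered[tuple(index)] = keep
    return filtered, props


def cluster_3d(
    filtered: np.ndarray,
    spacing: tuple[float, float, float],
    keep_largest: int = 2,
    min_cluster_voxels: int = 100,
) -> LungMask:
    """3D 26-connected clustering; retain the largest air clusters as lungs.

    Up to ``keep_largest`` clusters (default two — or one if the lungs merge)
    are kept after discarding clusters below ``min_cluster_voxels``.  Raises
    :class:`SegmentationError` when nothing survives.
    """
    filtered = np.asarray(filtered, dtype=bool)
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-neighbourhood
    labels, n = ndimage.label(filtered, structure=structure)
    if n == 0:
        raise SegmentationError("no air clusters found")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    candidates = [lab for lab in np.argsort(sizes)[::-1] if sizes[lab] >= min_cluster_voxels]
    kept = tuple(int(lab) for lab in candidates[:keep_largest])
    if not kept:
        raise SegmentationError("no air cluster above the size floor")
    mask = np.isin(labels, kept)
    return LungMask(mask=mask, labels=labels, kept_labels=kept, spacing=tuple(spacing))


def compute_volume(mask: LungMask, spacing: tuple[float, float, float] | None = None) -> float:
    """Volume in litres: voxel count × spacing product (mm³ → L)."""
    spacing = mask.spacing if spacing is None else tuple(spacing)
    return mask.voxel_count * float(np.prod(spacing)) / 1e6


def fractional_volume_series(volumes: Sequence[float]) -> np.ndarray:
    """Volumes over consecutive acquisitions normalised by the initial volume.

    The first element is exactly 1.0; unitless.
    """
    arr = np.asarray(volumes, dtype=float)
    if arr.size < 1:
        raise ValueError("at least one volume is required")
    if arr[0] <= 0:
        raise ValueError("initial volume must be > 0")
    return arr / arr[0]


def segment_lungs(
    grid: VoxelGrid,
    min_area: int = 50,
    keep_largest: int = 2,
    min_cluster_voxels: int = 100,
    slice_axis: int | None = None,
) -> tuple[LungMask, dict]:
    """Full segmentation pipeline on a voxel grid.

    ``slice_axis`` defaults to the AP axis (coronal acquisition planes).
    Returns the lung mask and a report with per-plane thresholds, plane
    degeneracy flags, and the total volume in litres.
    """
    if slice_axis is None:
        slice_axis = grid.axes.index("AP")
    binary = np.zeros(grid.shape, dtype=bool)
    thresholds: list[float | None] = []
    for k in range(grid.shape[slice_axis]):
        index = [slice(None)] * 3
        index[slice_axis] = k
        plane = grid.data[tuple(index)]
        try:
            thr, fg = adaptive_threshold_plane(plane)
        except DegeneratePlaneError:
            thresholds.append(None)
            continue
        thresholds.append(thr)
        binary[tuple(index)] = fg
    filtered, _ = label_and_filter(binary, min_area=min_area, slice_axis=slice_axis)
    mask = cluster_3d(
        filtered, grid.spacing, keep_largest=keep_largest,
        min_cluster_voxels=min_cluster_voxels,
    )
    report = {
        "volume_l": compute_volume(mask),
        "voxel_count": mask.voxel_count,
        "n_clusters_kept": len(mask.kept_labels),
        "plane_thresholds": thresholds,
        "n_degenerate_planes": sum(t is None for t in thresholds),
        "slice_axis": slice_axis,
    }
    return mask, report
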