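"""Analytic thorax phantoms with known lung volume, for the segmentation stage.

A phantom is a bright "body" ellipsoid on a dark background, containing two
dark ellipsoidal "air" lung compartments with small bright blobs at vessel
positions.  The air volume is analytic — the sum of the two lung-ellipsoid
volumes minus the blob volumes — and the ellipsoids are scaled so that this
analytic volume equals the requested target exactly, giving ground truth for
volume-recovery tests.

Default grid: 512 × 512 × 100 voxels at 0.7617 × 0.7617 × 2.2 mm spacing,
axes (RL, CC, AP) — coronal planes stacked along AP.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .cohort import SubjectAnatomy
from .segmentation import VoxelGrid

__all__ = [
    "GeometryError",
    "GridSpec",
    "PhantomGeometry",
    "PhantomTruth",
    "render_phantom",
    "rasterize",
    "save_phantom",
]

BACKGROUND_INTENSITY = 10.0
BODY_INTENSITY = 200.0
LUNG_INTENSITY = 25.0
BLOB_INTENSITY = 200.0

# Base lung semi-axes (mm) in (RL, CC, AP) order and lung center offsets from
# the grid center; scaled uniformly to hit the target volume.  Chosen so that
# targets up to ~7 L keep the two lungs disjoint and inside the body on the
# default grid.
_BASE_SEMI_AXES = np.array([60.0, 120.0, 62.0])
_LUNG_CENTER_RL = 85.0
# Blob centers as fractions of the lung semi-axes.
_BLOB_FRACTIONS = np.array(
    [[0.30, 0.20, 0.40], [-0.35, -0.10, 0.0], [0.10, 0.30, -0.45]]
)


class GeometryError(ValueError):
    """Requested geometry does not fit the grid or the body."""


@dataclass
class GridSpec:
    """Voxel grid specification: shape, spacing (mm), anatomical axis order."""

    shape: tuple[int, int, int] = (512, 512, 100)
    spacing: tuple[float, float, float] = (0.7617, 0.7617, 2.2)
    axes: tuple[str, str, str] = ("RL", "CC", "AP")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)


@dataclass
class PhantomGeometry:
    """Analytic phantom geometry; volumes follow in closed form."""

    lung_centers: np.ndarray  # (2, 3) mm, grid-centred coordinates
    lung_semi_axes: np.ndarray  # (2, 3) mm
    body_semi_axes: np.ndarray  # (3,) mm
    blob_centers: np.ndarray  # (n, 3) mm
    blob_radius: float  # mm

    @property
    def ellipsoid_volume_mm3(self) -> float:
        return float(
            (4.0 / 3.0) * math.pi * np.prod(self.lung_semi_axes, axis=1).sum()
        )

    @property
    def blob_volume_mm3(self) -> float:
        return len(self.blob_centers) * (4.0 / 3.0) * math.pi * self.blob_radius**3

    @property
    def analytic_lung_volume_mm3(self) -> float:
        """Air volume: two ellipsoids minus the bright blobs inside them."""
        return self.ellipsoid_volume_mm3 - self.blob_volume_mm3

    def check_containment(self, n_surface: int = 24) -> None:
        """Verify lungs (plus margin) lie inside the body ellipsoid and that
        blobs lie inside their lungs; raise :class:`GeometryError` otherwise."""
        theta = np.linspace(0, math.pi, n_surface)
        phi = np.linspace(0, 2 * math.pi, 2 * n_surface, endpoint=False)
        tt, pp = np.meshgrid(theta, phi, indexing="ij")
        unit = np.stack(
            [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], axis=-1
        ).reshape(-1, 3)
        surfaces = []
        for center, semi in zip(self.lung_centers, self.lung_semi_axes):
            surface = center + unit * semi
            surfaces.append(surface)
            q = np.sum((surface / self.body_semi_axes) ** 2, axis=1)
            if np.any(q >= 1.0):
                raise GeometryError("lung ellipsoid extends outside the body")
        # The analytic volume assumes disjoint lungs.
        for i, surface in enumerate(surfaces):
            for j, (center, semi) in enumerate(zip(self.lung_centers, self.lung_semi_axes)):
                if i == j:
                    continue
                q = np.sum(((surface - center) / semi) ** 2, axis=1)
                if np.any(q < 1.0):
                    raise GeometryError("lung ellipsoids overlap")
        for blob in self.blob_centers:
            inside_any = False
            for center, semi in zip(self.lung_centers, self.lung_semi_axes):
                offset = np.linalg.norm((blob - center) / semi)
                if offset + self.blob_radius / float(semi.min()) < 1.0:
                    inside_any = True
            if not inside_any:
                raise GeometryError("blob not fully inside a lung")


@dataclass
class PhantomTruth:
    """Ground-truth sidecar for a rendered phantom."""

    analytic_volume_l: float
    target_volume_l: float
    geometry: PhantomGeometry
    subject_id: str = ""
    noise_sd: float = 0.0

    def to_json(self, path) -> None:
        payload = {
            "analytic_volume_l": self.analytic_volume_l,
            "target_volume_l": self.target_volume_l,
            "subject_id": self.subject_id,
            "noise_sd": self.noise_sd,
            "lung_centers_mm": self.geometry.lung_centers.tolist(),
            "lung_semi_axes_mm": self.geometry.lung_semi_axes.tolist(),
            "body_semi_axes_mm": self.geometry.body_semi_axes.tolist(),
            "blob_centers_mm": self.geometry.blob_centers.tolist(),
            "blob_radius_mm": self.geometry.blob_radius,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _build_geometry(
    target_volume_l: float,
    grid: GridSpec,
    blob_radius: float,
    center_jitter: np.ndarray,
) -> PhantomGeometry:
    half_extent = grid.extent_mm / 2.0
    body_semi = 0.95 * half_extent
    target_mm3 = target_volume_l * 1e6
    n_blobs = 2 * len(_BLOB_FRACTIONS)
    blob_vol = n_blobs * (4.0 / 3.0) * math.pi * blob_radius**3
    base_total = 2.0 * (4.0 / 3.0) * math.pi * np.prod(_BASE_SEMI_AXES)
    scale = ((target_mm3 + blob_vol) / base_total) ** (1.0 / 3.0)
    semi = scale * _BASE_SEMI_AXES
    centers = np.array(
        [
            [-_LUNG_CENTER_RL, 0.0, 0.0],
            [_LUNG_CENTER_RL, 0.0, 0.0],
        ]
    ) + center_jitter
    blob_centers = np.concatenate(
        [center + _BLOB_FRACTIONS * semi for center in centers]
    )
    geometry = PhantomGeometry(
        lung_centers=centers,
        lung_semi_axes=np.tile(semi, (2, 1)),
        body_semi_axes=body_semi,
        blob_centers=blob_centers,
        blob_radius=blob_radius,
    )
    geometry.check_containment()
    return geometry


def rasterize(
    geometry: PhantomGeometry,
    grid: GridSpec,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> VoxelGrid:
    """Render a geometry onto a voxel grid (float32 intensities)."""
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(grid.shape, grid.spacing)
    ]
    xx = coords[0][:, None, None]
    yy = coords[1][None, :, None]
    zz = coords[2][None, None, :]

    data = np.full(grid.shape, BACKGROUND_INTENSITY, dtype=np.float32)
    bs = geometry.body_semi_axes
    body = (xx / bs[0]) ** 2 + (yy / bs[1]) ** 2 + (zz / bs[2]) ** 2 <= 1.0
    data[body] = BODY_INTENSITY
    for center, semi in zip(geometry.lung_centers, geometry.lung_semi_axes):
        lung = (
            ((xx - center[0]) / semi[0]) ** 2
            + ((yy - center[1]) / semi[1]) ** 2
            + ((zz - center[2]) / semi[2]) ** 2
            <= 1.0
        )
        data[lung] = LUNG_INTENSITY
    if geometry.blob_radius > 0:
        r2 = geometry.blob_radius**2
        for blob in geometry.blob_centers:
            sphere = (
                (xx - blob[0]) ** 2 + (yy - blob[1]) ** 2 + (zz - blob[2]) ** 2 <= r2
            )
            data[sphere] = BLOB_INTENSITY
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng()
        data += rng.normal(0.0, noise_sd, size=data.shape).astype(np.float32)
    origin = tuple((-(n - 1) / 2.0) * s for n, s in zip(grid.shape, grid.spacing))
    return VoxelGrid(data, grid.spacing, origin, grid.axes)


def render_phantom(
    anatomy: SubjectAnatomy | None,
    target_volume_l: float,
    grid: GridSpec | None = None,
    blob_radius: float = 4.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[VoxelGrid, PhantomTruth]:
    """Render a two-lung phantom whose analytic air volume equals the target.

    The base lung shape is scaled uniformly so that the analytic volume (two
    ellipsoids minus the vessel blobs) matches ``target_volume_l`` exactly;
    a :class:`GeometryError` is raised when the required lungs do not fit
    inside the body for the given grid.  ``rng`` adds Gaussian intensity
    noise (SD ``noise_sd``) and a small per-subject lung-center jitter.
    """
    if target_volume_l <= 0:
        raise ValueError("target_volume_l must be > 0")
    grid = grid if grid is not None else GridSpec()
    if min(grid.spacing) <= 0:
        raise ValueError("grid spacing must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    jitter = (
        rng.normal(0.0, 2.0, size=(2, 3)) if rng is not None else np.zeros((2, 3))
    )
    geometry = _build_geometry(target_volume_l, grid, blob_radius, jitter)
    volume = rasterize(geometry, grid, noise_sd=noise_sd, rng=rng)
    truth = PhantomTruth(
        analytic_volume_l=geometry.analytic_lung_volume_mm3 / 1e6,
        target_volume_l=target_volume_l,
        geometry=geometry,
        subject_id=anatomy.subject_id if anatomy is not None else "",
        noise_sd=noise_sd,
    )
    return volume, truth


def save_phantom(volume: VoxelGrid, truth: PhantomTruth, nifti_path, json_path) -> None:
    """Write the phantom as NIfTI with a JSON ground-truth sidecar."""
    volume.to_nifti(nifti_path)
    truth.to_json(json_path)
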