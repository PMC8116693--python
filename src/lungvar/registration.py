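"""Rigid-body setup estimation and translation-only interfractional correction.

Interfractional patient setup differences are modelled as rigid-body
transforms estimated from motion-invariant spine landmarks (the spinal
reference structure plus auxiliary paravertebral points).  Mirroring a
couch-based 3D offset correction, only the translation component of each
transform is applied to the landmark clouds; rotational residuals remain and
can be quantified geometrically (``rotation_residual_offset``).

Conventions
-----------
* Patient frame: RL = x, AP = y, CC = z, millimetres.
* Rotations: intrinsic rotations about RL, AP, CC in that order; angles in
  degrees.
* A :class:`RigidTransform` maps fixed-frame points to moving-frame points as
  ``x' = R (x - center) + center + translation``.  ``estimate_rigid`` places
  ``center`` at the fixed spine-point centroid, so the translation component
  is the displacement of the spine region — the quantity a translation-only
  couch correction nulls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "DegenerateConfigurationError",
    "RigidTransform",
    "estimate_rigid",
    "translation_only",
    "apply_correction",
    "rotation_residual_offset",
    "estimate_scan_transforms",
    "correct_landmarks",
]

_EULER_ORDER = "XYZ"  # intrinsic RL, AP, CC


class DegenerateConfigurationError(ValueError):
    """Fewer than three paired points, or (near-)collinear configuration."""


@dataclass
class RigidTransform:
    """Rotation about an explicit center plus a translation.

    ``apply`` maps ``x`` to ``R (x - center) + center + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    fixed_frame: str = ""
    moving_frame: str = ""

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-6 or not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-6):
            raise ValueError("rotation must be orthonormal with determinant +1")

    @classmethod
    def identity(cls, **frames) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), **frames)

    @classmethod
    def from_euler(
        cls,
        angles_deg: Sequence[float],
        translation: Sequence[float] = (0.0, 0.0, 0.0),
        center: Sequence[float] = (0.0, 0.0, 0.0),
        **frames,
    ) -> "RigidTransform":
        """Build from intrinsic RL/AP/CC rotation angles in degrees."""
        rot = Rotation.from_euler(_EULER_ORDER, angles_deg, degrees=True).as_matrix()
        return cls(rot, np.asarray(translation, float), np.asarray(center, float), **frames)

    @property
    def euler_angles_deg(self) -> np.ndarray:
        """Intrinsic RL/AP/CC rotation angles (degrees)."""
        return Rotation.from_matrix(self.rotation).as_euler(_EULER_ORDER, degrees=True)

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (center folded into the translation column)."""
        out = np.eye(4)
        out[:3, :3] = self.rotation
        out[:3, 3] = self.translation + self.center - self.rotation @ self.center
        return out

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (pts - self.center) @ self.rotation.T + self.center + self.translation

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        # Same center; solve for translation so that inverse(apply(x)) == x.
        t_inv = -rot_inv @ self.translation
        return RigidTransform(
            rot_inv, t_inv, self.center,
            fixed_frame=self.moving_frame, moving_frame=self.fixed_frame,
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        m = self.matrix @ other.matrix
        return RigidTransform(
            m[:3, :3], m[:3, 3], np.zeros(3),
            fixed_frame=other.fixed_frame, moving_frame=self.moving_frame,
        )

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "center": self.center.tolist(),
            "fixed_frame": self.fixed_frame,
            "moving_frame": self.moving_frame,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "RigidTransform":
        m = np.asarray(data["matrix"], dtype=float)
        center = np.asarray(data.get("center", (0.0, 0.0, 0.0)), dtype=float)
        rot = m[:3, :3]
        translation = m[:3, 3] - center + rot @ center
        return cls(rot, translation, center,
                   fixed_frame=data.get("fixed_frame", ""),
                   moving_frame=data.get("moving_frame", ""))


def estimate_rigid(fixed: np.ndarray, moving: np.ndarray,
                   fixed_frame: str = "", moving_frame: str = "") -> RigidTransform:
    """Least-squares rigid transform mapping ``fixed`` points onto ``moving``.

    Closed-form Kabsch solution: the rotation comes from the SVD of the
    centred cross-covariance (with a reflection guard), the rotation center is
    the fixed centroid, and the translation is the centroid displacement.
    Exact (residual at machine precision) when the two point sets differ by a
    pure rigid motion.

    Raises
    ------
    DegenerateConfigurationError
        For fewer than 3 pairs or collinear fixed points.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape or fixed.ndim != 2 or fixed.shape[1] != 3:
        raise ValueError("fixed and moving must be matching (n, 3) arrays")
    n = fixed.shape[0]
    if n < 3:
        raise DegenerateConfigurationError("at least 3 paired points are required")
    f_centroid = fixed.mean(axis=0)
    m_centroid = moving.mean(axis=0)
    fc = fixed - f_centroid
    mc = moving - m_centroid
    # Collinearity check: centred fixed points must span at least a plane.
    sv = np.linalg.svd(fc, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateConfigurationError("fixed points are collinear")
    h = fc.T @ mc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rot, m_centroid - f_centroid, f_centroid,
                          fixed_frame=fixed_frame, moving_frame=moving_frame)


def translation_only(transform: RigidTransform) -> np.ndarray:
    """Translation component (mm); the rotation is deliberately discarded."""
    return transform.translation.copy()


def apply_correction(points: np.ndarray, correction: np.ndarray) -> np.ndarray:
    """Shift all points by ``-correction`` (undo a measured setup translation).

    Pairwise distances are unchanged (rigid shift).
    """
    return np.asarray(points, dtype=float) - np.asarray(correction, dtype=float)


def rotation_residual_offset(lever_arm: float, angle_deg: float,
                             small_angle: bool = False) -> float:
    """Lateral offset (mm) induced at distance ``lever_arm`` by an uncorrected
    rotation of ``angle_deg`` about an orthogonal axis through the reference.

    ``offset = lever_arm * sin(angle)``; with ``small_angle=True`` the
    first-order approximation ``lever_arm * angle_rad`` is used instead.
    """
    if lever_arm < 0:
        raise ValueError("lever_arm must be >= 0")
    rad = np.deg2rad(angle_deg)
    return float(lever_arm * (rad if small_angle else np.sin(rad)))


# ---------------------------------------------------------------------------
# Landmark-table helpers


def _spine_points(scan: pd.DataFrame, spine_ids: Sequence[str]) -> np.ndarray:
    sub = scan[scan["structure_id"].isin(spine_ids)].sort_values("structure_id")
    return sub[["x_mm", "y_mm", "z_mm"]].to_numpy()


def estimate_scan_transforms(
    landmarks: pd.DataFrame, spine_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Estimate per-scan setup transforms from spine landmarks.

    For each subject and method, every scan of visits >= 2 is registered to
    scan 1 of visit 1 (the fixed reference); visit-1 transforms are taken as
    identity.  Returns a table with one row per (subject, method, visit,
    scan) and the transform plus its translation component.
    """
    if spine_ids is None:
        spine_ids = sorted(
            s for s in landmarks["structure_id"].unique()
            if s == "Ref_SC" or s.startswith("Spine_")
        )
    rows = []
    for (subject, method), group in landmarks.groupby(["subject_id", "method"], sort=True):
        ref_scan = group[(group["visit"] == 1) & (group["scan"] == 1)]
        fixed = _spine_points(ref_scan, spine_ids)
        for (visit, scan), scan_df in group.groupby(["visit", "scan"], sort=True):
            if visit == 1:
                tf = RigidTransform.identity(
                    fixed_frame=f"{subject}/{method}/v1s1",
                    moving_frame=f"{subject}/{method}/v{visit}s{scan}",
                )
            else:
                moving = _spine_points(scan_df, spine_ids)
                tf = estimate_rigid(
                    fixed, moving,
                    fixed_frame=f"{subject}/{method}/v1s1",
                    moving_frame=f"{subject}/{method}/v{visit}s{scan}",
                )
            t = translation_only(tf)
            rows.append((subject, method, visit, scan, tf, t[0], t[1], t[2]))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "method", "visit", "scan", "transform",
                 "t_rl_mm", "t_ap_mm", "t_cc_mm"],
    )


def correct_landmarks(
    landmarks: pd.DataFrame, transforms: pd.DataFrame
) -> pd.DataFrame:
    """Apply per-scan translation-only corrections to a landmark table."""
    corrected = landmarks.merge(
        transforms[["subject_id", "method", "visit", "scan",
                    "t_rl_mm", "t_ap_mm", "t_cc_mm"]],
        on=["subject_id", "method", "visit", "scan"],
        how="left",
        validate="many_to_one",
    )
    if corrected[["t_rl_mm", "t_ap_mm", "t_cc_mm"]].isna().any().any():
        missing = corrected[corrected["t_rl_mm"].isna()][
            ["subject_id", "method", "visit", "scan"]
        ].drop_duplicates()
        raise ValueError(f"no transform for scans:\n{missing}")
    for axis, col in zip(("x_mm", "y_mm", "z_mm"), ("t_rl_mm", "t_ap_mm", "t_cc_mm")):
        corrected[axis] = corrected[axis] - corrected[col]
    return corrected.drop(columns=["t_rl_mm", "t_ap_mm", "t_cc_mm"])
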