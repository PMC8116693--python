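"""Positional clusters and 95 %-CL "volume of variability" ellipsoids.

After translation-only setup correction, each structure's positions over a
method's scans form a cluster.  Its per-axis standard deviations define an
axis-aligned 95 % confidence ellipsoid with semi-axes ``k σ_axis`` where
``k = sqrt(χ²_{0.95, 3 df}) ≈ 2.7955`` (a point of a trivariate Gaussian with
independent axes lies inside with probability 0.95).  Its volume

    VolOfVar = (4/3) π k³ σ_RL σ_AP σ_CC   [mm³]

is the "volume of variability"; divided by the subject's mean lung volume it
becomes fractional, and the log10 ratio of the two methods' fractional
volumes compares them per subject and structure (negative ⇔ less variability
with eDIBH).  Only ratios of volumes are interpreted, so the choice of k
cancels there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import VESSEL_IDS

__all__ = [
    "CHI2_95_3DF",
    "K95",
    "PositionCluster",
    "build_cluster",
    "cluster_table",
    "ellipsoid_volume_95",
    "fractional_volvar",
    "volvar_log_ratio",
    "volvar_table",
    "axis_sd_table",
    "rotation_contribution_estimate",
]

CHI2_95_3DF = float(stats.chi2.ppf(0.95, df=3))
K95 = math.sqrt(CHI2_95_3DF)


@dataclass
class PositionCluster:
    """Corrected positions of one structure over a method's scans."""

    positions: np.ndarray  # (n, 3) mm
    mean: np.ndarray  # (3,) mm
    sd: np.ndarray  # (σ_RL, σ_AP, σ_CC) mm, sample SDs
    covariance: np.ndarray  # (3, 3) mm², sample covariance
    subject_id: str = ""
    structure_id: str = ""
    method: str = ""

    @property
    def degenerate(self) -> bool:
        """True when any per-axis SD is zero (flat cluster)."""
        return bool(np.any(self.sd == 0.0))


def build_cluster(
    positions: np.ndarray,
    subject_id: str = "",
    structure_id: str = "",
    method: str = "",
) -> PositionCluster:
    """Mean, per-axis sample SDs (n−1), and covariance of >= 2 positions."""
    pts = np.asarray(positions, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValueError("positions must be an (n >= 2, 3) array")
    mean = pts.mean(axis=0)
    sd = pts.std(axis=0, ddof=1)
    cov = np.cov(pts, rowvar=False, ddof=1)
    return PositionCluster(pts, mean, sd, cov, subject_id, structure_id, method)


def ellipsoid_volume_95(cluster: PositionCluster, use_pca: bool = False) -> float:
    """Volume (mm³) of the cluster's 95 % CL ellipsoid.

    Default: axis-aligned semi-axes ``K95 * σ_axis`` (matches Cartesian
    per-axis SD reporting).  With ``use_pca=True`` the semi-axes are the
    square roots of the covariance eigenvalues instead (principal axes);
    volumes differ only when axes are correlated.  Degenerate clusters (any
    zero SD) yield 0.
    """
    if use_pca:
        eigvals = np.linalg.eigvalsh(cluster.covariance)
        eigvals = np.clip(eigvals, 0.0, None)
        prod = float(np.sqrt(np.prod(eigvals)))
    else:
        prod = float(np.prod(cluster.sd))
    return (4.0 / 3.0) * math.pi * K95**3 * prod


def fractional_volvar(vol_of_var_mm3: float, mean_lung_volume_l: float) -> float:
    """VolOfVar divided by the mean lung volume (litres → mm³); unitless."""
    if mean_lung_volume_l <= 0:
        raise ValueError("mean lung volume must be > 0")
    return vol_of_var_mm3 / (mean_lung_volume_l * 1e6)


def volvar_log_ratio(fractional_edibh: float, fractional_hfpv: float) -> float:
    """log10 ratio of fractional volumes of variability (negative ⇔ eDIBH)."""
    if fractional_edibh <= 0 or fractional_hfpv <= 0:
        raise ValueError("fractional volumes of variability must be > 0")
    return math.log10(fractional_edibh / fractional_hfpv)


def cluster_table(corrected_landmarks: pd.DataFrame) -> pd.DataFrame:
    """Per subject × structure × method cluster statistics.

    Expects a corrected landmark table; spine structures are excluded, the
    reference is retained (its SDs quantify the registration residual).
    """
    df = corrected_landmarks[
        ~corrected_landmarks["structure_id"].str.startswith("Spine_")
    ]
    grouped = df.groupby(["subject_id", "structure_id", "method"], sort=True)
    rows = []
    for (subject, sid, method), group in grouped:
        pts = group[["x_mm", "y_mm", "z_mm"]].to_numpy()
        if pts.shape[0] < 2:
            continue
        c = build_cluster(pts, subject, sid, method)
        rows.append(
            {
                "subject_id": subject,
                "structure_id": sid,
                "method": method,
                "n_scans": pts.shape[0],
                "mean_x_mm": c.mean[0],
                "mean_y_mm": c.mean[1],
                "mean_z_mm": c.mean[2],
                "sd_rl_mm": c.sd[0],
                "sd_ap_mm": c.sd[1],
                "sd_cc_mm": c.sd[2],
            }
        )
    return pd.DataFrame(rows)


def volvar_table(
    clusters: pd.DataFrame,
    volumes: pd.DataFrame,
    ratio_structures: Sequence[str] = VESSEL_IDS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """VolOfVar per subject × structure × method, plus method log-ratios.

    Parameters
    ----------
    clusters
        Output of :func:`cluster_table`.
    volumes
        Per subject × method mean lung volume, columns ``subject_id``,
        ``method``, ``mean_l`` (e.g. from segmentation or generator truth).
    ratio_structures
        Structures entering the ratio analysis (default: the six vessels).

    Returns
    -------
    (volvar, ratios)
        ``volvar``: one row per subject × structure × method with VolOfVar
        (mm³), the degenerate flag, and the fractional VolOfVar.  ``ratios``:
        one row per subject × ratio structure with the log10 ratio; entries
        where either method is degenerate are excluded (``defined`` False).
    """
    df = clusters.copy()
    df["vol_of_var_mm3"] = (
        (4.0 / 3.0) * math.pi * K95**3
        * df["sd_rl_mm"] * df["sd_ap_mm"] * df["sd_cc_mm"]
    )
    df["degenerate"] = (
        (df["sd_rl_mm"] == 0) | (df["sd_ap_mm"] == 0) | (df["sd_cc_mm"] == 0)
    )
    df = df.merge(
        volumes[["subject_id", "method", "mean_l"]],
        on=["subject_id", "method"],
        validate="many_to_one",
    )
    df["fractional_volvar"] = df["vol_of_var_mm3"] / (df["mean_l"] * 1e6)

    sub = df[df["structure_id"].isin(ratio_structures)]
    wide = sub.pivot_table(
        index=["subject_id", "structure_id"],
        columns="method",
        values="fractional_volvar",
    ).reset_index()
    defined = (wide.get("eDIBH", np.nan) > 0) & (wide.get("HFPV", np.nan) > 0)
    wide["log_ratio"] = np.where(
        defined, np.log10(wide["eDIBH"] / wide["HFPV"]), np.nan
    )
    wide["defined"] = defined
    return df, wide


def axis_sd_table(clusters: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-axis SD table (structure × method × axis) for reporting."""
    long = clusters.melt(
        id_vars=["subject_id", "structure_id", "method"],
        value_vars=["sd_rl_mm", "sd_ap_mm", "sd_cc_mm"],
        var_name="axis",
        value_name="sd_mm",
    )
    long["axis"] = long["axis"].map(
        {"sd_rl_mm": "RL", "sd_ap_mm": "AP", "sd_cc_mm": "CC"}
    )
    return long


def rotation_contribution_estimate(
    lever_arm_mm, rotation_sd_deg, total_sd_mm
):
    """Fraction of observed displacement SD attributable to uncorrected
    rotations.

    The rotation-induced displacement SD at a structure is approximately
    ``lever_arm × rotation SD`` (small angles, radians); its ratio to the
    total observed SD estimates the rotational contribution.  Values above 1
    are capped at 1.0 and flagged.

    Returns ``(contribution, capped)`` as floats/arrays.
    """
    lever = np.asarray(lever_arm_mm, dtype=float)
    rot_sd = np.deg2rad(np.asarray(rotation_sd_deg, dtype=float))
    total = np.asarray(total_sd_mm, dtype=float)
    if np.any(lever < 0) or np.any(rot_sd < 0):
        raise ValueError("lever arms and rotation SDs must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(total > 0, lever * rot_sd / total, np.inf)
    raw = np.where((lever * rot_sd == 0), 0.0, raw)
    capped = raw > 1.0
    contribution = np.minimum(raw, 1.0)
    if contribution.ndim == 0:
        return float(contribution), bool(capped)
    return contribution, capped
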