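"""Lung-structure distance metric, fractional variations, and γ log-ratios.

The intrapulmonary lung-structure metric is the set of difference vectors
``r_i = position(LSC_i) - position(Ref_SC)`` between each mobile lung
structure and the motion-invariant spinal reference within one scan.  Over a
method's repeated scans (8 in the reference design: 2 scans × 4 visits), the
radial distances ``r_i = |r_i|`` yield per-structure means μ, standard
deviations σ, and fractional variations σ/μ (a coefficient of variation).

Methods are compared per subject and structure by the log-ratio

    γ = log10[ (σ/μ)_eDIBH / (σ/μ)_HFPV ]

whose sign favours the method with less variability (negative ⇔ eDIBH).
Because the radial distance is computed within a scan, it is invariant to the
per-scan rigid setup transform; no correction is needed for this analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import METHODS, REFERENCE_ID

__all__ = [
    "DegenerateStructureError",
    "UndefinedGammaError",
    "DistanceMetric",
    "VariationSummary",
    "distance_metric",
    "radial_distance_table",
    "fractional_variation",
    "variation_table",
    "volume_variation_table",
    "gamma_ratio",
    "gamma_table",
    "compare_methods_table",
    "count_preferences",
    "PreferenceSummary",
    "fit_binomial_preference",
]


class DegenerateStructureError(ValueError):
    """Fractional variation undefined (mean radial distance is zero)."""


class UndefinedGammaError(ValueError):
    """γ undefined (a fractional variation is zero or negative)."""


@dataclass
class DistanceMetric:
    """Difference vectors and radial distances of one scan's landmarks."""

    vectors: dict[str, np.ndarray]  # structure_id -> r_i (mm, 3D)
    radial: dict[str, float]  # structure_id -> |r_i| (mm)


def distance_metric(landmarks: Mapping[str, np.ndarray]) -> DistanceMetric:
    """Compute the lung-structure metric for one scan.

    ``landmarks`` maps structure ids to 3D positions (mm) and must contain
    the reference ``Ref_SC``; the reference itself (and any auxiliary spine
    point) is excluded from the output.
    """
    if REFERENCE_ID not in landmarks:
        raise ValueError(f"landmarks must contain the reference {REFERENCE_ID!r}")
    ref = np.asarray(landmarks[REFERENCE_ID], dtype=float)
    vectors: dict[str, np.ndarray] = {}
    radial: dict[str, float] = {}
    for sid, pos in landmarks.items():
        if sid == REFERENCE_ID or sid.startswith("Spine_"):
            continue
        vec = np.asarray(pos, dtype=float) - ref
        vectors[sid] = vec
        radial[sid] = float(np.linalg.norm(vec))
    return DistanceMetric(vectors, radial)


def radial_distance_table(landmarks: pd.DataFrame) -> pd.DataFrame:
    """Vectorized per-scan radial distances for a tidy landmark table.

    Returns one row per scan × mobile structure with the difference vector
    components and the radial distance ``r_mm``.
    """
    keys = ["subject_id", "visit", "scan", "method"]
    ref = landmarks[landmarks["structure_id"] == REFERENCE_ID]
    ref = ref[keys + ["x_mm", "y_mm", "z_mm"]].rename(
        columns={"x_mm": "ref_x", "y_mm": "ref_y", "z_mm": "ref_z"}
    )
    mobile = landmarks[
        (landmarks["structure_id"] != REFERENCE_ID)
        & ~landmarks["structure_id"].str.startswith("Spine_")
    ]
    merged = mobile.merge(ref, on=keys, validate="many_to_one")
    merged["dx_mm"] = merged["x_mm"] - merged["ref_x"]
    merged["dy_mm"] = merged["y_mm"] - merged["ref_y"]
    merged["dz_mm"] = merged["z_mm"] - merged["ref_z"]
    merged["r_mm"] = np.sqrt(
        merged["dx_mm"] ** 2 + merged["dy_mm"] ** 2 + merged["dz_mm"] ** 2
    )
    cols = keys + ["structure_id", "dx_mm", "dy_mm", "dz_mm", "r_mm"]
    if "true_volume_l" in merged.columns:
        cols.append("true_volume_l")
    return merged[cols].reset_index(drop=True)


@dataclass
class VariationSummary:
    """μ, σ and σ/μ of one structure's radial distances over a method's scans."""

    structure_id: str
    method: str
    n_scans: int
    mean_mm: float
    sd_mm: float
    fractional_variation: float


def fractional_variation(
    values: Sequence[float],
    structure_id: str = "",
    method: str = "",
) -> VariationSummary:
    """Sample SD over mean of radial distances (n−1 denominator).

    Raises
    ------
    ValueError for fewer than 2 values; DegenerateStructureError for μ <= 0.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("at least 2 values are required")
    mean = float(arr.mean())
    if mean <= 0:
        raise DegenerateStructureError("mean radial distance must be > 0")
    sd = float(arr.std(ddof=1))
    return VariationSummary(structure_id, method, int(arr.size), mean, sd, sd / mean)


def variation_table(radial_distances: pd.DataFrame) -> pd.DataFrame:
    """Per subject × structure × method variation summaries.

    Pools all scans of a method (2 scans × 4 visits = 8 in the reference
    design) per structure.
    """
    grouped = radial_distances.groupby(
        ["subject_id", "structure_id", "method"], sort=True
    )["r_mm"]
    out = grouped.agg(n_scans="size", mean_mm="mean", sd_mm=lambda v: v.std(ddof=1))
    out = out.reset_index()
    out["fractional_variation"] = out["sd_mm"] / out["mean_mm"]
    return out


def volume_variation_table(landmarks: pd.DataFrame) -> pd.DataFrame:
    """Per subject × method fractional variation of total lung volume."""
    per_scan = (
        landmarks.groupby(["subject_id", "method", "visit", "scan"], sort=True)[
            "true_volume_l"
        ]
        .first()
        .reset_index()
    )
    grouped = per_scan.groupby(["subject_id", "method"], sort=True)["true_volume_l"]
    out = grouped.agg(n_scans="size", mean_l="mean", sd_l=lambda v: v.std(ddof=1))
    out = out.reset_index()
    out["fractional_variation"] = out["sd_l"] / out["mean_l"]
    return out


def gamma_ratio(fv_edibh: float, fv_hfpv: float) -> float:
    """γ = log10 of the eDIBH/HFPV fractional-variation ratio.

    Negative γ means less variability with eDIBH.  Raises
    :class:`UndefinedGammaError` when either input is not strictly positive.
    """
    if fv_edibh <= 0 or fv_hfpv <= 0:
        raise UndefinedGammaError("fractional variations must be > 0")
    return math.log10(fv_edibh / fv_hfpv)


def gamma_table(
    variation: pd.DataFrame,
    volume_variation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per subject × structure γ log-ratios, optionally augmented by volume.

    ``variation`` is the output of :func:`variation_table`.  When
    ``volume_variation`` is given, a pseudo-structure ``"Volume"`` carrying
    the lung-volume γ is appended, giving 10 entries per subject in the
    reference design (9 structures + volume).  Entries where either
    fractional variation is non-positive are excluded and flagged in the
    ``defined`` column.
    """
    wide = variation.pivot_table(
        index=["subject_id", "structure_id"],
        columns="method",
        values="fractional_variation",
    ).reset_index()
    frames = [wide]
    if volume_variation is not None:
        vol = volume_variation.pivot_table(
            index="subject_id", columns="method", values="fractional_variation"
        ).reset_index()
        vol["structure_id"] = "Volume"
        frames.append(vol)
    table = pd.concat(frames, ignore_index=True)
    for method in METHODS:
        if method not in table.columns:
            raise ValueError(f"variation table lacks method {method!r}")
    defined = (table["eDIBH"] > 0) & (table["HFPV"] > 0)
    table["gamma"] = np.where(
        defined, np.log10(table["eDIBH"] / table["HFPV"]), np.nan
    )
    table["defined"] = defined
    return table[["subject_id", "structure_id", "eDIBH", "HFPV", "gamma", "defined"]]


def compare_methods_table(
    variation: pd.DataFrame, min_pairs: int = 6
) -> pd.DataFrame:
    """Per-structure method comparison of relative errors (table form).

    For each structure, the per-subject fractional variations of the two
    methods form a paired sample; reported are median and maximum relative
    error in percent for each method and the two-sided Wilcoxon signed-rank
    p-value (exact distribution for n <= 25, zero differences dropped).
    Fewer than ``min_pairs`` pairs flags the p-value as unreliable; identical
    paired samples give a degenerate test, reported as p = 1.
    """
    wide = variation.pivot_table(
        index=["subject_id", "structure_id"],
        columns="method",
        values="fractional_variation",
    ).reset_index()
    rows = []
    for sid, group in wide.groupby("structure_id", sort=True):
        paired = group.dropna(subset=["eDIBH", "HFPV"])
        fv_e = paired["eDIBH"].to_numpy()
        fv_h = paired["HFPV"].to_numpy()
        n = len(paired)
        if n and np.allclose(fv_e, fv_h):
            p_value = 1.0
        elif n >= 2:
            p_value = float(
                stats.wilcoxon(fv_e, fv_h, alternative="two-sided", method="auto").pvalue
            )
        else:
            p_value = np.nan
        rows.append(
            {
                "structure_id": sid,
                "n_pairs": n,
                "edibh_median_pct": 100 * float(np.median(fv_e)) if n else np.nan,
                "edibh_max_pct": 100 * float(np.max(fv_e)) if n else np.nan,
                "hfpv_median_pct": 100 * float(np.median(fv_h)) if n else np.nan,
                "hfpv_max_pct": 100 * float(np.max(fv_h)) if n else np.nan,
                "p_value": p_value,
                "reliable": n >= min_pairs,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PreferenceSummary:
    """Per-subject negative-γ counts and cohort-level preference fractions."""

    per_subject: pd.DataFrame  # subject_id, n_negative, n_defined, n_missing, class
    n_negative: int
    n_defined: int
    overall_negative_fraction: float
    n_green: int
    n_orange: int
    n_intermediate: int
    clear_fraction_edibh: float  # among clearly distinguished subjects

    def to_dict(self) -> dict:
        return {
            "n_negative": self.n_negative,
            "n_defined": self.n_defined,
            "overall_negative_fraction": self.overall_negative_fraction,
            "n_green": self.n_green,
            "n_orange": self.n_orange,
            "n_intermediate": self.n_intermediate,
            "clear_fraction_edibh": self.clear_fraction_edibh,
            "per_subject": self.per_subject.to_dict(orient="records"),
        }


def count_preferences(
    gamma: pd.DataFrame,
    entries_per_subject: int = 10,
    green_min: int = 8,
    orange_max: int = 3,
) -> PreferenceSummary:
    """Count negative γ entries per subject and classify subjects.

    A subject with at least ``green_min`` negative entries (of the nominal
    ``entries_per_subject``) clearly favours eDIBH ("green"); one with at
    most ``orange_max`` clearly favours HFPV ("orange"); others are
    intermediate.  γ exactly 0 favours neither method and is not counted as
    negative; undefined entries are counted as missing and reported.
    """
    rows = []
    for subject, group in gamma.groupby("subject_id", sort=True):
        valid = group[group["defined"] & group["gamma"].notna()]
        n_negative = int((valid["gamma"] < 0).sum())
        n_defined = len(valid)
        n_missing = entries_per_subject - n_defined
        if n_negative >= green_min:
            cls = "green"
        elif n_negative <= orange_max:
            cls = "orange"
        else:
            cls = "intermediate"
        rows.append(
            {
                "subject_id": subject,
                "n_negative": n_negative,
                "n_defined": n_defined,
                "n_missing": n_missing,
                "classification": cls,
            }
        )
    per_subject = pd.DataFrame(rows)
    n_negative = int(per_subject["n_negative"].sum())
    n_defined = int(per_subject["n_defined"].sum())
    n_green = int((per_subject["classification"] == "green").sum())
    n_orange = int((per_subject["classification"] == "orange").sum())
    n_clear = n_green + n_orange
    return PreferenceSummary(
        per_subject=per_subject,
        n_negative=n_negative,
        n_defined=n_defined,
        overall_negative_fraction=n_negative / n_defined if n_defined else float("nan"),
        n_green=n_green,
        n_orange=n_orange,
        n_intermediate=int((per_subject["classification"] == "intermediate").sum()),
        clear_fraction_edibh=n_green / n_clear if n_clear else float("nan"),
    )


def fit_binomial_preference(
    counts: Sequence[int],
    trials: int = 10,
    green_min: int = 8,
    orange_max: int = 3,
    grid_step: float = 0.001,
) -> dict:
    """Binomial model of per-subject negative-γ counts.

    Models each subject's count of eDIBH-favouring entries as
    ``Binomial(trials, p)``.  Returns the pooled maximum-likelihood estimate
    (total negatives / total trials) and a "clear-subjects-only" variant: the
    truncated-binomial MLE (grid search at ``grid_step``) using only subjects
    whose counts fall in the clearly-distinguished regions
    ``[green_min, trials]`` or ``[0, orange_max]``.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError("counts must be non-empty")
    if counts.min() < 0 or counts.max() > trials:
        raise ValueError(f"counts must lie in [0, {trials}]")
    p_pooled = float(counts.sum()) / (trials * counts.size)

    clear = counts[(counts >= green_min) | (counts <= orange_max)]
    p_clear = float("nan")
    if clear.size:
        grid = np.arange(grid_step, 1.0, grid_step)
        k = np.arange(trials + 1)
        in_region = (k >= green_min) | (k <= orange_max)
        pmf = stats.binom.pmf(k[None, :], trials, grid[:, None])
        region_mass = pmf[:, in_region].sum(axis=1)
        loglik = np.zeros_like(grid)
        for c in clear:
            loglik += np.log(pmf[:, c])
        loglik -= clear.size * np.log(region_mass)
        p_clear = float(grid[int(np.argmax(loglik))])
    return {
        "p_pooled": p_pooled,
        "p_clear_subjects": p_clear,
        "n_subjects": int(counts.size),
        "n_clear_subjects": int(clear.size),
        "trials": trials,
    }
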