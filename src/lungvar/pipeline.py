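"""End-to-end study pipeline: generate → (segment) → register/correct →
metrics → variability, with file-based stage coupling and a run manifest.

Stages exchange CSV/JSON (and NIfTI for phantoms) so that users can
substitute real contoured data for any stage.  ``run_study`` produces the
report bundle: variation summaries and method comparison (relative-error
table shape), the per-subject γ grid with preference counts, the per-axis SD
table, and the volume-of-variability ratios.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    LANDMARK_COLUMNS,
    METHODS,
    REFERENCE_ID,
    STRUCTURE_IDS,
    Cohort,
    CohortConfig,
    generate_cohort,
)
from .metrics import (
    compare_methods_table,
    count_preferences,
    fit_binomial_preference,
    gamma_table,
    radial_distance_table,
    variation_table,
    volume_variation_table,
)
from .registration import correct_landmarks, estimate_scan_transforms
from .variability import axis_sd_table, cluster_table, volvar_table

logger = logging.getLogger("lungvar")

__all__ = ["RunManifest", "StudyResult", "run_study", "validate_landmark_csv", "SchemaReport"]


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    config_hash: str
    seed: int
    package_version: str
    python_version: str
    outputs: dict[str, str]
    started_utc: str
    finished_utc: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


@dataclass
class StudyResult:
    """In-memory bundle of all pipeline stage outputs."""

    cohort: Cohort
    transforms: pd.DataFrame
    corrected: pd.DataFrame
    variation: pd.DataFrame
    comparison: pd.DataFrame
    gamma: pd.DataFrame
    preferences: dict
    clusters: pd.DataFrame
    volvar: pd.DataFrame
    volvar_ratios: pd.DataFrame
    axis_sds: pd.DataFrame
    manifest: RunManifest | None = None


def config_hash(config: CohortConfig) -> str:
    return hashlib.sha256(config.to_json().encode()).hexdigest()[:16]


def mean_volume_table(landmarks: pd.DataFrame) -> pd.DataFrame:
    """Per subject × method mean lung volume (litres) over the method's scans."""
    per_scan = (
        landmarks.groupby(["subject_id", "method", "visit", "scan"], sort=True)[
            "true_volume_l"
        ]
        .first()
        .reset_index()
    )
    out = (
        per_scan.groupby(["subject_id", "method"], sort=True)["true_volume_l"]
        .mean()
        .reset_index()
        .rename(columns={"true_volume_l": "mean_l"})
    )
    return out


def analyze_landmarks(landmarks: pd.DataFrame) -> dict:
    """Run the full analysis on a tidy landmark table; returns stage frames."""
    t0 = time.time()
    rdist = radial_distance_table(landmarks)
    variation = variation_table(rdist)
    vol_variation = volume_variation_table(landmarks)
    comparison = compare_methods_table(variation)
    gamma = gamma_table(variation, vol_variation)
    preferences = count_preferences(gamma)
    binomial = fit_binomial_preference(
        preferences.per_subject["n_negative"].to_numpy()
    )
    logger.info(
        "metrics: %d subjects, %d gamma entries (%d undefined)",
        gamma["subject_id"].nunique(), len(gamma), int((~gamma["defined"]).sum()),
    )
    transforms = estimate_scan_transforms(landmarks)
    corrected = correct_landmarks(landmarks, transforms)
    clusters = cluster_table(corrected)
    volumes = mean_volume_table(landmarks)
    volvar, ratios = volvar_table(clusters, volumes)
    axis_sds = axis_sd_table(clusters)
    logger.info(
        "variability: %d clusters, %d ratios defined of %d; %.2f s",
        len(clusters), int(ratios["defined"].sum()), len(ratios), time.time() - t0,
    )
    return {
        "transforms": transforms,
        "corrected": corrected,
        "variation": variation,
        "comparison": comparison,
        "gamma": gamma,
        "preferences": {**preferences.to_dict(), "binomial": binomial},
        "clusters": clusters,
        "volvar": volvar,
        "volvar_ratios": ratios,
        "axis_sds": axis_sds,
    }


def run_study(
    config: CohortConfig | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    landmarks: pd.DataFrame | None = None,
) -> StudyResult:
    """Run the full pipeline and (optionally) write the report bundle.

    Either generates a synthetic cohort from ``config`` (default
    configuration when None) or analyses a user-supplied ``landmarks``
    table.  With ``out_dir`` set, writes all stage outputs as CSV/JSON plus
    a manifest; rerunning with an identical config and seed reproduces
    identical files.
    """
    started = time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())
    config = config if config is not None else CohortConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    if landmarks is None:
        cohort = generate_cohort(config)
        landmarks = cohort.landmarks
        logger.info(
            "generate: %d subjects, %d scans", len(cohort.anatomies), len(cohort.scans)
        )
    else:
        report = validate_landmark_csv(landmarks)
        if report.violations:
            raise ValueError(
                "landmark table violates schema:\n" + "\n".join(report.violations)
            )
        cohort = Cohort(config, [], [])
        cohort._landmarks = landmarks

    stages = analyze_landmarks(landmarks)
    manifest = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        outputs: dict[str, str] = {}

        def write_csv(name: str, frame: pd.DataFrame) -> None:
            path = out_dir / name
            frame.round(9).to_csv(path, index=False)
            outputs[name] = str(path)

        write_csv("landmarks.csv", landmarks)
        write_csv(
            "transforms.csv",
            stages["transforms"].drop(columns=["transform"]),
        )
        with open(out_dir / "transforms.json", "w") as fh:
            json.dump(
                [t.to_dict() for t in stages["transforms"]["transform"]], fh, indent=2
            )
        outputs["transforms.json"] = str(out_dir / "transforms.json")
        write_csv("corrected_landmarks.csv", stages["corrected"])
        write_csv("variation_summary.csv", stages["comparison"])
        write_csv("fractional_variations.csv", stages["variation"])
        write_csv("gamma_table.csv", stages["gamma"])
        write_csv("clusters.csv", stages["clusters"])
        write_csv("volofvar.csv", stages["volvar"])
        write_csv("volofvar_ratios.csv", stages["volvar_ratios"])
        write_csv("axis_sd_table.csv", stages["axis_sds"])
        with open(out_dir / "preferences.json", "w") as fh:
            json.dump(stages["preferences"], fh, indent=2)
        outputs["preferences.json"] = str(out_dir / "preferences.json")
        manifest = RunManifest(
            config_hash=config_hash(config),
            seed=config.seed,
            package_version=__version__,
            python_version=platform.python_version(),
            outputs=outputs,
            started_utc=started,
            finished_utc=time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
        )
        manifest.to_json(out_dir / "manifest.json")

    return StudyResult(
        cohort=cohort,
        transforms=stages["transforms"],
        corrected=stages["corrected"],
        variation=stages["variation"],
        comparison=stages["comparison"],
        gamma=stages["gamma"],
        preferences=stages["preferences"],
        clusters=stages["clusters"],
        volvar=stages["volvar"],
        volvar_ratios=stages["volvar_ratios"],
        axis_sds=stages["axis_sds"],
        manifest=manifest,
    )


@dataclass
class SchemaReport:
    """All schema violations found in a landmark table (not just the first)."""

    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_landmark_csv(source) -> SchemaReport:
    """Validate a landmark CSV file (or DataFrame) against the schema.

    Checks column names, numeric coordinates (reporting row numbers),
    exactly one reference per scan, and presence of all 10 structures per
    scan.  All violations are collected.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        path = Path(source)
        if not path.exists():
            return SchemaReport([f"file not found: {path}"])
        df = pd.read_csv(path)
    violations: list[str] = []
    missing_cols = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing_cols:
        violations.append(f"missing columns: {missing_cols}")
        return SchemaReport(violations)
    for col in ("x_mm", "y_mm", "z_mm", "true_volume_l"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        for row in bad:
            violations.append(f"non-numeric {col} at row {row + 2}")  # 1-based + header
        if df[col].isna().any():
            for row in df.index[df[col].isna()]:
                violations.append(f"missing {col} at row {row + 2}")
    unknown_methods = sorted(set(df["method"].unique()) - set(METHODS))
    if unknown_methods:
        violations.append(f"unknown methods: {unknown_methods}")
    keys = ["subject_id", "visit", "scan", "method"]
    for scan_key, group in df.groupby(keys, sort=True):
        n_ref = int((group["structure_id"] == REFERENCE_ID).sum())
        if n_ref != 1:
            violations.append(
                f"scan {scan_key}: expected exactly one {REFERENCE_ID}, found {n_ref}"
            )
        present = set(group["structure_id"])
        missing = [s for s in STRUCTURE_IDS if s not in present]
        if missing:
            violations.append(f"scan {scan_key}: missing structures {missing}")
    return SchemaReport(violations)
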