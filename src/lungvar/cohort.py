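"""Seeded synthetic cohorts emulating a breath-hold motion-mitigation study.

The generator produces landmark tables (one spinal reference plus nine mobile
lung structures per scan), per-scan total lung volumes, and ground-truth setup
transforms for a cohort of subjects imaged at weekly visits under two
motion-mitigation methods:

* ``eDIBH`` — enhanced deep-inspiration breath hold (active breath hold after
  hyperoxic hyperventilation),
* ``HFPV`` — high-frequency percussive ventilation (passive apnoea-like
  ventilation).

All positions are in millimetres in a patient-based right-handed frame with
RL = x (toward patient left), AP = y (toward posterior), CC = z (toward
superior).  The spinal reference structure (``Ref_SC``) and the auxiliary
spine points are motion-invariant by construction: they receive the per-visit
setup transform but no respiratory noise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .registration import RigidTransform

__all__ = [
    "METHODS",
    "SEXES",
    "REFERENCE_ID",
    "STRUCTURE_IDS",
    "LSC_IDS",
    "VESSEL_IDS",
    "SPINE_AUX_IDS",
    "LANDMARK_COLUMNS",
    "ConfigError",
    "CohortConfig",
    "SubjectAnatomy",
    "ScanRecord",
    "Cohort",
    "default_noise_model",
    "generate_cohort",
    "simulate_volume_drift",
]

METHODS = ("eDIBH", "HFPV")
SEXES = ("M", "F")

REFERENCE_ID = "Ref_SC"
STRUCTURE_IDS = (
    "Ref_SC",
    "Apex",
    "Carina",
    "Diaphragm",
    "Vessel_LU",
    "Vessel_LM",
    "Vessel_LL",
    "Vessel_RU",
    "Vessel_RM",
    "Vessel_RL",
)
LSC_IDS = tuple(s for s in STRUCTURE_IDS if s != REFERENCE_ID)
VESSEL_IDS = tuple(s for s in STRUCTURE_IDS if s.startswith("Vessel"))

#: Auxiliary paravertebral points used (with Ref_SC) for rigid registration.
SPINE_AUX_IDS = ("Spine_Aux1", "Spine_Aux2", "Spine_Aux3", "Spine_Aux4")

LANDMARK_COLUMNS = (
    "subject_id",
    "sex",
    "visit",
    "scan",
    "method",
    "structure_id",
    "x_mm",
    "y_mm",
    "z_mm",
    "true_volume_l",
)

# Canonical landmark template (mm), expressed relative to Ref_SC at the
# origin.  The six vessels occupy three cranio-caudal bands (upper/mid/lower)
# with one left (x > 0) and one right (x < 0) vessel per band; Ref_SC lies
# between the CC extremes of apex and diaphragm.
_TEMPLATE_OFFSETS: dict[str, tuple[float, float, float]] = {
    "Ref_SC": (0.0, 0.0, 0.0),
    "Apex": (-30.0, -60.0, 140.0),
    "Carina": (0.0, -50.0, 60.0),
    "Diaphragm": (-40.0, -55.0, -120.0),
    "Vessel_LU": (60.0, -55.0, 90.0),
    "Vessel_LM": (75.0, -45.0, 10.0),
    "Vessel_LL": (65.0, -40.0, -70.0),
    "Vessel_RU": (-60.0, -55.0, 90.0),
    "Vessel_RM": (-75.0, -45.0, 10.0),
    "Vessel_RL": (-70.0, -40.0, -70.0),
}

_SPINE_AUX_OFFSETS: dict[str, tuple[float, float, float]] = {
    "Spine_Aux1": (0.0, 2.0, 25.0),
    "Spine_Aux2": (0.0, 2.0, -25.0),
    "Spine_Aux3": (10.0, 5.0, 0.0),
    "Spine_Aux4": (-10.0, 5.0, 0.0),
}

# Default per-structure positional noise SDs (mm) per (method, structure):
# (RL, AP, CC).  Differences between methods are largest in AP/CC and at the
# diaphragm (~3x) and the lower vessels (~2x); apex and upper vessels barely
# differ between methods.
_DEFAULT_NOISE: dict[str, dict[str, tuple[float, float, float]]] = {
    "eDIBH": {
        "Apex": (1.5, 1.0, 1.0),
        "Carina": (1.0, 1.2, 1.5),
        "Diaphragm": (2.0, 2.5, 3.5),
        "Vessel_LU": (1.2, 1.0, 1.2),
        "Vessel_LM": (1.2, 1.3, 1.6),
        "Vessel_LL": (1.5, 2.0, 2.5),
        "Vessel_RU": (1.2, 1.0, 1.2),
        "Vessel_RM": (1.2, 1.3, 1.6),
        "Vessel_RL": (1.5, 2.0, 2.5),
    },
    "HFPV": {
        "Apex": (1.6, 1.1, 1.1),
        "Carina": (1.4, 1.9, 2.4),
        "Diaphragm": (5.0, 7.5, 10.5),
        "Vessel_LU": (1.3, 1.2, 1.4),
        "Vessel_LM": (1.6, 2.0, 2.6),
        "Vessel_LL": (3.0, 4.0, 5.0),
        "Vessel_RU": (1.3, 1.2, 1.4),
        "Vessel_RM": (1.3, 1.5, 1.9),
        "Vessel_RL": (3.0, 4.0, 5.0),
    },
}

_DEFAULT_VOLUME_MEAN = {
    "eDIBH": {"M": 6.5, "F": 4.5},
    "HFPV": {"M": 5.4, "F": 3.6},
}
_DEFAULT_VOLUME_SD = {"M": 1.25, "F": 0.8}
_DEFAULT_INTRAFRACTION_SD = {"eDIBH": 0.20, "HFPV": 0.40}


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


def default_noise_model() -> dict[str, dict[str, tuple[float, float, float]]]:
    """A fresh copy of the default per-method/structure/axis noise SDs (mm)."""
    return {m: dict(v) for m, v in _DEFAULT_NOISE.items()}


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    Defaults emulate the reference design: 21 subjects (12 M / 9 F), four
    weekly visits with two consecutive scans per method per visit, sex- and
    method-specific lung volumes (eDIBH ≈ 6.5 L men / 4.5 L women, HFPV about
    1 L lower), anisotropic per-structure positional noise (largest in CC/AP,
    2-3x larger under HFPV at the diaphragm and lower vessels), per-visit
    setup translations (3 mm SD) and small rotations (1.5° SD), and an
    intra-breath-hold volume drift bound of 5 % per 70 s.
    """

    n_subjects: int = 21
    sex_split: tuple[int, int] = (12, 9)  # (male, female)
    n_visits: int = 4
    scans_per_visit_per_method: int = 2
    structure_ids: tuple[str, ...] = STRUCTURE_IDS
    n_spine_aux: int = 4
    setup_translation_sd: float = 3.0  # mm per axis
    setup_rotation_sd: float = 1.5  # degrees per axis
    method_noise_sd: Mapping[str, Mapping[str, Sequence[float]]] = field(
        default_factory=default_noise_model
    )
    #: Optional extra isotropic SD (mm) for HFPV percussion micro-oscillation.
    percussion_extra_sd: float = 0.0
    volume_mean: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in _DEFAULT_VOLUME_MEAN.items()}
    )
    volume_sd: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_VOLUME_SD))
    visit_volume_sd: float = 0.15  # litres, between-visit
    intrafraction_volume_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_INTRAFRACTION_SD)
    )
    drift_fraction_per_70s: float = 0.05
    anatomy_scale_sd: float = 0.06
    anatomy_jitter_sd: float = 3.0  # mm, per-subject per-structure
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if sum(self.sex_split) != self.n_subjects:
            raise ConfigError(
                f"sex_split {self.sex_split} must sum to n_subjects={self.n_subjects}"
            )
        if min(self.sex_split) < 0:
            raise ConfigError("sex_split entries must be non-negative")
        if self.n_visits < 1:
            raise ConfigError("n_visits must be >= 1")
        if self.scans_per_visit_per_method < 1:
            raise ConfigError("scans_per_visit_per_method must be >= 1")
        if REFERENCE_ID not in self.structure_ids:
            raise ConfigError(f"structure_ids must contain the reference {REFERENCE_ID!r}")
        if sum(s == REFERENCE_ID for s in self.structure_ids) != 1:
            raise ConfigError("structure_ids must contain exactly one reference")
        if len(set(self.structure_ids)) != len(self.structure_ids):
            raise ConfigError("structure_ids must be unique")
        unknown = [s for s in self.structure_ids if s not in _TEMPLATE_OFFSETS]
        if unknown:
            raise ConfigError(f"structure_ids contains unknown structures {unknown}")
        if not 0 <= self.n_spine_aux <= len(SPINE_AUX_IDS):
            raise ConfigError(f"n_spine_aux must be in [0, {len(SPINE_AUX_IDS)}]")
        for name in ("setup_translation_sd", "setup_rotation_sd", "percussion_extra_sd",
                     "visit_volume_sd", "anatomy_scale_sd", "anatomy_jitter_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for method in METHODS:
            if method not in self.method_noise_sd:
                raise ConfigError(f"method_noise_sd missing method {method!r}")
            for sid in self.structure_ids:
                if sid == REFERENCE_ID:
                    continue
                sd = np.asarray(self._noise_sd(method, sid), dtype=float)
                if sd.shape != (3,) or np.any(sd < 0):
                    raise ConfigError(
                        f"method_noise_sd[{method!r}][{sid!r}] must be three SDs >= 0"
                    )
            if method not in self.volume_mean:
                raise ConfigError(f"volume_mean missing method {method!r}")
            if self.intrafraction_volume_sd.get(method, -1.0) < 0:
                raise ConfigError(f"intrafraction_volume_sd[{method!r}] must be >= 0")
        for sex in SEXES:
            if self.volume_sd.get(sex, -1.0) < 0:
                raise ConfigError(f"volume_sd[{sex!r}] must be >= 0")
        if not 0.0 <= self.drift_fraction_per_70s <= 0.10:
            raise ConfigError("drift_fraction_per_70s must be in [0, 0.10]")

    def _noise_sd(self, method: str, structure_id: str) -> np.ndarray:
        entry = self.method_noise_sd[method]
        sd = entry.get(structure_id)
        if sd is None:
            sd = entry.get("default", 0.0)
        sd = np.asarray(sd, dtype=float)
        if sd.ndim == 0:
            sd = np.repeat(sd, 3)
        return sd

    def to_json(self) -> str:
        """Stable JSON serialization (used for config hashing and CLI IO)."""

        def convert(obj):
            if isinstance(obj, Mapping):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, (tuple, list, np.ndarray)):
                return [convert(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return json.dumps(convert(dataclasses.asdict(self)), sort_keys=True)

    @classmethod
    def from_mapping(cls, data: Mapping) -> "CohortConfig":
        kwargs = dict(data)
        if "sex_split" in kwargs:
            kwargs["sex_split"] = tuple(kwargs["sex_split"])
        if "structure_ids" in kwargs:
            kwargs["structure_ids"] = tuple(kwargs["structure_ids"])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**kwargs)


@dataclass
class SubjectAnatomy:
    """Canonical (setup- and noise-free) landmark geometry of one subject."""

    subject_id: str
    sex: str
    canonical_positions: dict[str, np.ndarray]
    baseline_lung_volume: float  # litres, eDIBH baseline

    @property
    def reference_position(self) -> np.ndarray:
        return self.canonical_positions[REFERENCE_ID]


@dataclass
class ScanRecord:
    """One MRI acquisition: landmark table, true volume, true setup transform."""

    subject_id: str
    sex: str
    visit: int
    scan: int
    method: str
    landmarks: dict[str, np.ndarray]
    true_lung_volume: float
    applied_setup_transform: RigidTransform


class Cohort:
    """A generated cohort: anatomies, scan records, and a tidy landmark table."""

    def __init__(self, config: CohortConfig, anatomies: list[SubjectAnatomy],
                 scans: list[ScanRecord]):
        self.config = config
        self.anatomies = anatomies
        self.scans = scans
        self._landmarks: pd.DataFrame | None = None

    @property
    def landmarks(self) -> pd.DataFrame:
        """Tidy landmark table (one row per scan × structure)."""
        if self._landmarks is None:
            rows = []
            for rec in self.scans:
                for sid, pos in rec.landmarks.items():
                    rows.append(
                        (rec.subject_id, rec.sex, rec.visit, rec.scan, rec.method,
                         sid, pos[0], pos[1], pos[2], rec.true_lung_volume)
                    )
            self._landmarks = pd.DataFrame(rows, columns=list(LANDMARK_COLUMNS))
        return self._landmarks

    def anatomy(self, subject_id: str) -> SubjectAnatomy:
        for a in self.anatomies:
            if a.subject_id == subject_id:
                return a
        raise KeyError(subject_id)

    def to_csv(self, path) -> None:
        self.landmarks.round(6).to_csv(path, index=False)

    def iter_scans(self) -> Iterator[ScanRecord]:
        return iter(self.scans)


def _subject_anatomy(config: CohortConfig, subject_id: str, sex: str,
                     rng: np.random.Generator) -> SubjectAnatomy:
    scale_mean = 1.05 if sex == "M" else 0.93
    scale = max(0.5, scale_mean + config.anatomy_scale_sd * rng.standard_normal())
    ref = np.array([0.0, 60.0, 0.0])
    positions: dict[str, np.ndarray] = {}
    for sid in config.structure_ids:
        offset = np.asarray(_TEMPLATE_OFFSETS[sid], dtype=float)
        jitter = (
            config.anatomy_jitter_sd * rng.standard_normal(3)
            if sid != REFERENCE_ID
            else np.zeros(3)
        )
        positions[sid] = ref + scale * offset + jitter
    for sid in SPINE_AUX_IDS[: config.n_spine_aux]:
        positions[sid] = ref + np.asarray(_SPINE_AUX_OFFSETS[sid], dtype=float)
    base_mean = config.volume_mean["eDIBH"][sex]
    baseline = max(1.0, base_mean + config.volume_sd[sex] * rng.standard_normal())
    return SubjectAnatomy(subject_id, sex, positions, baseline)


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate a deterministic synthetic cohort.

    Per scan, each mobile structure's position is
    ``canonical + setup transform (shared within a visit) + Gaussian noise``
    with method/structure/axis-specific noise SDs; Ref_SC and the auxiliary
    spine points receive the setup transform but no respiratory noise.  Per
    scan, the true lung volume is the subject/method baseline plus between-
    visit and within-visit Gaussian components.

    Parameters
    ----------
    config
        Cohort configuration; defaults describe the reference design.
    seed
        Overrides ``config.seed`` when given.
    """
    config = config if config is not None else CohortConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_male, n_female = config.sex_split
    sexes = ["M"] * n_male + ["F"] * n_female
    anatomies = [
        _subject_anatomy(config, f"S{idx + 1:03d}", sex, rng)
        for idx, sex in enumerate(sexes)
    ]

    mobile_ids = [s for s in config.structure_ids if s != REFERENCE_ID]
    rigid_ids = [REFERENCE_ID] + list(SPINE_AUX_IDS[: config.n_spine_aux])

    scans: list[ScanRecord] = []
    for anatomy in anatomies:
        ref = anatomy.reference_position
        # Subject effect is shared between methods (same lungs); the method
        # offset shifts the mean.
        subject_effect = anatomy.baseline_lung_volume - config.volume_mean["eDIBH"][anatomy.sex]
        for visit in range(1, config.n_visits + 1):
            if visit == 1:
                transform = RigidTransform.identity(
                    fixed_frame="visit1", moving_frame="visit1"
                )
            else:
                angles = config.setup_rotation_sd * rng.standard_normal(3)
                translation = config.setup_translation_sd * rng.standard_normal(3)
                transform = RigidTransform.from_euler(
                    angles, translation=translation, center=ref,
                    fixed_frame="visit1", moving_frame=f"visit{visit}",
                )
            for method in METHODS:
                visit_effect = config.visit_volume_sd * rng.standard_normal()
                method_mean = config.volume_mean[method][anatomy.sex]
                for scan in range(1, config.scans_per_visit_per_method + 1):
                    landmarks: dict[str, np.ndarray] = {}
                    for sid in rigid_ids:
                        landmarks[sid] = transform.apply(anatomy.canonical_positions[sid])
                    for sid in mobile_ids:
                        sd = config._noise_sd(method, sid).copy()
                        if method == "HFPV" and config.percussion_extra_sd > 0:
                            sd = np.sqrt(sd**2 + config.percussion_extra_sd**2)
                        noise = sd * rng.standard_normal(3)
                        landmarks[sid] = (
                            transform.apply(anatomy.canonical_positions[sid]) + noise
                        )
                    volume = (
                        method_mean
                        + subject_effect
                        + visit_effect
                        + config.intrafraction_volume_sd[method] * rng.standard_normal()
                    )
                    scans.append(
                        ScanRecord(
                            subject_id=anatomy.subject_id,
                            sex=anatomy.sex,
                            visit=visit,
                            scan=scan,
                            method=method,
                            landmarks=landmarks,
                            true_lung_volume=max(0.5, volume),
                            applied_setup_transform=transform,
                        )
                    )
    return Cohort(config, anatomies, scans)


def simulate_volume_drift(
    initial_volume: float,
    duration: float,
    drift_fraction_per_70s: float,
    dt: float = 70.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear intra-breath-hold lung volume drift.

    ``V(t) = V0 * (1 - f * t / 70)`` (clipped at zero), so the fractional
    decrease over any 70 s window, relative to the initial volume, equals the
    configured bound ``f``.

    Returns
    -------
    (times, volumes)
        Sample times (s) from 0 to ``duration`` in steps of ``dt``, and the
        volume trajectory (litres); monotone non-increasing.
    """
    if initial_volume <= 0:
        raise ValueError("initial_volume must be > 0")
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if drift_fraction_per_70s < 0:
        raise ValueError("drift_fraction_per_70s must be >= 0")
    n = int(np.floor(duration / dt + 1e-9))
    times = np.arange(n + 1) * dt
    if times[-1] < duration - 1e-9:
        times = np.append(times, duration)
    volumes = initial_volume * np.clip(1.0 - drift_fraction_per_70s * times / 70.0, 0.0, None)
    return times, volumes
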