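"""Synthetic serial-CT esophagus cohorts with a controllable radiosensitivity structure.

The generator emulates a thoracic chemoradiation cohort observed with weekly
CT during treatment: each patient has a baseline esophagus segmentation, a
planned dose grid on the same voxel lattice, weekly follow-up segmentations
in which the esophagus swells in the high-dose region, clinical covariates,
and a maximum esophagitis grade.

The statistical structure is deliberately simple but controllable:

* a latent three-class radiosensitivity mixture (sensitive / normal /
  resistant) sets both the expansion-per-dose slope and the range of
  delivered subvolume dose, producing three components in
  (mean subvolume dose, mean subvolume expansion) space;
* swelling is localized to the dose peak and applied as an in-plane dilation
  of the cross-section, so downstream area-based expansion metrics see a
  dose-shaped axial profile;
* a fixed number of low-dose patients (dose peak displaced off the
  esophagus, amplitude scaled so the delivered subvolume mean stays below
  20 Gy) are constructed explicitly, all asymptomatic (grade 0);
* maximum esophagitis grade >= 3 follows a logistic model on delivered
  subvolume dose plus a sensitive-class boost; the grade-0-vs-2 split among
  the remainder follows a second dose-only logistic. Grade 1 is never
  generated.

Per-patient randomness is derived from the master seed by a counter scheme
(``seed_seq = [master_seed, patient_index]``), so a cohort is bit-reproducible
and stable under partial regeneration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import DoseGrid, EsophagusGeometry

__all__ = [
    "GradeModel",
    "GeneratorConfig",
    "PatientClinical",
    "SerialEsophagusStudy",
    "InfeasibleConfigError",
    "CohortSchemaError",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

CLASSES = ("sensitive", "normal", "resistant")
SMOKING_LEVELS = ("never", "former", "current")
HISTOLOGIES = ("squamous", "adeno", "large cell", "other")
STAGES = ("IIA", "IIB", "IIIA", "IIIB", "IV")
TUMOR_LOCATIONS = (
    "left lateral",
    "right lateral",
    "left medial",
    "right medial",
    "left upper",
    "right upper",
)


class InfeasibleConfigError(ValueError):
    """The generator configuration cannot produce a valid cohort."""


class CohortSchemaError(ValueError):
    """A cohort file violates the cohort schema."""


@dataclass(frozen=True)
class GradeModel:
    """Logistic outcome model for maximum esophagitis grade.

    ``P(grade >= 3) = sigmoid(grade3_intercept + grade3_dose_coef * D
    + grade3_sensitive_coef * 1[sensitive])`` with D the delivered mean
    subvolume dose in Gy at the analysis scan.  Patients below grade 3 are
    grade 2 with probability ``sigmoid(grade2_intercept + grade2_dose_coef * D)``
    and grade 0 otherwise.  Intercepts are calibrated by simulation so a
    default cohort lands near the 33/75/26 grade-0/2/3 composition.
    """

    grade3_intercept: float = -4.95
    grade3_dose_coef: float = 0.06
    grade3_sensitive_coef: float = 2.5
    grade2_intercept: float = -2.62
    grade2_dose_coef: float = 0.09


def _default_prescription_mix() -> dict[int, float]:
    # 74/66/60 Gy at the cohort's 88/38/8 composition
    return {74: 88 / 134, 66: 38 / 134, 60: 8 / 134}


def _default_class_proportions() -> dict[str, float]:
    return {"sensitive": 0.20, "normal": 0.30, "resistant": 0.50}


def _default_class_slopes() -> dict[str, float]:
    # percent expansion per delivered Gy
    return {"sensitive": 1.6, "normal": 0.55, "resistant": 0.8}


def _default_class_dose_ranges() -> dict[str, tuple[float, float]]:
    # delivered mean subvolume dose (Gy) at the analysis scan
    return {"sensitive": (35.0, 55.0), "normal": (22.0, 42.0), "resistant": (42.0, 62.0)}


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic cohort generator.

    Physical dimensions are mm; doses are Gy; expansions are percent.
    """

    n_patients: int = 134
    prescription_mix: dict[int, float] = field(default_factory=_default_prescription_mix)
    fraction_size: float = 2.0
    slice_thickness: float = 2.5
    in_plane_spacing: float = 0.98
    n_slices: int = 80
    in_plane_size: int = 64
    weekly_scan_fractions: tuple[int, ...] | None = None  # None -> multiples of 5
    latent_class_proportions: dict[str, float] = field(
        default_factory=_default_class_proportions
    )
    class_expansion_slope: dict[str, float] = field(default_factory=_default_class_slopes)
    class_dose_ranges: dict[str, tuple[float, float]] = field(
        default_factory=_default_class_dose_ranges
    )
    expansion_noise_sd: float = 26.0  # calibrated to ~30% within-10-Gy-bin SD
    slice_noise_frac: float = 0.05  # relative per-slice roughness; 0 when noise is 0
    swelling_profile_width: float = 30.0  # axial sigma of the dose falloff, mm
    in_plane_dose_sigma: float = 35.0  # transverse sigma of the dose falloff, mm
    grade_model: GradeModel = field(default_factory=GradeModel)
    n_low_dose_patients: int = 8
    low_dose_range: tuple[float, float] = (8.0, 16.0)  # delivered Gy, always < 20
    target_scan_fraction: int = 30
    seed: int = 0

    # geometry plausibility knobs
    z_margin: int = 4  # empty slices at each axial end
    radius_range_mm: tuple[float, float] = (6.0, 11.0)

    def validate(self) -> None:
        for name, props in (
            ("prescription_mix", self.prescription_mix),
            ("latent_class_proportions", self.latent_class_proportions),
        ):
            total = float(sum(props.values()))
            if abs(total - 1.0) > 1e-9:
                raise InfeasibleConfigError(f"{name} must sum to 1 (got {total})")
            if any(p < 0 for p in props.values()):
                raise InfeasibleConfigError(f"{name} has a negative proportion")
        if set(self.latent_class_proportions) != set(CLASSES):
            raise InfeasibleConfigError(
                f"latent_class_proportions must cover exactly {CLASSES}"
            )
        if not 0 <= self.n_low_dose_patients < self.n_patients:
            raise InfeasibleConfigError("n_low_dose_patients must be < n_patients")
        for dim in (self.slice_thickness, self.in_plane_spacing, self.fraction_size):
            if dim <= 0:
                raise InfeasibleConfigError("all physical dimensions must be positive")
        if self.n_slices <= 2 * self.z_margin + 16:
            raise InfeasibleConfigError("n_slices too small for the contoured extent")
        n_classed = self.n_patients - self.n_low_dose_patients
        for cls, p in self.latent_class_proportions.items():
            if p > 0 and p * n_classed < 1:
                raise InfeasibleConfigError(
                    f"class '{cls}' with proportion {p} is expected empty at "
                    f"n={n_classed}; increase n_patients or the proportion"
                )
        if not (0 < self.low_dose_range[0] <= self.low_dose_range[1] < 20):
            raise InfeasibleConfigError("low_dose_range must lie in (0, 20) Gy")

    @classmethod
    def informative_tag(cls, seed: int = 0) -> "GeneratorConfig":
        """The model-comparison study condition: a strongly informative tag.

        Differs from the default cohort on two calibrated axes. The
        grade-model coupling is strengthened (latent sensitive-class
        log-odds 4.0, dose log-odds 0.09/Gy, intercept recalibrated by
        simulation to preserve the ~26/134 grade-3 rate), and the expansion
        noise SD is reduced to 15% so the clusters track the latent classes
        reliably. Both are needed: clustering attenuates latent coupling
        through misassignment, and at the default 26% noise the realized
        *tag*-level endpoint odds ratio swings between ~3 and ~19 across
        cohort seeds. At 15% it stays >= ~8 — a strongly informative tag —
        while the dose metrics remain genuinely predictive on their own, as
        in the modelled comparison.
        """
        cfg = cls(seed=seed)
        cfg.expansion_noise_sd = 15.0
        cfg.grade_model = GradeModel(
            grade3_intercept=-6.95, grade3_dose_coef=0.09, grade3_sensitive_coef=4.0
        )
        return cfg

    @classmethod
    def separated(cls, seed: int = 0, **overrides) -> "GeneratorConfig":
        """A configuration with well-separated latent classes.

        Class expansion levels differ by far more than three generator noise
        SDs and the delivered-dose ranges do not overlap, so the latent
        mixture is recoverable by clustering. Only the analysis-time scan is
        generated, which keeps multi-cohort studies fast.
        """
        cfg = cls(
            class_expansion_slope={"sensitive": 2.0, "normal": 0.5, "resistant": 0.8},
            class_dose_ranges={
                "sensitive": (38.0, 46.0),
                "normal": (22.0, 30.0),
                "resistant": (52.0, 60.0),
            },
            expansion_noise_sd=5.0,
            weekly_scan_fractions=(30,),
            in_plane_size=48,
            seed=seed,
        )
        for key, value in overrides.items():
            setattr(cfg, key, value)
        return cfg


@dataclass(eq=True)
class PatientClinical:
    """Clinical covariates for one patient."""

    age: int
    gender: str  # "male" / "female"
    smoking_status: str
    induction_chemo: int
    gtv_volume: float  # cm^3
    histology: str
    nodal_involvement: int
    stage: str
    tumor_location: str
    prescription_dose: float  # Gy
    total_fractions: int

    def __post_init__(self) -> None:
        checks = {
            "smoking_status": SMOKING_LEVELS,
            "histology": HISTOLOGIES,
            "stage": STAGES,
            "tumor_location": TUMOR_LOCATIONS,
            "gender": ("male", "female"),
        }
        for fname, allowed in checks.items():
            if getattr(self, fname) not in allowed:
                raise CohortSchemaError(
                    f"{fname}={getattr(self, fname)!r} not in {allowed}"
                )
        if self.total_fractions != int(round(self.prescription_dose / 2.0)):
            raise CohortSchemaError(
                "total_fractions must equal prescription_dose / 2 Gy exactly"
            )


@dataclass(eq=False)
class SerialEsophagusStudy:
    """One patient's serial geometries, planned dose, covariates and outcome.

    ``latent_class`` is generator-only ground truth for testing and
    calibration; no analysis stage may consume it.
    """

    patient_id: str
    clinical: PatientClinical
    baseline_geometry: EsophagusGeometry
    followups: list[tuple[int, EsophagusGeometry]]
    planned_dose: DoseGrid
    max_grade: int
    latent_class: str

    def __post_init__(self) -> None:
        self.planned_dose.check_aligned(self.baseline_geometry)
        fractions = [f for f, _ in self.followups]
        if any(b <= a for a, b in zip(fractions, fractions[1:])):
            raise CohortSchemaError(
                f"patient {self.patient_id}: follow-up fractions must be strictly increasing"
            )
        if fractions and fractions[-1] > self.clinical.total_fractions:
            raise CohortSchemaError(
                f"patient {self.patient_id}: follow-up fraction beyond total_fractions"
            )
        if self.max_grade not in (0, 2, 3, 4, 5):
            raise CohortSchemaError(
                f"patient {self.patient_id}: max_grade {self.max_grade} invalid"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SerialEsophagusStudy):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.clinical == other.clinical
            and self.baseline_geometry == other.baseline_geometry
            and len(self.followups) == len(other.followups)
            and all(
                fa == fb and ga == gb
                for (fa, ga), (fb, gb) in zip(self.followups, other.followups)
            )
            and self.planned_dose == other.planned_dose
            and self.max_grade == other.max_grade
            and self.latent_class == other.latent_class
        )


def _sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def _nearest_fraction(fractions: list[int], target: int) -> int:
    """Fraction index nearest the target; ties resolve to the later fraction."""
    return max(fractions, key=lambda f: (-abs(f - target), f))


def _draw_clinical(rng: np.random.Generator, cfg: GeneratorConfig) -> PatientClinical:
    prescriptions = sorted(cfg.prescription_mix)
    probs = np.array([cfg.prescription_mix[p] for p in prescriptions], dtype=float)
    prescription = float(rng.choice(prescriptions, p=probs / probs.sum()))
    return PatientClinical(
        age=int(np.clip(round(rng.normal(66.0, 9.0)), 38, 85)),
        gender="male" if rng.random() < 75 / 134 else "female",
        smoking_status=str(
            rng.choice(SMOKING_LEVELS, p=np.array([11, 79, 44]) / 134.0)
        ),
        induction_chemo=int(rng.random() < 0.35),
        gtv_volume=float(np.round(np.exp(rng.normal(4.5, 0.6)), 2)),
        histology=str(rng.choice(HISTOLOGIES, p=np.array([47, 75, 5, 7]) / 134.0)),
        nodal_involvement=int(rng.random() < 0.80),
        stage=str(rng.choice(STAGES, p=np.array([5, 9, 59, 56, 5]) / 134.0)),
        tumor_location=str(rng.choice(TUMOR_LOCATIONS)),
        prescription_dose=prescription,
        total_fractions=int(round(prescription / cfg.fraction_size)),
    )


def _build_masks(
    cfg: GeneratorConfig,
    radii_mm: np.ndarray,
    cy: np.ndarray,
    cx: np.ndarray,
) -> np.ndarray:
    """Binary masks from per-slice radii (mm) and sub-pixel centerline (px)."""
    n = cfg.in_plane_size
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    d2 = (yy[None] - cy[:, None, None]) ** 2 + (xx[None] - cx[:, None, None]) ** 2
    r_px = radii_mm / cfg.in_plane_spacing
    return d2 <= (r_px**2)[:, None, None]


def _subvolume_slices(center: int, n_slices: int, edge_mm: float, thickness: float):
    """Half-open slice window [center - edge/2, center + edge/2)."""
    half = edge_mm / 2.0
    lo = int(np.ceil(center - half / thickness - 1e-9))
    hi = int(np.ceil(center + half / thickness - 1e-9))
    return np.arange(max(lo, 0), min(hi, n_slices))


def _simulate_patient(
    index: int,
    cfg: GeneratorConfig,
    latent_class: str,
    low_dose: bool,
) -> SerialEsophagusStudy:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, index]))
    clinical = _draw_clinical(rng, cfg)
    tf = clinical.total_fractions
    if cfg.weekly_scan_fractions is None:
        scans = list(range(5, tf + 1, 5))
    else:
        scans = sorted(f for f in cfg.weekly_scan_fractions if f <= tf)
    if not scans:
        raise InfeasibleConfigError("no scan fractions at or below total_fractions")
    f_ref = _nearest_fraction(scans, cfg.target_scan_fraction)

    nz, npx = cfg.n_slices, cfg.in_plane_size
    z = np.arange(nz, dtype=float)
    z0, z1 = cfg.z_margin, nz - cfg.z_margin

    # baseline anatomy: smooth radius profile + slowly wandering centerline
    r_lo, r_hi = cfg.radius_range_mm
    base_r = rng.uniform(r_lo + 1.0, r_hi - 1.0)
    phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
    radii = base_r + 1.0 * np.sin(2 * np.pi * z / 40.0 + phase1)
    radii = np.clip(radii, r_lo, r_hi)
    radii[:z0] = 0.0
    radii[z1:] = 0.0
    cy = npx / 2.0 + 2.5 * np.sin(2 * np.pi * z / 60.0 + phase2) + rng.uniform(-0.5, 0.5)
    cx = npx / 2.0 + 2.5 * np.cos(2 * np.pi * z / 55.0 + phase1) + rng.uniform(-0.5, 0.5)

    baseline_mask = _build_masks(cfg, radii, cy, cx)
    baseline = EsophagusGeometry(baseline_mask, cfg.slice_thickness, cfg.in_plane_spacing)

    # dose field: 3-D Gaussian-falloff high-dose region around a mid-esophagus
    # peak, riding on an axial background bath along the contoured esophagus.
    # The background keeps every possible analysis window of a non-low-dose
    # patient above the 20 Gy exclusion threshold by construction, so the
    # excluded set is exactly the constructed low-dose patients.
    z_peak = int(rng.integers(z0 + 9, z1 - 10))
    sigma_z = cfg.swelling_profile_width / cfg.slice_thickness
    sigma_r = cfg.in_plane_dose_sigma / cfg.in_plane_spacing
    if low_dose:
        axis_y = cy[z_peak] + 25.0 / cfg.in_plane_spacing  # peak displaced off-esophagus
        axis_x = cx[z_peak]
        target_delivered = rng.uniform(*cfg.low_dose_range)
        base_frac = 0.0
    else:
        axis_y, axis_x = cy[z_peak], cx[z_peak]
        target_delivered = rng.uniform(*cfg.class_dose_ranges[latent_class])
        base_frac = float(np.clip(22.0 / target_delivered, 0.3, 1.0))

    yy, xx = np.mgrid[0:npx, 0:npx].astype(float)
    radial = np.exp(-((yy - axis_y) ** 2 + (xx - axis_x) ** 2) / (2 * sigma_r**2))
    axial = base_frac + (1.0 - base_frac) * np.exp(-((z - z_peak) ** 2) / (2 * sigma_z**2))
    unit = axial[:, None, None] * radial[None]

    window = _subvolume_slices(z_peak, nz, 20.0, cfg.slice_thickness)
    in_window = baseline_mask[window]
    unit_sub_mean = float(unit[window][in_window].mean())
    target_planned = target_delivered / (f_ref / tf)
    amplitude = target_planned / unit_sub_mean
    dose_values = (amplitude * unit).astype(np.float32)
    dose = DoseGrid(dose_values)

    # per-slice planned dose over the baseline cross-section
    counts = baseline_mask.sum(axis=(1, 2))
    dose_profile = np.zeros(nz)
    nonempty = counts > 0
    dose_profile[nonempty] = (
        dose_values * baseline_mask
    ).sum(axis=(1, 2))[nonempty] / counts[nonempty]

    # Between-patient response heterogeneity: a mean-one lognormal factor on
    # the expansion-per-dose response, with sigma set so the absolute SD of
    # the analysis-scan subvolume expansion equals expansion_noise_sd. A
    # multiplicative factor keeps the axial expansion profile dose-peaked and
    # non-negative, so the low-dose construction stays exact.
    slope = cfg.class_expansion_slope[latent_class]
    amplitude_pct = slope * target_delivered
    if cfg.expansion_noise_sd > 0 and amplitude_pct > 0:
        sigma = min(
            np.sqrt(np.log1p((cfg.expansion_noise_sd / amplitude_pct) ** 2)), 1.6
        )
        response_factor = float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
        rel_jitter = cfg.slice_noise_frac
    else:
        response_factor, rel_jitter = 1.0, 0.0

    followups: list[tuple[int, EsophagusGeometry]] = []
    for f in scans:
        delivered_profile = dose_profile * (f / tf)
        jitter = rng.normal(0.0, rel_jitter, size=nz) if rel_jitter else np.zeros(nz)
        e = slope * response_factor * delivered_profile * (1.0 + jitter)
        e = np.clip(e, -90.0, None)
        r_f = radii * np.sqrt(1.0 + e / 100.0)
        geom = EsophagusGeometry(
            _build_masks(cfg, r_f, cy, cx), cfg.slice_thickness, cfg.in_plane_spacing
        )
        followups.append((f, geom))

    # outcome at the analysis scan, driven by the designed subvolume dose
    gm = cfg.grade_model
    if low_dose:
        grade = 0
    else:
        d_sub = target_delivered
        p3 = _sigmoid(
            gm.grade3_intercept
            + gm.grade3_dose_coef * d_sub
            + gm.grade3_sensitive_coef * (latent_class == "sensitive")
        )
        if rng.random() < p3:
            grade = 3
        else:
            p2 = _sigmoid(gm.grade2_intercept + gm.grade2_dose_coef * d_sub)
            grade = 2 if rng.random() < p2 else 0

    return SerialEsophagusStudy(
        patient_id=f"P{index:03d}",
        clinical=clinical,
        baseline_geometry=baseline,
        followups=followups,
        planned_dose=dose,
        max_grade=grade,
        latent_class="normal" if low_dose else latent_class,
    )


def generate_cohort(config: GeneratorConfig) -> list[SerialEsophagusStudy]:
    """Generate a seeded synthetic cohort.

    Deterministic for a fixed ``config.seed``. Exactly
    ``config.n_low_dose_patients`` patients are constructed with a delivered
    mean subvolume dose below 20 Gy, all grade 0.
    """
    config.validate()
    master = np.random.default_rng(np.random.SeedSequence([config.seed, 2**20]))
    n = config.n_patients
    low_dose_ids = set(
        master.choice(n, size=config.n_low_dose_patients, replace=False).tolist()
    )
    probs = np.array([config.latent_class_proportions[c] for c in CLASSES])
    classes = master.choice(len(CLASSES), size=n, p=probs / probs.sum())

    classed = [CLASSES[classes[i]] for i in range(n) if i not in low_dose_ids]
    for cls, p in config.latent_class_proportions.items():
        if p > 0 and cls not in classed:
            raise InfeasibleConfigError(
                f"latent class '{cls}' (proportion {p}) drew no members at "
                f"n={len(classed)}; the configuration is infeasible"
            )
    return [
        _simulate_patient(i, config, CLASSES[classes[i]], i in low_dose_ids)
        for i in range(n)
    ]


def slice_area_table(study: SerialEsophagusStudy):
    """Slice-indexed cross-sectional areas (mm^2) for human inspection.

    One row per axial slice (0 = most superior), one column for the baseline
    and one per follow-up scan; export with ``.to_csv``.
    """
    import pandas as pd

    data = {"baseline_mm2": study.baseline_geometry.areas_mm2()}
    for frac, geom in study.followups:
        data[f"fraction_{frac}_mm2"] = geom.areas_mm2()
    frame = pd.DataFrame(data)
    frame.index.name = "slice"
    return frame


# ---------------------------------------------------------------------------
# Cohort container I/O: a JSON manifest plus one .npz of arrays per patient.
# ---------------------------------------------------------------------------

_CLINICAL_FIELDS = [f.name for f in dataclasses.fields(PatientClinical)]


def write_cohort(cohort: list[SerialEsophagusStudy], path: str | Path) -> Path:
    """Write a cohort to ``path`` (a directory): manifest.json + per-patient npz.

    Masks are stored as uint8 and doses at their native dtype, so
    ``read_cohort(write_cohort(x)) == x`` exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"schema": "esotox-cohort/1", "patients": []}
    for study in cohort:
        arr_name = f"{study.patient_id}.npz"
        arrays = {
            "baseline_mask": study.baseline_geometry.slice_masks.astype(np.uint8),
            "dose": study.planned_dose.values,
            "followup_fractions": np.array([f for f, _ in study.followups], dtype=np.int64),
        }
        for k, (_, geom) in enumerate(study.followups):
            arrays[f"followup_mask_{k}"] = geom.slice_masks.astype(np.uint8)
        np.savez_compressed(path / arr_name, **arrays)
        manifest["patients"].append(
            {
                "patient_id": study.patient_id,
                "clinical": dataclasses.asdict(study.clinical),
                "slice_thickness": study.baseline_geometry.slice_thickness,
                "in_plane_spacing": study.baseline_geometry.in_plane_spacing,
                "max_grade": study.max_grade,
                "latent_class": study.latent_class,
                "arrays": arr_name,
            }
        )
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path


def read_cohort(path: str | Path) -> list[SerialEsophagusStudy]:
    """Read a cohort written by :func:`write_cohort`, validating the schema."""
    path = Path(path)
    try:
        with open(path / "manifest.json") as fh:
            manifest = json.load(fh)
    except FileNotFoundError as exc:
        raise CohortSchemaError(f"no manifest.json under {path}") from exc
    if manifest.get("schema") != "esotox-cohort/1":
        raise CohortSchemaError(f"unknown cohort schema {manifest.get('schema')!r}")
    cohort = []
    for rec in manifest["patients"]:
        pid = rec.get("patient_id", "<missing id>")
        for fname in ("clinical", "slice_thickness", "in_plane_spacing", "max_grade",
                      "arrays", "latent_class"):
            if fname not in rec:
                raise CohortSchemaError(f"patient {pid}: missing field '{fname}'")
        missing = [f for f in _CLINICAL_FIELDS if f not in rec["clinical"]]
        if missing:
            raise CohortSchemaError(
                f"patient {pid}: missing clinical field '{missing[0]}'"
            )
        clinical = PatientClinical(**{f: rec["clinical"][f] for f in _CLINICAL_FIELDS})
        with np.load(path / rec["arrays"]) as data:
            thickness, spacing = rec["slice_thickness"], rec["in_plane_spacing"]
            baseline = EsophagusGeometry(
                data["baseline_mask"].astype(bool), thickness, spacing
            )
            fractions = data["followup_fractions"].tolist()
            followups = [
                (
                    int(f),
                    EsophagusGeometry(
                        data[f"followup_mask_{k}"].astype(bool), thickness, spacing
                    ),
                )
                for k, f in enumerate(fractions)
            ]
            dose = DoseGrid(data["dose"])
        cohort.append(
            SerialEsophagusStudy(
                patient_id=rec["patient_id"],
                clinical=clinical,
                baseline_geometry=baseline,
                followups=followups,
                planned_dose=dose,
                max_grade=int(rec["max_grade"]),
                latent_class=rec["latent_class"],
            )
        )
    return cohort
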