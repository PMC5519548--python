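"""Esophageal expansion dose-response quantification.

Expansion is a CT-derived surrogate of radiation-induced esophageal swelling:
for each axial slice z the percent relative change in cross-sectional area
between the baseline (planning) segmentation and a follow-up segmentation,

    e(z) = 100 * (A_followup(z) - A_baseline(z)) / A_baseline(z).

The per-patient summary — the *expansion-response* — is the pair
(mean expansion %, mean delivered dose Gy) over an isotropic subvolume
centered at the slice of maximum axial expansion, evaluated at the imaging
time point nearest treatment fraction 30.  Delivered dose is the planned
voxel dose scaled by the fraction of treatment delivered at that scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DoseGrid, EsophagusGeometry, LatticeMismatchError
from .simulate import SerialEsophagusStudy

__all__ = [
    "ExpansionProfile",
    "ExpansionResponse",
    "axial_expansion_profile",
    "select_scan_nearest_fraction",
    "locate_max_expansion_slice",
    "subvolume_response",
    "quantify_cohort",
]


@dataclass(eq=False)
class ExpansionProfile:
    """Per-slice percent expansion e(z); NaN where baseline area is zero."""

    values: np.ndarray  # (n_slices,), percent; NaN = undefined

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ExpansionResponse:
    """Summary of one patient's expansion dose-response."""

    mean_expansion: float  # percent
    mean_delivered_dose: float  # Gy
    scan_fraction: int
    subvolume_slices: tuple[int, int]  # half-open [start, stop)
    center_slice: int
    patient_id: str = ""


def axial_expansion_profile(
    baseline: EsophagusGeometry, followup: EsophagusGeometry
) -> ExpansionProfile:
    """Percent relative cross-sectional area change per axial slice.

    Slices with zero baseline area are undefined (NaN), never zero-filled.
    """
    if not baseline.same_lattice(followup):
        raise LatticeMismatchError("baseline and follow-up lattices differ")
    a0 = baseline.voxel_counts().astype(float)
    a1 = followup.voxel_counts().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = 100.0 * (a1 - a0) / a0
    e[a0 == 0] = np.nan
    return ExpansionProfile(e)


def select_scan_nearest_fraction(
    followups: list[tuple[int, EsophagusGeometry]], target_fraction: int = 30
) -> tuple[int, EsophagusGeometry]:
    """Follow-up nearest the target fraction; ties resolve to the later scan."""
    if not followups:
        raise ValueError("no follow-up scans available")
    return max(followups, key=lambda fg: (-abs(fg[0] - target_fraction), fg[0]))


def locate_max_expansion_slice(profile: ExpansionProfile) -> int:
    """Index of the maximum-expansion slice; ties resolve most superior."""
    if not profile.defined.any():
        raise ValueError("expansion profile is undefined on every slice")
    values = np.where(profile.defined, profile.values, -np.inf)
    return int(np.argmax(values))  # argmax returns the first (most superior) tie


def _subvolume_window(
    center: int, n_slices: int, edge_mm: float, slice_thickness: float
) -> tuple[int, int]:
    """Half-open slice range covering [center - edge/2, center + edge/2)."""
    half = edge_mm / 2.0
    lo = int(np.ceil(center - half / slice_thickness - 1e-9))
    hi = int(np.ceil(center + half / slice_thickness - 1e-9))
    return max(lo, 0), min(hi, n_slices)


def subvolume_response(
    profile: ExpansionProfile,
    baseline: EsophagusGeometry,
    dose: DoseGrid,
    center: int,
    scan_fraction: int,
    total_fractions: int,
    edge_mm: float = 20.0,
    patient_id: str = "",
) -> ExpansionResponse:
    """Mean expansion and mean delivered dose over the isotropic subvolume.

    The subvolume is the set of axial slices within ``edge_mm`` (half-open
    about the center slice), intersected with the baseline esophagus mask.
    Delivered dose scales the planned dose by ``scan_fraction / total_fractions``.
    """
    dose.check_aligned(baseline)
    if not 0 <= center < baseline.n_slices:
        raise ValueError(f"center slice {center} outside [0, {baseline.n_slices})")
    if edge_mm <= baseline.slice_thickness:
        raise ValueError("subvolume edge must exceed the slice thickness")
    lo, hi = _subvolume_window(center, baseline.n_slices, edge_mm, baseline.slice_thickness)
    sub_mask = baseline.slice_masks[lo:hi]
    if not sub_mask.any():
        raise ValueError("subvolume contains no esophagus voxels")
    e_sub = profile.values[lo:hi]
    defined = ~np.isnan(e_sub)
    if not defined.any():
        raise ValueError("subvolume expansion undefined on every slice")
    mean_exp = float(e_sub[defined].mean())
    planned_mean = float(dose.values[lo:hi][sub_mask].mean())
    return ExpansionResponse(
        mean_expansion=mean_exp,
        mean_delivered_dose=planned_mean * scan_fraction / total_fractions,
        scan_fraction=scan_fraction,
        subvolume_slices=(lo, hi),
        center_slice=center,
        patient_id=patient_id,
    )


def quantify_cohort(
    cohort: list[SerialEsophagusStudy],
    target_fraction: int = 30,
    edge_mm: float = 20.0,
) -> list[ExpansionResponse]:
    """Expansion-response for every patient at the scan nearest the target fraction."""
    responses = []
    for study in cohort:
        frac, followup = select_scan_nearest_fraction(study.followups, target_fraction)
        profile = axial_expansion_profile(study.baseline_geometry, followup)
        center = locate_max_expansion_slice(profile)
        responses.append(
            subvolume_response(
                profile,
                study.baseline_geometry,
                study.planned_dose,
                center,
                scan_fraction=frac,
                total_fractions=study.clinical.total_fractions,
                edge_mm=edge_mm,
                patient_id=study.patient_id,
            )
        )
    return responses
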