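"""NTCP predictor catalogue: clinical indicators, DVH and dose-length metrics.

The catalogue is a fixed, indexed set of 49 predictors (50 with the optional
dichotomous radiosensitivity tag): clinical covariates with every category
kept as its own indicator (no reference-category dropping; collinearity is
left to the L1 penalty), esophageal dose-volume metrics (MED, Dmax,
V10..V70 in 5-Gy steps, percent of esophagus volume), and dose-length
metrics LEx_y% — the esophageal length (cm) over which at least y% of the
slice's cross-sectional area receives at least x Gy.

Standardization is z-scoring with the population SD (divide by n), with
parameters fit on a designated row subset (the training set during
cross-validation) and applied to all rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import DoseGrid, EsophagusGeometry
from .simulate import (
    HISTOLOGIES,
    SMOKING_LEVELS,
    STAGES,
    TUMOR_LOCATIONS,
    SerialEsophagusStudy,
)

__all__ = [
    "PREDICTOR_CATALOGUE",
    "TAG_NAME",
    "FeatureMatrix",
    "dvh_metrics",
    "dose_length_metrics",
    "assemble_features",
    "standardize",
]

_V_LEVELS = tuple(range(10, 75, 5))  # V10 .. V70
_LE_LEVELS = (10, 20, 30, 40, 50, 60)

TAG_NAME = "Radiosensitivity Tag"

#: predictor index -> predictor name, in catalogue order
PREDICTOR_CATALOGUE: dict[int, str] = {
    1: "Smoking Status",
    2: "Induction Chemotherapy",
    3: "GTV",
    4: "Histology-other",
    5: "Histology-Large Cell",
    6: "Histology-Adenocarcinoma",
    7: "Histology-Squamous Cell",
    8: "Nodal Involvement",
    9: "Stage-IV",
    10: "Stage-IIIB",
    11: "Stage-IIIA",
    12: "Stage-IIB",
    13: "Stage-IIA",
    14: "Tumor Location-Left Lateral",
    15: "Tumor Location-Right Lateral",
    16: "Tumor Location-Left Medial",
    17: "Tumor Location-Right Medial",
    18: "Tumor Location-Left Upper",
    19: "Tumor Location-Right Upper",
    20: "Gender",
    21: "Age",
    **{21 + i: f"LE{x}_100%" for i, x in enumerate(reversed(_LE_LEVELS), start=1)},
    **{27 + i: f"LE{x}_25%" for i, x in enumerate(reversed(_LE_LEVELS), start=1)},
    **{33 + i: f"V{x}" for i, x in enumerate(reversed(_V_LEVELS), start=1)},
    47: "MED",
    48: "Dmax",
    49: "Prescription Dose",
    50: TAG_NAME,
}

_HISTOLOGY_ORDER = ("other", "large cell", "adeno", "squamous")  # indices 4..7
_STAGE_ORDER = ("IV", "IIIB", "IIIA", "IIB", "IIA")  # indices 9..13
_LOCATION_ORDER = TUMOR_LOCATIONS  # indices 14..19, catalogue order


@dataclass
class FeatureMatrix:
    """Cohort-by-predictor matrix with a stable predictor-index map.

    ``values`` columns follow catalogue index order. When standardized,
    ``means``/``sds`` hold the parameters (fit on ``fit_rows``) and
    ``constant_columns`` flags predictors with zero spread on that subset.
    """

    values: pd.DataFrame
    index_map: dict[int, str] = field(
        default_factory=lambda: dict(PREDICTOR_CATALOGUE)
    )
    means: pd.Series | None = None
    sds: pd.Series | None = None
    constant_columns: tuple[str, ...] = ()

    @property
    def has_tag(self) -> bool:
        return TAG_NAME in self.values.columns

    @property
    def n_predictors(self) -> int:
        return self.values.shape[1]

    def predictor_index(self, name: str) -> int:
        for idx, n in self.index_map.items():
            if n == name:
                return idx
        raise KeyError(name)

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def export(self, csv_path, params_path=None) -> None:
        """Write the matrix as CSV; standardization parameters as sidecar JSON."""
        import json

        self.values.to_csv(csv_path)
        if params_path is not None:
            if self.means is None:
                raise ValueError("matrix is not standardized; no parameters to export")
            with open(params_path, "w") as fh:
                json.dump(
                    {
                        "means": self.means.to_dict(),
                        "sds": self.sds.to_dict(),
                        "constant_columns": list(self.constant_columns),
                        "sd_denominator": "population (n)",
                    },
                    fh,
                    indent=1,
                    sort_keys=True,
                )


def dvh_metrics(dose: DoseGrid, geometry: EsophagusGeometry) -> dict[str, float]:
    """MED, Dmax and V10..V70 (percent of esophagus volume receiving >= x Gy)."""
    dose.check_aligned(geometry)
    mask = geometry.slice_masks
    if not mask.any():
        raise ValueError("esophagus mask is empty")
    doses = np.asarray(dose.values, dtype=float)[mask]
    out = {"MED": float(doses.mean()), "Dmax": float(doses.max())}
    for x in _V_LEVELS:
        out[f"V{x}"] = float(100.0 * (doses >= x).mean())
    return out


def dose_length_metrics(
    dose: DoseGrid, geometry: EsophagusGeometry, contiguous: bool = False
) -> dict[str, float]:
    """LEx_25% and LEx_100% for x in 10..60 Gy, in cm.

    For each non-empty slice, f(z) is the fraction of the slice's esophagus
    area with dose >= x; a slice qualifies when f(z) >= y. By default
    qualifying slices need not be contiguous; with ``contiguous=True`` the
    longest contiguous qualifying run is used instead.
    """
    dose.check_aligned(geometry)
    mask = geometry.slice_masks
    if not mask.any():
        raise ValueError("esophagus mask is empty")
    counts = mask.sum(axis=(1, 2))
    nonempty = counts > 0
    values = np.asarray(dose.values, dtype=float)
    out: dict[str, float] = {}
    cm_per_slice = geometry.slice_thickness / 10.0
    for x in _LE_LEVELS:
        hot = (values >= x) & mask
        frac = np.zeros(geometry.n_slices)
        frac[nonempty] = hot.sum(axis=(1, 2))[nonempty] / counts[nonempty]
        for y in (25, 100):
            qual = nonempty & (frac >= y / 100.0)
            n_slices = _longest_run(qual) if contiguous else int(qual.sum())
            out[f"LE{x}_{y}%"] = float(n_slices * cm_per_slice)
    return out


def _longest_run(qualifying: np.ndarray) -> int:
    best = run = 0
    for q in qualifying:
        run = run + 1 if q else 0
        best = max(best, run)
    return best


def _indicator_block(value: str, order: tuple[str, ...], prefix_names: list[str]):
    return {name: float(value == cat) for name, cat in zip(prefix_names, order)}


def _clinical_features(study: SerialEsophagusStudy) -> dict[str, float]:
    c = study.clinical
    row: dict[str, float] = {
        "Smoking Status": float(SMOKING_LEVELS.index(c.smoking_status)),
        "Induction Chemotherapy": float(c.induction_chemo),
        "GTV": float(c.gtv_volume),
        "Nodal Involvement": float(c.nodal_involvement),
        "Gender": float(c.gender == "male"),
        "Age": float(c.age),
        "Prescription Dose": float(c.prescription_dose),
    }
    if c.histology not in _HISTOLOGY_ORDER:
        raise ValueError(f"patient {study.patient_id}: unknown histology {c.histology!r}")
    if c.stage not in _STAGE_ORDER:
        raise ValueError(f"patient {study.patient_id}: unknown stage {c.stage!r}")
    if c.tumor_location not in _LOCATION_ORDER:
        raise ValueError(
            f"patient {study.patient_id}: unknown tumor location {c.tumor_location!r}"
        )
    row.update(
        _indicator_block(
            c.histology, _HISTOLOGY_ORDER, [PREDICTOR_CATALOGUE[i] for i in range(4, 8)]
        )
    )
    row.update(
        _indicator_block(
            c.stage, _STAGE_ORDER, [PREDICTOR_CATALOGUE[i] for i in range(9, 14)]
        )
    )
    row.update(
        _indicator_block(
            c.tumor_location,
            _LOCATION_ORDER,
            [PREDICTOR_CATALOGUE[i] for i in range(14, 20)],
        )
    )
    return row


def assemble_features(
    cohort: list[SerialEsophagusStudy],
    expansion_tags: np.ndarray | None = None,
    contiguous_lengths: bool = False,
) -> FeatureMatrix:
    """Assemble the predictor matrix for a cohort, in catalogue index order.

    With ``expansion_tags`` (a 0/1 vector aligned to ``cohort`` order) the
    matrix has 50 columns including the radiosensitivity tag; without, 49.
    """
    if expansion_tags is not None and len(expansion_tags) != len(cohort):
        raise ValueError(
            f"tag vector length {len(expansion_tags)} != cohort size {len(cohort)}"
        )
    rows = []
    for study in cohort:
        row = _clinical_features(study)
        row.update(dvh_metrics(study.planned_dose, study.baseline_geometry))
        row.update(
            dose_length_metrics(
                study.planned_dose, study.baseline_geometry, contiguous_lengths
            )
        )
        rows.append(row)
    df = pd.DataFrame(rows, index=[s.patient_id for s in cohort])
    if expansion_tags is not None:
        df[TAG_NAME] = np.asarray(expansion_tags, dtype=float)
    ordered = [
        PREDICTOR_CATALOGUE[i]
        for i in sorted(PREDICTOR_CATALOGUE)
        if PREDICTOR_CATALOGUE[i] in df.columns
    ]
    df = df[ordered]
    if df.isna().any().any():
        bad = df.columns[df.isna().any()][0]
        raise ValueError(f"missing values after assembly in predictor {bad!r}")
    index_map = {i: n for i, n in PREDICTOR_CATALOGUE.items() if n in df.columns}
    return FeatureMatrix(values=df, index_map=index_map)


def standardize(matrix: FeatureMatrix, fit_rows: np.ndarray | None = None) -> FeatureMatrix:
    """Z-score each predictor using population-SD parameters fit on ``fit_rows``.

    Parameters are computed on the fit subset only and applied to all rows.
    Constant columns (zero SD on the fit subset) are set to 0 and flagged.
    """
    df = matrix.values
    if fit_rows is None:
        fit_rows = np.arange(len(df))
    fit_rows = np.asarray(fit_rows)
    if fit_rows.dtype == bool:
        fit_rows = np.flatnonzero(fit_rows)
    if fit_rows.size == 0:
        raise ValueError("fit_rows must be non-empty")
    fit = df.iloc[fit_rows]
    means = fit.mean()
    sds = fit.std(ddof=0)
    constant = sds <= 1e-12
    safe_sds = sds.where(~constant, 1.0)
    standardized = (df - means) / safe_sds
    standardized.loc[:, constant[constant].index] = 0.0
    return replace(
        matrix,
        values=standardized,
        means=means,
        sds=sds,
        constant_columns=tuple(constant[constant].index),
    )
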