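"""K-Means stratification of the expansion dose-response into radiosensitivity groups.

Patients with a delivered mean subvolume dose below 20 Gy are excluded
(insufficient dose to incite an expansion-response); the remainder are
clustered in (mean delivered dose, mean expansion) space with k = 3 and
squared-Euclidean dissimilarity. Cluster roles are then decided from centroid
arithmetic only — the step is fully unsupervised with respect to esophagitis
outcome:

* radiosensitive — the centroid with the highest expansion-per-dose ratio;
* radioresistant — of the remaining two, the higher-dose centroid;
* radionormal   — the other.

The radiosensitive membership is exported as a dichotomous tag
(1 = radiosensitive, 0 = otherwise) for use as an NTCP model predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .expansion import ExpansionResponse

__all__ = [
    "ClusterConfig",
    "ClusterResult",
    "DegenerateClusterGeometryError",
    "RadiosensitivityKMeans",
    "filter_low_dose",
    "kmeans_cluster",
    "assign_roles",
    "make_tag",
    "cluster_responses",
]

ROLES = ("radiosensitive", "radionormal", "radioresistant")


class DegenerateClusterGeometryError(RuntimeError):
    """Centroid geometry does not admit an unambiguous role assignment."""


@dataclass
class ClusterConfig:
    k: int = 3
    dose_exclusion_gy: float = 20.0
    n_restarts: int = 50
    seed: int = 0
    standardize_inputs: bool = True
    method: str = "kmeans"  # or "gmm" (sensitivity-analysis alternative)

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.dose_exclusion_gy <= 0:
            raise ValueError("dose_exclusion_gy must be positive")
        if self.method not in ("kmeans", "gmm"):
            raise ValueError(f"unknown clustering method {self.method!r}")


@dataclass
class ClusterResult:
    """Cluster labels, centroids in original units, roles and the tag."""

    patient_ids: tuple[str, ...]  # retained patients, clustering order
    labels: np.ndarray  # per retained patient
    centroids: np.ndarray  # (k, 2): columns (dose Gy, expansion %)
    role_map: dict[int, str]
    tag: np.ndarray  # per retained patient, 1 = radiosensitive
    assumption_check: dict = field(default_factory=dict)
    excluded_ids: tuple[str, ...] = ()

    def role_of(self, patient_pos: int) -> str:
        return self.role_map[int(self.labels[patient_pos])]


def filter_low_dose(
    responses: list[ExpansionResponse], threshold: float = 20.0
) -> tuple[list[ExpansionResponse], list[ExpansionResponse]]:
    """Partition responses by delivered subvolume dose; strictly below is excluded."""
    retained = [r for r in responses if not r.mean_delivered_dose < threshold]
    excluded = [r for r in responses if r.mean_delivered_dose < threshold]
    return retained, excluded


class RadiosensitivityKMeans(BaseEstimator, ClusterMixin):
    """Scikit-learn style estimator for radiosensitivity stratification.

    Fits K-Means (or, optionally, a Gaussian mixture) on a two-column array
    ``X = [[mean_delivered_dose, mean_expansion], ...]``, optionally
    z-standardized internally; centroids are reported back in original units
    and mapped to radiosensitivity roles.

    Attributes (after ``fit``)
    --------------------------
    labels_ : ndarray of cluster ids
    centroids_ : ndarray, (k, 2), original units
    role_map_ : dict cluster id -> role
    tag_ : ndarray of {0, 1}, 1 = radiosensitive
    assumption_check_ : dict with keys ``status`` ("pass"/"warn") and ``warnings``
    """

    def __init__(
        self,
        n_clusters: int = 3,
        n_restarts: int = 50,
        standardize: bool = True,
        method: str = "kmeans",
        random_state: int | None = 0,
    ):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.standardize = standardize
        self.method = method
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_patients, 2): dose and expansion columns")
        if np.unique(X, axis=0).shape[0] < self.n_clusters:
            raise ValueError(
                f"need at least {self.n_clusters} distinct points, "
                f"got {np.unique(X, axis=0).shape[0]}"
            )
        if self.standardize:
            mu, sd = X.mean(axis=0), X.std(axis=0)
            sd = np.where(sd <= 1e-12, 1.0, sd)
            Z = (X - mu) / sd
        else:
            Z = X
        if self.method == "gmm":
            model = GaussianMixture(
                n_components=self.n_clusters,
                n_init=self.n_restarts,
                random_state=self.random_state,
            ).fit(Z)
            labels = model.predict(Z)
        elif self.method == "kmeans":
            model = KMeans(
                n_clusters=self.n_clusters,
                n_init=self.n_restarts,
                random_state=self.random_state,
            ).fit(Z)
            labels = model.labels_
        else:
            raise ValueError(f"unknown clustering method {self.method!r}")
        self.labels_ = np.asarray(labels)
        # centroids in original units, from the assigned members
        self.centroids_ = np.vstack(
            [X[self.labels_ == c].mean(axis=0) for c in range(self.n_clusters)]
        )
        if self.n_clusters == 3:
            self.role_map_, self.assumption_check_ = assign_roles(self.centroids_)
            sensitive = {c for c, r in self.role_map_.items() if r == "radiosensitive"}
            self.tag_ = np.isin(self.labels_, list(sensitive)).astype(int)
        else:
            self.role_map_, self.assumption_check_, self.tag_ = {}, {}, None
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def kmeans_cluster(
    responses: list[ExpansionResponse], config: ClusterConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster expansion-responses; returns (labels, centroids in original units)."""
    config.validate()
    X = np.array([[r.mean_delivered_dose, r.mean_expansion] for r in responses])
    est = RadiosensitivityKMeans(
        n_clusters=config.k,
        n_restarts=config.n_restarts,
        standardize=config.standardize_inputs,
        method=config.method,
        random_state=config.seed,
    ).fit(X)
    return est.labels_, est.centroids_


def assign_roles(centroids: np.ndarray) -> tuple[dict[int, str], dict]:
    """Map k=3 centroids to radiosensitivity roles by centroid arithmetic.

    Raises :class:`DegenerateClusterGeometryError` when two centroids share
    the maximal expansion/dose ratio (no unambiguous radiosensitive cluster);
    records warnings (never failures) when the secondary geometric
    expectations do not hold.
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape != (3, 2):
        raise ValueError("role assignment requires exactly 3 (dose, expansion) centroids")
    if np.any(centroids[:, 0] <= 0):
        raise ValueError("centroid doses must be positive")
    ratios = centroids[:, 1] / centroids[:, 0]
    order = np.argsort(ratios)
    if np.isclose(ratios[order[-1]], ratios[order[-2]], rtol=1e-9, atol=1e-12):
        raise DegenerateClusterGeometryError(
            f"two centroids share the maximal expansion/dose ratio "
            f"({ratios[order[-1]]:.6g}); reseed the clustering"
        )
    sensitive = int(order[-1])
    rest = [c for c in range(3) if c != sensitive]
    resistant = int(max(rest, key=lambda c: centroids[c, 0]))
    normal = int(next(c for c in rest if c != resistant))
    role_map = {
        sensitive: "radiosensitive",
        resistant: "radioresistant",
        normal: "radionormal",
    }
    warnings = []
    if not (
        centroids[normal, 0] <= min(centroids[sensitive, 0], centroids[resistant, 0])
        and centroids[normal, 1] <= min(centroids[sensitive, 1], centroids[resistant, 1])
    ):
        warnings.append("radionormal centroid is not lowest in both dose and expansion")
    if centroids[resistant, 0] < centroids[:, 0].max():
        warnings.append("radioresistant centroid does not have the highest dose")
    check = {"status": "warn" if warnings else "pass", "warnings": warnings}
    return role_map, check


def make_tag(result: ClusterResult, retained_ids: list[str]) -> np.ndarray:
    """Dichotomous radiosensitivity vector aligned to ``retained_ids`` order."""
    if sorted(retained_ids) != sorted(result.patient_ids):
        raise ValueError("retained patient ids do not match the clustering result")
    pos = {pid: i for i, pid in enumerate(result.patient_ids)}
    return np.array([result.tag[pos[pid]] for pid in retained_ids], dtype=int)


def cluster_responses(
    responses: list[ExpansionResponse], config: ClusterConfig | None = None
) -> ClusterResult:
    """Full stratification stage: low-dose exclusion, k=3 clustering, roles, tag."""
    config = config or ClusterConfig()
    config.validate()
    retained, excluded = filter_low_dose(responses, config.dose_exclusion_gy)
    if len(retained) < config.k:
        raise ValueError(
            f"only {len(retained)} patients retained after the "
            f"{config.dose_exclusion_gy} Gy exclusion; cannot form {config.k} clusters"
        )
    X = np.array([[r.mean_delivered_dose, r.mean_expansion] for r in retained])
    est = RadiosensitivityKMeans(
        n_clusters=config.k,
        n_restarts=config.n_restarts,
        standardize=config.standardize_inputs,
        method=config.method,
        random_state=config.seed,
    ).fit(X)
    return ClusterResult(
        patient_ids=tuple(r.patient_id for r in retained),
        labels=est.labels_,
        centroids=est.centroids_,
        role_map=est.role_map_,
        tag=est.tag_,
        assumption_check=est.assumption_check_,
        excluded_ids=tuple(r.patient_id for r in excluded),
    )
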