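import numpy as np
import pytest

from esotox import clustering, expansion, features, simulate


def small_config(seed: int = 5, **overrides) -> simulate.GeneratorConfig:
    """A fast, reduced cohort for unit tests (defaults stay untouched)."""
    cfg = simulate.GeneratorConfig(
        n_patients=28,
        n_low_dose_patients=2,
        in_plane_size=48,
        n_slices=64,
        weekly_scan_fractions=(10, 30),
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@pytest.fixture(scope="session")
def small_cohort():
    return simulate.generate_cohort(small_config())


@pytest.fixture(scope="session")
def default_cohort():
    """The packaged fixture cohort: full default study conditions, seed 1."""
    return simulate.generate_cohort(simulate.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_responses(default_cohort):
    return expansion.quantify_cohort(default_cohort)


@pytest.fixture(scope="session")
def informative_study():
    """Feature matrices and grades for the strongly-informative-tag cohort.

    Returns ``(fm_with, fm_without, grades)``; the geometry-heavy cohort is
    released once features are assembled.
    """
    cohort = simulate.generate_cohort(simulate.GeneratorConfig.informative_tag(seed=1))
    responses = expansion.quantify_cohort(cohort)
    result = clustering.cluster_responses(responses)
    retained = set(result.patient_ids)
    analyzed = [s for s in cohort if s.patient_id in retained]
    tag = clustering.make_tag(result, [s.patient_id for s in analyzed])
    grades = np.array([s.max_grade for s in analyzed])
    fm_with = features.assemble_features(analyzed, tag)
    fm_without = features.assemble_features(analyzed)
    return fm_with, fm_without, grades
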