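"""Expansion quantification: profiles, scan selection, subvolume response."""

import numpy as np
import pytest

from esotox.expansion import (
    ExpansionProfile,
    axial_expansion_profile,
    locate_max_expansion_slice,
    quantify_cohort,
    select_scan_nearest_fraction,
    subvolume_response,
)
from esotox.geometry import DoseGrid, EsophagusGeometry, LatticeMismatchError
from esotox import simulate

from conftest import small_config


def geom_from_counts(counts, ny=8, nx=8, thickness=2.5, spacing=1.0):
    """Geometry whose slice z has exactly counts[z] voxels set."""
    masks = np.zeros((len(counts), ny, nx), dtype=bool)
    for z, c in enumerate(counts):
        masks[z].flat[:c] = True
    return EsophagusGeometry(masks, thickness, spacing)


class TestAxialProfile:
    def test_identical_geometries_give_zero_profile(self):
        g = geom_from_counts([4, 9, 16, 9])
        profile = axial_expansion_profile(g, g)
        assert np.all(profile.values == 0.0)

    def test_doubled_area_gives_100_percent(self):
        base = geom_from_counts([10, 10])
        follow = geom_from_counts([20, 20])
        assert np.all(axial_expansion_profile(base, follow).values == 100.0)

    def test_zero_baseline_slices_are_undefined_not_zero(self):
        base = geom_from_counts([0, 10, 0])
        follow = geom_from_counts([0, 15, 3])
        profile = axial_expansion_profile(base, follow)
        assert np.isnan(profile.values[0]) and np.isnan(profile.values[2])
        assert profile.values[1] == 50.0

    def test_lattice_mismatch_fails(self):
        with pytest.raises(LatticeMismatchError):
            axial_expansion_profile(
                geom_from_counts([4, 4]), geom_from_counts([4, 4], thickness=3.0)
            )

    def test_profile_matches_analytic_dilation_on_fine_lattice(self):
        """Measured e(z) tracks the closed-form area ratio of the dilation.

        A fine 0.5 mm lattice keeps mask discretization within the 2-point
        tolerance of the analytic value 100 * (k^2 - 1) for radius factor k.
        """
        cfg = small_config(
            n_patients=6,
            n_low_dose_patients=0,
            latent_class_proportions={"sensitive": 0.5, "normal": 0.0, "resistant": 0.5},
            in_plane_spacing=0.25,
            in_plane_size=160,
            expansion_noise_sd=0.0,
            swelling_profile_width=10.0,
        )
        for study in simulate.generate_cohort(cfg):
            frac, follow = select_scan_nearest_fraction(study.followups)
            profile = axial_expansion_profile(study.baseline_geometry, follow)
            base_counts = study.baseline_geometry.voxel_counts()
            dose = study.planned_dose.values
            sf_tf = frac / study.clinical.total_fractions
            slope = cfg.class_expansion_slope[study.latent_class]
            for z in np.flatnonzero(base_counts > 0):
                d_z = dose[z][study.baseline_geometry.slice_masks[z]].mean()
                analytic = slope * d_z * sf_tf  # area change % = 100*(k^2-1)
                assert profile.values[z] == pytest.approx(analytic, abs=2.0)


class TestScanSelection:
    @pytest.mark.parametrize(
        "fractions, expected",
        [((10, 20, 30), 30), ((25, 35), 35), ((28, 33), 28), ((30,), 30)],
    )
    def test_nearest_fraction_with_later_tie_rule(self, fractions, expected):
        followups = [(f, geom_from_counts([4])) for f in fractions]
        assert select_scan_nearest_fraction(followups)[0] == expected

    def test_empty_followups_fail(self):
        with pytest.raises(ValueError):
            select_scan_nearest_fraction([])


class TestMaxSlice:
    def test_argmax_and_superior_tie_rule(self):
        assert locate_max_expansion_slice(ExpansionProfile([0, 5, 40, 5])) == 2
        assert locate_max_expansion_slice(ExpansionProfile([7, 7, 3])) == 0

    def test_all_undefined_fails(self):
        with pytest.raises(ValueError):
            locate_max_expansion_slice(ExpansionProfile([np.nan, np.nan]))

    def test_max_slice_near_generator_dose_peak_without_noise(self):
        cfg = small_config(
            n_patients=6,
            n_low_dose_patients=0,
            latent_class_proportions={"sensitive": 0.5, "normal": 0.0, "resistant": 0.5},
            expansion_noise_sd=0.0,
            swelling_profile_width=10.0,
            in_plane_spacing=0.5,
            in_plane_size=96,
        )
        for study in simulate.generate_cohort(cfg):
            _, follow = select_scan_nearest_fraction(study.followups)
            profile = axial_expansion_profile(study.baseline_geometry, follow)
            center = locate_max_expansion_slice(profile)
            masks = study.baseline_geometry.slice_masks
            counts = masks.sum(axis=(1, 2))
            dose_profile = np.zeros(len(counts))
            nz = counts > 0
            dose_profile[nz] = (study.planned_dose.values * masks).sum(axis=(1, 2))[nz] / counts[nz]
            z_star = int(np.argmax(dose_profile))
            assert abs(center - z_star) <= 1


class TestSubvolumeResponse:
    def uniform_fixture(self, dose_gy, n_slices=12):
        geom = geom_from_counts([9] * n_slices, thickness=2.5)
        dose = DoseGrid(np.full(geom.shape, dose_gy, dtype=float))
        return geom, dose

    def test_delivered_dose_is_linear_fraction_scaling(self):
        geom, dose = self.uniform_fixture(74.0)
        profile = ExpansionProfile(np.full(12, 25.0))
        resp = subvolume_response(profile, geom, dose, center=6,
                                  scan_fraction=30, total_fractions=37)
        assert resp.mean_delivered_dose == pytest.approx(74.0 * 30 / 37)
        assert resp.mean_expansion == 25.0

    def test_hand_computed_five_slice_fixture(self):
        # areas irrelevant to the means below; doses and expansions per slice:
        #   slice:      0     1     2     3     4
        #   e(z) %:    10    20    40    20    10
        #   dose Gy:   20    40    60    40    20
        # center 2, edge 10 mm at 2.5 mm slices -> half-open window slices 0..3
        geom = geom_from_counts([4, 4, 4, 4, 4], thickness=2.5)
        vals = np.zeros(geom.shape)
        for z, d in enumerate([20.0, 40.0, 60.0, 40.0, 20.0]):
            vals[z] = d
        profile = ExpansionProfile([10.0, 20.0, 40.0, 20.0, 10.0])
        resp = subvolume_response(profile, geom, DoseGrid(vals), center=2,
                                  scan_fraction=30, total_fractions=30, edge_mm=10.0)
        assert resp.subvolume_slices == (0, 4)
        assert resp.mean_expansion == pytest.approx((10 + 20 + 40 + 20) / 4)
        assert resp.mean_delivered_dose == pytest.approx((20 + 40 + 60 + 40) / 4)

    def test_window_is_eight_slices_at_default_edge(self):
        geom, dose = self.uniform_fixture(50.0, n_slices=20)
        profile = ExpansionProfile(np.zeros(20))
        resp = subvolume_response(profile, geom, dose, center=10,
                                  scan_fraction=30, total_fractions=30)
        lo, hi = resp.subvolume_slices
        assert hi - lo == 8

    def test_delivered_never_exceeds_planned(self):
        geom, dose = self.uniform_fixture(60.0)
        profile = ExpansionProfile(np.zeros(12))
        partial = subvolume_response(profile, geom, dose, 6, 30, 33)
        full = subvolume_response(profile, geom, dose, 6, 33, 33)
        assert partial.mean_delivered_dose < 60.0
        assert full.mean_delivered_dose == pytest.approx(60.0)

    def test_empty_subvolume_fails(self):
        geom = geom_from_counts([0, 0, 4, 0, 0])
        dose = DoseGrid(np.zeros(geom.shape))
        profile = ExpansionProfile([np.nan, np.nan, 0.0, np.nan, np.nan])
        with pytest.raises(ValueError):
            subvolume_response(profile, geom, dose, 0, 30, 30, edge_mm=5.1)


def test_translation_invariance_of_response(small_cohort):
    study = small_cohort[0]
    shift = 3
    frac, follow = select_scan_nearest_fraction(study.followups)
    profile = axial_expansion_profile(study.baseline_geometry, follow)
    center = locate_max_expansion_slice(profile)
    resp = subvolume_response(profile, study.baseline_geometry, study.planned_dose,
                              center, frac, study.clinical.total_fractions)

    def roll(geom):
        return EsophagusGeometry(
            np.roll(geom.slice_masks, shift, axis=0),
            geom.slice_thickness, geom.in_plane_spacing,
        )

    shifted_profile = axial_expansion_profile(roll(study.baseline_geometry), roll(follow))
    shifted_center = locate_max_expansion_slice(shifted_profile)
    assert shifted_center == center + shift
    shifted = subvolume_response(
        shifted_profile, roll(study.baseline_geometry),
        DoseGrid(np.roll(study.planned_dose.values, shift, axis=0)),
        shifted_center, frac, study.clinical.total_fractions,
    )
    assert shifted.mean_expansion == pytest.approx(resp.mean_expansion)
    assert shifted.mean_delivered_dose == pytest.approx(resp.mean_delivered_dose)


def test_enlarging_followup_never_decreases_mean_expansion():
    base = geom_from_counts([10] * 8)
    follow_counts = [12, 14, 16, 14, 12, 11, 10, 10]
    dose = DoseGrid(np.full(base.shape, 30.0))
    small = axial_expansion_profile(base, geom_from_counts(follow_counts))
    bigger = axial_expansion_profile(
        base, geom_from_counts([c + 2 for c in follow_counts])
    )
    r1 = subvolume_response(small, base, dose, 2, 30, 30)
    r2 = subvolume_response(bigger, base, dose, 2, 30, 30)
    assert r2.mean_expansion >= r1.mean_expansion


def test_quantify_cohort_returns_one_response_per_patient(small_cohort):
    responses = quantify_cohort(small_cohort)
    assert [r.patient_id for r in responses] == [s.patient_id for s in small_cohort]
    assert all(r.mean_delivered_dose >= 0 for r in responses)
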