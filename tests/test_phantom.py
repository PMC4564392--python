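"""Phantom generator: geometry, lesions, intensities, cohorts."""

import numpy as np
import pytest

from lesionmorph import phantom
from lesionmorph.volumes import Volume


class TestLabelmap:
    def test_shell_volume_matches_analytic(self):
        spec = phantom.PhantomSpec(
            grid_shape=(64, 64, 64), voxel_size_mm=1.0,
            wm_radius_mm=15.0, gm_thickness_mm=3.0,
        )
        labels = phantom.make_labelmap(spec)
        gm_count = int(np.sum(labels.data == phantom.LABEL_GM))
        analytic = 4.0 / 3.0 * np.pi * (18.0**3 - 15.0**3)
        assert gm_count == pytest.approx(analytic, rel=0.02)

    def test_slab_columns_have_exact_thickness(self, slab_spec):
        labels = phantom.make_labelmap(slab_spec)
        gm_per_column = (labels.data == phantom.LABEL_GM).sum(axis=2)
        assert (gm_per_column == 4).all()

    def test_zero_thickness_rejected(self):
        spec = phantom.PhantomSpec(gm_thickness_mm=0.0)
        with pytest.raises(ValueError):
            phantom.make_labelmap(spec)

    def test_oversized_anatomy_rejected(self):
        spec = phantom.PhantomSpec(grid_shape=(32, 32, 32), wm_radius_mm=14.0,
                                   gm_thickness_mm=3.0)
        with pytest.raises(ValueError, match="margin"):
            phantom.make_labelmap(spec)

    def test_partial_volume_maps_sum_to_one(self, shell_spec):
        tpms = phantom.partial_volume_tpms(shell_spec)
        total = tpms.class_sum()
        assert np.allclose(total, 1.0, atol=1e-12)


class TestLesions:
    def test_deterministic_under_seed(self, shell_labels):
        lesions = phantom.LesionSpec(n_wmh=5, n_li=2)
        _, wmh1, li1 = phantom.implant_lesions(shell_labels, lesions, seed=7)
        _, wmh2, li2 = phantom.implant_lesions(shell_labels, lesions, seed=7)
        assert np.array_equal(wmh1.data, wmh2.data)
        assert np.array_equal(li1.data, li2.data)

    def test_no_wmh_requested_gives_empty_mask(self, shell_labels):
        _, wmh, _ = phantom.implant_lesions(
            shell_labels, phantom.LesionSpec(n_wmh=0, n_li=1), seed=0
        )
        assert not wmh.data.any()

    def test_single_sphere_volume_near_analytic(self, shell_labels):
        lesions = phantom.LesionSpec(n_wmh=1, wmh_radius_mm_range=(3.0, 3.0), n_li=0)
        _, wmh, _ = phantom.implant_lesions(shell_labels, lesions, seed=3)
        assert wmh.data.sum() == pytest.approx(4 / 3 * np.pi * 27, rel=0.15)

    def test_masks_disjoint_and_inside_wm(self, shell_labels):
        lesions = phantom.LesionSpec(n_wmh=6, n_li=3)
        labels, wmh, li = phantom.implant_lesions(shell_labels, lesions, seed=5)
        wmh_m = np.asarray(wmh.data, bool)
        li_m = np.asarray(li.data, bool)
        assert not (wmh_m & li_m).any()
        assert (np.asarray(shell_labels.data)[wmh_m | li_m] == phantom.LABEL_WM).all()

    def test_excessive_lesion_load_rejected(self, shell_labels):
        with pytest.raises(ValueError, match="exceeds"):
            phantom.implant_lesion_load(
                shell_labels, 1e9, phantom.LesionSpec(), seed=0
            )


class TestIntensities:
    def test_zero_noise_gives_exact_class_means(self, shell_labels):
        lesions = phantom.LesionSpec(n_wmh=2, n_li=1)
        labels, wmh, li = phantom.implant_lesions(shell_labels, lesions, seed=1)
        model = phantom.IntensityModel(noise_scale=0.0)
        t1, flair = phantom.render_intensities(labels, wmh, li, model, seed=0)
        wmh_m = np.asarray(wmh.data, bool)
        assert np.allclose(t1.data[wmh_m], model.means["wmh"][0])
        assert np.allclose(flair.data[wmh_m], model.means["wmh"][1])
        gm_m = np.asarray(labels.data) == phantom.LABEL_GM
        assert np.allclose(t1.data[gm_m], model.means["gm"][0])

    def test_wm_sample_mean_within_clt_bound(self, lesioned_subject):
        s = lesioned_subject
        wm = (np.asarray(s["labels"].data) == phantom.LABEL_WM) & ~np.asarray(
            s["wmh"].data, bool
        ) & ~np.asarray(s["li"].data, bool)
        vals = np.asarray(s["t1"].data)[wm]
        sd = np.sqrt(s["model"].covariance("wm")[0, 0])
        assert abs(vals.mean() - s["model"].means["wm"][0]) < 3 * sd / np.sqrt(len(vals))

    def test_bias_field_preserves_contrast_ordering(self, shell_labels):
        lesions = phantom.LesionSpec(n_wmh=2, n_li=0)
        labels, wmh, li = phantom.implant_lesions(shell_labels, lesions, seed=2)
        model = phantom.IntensityModel(bias_field_amplitude=0.2)
        t1, _ = phantom.render_intensities(labels, wmh, li, model, seed=4)
        lab = np.asarray(labels.data)
        # per-octant class means keep CSF < GM < WM on T1
        n = lab.shape[0] // 2
        for sx in (slice(0, n), slice(n, None)):
            for sy in (slice(0, n), slice(n, None)):
                sub_lab = lab[sx, sy]
                sub_t1 = np.asarray(t1.data)[sx, sy]
                means = [
                    sub_t1[sub_lab == c].mean()
                    for c in (phantom.LABEL_CSF, phantom.LABEL_GM, phantom.LABEL_WM)
                ]
                assert means[0] < means[1] < means[2]

    def test_invalid_covariance_rejected(self):
        model = phantom.IntensityModel(
            covariances={"wm": np.array([[1.0, 2.0], [2.0, 1.0]])}
        )
        with pytest.raises(ValueError, match="positive definite"):
            model.validate()

    def test_wmh_intensity_invariants_enforced(self):
        bad = phantom.IntensityModel()
        bad.means = dict(bad.means)
        bad.means["wmh"] = (150.0, 140.0)  # outside the GM..WM T1 interval
        with pytest.raises(ValueError, match="between"):
            bad.validate()


class TestCohort:
    def test_deterministic_under_master_seed(self, shell_spec):
        cohort = phantom.CohortSpec(n_subjects=4, master_seed=9,
                                    wmhv_range_mm3=(500.0, 4000.0))
        t1, _ = phantom.make_cohort(cohort, shell_spec, phantom.LesionSpec(),
                                    phantom.IntensityModel())
        t2, _ = phantom.make_cohort(cohort, shell_spec, phantom.LesionSpec(),
                                    phantom.IntensityModel())
        assert t1.equals(t2)

    def test_zero_thinning_gives_shared_thickness(self, shell_spec):
        cohort = phantom.CohortSpec(n_subjects=3, master_seed=1,
                                    thinning_coefficient_mm_per_10k=0.0,
                                    wmhv_range_mm3=(500.0, 3000.0))
        table, _ = phantom.make_cohort(cohort, shell_spec, phantom.LesionSpec(),
                                       phantom.IntensityModel())
        assert np.allclose(table.true_thickness_mm, shell_spec.gm_thickness_mm)

    def test_recorded_wmhv_matches_truth_mask_exactly(self, shell_spec):
        cohort = phantom.CohortSpec(n_subjects=3, master_seed=2,
                                    wmhv_range_mm3=(500.0, 4000.0))
        table, subjects = phantom.make_cohort(cohort, shell_spec,
                                              phantom.LesionSpec(),
                                              phantom.IntensityModel())
        for row, s in zip(table.itertuples(), subjects):
            assert row.wmhv_mm3 == s.wmh_truth.data.sum() * s.labels.voxel_volume_mm3
            assert row.liv_mm3 == s.li_truth.data.sum() * s.labels.voxel_volume_mm3

    def test_thinning_induces_strong_negative_correlation(self):
        # wide lesion-load range on a larger phantom whose WM can host it
        spec = phantom.PhantomSpec(grid_shape=(72, 72, 72), wm_radius_mm=28.0,
                                   gm_thickness_mm=3.0)
        cohort = phantom.CohortSpec(
            n_subjects=10, master_seed=3, wmhv_range_mm3=(500.0, 30000.0),
            thinning_coefficient_mm_per_10k=0.5, warp_amplitude_mm=0.0,
        )
        table, _ = phantom.make_cohort(cohort, spec, phantom.LesionSpec(),
                                       phantom.IntensityModel())
        r = np.corrcoef(table.true_thickness_mm, table.wmhv_mm3)[0, 1]
        assert r < -0.9

    def test_excessive_thinning_rejected(self, shell_spec):
        cohort = phantom.CohortSpec(n_subjects=3,
                                    thinning_coefficient_mm_per_10k=5.0)
        with pytest.raises(ValueError, match="0.5 mm"):
            phantom.make_cohort(cohort, shell_spec, phantom.LesionSpec(),
                                phantom.IntensityModel())

    def test_grids_and_affines_shared(self, shell_spec):
        cohort = phantom.CohortSpec(n_subjects=3, master_seed=4,
                                    wmhv_range_mm3=(500.0, 4000.0))
        _, subjects = phantom.make_cohort(cohort, shell_spec, phantom.LesionSpec(),
                                          phantom.IntensityModel())
        ref = subjects[0].t1
        for s in subjects:
            for vol in (s.t1, s.flair, s.labels, s.wmh_truth, s.li_truth, s.head):
                assert ref.same_grid(vol)
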