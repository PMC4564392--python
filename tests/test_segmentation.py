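"""Mixture-of-Gaussians segmentation, priors, lacune growing, skull strip."""

import numpy as np
import pytest

from lesionmorph import phantom, segmentation
from lesionmorph.tpm import TPMSet
from lesionmorph.volumes import Volume


def _full_mask(shape):
    return Volume(np.ones(shape, dtype=np.uint8))


class TestFitMixture:
    def test_two_separated_gaussians_recovered(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(30, 5, 10_000), rng.normal(90, 5, 10_000)])
        rng.shuffle(x)
        vol = Volume(x.reshape(20, 100, 10))
        fit = segmentation.fit_mixture([vol], _full_mask(vol.shape), None, K=2, seed=0)
        means = np.sort(fit.means[:, 0])
        assert abs(means[0] - 30) < 1 and abs(means[1] - 90) < 1
        assert np.all(np.abs(fit.weights - 0.5) < 0.02)

    def test_phantom_class_means_recovered_within_2pct_of_separation(
        self, lesioned_subject
    ):
        s = lesioned_subject
        fit = segmentation.fit_mixture([s["t1"], s["flair"]], s["mask"], None,
                                       K=4, seed=0)
        order = segmentation.canonical_class_order(fit)
        true_means = {c: np.array(s["model"].means[c])
                      for c in ("csf", "gm", "wm", "wmh")}
        separation = min(
            np.linalg.norm(true_means[a] - true_means[b])
            for a in true_means for b in true_means if a < b
        )
        for cls, k in order.items():
            err = np.linalg.norm(fit.means[k] - true_means[cls])
            assert err < 0.02 * separation, cls
        # mixing weights match the true class fractions
        cls_map = phantom.class_map(s["labels"], s["wmh"], s["li"], 0.0)
        for cls, k in order.items():
            idx = ("csf", "gm", "wm", "wmh").index(cls)
            assert abs(fit.weights[k] - np.mean(cls_map == idx)) < 0.02

    def test_log_likelihood_monotone(self, lesioned_subject):
        s = lesioned_subject
        fit = segmentation.fit_mixture([s["t1"]], s["mask"], None, K=3, seed=0)
        ll = fit.log_likelihoods
        assert all(b >= a - 1e-8 * abs(a) for a, b in zip(ll, ll[1:]))

    def test_one_hot_priors_dominate(self, shell_labels, truth_tpms):
        model = phantom.IntensityModel(noise_scale=0.5)
        empty = shell_labels.with_data(np.zeros(shell_labels.shape, np.uint8))
        t1, flair = phantom.render_intensities(shell_labels, empty, empty, model, 1)
        mask = _full_mask(shell_labels.shape)
        fit = segmentation.fit_mixture([t1, flair], mask, priors=truth_tpms, seed=0)
        post = segmentation.posterior_maps(fit, [t1, flair], truth_tpms, mask)
        predicted = post.argmax_labels()  # 1-based in class order gm, wm, csf
        labels = np.asarray(shell_labels.data)
        truth_1based = np.select(
            [labels == phantom.LABEL_GM, labels == phantom.LABEL_WM], [1, 2], 3
        )
        assert (predicted == truth_1based).mean() > 0.999

    def test_empty_mask_rejected(self, lesioned_subject):
        s = lesioned_subject
        empty = s["t1"].with_data(np.zeros(s["t1"].shape, np.uint8))
        with pytest.raises(ValueError, match="mask"):
            segmentation.fit_mixture([s["t1"]], empty, None, K=2)

    def test_degenerate_support_rejected(self):
        vol = Volume(np.full((8, 8, 8), 5.0))
        with pytest.raises(ValueError, match="distinct"):
            segmentation.fit_mixture([vol], _full_mask(vol.shape), None, K=3)


class TestPosteriors:
    def test_sum_to_one_in_mask(self, lesioned_subject):
        s = lesioned_subject
        fit = segmentation.fit_mixture([s["t1"], s["flair"]], s["mask"], None,
                                       K=4, seed=0)
        post = segmentation.posterior_maps(fit, [s["t1"], s["flair"]], None,
                                           s["mask"])
        total = post.class_sum()
        assert np.allclose(total, 1.0, atol=1e-6)

    def test_voxel_at_class_mean_wins(self):
        model = segmentation.MixtureModel(
            class_names=["a", "b"],
            means=np.array([[10.0], [50.0]]),
            covariances=np.array([[[25.0]], [[25.0]]]),
            weights=np.array([0.5, 0.5]),
            channel_names=["t1"],
        )
        vol = Volume(np.full((2, 2, 2), 10.0))
        post = segmentation.posterior_maps(model, [vol], None, _full_mask((2, 2, 2)))
        assert (post["a"].data > post["b"].data).all()

    def test_raising_prior_raises_posterior(self, lesioned_subject, truth_tpms):
        s = lesioned_subject
        fit = segmentation.fit_mixture([s["t1"], s["flair"]], s["mask"], None,
                                       K=3, seed=0)
        fit.class_names = ["gm", "wm", "csf"]
        base = segmentation.posterior_maps(fit, [s["t1"], s["flair"]], truth_tpms,
                                           s["mask"])
        boosted_maps = {c: truth_tpms[c] for c in truth_tpms.classes}
        gm_up = np.clip(np.asarray(truth_tpms["gm"].data) * 4.0 + 0.05, 0, 1)
        boosted_maps["gm"] = truth_tpms["gm"].with_data(gm_up)
        boosted = segmentation.posterior_maps(
            fit, [s["t1"], s["flair"]],
            TPMSet(boosted_maps, validate=False), s["mask"],
        )
        assert (boosted["gm"].data >= base["gm"].data - 1e-9).all()

    def test_channel_mismatch_rejected(self, lesioned_subject):
        s = lesioned_subject
        fit = segmentation.fit_mixture([s["t1"], s["flair"]], s["mask"], None,
                                       K=3, seed=0)
        with pytest.raises(ValueError, match="channels"):
            segmentation.posterior_maps(fit, [s["t1"]], None, s["mask"])


class TestWMHFailureMode:
    """Two channels isolate WMH; a T1-only 3-class run sends it to GM."""

    def test_flair_channel_separates_wmh_from_gm(self, lesioned_subject,
                                                 shell_labels):
        s = lesioned_subject
        subj_tpms = []
        for seed in range(3):
            lab, wmh_s, _ = phantom.implant_lesions(
                shell_labels, phantom.LesionSpec(n_wmh=4, n_li=0), seed=20 + seed
            )
            subj_tpms.append(phantom.truth_tpms(lab, wmh_s))
        priors = segmentation.build_population_tpms(subj_tpms, smooth_fwhm_mm=4.0)
        fit = segmentation.fit_mixture([s["t1"], s["flair"]], s["mask"],
                                       priors=priors, seed=0)
        post = segmentation.posterior_maps(fit, [s["t1"], s["flair"]], priors,
                                           s["mask"])
        wmh_m = np.asarray(s["wmh"].data, bool)
        wins = np.mean(post["wmh"].data[wmh_m] > post["gm"].data[wmh_m])
        assert wins >= 0.9

    def test_t1_only_misclassifies_wmh_as_gm(self, lesioned_subject):
        s = lesioned_subject
        fit = segmentation.fit_mixture([s["t1"]], s["mask"], None, K=3, seed=0)
        order = segmentation.canonical_class_order(fit)
        post = segmentation.posterior_maps(fit, [s["t1"]], None, s["mask"])
        stack = np.stack(
            [np.asarray(post[f"class_{order[c]}"].data) for c in ("csf", "gm", "wm")]
        )
        argmax = np.argmax(stack, axis=0)
        wmh_m = np.asarray(s["wmh"].data, bool)
        assert np.mean(argmax[wmh_m] == 1) >= 0.9  # labelled grey matter


class TestPopulationTPMs:
    def _one_hot(self, labels):
        return phantom.truth_tpms(labels)

    def test_identical_inputs_reproduced_after_floor(self, shell_labels):
        tpms = self._one_hot(shell_labels)
        pop = segmentation.build_population_tpms([tpms, tpms], smooth_fwhm_mm=0.0)
        gm = np.asarray(shell_labels.data) == phantom.LABEL_GM
        assert np.allclose(pop["gm"].data[gm], 1.0, atol=2e-3)
        assert (pop["gm"].data[gm] > 0).all()

    def test_disagreement_averages(self, shell_labels):
        a = self._one_hot(shell_labels)
        flipped = shell_labels.with_data(
            np.where(shell_labels.data == phantom.LABEL_GM, phantom.LABEL_WM,
                     shell_labels.data)
        )
        b = self._one_hot(flipped)
        pop = segmentation.build_population_tpms([a, b], smooth_fwhm_mm=0.0,
                                                 floor=0.0)
        gm = np.asarray(shell_labels.data) == phantom.LABEL_GM
        assert np.allclose(pop["gm"].data[gm], 0.5, atol=1e-9)

    def test_class_sums_bounded(self, shell_labels):
        tpms = self._one_hot(shell_labels)
        pop = segmentation.build_population_tpms([tpms, tpms], smooth_fwhm_mm=4.0)
        assert pop.class_sum().max() <= 1.0 + 1e-4


class TestGrowLacune:
    def test_uniform_sphere_filled_exactly(self):
        shape = (24, 24, 24)
        g = np.indices(shape)
        r = np.sqrt(((g - 11.5) ** 2).sum(axis=0))
        data = np.where(r <= 5, 400.0, 50.0)
        vol = Volume(data)
        mask = segmentation.grow_lacune(vol, (11, 11, 11), 350, 500)
        assert np.array_equal(np.asarray(mask.data, bool), r <= 5)

    def test_single_iteration_limited_to_neighbourhood(self):
        vol = Volume(np.full((9, 9, 9), 400.0))
        mask = segmentation.grow_lacune(vol, (4, 4, 4), 350, 500, max_iters=1)
        assert mask.data.sum() == 7  # seed + 6-neighbourhood

    def test_seed_outside_window_rejected(self):
        vol = Volume(np.full((5, 5, 5), 100.0))
        with pytest.raises(ValueError, match="seed"):
            segmentation.grow_lacune(vol, (2, 2, 2), 350, 500)


class TestSkullStrip:
    def test_brain_mask_covers_tissue(self, shell_labels, truth_tpms,
                                      lesioned_subject):
        stripped, mask = segmentation.skull_strip(lesioned_subject["t1"], truth_tpms)
        tissue = np.asarray(shell_labels.data) != phantom.LABEL_CSF
        assert np.asarray(mask.data, bool)[tissue].all()

    def test_out_of_range_threshold_rejected(self, truth_tpms, lesioned_subject):
        with pytest.raises(ValueError):
            segmentation.skull_strip(lesioned_subject["t1"], truth_tpms,
                                     threshold=1.0)

    def test_disconnected_speck_removed(self):
        shape = (20, 20, 20)
        gm = np.zeros(shape)
        gm[8:12, 8:12, 8:12] = 1.0
        gm[1, 1, 1] = 0.2  # isolated speck above threshold
        zeros = np.zeros(shape)
        tpms = TPMSet(
            {"gm": Volume(gm), "wm": Volume(zeros), "csf": Volume(zeros)},
            validate=False,
        )
        _, mask = segmentation.skull_strip(Volume(np.ones(shape)), tpms)
        assert not mask.data[1, 1, 1]
        assert mask.data[9, 9, 9]
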