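"""Diffeomorphic warps: exponentials, registration, Jacobians, smoothing."""

import numpy as np
import pytest

from lesionmorph import phantom
from lesionmorph import registration as reg
from lesionmorph.tpm import TPMSet
from lesionmorph.volumes import Volume


@pytest.fixture(scope="module")
def smooth_velocity():
    return reg.random_velocity(
        (48, 48, 48), amplitude_vox=2.0, fwhm_vox=10.0,
        rng=np.random.default_rng(0),
    )


@pytest.fixture(scope="module")
def shell_tpms():
    spec = phantom.PhantomSpec(grid_shape=(32, 32, 32), wm_radius_mm=9.0,
                               gm_thickness_mm=3.0)
    return phantom.partial_volume_tpms(spec)


class TestExponential:
    def test_zero_velocity_gives_identity(self):
        v = reg.VelocityField(np.zeros((3, 8, 8, 8)))
        phi = reg.exp_velocity(v)
        assert np.allclose(phi.disp, 0.0)
        assert np.allclose(reg.jacobian_det(phi).data, 1.0)

    def test_uniform_translation_preserved(self):
        v = reg.VelocityField(np.zeros((3, 12, 12, 12)))
        v.disp[0] = 1.5
        phi = reg.exp_velocity(v)
        interior = (slice(None), slice(2, -2), slice(2, -2), slice(2, -2))
        assert np.allclose(phi.disp[interior][0], 1.5, atol=1e-6)
        assert np.allclose(
            reg.jacobian_det(phi).data[2:-2, 2:-2, 2:-2], 1.0, atol=1e-6
        )

    def test_forward_inverse_composition_below_tenth_voxel(self, smooth_velocity):
        phi = reg.exp_velocity(smooth_velocity)
        phi_inv = reg.exp_velocity(-smooth_velocity)
        residual = reg._compose_disp(phi.disp, phi_inv.disp)
        assert np.linalg.norm(residual, axis=0).max() < 0.1

    def test_jacobians_strictly_positive(self, smooth_velocity):
        jac = reg.jacobian_det(reg.exp_velocity(smooth_velocity))
        assert jac.data.min() > 0

    def test_non_finite_velocity_rejected(self):
        bad = np.zeros((3, 4, 4, 4))
        bad[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            reg.VelocityField(bad)


class TestWarping:
    def test_identity_warp_unchanged(self, shell_tpms):
        phi = reg.DeformationField(np.zeros((3,) + tuple(shell_tpms.shape)))
        out = reg.warp_volume(shell_tpms["gm"], phi)
        assert np.allclose(out.data, shell_tpms["gm"].data, atol=1e-12)

    def test_integer_translation_exact_at_order_zero(self):
        rng = np.random.default_rng(1)
        vol = Volume(rng.standard_normal((12, 12, 12)))
        disp = np.zeros((3, 12, 12, 12))
        disp[2] = 2.0  # sample from z + 2
        out = reg.warp_volume(vol, reg.DeformationField(disp), order=0)
        assert np.array_equal(out.data[:, :, :-2], vol.data[:, :, 2:])

    def test_warp_then_inverse_recovers_smooth_blob(self, smooth_velocity):
        g = np.indices((48, 48, 48))
        blob = np.exp(-(((g - 23.5) ** 2).sum(axis=0)) / (2 * 36.0))
        vol = Volume(blob)
        phi = reg.exp_velocity(smooth_velocity)
        phi_inv = reg.exp_velocity(-smooth_velocity)
        back = reg.warp_volume(reg.warp_volume(vol, phi), phi_inv)
        interior = (slice(3, -3),) * 3
        r = np.corrcoef(back.data[interior].ravel(), blob[interior].ravel())[0, 1]
        assert r >= 0.99

    def test_warped_mask_stays_binary(self, shell_tpms):
        v = reg.random_velocity((32, 32, 32), amplitude_vox=1.5, fwhm_vox=12.0,
                                rng=np.random.default_rng(5))
        mask = shell_tpms["gm"].with_data(
            (np.asarray(shell_tpms["gm"].data) > 0.5).astype(np.uint8)
        )
        out = reg.warp_mask(mask, reg.exp_velocity(v))
        assert set(np.unique(out.data)) <= {0, 1}


class TestJacobianAndModulation:
    def test_uniform_scaling_gives_cubed_determinant(self):
        n = 16
        g = _identity = np.indices((n, n, n)).astype(float)
        centre = (n - 1) / 2.0
        s = 1.1  # phi(x) = centre + s (x - centre)
        disp = (s - 1.0) * (g - centre)
        jac = reg.jacobian_det(reg.DeformationField(disp))
        assert np.allclose(jac.data, s**3, atol=1e-9)

    def test_modulation_identity_and_linearity(self, shell_tpms):
        ones = shell_tpms["gm"].with_data(np.ones(shell_tpms.shape))
        out = reg.modulate(shell_tpms["gm"], ones)
        assert np.array_equal(out.data, shell_tpms["gm"].data)
        twos = shell_tpms["gm"].with_data(np.full(shell_tpms.shape, 2.0))
        assert np.allclose(reg.modulate(shell_tpms["gm"], twos).data, 2 * out.data)

    def test_warped_modulated_gm_volume_conserved(self, shell_tpms):
        v = reg.random_velocity((32, 32, 32), amplitude_vox=1.5, fwhm_vox=10.0,
                                rng=np.random.default_rng(3))
        phi = reg.exp_velocity(v)
        warped = reg.warp_volume(shell_tpms["gm"], phi)
        mod = reg.modulate(warped, reg.jacobian_det(phi))
        native = float(np.sum(shell_tpms["gm"].data))
        assert abs(float(np.sum(mod.data)) - native) / native < 0.02


class TestRegisterPair:
    def test_identical_inputs_give_near_zero_velocity(self, shell_tpms):
        vel = reg.register_pair(shell_tpms, shell_tpms)
        phi = reg.exp_velocity(vel)
        assert np.abs(phi.disp).max() < 0.2

    def test_known_warp_recovered(self):
        spec = phantom.PhantomSpec(grid_shape=(48, 48, 48), wm_radius_mm=16.0,
                                   gm_thickness_mm=3.0)
        fixed = phantom.partial_volume_tpms(spec)
        v = reg.random_velocity((48, 48, 48), amplitude_vox=2.0, fwhm_vox=12.0,
                                rng=np.random.default_rng(4))
        phi = reg.exp_velocity(v)
        moving = TPMSet(
            {c: reg.warp_volume(fixed[c], phi).with_data(
                np.clip(reg.warp_volume(fixed[c], phi).data, 0, 1))
             for c in fixed.classes},
            validate=False,
        )
        shell_tpms = fixed
        interior = np.zeros((48, 48, 48), bool)
        interior[3:-3, 3:-3, 3:-3] = True

        def ssd(a: TPMSet, b: TPMSet) -> float:
            return sum(
                float(np.sum(((np.asarray(a[c].data) - np.asarray(b[c].data)) ** 2)[interior]))
                for c in a.classes
            )

        before = ssd(moving, shell_tpms)
        vel = reg.register_pair(moving, shell_tpms)
        phi_est = reg.exp_velocity(vel)
        warped = TPMSet(
            {c: reg.warp_volume(moving[c], phi_est) for c in moving.classes},
            validate=False,
        )
        assert ssd(warped, shell_tpms) <= 0.2 * before

    def test_mismatched_class_sets_rejected(self, shell_tpms):
        partial = TPMSet({"gm": shell_tpms["gm"]}, validate=False)
        with pytest.raises(ValueError, match="classes"):
            reg.register_pair(partial, shell_tpms)


class TestTemplate:
    def test_identical_subjects_reproduce_themselves(self, shell_tpms):
        template, vels = reg.build_template([shell_tpms, shell_tpms], n_outer=1)
        for c in shell_tpms.classes:
            diff = np.mean((template[c].data - shell_tpms[c].data) ** 2)
            assert diff < 1e-4
        for v in vels:
            assert np.abs(v.disp).max() < 0.5

    def test_zero_outer_iterations_is_plain_average(self, shell_tpms):
        other = TPMSet(
            {c: shell_tpms[c].with_data(np.roll(shell_tpms[c].data, 2, axis=0))
             for c in shell_tpms.classes},
            validate=False,
        )
        template, _ = reg.build_template([shell_tpms, other], n_outer=0)
        expected = 0.5 * (shell_tpms["gm"].data + other["gm"].data)
        assert np.allclose(template["gm"].data, expected, atol=1e-12)

    def test_template_sharper_than_naive_average_of_opposite_warps(self, shell_tpms):
        v = reg.random_velocity((32, 32, 32), amplitude_vox=2.0, fwhm_vox=10.0,
                                rng=np.random.default_rng(6))
        subs = []
        for vel in (v, -v):
            phi = reg.exp_velocity(vel)
            subs.append(TPMSet(
                {c: reg.warp_volume(shell_tpms[c], phi).with_data(
                    np.clip(reg.warp_volume(shell_tpms[c], phi).data, 0, 1))
                 for c in shell_tpms.classes},
                validate=False,
            ))
        naive, _ = reg.build_template(subs, n_outer=0)
        template, _ = reg.build_template(subs, n_outer=2)
        # registration re-concentrates the blurred-out GM probability mass
        assert (template["gm"].data > 0.9).sum() > (naive["gm"].data > 0.9).sum()


class TestWarpedWeightedSmooth:
    def test_constant_field_reproduced_in_support(self, shell_tpms):
        w = shell_tpms["gm"]
        t = w.with_data(np.full(w.shape, 2.5))
        out = reg.warped_weighted_smooth(t, w, fwhm_mm=6.0)
        support = np.asarray(w.data) > 0.5
        assert np.allclose(out.data[support], 2.5, atol=1e-6)

    def test_output_bounded_by_input_range(self):
        shape = (24, 24, 24)
        w = np.zeros(shape)
        w[8:16, 8:16, 8:16] = 1.0
        t = np.zeros(shape)
        t[8:12] = 2.0
        t[12:16] = 4.0
        out = reg.warped_weighted_smooth(Volume(t * (w > 0)), Volume(w), 6.0)
        inside = w > 0
        assert out.data[inside].min() >= 2.0 - 1e-9
        assert out.data[inside].max() <= 4.0 + 1e-9

    def test_all_zero_weights_rejected(self):
        z = Volume(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError):
            reg.warped_weighted_smooth(z, z, 6.0)
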