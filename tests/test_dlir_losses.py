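"""Loss oracles, mutual information estimators, warping and the U-Net shape."""

import numpy as np
import pytest

from mrgart.autodiff import Tensor
from mrgart.dlir import (
    RegistrationConfig,
    build_network,
    encoder_output_shape,
    l2_penalty,
    mutual_information,
    mutual_information_hard,
    smoothness_loss,
    soft_mutual_information_tensor,
    total_loss,
    warp,
)
from mrgart.volume import DisplacementField, Volume3D


def smoothness_bruteforce(u):
    """Nested-loop forward-difference oracle for the gradient penalty."""
    total = 0.0
    _, nx, ny, nz = u.shape
    for c in range(3):
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    if i + 1 < nx:
                        total += (u[c, i + 1, j, k] - u[c, i, j, k]) ** 2
                    if j + 1 < ny:
                        total += (u[c, i, j + 1, k] - u[c, i, j, k]) ** 2
                    if k + 1 < nz:
                        total += (u[c, i, j, k + 1] - u[c, i, j, k]) ** 2
    return total


class TestFieldRegularizers:
    def test_constant_field_zero_smoothness(self):
        u = np.full((3, 5, 5, 5), 2.5)
        assert smoothness_loss(u) == 0.0

    def test_linear_field_closed_form(self):
        # u_x = a*x: every forward x-difference equals a; count = (nx-1)*ny*nz
        a, n = 0.7, 6
        u = np.zeros((3, n, n, n))
        u[0] = a * np.arange(n)[:, None, None]
        expected = a**2 * (n - 1) * n * n
        assert smoothness_loss(u) == pytest.approx(expected, rel=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(3, 8, 8, 8))
        assert smoothness_loss(u) == pytest.approx(smoothness_bruteforce(u), rel=1e-6)

    def test_l2_zero_and_unit(self):
        assert l2_penalty(np.zeros((3, 4, 4, 4))) == 0.0
        u = np.zeros((3, 4, 4, 4)); u[0] = 1.0
        assert l2_penalty(u) == pytest.approx(4 * 4 * 4)

    def test_l2_matches_sum_of_squares(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(3, 8, 8, 8))
        assert l2_penalty(u) == pytest.approx(float((u**2).sum()), rel=1e-12)

    @pytest.mark.parametrize("c", [0.0, 0.5, 2.0, -3.0])
    def test_degree_two_homogeneity(self, c):
        rng = np.random.default_rng(2)
        u = rng.normal(size=(3, 6, 6, 6))
        assert smoothness_loss(c * u) == pytest.approx(c**2 * smoothness_loss(u), rel=1e-9)
        assert l2_penalty(c * u) == pytest.approx(c**2 * l2_penalty(u), rel=1e-9)


class TestMutualInformation:
    def test_two_level_self_mi_is_ln2(self):
        img = np.zeros((8, 8, 8)); img.ravel()[:256] = 1.0
        mi, dist = mutual_information_hard(img, img, bins=16)
        assert mi == pytest.approx(np.log(2.0), abs=1e-12)
        assert dist.joint.sum() == pytest.approx(1.0)

    def test_constant_image_gives_zero(self):
        f = np.random.default_rng(0).random((6, 6, 6))
        w = np.ones((6, 6, 6))
        assert mutual_information_hard(f, w)[0] == 0.0

    def test_permuted_pair_near_zero(self):
        rng = np.random.default_rng(3)
        f = rng.random(120_000)
        w = rng.permutation(f)
        mi, _ = mutual_information_hard(f, w, bins=16)
        assert mi < 0.05

    def test_mi_bounded_by_entropies(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            f = rng.random((12, 12, 12))
            w = f + 0.3 * rng.random((12, 12, 12))
            mi, dist = mutual_information_hard(f, w, bins=8)
            hf = -np.sum(dist.marginal_f[dist.marginal_f > 0] * np.log(dist.marginal_f[dist.marginal_f > 0]))
            hw = -np.sum(dist.marginal_w[dist.marginal_w > 0] * np.log(dist.marginal_w[dist.marginal_w > 0]))
            assert 0.0 <= mi <= min(hf, hw) + 1e-12

    def test_self_mi_equals_entropy(self):
        rng = np.random.default_rng(5)
        f = rng.random((10, 10, 10))
        mi, dist = mutual_information_hard(f, f, bins=8)
        pf = dist.marginal_f
        hf = -np.sum(pf[pf > 0] * np.log(pf[pf > 0]))
        assert mi == pytest.approx(hf, abs=1e-12)

    def test_soft_approaches_hard_as_kernel_narrows(self):
        rng = np.random.default_rng(6)
        f = rng.random((16, 16, 8))
        w = np.sqrt(f) + 0.05 * rng.random(f.shape)
        hard, _ = mutual_information_hard(f, w, bins=16)
        gaps = []
        for ratio in (1.0, 0.5, 0.25):
            soft, _ = mutual_information(f, w, bins=16, estimator="soft", sigma_ratio=ratio)
            gaps.append(abs(soft - hard))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] / hard < 0.05

    def test_masked_variant_restricts_population(self):
        rng = np.random.default_rng(7)
        f = rng.random((10, 10, 10))
        w = rng.random((10, 10, 10))
        mask = np.zeros_like(f, dtype=bool); mask[:5] = True
        mi_mask, _ = mutual_information_hard(f, w, mask=mask)
        mi_sub, _ = mutual_information_hard(f[:5], w[:5])
        assert mi_mask == pytest.approx(mi_sub, abs=1e-12)

    def test_empty_mask_raises(self):
        f = np.random.default_rng(8).random((6, 6, 6))
        with pytest.raises(ValueError, match="mask"):
            mutual_information_hard(f, f, mask=np.zeros_like(f, dtype=bool))


class TestWarp:
    def test_zero_field_is_exact_identity(self):
        rng = np.random.default_rng(0)
        m = Volume3D(rng.random((6, 7, 8)))
        out = warp(m, DisplacementField(np.zeros((3, 6, 7, 8))))
        np.testing.assert_array_equal(out.data, m.data)

    def test_integer_shift_matches_index_shift(self):
        rng = np.random.default_rng(1)
        m = Volume3D(rng.random((8, 8, 8)))
        u = np.zeros((3, 8, 8, 8)); u[0] = 1.0
        out = warp(m, DisplacementField(u))
        np.testing.assert_allclose(out.data[:-1], m.data[1:], atol=1e-12)
        np.testing.assert_allclose(out.data[-1], m.data[-1], atol=1e-12)  # border clamp

    def test_half_voxel_shift_on_ramp(self):
        n = 8
        ramp = np.broadcast_to(np.arange(n, dtype=float)[:, None, None], (n, n, n)).copy()
        u = np.zeros((3, n, n, n)); u[0] = 0.5
        out = warp(Volume3D(ramp), DisplacementField(u))
        np.testing.assert_allclose(out.data[: n - 1], ramp[: n - 1] + 0.5, atol=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            warp(Volume3D(np.zeros((4, 4, 4))), DisplacementField(np.zeros((3, 5, 5, 5))))


class TestNetworkArchitecture:
    def test_clinical_scale_encoder_shape(self):
        assert encoder_output_shape((256, 256, 128), n_levels=4) == (16, 16, 8)

    def test_desk_scale_encoder_shape(self):
        assert encoder_output_shape((64, 64, 32), n_levels=4) == (4, 4, 2)

    def test_desk_scale_forward_shapes(self):
        cfg = RegistrationConfig(base_channels=4, seed=0)
        model = build_network(cfg)
        x = Tensor(np.zeros((2, 32, 32, 16), dtype=np.float32))
        feats = model.encoder_forward(x)
        assert feats[-1].data.shape == (8, 2, 2, 1)
        field = model.forward(x)
        assert field.data.shape == (3, 32, 32, 16)

    def test_indivisible_axis_reported(self):
        cfg = RegistrationConfig()
        with pytest.raises(ValueError, match="axis 0"):
            cfg.validate_shape((60, 64, 32))

    def test_seeded_init_is_deterministic(self):
        a = build_network(RegistrationConfig(seed=42))
        b = build_network(RegistrationConfig(seed=42))
        for k in a.params:
            np.testing.assert_array_equal(a.params[k].data, b.params[k].data)


class TestTotalLoss:
    def test_identity_registration_gives_negative_entropy(self):
        rng = np.random.default_rng(0)
        f = rng.random((8, 8, 8))
        cfg = RegistrationConfig(lambda1=0.0, lambda2=0.0, mi_bins=8)
        value, comps = total_loss(f, f, np.zeros((3, 8, 8, 8)), cfg)
        mi_self, dist = mutual_information_hard(f, f, bins=8)
        assert value == pytest.approx(-mi_self, abs=1e-12)
        assert comps["smoothness"] == 0.0 and comps["l2"] == 0.0

    def test_lambda_composition_with_defaults(self):
        rng = np.random.default_rng(1)
        f, m = rng.random((8, 8, 8)), rng.random((8, 8, 8))
        u = rng.normal(scale=0.5, size=(3, 8, 8, 8))
        cfg = RegistrationConfig()  # lambda1 = 1e-2, lambda2 = 1e-5
        assert (cfg.lambda1, cfg.lambda2) == (1e-2, 1e-5)
        value, comps = total_loss(f, m, u, cfg)
        expected = comps["similarity"] + 1e-2 * smoothness_loss(u) + 1e-5 * l2_penalty(u)
        assert value == pytest.approx(expected, rel=1e-12)

    def test_zero_lambdas_leave_similarity_only(self):
        rng = np.random.default_rng(2)
        f, m = rng.random((8, 8, 8)), rng.random((8, 8, 8))
        u = rng.normal(scale=0.5, size=(3, 8, 8, 8))
        cfg = RegistrationConfig(lambda1=0.0, lambda2=0.0)
        value, comps = total_loss(f, m, u, cfg)
        assert value == pytest.approx(comps["similarity"], rel=1e-12)


class TestEndToEndGradient:
    def test_analytic_gradient_matches_numerical(self):
        """Full objective (soft MI + regularizers) vs central differences."""
        rng = np.random.default_rng(3)
        n = 8
        f = rng.random((n, n, n))
        m = rng.random((n, n, n))
        u0 = rng.normal(scale=0.3, size=(3, n, n, n))
        lam1, lam2 = 1e-2, 1e-5

        def objective(u_arr):
            from mrgart.autodiff import warp_trilinear

            u = Tensor(np.asarray(u_arr, dtype=np.float64), requires_grad=True)
            w = warp_trilinear(m, u)
            mi = soft_mutual_information_tensor(f, w, bins=8, sigma_ratio=1.0)
            dx = u[:, 1:, :, :] - u[:, :-1, :, :]
            dy = u[:, :, 1:, :] - u[:, :, :-1, :]
            dz = u[:, :, :, 1:] - u[:, :, :, :-1]
            smooth = (dx * dx).sum() + (dy * dy).sum() + (dz * dz).sum()
            loss = (-1.0) * mi + lam1 * smooth + lam2 * (u * u).sum()
            return loss, u

        loss, u = objective(u0)
        loss.backward()
        h = 1e-5
        rng2 = np.random.default_rng(4)
        for _ in range(12):
            c = rng2.integers(0, 3)
            i, j, k = rng2.integers(0, n, size=3)
            up = u0.copy(); up[c, i, j, k] += h
            dn = u0.copy(); dn[c, i, j, k] -= h
            num = (float(objective(up)[0].data) - float(objective(dn)[0].data)) / (2 * h)
            ana = u.grad[c, i, j, k]
            assert ana == pytest.approx(num, rel=1e-3, abs=1e-7)
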