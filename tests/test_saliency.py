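"""CAM / Grad-CAM computation, upsampling and normalisation."""

import numpy as np
import pytest

import camconcord as cx
from camconcord import models as mz
from camconcord import masks_metrics as mm
from camconcord.saliency import (
    CamCompatibilityError,
    cam,
    grad_cam,
    grad_cam_weights,
    normalize01,
    upsample,
    SaliencyMap,
)


class FixedMapsAdapter(mz.ModelAdapter):
    """CAM-compatible toy: fixed feature maps, linear GAP->dense head."""

    cam_compatible = True

    def __init__(self, fmaps: np.ndarray, weights: np.ndarray, id="toy"):
        self.fmaps = np.asarray(fmaps, dtype=np.float64)  # (h, w, K)
        self.weights = np.asarray(weights, dtype=np.float64)  # (K, 2)
        self.id = id

    def feature_maps(self, image):
        return self.fmaps

    def gap_values(self, image):
        return self.fmaps.mean(axis=(0, 1))

    def classifier_weights(self, class_c):
        return self.weights[:, class_c]

    def score(self, image, class_c):
        return float(self.gap_values(image) @ self.weights[:, class_c])

    def probabilities(self, image):
        z = self.gap_values(image) @ self.weights
        z = z - z.max()
        p = np.exp(z)
        return p / p.sum()

    def feature_gradients(self, image, class_c):
        h, w, k = self.fmaps.shape
        return np.broadcast_to(self.weights[:, class_c] / (h * w), (h, w, k)).copy()


class NonlinearHeadAdapter(mz.ModelAdapter):
    """Non-CAM toy whose score is nonlinear in the feature maps.

    The 'image' *is* the two feature maps, so finite differences can perturb
    the activations directly: y^1 = w1*G1 + w2*G2 + 0.5*G1^2 with
    G_k = GAP(A^k), hence dy/dA^1_ij = (w1 + G1)/Z and dy/dA^2_ij = w2/Z.
    """

    cam_compatible = False
    id = "nonlinear-toy"
    w = (0.7, -0.4)

    def feature_maps(self, image):
        return np.asarray(image, dtype=np.float64)

    def score(self, image, class_c):
        g = self.feature_maps(image).mean(axis=(0, 1))
        return float(self.w[0] * g[0] + self.w[1] * g[1] + 0.5 * g[0] ** 2)

    def feature_gradients(self, image, class_c):
        a = self.feature_maps(image)
        h, w, _ = a.shape
        g = a.mean(axis=(0, 1))
        per_channel = np.array([self.w[0] + g[0], self.w[1]])
        return np.broadcast_to(per_channel / (h * w), (h, w, 2)).copy()

    def probabilities(self, image):
        return np.array([0.0, 1.0])

    def gap_values(self, image):
        return self.feature_maps(image).mean(axis=(0, 1))

    def classifier_weights(self, class_c):  # pragma: no cover
        raise NotImplementedError


class TestCam:
    def test_single_unit_weight_returns_the_feature_map(self, rng):
        f = rng.random((4, 4, 1))
        adapter = FixedMapsAdapter(f, np.array([[1.0, 0.0]]))
        np.testing.assert_allclose(cam(adapter, None, 0).values, f[:, :, 0])

    def test_linearity_in_the_weights(self, rng):
        f = rng.random((4, 4, 2))
        adapter = FixedMapsAdapter(f, np.array([[1.0, 2.0], [-1.0, 0.5]]))
        np.testing.assert_allclose(
            cam(adapter, None, 0).values, f[:, :, 0] - f[:, :, 1]
        )
        # map(c) + map(c') = sum_k (w_kc + w_kc') f_k
        total = cam(adapter, None, 0).values + cam(adapter, None, 1).values
        expected = 3.0 * f[:, :, 0] + (-0.5) * f[:, :, 1]
        np.testing.assert_allclose(total, expected)

    def test_matches_double_loop_oracle_on_trained_cnn(self, trained_model, test_images):
        for sample in test_images[:5]:
            smap = cam(trained_model, sample.pixels, 1)
            fmaps = trained_model.feature_maps(sample.pixels)
            weights = trained_model.classifier_weights(1)
            h, w, k = fmaps.shape
            expected = np.zeros((h, w))
            for ki in range(k):
                for y in range(h):
                    for x in range(w):
                        expected[y, x] += weights[ki] * fmaps[y, x, ki]
            np.testing.assert_allclose(smap.values, expected, atol=1e-6)

    def test_non_cam_compatible_adapter_rejected(self):
        with pytest.raises(CamCompatibilityError, match="not CAM-compatible"):
            cam(NonlinearHeadAdapter(), np.zeros((4, 4, 2)), 0)

    def test_predicted_class_is_default(self, trained_model, test_images):
        img = test_images[0].pixels
        pred = int(np.argmax(trained_model.probabilities(img)))
        assert cam(trained_model, img).class_index == pred


class TestGradCam:
    def test_relu_annihilates_nonpositive_combinations(self, rng):
        f = rng.random((4, 4, 1))
        adapter = FixedMapsAdapter(f, np.array([[-1.0, 1.0]]))
        out = grad_cam(adapter, None, 0)  # alpha < 0, maps >= 0
        assert (out.values == 0).all()
        assert out.method == "GradCAM"

    def test_equals_relu_cam_over_z_on_cam_compatible_model(
        self, trained_model, test_images
    ):
        # chain rule through mean-GAP gives alpha_kc = w_kc / Z
        for sample in test_images[:5]:
            c = int(np.argmax(trained_model.probabilities(sample.pixels)))
            g = grad_cam(trained_model, sample.pixels, c).values
            m = cam(trained_model, sample.pixels, c).values
            z = g.size
            np.testing.assert_allclose(g, np.maximum(m, 0) / z, atol=1e-5)

    def test_alpha_matches_central_finite_differences_on_toy_model(self, rng):
        adapter = NonlinearHeadAdapter()
        maps = rng.random((6, 6, 2))
        cw = grad_cam_weights(adapter, maps, 1)
        eps = 1e-3
        fd_alpha = np.zeros(2)
        for k in range(2):
            grads = np.zeros((6, 6))
            for i in range(6):
                for j in range(6):
                    p = maps.copy()
                    p[i, j, k] += eps
                    m_ = maps.copy()
                    m_[i, j, k] -= eps
                    grads[i, j] = (
                        adapter.score(p, 1) - adapter.score(m_, 1)
                    ) / (2 * eps)
            fd_alpha[k] = grads.mean()
        np.testing.assert_allclose(cw.alpha, fd_alpha, rtol=1e-2)
        assert cw.z == 36

    def test_unknown_layer_rejected(self, trained_model, test_images):
        with pytest.raises(ValueError, match="layer"):
            grad_cam(trained_model, test_images[0].pixels, 1, layer="conv1")


def _bilinear_oracle(src, th, tw):
    """Loop-based align-corners bilinear interpolation."""
    h, w = src.shape
    out = np.zeros((th, tw))
    for i in range(th):
        for j in range(tw):
            y = i * (h - 1) / (th - 1) if th > 1 else 0.0
            x = j * (w - 1) / (tw - 1) if tw > 1 else 0.0
            y0, x0 = int(np.floor(y)), int(np.floor(x))
            y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
            fy, fx = y - y0, x - x0
            out[i, j] = (
                src[y0, x0] * (1 - fy) * (1 - fx)
                + src[y0, x1] * (1 - fy) * fx
                + src[y1, x0] * fy * (1 - fx)
                + src[y1, x1] * fy * fx
            )
    return out


def _smap(values, method="CAM"):
    values = np.asarray(values, dtype=np.float64)
    return SaliencyMap(
        values=values, method=method, model_id="m", class_index=1,
        source_size=values.shape,
    )


class TestUpsample:
    def test_constant_map_stays_constant(self):
        out = upsample(_smap(np.full((3, 3), 0.4)), (9, 9))
        np.testing.assert_allclose(out.values, 0.4)
        assert out.target_size == (9, 9)

    def test_same_size_is_identity(self, rng):
        v = rng.random((5, 5))
        np.testing.assert_array_equal(upsample(_smap(v), (5, 5)).values, v)

    def test_matches_hand_bilinear_oracle(self, rng):
        src = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = upsample(_smap(src), (4, 4)).values
        np.testing.assert_allclose(out, _bilinear_oracle(src, 4, 4), atol=1e-12)
        v = rng.random((3, 5))
        np.testing.assert_allclose(
            upsample(_smap(v), (7, 11)).values, _bilinear_oracle(v, 7, 11), atol=1e-12
        )

    def test_no_overshoot_beyond_source_range(self, rng):
        v = rng.random((4, 4))
        out = upsample(_smap(v), (13, 13)).values
        assert out.min() >= v.min() - 1e-12
        assert out.max() <= v.max() + 1e-12

    def test_downsampling_rejected(self, rng):
        with pytest.raises(ValueError, match="downsampling"):
            upsample(_smap(rng.random((4, 4))), (2, 8))


class TestNormalize01:
    def test_affine_rescale_example(self):
        out = normalize01(_smap([[2.0, 4.0], [6.0, 8.0]]))
        np.testing.assert_allclose(
            out.values, [[0.0, 1 / 3], [2 / 3, 1.0]]
        )
        assert not out.degenerate

    def test_constant_map_becomes_zeros_and_degenerate(self):
        out = normalize01(_smap(np.full((3, 3), 5.0)))
        assert out.degenerate
        np.testing.assert_array_equal(out.values, 0.0)

    def test_output_attains_both_bounds(self, rng):
        out = normalize01(_smap(rng.normal(size=(6, 6))))
        assert out.values.min() == 0.0 and out.values.max() == 1.0


class TestDownstreamInvariances:
    def test_gap_limit_equivalence_binarized_gradcam_equals_relu_cam(
        self, trained_model, test_images
    ):
        """Grad-CAM generalises CAM: on a GAP architecture the Otsu masks of
        Grad-CAM and ReLU(CAM) coincide bit-exactly."""
        for sample in test_images[:8]:
            c = int(np.argmax(trained_model.probabilities(sample.pixels)))
            g = normalize01(upsample(grad_cam(trained_model, sample.pixels, c), (32, 32)))
            m_raw = cam(trained_model, sample.pixels, c)
            m_relu = _smap(np.maximum(m_raw.values, 0.0))
            m = normalize01(upsample(m_relu, (32, 32)))
            if g.degenerate or m.degenerate:
                assert g.degenerate and m.degenerate
                continue
            mask_g = mm.binarize(g, mm.otsu_threshold(g)).mask
            mask_m = mm.binarize(m, mm.otsu_threshold(m)).mask
            np.testing.assert_array_equal(mask_g, mask_m)

    def test_positive_scaling_leaves_otsu_mask_and_com_unchanged(self, rng):
        v = rng.random((16, 16))
        for scale in (0.25, 7.0):
            a = normalize01(_smap(v))
            b = normalize01(_smap(v * scale))
            ta, tb = mm.otsu_threshold(a), mm.otsu_threshold(b)
            assert ta == tb
            np.testing.assert_array_equal(
                mm.binarize(a, ta).mask, mm.binarize(b, tb).mask
            )
            ca = mm.centre_of_mass(a)
            cb = mm.centre_of_mass(b)
            assert ca.x_cm == pytest.approx(cb.x_cm) and ca.y_cm == pytest.approx(cb.y_cm)
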