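import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corticalhue import (
    HueModel,
    LayerConfig,
    RectifierParams,
    compute_mv4_weights,
    gaussian_kernel,
    rectify,
)
from corticalhue.config import (
    MLGN_TYPES,
    MV2_ADDITIVE_TYPES,
    MV2_MULTIPLICATIVE_TYPES,
    MV2_TYPES,
    OpponentCellSpec,
    default_opponent_specs,
)
from corticalhue.errors import ConfigError, InputDomainError
from corticalhue.network import (
    LayerResponses,
    convolve_gaussian,
    mlgn_response,
    mv1_response,
    mv2_additive,
    mv2_multiplicative,
    mv2_pooling,
    mv4_response,
)
from corticalhue.stimuli import StimulusSpec, uniform_hue_field

from conftest import direct_gaussian_convolve


class TestRectifier:
    @pytest.mark.parametrize(
        "p, params, expected",
        [
            (-0.4, RectifierParams(1, 0, 0, 1), 0.0),   # below threshold
            (0.3, RectifierParams(1, 0, 0, 1), 0.3),    # linear band
            (1.7, RectifierParams(1, 0, 0, 1), 1.0),    # saturated
            (-0.5, RectifierParams(1, 0, -1, 1), -0.5),  # linear mLGN setting
        ],
    )
    def test_branch_table(self, p, params, expected):
        assert rectify(p, params) == pytest.approx(expected, abs=0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=st.floats(-100, 100), tau=st.floats(-1, 0.5), s=st.floats(0.5, 1))
    def test_output_confined_to_tau_one(self, p, tau, s):
        out = float(rectify(p, RectifierParams(1, 0, tau, s)))
        assert tau <= out <= 1.0


class TestGaussianKernel:
    @pytest.mark.parametrize("sigma, size", [(0.5, 3), (2.375, 19), (25.0, 153)])
    def test_normalized(self, sigma, size):
        k = gaussian_kernel(sigma, size)
        assert k.shape == (size, size)
        assert k.sum() == pytest.approx(1.0, abs=1e-12)

    def test_four_fold_symmetry(self):
        k = gaussian_kernel(1.7, 9)
        assert np.allclose(k, k[::-1])
        assert np.allclose(k, k[:, ::-1])
        assert np.allclose(k, k.T)

    def test_delta_limit(self):
        k = gaussian_kernel(1e-3, 7)
        assert k[3, 3] == pytest.approx(1.0, abs=1e-12)

    def test_even_size_rejected(self):
        with pytest.raises(InputDomainError):
            gaussian_kernel(1.0, 8)


class TestConvolution:
    def test_matches_direct_windowed_sum(self):
        """Separable implementation equals the naive direct sum (edge padding)."""
        rng = np.random.default_rng(7)
        img = rng.uniform(size=(16, 16))
        for sigma, size in [(0.8, 5), (2.0, 9)]:
            ours = convolve_gaussian(img, sigma, size)
            oracle = direct_gaussian_convolve(img, gaussian_kernel(sigma, size))
            assert np.max(np.abs(ours - oracle)) < 1e-10

    def test_kernel_larger_than_image_rejected(self):
        with pytest.raises(ConfigError):
            convolve_gaussian(np.zeros((8, 8)), 1.0, 9)


class TestMlgn:
    def _toy_spec(self):
        return OpponentCellSpec(
            name="L-on",
            centre_weights=(1.0, 0.0, 0.0),
            surround_weights=(0.5, 0.5, 0.0),
            centre_sigmas=(0.6, 0.6, 0.6),
            surround_sigmas=(1.2, 1.2, 1.2),
            rf_size=5,
        )

    def test_zero_input_zero_output(self):
        rect = RectifierParams(tau=-1.0, s=1.0)
        out = mlgn_response(np.zeros((8, 8, 3)), self._toy_spec(), rect)
        assert np.allclose(out, 0.0, atol=1e-14)

    def test_uniform_input_closed_form(self):
        """Uniform cones (1,0,0): 1*1 - 0.5*1 - 0.5*0 = 0.5 everywhere."""
        cones = np.zeros((12, 12, 3))
        cones[..., 0] = 1.0
        rect = RectifierParams(tau=-1.0, s=1.0)
        out = mlgn_response(cones, self._toy_spec(), rect)
        assert np.allclose(out, 0.5, atol=1e-12)

    def test_matches_brute_force_on_random_input(self):
        rng = np.random.default_rng(3)
        cones = rng.uniform(size=(16, 16, 3))
        spec = self._toy_spec()
        rect = RectifierParams(tau=-1.0, s=1.0)
        ours = mlgn_response(cones, spec, rect)
        acc = np.zeros((16, 16))
        for i in range(3):
            if spec.centre_weights[i]:
                acc += spec.centre_weights[i] * direct_gaussian_convolve(
                    cones[..., i], gaussian_kernel(spec.centre_sigmas[i], 5)
                )
            if spec.surround_weights[i]:
                acc -= spec.surround_weights[i] * direct_gaussian_convolve(
                    cones[..., i], gaussian_kernel(spec.surround_sigmas[i], 5)
                )
        assert np.max(np.abs(ours - rectify(acc, rect))) < 1e-10

    def test_kernel_too_large_is_config_error(self):
        spec = self._toy_spec()
        with pytest.raises(ConfigError):
            mlgn_response(np.zeros((3, 3, 3)), spec, RectifierParams())


@pytest.fixture(scope="module")
def tiny_cfg():
    return LayerConfig(
        image_size=16,
        rf_sizes={"mLGN": 5, "mV1": 5, "mV2": 5, "mV4": 5},
        sigma_mv1=1.0,
        sigma_mv2=1.0,
        sigma_mv4=1.0,
    )


class TestMv1AndMv2:
    def test_all_negative_map_rectified_to_zero(self, tiny_cfg):
        out = mv1_response(-np.ones((8, 8)), tiny_cfg)
        assert np.all(out == 0.0)

    def test_uniform_map_preserved(self, tiny_cfg):
        out = mv1_response(np.full((8, 8), 0.37), tiny_cfg)
        assert np.allclose(out, 0.37, atol=1e-12)

    def test_mv1_matches_direct_smooth_and_clip(self, tiny_cfg):
        rng = np.random.default_rng(11)
        m = rng.uniform(-0.5, 0.5, size=(12, 12))
        ours = mv1_response(m, tiny_cfg)
        oracle = np.clip(
            direct_gaussian_convolve(m, gaussian_kernel(tiny_cfg.sigma_mv1, 5)), 0, 1
        )
        assert np.max(np.abs(ours - oracle)) < 1e-10

    def test_mv2_additive_zero_input(self, tiny_cfg):
        assert np.all(mv2_additive(np.zeros((8, 8)), tiny_cfg) == 0.0)

    def test_multiplicative_annihilator(self, tiny_cfg):
        rng = np.random.default_rng(1)
        lm = rng.uniform(size=(8, 8))
        out = mv2_multiplicative(lm, np.zeros((8, 8)), tiny_cfg)
        assert np.allclose(out, 0.0, atol=1e-14)

    def test_multiplicative_identity(self, tiny_cfg):
        out = mv2_multiplicative(np.ones((8, 8)), np.ones((8, 8)), tiny_cfg)
        assert np.allclose(out, 1.0, atol=1e-12)

    def test_multiplicative_uniform_closed_form(self, tiny_cfg):
        u, v = 0.6, 0.7
        out = mv2_multiplicative(np.full((8, 8), u), np.full((8, 8), v), tiny_cfg)
        assert np.allclose(out, u * v, atol=1e-12)

    def test_multiplicative_shape_mismatch(self, tiny_cfg):
        with pytest.raises(InputDomainError):
            mv2_multiplicative(np.zeros((8, 8)), np.zeros((4, 4)), tiny_cfg)

    def test_pooling_zero_input(self, tiny_cfg):
        out = mv2_pooling(np.zeros((8, 8)), tiny_cfg, threshold=0.2)
        assert np.all(out == 0.0)

    def test_pooling_uniform_closed_form(self, tiny_cfg):
        out = mv2_pooling(np.full((8, 8), 0.5), tiny_cfg, threshold=0.2)
        assert np.allclose(out, 0.3, atol=1e-12)

    def test_pooling_window_larger_than_image(self, tiny_cfg):
        with pytest.raises(ConfigError):
            mv2_pooling(np.zeros((2, 2)), tiny_cfg, threshold=0.1)


class TestMv4Weights:
    def test_equal_distances_uniform_row(self):
        w = compute_mv4_weights(np.full(14, 90.0), np.full(6, 30.0), sigma=25.0)
        assert np.allclose(w.w, 1.0 / 14.0, atol=1e-12)

    def test_rows_sum_to_one(self, model):
        assert np.allclose(model.weight_matrix.w.sum(axis=1), 1.0, atol=1e-12)

    def test_gaussian_ratio_at_one_sigma(self):
        sigma = 30.0
        peaks = np.zeros(14)
        peaks[1] = sigma
        w = compute_mv4_weights(peaks, np.zeros(6), sigma=sigma)
        assert w.w[0, 0] / w.w[0, 1] == pytest.approx(np.exp(0.5), rel=1e-12)

    def test_wrap_around_distance(self):
        w = compute_mv4_weights(np.full(14, 350.0), np.full(6, 10.0), sigma=30.0)
        assert np.allclose(w.d, 20.0)


class TestMv4Response:
    def test_zero_maps_give_zero(self, tiny_cfg):
        v2 = LayerResponses("mV2", {t: np.zeros((8, 8)) for t in MV2_TYPES})
        w = compute_mv4_weights(np.zeros(14), np.zeros(6), sigma=30.0)
        out = mv4_response(v2, w, tiny_cfg)
        assert all(np.all(out[name] == 0.0) for name in out.labels)

    def test_single_active_map_reads_its_weight(self, tiny_cfg):
        maps = {t: np.zeros((8, 8)) for t in MV2_TYPES}
        maps[MV2_TYPES[3]] = np.ones((8, 8))
        v2 = LayerResponses("mV2", maps)
        w = compute_mv4_weights(np.arange(14) * 20.0, np.arange(6) * 60.0, sigma=30.0)
        out = mv4_response(v2, w, tiny_cfg)
        for i, name in enumerate(out.labels):
            assert np.allclose(out[name], w.w[i, 3], atol=1e-10)

    def test_wrong_map_set_rejected(self, tiny_cfg):
        v2 = LayerResponses("mV2", {"only": np.zeros((8, 8))})
        w = compute_mv4_weights(np.zeros(14), np.zeros(6), sigma=30.0)
        with pytest.raises(InputDomainError):
            mv4_response(v2, w, tiny_cfg)


class TestFullModel:
    def test_layer_map_counts(self, small_model):
        img = uniform_hue_field(StimulusSpec(30.0, 1.0, 0.5, 32))
        layers = small_model.run_model(img)
        assert [len(layers[k].maps) for k in ("mLGN", "mV1", "mV2", "mV4")] == [6, 6, 14, 6]
        assert tuple(layers["mV2"].labels) == MV2_TYPES

    def test_responses_within_rectifier_ranges(self, small_model):
        img = uniform_hue_field(StimulusSpec(200.0, 1.0, 0.5, 32))
        layers = small_model.run_model(img)
        assert np.all(layers["mLGN"].stack() >= -1.0)
        for name in ("mV1", "mV2", "mV4"):
            s = layers[name].stack()
            assert np.all(s >= 0.0) and np.all(s <= 1.0)

    def test_achromatic_input_silences_opponency(self, small_model):
        img = uniform_hue_field(StimulusSpec(0.0, 0.0, 0.5, 32))
        layers = small_model.run_model(img)
        on = layers["mLGN"]["L-on"]
        off = layers["mLGN"]["L-off"]
        assert np.max(np.abs(on)) < 1e-9 and np.max(np.abs(off)) < 1e-9

    def test_centre_pixel_matches_closed_form(self, model):
        """Full 256 px spatial run agrees with the uniform-stimulus algebra."""
        img = uniform_hue_field(StimulusSpec(96.0, 1.0, 0.5, 256))
        layers = model.run_model(img)
        pooled = model.run_pooled(img)
        cr = model.centre_responses(96.0)
        c = 128
        for layer in ("mLGN", "mV1", "mV2", "mV4"):
            for lab in layers[layer].labels:
                assert layers[layer][lab][c, c] == pytest.approx(cr[layer][lab], abs=1e-10)
        for lab in pooled.labels:
            assert pooled[lab][c, c] == pytest.approx(cr["mV2-pooled"][lab], abs=1e-10)

    def test_multiplicative_quadratic_additive_linear_in_contrast(self):
        """Scaling the chromatic contrast by alpha scales multiplicative mV2
        responses by ~alpha^2 and additive ones by ~alpha (unsaturated)."""
        from corticalhue.colourspace import hsl_to_rgb, rgb_to_lms, white_point_lms

        cfg = LayerConfig(multiplicative_gain=1.0)
        m = HueModel(cfg).calibrate()
        w = white_point_lms()
        c = rgb_to_lms(hsl_to_rgb(300.0, 1.0, 0.5))
        r1 = m._centre_from_cones(w + 0.5 * (c - w))
        r2 = m._centre_from_cones(w + 0.25 * (c - w))
        add = "L-on" if r1["mV2"]["L-on"] > 0 else "M-on"
        assert r1["mV2"][add] == pytest.approx(2.0 * r2["mV2"][add], rel=1e-6)
        mult = max(MV2_MULTIPLICATIVE_TYPES, key=lambda t: r1["mV2"][t])
        assert r1["mV2"][mult] == pytest.approx(4.0 * r2["mV2"][mult], rel=1e-6)

    def test_calibration_is_deterministic(self):
        a = HueModel().calibrate()
        b = HueModel().calibrate()
        assert a.multiplicative_gain == b.multiplicative_gain
        assert np.array_equal(a.weight_matrix.w, b.weight_matrix.w)
        assert np.array_equal(a.mv2_peak_hues, b.mv2_peak_hues)

    def test_default_specs_cover_canonical_types(self):
        specs = default_opponent_specs()
        assert tuple(s.name for s in specs) == MLGN_TYPES
        for s in specs:
            s.validate()

    def test_mv1_additive_mv2_identity_on_uniform_stimuli(self, curves):
        """Single-opponent mV2 replicates mV1 on uniform fields: mean |diff|
        across the 60-hue set is at most 1e-5 for every cell type."""
        for t in MV2_ADDITIVE_TYPES:
            d = np.abs(curves["mV1"][t].responses - curves["mV2"][t].responses)
            assert d.mean() <= 1e-5
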