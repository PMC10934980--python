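"""Translation strategies and the seeding loop's structural contracts.

The expensive, trained-model properties (intensity binding, the
unconditional limit, guidance monotonicity) live in the acceptance
suite; here the loop runs against small stub models.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirseed.color_transform import decouple_intensity, intensity_of_gray, replicate_gray
from nirseed.ddpm import make_schedule, sample_unconditional
from nirseed.iterative_seeding import (
    HighpassTranslator,
    IdentityTranslator,
    gaussian_kernel,
    get_translator,
    iterative_seeding,
    make_surrogate_translator,
    translate_highpass,
    translate_identity,
)
from nirseed.rng import derive_rng


class StubModel:
    """Deterministic, input-dependent ε-predictor for loop tests."""

    image_size = 8

    def __call__(self, x, t):
        return 0.3 * x + 0.01 * t


STUB_SCHEDULE = make_schedule(12, 1e-3, 0.02)


class TestIdentityTranslator:
    def test_returns_reference(self, rng):
        y, x = rng.standard_normal((2, 5, 5))
        np.testing.assert_array_equal(translate_identity(y, x), y)

    def test_sample_intensity_ignored(self, rng):
        y = rng.standard_normal((5, 5))
        out1 = translate_identity(y, rng.standard_normal((5, 5)))
        out2 = translate_identity(y, rng.standard_normal((5, 5)))
        np.testing.assert_array_equal(out1, out2)

    def test_idempotent(self, rng):
        y, x = rng.standard_normal((2, 5, 5))
        once = translate_identity(y, x)
        np.testing.assert_array_equal(translate_identity(once, x), once)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            translate_identity(np.zeros((2, 2)), np.zeros((3, 3)))


class TestGaussianKernel:
    @given(st.floats(min_value=0.2, max_value=6.0))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_unit_sum_and_symmetry(self, sigma):
        k = gaussian_kernel(sigma).kernel
        assert abs(k.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(k, k.T, atol=1e-15)
        np.testing.assert_allclose(k, np.rot90(k), atol=1e-15)
        np.testing.assert_allclose(k, k[::-1], atol=1e-15)
        assert k.shape[0] == 2 * int(np.ceil(3 * sigma)) + 1

    def test_sigma_zero_is_identity_kernel(self):
        np.testing.assert_array_equal(gaussian_kernel(0.0).kernel, [[1.0]])

    def test_center_to_neighbor_ratio(self):
        # G(0,0)/G(1,0) = exp(1/(2 sigma^2)); at sigma=2.3 that is 1.0991
        sigma = 2.3
        k = gaussian_kernel(sigma).kernel
        c = k.shape[0] // 2
        ratio = k[c, c] / k[c, c + 1]
        assert abs(ratio - np.exp(1 / (2 * sigma**2))) < 1e-12
        assert round(ratio, 4) == 1.0991

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kernel(-1.0)


class TestHighpassTranslator:
    def test_self_fusion_reconstructs(self, rng):
        y = rng.standard_normal((10, 10))
        np.testing.assert_allclose(translate_highpass(y, y, 2.3), y, atol=1e-12)

    def test_sigma_zero_returns_sample_intensity(self, rng):
        y = rng.standard_normal((10, 10))
        x = rng.standard_normal((10, 10))
        np.testing.assert_array_equal(translate_highpass(y, x, 0.0), x)

    def test_constant_reference_yields_smoothed_sample(self, rng):
        from scipy import ndimage

        x = rng.standard_normal((10, 10))
        y = np.full((10, 10), 0.7)
        spec = gaussian_kernel(1.5)
        expected = ndimage.convolve(x, spec.kernel, mode="reflect")
        np.testing.assert_allclose(translate_highpass(y, x, 1.5), expected, atol=1e-12)


class TestSurrogateTranslator:
    def test_gray_surrogate_collapses_to_identity(self):
        rng = np.random.default_rng(0)
        nir = rng.uniform(-0.5, 0.5, (8, 8))
        surrogate = replicate_gray(nir)
        model = StubModel()
        out_sur = iterative_seeding(
            model, nir, make_surrogate_translator(surrogate), STUB_SCHEDULE, seed=4
        )
        out_id = iterative_seeding(model, nir, IdentityTranslator(), STUB_SCHEDULE, seed=4)
        np.testing.assert_allclose(out_sur, out_id, atol=1e-12)

    def test_output_intensity_equals_surrogate_intensity(self):
        rng = np.random.default_rng(1)
        nir = rng.uniform(-0.5, 0.5, (8, 8))
        surrogate = np.clip(rng.uniform(-0.6, 0.6, (8, 8, 3)), -1, 1)
        out = iterative_seeding(
            StubModel(),
            nir,
            make_surrogate_translator(surrogate),
            STUB_SCHEDULE,
            seed=4,
            clip=False,
        )
        out_I, _ = decouple_intensity(out)
        sur_I, _ = decouple_intensity(surrogate)
        assert np.abs(out_I - sur_I).max() < 1e-6

    def test_only_intensity_consumed(self):
        """Two surrogates with equal intensity but different colors give
        identical colorizations under a fixed seed."""
        rng = np.random.default_rng(2)
        nir = rng.uniform(-0.5, 0.5, (8, 8))
        intensity = rng.uniform(-0.8, 0.8, (8, 8))
        from nirseed.color_transform import couple_intensity

        sur_a = couple_intensity(intensity, 0.1 * rng.standard_normal((8, 8, 2)))
        sur_b = couple_intensity(intensity, 0.1 * rng.standard_normal((8, 8, 2)))
        out_a = iterative_seeding(
            StubModel(), nir, make_surrogate_translator(sur_a), STUB_SCHEDULE, seed=9
        )
        out_b = iterative_seeding(
            StubModel(), nir, make_surrogate_translator(sur_b), STUB_SCHEDULE, seed=9
        )
        np.testing.assert_allclose(out_a, out_b, atol=1e-9)

    def test_size_mismatch_rejected(self):
        sur = np.zeros((4, 4, 3))
        with pytest.raises(ValueError):
            iterative_seeding(
                StubModel(),
                np.zeros((8, 8)),
                make_surrogate_translator(sur),
                STUB_SCHEDULE,
                seed=0,
            )

    def test_factory_requires_surrogate(self):
        with pytest.raises(ValueError):
            get_translator("surrogate")


class TestSeedingLoop:
    def test_intensity_binding_with_identity_translator(self):
        """Output intensity equals the reference intensity: at the final
        step the reference diffused to level 0 is exact."""
        rng = np.random.default_rng(3)
        nir = rng.uniform(-0.5, 0.5, (8, 8))
        out = iterative_seeding(
            StubModel(), nir, IdentityTranslator(), STUB_SCHEDULE, seed=2, clip=False
        )
        out_I, _ = decouple_intensity(out)
        assert np.abs(out_I - intensity_of_gray(nir)).max() < 1e-6

    def test_sigma_zero_equals_unconditional_bitwise(self):
        """σ=0 high-pass seeding consumes the sampler stream exactly like
        unconditional sampling and returns bit-identical images."""
        rng = np.random.default_rng(4)
        nir = rng.uniform(-0.5, 0.5, (3, 8, 8))
        out = iterative_seeding(StubModel(), nir, HighpassTranslator(0.0), STUB_SCHEDULE, seed=5)
        unc = sample_unconditional(StubModel(), 3, STUB_SCHEDULE, derive_rng(5, "sampler"))
        np.testing.assert_array_equal(out, unc)

    def test_fixed_seed_bit_identical(self):
        rng = np.random.default_rng(5)
        nir = rng.uniform(-0.5, 0.5, (8, 8))
        a = iterative_seeding(StubModel(), nir, HighpassTranslator(1.0), STUB_SCHEDULE, seed=6)
        b = iterative_seeding(StubModel(), nir, HighpassTranslator(1.0), STUB_SCHEDULE, seed=6)
        np.testing.assert_array_equal(a, b)

    def test_chrominance_comes_from_the_sample(self):
        """At every step the recoupled chrominance is the model sample's,
        never the reference's (instrumented via the step hook)."""
        rng = np.random.default_rng(6)
        nir = rng.uniform(-0.5, 0.5, (8, 8))
        records = []

        def hook(t, y_I, x_tilde, x_I, new_I, x_C):
            _, tilde_C = decouple_intensity(x_tilde)
            records.append(np.array_equal(x_C, tilde_C))

        iterative_seeding(
            StubModel(), nir, IdentityTranslator(), STUB_SCHEDULE, seed=7, step_hook=hook
        )
        assert len(records) == STUB_SCHEDULE.T
        assert all(records)

    def test_wrong_size_reference_rejected(self):
        with pytest.raises(ValueError):
            iterative_seeding(
                StubModel(), np.zeros((4, 4)), IdentityTranslator(), STUB_SCHEDULE, seed=0
            )
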