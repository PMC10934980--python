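"""Fréchet distance machinery and paired content metrics."""

import numpy as np
import pytest

from nirseed.color_transform import couple_intensity, intensity_of_gray
from nirseed.ddpm import make_schedule
from nirseed.evaluation import (
    FrechetStats,
    content_preservation_report,
    fit_gaussian_stats,
    frechet_between,
    frechet_distance,
    get_extractor,
    sigma_sweep,
)
from nirseed.synthetic_data import EvalPair, NirRenderParams, SceneParams, generate_rgb_scene, render_pseudo_nir


class TestGaussianStats:
    def test_identical_rows_give_zero_covariance(self):
        stats = fit_gaussian_stats(np.array([[1.0, 2.0], [1.0, 2.0]]))
        np.testing.assert_array_equal(stats.cov, np.zeros((2, 2)))

    def test_hand_computed_example(self):
        stats = fit_gaussian_stats(np.array([[0.0, 0.0], [2.0, 0.0]]))
        np.testing.assert_array_equal(stats.mean, [1.0, 0.0])
        np.testing.assert_array_equal(stats.cov, [[2.0, 0.0], [0.0, 0.0]])

    def test_row_permutation_invariant(self, rng):
        feats = rng.standard_normal((20, 4))
        a = fit_gaussian_stats(feats)
        b = fit_gaussian_stats(feats[rng.permutation(20)])
        np.testing.assert_allclose(a.mean, b.mean, atol=1e-12)
        np.testing.assert_allclose(a.cov, b.cov, atol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_stats(np.zeros((1, 3)))


class TestFrechetDistance:
    def test_zero_on_identical_stats(self, rng):
        feats = rng.standard_normal((30, 5))
        s = fit_gaussian_stats(feats)
        assert frechet_distance(s, s) < 1e-8

    def test_shared_covariance_closed_form(self):
        mu = np.array([0.5, -1.0, 2.0])
        a = FrechetStats(mean=np.zeros(3), cov=np.eye(3), n=10)
        b = FrechetStats(mean=mu, cov=np.eye(3), n=10)
        assert abs(frechet_distance(a, b) - mu @ mu) < 1e-10

    def test_symmetric(self, rng):
        sa = fit_gaussian_stats(rng.standard_normal((25, 4)))
        sb = fit_gaussian_stats(rng.standard_normal((25, 4)) + 0.5)
        assert abs(frechet_distance(sa, sb) - frechet_distance(sb, sa)) < 1e-8

    def test_dimension_mismatch_rejected(self):
        a = FrechetStats(mean=np.zeros(2), cov=np.eye(2), n=5)
        b = FrechetStats(mean=np.zeros(3), cov=np.eye(3), n=5)
        with pytest.raises(ValueError):
            frechet_distance(a, b)

    def test_univariate_closed_form(self):
        # d = (mu_a-mu_b)^2 + (s_a - s_b)^2 for 1-D Gaussians
        a = FrechetStats(mean=np.array([0.0]), cov=np.array([[4.0]]), n=9)
        b = FrechetStats(mean=np.array([1.0]), cov=np.array([[9.0]]), n=9)
        assert abs(frechet_distance(a, b) - (1.0 + (2.0 - 3.0) ** 2)) < 1e-10

    def test_noise_increases_distance(self):
        """Corrupting one image set moves it away from a clean reference."""
        rng = np.random.default_rng(0)
        scenes = [
            generate_rgb_scene(SceneParams(), np.random.default_rng(s))[0]
            for s in range(24)
        ]
        clean = np.stack(scenes[:12])
        other = np.stack(scenes[12:])
        noisy = np.clip(other + 0.4 * rng.standard_normal(other.shape), -1, 1)
        assert frechet_between(noisy, clean) > frechet_between(other, clean)

    def test_unknown_extractor_rejected(self):
        with pytest.raises(ValueError):
            get_extractor("resnet")
        with pytest.raises(RuntimeError):
            get_extractor("inception")

    def test_randproj_extractor_deterministic(self, rng):
        imgs = rng.uniform(-1, 1, (4, 8, 8, 3))
        fn = get_extractor("randproj", seed=3)
        np.testing.assert_array_equal(fn(imgs), fn(imgs))


def _make_pairs(n, seed0=100):
    pairs = []
    for s in range(seed0, seed0 + n):
        rgb, masks = generate_rgb_scene(SceneParams(), np.random.default_rng(s))
        nir = render_pseudo_nir(rgb, masks, NirRenderParams(), np.random.default_rng(s))
        gray = ((rgb + 1) / 2).mean(axis=-1) * 2 - 1
        pairs.append(EvalPair(seed=s, rgb=rgb, gray=gray, nir=nir, masks=masks))
    return pairs


class TestContentReport:
    def test_perfect_imputation_has_unit_intensity_correlation(self):
        pairs = _make_pairs(4)
        outputs = []
        for p in pairs:
            from nirseed.color_transform import decouple_intensity

            _, true_C = decouple_intensity(p.rgb)
            outputs.append(couple_intensity(intensity_of_gray(p.nir), true_C))
        rep = content_preservation_report(pairs, outputs)
        assert rep["intensity_corr_mean"] > 0.9999
        assert rep["sky_shift_fraction"] == 0.0

    def test_independent_images_have_no_highpass_correlation(self):
        """Outputs whose detail is unrelated to the NIR frames score a mean
        high-pass correlation statistically indistinguishable from zero
        (32 images).  Band-limited noise is used as the unrelated content;
        images from the same scene family are *not* independent — they share
        cone/horizon structure and correlate at r ≈ 0.2."""
        from scipy import ndimage

        pairs = _make_pairs(32)
        rng = np.random.default_rng(9000)
        outputs = [
            np.clip(
                ndimage.gaussian_filter(rng.standard_normal((16, 16, 3)), (1.2, 1.2, 0)),
                -1,
                1,
            )
            for _ in range(32)
        ]
        rep = content_preservation_report(pairs, outputs)
        assert abs(rep["highpass_corr_mean"]) < 0.2

    def test_deterministic(self):
        pairs = _make_pairs(3)
        outputs = [p.rgb for p in pairs]
        a = content_preservation_report(pairs, outputs)
        b = content_preservation_report(pairs, outputs)
        assert a == b

    def test_unregistered_sizes_rejected(self):
        pairs = _make_pairs(1)
        with pytest.raises(ValueError):
            content_preservation_report(pairs, [np.zeros((4, 4, 3))])


class StubModel:
    image_size = 16

    def __call__(self, x, t):
        return 0.2 * x


class TestSigmaSweep:
    SCHEDULE = make_schedule(10, 1e-3, 0.02)

    def _refs_and_reference(self):
        pairs = _make_pairs(4, seed0=300)
        refs = np.stack([p.nir for p in pairs])
        reference = np.stack(
            [generate_rgb_scene(SceneParams(), np.random.default_rng(s))[0] for s in range(400, 412)]
        )
        return pairs, refs, reference

    def test_table_shape_and_determinism(self, tmp_path):
        pairs, refs, reference = self._refs_and_reference()
        sigmas = [0.0, 1.0, 2.3]
        t1 = sigma_sweep(
            StubModel(), refs, sigmas, self.SCHEDULE, seed=3,
            reference_images=reference, pairs=pairs,
            out_path=tmp_path / "sweep.tsv",
        )
        t2 = sigma_sweep(
            StubModel(), refs, sigmas, self.SCHEDULE, seed=3,
            reference_images=reference, pairs=pairs,
        )
        assert list(t1["sigma"]) == sigmas
        assert {"frechet", "intensity_corr", "highpass_corr"} <= set(t1.columns)
        assert t1.equals(t2)
        assert (tmp_path / "sweep.tsv").is_file()

    def test_sigma_zero_row_matches_unconditional_score(self):
        from nirseed.ddpm import sample_unconditional
        from nirseed.evaluation import frechet_between
        from nirseed.rng import derive_rng

        pairs, refs, reference = self._refs_and_reference()
        table = sigma_sweep(
            StubModel(), refs, [0.0], self.SCHEDULE, seed=8, reference_images=reference
        )
        unc = sample_unconditional(
            StubModel(), refs.shape[0], self.SCHEDULE, derive_rng(8, "sampler")
        )
        assert table["frechet"][0] == frechet_between(unc, reference)
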