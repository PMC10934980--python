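"""Iterative seeding: conditioning an unconditional diffusion model on a
gray near-infrared reference at sampling time.

Colorization is treated as imputation: brightness is (approximately)
known, the two chrominance coordinates are not.  At every reverse step
the loop

1. diffuses the reference y₀ to level t−1 with fresh forward-process
   noise (exact at t−1 = 0, where ᾱ₀ = 1),
2. draws x̃_{t−1} from the unconditional model,
3. decouples both into intensity and chrominance,
4. replaces the sample's intensity with ``translate(y_I, x̃_I)``,
5. recouples the translated intensity with the *sample's* chrominance.

The translation strategies:

``identity``
    returns the reference intensity unchanged — the output's brightness
    is pinned to the NIR frame exactly, the model only picks colors.
    NIR reflectance differs from visible reflectance (vegetation in
    particular is brighter in NIR), so this pins the wrong brightness
    where the asymmetry matters.
``highpass``
    Gaussian high-pass fusion: keep the reference's high spatial
    frequencies (edges, texture) and let the model generate the low
    frequencies (illumination) — the standard VIS–NIR fusion recipe.
    σ (pixels) sets the crossover; σ = 0 degenerates to unconditional
    sampling.
``surrogate``
    like ``identity`` but the diffused reference is the intensity of an
    externally produced colorization of the same frame (any method);
    only that intensity is consumed, its colors are discarded.

rng discipline: the sampler stream is ``derive_rng(seed, "sampler")``
and consumes draws in exactly the order ``sample_unconditional`` does;
reference diffusion uses the independent stream
``derive_rng(seed, "reference")``.  Hence high-pass seeding with σ = 0
is bit-identical to ``sample_unconditional(model, n, schedule,
derive_rng(seed, "sampler"))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .color_transform import (
    INTENSITY_SCALE,
    couple_intensity,
    decouple_intensity,
    replicate_gray,
)
from .ddpm import NoiseSchedule, p_sample_step, q_sample
from .rng import derive_rng

__all__ = [
    "GaussianFilterSpec",
    "gaussian_kernel",
    "translate_identity",
    "translate_highpass",
    "IdentityTranslator",
    "HighpassTranslator",
    "make_surrogate_translator",
    "get_translator",
    "iterative_seeding",
]


# ---------------------------------------------------------------------------
# translation strategies


def _check_shapes(y_I: np.ndarray, x_I: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y_I = np.asarray(y_I, dtype=np.float64)
    x_I = np.asarray(x_I, dtype=np.float64)
    if y_I.shape != x_I.shape:
        raise ValueError(f"intensity shape mismatch: {y_I.shape} vs {x_I.shape}")
    return y_I, x_I


def translate_identity(y_I: np.ndarray, x_I: np.ndarray) -> np.ndarray:
    """Return the reference intensity unchanged (the sample's is ignored)."""
    y_I, _ = _check_shapes(y_I, x_I)
    return y_I.copy()


@dataclass(frozen=True)
class GaussianFilterSpec:
    """A discrete, unit-sum Gaussian kernel of radius ⌈3σ⌉."""

    sigma: float
    kernel: np.ndarray = field(repr=False)


def gaussian_kernel(sigma: float) -> GaussianFilterSpec:
    """Sample G(u,v) ∝ exp(−(u²+v²)/(2σ²)) on integer offsets within
    radius ⌈3σ⌉ and renormalize to unit sum; σ = 0 gives the 1×1 identity."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return GaussianFilterSpec(sigma=0.0, kernel=np.ones((1, 1)))
    radius = int(np.ceil(3.0 * sigma))
    u = np.arange(-radius, radius + 1, dtype=np.float64)
    g1 = np.exp(-(u**2) / (2.0 * sigma**2))
    kernel = np.outer(g1, g1)
    kernel /= kernel.sum()
    return GaussianFilterSpec(sigma=float(sigma), kernel=kernel)


def _smooth(img: np.ndarray, spec: GaussianFilterSpec) -> np.ndarray:
    if spec.kernel.shape == (1, 1):
        return img * spec.kernel[0, 0]
    return ndimage.convolve(img, spec.kernel, mode="reflect")


def translate_highpass(
    y_I: np.ndarray, x_I: np.ndarray, sigma: float | GaussianFilterSpec
) -> np.ndarray:
    """Fuse the sample's low frequencies with the reference's high
    frequencies: (x_I ∗ G_σ) + (y_I − y_I ∗ G_σ), reflect padding."""
    y_I, x_I = _check_shapes(y_I, x_I)
    spec = sigma if isinstance(sigma, GaussianFilterSpec) else gaussian_kernel(sigma)
    x_low = _smooth(x_I, spec)
    y_high = y_I - _smooth(y_I, spec)
    return x_low + y_high


class IdentityTranslator:
    """TranslateIntensity := reference intensity (pin brightness to NIR)."""

    name = "identity"

    def __call__(self, y_I: np.ndarray, x_I: np.ndarray) -> np.ndarray:
        return translate_identity(y_I, x_I)

    def reference_gray(self, nir: np.ndarray) -> np.ndarray:
        return nir


class HighpassTranslator:
    """Gaussian high-pass VIS–NIR fusion with std-dev ``sigma`` (pixels)."""

    name = "highpass"

    def __init__(self, sigma: float = 2.3):
        self.sigma = float(sigma)
        self.spec = gaussian_kernel(self.sigma)

    def __call__(self, y_I: np.ndarray, x_I: np.ndarray) -> np.ndarray:
        y_I, x_I = _check_shapes(y_I, x_I)
        if y_I.ndim == 2:
            return translate_highpass(y_I, x_I, self.spec)
        # batched: filter each image independently
        return np.stack(
            [translate_highpass(y, x, self.spec) for y, x in zip(y_I, x_I)]
        )

    def reference_gray(self, nir: np.ndarray) -> np.ndarray:
        return nir


class SurrogateTranslator:
    """Identity translation against a surrogate colorization's intensity.

    The reference diffused through the loop is not the NIR frame but the
    decoupled intensity of an externally produced colorization of it;
    only that intensity is consumed, the surrogate's colors are ignored.
    """

    name = "surrogate"

    def __init__(self, surrogate: np.ndarray):
        surrogate = np.asarray(surrogate, dtype=np.float64)
        if surrogate.ndim != 3 or surrogate.shape[-1] != 3:
            raise ValueError("surrogate must be an HxWx3 RGB image")
        intensity, _ = decouple_intensity(surrogate)
        # gray image whose replicated intensity equals the surrogate's
        self._gray = intensity / (3.0 * INTENSITY_SCALE)

    def __call__(self, y_I: np.ndarray, x_I: np.ndarray) -> np.ndarray:
        return translate_identity(y_I, x_I)

    def reference_gray(self, nir: np.ndarray) -> np.ndarray:
        if self._gray.shape != np.asarray(nir).shape[-2:]:
            raise ValueError(
                f"surrogate size {self._gray.shape} does not match "
                f"NIR frame {np.asarray(nir).shape}"
            )
        return np.broadcast_to(self._gray, np.asarray(nir).shape).copy()


def make_surrogate_translator(surrogate: np.ndarray) -> SurrogateTranslator:
    """Translator that swaps the reference for a surrogate colorization's
    intensity (see :class:`SurrogateTranslator`)."""
    return SurrogateTranslator(surrogate)


def get_translator(name: str, sigma: float = 2.3, surrogate: np.ndarray | None = None):
    if name == "identity":
        return IdentityTranslator()
    if name == "highpass":
        return HighpassTranslator(sigma)
    if name == "surrogate":
        if surrogate is None:
            raise ValueError("surrogate translator requires a surrogate image")
        return make_surrogate_translator(surrogate)
    raise ValueError(f"unknown translator {name!r}")


# ---------------------------------------------------------------------------
# the conditioning loop


def _batch_intensity(rgb: np.ndarray) -> np.ndarray:
    """Intensity channel (r+g+b)/√3 of a (..., 3) array."""
    return rgb.sum(axis=-1) * INTENSITY_SCALE


def iterative_seeding(
    model,
    y0: np.ndarray,
    translator,
    schedule: NoiseSchedule,
    seed: int = 0,
    *,
    clip: bool = True,
    step_hook=None,
) -> np.ndarray:
    """Colorize gray reference(s) ``y0`` with the given translation strategy.

    Parameters
    ----------
    y0:
        (H, W) gray NIR frame in [−1, 1], or (B, H, W) for a batch.
    translator:
        A callable ``(y_I, x_I) -> I`` (see module docstring).  Objects may
        additionally provide ``reference_gray(nir)`` to substitute the
        diffused reference (the surrogate strategy does).
    seed:
        All randomness derives from this integer; see the module docstring
        for the stream layout.
    clip:
        Clip the returned x₀ to [−1, 1] (on by default).
    step_hook:
        Optional callable ``(t, y_I, x_tilde, x_I, new_I, x_C)`` invoked
        each step — debug instrumentation, e.g. to verify chrominance
        provenance.

    Returns
    -------
    (H, W, 3) colorized image, or (B, H, W, 3) for batched input.
    """
    y0 = np.asarray(y0, dtype=np.float64)
    single = y0.ndim == 2
    if single:
        y0 = y0[None]
    if y0.ndim != 3:
        raise ValueError(f"y0 must be (H, W) or (B, H, W), got {y0.shape}")
    if hasattr(translator, "reference_gray"):
        y0 = np.asarray(translator.reference_gray(y0), dtype=np.float64)
    B, H, W = y0.shape
    if H != model.image_size or W != model.image_size:
        raise ValueError(
            f"reference is {H}x{W} but model expects "
            f"{model.image_size}x{model.image_size}"
        )

    y0_rgb = np.stack([replicate_gray(g) for g in y0])
    rng_sampler = derive_rng(seed, "sampler")
    rng_ref = derive_rng(seed, "reference")

    x = rng_sampler.standard_normal((B, H, W, 3))
    for t in range(schedule.T, 0, -1):
        x_tilde = p_sample_step(model, x, t, schedule, rng_sampler)
        if t - 1 == 0:
            y = y0_rgb  # ᾱ₀ = 1: diffusion to level 0 is exact
        else:
            noise = rng_ref.standard_normal(y0_rgb.shape)
            y = q_sample(y0_rgb, t - 1, noise, schedule)
        y_I = _batch_intensity(y)
        x_I, x_C = decouple_intensity(x_tilde)
        new_I = translator(y_I, x_I)
        if step_hook is not None:
            step_hook(t, y_I, x_tilde, x_I, new_I, x_C)
        if np.array_equal(new_I, x_I):
            # translation left the sample's intensity untouched: skip the
            # recoupling round-trip so the step is bit-identical to the
            # unconditional transition
            x = x_tilde
        else:
            x = couple_intensity(new_I, x_C)

    if clip:
        x = np.clip(x, -1.0, 1.0)
    return x[0] if single else x
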