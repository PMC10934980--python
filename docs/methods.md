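# Methods

## Model

`nirseed` colorizes single-channel near-infrared (NIR) frames by
sampling an *unconditional* denoising diffusion model under an
intensity constraint, so no paired NIR/RGB supervision is needed.

**Diffusion core.** The forward process adds Gaussian noise over `T`
steps with a linear variance schedule β₁…β_T; with α_t = 1 − β_t,
ᾱ_t = ∏ α_s (and ᾱ₀ := 1) it has the closed form
q(x_t | x₀) = N(√ᾱ_t x₀, (1 − ᾱ_t) I). The reverse process is Gaussian
with mean μ_θ(x_t, t) = (x_t − β_t/√(1−ᾱ_t) ε̂_θ(x_t, t))/√α_t and fixed
variance σ_t². Training minimizes E‖ε − ε̂_θ(√ᾱ_t x₀ + √(1−ᾱ_t) ε, t)‖²
with t uniform on [1, T] and fresh ε per example.

**Intensity/chrominance decoupling.** Pixels are mapped by the fixed
orthogonal matrix

    C = [[ a, −b,  c],
         [ a,  c, −b],
         [ a,  a,  a]],   a = 1/√3,  b = 1/2 + 1/(2√3),  c = 1/2 − 1/(2√3)

so that the first coordinate of p·C is a(r+g+b) — the intensity — and
the other two are chrominance; orthogonality makes the split lossless
and energy-preserving. The matrix is hard-coded in this closed form
(bit-stable across platforms); the test-suite re-derives the intensity
axis independently by QR factorization as an oracle. Other valid
decouplings exist (any rotation of the two chrominance axes); this one
is the package's canonical choice. No rescaling is applied to either
channel inside the loop — the transform is purely orthogonal.

**Iterative seeding.** At each reverse step t → t−1 the loop diffuses
the reference y₀ to level t−1 with *fresh* forward-process noise, draws
x̃_{t−1} from the model, decouples both, replaces the sample's intensity
with `TranslateIntensity(y_I, x̃_I)` and recouples with the *sample's*
chrominance (the diffused reference's chrominance is never consumed; a
step hook exposes it for instrumentation). Strategies:

* **identity** — y_I; pins output brightness to the reference exactly.
* **highpass** — (x̃_I ∗ G_σ) + (y_I − y_I ∗ G_σ); the reference
  contributes only spatial frequencies above the Gaussian crossover.
* **surrogate** — identity translation against a substitute reference:
  the intensity of an externally produced colorization of the same
  frame. Only that intensity is read; the surrogate's colors are
  discarded.

Because ᾱ₀ = 1, the reference "diffused" to level 0 at the final step
is the reference itself, which gives the identity variant an exact
binding property: the output's decoupled intensity equals the
reference's to machine precision (≈1e−15 in the tests).

## Parameters that matter

| parameter | default | role |
|---|---|---|
| T | 1000 (desk: 200) | diffusion steps; linear β from 1e−4 to 0.02 (desk: to 0.1) |
| σ_t² | β̃_t | reverse variance; β̃_t = (1−ᾱ_{t−1})/(1−ᾱ_t)·β_t, 0 at t=1; plain β_t selectable |
| σ (high-pass) | 2.3 px | guidance crossover: ↑σ = more NIR detail imposed, less generative freedom |
| image size | 128 (desk: 16) | must be a multiple of 2^depth |
| base channels / mult | 64 / (1,1,2,2,4) (desk: 16 / (1,2,2)) | U-Net width/depth |
| attention | 32,16,8 px (desk: 4 px) | self-attention resolutions |
| batch / lr / steps | 256 / 1e−4 / 200k (desk: 16 / 1e−3 / 6000) | Adam training |

When T is reduced, β_end must scale (roughly by 1000/T) so that ᾱ_T
stays below 1e−4: the reverse chain starts from N(0, I), and a terminal
marginal that still carries signal (e.g. ᾱ_T ≈ 0.13 if the full-scale β
range is reused at T = 200) systematically biases every sample's
brightness toward zero. The desk defaults encode this.

σ is interpreted in pixels at the working resolution; at 16×16 a σ of
2.3 already reaches most of the spectrum, so desk-scale results probe
the same mechanism as full scale but with coarser granularity.

## Numerical and design choices

* **Conventions where the formulation leaves a choice:** no noise is
  added at the final reverse step (t = 1); latents are never clipped
  mid-chain, only the final x₀ is clipped to [−1, 1]; the loss is
  mean-reduced over tensor elements so learning-rate semantics are
  size-invariant; the optimizer is Adam (β = 0.9/0.999), no EMA.
* **Clipping vs binding.** Hard-clipping an out-of-gamut pixel changes
  its intensity, so the exact binding property is stated (and tested)
  with output clipping disabled; with clipping on, deviations are
  bounded by the out-of-gamut excess of the recoupled pixels. File
  output always clips.
* **Gaussian kernel:** sampled on integer offsets within radius ⌈3σ⌉,
  renormalized to unit sum; reflect padding for the convolution; σ = 0
  is defined as the 1×1 identity kernel, which makes σ = 0 high-pass
  seeding *bit-identical* to unconditional sampling (the loop skips the
  recoupling round-trip whenever translation returns the sample's
  intensity unchanged).
* **Seeding discipline:** every stage derives its generator as
  sha256(seed, stage-name), so adding stages never perturbs existing
  streams; training randomness for step s depends only on (seed, s),
  making checkpoint-resume trajectories exact.
* **Fréchet distance:** unbiased (n−1) covariance;
  tr((Σ_a Σ_b)^{1/2}) computed through the symmetric eigendecomposition
  of Σ_a^{1/2} Σ_b Σ_a^{1/2}; eigenvalues above −1e−8 (relative) are
  clamped to zero, more negative ones raise.
* **The numpy network:** the denoiser and its training loop run on a
  compact reverse-mode autodiff engine written for this package
  (conv/attention/groupnorm primitives, validated against central
  finite differences to 1e−5 in the tests). Parameters are float32;
  the diffusion arithmetic around the network is float64.

## The synthetic data, and what the tests do and do not show

`synthetic_data` emulates the statistical skeleton of night camera-trap
imagery: a flash-illumination cone, one or two elliptical "animal"
blobs, band-limited "vegetation" texture, a sky band, and a pseudo-NIR
renderer whose vegetation gain γ_veg = 1.5 (> 1) reproduces the one
asymmetry the method must confront — vegetation is brighter in NIR than
in the visible-light grayscale. Channel weights (0.4, 0.4, 0.2) and a
mild sensor gamma of 0.9 are fixed, documented choices with no claim of
radiometric accuracy. Scenes are deterministic in their integer seed;
the RGB and NIR training scenes come from disjoint seed sets (unpaired
discipline), while the small evaluation set is pixel-registered.

Desk-scale experiments use 16×16 scenes, 256 training images and a
6 000-step training run (roughly a quarter hour on one CPU); the
evaluation embedding is pooled color/gradient statistics, not an
Inception network. Passing
tests therefore demonstrate the *mechanics* of the method — exact
binding, the σ = 0 unconditional limit, monotone guidance with σ, and
directional content-preservation results — on data whose statistics the
model can actually learn at this scale. They do not certify realism on
real camera-trap footage, and Fréchet scores here are not comparable to
published Inception-FID values.

## Known limitations

* The identity variant inherits NIR brightness errors wherever NIR and
  visible reflectance disagree (vegetation); that is the motivation for
  the high-pass variant, and the synthetic generator builds the
  asymmetry in so the tests can exercise it.
* High-pass seeding can hallucinate plausible-but-wrong low-frequency
  content (e.g. sky color); the evaluation module reports a sky-chroma
  shift fraction (threshold 0.15) as a proxy.
* The sampler is the plain ancestral one; no DDIM-style acceleration,
  classifier guidance, or learned variances.
* At 16×16 the σ-axis is compressed; σ sweeps at desk scale are
  qualitative analogues, not calibrations, of full-scale behavior.
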