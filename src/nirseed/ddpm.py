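"""Denoising diffusion probabilistic model core.

The forward process corrupts an image with Gaussian noise over ``T`` steps
following a linear variance schedule β₁…β_T; with α_t = 1 − β_t and
ᾱ_t = ∏_{s≤t} α_s (convention ᾱ₀ = 1) it has the closed form

    q(x_t | x_0) = N(√ᾱ_t · x_0, (1 − ᾱ_t) I).

The reverse process is a learned Gaussian p_θ(x_{t−1} | x_t) with mean

    μ_θ(x_t, t) = (x_t − β_t/√(1 − ᾱ_t) · ε̂_θ(x_t, t)) / √α_t

and fixed variance σ_t², either β_t or the posterior variance
β̃_t = (1 − ᾱ_{t−1})/(1 − ᾱ_t) · β_t (the default here).  Training
minimizes the simplified objective E ‖ε − ε̂_θ(√ᾱ_t x_0 + √(1−ᾱ_t) ε, t)‖²,
mean-reduced over tensor elements, with t uniform on [1, T] and unit-normal
ε per example.

Conventions adopted where the formulation leaves a choice: no noise is
added at the final reverse step (t = 1), and samples are clipped to
[−1, 1] only at the very end.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .config import DiffusionConfig
from .network import DenoiserUNet
from .rng import as_rng, derive_rng, derive_seed

__all__ = [
    "NoiseSchedule",
    "make_schedule",
    "schedule_for",
    "q_sample",
    "reverse_mean",
    "p_sample_step",
    "loss_simple",
    "build_denoiser",
    "train",
    "sample_unconditional",
    "Checkpoint",
]

CHECKPOINT_FORMAT = 1


@dataclass(frozen=True)
class NoiseSchedule:
    """β/α/ᾱ sequences and reverse-step variances for a T-step diffusion."""

    T: int
    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray
    sigma2: np.ndarray
    variance_choice: str = "beta_tilde"

    def alpha_bar_at(self, t: int | np.ndarray):
        """ᾱ_t with the convention ᾱ₀ = 1 (t may be 0…T)."""
        padded = np.concatenate([[1.0], self.alpha_bar])
        return padded[t]

    @property
    def hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.beta.tobytes())
        h.update(self.variance_choice.encode())
        return h.hexdigest()[:16]


def make_schedule(
    T: int, beta1: float, betaT: float, variance_choice: str = "beta_tilde"
) -> NoiseSchedule:
    """Linear variance schedule with all derived sequences.

    ``variance_choice`` selects the reverse-step variance: ``"beta"`` uses
    σ_t² = β_t, ``"beta_tilde"`` (default) the posterior variance
    β̃_t = (1 − ᾱ_{t−1})/(1 − ᾱ_t) · β_t, which is 0 at t = 1.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (0.0 < beta1 <= betaT < 1.0):
        raise ValueError("need 0 < beta1 <= betaT < 1")
    if variance_choice not in ("beta", "beta_tilde"):
        raise ValueError("variance_choice must be 'beta' or 'beta_tilde'")
    beta = np.linspace(beta1, betaT, T)
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    alpha_bar_prev = np.concatenate([[1.0], alpha_bar[:-1]])
    beta_tilde = (1.0 - alpha_bar_prev) / (1.0 - alpha_bar) * beta
    sigma2 = beta.copy() if variance_choice == "beta" else beta_tilde
    return NoiseSchedule(
        T=T,
        beta=beta,
        alpha=alpha,
        alpha_bar=alpha_bar,
        sigma2=sigma2,
        variance_choice=variance_choice,
    )


def schedule_for(config: DiffusionConfig) -> NoiseSchedule:
    return make_schedule(
        config.timesteps, config.beta_start, config.beta_end, config.variance_choice
    )


def q_sample(x0: np.ndarray, t: int, noise: np.ndarray, schedule: NoiseSchedule) -> np.ndarray:
    """Draw x_t ~ q(x_t | x_0) given the noise realization.

    Returns √ᾱ_t·x₀ + √(1−ᾱ_t)·noise; at t = 0 the input is returned
    unchanged (ᾱ₀ = 1 exactly, no arithmetic applied).
    """
    if not 0 <= t <= schedule.T:
        raise ValueError(f"t={t} outside [0, {schedule.T}]")
    x0 = np.asarray(x0, dtype=np.float64)
    if t == 0:
        return x0.copy()
    noise = np.asarray(noise, dtype=np.float64)
    if noise.shape != x0.shape:
        raise ValueError("noise shape must match x0")
    ab = schedule.alpha_bar[t - 1]
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * noise


def reverse_mean(
    eps_hat: np.ndarray, x_t: np.ndarray, t: int, schedule: NoiseSchedule
) -> np.ndarray:
    """Posterior mean μ_θ = (x_t − β_t/√(1−ᾱ_t)·ε̂) / √α_t."""
    if not 1 <= t <= schedule.T:
        raise ValueError(f"t={t} outside [1, {schedule.T}] (no reverse step from x0)")
    x_t = np.asarray(x_t, dtype=np.float64)
    eps_hat = np.asarray(eps_hat, dtype=np.float64)
    beta = schedule.beta[t - 1]
    alpha = schedule.alpha[t - 1]
    ab = schedule.alpha_bar[t - 1]
    return (x_t - beta / np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(alpha)


def p_sample_step(
    model, x_t: np.ndarray, t: int, schedule: NoiseSchedule, rng
) -> np.ndarray:
    """One reverse transition x_t → x_{t−1}.

    Adds σ_t·z with z ~ N(0, I) for t > 1; the final step (t = 1) is
    deterministic (no noise drawn, keeping rng streams aligned across
    callers).
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    eps_hat = model(x_t, t)
    mu = reverse_mean(eps_hat, x_t, t, schedule)
    if t <= 1:
        return mu
    sigma = np.sqrt(schedule.sigma2[t - 1])
    return mu + sigma * as_rng(rng).standard_normal(x_t.shape)


def loss_simple(model, x0: np.ndarray, t: int, noise: np.ndarray, schedule: NoiseSchedule) -> float:
    """Simplified training objective at a single (x₀, t, ε).

    Mean over all tensor elements of (ε − ε̂_θ(x_t, t))² with
    x_t = q_sample(x₀, t, ε).
    """
    if not 1 <= t <= schedule.T:
        raise ValueError(f"t={t} outside [1, {schedule.T}]")
    x_t = q_sample(x0, t, noise, schedule)
    eps_hat = model(x_t, t)
    return float(np.mean((np.asarray(noise, dtype=np.float64) - eps_hat) ** 2))


def build_denoiser(config: DiffusionConfig, dtype=np.float32) -> DenoiserUNet:
    """Instantiate the ε-predicting U-Net described by ``config`` (seeded)."""
    return DenoiserUNet(
        image_size=config.image_size,
        base_channels=config.base_channels,
        channel_mult=config.channel_mult,
        attention_resolutions=config.attention_resolutions,
        time_embed_dim=config.time_embed_dim,
        groups=config.groups,
        dtype=dtype,
        seed=derive_seed(config.seed, "model-init"),
    )


@dataclass
class Checkpoint:
    """Serialized model parameters plus training metadata."""

    config: DiffusionConfig
    params: dict[str, np.ndarray]
    schedule_hash: str
    step: int
    opt_state: dict | None = None
    loss_history: list = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        arrays = {f"param:{k}": v for k, v in self.params.items()}
        if self.opt_state is not None:
            for i, m in enumerate(self.opt_state["m"]):
                arrays[f"opt:m:{i}"] = m
            for i, v in enumerate(self.opt_state["v"]):
                arrays[f"opt:v:{i}"] = v
        meta = {
            "format": CHECKPOINT_FORMAT,
            "config": self.config.to_dict(),
            "schedule_hash": self.schedule_hash,
            "step": self.step,
            "opt_t": None if self.opt_state is None else self.opt_state["t"],
            "loss_history": [float(x) for x in self.loss_history],
        }
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            if meta["format"] != CHECKPOINT_FORMAT:
                raise ValueError(f"unsupported checkpoint format {meta['format']}")
            params = {
                k[len("param:") :]: data[k] for k in data.files if k.startswith("param:")
            }
            opt_state = None
            if meta["opt_t"] is not None:
                n = len([k for k in data.files if k.startswith("opt:m:")])
                opt_state = {
                    "t": meta["opt_t"],
                    "m": [data[f"opt:m:{i}"] for i in range(n)],
                    "v": [data[f"opt:v:{i}"] for i in range(n)],
                }
        return cls(
            config=DiffusionConfig.from_dict(meta["config"]),
            params=params,
            schedule_hash=meta["schedule_hash"],
            step=meta["step"],
            opt_state=opt_state,
            loss_history=meta["loss_history"],
        )

    def build_model(self, dtype=np.float32) -> DenoiserUNet:
        model = build_denoiser(self.config, dtype=dtype)
        model.load_state_dict(self.params)
        return model


def train(
    config: DiffusionConfig,
    dataset: np.ndarray,
    *,
    steps: int | None = None,
    resume: Checkpoint | None = None,
    checkpoint_path: str | Path | None = None,
    checkpoint_every: int | None = None,
    progress: bool = False,
) -> Checkpoint:
    """Optimize the simplified objective on a set of RGB images.

    ``dataset`` is (N, H, W, 3) in [−1, 1].  Each step draws a batch with
    replacement, a uniform timestep and fresh unit-normal noise per
    example.  All randomness for step ``s`` derives from
    ``(config.seed, s)``, so a run resumed from a checkpoint reproduces
    the exact loss trajectory of an uninterrupted run.
    """
    dataset = np.asarray(dataset, dtype=np.float64)
    if dataset.ndim != 4 or dataset.shape[0] == 0 or dataset.shape[3] != 3:
        raise ValueError("dataset must be a nonempty (N, H, W, 3) array")
    if dataset.shape[1] != config.image_size or dataset.shape[2] != config.image_size:
        raise ValueError(
            f"dataset images are {dataset.shape[1]}x{dataset.shape[2]}, "
            f"config expects {config.image_size}x{config.image_size}"
        )
    schedule = schedule_for(config)
    total_steps = config.train_steps if steps is None else steps

    model = build_denoiser(config)
    opt = Adam(model.param_list(), lr=config.learning_rate)
    start_step = 0
    loss_history: list[float] = []
    if resume is not None:
        if resume.schedule_hash != schedule.hash:
            raise ValueError("checkpoint schedule does not match config schedule")
        model.load_state_dict(resume.params)
        if resume.opt_state is not None:
            opt.load_state_dict(resume.opt_state)
        start_step = resume.step
        loss_history = list(resume.loss_history)

    N = dataset.shape[0]
    B = config.batch_size  # batches draw with replacement, so N < B is fine
    sqrt_ab = np.sqrt(schedule.alpha_bar)
    sqrt_1mab = np.sqrt(1.0 - schedule.alpha_bar)

    iterator = range(start_step, start_step + total_steps)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="train", unit="step")

    for step in iterator:
        rng = derive_rng(config.seed, f"train-step-{step}")
        idx = rng.integers(0, N, size=B)
        t = rng.integers(1, schedule.T + 1, size=B)
        eps = rng.standard_normal((B,) + dataset.shape[1:])
        x0 = dataset[idx]
        xt = sqrt_ab[t - 1, None, None, None] * x0 + sqrt_1mab[t - 1, None, None, None] * eps

        xin = Tensor(
            np.ascontiguousarray(xt.transpose(0, 3, 1, 2)).astype(model.dtype)
        )
        target = Tensor(
            np.ascontiguousarray(eps.transpose(0, 3, 1, 2)).astype(model.dtype)
        )
        out = model.forward_tensor(xin, t)
        diff = ad.add(out, ad.mul(target, -1.0))
        loss = ad.tmean(ad.mul(diff, diff))
        opt.zero_grad()
        loss.backward()
        opt.step()
        loss_history.append(float(loss.data))

        if (
            checkpoint_path is not None
            and checkpoint_every
            and (step + 1) % checkpoint_every == 0
        ):
            Checkpoint(
                config=config,
                params=model.state_dict(),
                schedule_hash=schedule.hash,
                step=step + 1,
                opt_state=opt.state_dict(),
                loss_history=loss_history,
            ).save(checkpoint_path)

    ckpt = Checkpoint(
        config=config,
        params=model.state_dict(),
        schedule_hash=schedule.hash,
        step=start_step + total_steps,
        opt_state=opt.state_dict(),
        loss_history=loss_history,
    )
    if checkpoint_path is not None:
        ckpt.save(checkpoint_path)
    return ckpt


def sample_unconditional(
    model, n: int, schedule: NoiseSchedule, rng
) -> np.ndarray:
    """Draw ``n`` unconditional samples, returned as (n, H, W, 3) in [−1, 1].

    Starts from x_T ~ N(0, I) and applies the reverse transition for
    t = T … 1; values are clipped to [−1, 1] only at the final step.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = as_rng(rng)
    size = model.image_size
    x = rng.standard_normal((n, size, size, 3))
    for t in range(schedule.T, 0, -1):
        x = p_sample_step(model, x, t, schedule, rng)
    return np.clip(x, -1.0, 1.0)
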