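"""The noise-prediction U-Net, written on the package's numpy autodiff.

The network maps a noised image and a timestep to a prediction of the
injected Gaussian noise.  It is a standard encoder/decoder with residual
blocks, a sinusoidal timestep embedding injected into every block, and
single-head self-attention at configurable resolutions.  Channel counts,
depth and attention placement come from :class:`~nirseed.config.DiffusionConfig`,
so the same code covers the full-scale architecture and the 16x16
desk-scale model used in the test-suite.

Images cross the public boundary in H x W x 3 (or B x H x W x 3) float64
layout; internally the network runs B x C x H x W in ``dtype``
(float32 by default).
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["DenoiserUNet", "timestep_embedding"]


def timestep_embedding(t: np.ndarray, dim: int) -> np.ndarray:
    """Sinusoidal embedding of integer timesteps, shape (B, dim)."""
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / half)
    args = t[:, None] * freqs[None, :]
    return np.concatenate([np.sin(args), np.cos(args)], axis=1)


class DenoiserUNet:
    """ε-predicting U-Net with timestep conditioning.

    Parameters are plain named numpy arrays (wrapped in autodiff Tensors),
    which makes checkpoints a flat name → array mapping.
    """

    def __init__(
        self,
        image_size: int,
        base_channels: int = 16,
        channel_mult: tuple[int, ...] = (1, 2, 2),
        attention_resolutions: tuple[int, ...] = (4,),
        time_embed_dim: int = 32,
        groups: int = 8,
        dtype=np.float32,
        seed: int = 0,
    ):
        depth = len(channel_mult)
        if image_size % (2**depth):
            raise ValueError(
                f"image size {image_size} incompatible with depth {depth} "
                f"(must be a multiple of {2**depth})"
            )
        self.image_size = image_size
        self.base_channels = base_channels
        self.channel_mult = tuple(channel_mult)
        self.attention_resolutions = tuple(attention_resolutions)
        self.time_embed_dim = time_embed_dim
        self.groups = groups
        self.dtype = dtype
        self.seed = seed
        self.params: dict[str, Tensor] = {}
        self._rng = np.random.default_rng(seed)
        self._build()

    # -- parameter creation -------------------------------------------------

    def _param(self, name: str, shape, fan_in: int) -> Tensor:
        scale = np.sqrt(2.0 / fan_in)
        data = (self._rng.standard_normal(shape) * scale).astype(self.dtype)
        p = Tensor(data)
        self.params[name] = p
        return p

    def _zeros(self, name: str, shape) -> Tensor:
        p = Tensor(np.zeros(shape, dtype=self.dtype))
        self.params[name] = p
        return p

    def _ones(self, name: str, shape) -> Tensor:
        p = Tensor(np.ones(shape, dtype=self.dtype))
        self.params[name] = p
        return p

    def _make_conv(self, name: str, cin: int, cout: int, k: int = 3) -> None:
        self._param(f"{name}.w", (cout, cin, k, k), cin * k * k)
        self._zeros(f"{name}.b", (cout,))

    def _make_dense(self, name: str, din: int, dout: int) -> None:
        self._param(f"{name}.w", (din, dout), din)
        self._zeros(f"{name}.b", (dout,))

    def _make_gn(self, name: str, ch: int) -> None:
        self._ones(f"{name}.g", (ch,))
        self._zeros(f"{name}.b", (ch,))

    def _make_resblock(self, name: str, cin: int, cout: int) -> None:
        self._make_gn(f"{name}.gn1", cin)
        self._make_conv(f"{name}.conv1", cin, cout)
        self._make_dense(f"{name}.tproj", self.time_embed_dim, cout)
        self._make_gn(f"{name}.gn2", cout)
        self._make_conv(f"{name}.conv2", cout, cout)
        if cin != cout:
            self._make_conv(f"{name}.skip", cin, cout, k=1)

    def _make_attn(self, name: str, ch: int) -> None:
        self._make_gn(f"{name}.gn", ch)
        for proj in ("wq", "wk", "wv", "wo"):
            self._param(f"{name}.{proj}", (ch, ch), ch)

    def _build(self) -> None:
        chs = [self.base_channels * m for m in self.channel_mult]
        E = self.time_embed_dim
        self._make_dense("temb.d1", E, E)
        self._make_dense("temb.d2", E, E)
        self._make_conv("in", 3, chs[0])
        res = self.image_size
        prev = chs[0]
        for i, ch in enumerate(chs):
            if i > 0:
                res //= 2
            self._make_resblock(f"down{i}", prev, ch)
            if res in self.attention_resolutions:
                self._make_attn(f"down{i}.attn", ch)
            prev = ch
        self._make_resblock("mid1", chs[-1], chs[-1])
        if res in self.attention_resolutions:
            self._make_attn("mid.attn", chs[-1])
        self._make_resblock("mid2", chs[-1], chs[-1])
        for i in reversed(range(len(chs))):
            self._make_resblock(f"up{i}", chs[i], chs[i])
            r = self.image_size // (2**i)
            if r in self.attention_resolutions:
                self._make_attn(f"up{i}.attn", chs[i])
            if i > 0:
                self._make_conv(f"up{i}.proj", chs[i], chs[i - 1], k=1)
        self._make_gn("out.gn", chs[0])
        self._make_conv("out", chs[0], 3)

    # -- forward ------------------------------------------------------------

    def _conv(self, name: str, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.params[f"{name}.w"], self.params[f"{name}.b"])

    def _dense(self, name: str, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.params[f"{name}.w"]), self.params[f"{name}.b"])

    def _gn(self, name: str, x: Tensor) -> Tensor:
        ch = self.params[f"{name}.g"].data.shape[0]
        groups = self.groups if ch % self.groups == 0 else 1
        return ad.groupnorm(x, self.params[f"{name}.g"], self.params[f"{name}.b"], groups)

    def _resblock(self, name: str, x: Tensor, temb: Tensor) -> Tensor:
        cin = self.params[f"{name}.conv1.w"].data.shape[1]
        cout = self.params[f"{name}.conv1.w"].data.shape[0]
        h = self._conv(f"{name}.conv1", ad.silu(self._gn(f"{name}.gn1", x)))
        tb = self._dense(f"{name}.tproj", ad.silu(temb))
        B = tb.data.shape[0]
        h = ad.add(h, ad.reshape(tb, (B, cout, 1, 1)))
        h = self._conv(f"{name}.conv2", ad.silu(self._gn(f"{name}.gn2", h)))
        skip = self._conv(f"{name}.skip", x) if cin != cout else x
        return ad.add(skip, h)

    def _attn(self, name: str, x: Tensor) -> Tensor:
        B, C, H, W = x.data.shape
        h = self._gn(f"{name}.gn", x)
        hf = ad.transpose(ad.reshape(h, (B, C, H * W)), (0, 2, 1))  # (B, HW, C)
        q = ad.matmul(hf, self.params[f"{name}.wq"])
        k = ad.matmul(hf, self.params[f"{name}.wk"])
        v = ad.matmul(hf, self.params[f"{name}.wv"])
        scores = ad.mul(ad.matmul(q, ad.transpose(k, (0, 2, 1))), C**-0.5)
        attn = ad.softmax(scores, axis=-1)
        o = ad.matmul(ad.matmul(attn, v), self.params[f"{name}.wo"])
        o = ad.reshape(ad.transpose(o, (0, 2, 1)), (B, C, H, W))
        return ad.add(x, o)

    def forward_tensor(self, x: Tensor, t: np.ndarray) -> Tensor:
        """Graph-building forward pass; ``x`` is (B, 3, H, W) in ``dtype``."""
        B = x.data.shape[0]
        t = np.broadcast_to(np.atleast_1d(np.asarray(t)), (B,))
        temb_np = timestep_embedding(t, self.time_embed_dim).astype(self.dtype)
        temb = self._dense("temb.d2", ad.silu(self._dense("temb.d1", Tensor(temb_np))))

        chs = [self.base_channels * m for m in self.channel_mult]
        res = self.image_size
        h = self._conv("in", x)
        skips = []
        for i in range(len(chs)):
            if i > 0:
                h = ad.avgpool2(h)
                res //= 2
            h = self._resblock(f"down{i}", h, temb)
            if res in self.attention_resolutions:
                h = self._attn(f"down{i}.attn", h)
            skips.append(h)
        h = self._resblock("mid1", h, temb)
        if res in self.attention_resolutions:
            h = self._attn("mid.attn", h)
        h = self._resblock("mid2", h, temb)
        for i in reversed(range(len(chs))):
            h = ad.add(h, skips[i])
            h = self._resblock(f"up{i}", h, temb)
            r = self.image_size // (2**i)
            if r in self.attention_resolutions:
                h = self._attn(f"up{i}.attn", h)
            if i > 0:
                h = ad.upsample2(h)
                h = self._conv(f"up{i}.proj", h)
        h = self._conv("out", ad.silu(self._gn("out.gn", h)))
        return h

    def __call__(self, x: np.ndarray, t) -> np.ndarray:
        """Predict ε for image(s) ``x`` (HxWx3 or BxHxWx3) at timestep ``t``."""
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 3
        if single:
            x = x[None]
        if x.ndim != 4 or x.shape[-1] != 3:
            raise ValueError(f"expected (B,H,W,3) input, got {x.shape}")
        xin = Tensor(np.ascontiguousarray(x.transpose(0, 3, 1, 2)).astype(self.dtype))
        out = self.forward_tensor(xin, t)
        eps = out.data.astype(np.float64).transpose(0, 2, 3, 1)
        return eps[0] if single else eps

    # -- state --------------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        missing = set(self.params) - set(state)
        extra = set(state) - set(self.params)
        if missing or extra:
            raise ValueError(
                f"parameter name mismatch (missing {sorted(missing)}, extra {sorted(extra)})"
            )
        for k, p in self.params.items():
            arr = np.asarray(state[k], dtype=self.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = arr.copy()

    def param_list(self) -> list[Tensor]:
        return [self.params[k] for k in sorted(self.params)]
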