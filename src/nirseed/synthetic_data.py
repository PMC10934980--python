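"""Procedural night camera-trap scenes with pseudo-NIR counterparts.

Real training data for NIR colorization is a corpus of *unpaired* night
photographs: visible-light (RGB) frames on one side, near-infrared
frames on the other.  This module fabricates the pieces of that
statistical structure the method actually interacts with, at any
resolution, with no downloads:

* a flash-illumination cone (bright center, falloff to dark edges),
* a foreground "animal" — one or two elliptical blobs of gray-brown
  albedo,
* textured "vegetation" from band-limited noise, and
* a sky band above a horizon line.

The pseudo-NIR renderer converts an RGB scene to a single channel via
fixed channel weights and a sensor gamma, then multiplies vegetation by
a gain γ_veg > 1 before adding sensor noise.  This builds in the one
physical asymmetry the colorization strategies must confront: vegetation
reflects near-infrared light more strongly than visible light, so its
NIR intensity exceeds its visible-gray intensity.  No claim of physical
NIR accuracy is made beyond that inequality.

Scenes are deterministic functions of an integer scene seed, which is
what makes unpaired-split discipline checkable: the RGB and NIR training
sets are generated from disjoint seed sets, while the (small) evaluation
set is pixel-registered by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image_io import write_image
from .rng import as_rng, derive_seed

__all__ = [
    "SceneParams",
    "NirRenderParams",
    "DatasetSplit",
    "EvalPair",
    "generate_rgb_scene",
    "render_pseudo_nir",
    "make_dataset",
]


@dataclass(frozen=True)
class SceneParams:
    """Geometry and palette of a synthetic scene."""

    size: int = 16
    dusk_weight: float = 0.15  # probability of a dusk (bluish-sky) scene
    animal_count: tuple[int, int] = (1, 2)
    animal_size: tuple[float, float] = (0.12, 0.3)  # half-axes, fraction of size
    animal_albedo: tuple[float, float] = (0.35, 0.75)
    vegetation_density: float = 0.35
    texture_scale: float = 1.2  # smoothing radius of the vegetation noise, px
    cone_width: float = 0.7  # illumination cone width, fraction of size

    def __post_init__(self) -> None:
        if self.size < 4:
            raise ValueError("size must be >= 4")
        if not 0.0 <= self.vegetation_density <= 1.0:
            raise ValueError("vegetation_density must lie in [0, 1]")
        if not 0.0 <= self.dusk_weight <= 1.0:
            raise ValueError("dusk_weight must lie in [0, 1]")


@dataclass(frozen=True)
class NirRenderParams:
    """Pseudo-NIR sensor model."""

    weights: tuple[float, float, float] = (0.4, 0.4, 0.2)
    veg_gain: float = 1.5  # γ_veg: NIR reflectance gain of vegetation
    gamma: float = 0.9
    noise_scale: float = 0.01

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be nonnegative and sum to 1")
        if self.veg_gain < 1.0:
            raise ValueError("veg_gain must be >= 1")


def generate_rgb_scene(
    params: SceneParams, rng
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Render one RGB scene in [−1, 1] plus boolean masks.

    Returns ``(image, masks)`` with masks ``animal``, ``vegetation``,
    ``sky`` (H x W bool).  Deterministic given the rng state.
    """
    rng = as_rng(rng)
    n = params.size
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64) / (n - 1)

    dusk = rng.random() < params.dusk_weight
    horizon = 0.35 + 0.1 * rng.random()
    sky_mask = yy < horizon

    # base palette (linear [0,1] RGB)
    if dusk:
        sky_color = np.array([0.25, 0.32, 0.55]) * (0.8 + 0.4 * rng.random())
        ground_color = np.array([0.30, 0.26, 0.16])
    else:
        sky_color = np.array([0.05, 0.06, 0.10]) * (0.6 + 0.8 * rng.random())
        ground_color = np.array([0.28, 0.24, 0.14]) * (0.7 + 0.6 * rng.random())
    img = np.where(
        sky_mask[..., None], sky_color[None, None], ground_color[None, None]
    ) * (0.6 + 0.5 * yy[..., None])  # ground brightens toward the camera

    # animal geometry first, so the vegetation threshold can be chosen over
    # pixels the blobs do not occlude and the mask fraction tracks the
    # requested density
    lo, hi = params.animal_count
    animal_mask = np.zeros((n, n), dtype=bool)
    blobs = []
    for _ in range(int(rng.integers(lo, hi + 1))):
        cy = horizon + (1 - horizon) * (0.2 + 0.6 * rng.random())
        cx = 0.2 + 0.6 * rng.random()
        ay = params.animal_size[0] + (
            params.animal_size[1] - params.animal_size[0]
        ) * rng.random()
        ax = ay * (1.2 + 0.6 * rng.random())
        blob = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
        albedo = params.animal_albedo[0] + (
            params.animal_albedo[1] - params.animal_albedo[0]
        ) * rng.random()
        blobs.append((blob, np.array([1.0, 0.92, 0.8]) * albedo))
        animal_mask |= blob

    # vegetation: band-limited noise thresholded by quantile; it may
    # overhang the horizon a little but not fill the sky
    noise_field = ndimage.gaussian_filter(
        rng.standard_normal((n, n)), params.texture_scale, mode="wrap"
    )
    allowed = (yy >= horizon - 0.25) & ~animal_mask
    want = params.vegetation_density * n * n
    q = 1.0 - min(1.0, want / max(int(allowed.sum()), 1))
    thresh = np.quantile(noise_field[allowed], q)
    veg_mask = allowed & (noise_field >= thresh)
    veg_shade = 0.5 + 0.5 * (noise_field - noise_field.min()) / (
        np.ptp(noise_field) + 1e-12
    )
    veg_color = np.stack(
        [0.16 * veg_shade, 0.30 * veg_shade, 0.10 * veg_shade], axis=-1
    )
    img = np.where(veg_mask[..., None], veg_color, img)
    for blob, tint in blobs:
        img = np.where(blob[..., None], tint[None, None], img)

    # flash-illumination cone centered low in the frame
    cx0 = 0.4 + 0.2 * rng.random()
    cy0 = 0.7 + 0.2 * rng.random()
    r2 = (yy - cy0) ** 2 + (xx - cx0) ** 2
    cone = 0.25 + 0.75 * np.exp(-r2 / (params.cone_width**2))
    img = img * cone[..., None]

    img = img + 0.01 * rng.standard_normal(img.shape)
    img = np.clip(img, 0.0, 1.0)
    masks = {
        "animal": animal_mask,
        "vegetation": veg_mask,
        "sky": sky_mask & ~animal_mask,
    }
    return img * 2.0 - 1.0, masks


def render_pseudo_nir(
    rgb: np.ndarray,
    masks: dict[str, np.ndarray],
    params: NirRenderParams,
    rng,
) -> np.ndarray:
    """Single-channel pseudo-NIR view of an RGB scene, in [−1, 1].

    ``nir = clip(gamma(w · rgb_linear) · (1 + (γ_veg − 1) · veg) + noise)``;
    with γ_veg > 1 vegetation comes out brighter than in the equal-weight
    grayscale of the same scene.
    """
    rng = as_rng(rng)
    rgb = np.asarray(rgb, dtype=np.float64)
    lin = (rgb + 1.0) / 2.0
    w = np.asarray(params.weights, dtype=np.float64)
    base = np.clip(lin @ w, 0.0, None)
    nir = base**params.gamma
    veg = masks["vegetation"].astype(np.float64)
    nir = nir * (1.0 + (params.veg_gain - 1.0) * veg)
    if params.noise_scale > 0:
        nir = nir + params.noise_scale * rng.standard_normal(nir.shape)
    nir = np.clip(nir, 0.0, 1.0)
    return nir * 2.0 - 1.0


@dataclass(frozen=True)
class EvalPair:
    """A pixel-registered evaluation scene."""

    seed: int
    rgb: np.ndarray
    gray: np.ndarray  # equal-weight grayscale of rgb
    nir: np.ndarray  # pseudo-NIR render
    masks: dict[str, np.ndarray] = field(repr=False)


@dataclass
class DatasetSplit:
    """Unpaired train sets plus a paired eval set, with the seeds used."""

    train_rgb: np.ndarray  # (n, H, W, 3)
    train_nir: np.ndarray  # (n, H, W)
    eval_pairs: list[EvalPair]
    rgb_seeds: list[int]
    nir_seeds: list[int]
    eval_seeds: list[int]


def _scene_bundle(scene_seed: int, scene: SceneParams, nir: NirRenderParams):
    rng = np.random.default_rng(scene_seed)
    rgb, masks = generate_rgb_scene(scene, rng)
    pseudo = render_pseudo_nir(rgb, masks, nir, rng)
    gray = ((rgb + 1.0) / 2.0).mean(axis=-1) * 2.0 - 1.0
    return rgb, gray, pseudo, masks


def make_dataset(
    n_train: int,
    n_eval: int,
    scene: SceneParams | None = None,
    nir: NirRenderParams | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> DatasetSplit:
    """Generate an unpaired RGB/NIR training split and a paired eval set.

    Scene seeds are laid out as ``base + 3i`` (RGB train), ``base + 3i + 1``
    (NIR train) and ``base + 3i + 2`` (eval), so the RGB and NIR training
    scenes are guaranteed disjoint.  When ``out_dir`` is given, images are
    written as 8-bit PNG plus a tab-separated ``manifest.tsv`` with columns
    (split, role, seed, path); re-running with the same seed reproduces
    the files byte-identically.
    """
    if n_train < 1 or n_eval < 1:
        raise ValueError("n_train and n_eval must be >= 1")
    scene = scene or SceneParams()
    nir = nir or NirRenderParams()
    base = derive_seed(seed, "dataset")

    rgb_seeds = [(base + 3 * i) % 2**31 for i in range(n_train)]
    nir_seeds = [(base + 3 * i + 1) % 2**31 for i in range(n_train)]
    eval_seeds = [(base + 3 * i + 2) % 2**31 for i in range(n_eval)]
    assert not set(rgb_seeds) & set(nir_seeds)

    train_rgb = np.stack([_scene_bundle(s, scene, nir)[0] for s in rgb_seeds])
    train_nir = np.stack([_scene_bundle(s, scene, nir)[2] for s in nir_seeds])
    eval_pairs = []
    for s in eval_seeds:
        rgb, gray, pseudo, masks = _scene_bundle(s, scene, nir)
        eval_pairs.append(EvalPair(seed=s, rgb=rgb, gray=gray, nir=pseudo, masks=masks))

    split = DatasetSplit(
        train_rgb=train_rgb,
        train_nir=train_nir,
        eval_pairs=eval_pairs,
        rgb_seeds=rgb_seeds,
        nir_seeds=nir_seeds,
        eval_seeds=eval_seeds,
    )
    if out_dir is not None:
        _write_split(split, Path(out_dir))
    return split


def _write_split(split: DatasetSplit, out_dir: Path) -> None:
    rows = []
    for sub in ("train_rgb", "train_nir", "eval"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    for i, (img, s) in enumerate(zip(split.train_rgb, split.rgb_seeds)):
        path = out_dir / "train_rgb" / f"rgb_{i:05d}.png"
        write_image(path, img)
        rows.append(("train", "rgb", s, path.relative_to(out_dir)))
    for i, (img, s) in enumerate(zip(split.train_nir, split.nir_seeds)):
        path = out_dir / "train_nir" / f"nir_{i:05d}.png"
        write_image(path, img)
        rows.append(("train", "nir", s, path.relative_to(out_dir)))
    for i, pair in enumerate(split.eval_pairs):
        for role, img in (("rgb", pair.rgb), ("gray", pair.gray), ("nir", pair.nir)):
            path = out_dir / "eval" / f"{role}_{i:05d}.png"
            write_image(path, img)
            rows.append(("eval", role, pair.seed, path.relative_to(out_dir)))
    with open(out_dir / "manifest.tsv", "w") as fh:
        fh.write("split\trole\tseed\tpath\n")
        for split_name, role, s, path in rows:
            fh.write(f"{split_name}\t{role}\t{s}\t{path}\n")
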