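"""Orthogonal intensity/chrominance decoupling of RGB images.

Colorizing a gray reference amounts to imputing the two color coordinates
that are orthogonal to brightness.  We work with a fixed 3x3 orthogonal
matrix ``C`` whose first column is ``(a, a, a)`` with ``a = 3**-0.5``, so the
first coordinate of ``p @ C`` is the intensity ``a * (r + g + b)`` and the
remaining two coordinates carry the chrominance.  Because ``C`` is
orthogonal the decomposition is lossless: ``p = (p @ C) @ C.T``.

Pixels live in the working range ``[-1, 1]`` (8-bit files are mapped
affinely on read/write elsewhere); intensity consequently lives in
``[-sqrt(3), sqrt(3)]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DecouplingMatrix",
    "build_decoupling_matrix",
    "decouple_intensity",
    "couple_intensity",
    "replicate_gray",
    "intensity_of_gray",
]

#: intensity proportionality constant a = 3**-0.5
INTENSITY_SCALE = 1.0 / np.sqrt(3.0)


@dataclass(frozen=True)
class DecouplingMatrix:
    """The 3x3 orthogonal transform separating intensity from chrominance.

    Attributes
    ----------
    entries:
        The matrix ``C``; pixels transform row-vector style, ``p' = p @ C``.
    a:
        The intensity proportionality constant, ``3**-0.5``.
    """

    entries: np.ndarray = field(repr=False)
    a: float = INTENSITY_SCALE

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", np.asarray(self.entries, dtype=np.float64))
        if self.entries.shape != (3, 3):
            raise ValueError("decoupling matrix must be 3x3")


def build_decoupling_matrix() -> DecouplingMatrix:
    """Return the canonical decoupling matrix in closed form.

    The matrix is hard-coded (not re-derived by QR at runtime) so results
    are bit-stable across platforms::

        C = [[ a, -b,  c],
             [ a,  c, -b],
             [ a,  a,  a]]   with  a = 1/sqrt(3),
                                   b = 1/2 + 1/(2*sqrt(3)),
                                   c = 1/2 - 1/(2*sqrt(3))

    Its first column is ``(a, a, a)`` (intensity axis) and ``C @ C.T`` is the
    identity to machine precision.
    """
    a = INTENSITY_SCALE
    b = 0.5 + 0.5 * a
    c = 0.5 - 0.5 * a
    C = np.array(
        [
            [a, -b, c],
            [a, c, -b],
            [a, a, a],
        ],
        dtype=np.float64,
    )
    return DecouplingMatrix(entries=C)


_MATRIX = build_decoupling_matrix()


def _validate_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim < 2 or img.shape[-1] != 3:
        raise ValueError(f"expected an (..., 3) RGB array, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("RGB image contains non-finite values")
    return img


def decouple_intensity(
    img: np.ndarray, matrix: DecouplingMatrix | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split an RGB image into intensity and chrominance, ``p' = p @ C``.

    Parameters
    ----------
    img:
        ``H x W x 3`` array of finite reals (working range ``[-1, 1]``).

    Returns
    -------
    intensity:
        ``H x W`` array, equal to ``(r + g + b) / sqrt(3)`` per pixel.
    chroma:
        ``H x W x 2`` array, the two remaining orthogonal coordinates.
    """
    img = _validate_rgb(img)
    C = (matrix or _MATRIX).entries
    transformed = img @ C
    return transformed[..., 0], transformed[..., 1:]


def couple_intensity(
    intensity: np.ndarray,
    chroma: np.ndarray,
    matrix: DecouplingMatrix | None = None,
) -> np.ndarray:
    """Inverse of :func:`decouple_intensity`: ``p = (I, c1, c2) @ C.T``."""
    intensity = np.asarray(intensity, dtype=np.float64)
    chroma = np.asarray(chroma, dtype=np.float64)
    if chroma.shape != intensity.shape + (2,):
        raise ValueError(
            f"shape mismatch: intensity {intensity.shape} vs chroma {chroma.shape}"
        )
    C = (matrix or _MATRIX).entries
    stacked = np.concatenate([intensity[..., None], chroma], axis=-1)
    return stacked @ C.T


def replicate_gray(gray: np.ndarray) -> np.ndarray:
    """Replicate a single-channel image to 3 identical channels.

    Used to feed a gray NIR reference through machinery that expects RGB;
    the replicated image has chrominance identically zero and intensity
    ``sqrt(3) * v`` per pixel.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError(f"expected an HxW gray array, got shape {gray.shape}")
    return np.repeat(gray[..., None], 3, axis=-1)


def intensity_of_gray(gray: np.ndarray) -> np.ndarray:
    """Intensity channel of ``replicate_gray(gray)`` without the chroma work.

    Equals ``sqrt(3) * gray`` exactly (three equal channels summed times
    ``1/sqrt(3)``); a fast path for the seeding loop, which never consumes
    the reference's chrominance.
    """
    gray = np.asarray(gray, dtype=np.float64)
    return 3.0 * INTENSITY_SCALE * gray
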