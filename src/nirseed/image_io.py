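"""8-bit image file plumbing.

Files are PNG/TIFF/JPEG, 8-bit; the in-memory working range is [−1, 1]
mapped affinely from [0, 255].  Writing rounds half-to-even.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image", "read_gray", "to_uint8", "from_uint8"]


def from_uint8(arr: np.ndarray) -> np.ndarray:
    """[0, 255] uint8 → [−1, 1] float64."""
    return np.asarray(arr, dtype=np.float64) / 255.0 * 2.0 - 1.0


def to_uint8(arr: np.ndarray) -> np.ndarray:
    """[−1, 1] float → [0, 255] uint8, round-half-even, clipped."""
    scaled = (np.clip(np.asarray(arr, dtype=np.float64), -1.0, 1.0) + 1.0) / 2.0 * 255.0
    return np.rint(scaled).astype(np.uint8)


def read_image(path: str | Path) -> np.ndarray:
    """Read an image file into [−1, 1]; (H, W, 3) for color, (H, W) for gray.

    RGBA alpha is dropped; 16-bit files are rescaled through their dtype
    maximum.
    """
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint16:
        arr = (arr / 257.0).round().astype(np.uint8)
    return from_uint8(arr)


def read_gray(path: str | Path) -> np.ndarray:
    """Read a file as a single-channel image in [−1, 1].

    Color files are reduced by the equal-weight channel mean.
    """
    img = read_image(path)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    return img


def write_image(path: str | Path, arr: np.ndarray) -> None:
    """Write a [−1, 1] array as an 8-bit PNG/TIFF/JPEG (by extension)."""
    iio.imwrite(Path(path), to_uint8(arr))
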