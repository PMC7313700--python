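"""Image and mask I/O, resolution halving, and the mask-application stage.

Images are plain ``uint8`` numpy arrays: RGB images with shape ``(N, M, 3)``,
binary masks with shape ``(N, M)`` and values in ``{0, 1}``.  The coordinate
convention is row index ``i`` in ``[0, N-1]`` top to bottom, column index
``j`` in ``[0, M-1]`` left to right, matching the pixel-stream scan order
(first line, left to right).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "ImageIOError",
    "UnreadableImageError",
    "ShapeMismatchError",
    "EmptyMaskError",
    "MaskedChannels",
    "as_rgb_image",
    "as_binary_mask",
    "load_image_pair",
    "save_image",
    "save_mask",
    "halve_resolution",
    "apply_mask",
]


class ImageIOError(ValueError):
    pass


class UnreadableImageError(ImageIOError):
    pass


class ShapeMismatchError(ImageIOError):
    pass


class EmptyMaskError(ImageIOError):
    pass


@dataclass(frozen=True)
class MaskedChannels:
    """Per-channel pixel intensities after the lesion mask is applied.

    Equals the original channel where the mask is 1 and zero elsewhere
    (the AND-gate semantics: mask bit 1 expands to 0xFF).
    """

    rm: np.ndarray
    gm: np.ndarray
    bm: np.ndarray


def as_rgb_image(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageIOError(f"RGB image must have shape (N, M, 3), got {arr.shape}")
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise ImageIOError("RGB channel values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def as_binary_mask(arr: np.ndarray) -> np.ndarray:
    """Binarize a mask array: any nonzero byte becomes 1."""
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ImageIOError(f"mask must be 2-D, got shape {arr.shape}")
    return (arr != 0).astype(np.uint8)


def load_image_pair(image_path, mask_path) -> tuple[np.ndarray, np.ndarray]:
    """Load an RGB dermoscopic image and its binary lesion mask.

    The mask is binarized (nonzero -> 1) and validated against the image
    shape; an all-zero mask (no lesion) is rejected.
    """
    img = _read(image_path, "RGB")
    mask = as_binary_mask(_read(mask_path, "L"))
    if img.shape[:2] != mask.shape:
        raise ShapeMismatchError(
            f"image shape {img.shape[:2]} != mask shape {mask.shape}"
        )
    if not mask.any():
        raise EmptyMaskError(f"mask {mask_path} contains no lesion pixels")
    return as_rgb_image(img), mask


def _read(path, pil_mode: str) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise UnreadableImageError(f"no such file: {path}")
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert(pil_mode))
    except UnidentifiedImageError as exc:
        raise UnreadableImageError(f"cannot decode image file: {path}") from exc


def save_image(arr: np.ndarray, path) -> None:
    Image.fromarray(as_rgb_image(arr), mode="RGB").save(path)


def save_mask(mask: np.ndarray, path) -> None:
    Image.fromarray(as_binary_mask(mask) * 255, mode="L").save(path)


def halve_resolution(
    img: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Halve the resolution per axis (e.g. 768x560 -> 384x280).

    RGB blocks of 2x2 are box-averaged with truncation to integer; mask
    blocks take the 2x2 majority, ties resolved to 1 (lesion), which keeps
    the mask binary and area-stable.  Odd dimensions are padded first by
    edge replication.
    """
    img = as_rgb_image(img)
    mask = as_binary_mask(mask)
    if img.shape[:2] != mask.shape:
        raise ShapeMismatchError("image and mask shapes differ")
    n, m = mask.shape
    if n % 2 or m % 2:
        pn, pm = n % 2, m % 2
        img = np.pad(img, ((0, pn), (0, pm), (0, 0)), mode="edge")
        mask = np.pad(mask, ((0, pn), (0, pm)), mode="edge")
        n, m = mask.shape
    blocks = img.reshape(n // 2, 2, m // 2, 2, 3).astype(np.uint32)
    out_img = (blocks.sum(axis=(1, 3)) // 4).astype(np.uint8)
    msum = mask.reshape(n // 2, 2, m // 2, 2).astype(np.uint8).sum(axis=(1, 3))
    out_mask = (msum >= 2).astype(np.uint8)
    return out_img, out_mask


def apply_mask(img: np.ndarray, mask: np.ndarray) -> MaskedChannels:
    """AND each channel with the mask expanded to 8 bits (1 -> 255)."""
    img = as_rgb_image(img)
    mask = as_binary_mask(mask)
    if img.shape[:2] != mask.shape:
        raise ShapeMismatchError("image and mask shapes differ")
    m255 = mask * np.uint8(255)
    return MaskedChannels(
        rm=img[:, :, 0] & m255,
        gm=img[:, :, 1] & m255,
        bm=img[:, :, 2] & m255,
    )
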