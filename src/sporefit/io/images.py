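"""Lossless PNG I/O for plate photographs and label images."""

from __future__ import annotations

import numpy as np
from imageio.v3 import imread, imwrite


def write_plate_image(image: np.ndarray, path) -> None:
    """Write an RGB plate photograph as PNG (lossless)."""
    if image.dtype != np.uint8 or image.ndim != 3:
        raise ValueError("expected a uint8 RGB image")
    imwrite(str(path), image)


def read_plate_image(path) -> np.ndarray:
    image = imread(str(path))
    if image.ndim == 3 and image.shape[2] == 4:  # drop alpha if present
        image = image[..., :3]
    return image


def write_label_image(labels: np.ndarray, path) -> None:
    """Write a per-pixel class-label image as single-channel PNG."""
    if labels.ndim != 2:
        raise ValueError("expected a 2-D label image")
    imwrite(str(path), labels.astype(np.uint8))


def read_label_image(path) -> np.ndarray:
    return imread(str(path)).astype(np.uint8)
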