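"""Cropping detected wells to normalized 256x256 tiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .wells import WellRegion

CROP_SIZE = 256
#: square crop side as a multiple of the well radius; leaves a margin of
#: plate housing around the disk so the in-well mask is unambiguous
CROP_SCALE = 2.2


@dataclass
class WellCrop:
    """A 256x256 RGB tile centered on one well."""

    pixels: np.ndarray  # (256, 256, 3) uint8
    source_region: WellRegion
    time_h: float | None = None
    source_side_px: int | None = None  # square side before resizing

    def __post_init__(self):
        if self.pixels.shape != (CROP_SIZE, CROP_SIZE, 3):
            raise ValueError(f"crop must be {CROP_SIZE}x{CROP_SIZE}x3")

    @property
    def well_radius_px(self) -> float:
        """The well radius in crop coordinates (after resizing)."""
        if self.source_side_px:
            return self.source_region.radius_px * CROP_SIZE / self.source_side_px
        return CROP_SIZE / CROP_SCALE


def crop_and_normalize(
    image: np.ndarray,
    region: WellRegion,
    time_h: float | None = None,
    scale: float = CROP_SCALE,
) -> WellCrop:
    """Square crop centered on the well, edge-padded, resized to 256x256.

    The crop side is ``scale * well radius`` (rounded); parts falling
    outside the image are filled by edge replication.  Resizing is
    bilinear; a crop whose side is already 256 passes through unchanged.
    """
    H, W = image.shape[:2]
    side = max(2, int(round(2 * region.radius_px * scale / 2)))
    x0 = int(round(region.center_x_px - side / 2))
    y0 = int(round(region.center_y_px - side / 2))
    if x0 + side <= 0 or y0 + side <= 0 or x0 >= W or y0 >= H:
        raise ValueError(f"well {region.well_id} lies fully outside the image")

    pad_left = max(0, -x0)
    pad_top = max(0, -y0)
    pad_right = max(0, x0 + side - W)
    pad_bottom = max(0, y0 + side - H)
    xs = slice(max(0, x0), min(W, x0 + side))
    ys = slice(max(0, y0), min(H, y0 + side))
    tile = image[ys, xs]
    if pad_left or pad_top or pad_right or pad_bottom:
        tile = np.pad(
            tile, ((pad_top, pad_bottom), (pad_left, pad_right), (0, 0)), mode="edge"
        )
    if tile.shape[0] != CROP_SIZE:
        tile = resize(
            tile.astype(float),
            (CROP_SIZE, CROP_SIZE),
            order=1,
            anti_aliasing=False,
            preserve_range=True,
        )
        tile = np.clip(tile, 0, 255).round()
    return WellCrop(
        pixels=tile.astype(np.uint8), source_region=region, time_h=time_h,
        source_side_px=side,
    )
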