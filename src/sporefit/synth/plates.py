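"""Synthetic 96-well phenotype-plate photographs with per-pixel truth.

Wells are rendered as filled disks on a regular grid (optionally rotated a
few degrees); fungal growth inside a well is rendered from a smoothed
random field thresholded at the exact pixel quantile that realizes the
requested coverage, so the emitted label image is the ground truth by
construction.  Colors follow the visual classes a plate photograph
separates: low-saturation gray background, beige medium, bright
low-saturation aerial hyphae, dark saturated green conidia.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb

from .rng import stream

LABEL_OUTSIDE, LABEL_MEDIUM, LABEL_HYPHAE, LABEL_CONIDIA = 0, 1, 2, 3
LABEL_NAMES = {0: "outside", 1: "medium", 2: "hyphae", 3: "conidia"}


@dataclass
class PlateSpec:
    """Geometry, colors and noise of a rendered plate photograph."""

    n_rows: int = 8
    n_cols: int = 12
    image_width_px: int = 640
    image_height_px: int = 448
    well_radius_px: int = 18
    pitch_px: int = 46
    # HSV in [0,1]^3; jitter is a per-well hue/sat/val perturbation SD
    background_hsv: tuple = (0.10, 0.05, 0.45)
    medium_hsv: tuple = (0.09, 0.38, 0.82)
    hyphae_hsv: tuple = (0.12, 0.16, 0.97)
    conidia_hsv: tuple = (0.33, 0.65, 0.35)
    color_jitter_sd: float = 0.02
    rotation_deg: float = 0.0
    noise_sd: float = 0.015
    seed: int = 0

    def __post_init__(self):
        if abs(self.rotation_deg) > 3.0:
            raise ValueError("rotation is limited to +/- 3 degrees")
        span_x = (self.n_cols - 1) * self.pitch_px + 2 * self.well_radius_px
        span_y = (self.n_rows - 1) * self.pitch_px + 2 * self.well_radius_px
        if span_x > self.image_width_px or span_y > self.image_height_px:
            raise ValueError("well grid does not fit inside the image")
        if self.pitch_px < 2 * self.well_radius_px:
            raise ValueError("wells overlap: pitch < well diameter")
        interior_min_sat = min(self.medium_hsv[1], self.hyphae_hsv[1], self.conidia_hsv[1])
        if interior_min_sat - self.background_hsv[1] < 0.1:
            raise ValueError("well-interior saturation must exceed background saturation")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    def well_centers(self) -> list:
        """(row, col, x, y) for every well, after global rotation."""
        cx, cy = self.image_width_px / 2.0, self.image_height_px / 2.0
        theta = np.deg2rad(self.rotation_deg)
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        out = []
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                x0 = cx + (c - (self.n_cols - 1) / 2.0) * self.pitch_px
                y0 = cy + (r - (self.n_rows - 1) / 2.0) * self.pitch_px
                dx, dy = x0 - cx, y0 - cy
                out.append(
                    (r, c, cx + cos_t * dx - sin_t * dy, cy + sin_t * dx + cos_t * dy)
                )
        return out


@dataclass
class PlateGroundTruth:
    """Per-pixel labels and exact per-well coverage for one rendered plate."""

    well_centers: list  # (row, col, x_px, y_px)
    pixel_labels: np.ndarray  # (H, W) uint8, LABEL_* codes
    coverage_truth: np.ndarray  # (n_wells, 2): % hyphae, % conidia, row-major


def _well_window(spec: PlateSpec, x: float, y: float):
    """Bounding-box slices and in-disk mask for one well."""
    r = spec.well_radius_px
    x0, x1 = int(np.floor(x - r - 1)), int(np.ceil(x + r + 2))
    y0, y1 = int(np.floor(y - r - 1)), int(np.ceil(y + r + 2))
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, spec.image_width_px), min(y1, spec.image_height_px)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    disk = (xx - x) ** 2 + (yy - y) ** 2 <= r**2
    return (slice(y0, y1), slice(x0, x1)), disk


def generate_plate_image(spec: PlateSpec, coverage_request=None):
    """Render a plate and its ground truth.

    Parameters
    ----------
    coverage_request : array-like (n_wells, 2) or None
        Requested (%hyphae, %conidia) per well in row-major well order;
        ``None`` means an empty (all-medium) plate.  Per-well sums must
        not exceed 100.

    Returns
    -------
    (image, truth) : (uint8 RGB array (H, W, 3), PlateGroundTruth)
        Realized coverage is within one percentage point of the request
        (pixel discretization only).
    """
    n_wells = spec.n_wells
    if coverage_request is None:
        coverage_request = np.zeros((n_wells, 2))
    req = np.asarray(coverage_request, dtype=float)
    if req.shape != (n_wells, 2):
        raise ValueError(f"coverage_request must have shape ({n_wells}, 2)")
    if (req < 0).any() or (req.sum(axis=1) > 100 + 1e-9).any():
        raise ValueError("per-well %hyphae + %conidia must lie in [0, 100]")

    H, W = spec.image_height_px, spec.image_width_px
    labels = np.zeros((H, W), dtype=np.uint8)
    hsv = np.empty((H, W, 3))
    hsv[:] = spec.background_hsv
    rng = stream(spec.seed, "plate")
    centers = spec.well_centers()
    coverage = np.zeros((n_wells, 2))
    palettes = {
        LABEL_MEDIUM: np.array(spec.medium_hsv),
        LABEL_HYPHAE: np.array(spec.hyphae_hsv),
        LABEL_CONIDIA: np.array(spec.conidia_hsv),
    }

    for w, (r, c, x, y) in enumerate(centers):
        window, disk = _well_window(spec, x, y)
        n_disk = int(disk.sum())
        lab = labels[window]
        lab[disk] = LABEL_MEDIUM
        n_cov = int(round(req[w].sum() / 100.0 * n_disk))
        n_con = int(round(req[w, 1] / 100.0 * n_disk))
        if n_cov:
            field = gaussian_filter(
                rng.normal(size=disk.shape), sigma=spec.well_radius_px / 4.0
            )
            order = np.argsort(field[disk])[::-1]
            iy, ix = np.nonzero(disk)
            lab[iy[order[:n_cov]], ix[order[:n_cov]]] = LABEL_HYPHAE
            # conidia sit on the most densely covered cores of the growth
            lab[iy[order[:n_con]], ix[order[:n_con]]] = LABEL_CONIDIA
        coverage[w, 0] = 100.0 * (n_cov - n_con) / n_disk
        coverage[w, 1] = 100.0 * n_con / n_disk

        jitter = rng.normal(0, spec.color_jitter_sd, size=3)
        view = hsv[window]
        for code, base in palettes.items():
            sel = disk & (lab == code)
            view[sel] = np.clip(base + jitter, 0, 1)

    rgb = hsv2rgb(hsv)
    rgb += rng.normal(0, spec.noise_sd, size=rgb.shape)
    image = (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8)
    return image, PlateGroundTruth(
        well_centers=centers, pixel_labels=labels, coverage_truth=coverage
    )


def truth_mask_for_crop(truth: PlateGroundTruth, crop):
    """Ground-truth class mask resampled into a crop's 256x256 frame.

    Nearest-neighbor resampling that mirrors the crop geometry exactly
    (same square side, origin rounding and pixel-center convention as the
    crop itself), with the generator's four labels collapsed onto the
    classifier's three (outside/medium -> background).
    """
    from ..repaint.classify import ClassMask

    region = crop.source_region
    side = crop.source_side_px
    size = crop.pixels.shape[0]
    x0 = int(round(region.center_x_px - side / 2))
    y0 = int(round(region.center_y_px - side / 2))
    src = (np.arange(size) + 0.5) * side / size - 0.5
    yi = np.clip((y0 + src).round().astype(int), 0, truth.pixel_labels.shape[0] - 1)
    xi = np.clip((x0 + src).round().astype(int), 0, truth.pixel_labels.shape[1] - 1)
    labels = truth.pixel_labels[np.ix_(yi, xi)]
    out = np.zeros_like(labels)
    out[labels == LABEL_HYPHAE] = 1
    out[labels == LABEL_CONIDIA] = 2
    return ClassMask(labels=out.astype(np.uint8))
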