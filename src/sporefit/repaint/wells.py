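"""Well detection on plate photographs.

Wells read as high-saturation blobs against the plate housing, so
detection thresholds the HSV saturation channel at Otsu's level, cleans
the mask morphologically, filters connected components by plausible disk
area, and reconciles the surviving blobs against a least-squares grid
fit.  Wells the blob stage misses (e.g. fully overgrown with white
mycelium) are imputed from the fitted grid and flagged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes, gaussian_filter
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import closing, disk, opening

log = logging.getLogger(__name__)

#: minimum saturation contrast between well blobs and background for a
#: detection to count; a flat image yields no wells instead of noise
MIN_SATURATION_CONTRAST = 0.08


@dataclass
class WellRegion:
    """One detected (or grid-imputed) well."""

    row_index: int
    col_index: int
    well_id: str
    center_x_px: float
    center_y_px: float
    radius_px: float
    imputed: bool = False


def well_name(row: int, col: int) -> str:
    """Row letter + 1-based column, e.g. (0, 0) -> 'A1'."""
    return f"{chr(ord('A') + row)}{col + 1}"


def _blob_centroids(image: np.ndarray, n_expected: int) -> tuple:
    """Saturation-blob centroids and the median blob radius.

    Well interiors read as a saturation plateau (medium, conidia); dense
    aerial mycelium inside a well is instead much brighter than the plate
    housing, so the well mask is the union of the Otsu-thresholded
    saturation and value channels, closed and hole-filled before
    connected components are taken.
    """
    hsv = rgb2hsv(image)
    sat = gaussian_filter(hsv[..., 1], sigma=1.5)
    val = gaussian_filter(hsv[..., 2], sigma=1.5)
    try:
        thr = threshold_otsu(sat)
    except ValueError:  # constant image
        return np.empty((0, 2)), 0.0
    mask = sat > thr
    if not mask.any() or mask.all():
        return np.empty((0, 2)), 0.0
    if sat[mask].mean() - sat[~mask].mean() < MIN_SATURATION_CONTRAST:
        return np.empty((0, 2)), 0.0
    bright = val > threshold_otsu(val)
    if bright.any() and not bright.all():
        if val[bright].mean() - val[~bright].mean() >= MIN_SATURATION_CONTRAST:
            mask = mask | bright
    mask = binary_fill_holes(closing(mask, disk(4)))
    mask = opening(mask, disk(3))
    props = regionprops(cc_label(mask))
    if not props:
        return np.empty((0, 2)), 0.0
    # reference area: the median of the largest plausible-well blobs, so
    # stray specks cannot drag the filter toward themselves
    areas = np.sort([p.area for p in props])[::-1]
    expected = float(np.median(areas[: max(1, min(len(areas), n_expected))]))
    keep = [p for p in props if 0.4 * expected <= p.area <= 2.2 * expected]
    cents = np.array([(p.centroid[1], p.centroid[0]) for p in keep])  # (x, y)
    radius = float(np.median([np.sqrt(p.area / np.pi) for p in keep]))
    return cents, radius


def _estimate_rotation(cents: np.ndarray) -> float:
    """Grid rotation (radians) from nearest-neighbor displacement angles."""
    if len(cents) < 2:
        return 0.0
    angles = []
    for i, c in enumerate(cents):
        d = cents - c
        dist = np.hypot(d[:, 0], d[:, 1])
        dist[i] = np.inf
        j = int(np.argmin(dist))
        ang = np.arctan2(d[j, 1], d[j, 0])
        # fold onto (-45, 45] degrees: grid vectors are multiples of 90
        ang = (ang + np.pi / 4) % (np.pi / 2) - np.pi / 4
        angles.append(ang)
    return float(np.median(angles))


def _cluster_1d(values: np.ndarray, expected: int) -> tuple:
    """Assign sorted 1-D coordinates to grid lines by gap splitting."""
    order = np.argsort(values)
    sv = values[order]
    gaps = np.diff(sv)
    if expected > 1 and len(sv) > 1:
        span = sv[-1] - sv[0]
        thr = max(span / (2.0 * (expected - 1)), 1.0)
    else:
        thr = np.inf
    groups = np.zeros(len(sv), dtype=int)
    for k, g in enumerate(gaps):
        groups[k + 1] = groups[k] + (1 if g > thr else 0)
    assign = np.empty(len(sv), dtype=int)
    assign[order] = groups
    centers = np.array([values[assign == g].mean() for g in range(groups[-1] + 1)])
    return assign, centers


def detect_wells(image: np.ndarray, expected_grid: tuple = (8, 12)) -> list:
    """Detect the well grid on an RGB plate photograph.

    Returns regions sorted row-major (A1..H12).  Missing wells are imputed
    from the fitted grid and flagged ``imputed=True``; an image with no
    detectable blobs yields an empty list (with a warning logged).
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    n_rows, n_cols = expected_grid
    cents, radius = _blob_centroids(image, n_rows * n_cols)
    if len(cents) == 0:
        log.warning("no saturation blobs found; returning no wells")
        return []

    theta = _estimate_rotation(cents)
    cx, cy = image.shape[1] / 2.0, image.shape[0] / 2.0
    cos_t, sin_t = np.cos(-theta), np.sin(-theta)
    dx, dy = cents[:, 0] - cx, cents[:, 1] - cy
    ux = cx + cos_t * dx - sin_t * dy
    uy = cy + sin_t * dx + cos_t * dy

    col_of, col_centers = _cluster_1d(ux, n_cols)
    row_of, row_centers = _cluster_1d(uy, n_rows)
    if len(col_centers) > n_cols or len(row_centers) > n_rows:
        warnings.warn(
            f"found {len(row_centers)}x{len(col_centers)} grid lines for an "
            f"expected {n_rows}x{n_cols} grid"
        )

    # least-squares line through the cluster centers gives origin + pitch
    def fit_axis(centers: np.ndarray, expected: int) -> tuple:
        if len(centers) == 1:
            return centers[0], 0.0
        idx = np.arange(len(centers))
        pitch, origin = np.polyfit(idx, np.sort(centers), 1)
        return origin, pitch

    x0, px = fit_axis(col_centers, n_cols)
    y0, py = fit_axis(row_centers, n_rows)
    # anchor the grid so detected lines map onto 0..expected-1; if fewer
    # lines were found than expected, shift so the grid stays in-image
    if len(col_centers) < n_cols and px > 0:
        shift = round((x0 - (cx - (n_cols - 1) / 2.0 * px)) / px)
        x0 -= shift * px if abs(shift) <= n_cols - len(col_centers) else 0.0
    if len(row_centers) < n_rows and py > 0:
        shift = round((y0 - (cy - (n_rows - 1) / 2.0 * py)) / py)
        y0 -= shift * py if abs(shift) <= n_rows - len(row_centers) else 0.0

    cos_b, sin_b = np.cos(theta), np.sin(theta)
    regions = []
    for r in range(n_rows):
        for c in range(n_cols):
            gx, gy = x0 + c * px, y0 + r * py
            # nearest detected blob (in derotated frame)
            d2 = (ux - gx) ** 2 + (uy - gy) ** 2
            j = int(np.argmin(d2))
            tol = 0.5 * max(px, py) if max(px, py) > 0 else 3 * radius
            if d2[j] <= tol**2:
                bx, by = float(cents[j, 0]), float(cents[j, 1])
                imputed = False
            else:
                ddx, ddy = gx - cx, gy - cy
                bx = cx + cos_b * ddx - sin_b * ddy
                by = cy + sin_b * ddx + cos_b * ddy
                imputed = True
            regions.append(
                WellRegion(
                    row_index=r,
                    col_index=c,
                    well_id=well_name(r, c),
                    center_x_px=bx,
                    center_y_px=by,
                    radius_px=radius,
                    imputed=imputed,
                )
            )
    n_imputed = sum(r.imputed for r in regions)
    if n_imputed:
        log.warning("imputed %d of %d wells from the grid fit", n_imputed, len(regions))
    return regions
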