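"""Coverage quantification and time-series assembly."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CLASS_CONIDIA, CLASS_HYPHAE, ClassMask
from .crop import CROP_SCALE, CROP_SIZE

#: imaging hours post inoculation at which plates are photographed
REPAINT_TIMEPOINTS = (72, 96, 120, 144, 168)


@dataclass
class CoverageRecord:
    """Percent of one well's area covered by hyphae and by conidia."""

    well_id: str
    pct_hyphae: float
    pct_conidia: float
    time_h: float | None = None
    carbon_source: str | None = None

    def __post_init__(self):
        for v in (self.pct_hyphae, self.pct_conidia):
            if not 0.0 <= v <= 100.0:
                raise ValueError("coverage percentages must lie in [0, 100]")
        if self.pct_hyphae + self.pct_conidia > 100.0 + 1e-9:
            raise ValueError("hyphae + conidia coverage cannot exceed 100%")


def well_disk_mask(size: int = CROP_SIZE, scale: float = CROP_SCALE,
                   radius: float | None = None) -> np.ndarray:
    """Boolean in-well disk for a normalized crop.

    By default the radius follows from the crop geometry (side =
    ``scale`` x well radius, resized to ``size``); pass ``radius`` to use
    a crop's exact effective well radius instead.
    """
    if radius is None:
        radius = size / scale
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius**2


def coverage(
    mask: ClassMask,
    disk: np.ndarray | None = None,
    well_id: str = "?",
    time_h: float | None = None,
    carbon_source: str | None = None,
) -> CoverageRecord:
    """Coverage percentages computed over in-well pixels only."""
    labels = mask.labels
    if disk is None:
        disk = well_disk_mask(labels.shape[0])
    if disk.shape != labels.shape:
        raise ValueError("well disk mask must match the class mask shape")
    n = int(disk.sum())
    if n == 0:
        raise ValueError("empty well disk")
    in_well = labels[disk]
    return CoverageRecord(
        well_id=well_id,
        pct_hyphae=100.0 * float((in_well == CLASS_HYPHAE).sum()) / n,
        pct_conidia=100.0 * float((in_well == CLASS_CONIDIA).sum()) / n,
        time_h=time_h,
        carbon_source=carbon_source,
    )


def assemble_timeseries(records) -> pd.DataFrame:
    """Long-format (well, time) coverage table.

    Missing timepoints simply yield no row (never interpolated); duplicate
    (well, time) keys with conflicting values raise.
    """
    rows = [
        {
            "well_id": r.well_id,
            "time_h": r.time_h,
            "carbon_source": r.carbon_source,
            "pct_hyphae": r.pct_hyphae,
            "pct_conidia": r.pct_conidia,
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    dup = df.groupby(["well_id", "time_h"], dropna=False)[["pct_hyphae", "pct_conidia"]].nunique()
    if (dup > 1).any().any():
        bad = dup[(dup > 1).any(axis=1)].index.tolist()
        raise ValueError(f"conflicting duplicate (well, time) records: {bad}")
    df = df.drop_duplicates(subset=["well_id", "time_h"])
    return df.sort_values(["well_id", "time_h"], kind="stable").reset_index(drop=True)


def quantify_plate(
    image: np.ndarray,
    classifier,
    time_h: float | None = None,
    layout: dict | None = None,
    expected_grid: tuple = (8, 12),
) -> list:
    """Full REPAINT pass on one photograph: detect, crop, segment, quantify."""
    from .crop import crop_and_normalize
    from .classify import segment
    from .wells import detect_wells

    records = []
    for region in detect_wells(image, expected_grid):
        crop = crop_and_normalize(image, region, time_h=time_h)
        mask = segment(crop, classifier)
        records.append(
            coverage(
                mask,
                disk=well_disk_mask(radius=crop.well_radius_px),
                well_id=region.well_id,
                time_h=time_h,
                carbon_source=(layout or {}).get(region.well_id),
            )
        )
    return records
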