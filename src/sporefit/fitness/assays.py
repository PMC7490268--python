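"""Elementary assay statistics: dispersal indices, CFU titers, survival,
spore wettability."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: contact-angle boundary: droplets wet the surface below 90 degrees
WCA_HYDROPHILIC_BOUNDARY_DEG = 90.0
#: two dilution series must agree within this factor to accept a titer
TITER_AGREEMENT_FOLD = 2.0


@dataclass
class DispersalRecord:
    """One dispersal measurement: raw count plus its normalization OD."""

    genotype: str
    medium: str  # "air" (CFU per trap plate) or "water" (spores per volume)
    raw_count: float
    norm_od: float
    replicate: int = 1

    def __post_init__(self):
        if self.medium not in ("air", "water"):
            raise ValueError(f"medium must be 'air' or 'water', got {self.medium!r}")
        if self.raw_count < 0:
            raise ValueError("raw_count must be non-negative")
        if self.norm_od <= 0:
            raise ValueError("normalization OD must be positive")


def dispersal_index(record: DispersalRecord) -> float:
    """Spore abundance normalized by suspension optical density.

    Division by the OD of spores washed from a matched culture plug makes
    counts comparable across cultures with different sporulation density.
    """
    return record.raw_count / record.norm_od


@dataclass
class StressSeries:
    """Dilution-plating series: (dilution_factor, plated_volume_mL, colonies)."""

    series: list

    def __post_init__(self):
        if not self.series:
            raise ValueError("need at least one dilution-series triple")
        for d, v, n in self.series:
            if d < 1:
                raise ValueError("dilution factor must be >= 1")
            if v <= 0:
                raise ValueError("plated volume must be positive")
            if n < 0:
                raise ValueError("colony counts must be non-negative")


def titer_from_dilution_series(series, tolerance_fold: float = TITER_AGREEMENT_FOLD):
    """CFU/mL from dilution plating, with the two-series acceptance rule.

    Each (dilution_factor, volume_mL, colonies) triple implies
    ``colonies * dilution_factor / volume_mL`` CFU/mL; the mean over
    series is reported.  The result is accepted only if at least two
    series agree within ``tolerance_fold`` (an all-zero pair of series
    counts as agreement on titer zero).

    Returns
    -------
    (titer, accepted) : (float, bool)
    """
    ss = StressSeries(list(series)).series
    titers = [n * d / v for d, v, n in ss]
    titer = float(np.mean(titers))
    if len(titers) < 2:
        return titer, False
    nonzero = [t for t in titers if t > 0]
    if not nonzero:
        return 0.0, True
    if len(nonzero) < 2:
        return titer, False
    accepted = max(nonzero) / min(nonzero) <= tolerance_fold
    return titer, bool(accepted)


def survival_percent(treated_titer: float, control_titer: float) -> float:
    """Survival as the CFU percentage of treated versus untreated spores."""
    if control_titer <= 0:
        raise ValueError("survival is undefined for a non-positive control titer")
    if treated_titer < 0:
        raise ValueError("treated titer must be non-negative")
    return 100.0 * treated_titer / control_titer


@dataclass
class WCARecord:
    """One water-contact-angle measurement in degrees."""

    genotype: str
    theta_deg: float
    replicate: int = 1

    def __post_init__(self):
        if not 0.0 < self.theta_deg < 180.0:
            raise ValueError(f"contact angle must lie in (0, 180), got {self.theta_deg}")


def classify_wettability(theta_deg: float) -> str:
    """'hydrophilic' below 90 degrees, 'hydrophobic' at or above.

    The boundary value itself is assigned to hydrophobic: only angles
    strictly below 90 degrees count as wetting.
    """
    if not 0.0 < theta_deg < 180.0:
        raise ValueError(f"contact angle must lie in (0, 180), got {theta_deg}")
    return "hydrophilic" if theta_deg < WCA_HYDROPHILIC_BOUNDARY_DEG else "hydrophobic"
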