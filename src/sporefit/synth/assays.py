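"""Synthetic assay tables: dispersal, stress survival, wettability, qPCR, growth.

Noise models follow the nature of each measurement: colony and spore
counts are Poisson, optical densities, contact angles and Ct values are
Gaussian.  Every table conforms to the reader schemas in ``sporefit.io``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rng import stream

STRESSORS = ("desiccation", "freeze", "UV")
STAGES = ("48h", "72h", "120h")
BIOLOG_TIMEPOINTS = (12, 18, 24, 36, 48, 60, 72, 96, 120, 144, 168)


@dataclass
class GenotypeEffects:
    """True per-genotype assay means the generator draws around.

    Attributes
    ----------
    air_cfu_mean, water_count_mean : float
        Expected raw dispersal counts at unit optical density.
    survival : dict
        Stressor -> true survival probability in [0, 1].
    wca_mean_deg : float
        Mean water contact angle in degrees.
    expression_log2fold : dict
        Gene -> stage -> true log2 fold change relative to the calibrator
        stage (first stage by convention).
    growth_capacity, growth_rate, growth_midpoint_h : float
        Logistic OD750 curve parameters (plateau, 1/h rate, inflection h).
    """

    air_cfu_mean: float = 50.0
    water_count_mean: float = 50.0
    norm_od_mean: float = 1.0
    survival: dict = field(default_factory=lambda: {s: 0.5 for s in STRESSORS})
    wca_mean_deg: float = 120.0
    expression_log2fold: dict = field(default_factory=dict)
    growth_capacity: float = 1.0
    growth_rate: float = 0.08
    growth_midpoint_h: float = 60.0

    def __post_init__(self):
        for s, p in self.survival.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"survival probability for {s} must be in [0,1], got {p}")
        for v in (self.air_cfu_mean, self.water_count_mean, self.norm_od_mean,
                  self.growth_capacity, self.growth_rate):
            if v < 0:
                raise ValueError("rate/mean parameters must be non-negative")
        if not 0 < self.wca_mean_deg < 180:
            raise ValueError("mean contact angle must lie in (0, 180) degrees")


@dataclass
class AssaySimSpec:
    """Design of a full synthetic assay campaign."""

    genotypes: list
    trait_effects: dict  # genotype -> GenotypeEffects
    n_dispersal: int = 6
    n_stress: int = 8
    n_wca: int = 12
    n_qpcr: int = 3
    n_biolog: int = 3
    od_sd: float = 0.05
    wca_sd_deg: float = 5.0
    ct_sd: float = 0.15
    biolog_od_sd: float = 0.02
    control_titer: float = 1e8  # spores/mL entering the stress assays
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.trait_effects) - set(self.genotypes)
        if unknown:
            raise ValueError(f"trait_effects for unknown genotype(s): {sorted(unknown)}")
        missing = set(self.genotypes) - set(self.trait_effects)
        if missing:
            raise ValueError(f"genotype(s) missing trait_effects: {sorted(missing)}")
        for n in (self.n_dispersal, self.n_stress, self.n_wca, self.n_qpcr, self.n_biolog):
            if n < 1:
                raise ValueError("replicate counts must be >= 1")


def _dilution_counts(rng, titer, dilutions, volume_ml=0.1):
    """Poisson colony counts for a plated dilution series."""
    return [
        (d, volume_ml, int(rng.poisson(titer * volume_ml / d))) for d in dilutions
    ]


def simulate_assay_tables(spec: AssaySimSpec) -> dict:
    """Generate every assay table as a tidy DataFrame.

    Returns a dict with keys ``dispersal``, ``stress``, ``wca``, ``qpcr``
    and ``biolog``.
    """
    out = {}

    rng = stream(spec.seed, "dispersal")
    rows = []
    for g in spec.genotypes:
        eff = spec.trait_effects[g]
        for medium, mean in (("air", eff.air_cfu_mean), ("water", eff.water_count_mean)):
            for rep in range(1, spec.n_dispersal + 1):
                od = max(1e-3, rng.normal(eff.norm_od_mean, spec.od_sd))
                rows.append(
                    {
                        "genotype": g,
                        "medium": medium,
                        "replicate": rep,
                        "raw_count": int(rng.poisson(mean * od)),
                        "norm_od": od,
                    }
                )
    out["dispersal"] = pd.DataFrame(rows)

    rng = stream(spec.seed, "stress")
    rows = []
    dilutions = (1e5, 1e6)
    for g in spec.genotypes:
        eff = spec.trait_effects[g]
        for stressor in STRESSORS:
            p = eff.survival[stressor]
            for rep in range(1, spec.n_stress + 1):
                for arm, titer in (("control", spec.control_titer),
                                   ("treated", spec.control_titer * p)):
                    for d, v, n in _dilution_counts(rng, titer, dilutions):
                        rows.append(
                            {
                                "genotype": g,
                                "stressor": stressor,
                                "replicate": rep,
                                "arm": arm,
                                "dilution_factor": d,
                                "plated_volume_ml": v,
                                "colony_count": n,
                            }
                        )
    out["stress"] = pd.DataFrame(rows)

    rng = stream(spec.seed, "wca")
    rows = [
        {
            "genotype": g,
            "replicate": rep,
            "theta_deg": float(
                np.clip(rng.normal(spec.trait_effects[g].wca_mean_deg, spec.wca_sd_deg),
                        1.0, 179.0)
            ),
        }
        for g in spec.genotypes
        for rep in range(1, spec.n_wca + 1)
    ]
    out["wca"] = pd.DataFrame(rows)

    rng = stream(spec.seed, "qpcr")
    rows = []
    for g in spec.genotypes:
        eff = spec.trait_effects[g]
        for gene, stage_folds in eff.expression_log2fold.items():
            for stage in STAGES:
                log2fold = stage_folds.get(stage, 0.0)
                for rep in range(1, spec.n_qpcr + 1):
                    ct_ref = rng.normal(20.0, spec.ct_sd)
                    # a lower target Ct means more transcript: subtract the fold
                    ct_target = ct_ref + 5.0 - log2fold + rng.normal(0, spec.ct_sd)
                    rows.append(
                        {
                            "genotype": g,
                            "gene": gene,
                            "stage": stage,
                            "replicate": rep,
                            "ct_target": ct_target,
                            "ct_ref": ct_ref,
                        }
                    )
    out["qpcr"] = pd.DataFrame(rows)

    rng = stream(spec.seed, "biolog")
    rows = []
    for g in spec.genotypes:
        eff = spec.trait_effects[g]
        for rep in range(1, spec.n_biolog + 1):
            for t in BIOLOG_TIMEPOINTS:
                od = eff.growth_capacity / (
                    1.0 + np.exp(-eff.growth_rate * (t - eff.growth_midpoint_h))
                )
                rows.append(
                    {
                        "genotype": g,
                        "replicate": rep,
                        "time_h": t,
                        "od750": float(max(0.0, od + rng.normal(0, spec.biolog_od_sd))),
                    }
                )
    out["biolog"] = pd.DataFrame(rows)
    return out
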