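"""Dispersal, stress-survival and wettability analytics for mutant panels.

Simulates assay tables for a wild type and two deletion mutants with
known trait effects, then runs the standard analyses: OD-normalized
dispersal indices with ANOVA + Tukey letters, dilution-series titers and
survival percentages, and the contact-angle wettability call.
"""

import numpy as np

from sporefit.fitness import (
    classify_wettability,
    compare_genotypes,
    survival_percent,
    titer_from_dilution_series,
)
from sporefit.synth import AssaySimSpec, GenotypeEffects, simulate_assay_tables

effects = {
    "WT": GenotypeEffects(air_cfu_mean=50, water_count_mean=80,
                          survival={"desiccation": 0.5, "freeze": 0.3, "UV": 0.25},
                          wca_mean_deg=125),
    "dhfb4": GenotypeEffects(air_cfu_mean=110, water_count_mean=75,
                             survival={"desiccation": 0.3, "freeze": 0.6, "UV": 0.25},
                             wca_mean_deg=70),
    "dhfb10": GenotypeEffects(air_cfu_mean=95, water_count_mean=85,
                              survival={"desiccation": 0.45, "freeze": 0.3, "UV": 0.25},
                              wca_mean_deg=115),
}
tables = simulate_assay_tables(AssaySimSpec(genotypes=list(effects),
                                            trait_effects=effects, seed=11))

air = tables["dispersal"].query("medium == 'air'").assign(
    value=lambda d: d.raw_count / d.norm_od
)
result = compare_genotypes(air[["genotype", "value"]])
print("air dispersal (CFU per unit OD), ANOVA across genotypes:")
print(f"  F = {result.f_statistic:.1f}, p = {result.p_value:.2e}")
for g, sub in air.groupby("genotype"):
    print(f"  {g:<7} mean index {sub.value.mean():6.1f}   letters: {result.letters[g]}")

print("\nfreeze survival from dilution plating:")
for g, sub in tables["stress"].query("stressor == 'freeze'").groupby("genotype"):
    titers = {}
    for arm, arm_rows in sub.query("replicate == 1").groupby("arm"):
        series = list(zip(arm_rows.dilution_factor, arm_rows.plated_volume_ml,
                          arm_rows.colony_count))
        titers[arm], accepted = titer_from_dilution_series(series)
    pct = survival_percent(titers["treated"], titers["control"])
    print(f"  {g:<7} control {titers['control']:.2e} CFU/mL -> survival {pct:5.1f}%")

print("\nspore wettability from mean contact angle:")
for g, sub in tables["wca"].groupby("genotype"):
    theta = sub.theta_deg.mean()
    print(f"  {g:<7} theta = {theta:6.1f} deg -> {classify_wettability(theta)}")
print("\nGenotypes sharing a Tukey letter are statistically indistinguishable;")
print("an angle below 90 degrees means the spore surface wets (hydrophilic).")
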