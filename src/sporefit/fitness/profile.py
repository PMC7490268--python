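"""The integrated eight-parameter fitness profile per genotype."""

from __future__ import annotations

from dataclasses import dataclass, field

#: the default trait set integrating development, dispersal and stress
#: resistance of spores
FITNESS_TRAITS = (
    "growth",             # OD750 area under the curve
    "aerial_hyphae_pct",  # mean % well coverage by aerial hyphae
    "conidiation_pct",    # mean % well coverage by conidia
    "air_dispersal",      # OD-normalized CFU per trap plate
    "water_dispersal",    # OD-normalized spores per droplet volume
    "desiccation_survival_pct",
    "freeze_survival_pct",
    "uv_survival_pct",
)


@dataclass
class FitnessProfile:
    """Per-genotype vector of fitness parameters; partial profiles allowed."""

    genotype: str
    traits: dict = field(default_factory=dict)
    trait_names: tuple = FITNESS_TRAITS

    @property
    def missing(self) -> tuple:
        return tuple(t for t in self.trait_names if t not in self.traits)

    @property
    def complete(self) -> bool:
        return not self.missing

    def as_dict(self) -> dict:
        out = {"genotype": self.genotype}
        for t in self.trait_names:
            out[t] = self.traits.get(t)
        return out


def assemble_fitness_profile(genotype: str, trait_summaries: dict,
                             trait_names: tuple = FITNESS_TRAITS) -> FitnessProfile:
    """Bundle per-trait summaries into one profile.

    ``trait_summaries`` maps trait name -> scalar; traits absent from the
    mapping are recorded as missing rather than raising.  Survival
    percentages must be non-negative.
    """
    unknown = set(trait_summaries) - set(trait_names)
    if unknown:
        raise ValueError(f"unknown trait(s): {sorted(unknown)}")
    for name, value in trait_summaries.items():
        if name.endswith("_pct") or name.endswith("survival_pct"):
            if value is not None and value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
    return FitnessProfile(
        genotype=genotype,
        traits={k: float(v) for k, v in trait_summaries.items() if v is not None},
        trait_names=trait_names,
    )
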