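"""96-well plate layouts mapping well ids to substrates.

The packaged default reconstructs a fungal phenotype-array layout with 95
distinct carbon sources plus one water well; any CSV with ``well_id`` and
``substrate`` columns can replace it.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

WATER_LABEL = "Water"


class PlateLayout(dict):
    """well_id -> substrate for a full 96-well plate (exactly one water well)."""

    def __init__(self, mapping: dict):
        super().__init__(mapping)
        if len(self) != 96:
            raise ValueError(f"plate layout must have exactly 96 wells, got {len(self)}")
        waters = [w for w, s in self.items() if s == WATER_LABEL]
        if len(waters) != 1:
            raise ValueError(f"plate layout must have exactly one water well, got {len(waters)}")

    @property
    def water_well(self) -> str:
        return next(w for w, s in self.items() if s == WATER_LABEL)

    @classmethod
    def from_csv(cls, path) -> "PlateLayout":
        df = pd.read_csv(path)
        if not {"well_id", "substrate"} <= set(df.columns):
            raise ValueError("layout CSV needs 'well_id' and 'substrate' columns")
        return cls(dict(zip(df["well_id"], df["substrate"])))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"well_id": list(self), "substrate": list(self.values())}
        ).to_csv(path, index=False)


def default_ff_layout() -> PlateLayout:
    """The packaged 95-carbon-source + water layout."""
    with resources.as_file(
        resources.files("sporefit").joinpath("data/ff_plate_layout.csv")
    ) as p:
        return PlateLayout.from_csv(Path(p))
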