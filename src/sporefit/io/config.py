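"""Pipeline configuration: one structured YAML file with full defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

KNOWN_STAGES = ("repaint", "fitness", "selection")


@dataclass
class PipelineConfig:
    """Everything the all-synthetic demo pipeline needs.

    ``stages`` selects which parts run; each stage generates its own
    synthetic inputs from the shared ``seed`` and writes CSV/JSON outputs
    under ``output_dir``.
    """

    output_dir: str = "sporefit_run"
    stages: tuple = KNOWN_STAGES
    seed: int = 0
    alpha: float = 0.05
    # repaint stage
    classifier: str = "rule"  # rule | learned
    n_plates: int = 2
    plate_time_h: float = 120.0
    layout_csv: str | None = None  # defaults to the packaged FF layout
    # fitness stage
    genotypes: tuple = ("WT", "dhfb4", "dhfb10")
    # selection stage
    alignment_fasta: str | None = None  # synthetic when absent
    tree_newick: str | None = None
    n_codon_sites: int = 300
    selection_models: tuple = ("M0", "two_ratio")
    freq_mode: str = "F3x4"
    fix_branch_lengths: bool = False

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        unknown = set(self.stages) - set(KNOWN_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}; known: {KNOWN_STAGES}")
        if self.classifier not in ("rule", "learned"):
            raise ValueError("classifier must be 'rule' or 'learned'")
        for attr in ("layout_csv", "alignment_fasta", "tree_newick"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr} points to a missing path: {p}")
        if (self.alignment_fasta is None) != (self.tree_newick is None):
            raise ValueError("alignment_fasta and tree_newick must be given together")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("stages", "genotypes", "selection_models"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for key in ("stages", "genotypes", "selection_models"):
            data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
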