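"""Relative qPCR expression (2^-ddCt) and expression-profile clustering."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage


@dataclass
class ExpressionRecord:
    """Paired target/reference Ct values for one gene at one stage."""

    gene: str
    stage: str
    ct_target: float
    ct_ref: float
    reference_gene: str = "tef1"

    def __post_init__(self):
        for ct in (self.ct_target, self.ct_ref):
            if not np.isfinite(ct) or ct <= 0:
                raise ValueError("Ct values must be finite and positive")


def relative_expression(record: ExpressionRecord, calibrator: ExpressionRecord) -> float:
    """Fold change by the 2^-ddCt method against a calibrator condition.

    dCt = Ct_target - Ct_reference within each condition; ddCt subtracts
    the calibrator's dCt; the fold change is 2^-ddCt (1.0 means no change
    relative to the calibrator).
    """
    if record.gene != calibrator.gene:
        raise ValueError(
            f"gene mismatch: {record.gene!r} vs calibrator {calibrator.gene!r}"
        )
    if record.reference_gene != calibrator.reference_gene:
        raise ValueError("record and calibrator use different reference genes")
    d_ct = record.ct_target - record.ct_ref
    d_ct_cal = calibrator.ct_target - calibrator.ct_ref
    return float(2.0 ** (-(d_ct - d_ct_cal)))


def expression_matrix(records, calibrator_stage: str | None = None):
    """Gene x stage fold-change matrix with complete-linkage gene clustering.

    Parameters
    ----------
    records : iterable of ExpressionRecord
        At least two genes and two stages.  Replicates of the same
        (gene, stage) cell are averaged on the Ct scale first.
    calibrator_stage : str, optional
        Stage used as each gene's calibrator; defaults to the first stage
        in sorted order.

    Returns
    -------
    (matrix, linkage_matrix) : (pandas.DataFrame, numpy.ndarray)
        ``matrix`` has one row per gene; genes with missing cells are
        excluded from clustering with a warning.  Clustering is
        agglomerative with complete linkage on Euclidean distances
        between fold-change rows.
    """
    df = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "stage": r.stage,
                "d_ct": r.ct_target - r.ct_ref,
            }
            for r in records
        ]
    )
    if df.empty or df["gene"].nunique() < 2 or df["stage"].nunique() < 2:
        raise ValueError("need at least 2 genes and 2 stages")
    cells = df.groupby(["gene", "stage"], sort=True)["d_ct"].mean().unstack("stage")
    if calibrator_stage is None:
        calibrator_stage = cells.columns[0]
    if calibrator_stage not in cells.columns:
        raise ValueError(f"calibrator stage {calibrator_stage!r} not present")
    folds = 2.0 ** (-(cells.sub(cells[calibrator_stage], axis=0)))

    complete_rows = folds.dropna()
    dropped = sorted(set(folds.index) - set(complete_rows.index))
    if dropped:
        warnings.warn(f"gene(s) excluded from clustering for missing stages: {dropped}")
    if len(complete_rows) < 2:
        raise ValueError("fewer than 2 genes with complete profiles; cannot cluster")
    Z = linkage(complete_rows.to_numpy(), method="complete", metric="euclidean")
    return folds, Z
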