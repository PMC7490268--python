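"""Group statistics: ANOVA + Tukey letters, dispersal-mode clustering,
wild-type/mutant effect scatter, PCA, growth summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class GenotypeComparison:
    """One-way ANOVA with Tukey HSD letters across genotypes."""

    f_statistic: float
    p_value: float
    letters: dict  # genotype -> compact letter display, e.g. "a", "ab"
    tukey_table: pd.DataFrame
    alpha: float = 0.05


def compare_genotypes(table: pd.DataFrame, value_col: str = "value",
                      group_col: str = "genotype", alpha: float = 0.05) -> GenotypeComparison:
    """One-way ANOVA and Tukey HSD multiple comparisons at ``alpha``.

    The compact letter display assigns letters so that two genotypes share
    a letter if and only if Tukey finds them not significantly different
    (greedy insert-absorb over groups in sorted-mean order, deterministic).
    """
    groups = {g: sub[value_col].to_numpy(float) for g, sub in table.groupby(group_col)}
    if len(groups) < 2:
        raise ValueError("need at least two genotypes")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("need at least two replicates per genotype")

    arrays = list(groups.values())
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) > 1:
        # zero within-group variance with differing means: F degenerates
        f_stat, p_val = np.inf, np.finfo(float).tiny
    else:
        f_stat, p_val = stats.f_oneway(*arrays)

    tukey = pairwise_tukeyhsd(
        endog=table[value_col].to_numpy(float),
        groups=table[group_col].to_numpy(),
        alpha=alpha,
    )
    tk = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    # significance matrix from the pairwise results
    names = sorted(groups)
    differ = {frozenset((a, b)): rej for a, b, rej in zip(tk["group1"], tk["group2"], tk["reject"])}

    order = sorted(names, key=lambda g: (float(np.mean(groups[g])), g))
    letter_sets: list = []  # each is a set of genotypes sharing a letter
    for g in order:
        placed = False
        for s in letter_sets:
            if all(not differ.get(frozenset((g, h)), False) for h in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb: drop letter groups fully contained in another
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(i != j and s < t for j, t in enumerate(letter_sets))
    ]
    letters = {g: "" for g in names}
    for k, s in enumerate(letter_sets):
        for g in sorted(s):
            letters[g] += chr(ord("a") + k)

    return GenotypeComparison(
        f_statistic=float(f_stat),
        p_value=float(p_val),
        letters=letters,
        tukey_table=tk,
        alpha=alpha,
    )


def cluster_dispersal(matrix: pd.DataFrame, height: float | None = None):
    """Complete-linkage clustering of genotypes by (air, water) dispersal.

    Parameters
    ----------
    matrix : DataFrame
        Genotypes as rows, dispersal indices as columns; must be complete.
    height : float, optional
        Cut height for flat clusters; default merges nothing (every
        genotype reported, cluster labels from the full-height cut).

    Returns
    -------
    (linkage_matrix, flat_clusters) : (ndarray, dict genotype -> int)
    """
    if matrix.isna().any().any():
        raise ValueError("dispersal matrix must be complete")
    if len(matrix) == 1:
        return np.empty((0, 4)), {matrix.index[0]: 1}
    Z = linkage(matrix.to_numpy(float), method="complete", metric="euclidean")
    if height is None:
        height = float(Z[:, 2].max()) + 1.0
    flat = fcluster(Z, t=height, criterion="distance")
    return Z, dict(zip(matrix.index, (int(k) for k in flat)))


@dataclass
class EffectScatter:
    """Mutant-vs-wild-type comparison across carbon sources."""

    pairs: pd.DataFrame  # columns: carbon_source, wt, mutant, ratio, no_effect
    slope: float  # least-squares trend through the origin
    band: float


def genotype_effect_scatter(wt: dict, mutant: dict, no_effect_band: float = 0.10) -> EffectScatter:
    """Per-carbon-source mutant/wild-type comparison with an origin trend.

    Sources present in only one genotype are excluded with a warning.  The
    trend slope is the least-squares fit through the origin (sum(xy)/sum(x^2));
    a source is flagged ``no_effect`` when its mutant value lies within
    ``no_effect_band`` (fractional) of the wild-type value.
    """
    shared = sorted(set(wt) & set(mutant))
    skipped = sorted(set(wt) ^ set(mutant))
    if skipped:
        warnings.warn(f"unpaired carbon source(s) excluded: {skipped}")
    if not shared:
        raise ValueError("no carbon sources shared between wild type and mutant")
    x = np.array([wt[s] for s in shared], float)
    y = np.array([mutant[s] for s in shared], float)
    sxx = float(np.sum(x * x))
    slope = float(np.sum(x * y) / sxx) if sxx > 0 else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(x != 0, y / x, np.nan)
    no_effect = np.abs(y - x) <= no_effect_band * np.abs(x)
    pairs = pd.DataFrame(
        {
            "carbon_source": shared,
            "wt": x,
            "mutant": y,
            "ratio": ratio,
            "no_effect": no_effect,
        }
    )
    return EffectScatter(pairs=pairs, slope=slope, band=no_effect_band)


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    pct_variance: np.ndarray


def pca_projection(matrix: pd.DataFrame, scale: bool = True) -> PCAResult:
    """Principal components of a samples x traits matrix.

    Columns are centered and (by default) scaled to unit variance;
    constant columns are dropped with a warning under scaling.  Components
    are ordered by explained variance.
    """
    X = matrix.astype(float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    sd = X.std(axis=0, ddof=1)
    if scale:
        constant = sd[sd == 0].index.tolist()
        if constant:
            warnings.warn(f"constant column(s) dropped under unit-variance scaling: {constant}")
            X = X.drop(columns=constant)
            sd = sd.drop(constant)
        X = (X - X.mean(axis=0)) / sd
    else:
        X = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X.to_numpy(), full_matrices=False)
    # deterministic sign: largest-magnitude loading positive per component
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    var = s**2 / (X.shape[0] - 1)
    pct = 100.0 * var / var.sum()
    comp = [f"PC{k + 1}" for k in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(U * s, index=X.index, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=X.columns, columns=comp),
        pct_variance=pct,
    )


def growth_auc(time_h, od750) -> float:
    """Scalar growth summary: area under the OD750 curve (trapezoid rule)."""
    t = np.asarray(time_h, float)
    od = np.asarray(od750, float)
    if t.size != od.size or t.size < 2:
        raise ValueError("need matching time/OD vectors of length >= 2")
    order = np.argsort(t)
    return float(np.trapezoid(od[order], t[order]))
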