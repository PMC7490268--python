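"""Self-validation batteries run by the acceptance machinery.

Each function regenerates synthetic inputs with known truth, runs the
corresponding analysis path, and returns the quality metric it measures.
These are the package's desk-scale checks: likelihood correctness against
enumeration, parameter recovery, test calibration, well detection and
coverage accuracy, and classifier quality.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .fitness import compare_genotypes
from .repaint import (
    RuleBasedClassifier,
    TrainingConfig,
    crop_and_normalize,
    detect_wells,
    quantify_plate,
    segment,
    train_classifier,
)
from .selection import (
    PruningEngine,
    SpectralPropagator,
    build_rate_matrix,
    equal_frequencies,
    fit,
    lrt,
)
from .selection.likelihood import enumeration_loglik
from .synth import (
    AssaySimSpec,
    CodonSimSpec,
    GenotypeEffects,
    PlateSpec,
    generate_plate_image,
    simulate_assay_tables,
    simulate_codon_alignment,
)
from .synth.plates import truth_mask_for_crop
from .trees import parse_newick

_SMALL_TREES = (
    "(A:{a},B:{b});",
    "((A:{a},B:{b}):{c},C:{d});",
    "((A:{a},B:{b}):{c},(C:{d},D:{e}):{f});",
)

_TREE_6 = "((A:0.15,B:0.15):0.1,(C:0.15,D:0.15) #1:0.1,(E:0.2,F:0.2):0.05);"
_TREE_8 = (
    "(((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1):0.1,"
    "((E:0.1,F:0.1):0.1,(G:0.1,H:0.1) #1:0.1):0.1);"
)


def pruning_vs_enumeration(n_draws: int = 50, seed: int = 0) -> float:
    """Max |lnL difference| between pruning and exhaustive enumeration.

    Random trees of 2-4 taxa, 3 codon sites, random (kappa, omega) per
    draw; the enumeration sums over all internal-node state combinations.
    """
    rng = np.random.default_rng(seed)
    pi = equal_frequencies()
    worst = 0.0
    for k in range(n_draws):
        shape = _SMALL_TREES[k % len(_SMALL_TREES)]
        lengths = {c: rng.uniform(0.02, 0.8) for c in "abcdef"}
        tree = parse_newick(shape.format(**{c: f"{v:.4f}" for c, v in lengths.items()}))
        kappa = rng.uniform(0.5, 5.0)
        omega = rng.uniform(0.05, 3.0)
        sim = simulate_codon_alignment(
            CodonSimSpec(tree=tree, kappa=kappa, regime="M0",
                         regime_params={"omega": omega}, n_sites=3,
                         seed=int(rng.integers(2**31)))
        )
        prop = SpectralPropagator(build_rate_matrix(sim.alignment.code, kappa, omega, pi), pi)
        P_of = lambda node: prop.prob(node.length)  # noqa: E731
        engine = PruningEngine(sim.alignment, tree)
        lnl = engine.total_loglik(engine.pattern_logliks(P_of, pi))
        oracle = enumeration_loglik(sim.alignment, tree, P_of, pi)
        worst = max(worst, abs(lnl - oracle))
    return worst


def omega_recovery(
    omegas=(0.2, 1.0, 2.0), n_replicates: int = 8, n_sites: int = 1000,
    seed: int = 0,
) -> dict:
    """Mean M0 omega estimate and bias per true omega (8-taxon tree)."""
    tree = parse_newick(_TREE_8)
    out = {}
    for i, omega in enumerate(omegas):
        estimates = []
        for r in range(n_replicates):
            sim = simulate_codon_alignment(
                CodonSimSpec(tree=tree, kappa=2.0, regime="M0",
                             regime_params={"omega": omega}, n_sites=n_sites,
                             seed=seed + 1000 * i + r)
            )
            f = fit(sim.alignment, tree, "M0", freq_mode="equal",
                    fix_branch_lengths=True, n_starts=1)
            estimates.append(f.params["omega"])
        mean = float(np.mean(estimates))
        out[omega] = {"mean_estimate": mean, "bias": mean - omega}
    return out


def lrt_null_calibration(
    n_replicates: int = 200, n_sites: int = 300, alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """M0-vs-two-ratio rejection rate under M0-simulated (null) data.

    Returns the observed rate plus the exact binomial 95% acceptance
    interval around ``alpha`` for this replicate count.
    """
    tree = parse_newick(_TREE_6)
    rejections = 0
    for r in range(n_replicates):
        sim = simulate_codon_alignment(
            CodonSimSpec(tree=tree, kappa=2.0, regime="M0",
                         regime_params={"omega": 0.4}, n_sites=n_sites,
                         seed=seed + r)
        )
        kw = dict(freq_mode="equal", fix_branch_lengths=True, n_starts=1)
        null = fit(sim.alignment, tree, "M0", **kw)
        alt = fit(sim.alignment, tree, "two_ratio", **kw)
        _, _, p = lrt(null, alt)
        rejections += p < alpha
    lo = int(stats.binom.ppf(0.025, n_replicates, alpha))
    hi = int(stats.binom.ppf(0.975, n_replicates, alpha))
    return {
        "rate": rejections / n_replicates,
        "rejections": rejections,
        "n": n_replicates,
        "accept_lo": lo / n_replicates,
        "accept_hi": hi / n_replicates,
    }


def _coverage_request(rng, n_wells):
    h = rng.uniform(0, 60, n_wells)
    c = rng.uniform(0, 30, n_wells)
    s = h + c
    scale = np.where(s > 100, 95.0 / s, 1.0)
    return np.column_stack([h * scale, c * scale])


def well_detection_benchmark(n_seeds: int = 20, seed: int = 0) -> dict:
    """Detection recall and worst center error over generator plates."""
    found, total = 0, 0
    worst = 0.0
    for k in range(n_seeds):
        spec = PlateSpec(seed=seed + k, rotation_deg=(k % 3) - 1.0)
        rng = np.random.default_rng(seed + k)
        image, truth = generate_plate_image(spec, _coverage_request(rng, spec.n_wells))
        regions = detect_wells(image)
        total += spec.n_wells
        for region, (_, _, x, y) in zip(regions, truth.well_centers):
            err = float(np.hypot(region.center_x_px - x, region.center_y_px - y))
            if not region.imputed and err <= 3.0:
                found += 1
            worst = max(worst, err)
    return {"recall": found / total, "found": found, "total": total,
            "max_center_error_px": worst}


def coverage_error_benchmark(n_plates: int = 2, seed: int = 100) -> dict:
    """Mean absolute coverage error (percentage points) of the rule-based
    classifier against generator truth."""
    rule = RuleBasedClassifier()
    errors = []
    for k in range(n_plates):
        spec = PlateSpec(seed=seed + k)
        rng = np.random.default_rng(seed + k)
        image, truth = generate_plate_image(spec, _coverage_request(rng, spec.n_wells))
        for w, rec in enumerate(quantify_plate(image, rule)):
            errors.append(abs(rec.pct_hyphae - truth.coverage_truth[w, 0]))
            errors.append(abs(rec.pct_conidia - truth.coverage_truth[w, 1]))
    return {"mae_points": float(np.mean(errors)), "n_wells": len(errors) // 2}


def _annotated_crops(seed, n, **spec_kwargs):
    spec = PlateSpec(seed=seed, **spec_kwargs)
    rng = np.random.default_rng(seed)
    image, truth = generate_plate_image(spec, _coverage_request(rng, spec.n_wells))
    regions = detect_wells(image)[:n]
    crops = [crop_and_normalize(image, r) for r in regions]
    masks = [truth_mask_for_crop(truth, c) for c in crops]
    return crops, masks


def learned_classifier_benchmark(seed: int = 0, n_train: int = 10,
                                 n_test: int = 8) -> dict:
    """Held-out pixel accuracy of the trained classifier on fresh plates."""
    train_crops, train_masks = _annotated_crops(seed + 500, n_train)
    clf = train_classifier(train_crops, train_masks, TrainingConfig(seed=seed))
    test_crops, test_masks = _annotated_crops(seed + 900, n_test)
    accs = [
        float((segment(c, clf).labels == m.labels).mean())
        for c, m in zip(test_crops, test_masks)
    ]
    return {"pixel_accuracy": float(np.mean(accs)), "n_test_crops": n_test}


def anova_type1_calibration(n_datasets: int = 500, alpha: float = 0.05,
                            seed: int = 0) -> dict:
    """Type-I error of the genotype comparison on no-effect synthetic tables."""
    rejections = 0
    for k in range(n_datasets):
        effects = {g: GenotypeEffects() for g in ("g1", "g2", "g3")}
        spec = AssaySimSpec(genotypes=list(effects), trait_effects=effects,
                            n_dispersal=6, n_stress=1, n_wca=1, n_qpcr=1,
                            n_biolog=1, seed=seed + k)
        disp = simulate_assay_tables(spec)["dispersal"]
        air = disp.query("medium == 'air'").assign(
            value=lambda d: d.raw_count / d.norm_od
        )
        result = compare_genotypes(air[["genotype", "value"]], alpha=alpha)
        rejections += result.p_value < alpha
    lo = int(stats.binom.ppf(0.025, n_datasets, alpha))
    hi = int(stats.binom.ppf(0.975, n_datasets, alpha))
    return {
        "rate": rejections / n_datasets,
        "rejections": rejections,
        "n": n_datasets,
        "accept_lo": lo / n_datasets,
        "accept_hi": hi / n_datasets,
    }


def dispersal_power(n_simulations: int = 200, alpha: float = 0.05,
                    seed: int = 0) -> dict:
    """Power to detect a programmed 2-fold air-dispersal effect
    (Poisson means 50 vs 100, n = 6 replicates)."""
    detected = 0
    for k in range(n_simulations):
        rng = np.random.default_rng(seed + k)
        rows = [
            {"genotype": g, "value": rng.poisson(mean)}
            for g, mean in (("wt", 50.0), ("mutant", 100.0))
            for _ in range(6)
        ]
        result = compare_genotypes(pd.DataFrame(rows), alpha=alpha)
        detected += result.p_value < alpha
    return {"power": detected / n_simulations, "n": n_simulations}
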