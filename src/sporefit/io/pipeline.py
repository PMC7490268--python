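"""End-to-end demo pipeline on fully synthetic inputs.

Each requested stage generates its inputs from the shared seed, runs the
corresponding analysis modules, and writes CSV/JSON outputs plus a run
log capturing seeds and parameter digests, so a rerun with the same
configuration reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .. import __version__
from ..fitness import (
    DispersalRecord,
    assemble_fitness_profile,
    classify_wettability,
    compare_genotypes,
    dispersal_index,
    growth_auc,
    survival_percent,
    titer_from_dilution_series,
)
from ..repaint import (
    REPAINT_TIMEPOINTS,
    RuleBasedClassifier,
    TrainingConfig,
    assemble_timeseries,
    quantify_plate,
    segment,
    train_classifier,
)
from ..selection import classify_selection, fit, lrt
from ..synth.plates import truth_mask_for_crop
from ..synth import (
    AssaySimSpec,
    CodonSimSpec,
    GenotypeEffects,
    PlateSpec,
    generate_plate_image,
    simulate_assay_tables,
    simulate_codon_alignment,
    stream,
)
from ..trees import parse_newick
from .config import PipelineConfig
from .fasta import read_codon_fasta
from .layout import default_ff_layout, PlateLayout
from .newick import read_labeled_newick

log = logging.getLogger(__name__)

_DEMO_TREE = "((A:0.3,B:0.3):0.2,(C:0.3,D:0.3) #1:0.2,(E:0.4,F:0.4):0.1);"


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _classifier_for(config: PipelineConfig):
    if config.classifier == "rule":
        return RuleBasedClassifier()
    # a quick synthetic training set at fixture scale
    from ..repaint import ClassMask, crop_and_normalize, detect_wells
    from ..repaint.classify import CLASS_BACKGROUND, CLASS_CONIDIA, CLASS_HYPHAE

    spec = _small_plate_spec(seed=config.seed + 90001)
    rng = stream(config.seed, "pipeline-train")
    req = np.column_stack(
        [rng.uniform(10, 50, spec.n_wells), rng.uniform(5, 30, spec.n_wells)]
    )
    image, truth = generate_plate_image(spec, req)
    crops, masks = [], []
    for region in detect_wells(image, (spec.n_rows, spec.n_cols)):
        crop = crop_and_normalize(image, region)
        crops.append(crop)
        masks.append(truth_mask_for_crop(truth, crop))
    return train_classifier(crops, masks, TrainingConfig(seed=config.seed))


def _small_plate_spec(seed: int) -> PlateSpec:
    return PlateSpec(
        n_rows=2, n_cols=3, image_width_px=180, image_height_px=140,
        well_radius_px=18, pitch_px=46, seed=seed,
    )


def _stage_repaint(config: PipelineConfig, outdir: Path) -> dict:
    layout = (
        PlateLayout.from_csv(config.layout_csv) if config.layout_csv else default_ff_layout()
    )
    classifier = _classifier_for(config)
    rng = stream(config.seed, "pipeline-plates")
    records = []
    times = list(REPAINT_TIMEPOINTS)[: config.n_plates]
    for k in range(config.n_plates):
        spec = PlateSpec(seed=config.seed + k)
        growth = min(1.0, (k + 1) / len(REPAINT_TIMEPOINTS))
        req = np.column_stack(
            [
                rng.uniform(5, 40, spec.n_wells) * growth,
                rng.uniform(0, 25, spec.n_wells) * growth,
            ]
        )
        image, _ = generate_plate_image(spec, req)
        records.extend(
            quantify_plate(image, classifier, time_h=times[k] if k < len(times) else None,
                           layout=layout)
        )
    table = assemble_timeseries(records)
    out = outdir / "coverage.csv"
    table.to_csv(out, index=False, float_format="%.6g")
    return {"coverage_csv": out.name, "n_records": int(len(table))}


def _default_effects(genotypes, seed: int) -> dict:
    rng = stream(seed, "pipeline-effects")
    effects = {}
    for i, g in enumerate(genotypes):
        effects[g] = GenotypeEffects(
            air_cfu_mean=60.0 + 25.0 * i,
            water_count_mean=80.0 - 15.0 * i,
            survival={
                "desiccation": min(0.9, 0.5 + 0.1 * i),
                "freeze": min(0.9, 0.3 + 0.15 * i),
                "UV": 0.25,
            },
            wca_mean_deg=125.0 - 20.0 * i,
            expression_log2fold={"hfb4": {"72h": 2.0 + i, "120h": 3.0}},
        )
    return effects


def _stage_fitness(config: PipelineConfig, outdir: Path) -> dict:
    genotypes = list(config.genotypes)
    spec = AssaySimSpec(
        genotypes=genotypes,
        trait_effects=_default_effects(genotypes, config.seed),
        seed=config.seed,
    )
    tables = simulate_assay_tables(spec)
    classifier = RuleBasedClassifier()
    rng = stream(config.seed, "pipeline-fitness-plates")

    profiles = []
    for gi, g in enumerate(genotypes):
        disp = tables["dispersal"].query("genotype == @g")
        idx = {
            medium: float(
                np.mean(
                    [
                        dispersal_index(
                            DispersalRecord(
                                genotype=g, medium=medium,
                                raw_count=r.raw_count, norm_od=r.norm_od,
                                replicate=r.replicate,
                            )
                        )
                        for r in sub.itertuples()
                    ]
                )
            )
            for medium, sub in disp.groupby("medium")
        }
        surv = {}
        stress = tables["stress"].query("genotype == @g")
        for stressor, sub in stress.groupby("stressor"):
            pcts = []
            for rep, srep in sub.groupby("replicate"):
                titers = {}
                for arm, sarm in srep.groupby("arm"):
                    series = list(
                        zip(sarm.dilution_factor, sarm.plated_volume_ml, sarm.colony_count)
                    )
                    titers[arm], _ = titer_from_dilution_series(series)
                if titers.get("control"):
                    pcts.append(survival_percent(titers["treated"], titers["control"]))
            surv[stressor] = float(np.mean(pcts)) if pcts else None

        bio = tables["biolog"].query("genotype == @g")
        auc = float(
            np.mean([growth_auc(s.time_h, s.od750) for _, s in bio.groupby("replicate")])
        )

        plate_spec = _small_plate_spec(seed=config.seed + 1000 + gi)
        req = np.column_stack(
            [
                np.full(plate_spec.n_wells, 20.0 + 8.0 * gi),
                np.full(plate_spec.n_wells, 10.0 + 4.0 * gi),
            ]
        )
        image, _ = generate_plate_image(plate_spec, req)
        recs = quantify_plate(image, classifier, expected_grid=(2, 3))
        cov_h = float(np.mean([r.pct_hyphae for r in recs])) if recs else None
        cov_c = float(np.mean([r.pct_conidia for r in recs])) if recs else None

        profile = assemble_fitness_profile(
            g,
            {
                "growth": auc,
                "aerial_hyphae_pct": cov_h,
                "conidiation_pct": cov_c,
                "air_dispersal": idx.get("air"),
                "water_dispersal": idx.get("water"),
                "desiccation_survival_pct": surv.get("desiccation"),
                "freeze_survival_pct": surv.get("freeze"),
                "uv_survival_pct": surv.get("UV"),
            },
        )
        profiles.append(profile.as_dict())

    disp_tab = tables["dispersal"].assign(
        value=lambda d: d.raw_count / d.norm_od
    ).query("medium == 'air'")[["genotype", "value"]]
    cmp_res = compare_genotypes(disp_tab, alpha=config.alpha)
    wca_classes = {
        g: classify_wettability(float(sub.theta_deg.mean()))
        for g, sub in tables["wca"].groupby("genotype")
    }
    report = {
        "profiles": profiles,
        "air_dispersal_anova": {
            "F": round(cmp_res.f_statistic, 6),
            "p": float(f"{cmp_res.p_value:.6g}"),
            "letters": cmp_res.letters,
        },
        "wettability": wca_classes,
    }
    out = outdir / "fitness_profiles.json"
    _json_dump(report, out)
    return {"fitness_json": out.name, "n_genotypes": len(genotypes)}


def _stage_selection(config: PipelineConfig, outdir: Path) -> dict:
    if config.alignment_fasta:
        aln = read_codon_fasta(config.alignment_fasta)
        tree = read_labeled_newick(config.tree_newick)
    else:
        tree = parse_newick(_DEMO_TREE)
        sim = simulate_codon_alignment(
            CodonSimSpec(
                tree=tree,
                regime="two_ratio",
                regime_params={"omega0": 0.2, "omega1": 1.5},
                n_sites=config.n_codon_sites,
                seed=config.seed,
            )
        )
        aln = sim.alignment

    fits = {}
    for model in config.selection_models:
        fits[model] = fit(
            aln, tree, model, freq_mode=config.freq_mode,
            fix_branch_lengths=config.fix_branch_lengths, seed=config.seed,
        )
    report = {m: f.summary() for m, f in fits.items()}
    if "M0" in fits:
        call = classify_selection(fits["M0"].params["omega"], fits["M0"].ds_zero)
        report["M0"]["selection"] = call.label
    if {"M0", "two_ratio"} <= set(fits):
        stat, df, p = lrt(fits["M0"], fits["two_ratio"])
        report["lrt_M0_vs_two_ratio"] = {"stat": round(stat, 4), "df": df, "p": float(f"{p:.6g}")}
    out = outdir / "selection_report.json"
    _json_dump(report, out)
    return {"selection_json": out.name, "models": list(config.selection_models)}


_STAGES = {
    "repaint": _stage_repaint,
    "fitness": _stage_fitness,
    "selection": _stage_selection,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested stages and return the report bundle (also logged).

    Outputs land under ``config.output_dir``: coverage CSV, fitness
    profile JSON, codon-model report JSON and ``run_log.json``.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    bundle: dict = {"version": __version__, "seed": config.seed, "config_digest": digest}
    for stage in _STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        bundle[stage] = _STAGES[stage](config, outdir)
        log.info("stage %s finished in %.1fs", stage, time.perf_counter() - t0)
    _json_dump(bundle, outdir / "run_log.json")
    return bundle
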