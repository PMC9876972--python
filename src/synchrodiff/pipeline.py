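"""Deterministic end-to-end orchestration on a simulated study.

Stages run in dependency order: simulate -> differential accessibility ->
footprinting -> scalar-on-function regression -> differential histone /
enhancer grammar -> expression clustering. Each stage writes a TSV under
the output directory and every run ends with a manifest of SHA-256 file
digests, so byte-identity under a repeated seed is directly checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

import pandas as pd

from . import accessibility, chromatin_state, expression, fda_regression, footprints
from .config import PipelineConfig, write_resolved
from .core import GenomicInterval, IntervalSet, insertion_track
from .simulate import SimulationConfig, simulate_study, stage_seed

log = logging.getLogger("synchrodiff")


def _sim_config(cfg: PipelineConfig) -> SimulationConfig:
    # region_rate 2.0 gives ~250 insertions per motif window per replicate,
    # the depth regime in which per-replicate FLR calls are reproducible
    return SimulationConfig(
        seed=stage_seed(cfg.seed, "simulate"),
        chrom_lengths={"chr1": cfg.sim_chrom_length, "chr2": cfg.sim_chrom_length},
        n_open_regions=cfg.sim_n_regions,
        n_genes=cfg.sim_n_genes,
        n_motif_sites=max(cfg.min_matches, cfg.sim_n_regions),
        n_enhancers=max(20, cfg.sim_n_regions // 3),
        region_rate=2.0,
        bias={"ACGTAC": 2.0},
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages on a freshly simulated desk-scale study."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    write_resolved(cfg, os.path.join(cfg.out_dir, "resolved_config.yaml"))
    log.info("pipeline start: seed=%d out=%s", cfg.seed, cfg.out_dir)

    # ---- stage 1: simulate -------------------------------------------------
    sim_cfg = _sim_config(cfg)
    study = simulate_study(sim_cfg)
    chrom_lengths = {c: len(s) for c, s in study.sequences.items()}
    tps = list(sim_cfg.time_points)
    study.truth.regions.to_csv(
        os.path.join(cfg.out_dir, "simulated_regions.tsv"), sep="\t", index=False
    )
    log.info("simulated %d regions, %d genes", len(study.truth.regions), len(study.truth.genes))

    # ---- stage 2: differential accessibility ------------------------------
    t1, t2 = tps[0], tps[3]  # a transition with planted shifts
    regions = IntervalSet(
        GenomicInterval(r.chrom, r.start, r.end) for _, r in study.truth.regions.iterrows()
    )
    tracks = {
        t: [insertion_track(rep, chrom_lengths, normalise=True) for rep in study.atac[t]]
        for t in (t1, t2)
    }
    acc_cfg = accessibility.ComparisonConfig(
        n_bins=cfg.n_bins,
        n_basis=cfg.n_basis,
        var_fraction=cfg.var_fraction,
        fc_threshold=cfg.fc_threshold,
        p_adj_threshold=cfg.p_adj_threshold,
        log_base=cfg.log_base,
    )
    diff = accessibility.diff_accessibility_test(tracks[t1], tracks[t2], regions, acc_cfg)
    diff.to_csv(os.path.join(cfg.out_dir, "diff_accessibility.tsv"), sep="\t", index=False)
    log.info(
        "diffacc %dh vs %dh: %d/%d significant",
        t1, t2, int((diff.status != "untested").sum()), len(diff),
    )

    # ---- stage 3: footprints ----------------------------------------------
    bias = footprints.build_bias_model(study.control, study.sequences)
    pwm = footprints.PWM(study.pwm["name"], study.pwm["matrix"], tfs=("SIM1",))
    matches = footprints.scan_pwm(study.sequences, pwm, p_threshold=1e-4)
    rep_calls = []
    for rep in study.atac[t1]:
        calls = footprints.footprint_flr(
            matches, rep, study.sequences, bias,
            flank=cfg.flank, min_matches=cfg.min_matches,
        )
        rep_calls.append(calls)
    pooled = pd.concat(study.atac[t1], ignore_index=True)
    ps = footprints.protection_score(matches, pooled, flank=cfg.flank)
    rep_calls[0] = rep_calls[0].assign(ps=ps)
    expr0 = study.fpkm[f"t{t1}"].mean()  # mean FPKM at t1 as the TF's expression
    curated = footprints.curate_footprints(
        rep_calls,
        pwm_tfs={pwm.name: pwm.tfs},
        expression={"SIM1": float(expr0)},
        config=footprints.CurationConfig(
            flr_min=cfg.flr_min,
            min_footprints_per_pwm=min(cfg.min_footprints_per_pwm, max(len(matches) // 4, 1)),
            ps_min=cfg.ps_min,
            expression_min=cfg.expression_min,
        ),
    )
    curated.to_csv(os.path.join(cfg.out_dir, "curated_footprints.tsv"), sep="\t", index=False)
    log.info("footprints: %d matches, %d curated", len(matches), len(curated))

    # ---- stage 4: scalar-on-function regression ---------------------------
    reg_cfg = fda_regression.RegressionConfig(
        fc_min=cfg.regress_fc_min,
        fc_max=cfg.regress_fc_max,
        min_footprints=cfg.regress_min_footprints,
        min_regions_hit=cfg.regress_min_regions_hit,
    )
    fits = []
    try:
        selected = fda_regression.select_regions(diff, reg_cfg)
        fp_set = IntervalSet(
            GenomicInterval(r.chrom, r.start, r.end) for _, r in curated.iterrows()
        )
        cov = fda_regression.build_functional_covariate(selected, fp_set, reg_cfg)
        if cov is not None:
            fits.append(
                fda_regression.fit_scalar_on_function(selected.y.to_numpy(), cov, tf="SIM1")
            )
    except ValueError as exc:
        log.warning("regression skipped: %s", exc)
    if fits:
        ranked = fda_regression.rank_tf_predictors(fits)
    else:
        ranked = pd.DataFrame(columns=["tf", "n", "rsq", "f_ratio", "p"])
    ranked.to_csv(os.path.join(cfg.out_dir, "tf_regression.tsv"), sep="\t", index=False)

    # ---- stage 5: chromatin state -----------------------------------------
    te1, te2 = tps[0], tps[3]
    dh = chromatin_state.diff_histone_gtest(
        study.chip_reads[("H3K27ac", te1)],
        study.chip_reads[("H3K27ac", te2)],
        study.chip_domains[("H3K27ac", te1)],
        study.chip_domains[("H3K27ac", te2)],
        chrom_lengths,
        window=cfg.gtest_window,
        step=cfg.gtest_step,
        fc_min=cfg.gtest_fc_min,
        alpha=cfg.gtest_alpha,
        gene_table=study.truth.genes,
        mark="H3K27ac",
    )
    dh.to_csv(os.path.join(cfg.out_dir, "diff_histone.tsv"), sep="\t", index=False)

    records_by_time = {}
    for t in tps:
        rec = chromatin_state.classify_enhancers(
            study.chip_domains[("H3K27ac", t)],
            study.chip_domains[("H3K4me1", t)],
            study.chip_domains[("H3K4me3", t)],
            se_threshold=cfg.se_threshold,
            time_point=t,
        )
        records_by_time[t] = rec
    all_rec = pd.concat(records_by_time.values(), ignore_index=True)
    all_rec.to_csv(os.path.join(cfg.out_dir, "enhancers.tsv"), sep="\t", index=False)
    dyn = chromatin_state.enhancer_dynamics(records_by_time)
    dyn["jaccard"].to_csv(os.path.join(cfg.out_dir, "enhancer_jaccard.tsv"), sep="\t")
    log.info("enhancers: %d records, %d classes", len(all_rec), all_rec["class"].nunique())

    # ---- stage 6: expression clustering -----------------------------------
    de_genes = study.truth.de_genes.gene_id.unique()
    de_fpkm = study.fpkm.loc[study.fpkm.index.intersection(de_genes)]
    model = expression.select_k_cluster(
        de_fpkm,
        k_range=range(cfg.k_min, cfg.k_max + 1),
        seed=stage_seed(cfg.seed, "cluster"),
        n_init=cfg.n_init,
    )
    model.assignments.to_csv(os.path.join(cfg.out_dir, "expression_clusters.tsv"), sep="\t")
    model.bic.rename("bic").to_csv(os.path.join(cfg.out_dir, "cluster_bic.tsv"), sep="\t")
    log.info("expression clustering: K=%d over %d DE genes", model.k, len(de_fpkm))

    manifest = _write_manifest(cfg.out_dir)
    return {
        "diff_accessibility": diff,
        "curated_footprints": curated,
        "regression": ranked,
        "diff_histone": dh,
        "enhancers": all_rec,
        "cluster_k": model.k,
        "manifest": manifest,
    }


def _write_manifest(out_dir: str) -> dict:
    digests = {}
    for name in sorted(os.listdir(out_dir)):
        path = os.path.join(out_dir, name)
        if name == "run_manifest.json" or not os.path.isfile(path):
            continue
        with open(path, "rb") as fh:
            digests[name] = hashlib.sha256(fh.read()).hexdigest()
    manifest = {"files": digests}
    with open(os.path.join(out_dir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
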