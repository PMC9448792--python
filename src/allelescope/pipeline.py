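"""End-to-end orchestration: filter -> count -> ASCA -> link -> GLMM -> summaries.

The pipeline is a deterministic chain over the module operations; running it
is identical to running the subcommands stage by stage on the same inputs.
All randomness (only the simulator has any) flows from the single config
seed.  Every stage contributes counters to a QC report so that fragment
accounting is auditable (fragments in = assigned + rejected).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import allele_counting, asca, glmm, io as asio, links, variant_filter

log = logging.getLogger("allelescope")

DEFAULTS = {
    "fs_max": 30.0,
    "qd_min": 2.0,
    "cluster_n": 3,
    "cluster_window": 35,
    "min_base_quality": 20,
    "cell_types": None,          # None = all cells
    "window_bp": 500_000,
    "k_background": 200,
    "link_alpha": 0.05,
    "models": ["base", "m2", "m3"],
    "n_quad": 9,
    "alpha": 0.05,
    "seed": 0,
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    merged = dict(DEFAULTS)
    merged.update(cfg)
    return merged


def accessibility_matrix(fragments: pd.DataFrame, peaks: pd.DataFrame,
                         meta: pd.DataFrame) -> pd.DataFrame:
    """Cells x peaks fragment-count matrix over the metadata barcodes."""
    pairs = allele_counting.assign_to_peaks(
        fragments[["chrom", "start", "end", "barcode"]], peaks
    )
    counts = (
        pairs.groupby(["barcode", "peak_id"], sort=True)
        .size()
        .unstack("peak_id", fill_value=0)
    )
    mat = counts.reindex(
        index=meta["barcode"], columns=peaks["peak_id"], fill_value=0
    ).fillna(0)
    return mat


def run_pipeline(cfg: dict, outdir) -> dict:
    """Run every stage, writing results tables and a QC report to ``outdir``."""
    required = ("fragments", "vcf", "peaks", "genes", "cells", "base_obs",
                "mtx", "barcodes", "features")
    for key in required:
        if key not in cfg:
            raise ValueError(f"pipeline config is missing required input {key!r}")
        if not Path(cfg[key]).exists():
            raise FileNotFoundError(f"--{key}: no such file {cfg[key]!r}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    qc: dict = {}
    t0 = time.time()

    def stage(name):
        log.info("stage %-12s %6.1fs", name, time.time() - t0)

    # -- inputs ------------------------------------------------------------
    frags, fstats = asio.read_fragments(cfg["fragments"], return_stats=True)
    qc["fragments"] = vars(fstats)
    variants, vstats = asio.read_phased_vcf(cfg["vcf"], return_stats=True)
    qc["vcf"] = vars(vstats)
    peaks = asio.read_peaks(cfg["peaks"])
    genes = asio.read_genes(cfg["genes"])
    meta = asio.read_cell_meta(cfg["cells"])
    obs = asio.read_base_observations(cfg["base_obs"])
    expr = asio.read_expression(cfg["mtx"], cfg["barcodes"], cfg["features"])
    if cfg.get("cell_types"):
        meta = meta[meta["cell_type"].isin(cfg["cell_types"])].reset_index(drop=True)
    stage("read")

    # -- variant filtering -------------------------------------------------
    fcfg = variant_filter.FilterConfig(
        fs_max=cfg["fs_max"], qd_min=cfg["qd_min"],
        cluster_n=cfg["cluster_n"], cluster_window=cfg["cluster_window"],
    )
    kept, fcounts = variant_filter.hard_filter_snv(variants, fcfg)
    kept = variant_filter.select_het_phased(kept)
    qc["variant_filter"] = fcounts | {"n_het_phased": len(kept)}
    asio.write_results_table(kept, out / "filtered_variants.tsv")
    stage("filter")

    # -- allele calling and counting ---------------------------------------
    # observations at filtered-out variants are no longer informative
    obs_key = pd.MultiIndex.from_frame(obs[["chrom", "pos"]])
    kept_key = pd.MultiIndex.from_frame(kept[["chrom", "pos"]])
    obs = obs[obs_key.isin(kept_key)]
    calls = allele_counting.call_alleles(obs, kept, cfg["min_base_quality"])
    counts, cstats = allele_counting.count_alleles_per_peak(
        calls, peaks, meta, return_stats=True
    )
    qc["counting"] = cstats
    asio.write_results_table(counts, out / "counts.tsv")
    stage("count")

    # -- aggregate binomial ASCA -------------------------------------------
    totals = allele_counting.aggregate_counts(counts)
    asca_tab = asca.asca_table(totals, alpha=cfg["alpha"])
    asio.write_results_table(asca_tab, out / "asca.tsv")
    qc["asca"] = {
        "n_peaks": int(len(asca_tab)),
        "n_pass_filter": int(asca_tab["passes_filter"].sum()),
        "n_significant": int(asca_tab["significant"].sum()),
    }
    stage("asca")

    # -- peak-gene links -----------------------------------------------------
    access = accessibility_matrix(frags, peaks, meta)
    feat = links.compute_peak_features(
        peaks, access, gc_table=pd.read_csv(cfg["peak_features"], sep="\t")
        if cfg.get("peak_features") else None,
        genome_fasta=cfg.get("genome_fasta"),
    )
    expr_cells = expr.subset_barcodes(meta["barcode"])
    expr_df = expr_cells.to_dense()
    link_tab = links.link_peaks(
        access, expr_df, feat, genes,
        window_bp=cfg["window_bp"], k_background=min(cfg["k_background"],
                                                     max(len(peaks) - 1, 1)),
    )
    asio.write_results_table(link_tab, out / "links.tsv")
    qc["links"] = {"n_links": int(len(link_tab))}
    stage("link")

    # -- GLMM designs and fits ----------------------------------------------
    norm_expr, dropped = glmm.normalize_expression_matrix(expr_cells)
    qc["expression"] = {"n_genes_dropped_zero_range": len(dropped)}
    passing = set(asca_tab.loc[asca_tab["passes_filter"], "peak_id"])
    selected = link_tab[link_tab["p_value"] < cfg["link_alpha"]]
    assigned = allele_counting.assign_to_peaks(calls, peaks)
    design = glmm.build_design(
        assigned, selected, norm_expr, meta, peak_ids=passing
    )
    asio.write_results_table(design, out / "design.tsv")
    qc["design"] = {
        "n_rows": int(len(design)),
        "n_combinations": int(
            design.groupby(["peak_id", "gene_id"]).ngroups if len(design) else 0
        ),
    }
    stage("design")

    fits = {}
    for model_id in cfg["models"]:
        tab = glmm.fit_all_glmm(design, model_id, n_quad=cfg["n_quad"])
        fits[model_id] = tab
        asio.write_results_table(tab, out / f"fits_{model_id}.tsv")
        qc[f"glmm_{model_id}"] = glmm.multiple_testing_summary(tab)
    stage("glmm")

    donor = glmm.fit_all_donors(design)
    asio.write_results_table(donor, out / "donor_fits.tsv")
    conc = glmm.donor_concordance(donor, alpha=cfg["alpha"])
    asio.write_results_table(pd.DataFrame([conc]), out / "concordance.tsv")
    qc["concordance"] = conc
    stage("donor")

    with open(out / "qc_report.json", "w") as fh:
        json.dump(qc, fh, indent=2, default=str)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return {
        "qc": qc, "asca": asca_tab, "links": link_tab, "design": design,
        "fits": fits, "donor_fits": donor, "concordance": conc,
    }
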