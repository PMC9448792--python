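"""Synthetic multimodal cohorts with known ground truth.

The generator mirrors the study design generatively: a case/control cohort of
snATAC libraries, peaks carrying phased heterozygous SNVs, negative-binomial
per-(cell, peak) fragment coverage, per-cell imputed gene expression, and
allele emission from the same random-intercept logistic model the inference
stage fits,

    P(alt) = logistic(beta0 + beta_expr * x + beta_dia * d + beta_int * x * d + u_s),

with x the linked gene's expression min-max scaled to [0, 100] across all
cells and u_s ~ N(0, sigma_u^2) per library.  Every emitted file round-trips
through :mod:`allelescope.io`, and a truth table records all draws.

Default scale is a desk-size cohort (12 samples, 6 control / 6 disease,
300 cells per sample, 500 peaks, 400 genes) that runs in seconds.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as asio

_BASES = np.array(list("ACGT"))


@dataclasses.dataclass
class SimConfig:
    """Generating conditions for :func:`simulate_cohort`.

    Coefficients are on the log-odds scale of the allele model; ``beta_expr``
    for each truly linked peak-gene pair is drawn from
    N(beta_expr_mean, beta_expr_sd^2).  ``coverage_mean`` is the expected
    fragment count per cell-peak; negative-binomial with ``nb_dispersion``
    (gamma shape; smaller = more overdispersed).  ``ref_bias`` optionally
    flips alt base observations to ref with that probability, emulating
    mapping bias.
    """

    seed: int
    n_samples: int = 12
    disease_fraction: float = 0.5
    n_cells_per_sample: int = 300
    n_peaks: int = 500
    frac_peaks_with_het_snv: float = 0.8
    snvs_per_peak: int = 1
    n_genes: int = 400
    frac_linked_pairs: float = 0.6
    coverage_mean: float = 0.1
    nb_dispersion: float = 0.5
    beta0: float = 0.0
    beta_expr_mean: float = 0.0
    beta_expr_sd: float = 0.01
    beta_dia: float = 0.0
    beta_int: float = 0.0
    sigma_u: float = 0.5
    link_strength: float = 0.8
    expr_meanlog: float = 1.0
    expr_sdlog: float = 0.7
    base_qual_mean: float = 37.0
    base_qual_sd: float = 3.0
    ref_bias: float = 0.0
    chrom: str = "chr1"

    def __post_init__(self):
        for name in ("disease_fraction", "frac_peaks_with_het_snv",
                     "frac_linked_pairs", "ref_bias"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")
        if self.n_samples < 1 or self.n_cells_per_sample < 1 or self.n_peaks < 1:
            raise ValueError("infeasible config: need >= 1 sample, cell and peak")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclasses.dataclass
class SimulatedCohort:
    """In-memory cohort; ``write`` emits the on-disk formats io_core reads."""

    config: SimConfig
    meta: pd.DataFrame
    peaks: pd.DataFrame           # chrom/start/end/peak_id/gc_fraction
    variants: pd.DataFrame        # io.VARIANT_COLUMNS
    genes: pd.DataFrame           # chrom/start/end/gene_id/strand
    fragments: pd.DataFrame       # io.FRAGMENT_COLUMNS
    base_obs: pd.DataFrame        # io.BASEOBS_COLUMNS
    expression: asio.ExpressionMatrix
    truth_samples: pd.DataFrame   # sample_id/condition/u
    truth_links: pd.DataFrame     # peak_id/gene_id/beta_expr
    truth_peaks: pd.DataFrame     # peak_id/has_snv/gene_id/imbalanced/exp_alt_frac

    def write(self, outdir) -> dict:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fragments": out / "fragments.tsv",
            "vcf": out / "variants.vcf",
            "peaks": out / "peaks.bed",
            "peak_features": out / "peak_features.tsv",
            "genes": out / "genes.bed",
            "base_obs": out / "base_observations.tsv",
            "meta": out / "cells.tsv",
            "mtx": out / "expression.mtx",
            "barcodes": out / "barcodes.tsv",
            "features": out / "features.tsv",
            "truth_samples": out / "truth_samples.tsv",
            "truth_links": out / "truth_links.tsv",
            "truth_peaks": out / "truth_peaks.tsv",
        }
        asio.write_fragments(self.fragments, paths["fragments"])
        asio.write_phased_vcf(self.variants, paths["vcf"])
        asio.write_bed(self.peaks, paths["peaks"],
                       columns=["chrom", "start", "end", "peak_id"])
        self.peaks[["peak_id", "gc_fraction"]].to_csv(
            paths["peak_features"], sep="\t", index=False
        )
        genes = self.genes.copy()
        genes["score"] = 0
        asio.write_bed(genes, paths["genes"],
                       columns=["chrom", "start", "end", "gene_id", "score", "strand"])
        self.base_obs.to_csv(paths["base_obs"], sep="\t", index=False)
        self.meta.to_csv(paths["meta"], sep="\t", index=False)
        asio.write_expression(
            self.expression, paths["mtx"], paths["barcodes"], paths["features"]
        )
        self.truth_samples.to_csv(paths["truth_samples"], sep="\t", index=False)
        self.truth_links.to_csv(paths["truth_links"], sep="\t", index=False)
        self.truth_peaks.to_csv(paths["truth_peaks"], sep="\t", index=False)
        return paths


def _negative_binomial(rng, mean, dispersion, size):
    """NB via gamma-Poisson mixture; var = mean + mean^2 / dispersion."""
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion, size=size)
    return rng.poisson(lam)


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Generate a complete cohort; fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)

    # -- samples and cells -------------------------------------------------
    n_disease = int(round(cfg.n_samples * cfg.disease_fraction))
    sample_ids = np.array([f"S{i + 1:02d}" for i in range(cfg.n_samples)])
    condition = np.array(
        ["control"] * (cfg.n_samples - n_disease) + ["disease"] * n_disease
    )
    u = rng.normal(0.0, cfg.sigma_u, size=cfg.n_samples)
    truth_samples = pd.DataFrame(
        {"sample_id": sample_ids, "condition": condition, "u": u}
    )

    n_cells = cfg.n_samples * cfg.n_cells_per_sample
    cell_sample = np.repeat(np.arange(cfg.n_samples), cfg.n_cells_per_sample)
    barcodes = np.array(
        [
            f"{sample_ids[s]}_{i % cfg.n_cells_per_sample + 1:05d}-1"
            for i, s in enumerate(cell_sample)
        ]
    )
    meta = pd.DataFrame(
        {
            "barcode": barcodes,
            "sample_id": sample_ids[cell_sample],
            "cell_type": "PT",
            "condition": condition[cell_sample],
        }
    )

    # -- genome layout: non-overlapping peaks on one chromosome -----------
    widths = rng.integers(300, 800, size=cfg.n_peaks)
    gaps = rng.integers(2000, 6000, size=cfg.n_peaks)
    starts = 10_000 + np.cumsum(gaps) + np.concatenate([[0], np.cumsum(widths)[:-1]])
    peaks = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "start": starts,
            "end": starts + widths,
            "peak_id": [f"peak_{i + 1:05d}" for i in range(cfg.n_peaks)],
            "gc_fraction": rng.uniform(0.3, 0.7, size=cfg.n_peaks),
        }
    )
    span = int(peaks["end"].max()) + 10_000

    gene_tss = rng.integers(5_000, span, size=cfg.n_genes)
    gene_strand = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
    gene_len = rng.integers(5_000, 50_000, size=cfg.n_genes)
    genes = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "start": np.where(gene_strand == "+", gene_tss, np.maximum(gene_tss - gene_len, 0)),
            "end": np.where(gene_strand == "+", gene_tss + gene_len, gene_tss),
            "gene_id": [f"gene_{i + 1:05d}" for i in range(cfg.n_genes)],
            "strand": gene_strand,
        }
    ).sort_values("start", kind="mergesort").reset_index(drop=True)

    # -- phased het SNVs, one (or more) per selected peak ------------------
    has_snv = rng.random(cfg.n_peaks) < cfg.frac_peaks_with_het_snv
    snv_peaks = np.flatnonzero(has_snv)
    var_rows = []
    for k in range(cfg.snvs_per_peak):
        # spread multiple SNVs across the peak; offset keeps them distinct
        frac = (k + 1) / (cfg.snvs_per_peak + 1)
        pos = (
            peaks["start"].to_numpy()[snv_peaks]
            + (frac * widths[snv_peaks]).astype(int)
        )
        ref_i = rng.integers(0, 4, size=len(snv_peaks))
        alt_i = (ref_i + rng.integers(1, 4, size=len(snv_peaks))) % 4
        var_rows.append(
            pd.DataFrame(
                {
                    "chrom": cfg.chrom,
                    "pos": pos,
                    "ref_allele": _BASES[ref_i],
                    "alt_allele": _BASES[alt_i],
                    "hap_of_alt": rng.integers(0, 2, size=len(snv_peaks)),
                    "fs": rng.uniform(0.0, 10.0, size=len(snv_peaks)),
                    "qd": rng.uniform(10.0, 30.0, size=len(snv_peaks)),
                    "is_het": True,
                    "is_phased": True,
                    "peak_idx": snv_peaks,
                }
            )
        )
    variants = (
        pd.concat(var_rows, ignore_index=True)
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )

    # -- expression: per-gene lognormal, then the [0,100] scale ------------
    gene_mu = rng.normal(cfg.expr_meanlog, 0.5, size=cfg.n_genes)
    expr = rng.lognormal(
        mean=gene_mu[None, :], sigma=cfg.expr_sdlog, size=(n_cells, cfg.n_genes)
    )
    lo = expr.min(axis=0)
    hi = expr.max(axis=0)
    x_norm = (expr - lo) / np.where(hi > lo, hi - lo, 1.0) * 100.0

    # -- truth links: each SNV peak may couple to its nearest gene ---------
    linked = rng.random(len(snv_peaks)) < cfg.frac_linked_pairs
    peak_mid = (
        peaks["start"].to_numpy()[snv_peaks] + peaks["end"].to_numpy()[snv_peaks]
    ) // 2
    tss_sorted = np.where(
        genes["strand"].to_numpy() == "+",
        genes["start"].to_numpy(),
        genes["end"].to_numpy(),
    )
    link_gene = np.abs(peak_mid[:, None] - tss_sorted[None, :]).argmin(axis=1)
    beta_expr = np.where(
        linked, rng.normal(cfg.beta_expr_mean, cfg.beta_expr_sd, size=len(snv_peaks)), 0.0
    )
    peak_gene = np.full(cfg.n_peaks, -1)
    peak_beta = np.zeros(cfg.n_peaks)
    peak_gene[snv_peaks[linked]] = link_gene[linked]
    peak_beta[snv_peaks] = beta_expr
    truth_links = pd.DataFrame(
        {
            "peak_id": peaks["peak_id"].to_numpy()[snv_peaks[linked]],
            "gene_id": genes["gene_id"].to_numpy()[link_gene[linked]],
            "beta_expr": beta_expr[linked],
        }
    )

    # -- fragment coverage and allele emission -----------------------------
    # linked peaks get coverage modulated by their gene's expression, so
    # accessibility genuinely correlates with expression at planted pairs
    mean_mat = np.full((n_cells, cfg.n_peaks), cfg.coverage_mean, dtype=np.float32)
    if cfg.link_strength > 0:
        log_e = np.log(expr)
        zlog = (log_e - log_e.mean(axis=0)) / np.where(
            log_e.std(axis=0) > 0, log_e.std(axis=0), 1.0
        )
        ls = cfg.link_strength
        for pk, g in zip(snv_peaks[linked], link_gene[linked]):
            mean_mat[:, pk] *= np.exp(ls * zlog[:, g] - 0.5 * ls * ls).astype(
                np.float32
            )
    counts = _negative_binomial(rng, mean_mat, cfg.nb_dispersion, mean_mat.shape)
    cell_idx, peak_idx = np.nonzero(counts)
    reps = counts[cell_idx, peak_idx]
    f_cell = np.repeat(cell_idx, reps)
    f_peak = np.repeat(peak_idx, reps)
    n_frag = len(f_cell)

    frag_len = rng.integers(120, 400, size=n_frag)
    p_start = peaks["start"].to_numpy()[f_peak]
    p_end = peaks["end"].to_numpy()[f_peak]
    # anchor fragments inside the peak; they cover the peak's central SNV
    # whenever length allows
    anchor = (p_start + p_end) // 2
    jitter = rng.integers(0, np.maximum(frag_len, 1))
    f_start = np.maximum(anchor - jitter, 0)
    f_end = f_start + frag_len

    # allele model: x is the linked gene's normalized expression in the cell
    g_of_frag = peak_gene[f_peak]
    x = np.where(g_of_frag >= 0, x_norm[f_cell, np.maximum(g_of_frag, 0)], 0.0)
    d = (meta["condition"].to_numpy() == "disease").astype(float)[f_cell]
    s = cell_sample[f_cell]
    eta = (
        cfg.beta0
        + peak_beta[f_peak] * x
        + cfg.beta_dia * d
        + cfg.beta_int * x * d
        + u[s]
    )
    p_alt = 1.0 / (1.0 + np.exp(-eta))
    is_alt = rng.random(n_frag) < p_alt

    fragments = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "start": f_start,
            "end": f_end,
            "barcode": barcodes[f_cell],
            "support": 1 + rng.poisson(0.5, size=n_frag),
        }
    )
    # 10x fragment records are unique on (chrom,start,end,barcode); merge the
    # rare coordinate collisions, keeping their base observations separate
    dedup = fragments.groupby(
        ["chrom", "start", "end", "barcode"], sort=True, as_index=False
    ).agg(support=("support", "sum"))

    # -- base observations at every covered SNV ----------------------------
    v_pos = variants["pos"].to_numpy()
    v_peak = variants["peak_idx"].to_numpy()
    v_ref = variants["ref_allele"].to_numpy()
    v_alt = variants["alt_allele"].to_numpy()
    order = np.argsort(v_peak, kind="mergesort")
    v_pos, v_ref, v_alt = v_pos[order], v_ref[order], v_alt[order]
    v_peak = v_peak[order]
    first = np.searchsorted(v_peak, np.arange(cfg.n_peaks), side="left")
    last = np.searchsorted(v_peak, np.arange(cfg.n_peaks), side="right")
    nvar = (last - first)[f_peak]
    total_obs = int(nvar.sum())
    frep = np.repeat(np.arange(n_frag), nvar)
    within = np.arange(total_obs) - np.repeat(np.cumsum(nvar) - nvar, nvar)
    vidx = np.repeat(first[f_peak], nvar) + within
    covered = (v_pos[vidx] >= f_start[frep]) & (v_pos[vidx] < f_end[frep])
    frep, vidx = frep[covered], vidx[covered]

    obs_base = np.where(is_alt[frep], v_alt[vidx], v_ref[vidx])
    if cfg.ref_bias > 0:
        flip = (obs_base == v_alt[vidx]) & (rng.random(len(frep)) < cfg.ref_bias)
        obs_base = np.where(flip, v_ref[vidx], obs_base)
    qual = np.clip(
        rng.normal(cfg.base_qual_mean, cfg.base_qual_sd, size=len(frep)), 2.0, 60.0
    )
    base_obs = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "start": f_start[frep],
            "end": f_end[frep],
            "barcode": barcodes[f_cell[frep]],
            "pos": v_pos[vidx],
            "base": obs_base,
            "qual": np.round(qual, 1),
        }
    ).sort_values(["chrom", "start", "end", "barcode", "pos"],
                  kind="mergesort").reset_index(drop=True)

    # -- per-peak truth -----------------------------------------------------
    grp = pd.DataFrame({"peak": f_peak, "p_alt": p_alt}).groupby("peak")["p_alt"]
    exp_alt = grp.mean()
    truth_peaks = pd.DataFrame(
        {
            "peak_id": peaks["peak_id"],
            "has_snv": has_snv,
            "gene_id": [
                genes["gene_id"].iloc[g] if g >= 0 else ""
                for g in peak_gene
            ],
            "beta_expr": peak_beta,
            "imbalanced": has_snv
            & (
                (np.abs(peak_beta) > 0)
                | (cfg.beta0 != 0)
                | (cfg.beta_dia != 0)
                | (cfg.beta_int != 0)
            ),
            "expected_alt_fraction": peaks.index.map(exp_alt).to_numpy(),
        }
    )

    expression = asio.ExpressionMatrix(
        np.round(expr, 4), barcodes, genes["gene_id"]
    )
    return SimulatedCohort(
        config=cfg,
        meta=meta,
        peaks=peaks,
        variants=variants.drop(columns=["peak_idx"]),
        genes=genes,
        fragments=dedup,
        base_obs=base_obs,
        expression=expression,
        truth_samples=truth_samples,
        truth_links=truth_links,
        truth_peaks=truth_peaks,
    )


def simulate_glmm_design(
    seed: int,
    n_samples: int = 12,
    n_fragments_per_sample: int = 2000,
    beta0: float = 0.0,
    beta_expr: float = 0.01,
    beta_dia: float = 0.0,
    beta_int: float = 0.0,
    sigma_u: float = 0.5,
    disease_fraction: float = 0.5,
    expr_sdlog: float = 0.7,
    peak_id: str = "peak_sim",
    gene_id: str = "gene_sim",
) -> pd.DataFrame:
    """Fragment-level design table for one peak-gene combination.

    The focused instrument for parameter-recovery and calibration work on
    the mixed model: x is lognormal expression min-max scaled to [0, 100]
    over all fragments, d is the per-sample disease indicator, u_s the
    per-sample random intercept, and y ~ Bernoulli(logistic(eta)).  Returns
    the same columns :func:`allelescope.glmm.build_design` produces, plus
    the truth in ``attrs['truth']``.
    """
    rng = np.random.default_rng(seed)
    n = n_samples * n_fragments_per_sample
    s = np.repeat(np.arange(n_samples), n_fragments_per_sample)
    n_disease = int(round(n_samples * disease_fraction))
    d_sample = np.array([0] * (n_samples - n_disease) + [1] * n_disease)
    u = rng.normal(0.0, sigma_u, size=n_samples)
    raw = rng.lognormal(mean=1.0, sigma=expr_sdlog, size=n)
    x = (raw - raw.min()) / (raw.max() - raw.min()) * 100.0
    d = d_sample[s]
    eta = beta0 + beta_expr * x + beta_dia * d + beta_int * x * d + u[s]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    out = pd.DataFrame(
        {
            "peak_id": peak_id,
            "gene_id": gene_id,
            "y": y,
            "x_expr": x,
            "dia": d,
            "sample_id": np.array([f"S{i + 1:02d}" for i in range(n_samples)])[s],
            "barcode": [f"bc{i:07d}" for i in range(n)],
        }
    )
    out.attrs["truth"] = {
        "beta0": beta0, "beta_expr": beta_expr, "beta_dia": beta_dia,
        "beta_int": beta_int, "sigma_u": sigma_u, "u": tuple(u),
    }
    return out


# ---------------------------------------------------------------------------
# link-matrix fixture generator


@dataclasses.dataclass
class LinkSimConfig:
    """Conditions for :func:`simulate_link_matrices`.

    Planted pairs share a latent Gaussian factor with correlation ``rho``
    before the count/expression observation noise; null pairs are
    independent.  Peak nuisance features (GC, width, baseline accessibility)
    vary so that background matching is nontrivial.
    """

    seed: int
    n_cells: int = 500
    n_peaks: int = 300
    n_genes: int = 40
    frac_planted: float = 0.5
    rho: float = 0.9
    gene_spacing_bp: int = 100_000
    latent_sd: float = 0.5
    count_mean_log_range: tuple = (np.log(2.0), np.log(8.0))


def simulate_link_matrices(cfg: LinkSimConfig) -> dict:
    """Peak x cell counts, gene x cell expression, and planted link truth."""
    rng = np.random.default_rng(cfg.seed)
    span = cfg.n_genes * cfg.gene_spacing_bp

    tss = np.arange(cfg.n_genes) * cfg.gene_spacing_bp + cfg.gene_spacing_bp // 2
    genes = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": tss,
            "end": tss + 10_000,
            "gene_id": [f"gene_{i + 1:04d}" for i in range(cfg.n_genes)],
            "strand": "+",
        }
    )
    starts = np.sort(rng.integers(0, span, size=cfg.n_peaks))
    widths = rng.integers(200, 1000, size=cfg.n_peaks)
    peaks = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + widths,
            "peak_id": [f"peak_{i + 1:04d}" for i in range(cfg.n_peaks)],
            "gc_fraction": rng.uniform(0.3, 0.7, size=cfg.n_peaks),
        }
    )

    planted_genes = np.flatnonzero(rng.random(cfg.n_genes) < cfg.frac_planted)
    mid = (peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2
    planted_peak = np.array(
        [int(np.argmin(np.abs(mid - tss[g]))) for g in planted_genes], dtype=int
    )

    latent_gene = rng.normal(0, 1, size=(cfg.n_cells, cfg.n_genes))
    latent_peak = rng.normal(0, 1, size=(cfg.n_cells, cfg.n_peaks))
    for g, p in zip(planted_genes, planted_peak):
        shared = rng.normal(0, 1, size=cfg.n_cells)
        noise_g = rng.normal(0, 1, size=cfg.n_cells)
        noise_p = rng.normal(0, 1, size=cfg.n_cells)
        latent_gene[:, g] = np.sqrt(cfg.rho) * shared + np.sqrt(1 - cfg.rho) * noise_g
        latent_peak[:, p] = np.sqrt(cfg.rho) * shared + np.sqrt(1 - cfg.rho) * noise_p

    mu_log = rng.uniform(*cfg.count_mean_log_range, size=cfg.n_peaks)
    rate = np.exp(mu_log[None, :] + cfg.latent_sd * latent_peak)
    counts = rng.poisson(rate)
    expr = np.exp(1.0 + cfg.latent_sd * latent_gene)

    cells = [f"cell_{i + 1:05d}" for i in range(cfg.n_cells)]
    accessibility = pd.DataFrame(counts, index=cells, columns=peaks["peak_id"])
    expression = pd.DataFrame(expr, index=cells, columns=genes["gene_id"])
    truth = pd.DataFrame(
        {
            "peak_id": peaks["peak_id"].to_numpy()[planted_peak],
            "gene_id": genes["gene_id"].to_numpy()[planted_genes],
            "rho": cfg.rho,
        }
    )
    return {
        "accessibility": accessibility,
        "expression": expression,
        "peaks": peaks,
        "genes": genes,
        "truth": truth,
    }
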