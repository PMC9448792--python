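"""Peak-gene linking against a feature-matched background null.

For every gene and every peak whose midpoint lies within ``window_bp`` of the
gene's TSS, the observed Pearson correlation between per-cell peak
accessibility and per-cell expression is compared with the correlations of
``k_background`` peaks matched on GC content, mean accessibility and width
(nearest neighbours in z-scored feature space, drawn from outside the gene's
window).  The link statistic is z = (r_obs - null_mean) / null_sd with a
two-sided normal p-value; matching on the nuisance features is what corrects
the test for GC, accessibility and width, while the window restriction plus
the reported TSS distance handle distance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

FEATURE_COLUMNS = ["gc_fraction", "mean_accessibility", "width"]


def gc_fraction(seq: str) -> float:
    """(G+C) / (A+C+G+T) over a sequence; N and other codes leave the denominator."""
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def compute_peak_features(
    peaks: pd.DataFrame,
    accessibility: pd.DataFrame,
    genome_fasta=None,
    gc_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach gc_fraction, mean_accessibility and width to a peak table.

    GC comes from a genome FASTA (via pysam) or a precomputed table with
    columns (peak_id, gc_fraction); accessibility is the cells x peaks count
    matrix whose column means give mean accessibility.
    """
    out = peaks.copy()
    out["width"] = out["end"] - out["start"]
    if (out["width"] <= 0).any():
        raise ValueError("peaks must have positive width")
    if gc_table is not None:
        out = out.merge(gc_table[["peak_id", "gc_fraction"]], on="peak_id", how="left")
    elif genome_fasta is not None:
        import pysam

        with pysam.FastaFile(str(genome_fasta)) as fa:
            gcs = []
            for row in out.itertuples(index=False):
                if row.chrom not in fa.references:
                    raise ValueError(f"peak chrom {row.chrom} not in genome")
                if row.end > fa.get_reference_length(row.chrom):
                    raise ValueError(f"peak {row.peak_id} outside genome bounds")
                gcs.append(gc_fraction(fa.fetch(row.chrom, row.start, row.end)))
        out["gc_fraction"] = gcs
    elif "gc_fraction" not in out.columns:
        raise ValueError("need genome_fasta or gc_table to compute GC content")
    means = accessibility.mean(axis=0)
    out["mean_accessibility"] = out["peak_id"].map(means)
    if out["mean_accessibility"].isna().any():
        missing = out.loc[out["mean_accessibility"].isna(), "peak_id"].iloc[:3]
        raise ValueError(f"peaks missing from accessibility matrix: {list(missing)}")
    return out


def match_background(
    target_peak_id: str,
    candidate_peak_ids,
    features: pd.DataFrame,
    k: int,
) -> list:
    """k background peaks nearest to the target in z-scored feature space.

    ``features`` must be indexed by peak_id with FEATURE_COLUMNS; features
    are standardized over all peaks in the table, distances are Euclidean
    and ties break deterministically by (distance, peak_id).
    """
    candidates = [p for p in candidate_peak_ids if p != target_peak_id]
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds {len(candidates)} candidates")
    F = features[FEATURE_COLUMNS].to_numpy(float)
    mu = F.mean(axis=0)
    sd = F.std(axis=0)
    sd[sd == 0] = 1.0
    Z = pd.DataFrame((F - mu) / sd, index=features.index, columns=FEATURE_COLUMNS)
    t = Z.loc[target_peak_id].to_numpy()
    C = Z.loc[candidates].to_numpy()
    dist = np.sqrt(((C - t) ** 2).sum(axis=1))
    order = sorted(range(len(candidates)), key=lambda i: (dist[i], candidates[i]))
    return [candidates[i] for i in order[:k]]


def _standardize_columns(M: np.ndarray):
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(M, dtype=float)
    Z[:, ok] = (M[:, ok] - mu[ok]) / sd[ok]
    return Z, ok


class PeakGeneLinker(BaseEstimator):
    """Estimator computing peak-gene links with a matched-background null.

    Parameters
    ----------
    window_bp : candidate peaks have midpoints within this distance of the
        gene TSS (TSS = gene start on '+', gene end on '-').
    k_background : matched background peaks per link.

    Attributes (after fit)
    ----------------------
    links_ : DataFrame of PeakGeneLink records.
    skipped_ : list of (peak_id, gene_id, reason) for degenerate pairs.
    """

    def __init__(self, window_bp: int = 500_000, k_background: int = 200):
        self.window_bp = window_bp
        self.k_background = k_background

    def fit(self, accessibility: pd.DataFrame, expression: pd.DataFrame,
            peaks: pd.DataFrame, genes: pd.DataFrame):
        """Compute all links.

        ``accessibility`` (cells x peaks) and ``expression`` (cells x genes)
        must share their row (barcode) order; ``peaks`` carries
        FEATURE_COLUMNS (see :func:`compute_peak_features`) and ``genes``
        carries chrom/start/end/gene_id/strand.
        """
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if not accessibility.index.equals(expression.index):
            raise ValueError("accessibility and expression need identical cell order")
        peaks = peaks.reset_index(drop=True)
        n_cells = len(accessibility)

        A = accessibility[peaks["peak_id"]].to_numpy(float)
        Za, peak_ok = _standardize_columns(A)

        F = peaks[FEATURE_COLUMNS].to_numpy(float)
        mu, sd = F.mean(axis=0), F.std(axis=0)
        sd[sd == 0] = 1.0
        Zf = (F - mu) / sd

        mid = (peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2
        peak_chrom = peaks["chrom"].to_numpy()
        peak_ids = peaks["peak_id"].to_numpy()

        tss = np.where(
            genes["strand"].to_numpy() == "+",
            genes["start"].to_numpy(),
            genes["end"].to_numpy(),
        )

        records, skipped = [], []
        for gi, gene in enumerate(genes.itertuples(index=False)):
            gene_id = gene.gene_id
            if gene_id not in expression.columns:
                skipped.append((None, gene_id, "gene not in expression matrix"))
                continue
            e = expression[gene_id].to_numpy(float)
            esd = e.std()
            if esd == 0:
                skipped.append((None, gene_id, "zero-variance expression"))
                continue
            ze = (e - e.mean()) / esd
            r_all = Za.T @ ze / n_cells  # Pearson r with every peak

            same_chrom = peak_chrom == gene.chrom
            dist = mid - tss[gi]
            in_window = same_chrom & (np.abs(dist) <= self.window_bp)
            cand_idx = np.flatnonzero(in_window)
            if cand_idx.size == 0:
                continue
            bg_pool = np.flatnonzero(~in_window & peak_ok)
            for pi in cand_idx:
                if not peak_ok[pi]:
                    skipped.append((peak_ids[pi], gene_id, "zero-variance peak"))
                    continue
                if bg_pool.size < self.k_background:
                    skipped.append((peak_ids[pi], gene_id, "too few background peaks"))
                    continue
                d = np.sqrt(((Zf[bg_pool] - Zf[pi]) ** 2).sum(axis=1))
                order = np.lexsort((peak_ids[bg_pool], d))
                bg = bg_pool[order[: self.k_background]]
                null = r_all[bg]
                null_mean = float(null.mean())
                null_sd = float(null.std(ddof=1))
                if null_sd == 0:
                    skipped.append((peak_ids[pi], gene_id, "degenerate null"))
                    continue
                z = (float(r_all[pi]) - null_mean) / null_sd
                records.append(
                    {
                        "peak_id": peak_ids[pi],
                        "gene_id": gene_id,
                        "distance_bp": int(dist[pi]),
                        "r_obs": float(r_all[pi]),
                        "null_mean": null_mean,
                        "null_sd": null_sd,
                        "z_score": z,
                        "p_value": float(2 * norm.sf(abs(z))),
                        "n_background": int(self.k_background),
                    }
                )
        self.links_ = pd.DataFrame(
            records,
            columns=[
                "peak_id", "gene_id", "distance_bp", "r_obs", "null_mean",
                "null_sd", "z_score", "p_value", "n_background",
            ],
        )
        self.skipped_ = skipped
        return self


def link_peaks(
    accessibility: pd.DataFrame,
    expression: pd.DataFrame,
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    window_bp: int = 500_000,
    k_background: int = 200,
) -> pd.DataFrame:
    """Functional wrapper over :class:`PeakGeneLinker` returning the link table."""
    linker = PeakGeneLinker(window_bp=window_bp, k_background=k_background)
    return linker.fit(accessibility, expression, peaks, genes).links_


def gene_targets_per_peak(links: pd.DataFrame, alpha: float = 0.05,
                          adjusted: bool = False) -> pd.Series:
    """Multiplicity distribution: number of linked gene targets per peak."""
    from .asca import bh_adjust

    sig = links.copy()
    if adjusted:
        sig["p_adjusted"] = bh_adjust(sig["p_value"].to_numpy())
        sig = sig[sig["p_adjusted"] < alpha]
    else:
        sig = sig[sig["p_value"] < alpha]
    counts = sig.groupby("peak_id")["gene_id"].nunique()
    return counts.value_counts().sort_index()
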