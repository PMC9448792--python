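"""Hard filters and selection rules producing the analysis-ready SNV set.

Variants failing the Fisher-strand (FS) or quality-by-depth (QD) thresholds
are removed, as is every member of any cluster of ``cluster_n`` SNVs whose
outermost positions span at most ``cluster_window`` bp.  Records with a
missing FS or QD annotation pass that rule but are counted in the QC report.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd


@dataclasses.dataclass
class FilterConfig:
    """Thresholds for the SNV hard filter.

    fs_max : remove variants with FS strictly above this (strand bias).
    qd_min : remove variants with QD strictly below this.
    cluster_n / cluster_window : remove any run of ``cluster_n`` consecutive
        SNVs on a chromosome spanning <= ``cluster_window`` bp (the
        conventional short-variant clustering recipe, 3 SNVs per 35 bp).
    """

    fs_max: float = 30.0
    qd_min: float = 2.0
    cluster_n: int = 3
    cluster_window: int = 35

    def __post_init__(self):
        if self.fs_max <= 0 or self.qd_min <= 0 or self.cluster_window <= 0:
            raise ValueError("thresholds must be positive")
        if self.cluster_n < 2:
            raise ValueError("cluster_n must be >= 2")


def _cluster_mask(pos: np.ndarray, cluster_n: int, cluster_window: int) -> np.ndarray:
    """Flag members of any cluster_n-run of sorted positions spanning <= window."""
    n = len(pos)
    flagged = np.zeros(n, dtype=bool)
    if n < cluster_n:
        return flagged
    span = pos[cluster_n - 1:] - pos[: n - cluster_n + 1]
    starts = np.flatnonzero(span <= cluster_window)
    for s in starts:
        flagged[s : s + cluster_n] = True
    return flagged


def hard_filter_snv(variants: pd.DataFrame, cfg: FilterConfig | None = None):
    """Apply FS/QD hard filters and the SNV cluster rule.

    ``variants`` must be sorted by (chrom, pos).  Returns
    ``(kept, counts)`` where ``counts`` holds per-rule rejection tallies and
    the number of records whose FS/QD were missing (treated as passing).
    """
    cfg = cfg or FilterConfig()
    if len(variants) == 0:
        return variants.copy(), {
            "n_in": 0, "fail_fs": 0, "fail_qd": 0, "fail_cluster": 0,
            "missing_fs": 0, "missing_qd": 0, "n_out": 0,
        }
    chrom = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()
    order_ok = True
    for c in pd.unique(chrom):
        p = pos[chrom == c]
        if np.any(np.diff(p) < 0):
            order_ok = False
            break
    if not order_ok:
        raise ValueError("variants must be sorted by (chrom, pos)")

    fs = variants["fs"].to_numpy(dtype=float)
    qd = variants["qd"].to_numpy(dtype=float)
    fail_fs = np.nan_to_num(fs, nan=-np.inf) > cfg.fs_max
    fail_qd = np.nan_to_num(qd, nan=np.inf) < cfg.qd_min

    fail_cluster = np.zeros(len(variants), dtype=bool)
    for c in pd.unique(chrom):
        m = chrom == c
        fail_cluster[m] = _cluster_mask(pos[m], cfg.cluster_n, cfg.cluster_window)

    drop = fail_fs | fail_qd | fail_cluster
    counts = {
        "n_in": int(len(variants)),
        "fail_fs": int(fail_fs.sum()),
        "fail_qd": int(fail_qd.sum()),
        "fail_cluster": int(fail_cluster.sum()),
        "missing_fs": int(np.isnan(fs).sum()),
        "missing_qd": int(np.isnan(qd).sum()),
        "n_out": int((~drop).sum()),
    }
    return variants[~drop].reset_index(drop=True), counts


def select_het_phased(variants: pd.DataFrame) -> pd.DataFrame:
    """Retain heterozygous, phased variants only (idempotent)."""
    keep = variants["is_het"].to_numpy(bool) & variants["is_phased"].to_numpy(bool)
    return variants[keep].reset_index(drop=True)
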