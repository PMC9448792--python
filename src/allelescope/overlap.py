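"""Genomic interval overlap and hypergeometric enrichment.

Intervals are 0-based half-open throughout; two intervals overlap iff they
share at least one base.  The join is a per-chromosome sorted sweep with a
bounded back-scan, so subject intervals may overlap each other.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


def overlap_join(query: pd.DataFrame, subject: pd.DataFrame) -> pd.DataFrame:
    """All (query, subject) index pairs with >=1 bp overlap.

    Both frames need chrom/start/end columns.  Returns a DataFrame with
    ``query_idx`` and ``subject_idx`` positional indices.
    """
    q_idx_out: list[np.ndarray] = []
    s_idx_out: list[np.ndarray] = []
    qpos = np.arange(len(query))
    spos = np.arange(len(subject))
    for chrom, qsub in query.groupby("chrom", sort=False):
        smask = subject["chrom"].to_numpy() == chrom
        if not smask.any():
            continue
        s_start = subject.loc[smask, "start"].to_numpy()
        s_end = subject.loc[smask, "end"].to_numpy()
        s_ids = spos[smask]
        order = np.argsort(s_start, kind="mergesort")
        s_start, s_end, s_ids = s_start[order], s_end[order], s_ids[order]
        max_len = int((s_end - s_start).max())

        q_start = qsub["start"].to_numpy()
        q_end = qsub["end"].to_numpy()
        q_ids = qpos[query["chrom"].to_numpy() == chrom]
        # candidates: subject.start in [q.start - max_len, q.end)
        lo = np.searchsorted(s_start, q_start - max_len, side="left")
        hi = np.searchsorted(s_start, q_end, side="left")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            continue
        qrep = np.repeat(np.arange(len(q_start)), counts)
        within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        sidx = np.repeat(lo, counts) + within
        keep = s_end[sidx] > q_start[qrep]
        if keep.any():
            q_idx_out.append(q_ids[qrep[keep]])
            s_idx_out.append(s_ids[sidx[keep]])
    if not q_idx_out:
        return pd.DataFrame({"query_idx": np.array([], int), "subject_idx": np.array([], int)})
    return pd.DataFrame(
        {"query_idx": np.concatenate(q_idx_out), "subject_idx": np.concatenate(s_idx_out)}
    )


def overlap_with_flank(query: pd.DataFrame, subject: pd.DataFrame, flank_bp: int = 0):
    """Query intervals hitting any subject interval expanded by ``flank_bp``.

    Subject intervals are widened by ``flank_bp`` on both sides (clipped at 0)
    before the >=1 bp overlap test.  Returns ``(hits, n_hit, n_query)`` where
    ``hits`` is the subset of query rows with at least one overlap.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    expanded = subject.copy()
    expanded["start"] = np.maximum(subject["start"].to_numpy() - flank_bp, 0)
    expanded["end"] = subject["end"].to_numpy() + flank_bp
    pairs = overlap_join(query, expanded)
    hit_idx = np.unique(pairs["query_idx"].to_numpy())
    hits = query.iloc[hit_idx]
    return hits, len(hits), len(query)


def hypergeometric_enrichment(
    n_hit: int, n_query: int, n_subject_in_universe: int, n_universe: int
) -> float:
    """Upper-tail P(X >= n_hit), X ~ Hypergeom(universe, subject, draws=query)."""
    if not (0 <= n_hit <= min(n_query, n_subject_in_universe) <= n_universe):
        raise ValueError(
            "inconsistent counts: need 0 <= n_hit <= min(n_query, n_subject) <= n_universe"
        )
    if n_query > n_universe:
        raise ValueError("n_query cannot exceed n_universe")
    return float(hypergeom.sf(n_hit - 1, n_universe, n_subject_in_universe, n_query))
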