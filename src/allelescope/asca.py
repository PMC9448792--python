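"""Aggregate binomial test for allele-specific chromatin accessibility.

Per-peak reference/alternate totals (aggregated across cells and libraries)
are screened with strict count filters — total ref+alt > 20, ref > 5, alt > 5
— and the surviving peaks tested against a balanced binomial (p = 1/2) with
the exact two-sided test (minimum-likelihood tail), followed by
Benjamini-Hochberg FDR control.  'Other' bases never enter the trial total.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

MIN_TOTAL = 20  # exclusive
MIN_REF = 5  # exclusive
MIN_ALT = 5  # exclusive


def filter_peak_counts(
    totals: pd.DataFrame,
    min_total: int = MIN_TOTAL,
    min_ref: int = MIN_REF,
    min_alt: int = MIN_ALT,
) -> pd.DataFrame:
    """Flag peaks passing the aggregate count filters (strict inequalities).

    ``passes_filter`` is true iff ref+alt > min_total AND ref > min_ref AND
    alt > min_alt.
    """
    ref = totals["ref_total"].to_numpy()
    alt = totals["alt_total"].to_numpy()
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("negative allele counts")
    out = totals.copy()
    out["passes_filter"] = (ref + alt > min_total) & (ref > min_ref) & (alt > min_alt)
    return out


def binomial_asca(ref_total: int, alt_total: int) -> float:
    """Two-sided exact binomial p-value of (ref, alt) against proportion 1/2.

    Uses the minimum-likelihood tail (outcomes no more probable than the one
    observed), so the result is symmetric in its arguments.
    """
    n = int(ref_total) + int(alt_total)
    if n <= 0:
        raise ValueError("zero trials: ref_total + alt_total must be > 0")
    return float(binomtest(int(alt_total), n, 0.5, alternative="two-sided").pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def asca_table(totals: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Full ASCA result table from per-peak totals.

    Applies the count filters, computes the exact binomial p-value per
    passing peak and BH-adjusts across them.  Peaks failing the filter are
    retained with NaN p-values so the screen is auditable.
    """
    out = filter_peak_counts(totals)
    ref = out["ref_total"].to_numpy()
    alt = out["alt_total"].to_numpy()
    with np.errstate(invalid="ignore"):
        out["alt_fraction"] = np.where(
            ref + alt > 0, alt / np.maximum(ref + alt, 1), np.nan
        )
    pvals = np.full(len(out), np.nan)
    mask = out["passes_filter"].to_numpy()
    pvals[mask] = [binomial_asca(r, a) for r, a in zip(ref[mask], alt[mask])]
    out["p_value"] = pvals
    padj = np.full(len(out), np.nan)
    if mask.any():
        padj[mask] = bh_adjust(pvals[mask])
    out["p_adjusted"] = padj
    out["significant"] = (out["p_adjusted"] < alpha).fillna(False)
    return out
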