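"""Haplotype assignment of fragments and per-cell, per-peak allele counts.

Each fragment overlapping one or more phased heterozygous SNVs is assigned to
a haplotype from the bases it reports at those positions.  Assignment uses
haplotype consistency, not majority vote: every informative base implies a
haplotype (the one carrying that base under the phase), and a fragment is
called only when all implied haplotypes agree AND all markers agree on the
ref/alt label; any inconsistency yields ``ambiguous`` and the fragment is
excluded downstream.  A fragment is one Bernoulli observation regardless of
its read-pair support, so PCR duplicates are never double-counted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .overlap import overlap_join

CALL_ORDER = ["ref", "alt", "other", "ambiguous"]
DEFAULT_MIN_BASE_QUALITY = 20

_FRAG_KEY = ["chrom", "start", "end", "barcode"]


def _annotate_votes(obs: pd.DataFrame, variants: pd.DataFrame) -> pd.DataFrame:
    """Join observations to variants on (chrom, pos) and derive votes.

    Adds ``label`` in {ref, alt, other} and ``hap`` (implied haplotype for
    base-matching votes, -1 for 'other').  An observation at a position with
    no phased-het variant is a caller bug and raises.
    """
    merged = obs.merge(
        variants[["chrom", "pos", "ref_allele", "alt_allele", "hap_of_alt"]],
        on=["chrom", "pos"], how="left", validate="many_to_one",
    )
    if merged["ref_allele"].isna().any():
        bad = merged[merged["ref_allele"].isna()].iloc[0]
        raise ValueError(
            f"base observation at {bad['chrom']}:{bad['pos']} has no variant "
            "in the analysis set"
        )
    base = merged["base"].to_numpy(str)
    is_ref = base == merged["ref_allele"].to_numpy(str)
    is_alt = base == merged["alt_allele"].to_numpy(str)
    hap_of_alt = merged["hap_of_alt"].to_numpy(int)
    merged["label"] = np.where(is_ref, "ref", np.where(is_alt, "alt", "other"))
    merged["hap"] = np.where(
        is_alt, hap_of_alt, np.where(is_ref, 1 - hap_of_alt, -1)
    )
    return merged


def call_alleles(
    obs: pd.DataFrame,
    variants: pd.DataFrame,
    min_base_quality: float = DEFAULT_MIN_BASE_QUALITY,
) -> pd.DataFrame:
    """Per-fragment allele calls from base observations.

    Parameters
    ----------
    obs
        Base-observation table (io.BASEOBS_COLUMNS); one row per
        (fragment, variant) overlap with the observed base and quality.
    variants
        Phased heterozygous SNV table (the analysis set).
    min_base_quality
        Observations below this phred score are dropped before voting.

    Returns
    -------
    DataFrame keyed by fragment (chrom, start, end, barcode) with a ``call``
    column in {ref, alt, other, ambiguous}.  Fragments whose observations
    were all below the quality cutoff are absent.
    """
    obs = obs[obs["qual"] >= min_base_quality]
    if obs.empty:
        return pd.DataFrame(columns=_FRAG_KEY + ["call"])
    votes = _annotate_votes(obs, variants)

    # numeric encodings keep the per-fragment aggregation in cython:
    # a fragment is consistent iff its base-matching votes agree on both the
    # implied haplotype and the ref/alt label (min == max for each).
    is_base = (votes["label"] != "other").to_numpy()
    votes["label_code"] = np.where(votes["label"] == "alt", 1, 0)
    votes["hap_w"] = np.where(is_base, votes["hap"], np.nan)
    votes["label_w"] = np.where(is_base, votes["label_code"], np.nan)

    agg = votes.groupby(_FRAG_KEY, sort=True).agg(
        hap_min=("hap_w", "min"),
        hap_max=("hap_w", "max"),
        label_min=("label_w", "min"),
        label_max=("label_w", "max"),
    )
    no_base = agg["hap_min"].isna()
    consistent = (agg["hap_min"] == agg["hap_max"]) & (
        agg["label_min"] == agg["label_max"]
    )
    call = np.where(
        no_base,
        "other",
        np.where(
            consistent & ~no_base,
            np.where(agg["label_min"] == 1, "alt", "ref"),
            "ambiguous",
        ),
    )
    out = agg.reset_index()[_FRAG_KEY]
    out["call"] = call
    return out


def call_fragment_allele(
    obs: pd.DataFrame,
    variants: pd.DataFrame,
    min_base_quality: float = DEFAULT_MIN_BASE_QUALITY,
) -> str:
    """Allele call for the observations of a single fragment.

    Returns one of {ref, alt, other, ambiguous}, or ``none`` when every
    observation fell below the quality cutoff.
    """
    if obs[_FRAG_KEY].drop_duplicates().shape[0] > 1:
        raise ValueError("observations belong to more than one fragment")
    calls = call_alleles(obs, variants, min_base_quality)
    if calls.empty:
        return "none"
    return str(calls["call"].iloc[0])


def assign_to_peaks(calls: pd.DataFrame, peaks: pd.DataFrame) -> pd.DataFrame:
    """Expand fragment calls to one row per (fragment, overlapped peak).

    A fragment overlapping two abutting peaks appears twice, once with each
    ``peak_id``; fragments outside every peak are absent.
    """
    pairs = overlap_join(calls, peaks)
    assigned = calls.iloc[pairs["query_idx"]].reset_index(drop=True)
    assigned["peak_id"] = peaks["peak_id"].to_numpy()[pairs["subject_idx"]]
    return assigned


def count_alleles_per_peak(
    calls: pd.DataFrame,
    peaks: pd.DataFrame,
    meta: pd.DataFrame,
    *,
    return_stats: bool = False,
) -> pd.DataFrame:
    """Accumulate per-(peak, cell) ref/alt/other counts from fragment calls.

    A fragment contributes to every peak it overlaps by >=1 bp (abutting
    peaks can share a fragment; such events are tallied in the stats).
    Ambiguous calls are excluded; barcodes absent from ``meta`` are dropped
    with a count.  Output is sparse: (peak, cell) pairs with no informative
    fragment are absent.
    """
    stats = {
        "n_fragments": int(len(calls)),
        "n_ambiguous": int((calls["call"] == "ambiguous").sum()),
        "n_barcode_dropped": 0,
        "n_multi_peak_fragments": 0,
        "n_unassigned_to_peak": 0,
    }
    informative = calls[calls["call"] != "ambiguous"].reset_index(drop=True)
    known = informative["barcode"].isin(set(meta["barcode"]))
    stats["n_barcode_dropped"] = int((~known).sum())
    informative = informative[known].reset_index(drop=True)

    pairs = overlap_join(informative, peaks)
    hits_per_frag = np.bincount(pairs["query_idx"], minlength=len(informative))
    stats["n_multi_peak_fragments"] = int((hits_per_frag > 1).sum())
    stats["n_unassigned_to_peak"] = int((hits_per_frag == 0).sum())

    assigned = informative.iloc[pairs["query_idx"]].reset_index(drop=True)
    assigned["peak_id"] = peaks["peak_id"].to_numpy()[pairs["subject_idx"]]

    tab = (
        assigned.groupby(["peak_id", "barcode", "call"], sort=True)
        .size()
        .unstack("call", fill_value=0)
        .reindex(columns=["ref", "alt", "other"], fill_value=0)
        .reset_index()
    )
    tab.columns.name = None
    tab = tab.rename(
        columns={"ref": "ref_count", "alt": "alt_count", "other": "other_count"}
    )
    tab = tab.merge(meta[["barcode", "sample_id"]], on="barcode", how="left")
    tab = tab[["peak_id", "barcode", "sample_id", "ref_count", "alt_count", "other_count"]]
    return (tab, stats) if return_stats else tab


def aggregate_counts(
    per_cell: pd.DataFrame, cell_subset=None
) -> pd.DataFrame:
    """Aggregate per-cell counts to per-peak totals over a barcode subset.

    Returns per-peak (ref_total, alt_total, other_total, n_cells); an empty
    subset yields an empty frame.
    """
    sub = per_cell
    if cell_subset is not None:
        sub = per_cell[per_cell["barcode"].isin(set(cell_subset))]
    out = (
        sub.groupby("peak_id", sort=True)
        .agg(
            ref_total=("ref_count", "sum"),
            alt_total=("alt_count", "sum"),
            other_total=("other_count", "sum"),
            n_cells=("barcode", "nunique"),
        )
        .reset_index()
    )
    return out
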