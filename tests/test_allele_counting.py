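import itertools

import numpy as np
import pandas as pd
import pytest

from allelescope.allele_counting import (
    aggregate_counts,
    call_alleles,
    call_fragment_allele,
    count_alleles_per_peak,
)
from conftest import make_obs


def _two_snv_variants(hap1=1, hap2=1):
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "pos": [120, 160],
            "ref_allele": ["A", "C"],
            "alt_allele": ["G", "T"],
            "hap_of_alt": [hap1, hap2],
            "fs": [1.0, 1.0],
            "qd": [20.0, 20.0],
            "is_het": [True, True],
            "is_phased": [True, True],
        }
    )


class TestCallFragmentAllele:
    def test_single_snv_alt_base(self):
        obs = make_obs([("chr1", 100, 200, "bc1", 120, "G", 37.0)])
        assert call_fragment_allele(obs, _two_snv_variants()) == "alt"

    def test_low_quality_observation_dropped(self):
        obs = make_obs([("chr1", 100, 200, "bc1", 120, "G", 10.0)])
        assert call_fragment_allele(obs, _two_snv_variants(), 20) == "none"

    def test_non_matching_base_is_other(self):
        obs = make_obs([("chr1", 100, 200, "bc1", 120, "C", 37.0)])
        assert call_fragment_allele(obs, _two_snv_variants()) == "other"

    def test_observation_without_variant_is_a_caller_bug(self):
        obs = make_obs([("chr1", 100, 200, "bc1", 150, "A", 37.0)])
        with pytest.raises(ValueError, match="no variant"):
            call_fragment_allele(obs, _two_snv_variants())

    def test_two_snv_enumeration_matches_haplotype_oracle(self):
        """All 16 base combinations at two same-orientation phased SNVs.

        Oracle: a combination is called iff it matches exactly one haplotype
        sequence; informative but haplotype-inconsistent combinations are
        ambiguous.
        """
        variants = _two_snv_variants(hap1=1, hap2=1)
        # haplotype 1 carries both alts, haplotype 0 both refs
        hap_seq = {0: ("A", "C"), 1: ("G", "T")}
        for b1, b2 in itertools.product("ACGT", repeat=2):
            obs = make_obs(
                [
                    ("chr1", 100, 200, "bc1", 120, b1, 37.0),
                    ("chr1", 100, 200, "bc1", 160, b2, 37.0),
                ]
            )
            got = call_fragment_allele(obs, variants)
            informative = [
                (i, b) for i, b in enumerate((b1, b2)) if b in hap_seq[0][i] + hap_seq[1][i]
            ]
            matches = [
                h for h in (0, 1)
                if all(hap_seq[h][i] == b for i, b in informative)
            ]
            if not informative:
                expected = "other"
            elif len(matches) == 1:
                expected = "alt" if matches[0] == 1 else "ref"
            else:
                expected = "ambiguous"
            assert got == expected, (b1, b2)

    def test_mixed_orientation_consistent_hap_is_ambiguous(self):
        # alt of SNV1 on hap 1, alt of SNV2 on hap 0: a fragment from hap 1
        # carries alt at SNV1 and ref at SNV2 -- haplotype-resolved but with
        # no single ref/alt label, so it is excluded as ambiguous
        variants = _two_snv_variants(hap1=1, hap2=0)
        obs = make_obs(
            [
                ("chr1", 100, 200, "bc1", 120, "G", 37.0),
                ("chr1", 100, 200, "bc1", 160, "C", 37.0),
            ]
        )
        assert call_fragment_allele(obs, variants) == "ambiguous"


def _meta(barcodes):
    return pd.DataFrame(
        {
            "barcode": barcodes,
            "sample_id": ["s1"] * len(barcodes),
            "cell_type": ["PT"] * len(barcodes),
            "condition": ["control"] * len(barcodes),
        }
    )


class TestCounting:
    peaks = pd.DataFrame(
        {"chrom": ["chr1"], "start": [100], "end": [300], "peak_id": ["pk1"]}
    )

    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "call"])

    def test_counts_partition_by_call(self):
        calls = self._calls(
            [
                ("chr1", 110, 200, "bc1", "ref"),
                ("chr1", 120, 210, "bc1", "alt"),
                ("chr1", 130, 220, "bc1", "alt"),
            ]
        )
        tab = count_alleles_per_peak(calls, self.peaks, _meta(["bc1"]))
        assert len(tab) == 1
        row = tab.iloc[0]
        assert (row.ref_count, row.alt_count, row.other_count) == (1, 2, 0)

    def test_fragment_spanning_two_peaks_counts_in_both(self):
        peaks = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [100, 200],
                "end": [200, 300],
                "peak_id": ["pk1", "pk2"],
            }
        )
        calls = self._calls([("chr1", 190, 210, "bc1", "alt")])
        tab, stats = count_alleles_per_peak(
            calls, peaks, _meta(["bc1"]), return_stats=True
        )
        assert sorted(tab["peak_id"]) == ["pk1", "pk2"]
        assert stats["n_multi_peak_fragments"] == 1

    def test_ambiguous_and_unknown_barcodes_excluded(self):
        calls = self._calls(
            [
                ("chr1", 110, 200, "bc1", "ambiguous"),
                ("chr1", 110, 200, "bcX", "alt"),
            ]
        )
        tab, stats = count_alleles_per_peak(
            calls, self.peaks, _meta(["bc1"]), return_stats=True
        )
        assert len(tab) == 0  # sparse contract: nothing informative remains
        assert stats["n_ambiguous"] == 1
        assert stats["n_barcode_dropped"] == 1

    def test_aggregate_totals_and_conservation(self):
        per_cell = pd.DataFrame(
            {
                "peak_id": ["pk1", "pk1"],
                "barcode": ["bc1", "bc2"],
                "sample_id": ["s1", "s1"],
                "ref_count": [1, 4],
                "alt_count": [2, 0],
                "other_count": [0, 0],
            }
        )
        tot = aggregate_counts(per_cell)
        assert (tot.iloc[0].ref_total, tot.iloc[0].alt_total) == (5, 2)
        assert tot.iloc[0].n_cells == 2
        # partition conservation
        a = aggregate_counts(per_cell, {"bc1"})
        b = aggregate_counts(per_cell, {"bc2"})
        assert a["ref_total"].sum() + b["ref_total"].sum() == 5
        assert aggregate_counts(per_cell, set())["ref_total"].sum() == 0


# ---------------------------------------------------------------------------
# randomized exhaustive oracle


def oracle_instance(seed, max_fragments=50):
    """Random small instance plus a brute-force per-triple oracle result."""
    rng = np.random.default_rng(seed)
    n_peaks = rng.integers(1, 5)
    starts = np.sort(rng.choice(np.arange(10, 400, 10), size=n_peaks, replace=False))
    peaks = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + rng.integers(20, 80, size=n_peaks),
            "peak_id": [f"pk{i}" for i in range(n_peaks)],
        }
    )
    n_var = rng.integers(1, 6)
    vpos = np.sort(rng.choice(np.arange(0, 500), size=n_var, replace=False))
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, n_var)
    alt = (ref + rng.integers(1, 4, n_var)) % 4
    variants = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": vpos,
            "ref_allele": bases[ref],
            "alt_allele": bases[alt],
            "hap_of_alt": rng.integers(0, 2, n_var),
            "fs": 1.0,
            "qd": 20.0,
            "is_het": True,
            "is_phased": True,
        }
    )
    n_frag = rng.integers(1, max_fragments + 1)
    barcodes = [f"bc{i}" for i in rng.integers(0, 6, n_frag)]
    f_start = rng.integers(0, 450, n_frag)
    f_end = f_start + rng.integers(10, 120, n_frag)
    # unique fragment keys (collisions would merge observations)
    frags = pd.DataFrame(
        {"chrom": "chr1", "start": f_start, "end": f_end, "barcode": barcodes}
    ).drop_duplicates(["chrom", "start", "end", "barcode"]).reset_index(drop=True)

    obs_rows = []
    for frow in frags.itertuples(index=False):
        for vrow in variants.itertuples(index=False):
            if frow.start <= vrow.pos < frow.end:
                b = rng.choice(bases) if rng.random() < 0.2 else (
                    vrow.alt_allele if rng.random() < 0.5 else vrow.ref_allele
                )
                q = 37.0 if rng.random() < 0.9 else 10.0
                obs_rows.append(
                    (frow.chrom, frow.start, frow.end, frow.barcode, vrow.pos, b, q)
                )
    obs = make_obs(obs_rows)
    return frags, peaks, variants, obs


def oracle_counts(frags, peaks, variants, obs, minq=20):
    """Independent nested-loop reimplementation of calling and counting."""
    varmap = {row.pos: row for row in variants.itertuples(index=False)}
    calls = {}
    for frow in frags.itertuples(index=False):
        key = (frow.chrom, frow.start, frow.end, frow.barcode)
        votes = []
        sub = obs[
            (obs["start"] == frow.start)
            & (obs["end"] == frow.end)
            & (obs["barcode"] == frow.barcode)
        ]
        for o in sub.itertuples(index=False):
            if o.qual < minq:
                continue
            v = varmap[o.pos]
            if o.base == v.ref_allele:
                votes.append(("ref", 1 - v.hap_of_alt))
            elif o.base == v.alt_allele:
                votes.append(("alt", v.hap_of_alt))
            else:
                votes.append(("other", None))
        base_votes = [v for v in votes if v[0] != "other"]
        if not votes:
            continue
        if not base_votes:
            calls[key] = "other"
        elif (
            len({h for _, h in base_votes}) == 1
            and len({l for l, _ in base_votes}) == 1
        ):
            calls[key] = base_votes[0][0]
        else:
            calls[key] = "ambiguous"
    counts = {}
    for key, call in calls.items():
        if call == "ambiguous":
            continue
        chrom, s, e, bc = key
        for prow in peaks.itertuples(index=False):
            if s < prow.end and prow.start < e:
                k = (prow.peak_id, bc)
                c = counts.setdefault(k, [0, 0, 0])
                c[["ref", "alt", "other"].index(call)] += 1
    return calls, counts


@pytest.mark.parametrize("seed_block", range(10))
def test_counting_matches_exhaustive_oracle(seed_block):
    for seed in range(seed_block * 30, seed_block * 30 + 30):
        frags, peaks, variants, obs = oracle_instance(seed)
        if obs.empty:
            continue
        expected_calls, expected_counts = oracle_counts(frags, peaks, variants, obs)
        got = call_alleles(obs, variants)
        got_calls = {
            (r.chrom, r.start, r.end, r.barcode): r.call
            for r in got.itertuples(index=False)
        }
        assert got_calls == expected_calls, f"seed {seed}"
        meta = _meta(sorted(set(frags["barcode"])))
        tab = count_alleles_per_peak(got, peaks, meta)
        got_counts = {
            (r.peak_id, r.barcode): [r.ref_count, r.alt_count, r.other_count]
            for r in tab.itertuples(index=False)
        }
        assert got_counts == expected_counts, f"seed {seed}"


def test_haplotype_relabeling_swaps_ref_and_alt():
    """Swapping ref/alt alleles and hap_of_alt on every variant must swap
    ref_count and alt_count exactly."""
    frags, peaks, variants, obs = oracle_instance(12345)
    if obs.empty:
        pytest.skip("degenerate instance")
    meta = _meta(sorted(set(frags["barcode"])))
    tab1 = count_alleles_per_peak(call_alleles(obs, variants), peaks, meta)
    swapped = variants.copy()
    swapped["ref_allele"] = variants["alt_allele"]
    swapped["alt_allele"] = variants["ref_allele"]
    swapped["hap_of_alt"] = 1 - variants["hap_of_alt"]
    tab2 = count_alleles_per_peak(call_alleles(obs, swapped), peaks, meta)
    merged = tab1.merge(tab2, on=["peak_id", "barcode"], suffixes=("_1", "_2"))
    assert len(merged) == len(tab1) == len(tab2)
    assert (merged["ref_count_1"] == merged["alt_count_2"]).all()
    assert (merged["alt_count_1"] == merged["ref_count_2"]).all()
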