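import numpy as np
import pandas as pd
import pytest

from allelescope import io as asio
from allelescope.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared across tests."""
    cfg = SimConfig(
        seed=20240101, n_samples=6, n_cells_per_sample=60, n_peaks=80,
        n_genes=40, coverage_mean=0.4, link_strength=1.0,
        beta_expr_mean=0.02, beta_expr_sd=0.005,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def variants_frame():
    """Hand-built variant table covering het/hom and phased/unphased cases."""
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "pos": [100, 200, 300, 400],
            "ref_allele": ["A", "C", "G", "T"],
            "alt_allele": ["G", "T", "A", "C"],
            "hap_of_alt": [1, 0, -1, -1],
            "fs": [1.0, 2.0, np.nan, 4.0],
            "qd": [20.0, 25.0, 30.0, np.nan],
            "is_het": [True, True, True, False],
            "is_phased": [True, True, False, False],
        }
    )


def make_obs(rows):
    """Rows of (chrom, start, end, barcode, pos, base, qual)."""
    return pd.DataFrame(rows, columns=asio.BASEOBS_COLUMNS)
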