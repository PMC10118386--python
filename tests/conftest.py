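import numpy as np
import pandas as pd
import pytest

from telosig.io_core import (CANONICAL_COLUMN_MAP, LDMatrix, SummaryStats,
                             write_ld_matrix, write_sumstats)


def make_sumstats(n=10, seed=0, trait_label="trait", trait_type="quantitative",
                  chrom="1", start_pos=1_000_000, spacing=10_000):
    """Small synthetic SummaryStats with well-behaved fields."""
    rng = np.random.default_rng(seed)
    # A/G only: non-palindromic by construction (tests override as needed)
    alleles = np.full(n, "A"), np.full(n, "G")
    tab = pd.DataFrame({
        "variant_id": [f"rs{i + 1}" for i in range(n)],
        "chrom": chrom,
        "pos": start_pos + np.arange(n) * spacing,
        "effect_allele": alleles[0],
        "other_allele": alleles[1],
        "eaf": rng.uniform(0.05, 0.95, n),
        "beta": rng.normal(0, 0.05, n),
        "se": rng.uniform(0.005, 0.02, n),
        "pval": rng.uniform(1e-12, 0.9, n),
        "n": 50_000.0,
        "n_cases": np.nan,
        "n_controls": np.nan,
    })
    if trait_type == "case-control":
        tab["n_cases"] = 20_000.0
        tab["n_controls"] = 30_000.0
    return SummaryStats(trait_label, tab, trait_type=trait_type)


@pytest.fixture
def toy_sumstats():
    return make_sumstats(n=10, seed=1)


@pytest.fixture
def identity_ld():
    def _make(ids):
        return LDMatrix(list(ids), np.eye(len(ids)))
    return _make


@pytest.fixture
def tmp_sumstats_file(tmp_path):
    def _write(ss, name="ss.tsv"):
        path = tmp_path / name
        write_sumstats(ss, path)
        return path, CANONICAL_COLUMN_MAP
    return _write


@pytest.fixture
def tmp_ld_file(tmp_path):
    def _write(ld, name="ld.tsv"):
        path = tmp_path / name
        write_ld_matrix(ld, path)
        return path
    return _write
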