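import numpy as np
import pandas as pd
import pytest

from sexmr.sumstats import HarmonizedInstruments, SumstatTable


def make_table(
    snps,
    beta,
    se,
    pvalue=None,
    ea="A",
    oa="G",
    n=100_000,
    stratum="combined",
    trait_label="trait",
):
    """Build a SumstatTable from vectors (single-letter alleles broadcast)."""
    m = len(snps)
    if pvalue is None:
        from scipy import stats

        pvalue = 2 * stats.norm.sf(np.abs(np.asarray(beta) / np.asarray(se)))
    ea = [ea] * m if isinstance(ea, str) else list(ea)
    oa = [oa] * m if isinstance(oa, str) else list(oa)
    return SumstatTable(
        records=pd.DataFrame(
            {
                "snp": list(snps),
                "chr": "1",
                "pos": np.arange(1, m + 1),
                "effect_allele": ea,
                "other_allele": oa,
                "beta": np.asarray(beta, dtype=float),
                "se": np.asarray(se, dtype=float),
                "pvalue": np.asarray(pvalue, dtype=float),
                "n": n,
            }
        ),
        trait_label=trait_label,
        stratum=stratum,
    )


def make_harmonized(beta_x, se_y, beta_y, se_x=None, pvalue_y=None, snps=None):
    """Build a HarmonizedInstruments set directly from effect vectors."""
    k = len(beta_x)
    if se_x is None:
        se_x = np.full(k, 0.01)
    if pvalue_y is None:
        from scipy import stats

        pvalue_y = 2 * stats.norm.sf(np.abs(np.asarray(beta_y) / np.asarray(se_y)))
    if snps is None:
        snps = [f"rs{i}" for i in range(k)]
    return HarmonizedInstruments(
        pd.DataFrame(
            {
                "snp": snps,
                "beta_x": np.asarray(beta_x, dtype=float),
                "se_x": np.asarray(se_x, dtype=float),
                "beta_y": np.asarray(beta_y, dtype=float),
                "se_y": np.asarray(se_y, dtype=float),
                "pvalue_y": np.asarray(pvalue_y, dtype=float),
            }
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
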