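"""Per-instrument sex heterogeneity and between-stratum effect correlation.

For a SNP with independent female and male effect estimates, the two-group
Cochran's Q statistic reduces to the squared z of the effect difference,

    Q = (beta_f - beta_m)^2 / (se_f^2 + se_m^2),   df = 1,

with heterogeneity quantified by I^2 = max(0, (Q - 1)/Q) * 100. A Bonferroni
screen across the tested instruments flags SNPs with significant sex
heterogeneity. The Pearson correlation of instrument effects between strata
summarizes marginal genetic sharing; a leave-one-out jackknife Wald test is
provided for the null that the correlation equals one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from sexmr.sumstats import InstrumentSet, SumstatTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SexHetResult:
    """Cochran's Q sex-heterogeneity test for one SNP (df = 1)."""

    snp_id: str
    q: float
    pvalue: float
    pvalue_bonf: float
    i2: float  # percent, in [0, 100]


@dataclass(frozen=True)
class EffectCorrelation:
    """Pearson correlation of instrument effects between two strata.

    ``p_vs_zero`` tests H0: r = 0 (t statistic); ``p_vs_one`` tests
    H0: r = 1 with a Wald statistic using the leave-one-out jackknife
    standard error of r (Fisher's z is undefined at r = 1).
    """

    r: float
    n_snps: int
    p_vs_zero: float
    p_vs_one: float
    se_jackknife: float


def cochran_q_sex(
    beta_f: float,
    se_f: float,
    beta_m: float,
    se_m: float,
    snp_id: str = "",
    n_tests: int = 1,
) -> SexHetResult:
    """Two-group Cochran's Q test of a sex difference in SNP effect.

    ``n_tests`` is the number of SNPs screened, used for the Bonferroni
    adjustment ``pvalue_bonf = min(1, pvalue * n_tests)``.
    """
    if se_f <= 0 or se_m <= 0:
        raise ValueError("standard errors must be strictly positive")
    q = (beta_f - beta_m) ** 2 / (se_f**2 + se_m**2)
    pvalue = float(stats.chi2.sf(q, df=1))
    i2 = max(0.0, (q - 1.0) / q) * 100.0 if q > 0 else 0.0
    return SexHetResult(
        snp_id=snp_id,
        q=float(q),
        pvalue=pvalue,
        pvalue_bonf=min(1.0, pvalue * n_tests),
        i2=float(i2),
    )


def screen_heterogeneity(
    female: SumstatTable,
    male: SumstatTable,
    ivs: InstrumentSet,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Cochran's Q screen across an instrument set.

    Returns a per-SNP DataFrame (input order preserved) with columns
    ``snp, beta_f, se_f, beta_m, se_m, q, pvalue, pvalue_bonf, i2, flagged``
    and the list of flagged SNP ids (Bonferroni-adjusted p below ``alpha``).
    Raises if an instrument is missing from either stratum.
    """
    f = female.records.set_index("snp")
    m = male.records.set_index("snp")
    for snp in ivs.snp_ids:
        if snp not in f.index:
            raise KeyError(f"instrument {snp} missing from the female-stratum table")
        if snp not in m.index:
            raise KeyError(f"instrument {snp} missing from the male-stratum table")
    n_tests = len(ivs)
    rows = []
    for snp in ivs.snp_ids:
        res = cochran_q_sex(
            float(f.loc[snp, "beta"]),
            float(f.loc[snp, "se"]),
            float(m.loc[snp, "beta"]),
            float(m.loc[snp, "se"]),
            snp_id=snp,
            n_tests=n_tests,
        )
        rows.append(
            {
                "snp": snp,
                "beta_f": float(f.loc[snp, "beta"]),
                "se_f": float(f.loc[snp, "se"]),
                "beta_m": float(m.loc[snp, "beta"]),
                "se_m": float(m.loc[snp, "se"]),
                "q": res.q,
                "pvalue": res.pvalue,
                "pvalue_bonf": res.pvalue_bonf,
                "i2": res.i2,
            }
        )
    df = pd.DataFrame(rows)
    df["flagged"] = df["pvalue_bonf"] < alpha
    flagged = list(df.loc[df["flagged"], "snp"])
    logger.info(
        "heterogeneity screen: %d of %d instruments flagged at Bonferroni alpha=%g",
        len(flagged),
        n_tests,
        alpha,
    )
    return df, flagged


def pearson_effect_correlation(
    beta_a: np.ndarray, beta_b: np.ndarray
) -> EffectCorrelation:
    """Pearson correlation of two effect-size vectors with tests vs 0 and 1.

    Requires equal lengths >= 3 and nonzero variance in each vector. The
    test against r = 0 uses the usual t statistic; the test against r = 1
    uses (r - 1) / se_jack with the leave-one-out jackknife SE of r.
    """
    a = np.asarray(beta_a, dtype=float)
    b = np.asarray(beta_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    n = a.size
    if n < 3:
        raise ValueError("at least 3 SNPs are required for a correlation")
    if np.isclose(a.std(), 0) or np.isclose(b.std(), 0):
        raise ValueError("zero variance in an effect vector")

    r, p_vs_zero = stats.pearsonr(a, b)
    r = float(np.clip(r, -1.0, 1.0))

    # Leave-one-out jackknife SE of r.
    idx = np.arange(n)
    loo = np.empty(n)
    for i in range(n):
        keep = idx != i
        loo[i] = stats.pearsonr(a[keep], b[keep])[0]
    se_jack = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
    if se_jack > 0:
        z = (r - 1.0) / se_jack
        p_vs_one = float(2 * stats.norm.sf(abs(z)))
    else:
        # Degenerate (e.g. exactly collinear data): the jackknife carries no
        # information; report 1 when r is exactly 1, else NaN.
        p_vs_one = 1.0 if r == 1.0 else float("nan")
    return EffectCorrelation(
        r=r,
        n_snps=n,
        p_vs_zero=float(p_vs_zero),
        p_vs_one=p_vs_one,
        se_jackknife=se_jack,
    )
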