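"""Formal comparison of sex-combined and sex-specific causal estimates.

The two estimates share instruments and outcome data, so they are strongly
correlated; the comparison statistic

    u = (theta_c - theta_s) / sqrt(se_c^2 + se_s^2 - 2 rho se_c se_s)

is asymptotically standard normal under H0: theta_combined = theta_specific.
The correlation rho is estimated by a paired leave-one-instrument-out
jackknife: each instrument in the union of the two sets is removed in turn,
both causal effects are recomputed, and rho is the Pearson correlation of
the paired series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from sexmr.estimators import ESTIMATORS, MREstimate, ivw_fixed
from sexmr.sumstats import (
    HarmonizedInstruments,
    InstrumentSet,
    SumstatTable,
    harmonize,
    qc_filter_outcome_associated,
)

logger = logging.getLogger(__name__)


class DegenerateComparisonError(ValueError):
    """The u-test denominator is non-positive (rho ~ 1 with equal SEs)."""


@dataclass(frozen=True)
class ComparisonResult:
    """Result of the u-test comparing two correlated causal estimates."""

    u: float
    pvalue: float
    rho: float
    theta_combined: float
    theta_specific: float
    se_combined: float
    se_specific: float
    n_jackknife: int = 0


def u_test(
    est_combined: MREstimate,
    est_specific: MREstimate,
    rho: float,
    n_jackknife: int = 0,
) -> ComparisonResult:
    """Test H0: theta_combined = theta_specific given their correlation rho."""
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [-1, 1], got {rho}")
    se_c, se_s = est_combined.se, est_specific.se
    denom2 = se_c**2 + se_s**2 - 2.0 * rho * se_c * se_s
    if denom2 <= 0:
        raise DegenerateComparisonError(
            "non-positive u-test variance (rho close to 1 with equal SEs); "
            "the two estimates are statistically indistinguishable — consider "
            "more instruments or an intersection-only jackknife"
        )
    u = (est_combined.theta - est_specific.theta) / np.sqrt(denom2)
    return ComparisonResult(
        u=float(u),
        pvalue=float(2 * stats.norm.sf(abs(u))),
        rho=float(rho),
        theta_combined=est_combined.theta,
        theta_specific=est_specific.theta,
        se_combined=se_c,
        se_specific=se_s,
        n_jackknife=n_jackknife,
    )


def jackknife_rho(
    h_combined: HarmonizedInstruments,
    h_specific: HarmonizedInstruments,
    estimator: str | Callable[[HarmonizedInstruments], MREstimate] = "ivw_fixed",
    intersection_only: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Correlation of the two estimates via a paired leave-one-out jackknife.

    Iterates over the union of the two instrument sets (or the intersection
    when ``intersection_only``): for each SNP the combined and specific
    effects are recomputed with that SNP excluded from whichever set(s)
    contain it; a set not containing the SNP contributes its full-set
    estimate for that pair. Returns the clamped Pearson correlation and the
    paired jackknife series for audit.
    """
    fn = ESTIMATORS[estimator] if isinstance(estimator, str) else estimator
    ids_c = list(h_combined.data["snp"])
    ids_s = list(h_specific.data["snp"])
    if intersection_only:
        ids = [s for s in ids_c if s in set(ids_s)]
    else:
        ids = ids_c + [s for s in ids_s if s not in set(ids_c)]
    if len(ids) < 3:
        raise ValueError("need at least 3 instruments in the union for a jackknife rho")
    if min(len(ids_c), len(ids_s)) < 2:
        raise ValueError("each instrument set needs at least 2 members")

    full_c = fn(h_combined).theta
    full_s = fn(h_specific).theta
    set_c, set_s = set(ids_c), set(ids_s)
    rows = []
    for snp in ids:
        tc = fn(h_combined.drop(snp)).theta if snp in set_c else full_c
        ts = fn(h_specific.drop(snp)).theta if snp in set_s else full_s
        rows.append({"snp": snp, "theta_combined": tc, "theta_specific": ts})
    series = pd.DataFrame(rows)
    tc = series["theta_combined"].to_numpy()
    ts = series["theta_specific"].to_numpy()
    if np.isclose(tc.std(), 0) or np.isclose(ts.std(), 0):
        raise ValueError(
            "constant jackknife series; rho is undefined — more instruments needed"
        )
    rho = float(stats.pearsonr(tc, ts)[0])
    if not -1.0 <= rho <= 1.0:
        logger.info("jackknife rho %.17g clamped to [-1, 1]", rho)
        rho = float(np.clip(rho, -1.0, 1.0))
    return rho, series


def compare_pipeline(
    exposure_combined: SumstatTable,
    exposure_specific: SumstatTable,
    outcome: SumstatTable,
    ivs_combined: InstrumentSet,
    ivs_specific: InstrumentSet,
    estimator: str = "ivw_fixed",
    qc_alpha: float = 0.05,
    intersection_only: bool = False,
    outdir: str | Path | None = None,
) -> ComparisonResult:
    """End-to-end comparison of sex-combined vs sex-specific causal effects.

    Harmonizes and QC-filters each instrument set against the common
    outcome, estimates both causal effects with the configured estimator,
    estimates rho by the paired jackknife (always with the same estimator),
    and applies the u-test. When ``outdir`` is given, intermediate artifacts
    (per-side estimates, jackknife series, result row) are written as TSV.
    """
    results: dict[str, HarmonizedInstruments] = {}
    for label, exposure, ivs in (
        ("combined", exposure_combined, ivs_combined),
        ("specific", exposure_specific, ivs_specific),
    ):
        try:
            h = harmonize(exposure, outcome, ivs)
            results[label] = qc_filter_outcome_associated(h, alpha=qc_alpha)
        except Exception as exc:
            raise type(exc)(f"[{label} arm] {exc}") from exc

    fn = ESTIMATORS[estimator]
    est_c = fn(results["combined"])
    est_s = fn(results["specific"])
    rho, series = jackknife_rho(
        results["combined"],
        results["specific"],
        estimator=estimator,
        intersection_only=intersection_only,
    )
    result = u_test(est_c, est_s, rho, n_jackknife=len(series))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        series.to_csv(outdir / "jackknife_series.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "arm": label,
                    "method": est.method,
                    "k": est.k,
                    "theta": est.theta,
                    "se": est.se,
                    "or": est.odds_ratio,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "pvalue": est.pvalue,
                }
                for label, est in (("combined", est_c), ("specific", est_s))
            ]
        ).to_csv(outdir / "estimates.tsv", sep="\t", index=False)
        pd.DataFrame([result.__dict__]).to_csv(
            outdir / "comparison.tsv", sep="\t", index=False
        )
    return result
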