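"""Synthetic GWAS summary statistics with planted, auditable structure.

Complementary to the individual-level simulator in :mod:`sexmr.simulate`,
this generator works directly at the summary-statistics level and plants
records with known properties so that every pipeline stage can be asserted
against ground truth: sex-concordant ("clean") instruments, instruments with
a prescribed sex-difference z-score (exercising the heterogeneity screen),
instruments directly associated with the outcome (exercising the Bonferroni
QC filter), outcome records with swapped alleles (harmonization must flip
signs) and with inconsistent alleles (harmonization must exclude), all tied
to a known true causal effect.

Observed sex-specific effects are constructed so that the female-male
difference z-score is exactly the configured value — flag counts downstream
are then deterministic, not merely probable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from sexmr.simulate import meta_fixed
from sexmr.sumstats import InstrumentSet, SumstatTable, write_sumstats

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


@dataclass(frozen=True)
class SyntheticConfig:
    """Composition of the planted instrument panel.

    ``n_clean`` concordant instruments (sex-difference z within
    ``clean_z_max``), ``n_het`` sex-heterogeneous instruments at exactly
    ``het_z``, ``n_outcome_assoc`` instruments with a direct outcome effect
    (outcome z = ``outcome_assoc_z``), ``n_swapped`` outcome records stored
    on the flipped allele (equivalent encoding) and ``n_mismatched`` outcome
    records with alleles inconsistent with the exposure. ``theta`` is the
    true causal effect (log-odds per SD); ``se_y`` controls the outcome
    noise scale and is chosen so the causal path alone does not trip the
    outcome-association QC filter.
    """

    n_clean: int = 30
    n_het: int = 0
    n_outcome_assoc: int = 0
    n_swapped: int = 0
    n_mismatched: int = 0
    theta: float = 0.3
    het_z: float = 8.0
    clean_z_max: float = 1.0
    outcome_assoc_z: float = 10.0
    n_female: int = 100_000
    n_male: int = 100_000
    n_outcome: int = 200_000
    se_y: float = 0.01
    beta_range: tuple[float, float] = (0.02, 0.06)

    def __post_init__(self) -> None:
        counts = (
            self.n_clean,
            self.n_het,
            self.n_outcome_assoc,
            self.n_swapped,
            self.n_mismatched,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all record counts must be non-negative")
        if self.n_clean + self.n_het == 0:
            raise ValueError("need at least one clean or heterogeneous instrument")
        if self.n_swapped + self.n_mismatched > self.total_snps:
            raise ValueError("more swapped/mismatched records than SNPs")
        if self.het_z <= self.clean_z_max:
            raise ValueError("het_z must exceed clean_z_max to be distinguishable")
        if self.se_y <= 0:
            raise ValueError("se_y must be positive")

    @property
    def total_snps(self) -> int:
        return self.n_clean + self.n_het + self.n_outcome_assoc


@dataclass(frozen=True)
class SyntheticData:
    """Generated tables plus the truth record for assertions."""

    exposure_female: SumstatTable
    exposure_male: SumstatTable
    exposure_combined: SumstatTable
    outcome: SumstatTable
    instruments: InstrumentSet
    truth: pd.DataFrame


def generate_synthetic_sumstats(
    config: SyntheticConfig, seed: int = 0, outdir: str | Path | None = None
) -> SyntheticData:
    """Generate the full set of sex-stratified exposure and outcome tables.

    The truth DataFrame records, per SNP: its category, the underlying
    female/male effects, the planted sex-difference z, whether its outcome
    record is allele-swapped or mismatched, and whether it carries a direct
    outcome association. When ``outdir`` is given, all tables, the
    instrument list and the truth record are written as TSV/text.
    """
    rng = np.random.default_rng(seed)
    m = config.total_snps
    categories = (
        ["clean"] * config.n_clean
        + ["heterogeneous"] * config.n_het
        + ["outcome_associated"] * config.n_outcome_assoc
    )

    snps = [f"rs{900000 + j}" for j in range(m)]
    alleles = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(m)]
    se_f = np.full(m, 1.0 / np.sqrt(config.n_female))
    se_m = np.full(m, 1.0 / np.sqrt(config.n_male))

    lo, hi = config.beta_range
    base = rng.uniform(lo, hi, size=m) * rng.choice([-1.0, 1.0], size=m)
    # Plant the observed sex difference exactly: beta_f - beta_m = z * sqrt(se_f^2 + se_m^2)
    z_diff = np.where(
        np.asarray(categories) == "heterogeneous",
        config.het_z * rng.choice([-1.0, 1.0], size=m),
        rng.uniform(-config.clean_z_max, config.clean_z_max, size=m),
    )
    gap = z_diff * np.sqrt(se_f**2 + se_m**2)
    beta_f = base + gap / 2.0
    beta_m = base - gap / 2.0
    p_f = 2 * stats.norm.sf(np.abs(beta_f / se_f))
    p_m = 2 * stats.norm.sf(np.abs(beta_m / se_m))

    # Outcome: causal path through the female exposure plus planted direct effects.
    se_y = np.full(m, config.se_y)
    direct = np.where(
        np.asarray(categories) == "outcome_associated",
        config.outcome_assoc_z * se_y * rng.choice([-1.0, 1.0], size=m),
        0.0,
    )
    beta_y = config.theta * beta_f + direct + rng.normal(0.0, se_y)
    p_y = 2 * stats.norm.sf(np.abs(beta_y / se_y))

    def table(beta, se, p, n, stratum):
        return SumstatTable(
            records=pd.DataFrame(
                {
                    "snp": snps,
                    "chr": "1",
                    "pos": np.arange(1, m + 1) * 1000,
                    "effect_allele": [a for a, _ in alleles],
                    "other_allele": [b for _, b in alleles],
                    "beta": beta,
                    "se": se,
                    "pvalue": p,
                    "n": n,
                }
            ),
            trait_label="synthetic_exposure",
            stratum=stratum,
        )

    exp_f = table(beta_f, se_f, p_f, config.n_female, "female")
    exp_m = table(beta_m, se_m, p_m, config.n_male, "male")
    exp_c = meta_fixed(exp_f, exp_m)

    # Outcome table: re-encode some records (swap = equivalent, mismatch = broken).
    swapped = np.zeros(m, dtype=bool)
    mismatched = np.zeros(m, dtype=bool)
    reencode = rng.permutation(m)[: config.n_swapped + config.n_mismatched]
    swapped[reencode[: config.n_swapped]] = True
    mismatched[reencode[config.n_swapped :]] = True

    out_ea, out_oa, out_beta = [], [], []
    for j in range(m):
        ea, oa = alleles[j]
        if mismatched[j]:
            # Replace the other allele with a third base.
            third = next(b for b in "ACGT" if b not in (ea, oa))
            out_ea.append(ea)
            out_oa.append(third)
            out_beta.append(beta_y[j])
        elif swapped[j]:
            out_ea.append(oa)
            out_oa.append(ea)
            out_beta.append(-beta_y[j])
        else:
            out_ea.append(ea)
            out_oa.append(oa)
            out_beta.append(beta_y[j])
    outcome = SumstatTable(
        records=pd.DataFrame(
            {
                "snp": snps,
                "chr": "1",
                "pos": np.arange(1, m + 1) * 1000,
                "effect_allele": out_ea,
                "other_allele": out_oa,
                "beta": out_beta,
                "se": se_y,
                "pvalue": p_y,
                "n": config.n_outcome,
            }
        ),
        trait_label="synthetic_outcome",
        stratum="female",
    )

    instruments = InstrumentSet(
        snp_ids=tuple(snps), source_stratum="combined", selection_threshold=5e-8
    )
    truth = pd.DataFrame(
        {
            "snp": snps,
            "category": categories,
            "beta_f": beta_f,
            "beta_m": beta_m,
            "z_diff": z_diff,
            "beta_y_true": config.theta * beta_f + direct,
            "direct_outcome_effect": direct,
            "swapped_alleles": swapped,
            "mismatched_alleles": mismatched,
            "theta_true": config.theta,
        }
    )

    data = SyntheticData(
        exposure_female=exp_f,
        exposure_male=exp_m,
        exposure_combined=exp_c,
        outcome=outcome,
        instruments=instruments,
        truth=truth,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sumstats(exp_f, outdir / "exposure_female.tsv")
        write_sumstats(exp_m, outdir / "exposure_male.tsv")
        write_sumstats(exp_c, outdir / "exposure_combined.tsv")
        write_sumstats(outcome, outdir / "outcome.tsv")
        (outdir / "instruments.txt").write_text("\n".join(snps) + "\n")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return data
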