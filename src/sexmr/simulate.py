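"""Monte Carlo study of sex-combined-instrument bias in sex-specific MR.

Each replicate emulates a female-specific two-sample MR study from first
principles: m uncorrelated biallelic SNPs (m ~ U{50..150}) with MAFs
~ U(0.01, 0.50) are genotyped under Hardy-Weinberg equilibrium in
independent male and female cohorts (1e5 each); per-SNP effects
(alpha_male_j, alpha_female_j) are bivariate normal with unit variances and
inter-sex correlation r_g, rescaled per sex so that delta^2 sum(alpha^2) /
(delta^2 sum(alpha^2) + 1) equals the target phenotypic variance explained
(PVE); exposures are genetic value plus standard-normal noise and the
female-specific outcome is y = theta * x_female + eps. Single-SNP
regressions yield sex-specific exposure summary statistics, a fixed-effects
meta-analysis yields sex-combined ones, instruments are selected at
P < 0.05/m (falling back to the single smallest-P SNP), and the causal
effect is estimated by fixed-effects IVW with combined-selected and
female-selected instruments in turn. Averaged over replicates, the
combined-instrument estimate is biased whenever the male and female genetic
architectures differ; the female-instrument estimate is not.

Scale conventions (see docs/methods.md): by default genotypes enter the
phenotype as raw 0/1/2 dosages exactly as in the generating equations, so
the realized PVE is below the nominal target by the mean 2*maf*(1-maf)
factor; ``standardize_genotypes=True`` switches to unit-variance genotype
columns, under which the PVE bookkeeping is exact. By default the outcome
GWAS is run on an independent female cohort (``outcome_cohort =
"independent"``), the two-sample design the summary statistics emulate;
``"shared"`` reuses the exposure cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from sexmr.estimators import ivw_fixed
from sexmr.sumstats import HarmonizedInstruments, InstrumentSet, SumstatTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one simulation condition.

    Defaults are the study conditions of the bias experiment: 1e5
    individuals per sex, m ~ U{50..150} candidate SNPs, MAF ~ U(0.01, 0.50),
    male/female PVE 1%/3%, instrument selection at P < 0.05/m, 200
    replicates.
    """

    r_g: float = 0.5
    theta: float = 0.5
    pve_male: float = 0.01
    pve_female: float = 0.03
    n_male: int = 100_000
    n_female: int = 100_000
    m_range: tuple[int, int] = (50, 150)
    maf_range: tuple[float, float] = (0.01, 0.50)
    iv_alpha: float = 0.05  # per-replicate selection threshold is iv_alpha / m
    n_replicates: int = 200
    seed: int = 0
    standardize_genotypes: bool = False
    outcome_cohort: str = "independent"  # or "shared"

    def __post_init__(self) -> None:
        if not -1.0 <= self.r_g <= 1.0:
            raise ValueError("r_g must lie in [-1, 1]")
        if not (0 < self.pve_male < 1 and 0 < self.pve_female < 1):
            raise ValueError("PVEs must lie in (0, 1)")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.m_range[0] > self.m_range[1] or self.m_range[0] < 1:
            raise ValueError("invalid m_range")
        if self.outcome_cohort not in ("independent", "shared"):
            raise ValueError("outcome_cohort must be 'independent' or 'shared'")


@dataclass(frozen=True)
class ReplicateResult:
    """IVW estimates from one replicate, for each instrument strategy."""

    theta_hat_combined: float
    theta_hat_specific: float
    se_combined: float
    se_specific: float
    k_combined: int
    k_specific: int
    fallback_used_combined: bool
    fallback_used_specific: bool


@dataclass(frozen=True)
class ScenarioSummary:
    """Replicate-averaged bias of each instrument strategy."""

    mean_bias_combined: float
    mean_bias_specific: float
    mc_se_combined: float
    mc_se_specific: float
    n_replicates: int
    scenario: SimulationScenario
    replicates: pd.DataFrame = field(repr=False, default=None)


def draw_architecture(
    sc: SimulationScenario, rng: np.random.Generator
) -> tuple[int, np.ndarray, np.ndarray, np.ndarray]:
    """Draw the SNP panel: m, MAFs, and per-sex effect sizes.

    Effects are iid bivariate normal across SNPs with zero means, unit
    variances and correlation r_g between the male and female effect of the
    same SNP.
    """
    m = int(rng.integers(sc.m_range[0], sc.m_range[1] + 1))
    mafs = rng.uniform(sc.maf_range[0], sc.maf_range[1], size=m)
    if abs(sc.r_g) == 1.0:  # degenerate: effects perfectly (anti)correlated
        a = rng.standard_normal(m)
        return m, mafs, a, np.sign(sc.r_g) * a.copy()
    cov = np.array([[1.0, sc.r_g], [sc.r_g, 1.0]])
    eff = rng.multivariate_normal(np.zeros(2), cov, size=m, method="cholesky")
    return m, mafs, eff[:, 0].copy(), eff[:, 1].copy()


def simulate_genotypes(
    n: int, mafs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """n x m genotype dosages under HWE and linkage equilibrium.

    Column j is Binomial(2, maf_j), drawn by thresholding one uniform per
    genotype at the Hardy-Weinberg cumulative probabilities (float32, for a
    single pass over the matrix).
    """
    mafs = np.asarray(mafs, dtype=np.float32)
    if (mafs <= 0).any() or (mafs > 0.5).any():
        raise ValueError("MAFs must lie in (0, 0.5]")
    u = rng.random((n, len(mafs)), dtype=np.float32)
    g = (u >= (1.0 - mafs) ** 2).astype(np.float32)
    g += u >= 1.0 - mafs**2
    return g


def rescale_to_pve(alpha: np.ndarray, pve: float) -> tuple[float, np.ndarray]:
    """Scale raw effect sizes so the PVE bookkeeping hits the target.

    Solves pve = d^2 S / (d^2 S + 1) with S = sum(alpha^2) for the scale
    d = sqrt(pve / ((1 - pve) S)); with unit-variance genotype columns and
    unit residual variance the realized PVE then equals the target exactly.
    """
    alpha = np.asarray(alpha, dtype=float)
    s = float(np.sum(alpha**2))
    if s == 0:
        raise ValueError("cannot rescale an all-zero effect vector")
    if not 0 < pve < 1:
        raise ValueError("pve must lie in (0, 1)")
    delta = float(np.sqrt(pve / ((1.0 - pve) * s)))
    return delta, delta * alpha


def _genetic_value(
    G: np.ndarray, alpha_scaled: np.ndarray, standardize: bool
) -> np.ndarray:
    """G @ alpha on either raw-dosage or unit-variance genotype columns."""
    a = np.asarray(alpha_scaled, dtype=np.float32)
    if standardize:
        mu = G.mean(axis=0)
        sd = G.std(axis=0)
        # (G - mu)/sd @ a without materializing the standardized matrix
        return G @ (a / sd) - float(np.sum(mu * a / sd))
    return G @ a


def build_phenotypes(
    G_male: np.ndarray,
    G_female: np.ndarray,
    alpha_male_scaled: np.ndarray,
    alpha_female_scaled: np.ndarray,
    theta: float,
    rng: np.random.Generator,
    standardize: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exposures per sex and the female-specific outcome.

    x = genetic value + standard-normal noise for each sex;
    y = theta * x_female + standard-normal noise, on the female cohort.
    """
    if G_male.shape[1] != len(alpha_male_scaled) or G_female.shape[1] != len(
        alpha_female_scaled
    ):
        raise ValueError("genotype/effect dimension mismatch")
    x_m = _genetic_value(G_male, alpha_male_scaled, standardize)
    x_m += rng.standard_normal(G_male.shape[0], dtype=np.float32)
    x_f = _genetic_value(G_female, alpha_female_scaled, standardize)
    x_f += rng.standard_normal(G_female.shape[0], dtype=np.float32)
    y = theta * x_f + rng.standard_normal(G_female.shape[0], dtype=np.float32)
    return x_m, x_f, y


def _sumstat_frame(beta, se, pvalue, n, m) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp": [f"sim_{j}" for j in range(m)],
            "chr": "1",
            "pos": np.arange(1, m + 1),
            "effect_allele": "A",
            "other_allele": "G",
            "beta": np.asarray(beta, dtype=float),
            "se": np.asarray(se, dtype=float),
            "pvalue": np.asarray(pvalue, dtype=float),
            "n": n,
        }
    )


def marginal_gwas(
    phen: np.ndarray,
    G: np.ndarray,
    trait_label: str = "",
    stratum: str = "combined",
) -> SumstatTable:
    """Single-SNP regressions of a phenotype on every genotype column.

    Each SNP is regressed separately (simple linear regression with
    intercept); betas are reported per unit-variance genotype, with
    two-sided t p-values on n - 2 df. Zero-variance columns are dropped
    with a warning. Synthetic ids ``sim_j`` and placeholder A/G alleles
    make the output a full :class:`SumstatTable` for the pipeline.
    """
    n, m = G.shape
    if len(phen) != n:
        raise ValueError("phenotype/genotype length mismatch")
    mu = G.mean(axis=0)
    sd = G.std(axis=0)
    ok = sd > 0
    if not ok.all():
        logger.warning("marginal_gwas: dropping %d zero-variance SNP(s)", int((~ok).sum()))
    yc = (phen - phen.mean()).astype(np.float32)
    syy = float(yc @ yc)
    # On unit-variance columns the regressor sum of squares is exactly n.
    sxy = (G.T @ yc) / np.where(ok, sd, 1.0)
    beta = sxy / n
    rss = np.maximum(syy - beta * sxy, 0.0)
    se = np.sqrt(rss / (n - 2) / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvalue = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    frame = _sumstat_frame(beta, se, pvalue, n, m)[np.asarray(ok)]
    return SumstatTable(
        records=frame.reset_index(drop=True), trait_label=trait_label, stratum=stratum
    )


def meta_fixed(female: SumstatTable, male: SumstatTable) -> SumstatTable:
    """Fixed-effects inverse-variance meta-analysis of two strata.

    Per SNP: beta_c = (beta_f/se_f^2 + beta_m/se_m^2) / (1/se_f^2 + 1/se_m^2),
    se_c = (1/se_f^2 + 1/se_m^2)^{-1/2}, p from the normal z. The two tables
    must cover identical SNP sets.
    """
    f = female.records
    m = male.records.set_index("snp").loc[f["snp"]].reset_index()
    if list(f["snp"]) != list(m["snp"]):
        raise ValueError("meta_fixed: SNP sets differ between strata")
    wf = f["se"].to_numpy(float) ** -2
    wm = m["se"].to_numpy(float) ** -2
    beta = (f["beta"].to_numpy(float) * wf + m["beta"].to_numpy(float) * wm) / (wf + wm)
    se = (wf + wm) ** -0.5
    pvalue = 2 * stats.norm.sf(np.abs(beta / se))
    rec = f.copy()
    rec["beta"] = beta
    rec["se"] = se
    rec["pvalue"] = pvalue
    if "n" in rec and "n" in m:
        rec["n"] = (f["n"].astype("Int64") + m["n"].astype("Int64"))
    return SumstatTable(records=rec, trait_label=female.trait_label, stratum="combined")


def select_ivs(table: SumstatTable, m: int, alpha: float = 0.05) -> InstrumentSet:
    """Instrument selection at the Bonferroni threshold alpha/m (strict <).

    When no SNP passes, the single minimum-p SNP is used and the
    ``fallback_used`` flag is set; ties on the minimum break by table order.
    """
    if len(table) == 0:
        raise ValueError("cannot select instruments from an empty table")
    p = table.records["pvalue"].to_numpy(float)
    threshold = alpha / m
    sel = p < threshold
    fallback = not sel.any()
    if fallback:
        sel = np.zeros(len(p), dtype=bool)
        sel[int(np.argmin(p))] = True
    ids = tuple(table.records.loc[sel, "snp"])
    return InstrumentSet(
        snp_ids=ids,
        source_stratum=table.stratum,
        selection_threshold=threshold,
        fallback_used=fallback,
    )


def _pair(
    exposure: SumstatTable, outcome: SumstatTable, ivs: InstrumentSet
) -> HarmonizedInstruments:
    """Fast alignment of simulator tables (identical ids/alleles by design)."""
    e = exposure.records.set_index("snp").loc[list(ivs.snp_ids)]
    o = outcome.records.set_index("snp").loc[list(ivs.snp_ids)]
    return HarmonizedInstruments(
        pd.DataFrame(
            {
                "snp": list(ivs.snp_ids),
                "beta_x": e["beta"].to_numpy(float),
                "se_x": e["se"].to_numpy(float),
                "beta_y": o["beta"].to_numpy(float),
                "se_y": o["se"].to_numpy(float),
                "pvalue_y": o["pvalue"].to_numpy(float),
            }
        )
    )


@dataclass(frozen=True)
class StudyData:
    """Summary statistics and instrument selections from one simulated study."""

    stats_male: SumstatTable
    stats_female: SumstatTable
    stats_combined: SumstatTable
    stats_outcome: SumstatTable
    ivs_combined: InstrumentSet
    ivs_specific: InstrumentSet
    m: int


def simulate_study(sc: SimulationScenario, rng: np.random.Generator) -> StudyData:
    """Generate one simulated study's summary statistics and IV selections.

    Composes architecture draw -> genotypes -> PVE rescale -> phenotypes ->
    per-sex exposure GWAS + outcome GWAS -> fixed-effects meta -> instrument
    selection at P < iv_alpha/m on the combined and on the female statistics
    separately.
    """
    m, mafs, a_m, a_f = draw_architecture(sc, rng)
    _, a_m = rescale_to_pve(a_m, sc.pve_male)
    _, a_f = rescale_to_pve(a_f, sc.pve_female)
    std = sc.standardize_genotypes

    G_m = simulate_genotypes(sc.n_male, mafs, rng)
    x_m = _genetic_value(G_m, a_m, std)
    x_m += rng.standard_normal(sc.n_male, dtype=np.float32)
    stats_m = marginal_gwas(x_m, G_m, stratum="male")
    del G_m

    G_f = simulate_genotypes(sc.n_female, mafs, rng)
    x_f = _genetic_value(G_f, a_f, std)
    x_f += rng.standard_normal(sc.n_female, dtype=np.float32)
    stats_f = marginal_gwas(x_f, G_f, stratum="female")

    if sc.outcome_cohort == "independent":
        del G_f
        G_out = simulate_genotypes(sc.n_female, mafs, rng)
        x_out = _genetic_value(G_out, a_f, std)
        x_out += rng.standard_normal(sc.n_female, dtype=np.float32)
    else:
        G_out, x_out = G_f, x_f
    y = sc.theta * x_out + rng.standard_normal(len(x_out), dtype=np.float32)
    stats_y = marginal_gwas(y, G_out, stratum="female")
    del G_out

    stats_c = meta_fixed(stats_f, stats_m)

    ivs_c = select_ivs(stats_c, m, alpha=sc.iv_alpha)
    ivs_f = select_ivs(stats_f, m, alpha=sc.iv_alpha)
    return StudyData(
        stats_male=stats_m,
        stats_female=stats_f,
        stats_combined=stats_c,
        stats_outcome=stats_y,
        ivs_combined=ivs_c,
        ivs_specific=ivs_f,
        m=m,
    )


def run_replicate(
    sc: SimulationScenario, rng: np.random.Generator
) -> ReplicateResult:
    """One full replicate of the bias experiment.

    Runs :func:`simulate_study` and estimates the causal effect by
    fixed-effects IVW for the combined-instrument and the female-instrument
    selections, both against the common female-outcome statistics.
    """
    d = simulate_study(sc, rng)
    ivs_c, ivs_f = d.ivs_combined, d.ivs_specific
    est_c = ivw_fixed(_pair(d.stats_combined, d.stats_outcome, ivs_c))
    est_f = ivw_fixed(_pair(d.stats_female, d.stats_outcome, ivs_f))
    return ReplicateResult(
        theta_hat_combined=est_c.theta,
        theta_hat_specific=est_f.theta,
        se_combined=est_c.se,
        se_specific=est_f.se,
        k_combined=len(ivs_c),
        k_specific=len(ivs_f),
        fallback_used_combined=ivs_c.fallback_used,
        fallback_used_specific=ivs_f.fallback_used,
    )


def run_scenario(sc: SimulationScenario) -> ScenarioSummary:
    """Replicate-averaged bias for one scenario.

    Each replicate runs on an independent random sub-stream spawned from the
    scenario seed, so results are reproducible and replicates independent.
    """
    if sc.n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    children = np.random.SeedSequence(sc.seed).spawn(sc.n_replicates)
    rows = []
    for i, child in enumerate(children):
        rng = np.random.Generator(np.random.SFC64(child))
        rep = run_replicate(sc, rng)
        rows.append({"replicate": i, **rep.__dict__})
    df = pd.DataFrame(rows)
    bias_c = df["theta_hat_combined"].to_numpy() - sc.theta
    bias_s = df["theta_hat_specific"].to_numpy() - sc.theta
    nrep = sc.n_replicates
    return ScenarioSummary(
        mean_bias_combined=float(bias_c.mean()),
        mean_bias_specific=float(bias_s.mean()),
        mc_se_combined=float(bias_c.std(ddof=1) / np.sqrt(nrep)),
        mc_se_specific=float(bias_s.std(ddof=1) / np.sqrt(nrep)),
        n_replicates=nrep,
        scenario=sc,
        replicates=df,
    )


def run_grid(
    base: SimulationScenario,
    r_g_values: Iterable[float],
    theta_values: Iterable[float] | None = None,
) -> pd.DataFrame:
    """Scenario grid over r_g (and optionally theta); one summary row each."""
    thetas = list(theta_values) if theta_values is not None else [base.theta]
    rows = []
    for theta in thetas:
        for r_g in r_g_values:
            sc = replace(base, r_g=r_g, theta=theta)
            s = run_scenario(sc)
            rows.append(
                {
                    "r_g": r_g,
                    "theta": theta,
                    "pve_male": sc.pve_male,
                    "pve_female": sc.pve_female,
                    "mean_bias_combined": s.mean_bias_combined,
                    "mean_bias_specific": s.mean_bias_specific,
                    "mc_se_combined": s.mc_se_combined,
                    "mc_se_specific": s.mc_se_specific,
                    "n_replicates": s.n_replicates,
                }
            )
    return pd.DataFrame(rows)
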