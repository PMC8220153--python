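"""Closed-form power for two-sample MR with a binary outcome.

Normal approximation: with an outcome GWAS of total size N and case
fraction p, instruments explaining a fraction PVE of the exposure variance,
and a true odds ratio OR per SD of exposure, the IVW z statistic is
approximately normal with non-centrality

    ncp = sqrt(N * PVE * p * (1 - p)) * |ln OR|,

giving power = Phi(ncp - z_{1-alpha/2}). At OR = 1 the approximation
returns Phi(-z_{1-alpha/2}) (0.025 at alpha = 0.05), the one-sided residual
of the two-sided test; power is symmetric in OR <-> 1/OR and increasing in
N, PVE and |ln OR|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PowerInput:
    """Inputs for the binary-outcome MR power approximation.

    ``n_outcome``: total outcome GWAS size; ``case_fraction``: cases / total;
    ``or_per_sd``: odds ratio per SD of exposure; ``pve``: fraction of
    exposure variance explained by the instruments (e.g. 0.0151 for 1.51%).
    """

    n_outcome: int
    case_fraction: float
    or_per_sd: float
    pve: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_outcome <= 0:
            raise ValueError("n_outcome must be positive")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")
        if self.or_per_sd <= 0:
            raise ValueError("or_per_sd must be positive")
        if not 0 < self.pve < 1:
            raise ValueError("pve must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def mr_power_binary(inp: PowerInput) -> float:
    """Power of the IVW test for a binary outcome, in (0, 1)."""
    b = abs(np.log(inp.or_per_sd))
    ncp = np.sqrt(
        inp.n_outcome * inp.pve * inp.case_fraction * (1.0 - inp.case_fraction)
    ) * b
    z_crit = stats.norm.ppf(1.0 - inp.alpha / 2.0)
    return float(stats.norm.cdf(ncp - z_crit))


def power_batch(scenarios: pd.DataFrame) -> pd.DataFrame:
    """Vectorized power over a table of scenarios.

    Expects columns ``n_outcome, case_fraction, or_per_sd, pve`` and an
    optional ``alpha`` (default 0.05); returns a copy with ``power`` and
    ``power_percent`` columns appended.
    """
    out = scenarios.copy()
    alphas = out["alpha"] if "alpha" in out else pd.Series(0.05, index=out.index)
    out["power"] = [
        mr_power_binary(
            PowerInput(
                n_outcome=int(row.n_outcome),
                case_fraction=float(row.case_fraction),
                or_per_sd=float(row.or_per_sd),
                pve=float(row.pve),
                alpha=float(a),
            )
        )
        for row, a in zip(out.itertuples(), alphas)
    ]
    out["power_percent"] = 100.0 * out["power"]
    return out
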