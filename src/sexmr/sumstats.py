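"""GWAS summary-statistics input/output, harmonization and instrument QC.

Summary statistics are per-SNP marginal association records: effect and
other allele, effect size (SD units for quantitative traits, log-odds for
binary outcomes), standard error, p-value and sample size. Exposure and
outcome tables are aligned into a harmonized instrument set — the unit every
MR estimator consumes — with allele-swap sign flips and exclusion of
inconsistent records, followed by a Bonferroni screen that removes
instruments directly associated with the outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = (
    "snp",
    "chr",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
    "n",
)

#: Columns that must be resolvable in any input file.
REQUIRED_COLUMNS = ("snp", "effect_allele", "other_allele", "beta", "se", "pvalue")

#: Case-insensitive header aliases accepted without an explicit dialect.
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "snp": ("snp", "rsid", "rs_id", "snpid", "markername", "marker"),
    "chr": ("chr", "chrom", "chromosome"),
    "pos": ("pos", "bp", "position", "base_pair_location"),
    "effect_allele": ("effect_allele", "a1", "allele1", "ea", "alt"),
    "other_allele": ("other_allele", "a2", "allele2", "oa", "nea", "ref"),
    "beta": ("beta", "b", "effect", "beta_hat"),
    "se": ("se", "stderr", "standard_error", "sebeta"),
    "pvalue": ("pvalue", "p", "pval", "p_value", "p-value"),
    "n": ("n", "samplesize", "sample_size", "n_samples", "nmiss"),
}

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

STRATA = ("female", "male", "combined")


class SumstatsFormatError(ValueError):
    """An input file cannot be interpreted as GWAS summary statistics."""


class EmptyInstrumentsError(RuntimeError):
    """No instruments survive harmonization/QC, so no MR analysis is possible."""


@dataclass(frozen=True)
class SumstatTable:
    """Per-SNP marginal association records for one trait and stratum.

    ``records`` is a DataFrame with the canonical columns (``snp``, ``chr``,
    ``pos``, ``effect_allele``, ``other_allele``, ``beta``, ``se``,
    ``pvalue``, ``n``); ``chr``/``pos``/``n`` are carried as metadata only.
    SNP ids are unique within a table.
    """

    records: pd.DataFrame
    trait_label: str = ""
    stratum: str = "combined"

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValueError(f"stratum must be one of {STRATA}, got {self.stratum!r}")
        dup = self.records["snp"][self.records["snp"].duplicated()]
        if len(dup):
            raise SumstatsFormatError(
                f"duplicate snp ids in table {self.trait_label!r}: {sorted(set(dup))}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, snp_ids: Sequence[str]) -> "SumstatTable":
        """Rows for ``snp_ids``, in the given order; missing ids are skipped."""
        idx = self.records.set_index("snp")
        present = [s for s in snp_ids if s in idx.index]
        sub = idx.loc[present].reset_index()
        return replace(self, records=sub[list(self.records.columns)])


@dataclass(frozen=True)
class InstrumentSet:
    """An ordered set of instrument rsIDs selected in one stratum."""

    snp_ids: tuple[str, ...]
    source_stratum: str = "combined"
    selection_threshold: float = 5e-8
    fallback_used: bool = False

    def __post_init__(self) -> None:
        if not self.snp_ids:
            raise ValueError("InstrumentSet must be non-empty")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("InstrumentSet contains duplicate snp ids")

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass(frozen=True)
class HarmonizedInstruments:
    """Aligned per-instrument exposure/outcome effects.

    ``data`` columns: ``snp``, ``beta_x``, ``se_x``, ``beta_y``, ``se_y``,
    ``pvalue_y``. After harmonization ``beta_y`` is expressed on the same
    effect allele as ``beta_x``.
    """

    data: pd.DataFrame
    exclusions: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise EmptyInstrumentsError("harmonized instrument set is empty")
        if (self.data["se_y"] <= 0).any() or (self.data["se_x"] <= 0).any():
            raise ValueError("standard errors must be strictly positive")

    @property
    def k(self) -> int:
        return len(self.data)

    def drop(self, snp_id: str) -> "HarmonizedInstruments":
        """All instruments except ``snp_id`` (leave-one-out helper)."""
        kept = self.data[self.data["snp"] != snp_id].reset_index(drop=True)
        return HarmonizedInstruments(kept)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_x, se_x, beta_y, se_y) as float arrays."""
        d = self.data
        return (
            d["beta_x"].to_numpy(float),
            d["se_x"].to_numpy(float),
            d["beta_y"].to_numpy(float),
            d["se_y"].to_numpy(float),
        )


def _resolve_columns(
    header: Sequence[str], dialect: Mapping[str, str] | None
) -> dict[str, str]:
    """Map canonical column names to actual file headers (case-insensitive)."""
    lower_to_actual = {h.lower(): h for h in header}
    mapping: dict[str, str] = {}
    dialect = {k: v for k, v in (dialect or {}).items()}
    for canon in CANONICAL_COLUMNS:
        if canon in dialect:
            actual = dialect[canon]
            if actual.lower() not in lower_to_actual:
                raise SumstatsFormatError(
                    f"dialect maps {canon!r} to {actual!r}, not found in header {list(header)}"
                )
            mapping[canon] = lower_to_actual[actual.lower()]
            continue
        for alias in DEFAULT_ALIASES[canon]:
            if alias in lower_to_actual:
                mapping[canon] = lower_to_actual[alias]
                break
    missing = [c for c in REQUIRED_COLUMNS if c not in mapping]
    if missing:
        raise SumstatsFormatError(
            f"cannot resolve required column(s) {missing} from header {list(header)}; "
            "supply a dialect mapping"
        )
    return mapping


def read_sumstats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    trait_label: str = "",
    stratum: str = "combined",
) -> SumstatTable:
    """Read a tab-separated summary-statistics file into a :class:`SumstatTable`.

    Column headers are matched case-insensitively against built-in aliases
    (e.g. ``SNP``/``rsid``, ``A1``/``effect_allele``); nonstandard headers are
    resolved through ``dialect``, a canonical-name -> file-header mapping.
    Rows with missing beta or standard error (or a non-positive standard
    error) are dropped with a logged count. Indel alleles are dropped with a
    parse warning: only single-nucleotide A/C/G/T variants are supported.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping = _resolve_columns(df.columns, dialect)
    out = pd.DataFrame()
    for canon in CANONICAL_COLUMNS:
        if canon in mapping:
            out[canon] = df[mapping[canon]]
    for col, typ in (("beta", float), ("se", float), ("pvalue", float)):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    if "pos" in out:
        out["pos"] = pd.to_numeric(out["pos"], errors="coerce").astype("Int64")
    if "n" in out:
        out["n"] = pd.to_numeric(out["n"], errors="coerce").astype("Int64")

    n0 = len(out)
    out = out[out["beta"].notna() & out["se"].notna() & (out["se"] > 0)]
    dropped = n0 - len(out)
    if dropped:
        logger.info("%s: dropped %d row(s) with missing/invalid beta or se", path.name, dropped)

    for col in ("effect_allele", "other_allele"):
        out[col] = out[col].str.upper()
    bad_allele = ~(
        out["effect_allele"].isin(VALID_ALLELES) & out["other_allele"].isin(VALID_ALLELES)
    ) | (out["effect_allele"] == out["other_allele"])
    if bad_allele.any():
        logger.warning(
            "%s: dropped %d row(s) with unsupported (indel/invalid) alleles",
            path.name,
            int(bad_allele.sum()),
        )
        out = out[~bad_allele]

    out = out.reset_index(drop=True)
    return SumstatTable(records=out, trait_label=trait_label, stratum=stratum)


def write_sumstats(table: SumstatTable, path: str | Path) -> None:
    """Write a table as tab-separated text with canonical headers.

    ``read_sumstats(write_sumstats(t))`` reproduces ``t``. Raises on an
    empty table.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty summary-statistics table")
    df = table.records.copy()
    # Full float precision so the round trip is exact.
    df.to_csv(Path(path), sep="\t", index=False, float_format="%.17g")


def read_instruments(
    path: str | Path,
    source_stratum: str = "combined",
    selection_threshold: float = 5e-8,
) -> InstrumentSet:
    """Read an instrument list: plain text, one rsID per line."""
    ids = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return InstrumentSet(
        snp_ids=tuple(ids),
        source_stratum=source_stratum,
        selection_threshold=selection_threshold,
    )


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def harmonize(
    exposure: SumstatTable,
    outcome: SumstatTable,
    ivs: InstrumentSet,
    drop_mismatch: bool = True,
    drop_palindromic: bool = False,
) -> HarmonizedInstruments:
    """Align outcome effects onto the exposure's effect alleles.

    For each instrument present in both tables: if the outcome record carries
    the same effect/other alleles the outcome beta is kept as-is; if the
    alleles are swapped the outcome beta's sign is flipped; otherwise the
    record is allele-inconsistent and is excluded (or raises when
    ``drop_mismatch`` is false). Instruments absent from the outcome table
    are excluded. Strand-ambiguous (A/T, C/G) variants are retained unless
    ``drop_palindromic`` is set. Exclusion counts are logged by reason.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise ValueError("exposure and outcome tables must be non-empty")
    exp = exposure.records.set_index("snp")
    out = outcome.records.set_index("snp")

    rows = []
    exclusions: dict[str, list[str]] = {
        "missing_exposure": [],
        "missing_outcome": [],
        "allele_mismatch": [],
        "palindromic": [],
    }
    for snp in ivs.snp_ids:
        if snp not in exp.index:
            exclusions["missing_exposure"].append(snp)
            continue
        if snp not in out.index:
            exclusions["missing_outcome"].append(snp)
            continue
        e = exp.loc[snp]
        o = out.loc[snp]
        ea, oa = str(e["effect_allele"]).upper(), str(e["other_allele"]).upper()
        oea, ooa = str(o["effect_allele"]).upper(), str(o["other_allele"]).upper()
        if drop_palindromic and _is_palindromic(ea, oa):
            exclusions["palindromic"].append(snp)
            continue
        if (oea, ooa) == (ea, oa):
            sign = 1.0
        elif (oea, ooa) == (oa, ea):
            sign = -1.0
        else:
            if not drop_mismatch:
                raise SumstatsFormatError(
                    f"allele-inconsistent instrument {snp}: exposure {ea}/{oa} "
                    f"vs outcome {oea}/{ooa}"
                )
            exclusions["allele_mismatch"].append(snp)
            continue
        rows.append(
            {
                "snp": snp,
                "beta_x": float(e["beta"]),
                "se_x": float(e["se"]),
                "beta_y": sign * float(o["beta"]),
                "se_y": float(o["se"]),
                "pvalue_y": float(o["pvalue"]),
            }
        )
    for reason, snps in exclusions.items():
        if snps:
            logger.info("harmonize: excluded %d instrument(s): %s", len(snps), reason)
    if not rows:
        raise EmptyInstrumentsError(
            "no instruments survived harmonization; no MR analysis is possible"
        )
    return HarmonizedInstruments(pd.DataFrame(rows), exclusions=exclusions)


def qc_filter_outcome_associated(
    h: HarmonizedInstruments, alpha: float = 0.05
) -> HarmonizedInstruments:
    """Remove instruments directly associated with the outcome.

    An instrument is removed when its outcome p-value is Bonferroni
    significant over the ``k`` instruments entering the filter, i.e. when
    ``pvalue_y * k < alpha``. This is a conservative guard against
    pleiotropic instruments for a binary outcome.
    """
    k = h.k
    removed = h.data[h.data["pvalue_y"] * k < alpha]
    kept = h.data[~(h.data["pvalue_y"] * k < alpha)].reset_index(drop=True)
    if len(removed):
        logger.info(
            "qc_filter: removed %d outcome-associated instrument(s) "
            "(Bonferroni over k=%d at alpha=%g): %s",
            len(removed),
            k,
            alpha,
            list(removed["snp"]),
        )
    if len(kept) == 0:
        raise EmptyInstrumentsError(
            "all instruments removed by the outcome-association QC filter"
        )
    exclusions = dict(h.exclusions)
    exclusions["outcome_associated"] = list(removed["snp"])
    return HarmonizedInstruments(kept, exclusions=exclusions)
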