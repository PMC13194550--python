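"""GWAS summary-statistic tables, instrument selection and allele harmonization.

The unit of data is one table per trait with one row per variant:
identifier, effect allele, other allele, effect-allele frequency (EAF),
additive effect ``beta`` (log-odds for binary traits, trait-SD units for
quantitative ones), its standard error, p-value and sample size.

Two-sample MR requires the exposure and outcome effects to refer to the
*same* effect allele at every variant.  :func:`harmonize` aligns the two
tables onto a shared effect-allele convention, flipping outcome effect signs
where the allele pair is reported in the opposite orientation, resolving
strand-complement reports, and dropping palindromic (A/T, C/G) variants whose
orientation cannot be established from allele frequencies.

Contract: input instruments are assumed independent (pre-clumped upstream or
synthetic).  This package performs no LD clumping and matches variants by
identifier only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    EmptyInstrumentError,
    HarmonizationError,
    InputError,
)

logger = logging.getLogger(__name__)

#: canonical column order of a summary-statistics table
CANONICAL_COLUMNS = ["snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]

_VALID_ALLELES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

# harmonization provenance flags
KEPT = "kept"
SIGN_FLIPPED = "sign_flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_INCOMPATIBLE = "dropped_incompatible"


@dataclass
class SummaryStatsTable:
    """Per-variant association records for one trait.

    Parameters
    ----------
    trait_label : str
        Human-readable trait name (e.g. a genus name or ``"UC"``).
    trait_type : {"binary", "quantitative"}
        Binary traits carry ``n_cases``/``n_controls`` and report ``beta`` on
        the log-odds scale.
    records : pandas.DataFrame
        Columns :data:`CANONICAL_COLUMNS`; ``snp`` values unique.
    """

    trait_label: str
    trait_type: str
    records: pd.DataFrame
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ConfigurationError(
                f"trait_type must be 'binary' or 'quantitative', got {self.trait_type!r}"
            )
        if self.trait_type == "binary":
            if not (self.n_cases and self.n_controls):
                raise ConfigurationError(
                    f"binary trait {self.trait_label!r} requires positive n_cases and n_controls"
                )
        missing = [c for c in CANONICAL_COLUMNS if c not in self.records.columns]
        if missing:
            raise ConfigurationError(f"records missing canonical columns: {missing}")
        if self.records["snp"].duplicated().any():
            dupes = self.records.loc[self.records["snp"].duplicated(), "snp"].tolist()
            raise InputError(f"duplicate variant ids in {self.trait_label!r}: {dupes[:5]}")
        self.records = self.records.reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.records)

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedSet:
    """Paired exposure/outcome effects on a common effect-allele convention.

    ``table`` has one row per variant in the id-intersection of the two input
    tables, with columns ``snp``, ``gamma_hat`` (exposure effect γ̂),
    ``se_gamma``, ``Gamma_hat`` (outcome effect Γ̂), ``se_Gamma``, ``status``
    (one of the provenance flags) and ``sign_flipped`` (bool).  The estimator
    arrays expose only the kept rows.
    """

    exposure_label: str
    outcome_label: str
    table: pd.DataFrame
    outcome_trait_type: str = "binary"

    @property
    def kept(self) -> pd.DataFrame:
        return self.table[self.table["status"] == KEPT]

    @property
    def n_snp(self) -> int:
        return int((self.table["status"] == KEPT).sum())

    @property
    def snp(self) -> np.ndarray:
        return self.kept["snp"].to_numpy()

    @property
    def gamma_hat(self) -> np.ndarray:
        return self.kept["gamma_hat"].to_numpy(dtype=float)

    @property
    def se_gamma(self) -> np.ndarray:
        return self.kept["se_gamma"].to_numpy(dtype=float)

    @property
    def Gamma_hat(self) -> np.ndarray:
        return self.kept["Gamma_hat"].to_numpy(dtype=float)

    @property
    def se_Gamma(self) -> np.ndarray:
        return self.kept["se_Gamma"].to_numpy(dtype=float)

    def drop_counts(self) -> dict[str, int]:
        counts = self.table["status"].value_counts().to_dict()
        return {k: int(counts.get(k, 0)) for k in (KEPT, DROPPED_PALINDROMIC, DROPPED_INCOMPATIBLE)}

    def subset(self, keep_ids) -> "HarmonizedSet":
        """Harmonized set restricted to kept variants whose id is in ``keep_ids``."""
        keep_ids = set(keep_ids)
        mask = (self.table["status"] == KEPT) & self.table["snp"].isin(keep_ids)
        sub = self.table[mask].reset_index(drop=True)
        return HarmonizedSet(self.exposure_label, self.outcome_label, sub, self.outcome_trait_type)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, exposure_label: str = "", outcome_label: str = "",
                 outcome_trait_type: str = "binary") -> "HarmonizedSet":
        table = pd.read_csv(path, sep="\t")
        return cls(exposure_label, outcome_label, table, outcome_trait_type)

    @classmethod
    def from_arrays(cls, gamma_hat, se_gamma, Gamma_hat, se_Gamma, snp=None,
                    exposure_label: str = "exposure", outcome_label: str = "outcome",
                    outcome_trait_type: str = "binary") -> "HarmonizedSet":
        """Build a fully-kept harmonized set directly from effect arrays."""
        gamma_hat = np.asarray(gamma_hat, dtype=float)
        if snp is None:
            snp = [f"rs{i}" for i in range(len(gamma_hat))]
        table = pd.DataFrame({
            "snp": snp,
            "gamma_hat": gamma_hat,
            "se_gamma": np.asarray(se_gamma, dtype=float),
            "Gamma_hat": np.asarray(Gamma_hat, dtype=float),
            "se_Gamma": np.asarray(se_Gamma, dtype=float),
            "status": KEPT,
            "sign_flipped": False,
        })
        return cls(exposure_label, outcome_label, table, outcome_trait_type)


def _detect_delimiter(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") else ","


def read_summary_stats(
    path: str | Path,
    trait_type: str,
    column_map: dict[str, str] | None = None,
    trait_label: str | None = None,
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> SummaryStatsTable:
    """Read a delimited summary-statistics file into a validated table.

    ``column_map`` maps *source* column names to canonical fields, e.g.
    ``{"BETA_FIXED": "beta", "SE": "se"}``; unmapped canonical names are taken
    verbatim from the header (case-insensitive).  The delimiter (tab or comma)
    is auto-detected from the header row.  Rows failing validation (``se <= 0``,
    ``eaf`` outside (0,1), non-ACGT or identical alleles, ``pval`` outside
    (0,1]) are dropped with a logged count.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise InputError(f"{path}: empty file")
    sep = _detect_delimiter(header)
    df = pd.read_csv(path, sep=sep)
    # case-insensitive canonical match, then explicit overrides
    rename: dict[str, str] = {}
    lower = {c.lower(): c for c in df.columns}
    for canon in CANONICAL_COLUMNS:
        if canon in lower:
            rename[lower[canon]] = canon
    for src, canon in (column_map or {}).items():
        if canon not in CANONICAL_COLUMNS:
            raise ConfigurationError(f"column_map target {canon!r} is not a canonical field")
        if src not in df.columns:
            raise ConfigurationError(f"{path}: column_map source column {src!r} not in header")
        rename[src] = canon
    df = df.rename(columns=rename)
    mandatory = [c for c in CANONICAL_COLUMNS if c != "eaf"]
    for col in mandatory:
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing mandatory column {col!r}")
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    df = df[CANONICAL_COLUMNS].copy()

    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    n0 = len(df)
    ok = (
        df["se"].gt(0)
        & df["beta"].notna()
        & df["pval"].gt(0) & df["pval"].le(1)
        & df["effect_allele"].isin(_VALID_ALLELES)
        & df["other_allele"].isin(_VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & (df["eaf"].isna() | (df["eaf"].gt(0) & df["eaf"].lt(1)))
    )
    dropped = int(n0 - ok.sum())
    if dropped:
        logger.warning("%s: dropped %d/%d rows failing validation", path.name, dropped, n0)
    df = df[ok].reset_index(drop=True)
    if df.empty:
        raise InputError(f"{path}: zero valid rows after validation")

    # soft consistency check: pval vs |beta/se| normal approximation
    with np.errstate(divide="ignore"):
        z = np.abs(df["beta"] / df["se"])
        implied = 2.0 * stats.norm.sf(z)
        lo = np.log10(np.maximum(implied, 1e-300))
        lp = np.log10(np.maximum(df["pval"].to_numpy(), 1e-300))
    n_inconsistent = int((np.abs(lo - lp) > 2.0).sum())
    if n_inconsistent:
        logger.warning(
            "%s: %d rows with pval inconsistent with |beta/se| by >2 orders of magnitude",
            path.name, n_inconsistent,
        )

    return SummaryStatsTable(
        trait_label=trait_label or path.stem,
        trait_type=trait_type,
        records=df,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def select_instruments(
    table: SummaryStatsTable,
    p_threshold: float = 1e-5,
    f_min: float = 10.0,
) -> SummaryStatsTable:
    """Keep variants with ``pval < p_threshold`` and approximate F = (beta/se)^2 >= f_min.

    The F bound is inclusive; input row order is preserved.  Raises
    :class:`EmptyInstrumentError` if nothing survives.
    """
    if table.n_variants == 0:
        raise InputError(f"{table.trait_label!r}: empty table")
    df = table.records
    f_stat = (df["beta"] / df["se"]) ** 2
    keep = (df["pval"] < p_threshold) & (f_stat >= f_min)
    kept = df[keep].reset_index(drop=True)
    logger.info(
        "%s: instrument selection kept %d/%d (p<%g, F>=%g)",
        table.trait_label, len(kept), len(df), p_threshold, f_min,
    )
    if kept.empty:
        raise EmptyInstrumentError(
            f"{table.trait_label!r}: no variant passes p<{p_threshold:g} and F>={f_min:g}"
        )
    return SummaryStatsTable(
        trait_label=table.trait_label,
        trait_type=table.trait_type,
        records=kept,
        n_cases=table.n_cases,
        n_controls=table.n_controls,
    )


def _is_palindromic(a1: str, a2: str) -> bool:
    return (a1, a2) in _PALINDROMIC_PAIRS


def harmonize(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Align outcome effects onto the exposure's effect-allele convention.

    For each variant present in both tables:

    * identical allele pair — keep as-is;
    * swapped pair (outcome effect/other = exposure other/effect) — negate the
      outcome beta, map its EAF to 1−EAF, flag ``sign_flipped``;
    * strand-complement report resolving to one of the above — resolve, then
      apply the same rule;
    * palindromic variant (A/T or C/G) — orientation is decided by allele
      frequency alone: kept (as-is) only when both EAFs are present, outside
      ``[0.5−w, 0.5+w]`` and on the same side of 0.5, otherwise dropped;
    * anything else — dropped as incompatible.

    Raises :class:`HarmonizationError` (with per-category drop counts) if no
    variant is kept.
    """
    if not 0 < palindrome_eaf_window < 0.5:
        raise ConfigurationError("palindrome_eaf_window must be in (0, 0.5)")
    w = palindrome_eaf_window
    exp = exposure.records.set_index("snp")
    out = outcome.records.set_index("snp")
    shared = [s for s in exp.index if s in out.index]  # exposure order

    rows = []
    for snp in shared:
        e = exp.loc[snp]
        o = out.loc[snp]
        ea_e, oa_e = e["effect_allele"], e["other_allele"]
        ea_o, oa_o = o["effect_allele"], o["other_allele"]
        beta_o = float(o["beta"])
        eaf_o = float(o["eaf"]) if pd.notna(o["eaf"]) else np.nan
        eaf_e = float(e["eaf"]) if pd.notna(e["eaf"]) else np.nan

        status = DROPPED_INCOMPATIBLE
        flipped = False
        if _is_palindromic(ea_e, oa_e):
            if {ea_o, oa_o} != {ea_e, oa_e}:
                status = DROPPED_INCOMPATIBLE
            else:
                unambiguous = (
                    np.isfinite(eaf_e) and np.isfinite(eaf_o)
                    and abs(eaf_e - 0.5) > w and abs(eaf_o - 0.5) > w
                    and (eaf_e - 0.5) * (eaf_o - 0.5) > 0
                )
                # allele strings cannot distinguish swap from strand flip here;
                # same-side frequencies are the only evidence of alignment
                status = KEPT if unambiguous else DROPPED_PALINDROMIC
        else:
            pairs = [(ea_o, oa_o), (_COMPLEMENT[ea_o], _COMPLEMENT[oa_o])]
            for a1, a2 in pairs:
                if (a1, a2) == (ea_e, oa_e):
                    status = KEPT
                    break
                if (a1, a2) == (oa_e, ea_e):
                    status = KEPT
                    flipped = True
                    beta_o = -beta_o
                    eaf_o = 1.0 - eaf_o if np.isfinite(eaf_o) else np.nan
                    break

        rows.append({
            "snp": snp,
            "gamma_hat": float(e["beta"]),
            "se_gamma": float(e["se"]),
            "Gamma_hat": beta_o if status == KEPT else float(o["beta"]),
            "se_Gamma": float(o["se"]),
            "status": status,
            "sign_flipped": flipped and status == KEPT,
        })

    table = pd.DataFrame(
        rows,
        columns=["snp", "gamma_hat", "se_gamma", "Gamma_hat", "se_Gamma", "status", "sign_flipped"],
    )
    hs = HarmonizedSet(exposure.trait_label, outcome.trait_label, table, outcome.trait_type)
    counts = hs.drop_counts()
    logger.info("harmonize %s~%s: %s", exposure.trait_label, outcome.trait_label, counts)
    if hs.n_snp < 1:
        raise HarmonizationError(
            f"no variant survived harmonization of {exposure.trait_label!r} vs "
            f"{outcome.trait_label!r}: {counts}",
            drop_counts=counts,
        )
    return hs
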