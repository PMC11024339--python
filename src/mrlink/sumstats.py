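"""GWAS summary-statistics data model and tab-delimited I/O.

A trait's association results live in a :class:`SumstatsTable`: a validated
pandas DataFrame with one row per SNP and the canonical columns

    rsid, chrom, pos, effect_allele, other_allele, eaf, beta, se, pval, n

``beta`` is the additive per-effect-allele association (log-odds for binary
traits, outcome units or trait SDs for continuous ones), ``se`` its standard
error, ``eaf`` the effect-allele frequency. ``eaf`` and ``n`` may be missing
(NA); everything else is mandatory. Only biallelic SNPs over {A,C,G,T} are
accepted — the strand/palindrome logic of harmonization is undefined for
indels and multi-allelic records.

Validation is total: every input row is either accepted or attributed to
exactly one rejection reason, and the per-reason counts are returned on the
table (``validation_counts``) and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyInputError

logger = logging.getLogger(__name__)

#: Canonical column order used everywhere, including on-disk files.
COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

VALID_ALLELES = frozenset("ACGT")

#: Rejection reasons, checked in this order; a row gets the first that fires.
REJECTION_REASONS = [
    "missing_field",
    "invalid_allele",
    "alleles_equal",
    "invalid_pos",
    "nonpositive_se",
    "invalid_pval",
    "invalid_eaf",
    "invalid_n",
    "duplicate_rsid",
]


@dataclass
class SumstatsTable:
    """One GWAS trait's per-SNP summary statistics.

    Parameters
    ----------
    trait_id : str
        Identifier for the trait (e.g. ``"crohns_disease"``).
    trait_type : {"binary", "continuous"}
        Drives the reporting scale downstream: binary outcomes are reported
        as odds ratios, continuous outcomes on the beta scale.
    data : pandas.DataFrame
        Canonical-column frame; ``eaf``/``n`` may hold NaN.
    ancestry_label : str
        Free-text metadata (never used computationally).
    validation_counts : dict
        Per-reason counts of rows rejected when the table was built.
    """

    trait_id: str
    trait_type: str
    data: pd.DataFrame
    ancestry_label: str = ""
    validation_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ConfigurationError(
                f"trait_type must be 'binary' or 'continuous', got {self.trait_type!r}"
            )
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"table missing columns: {missing}")
        self.data = self.data.loc[:, COLUMNS].reset_index(drop=True)
        if self.data["rsid"].duplicated().any():
            dupes = self.data.loc[self.data["rsid"].duplicated(), "rsid"].tolist()
            raise ConfigurationError(f"duplicate rsids in table: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SumstatsTable):
            return NotImplemented
        if (self.trait_id, self.trait_type) != (other.trait_id, other.trait_type):
            return False
        return tables_allclose(self.data, other.data)

    def subset(self, rsids) -> "SumstatsTable":
        """Row subset by rsid, preserving this table's order."""
        keep = self.data["rsid"].isin(set(rsids))
        return SumstatsTable(
            trait_id=self.trait_id,
            trait_type=self.trait_type,
            data=self.data.loc[keep].reset_index(drop=True),
            ancestry_label=self.ancestry_label,
        )


def tables_allclose(a: pd.DataFrame, b: pd.DataFrame, rtol: float = 1e-11) -> bool:
    """Field-for-field equality up to float representation (~12 sig. digits)."""
    if len(a) != len(b):
        return False
    for col in COLUMNS:
        xa, xb = a[col].to_numpy(), b[col].to_numpy()
        if col in ("eaf", "beta", "se", "pval", "n", "pos"):
            xa = pd.to_numeric(a[col]).to_numpy(dtype=float)
            xb = pd.to_numeric(b[col]).to_numpy(dtype=float)
            both_nan = np.isnan(xa) & np.isnan(xb)
            if not np.all(both_nan | np.isclose(xa, xb, rtol=rtol, atol=0, equal_nan=True)):
                return False
        else:
            if not np.array_equal(xa.astype(str), xb.astype(str)):
                return False
    return True


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Split a raw frame into (valid rows, rejection-reason counts)."""
    counts = dict.fromkeys(REJECTION_REASONS, 0)
    reason = pd.Series("", index=df.index, dtype=object)

    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    pos = pd.to_numeric(df["pos"], errors="coerce")
    beta = pd.to_numeric(df["beta"], errors="coerce")
    se = pd.to_numeric(df["se"], errors="coerce")
    pval = pd.to_numeric(df["pval"], errors="coerce")
    eaf = pd.to_numeric(df["eaf"], errors="coerce")
    n = pd.to_numeric(df["n"], errors="coerce")

    def flag(mask: pd.Series, why: str) -> None:
        hit = mask & (reason == "")
        reason[hit] = why
        counts[why] += int(hit.sum())

    flag(df["rsid"].isna() | (df["rsid"].astype(str).str.strip() == "")
         | beta.isna() | se.isna() | pval.isna() | pos.isna(), "missing_field")
    flag(~ea.isin(VALID_ALLELES) | ~oa.isin(VALID_ALLELES), "invalid_allele")
    flag(ea == oa, "alleles_equal")
    flag(pos < 1, "invalid_pos")
    flag(se <= 0, "nonpositive_se")
    flag((pval <= 0) | (pval > 1), "invalid_pval")
    # eaf optional: only a *present but out-of-range* value is an error
    flag(df["eaf"].notna() & (eaf.isna() | (eaf < 0) | (eaf > 1)), "invalid_eaf")
    flag(df["n"].notna() & (n.isna() | (n <= 0)), "invalid_n")
    ok = reason == ""
    # duplicates: keep the first occurrence among otherwise-valid rows
    dup = df["rsid"].astype(str).where(ok).duplicated() & ok
    flag(dup, "duplicate_rsid")
    ok = reason == ""

    out = pd.DataFrame({
        "rsid": df["rsid"].astype(str)[ok],
        "chrom": df["chrom"].astype(str)[ok],
        "pos": pos[ok].astype(np.int64),
        "effect_allele": ea[ok],
        "other_allele": oa[ok],
        "eaf": eaf[ok],
        "beta": beta[ok],
        "se": se[ok],
        "pval": pval[ok],
        "n": n[ok],
    }).reset_index(drop=True)
    counts = {k: v for k, v in counts.items() if v}
    return out, counts


def make_table(df: pd.DataFrame, trait_id: str, trait_type: str,
               ancestry_label: str = "") -> SumstatsTable:
    """Validate a raw frame (canonical column names) into a SumstatsTable."""
    for col in COLUMNS:
        if col not in df.columns:
            df = df.assign(**{col: np.nan})
    valid, counts = _validate_rows(df)
    if counts:
        logger.info("table %s: dropped rows by reason %s", trait_id, counts)
    if len(valid) == 0:
        raise EmptyInputError(f"no valid rows for trait {trait_id!r}")
    return SumstatsTable(trait_id=trait_id, trait_type=trait_type, data=valid,
                         ancestry_label=ancestry_label,
                         validation_counts=counts)


def read_sumstats(path, trait_id: str, trait_type: str,
                  column_map: Mapping[str, str] | None = None,
                  ancestry_label: str = "") -> SumstatsTable:
    """Read a tab- or comma-delimited summary-statistics file.

    ``column_map`` maps canonical names to the file's column names, e.g.
    ``{"rsid": "SNP", "pval": "P"}``; unmapped canonical names are taken
    verbatim. Rows violating the record invariants are dropped with a
    per-reason count in ``validation_counts``.
    """
    raw = pd.read_csv(path, sep=None, engine="python", dtype={"chrom": str},
                      na_values=["NA", ""], keep_default_na=True)
    column_map = dict(column_map or {})
    rename = {}
    for canon in COLUMNS:
        src = column_map.get(canon, canon)
        if src in raw.columns:
            rename[src] = canon
        elif canon in column_map:
            raise ConfigurationError(
                f"mapped column {src!r} (for {canon!r}) not found in {path}")
    df = raw.rename(columns=rename)
    for canon in ("rsid", "chrom", "pos", "effect_allele", "other_allele",
                  "beta", "se", "pval"):
        if canon not in df.columns:
            raise ConfigurationError(f"required column {canon!r} not found in {path}")
    return make_table(df, trait_id=trait_id, trait_type=trait_type,
                      ancestry_label=ancestry_label)


def write_sumstats(table: SumstatsTable, path) -> None:
    """Write a table as TSV in canonical column order.

    Floats are serialized with 17 significant digits so that a
    write-then-read round trip reproduces the table to well beyond the
    guaranteed 12 significant digits; missing ``eaf``/``n`` become ``NA``.
    """
    df = table.data.copy()
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_annotations(path) -> pd.DataFrame:
    """Read a confounder-annotation table (columns rsid, trait, pval).

    Emulates a PhenoScanner export: each row says SNP ``rsid`` is associated
    with ``trait`` at ``pval``. Rows with pval outside (0, 1] are dropped.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("rsid", "trait", "pval"):
        if col not in df.columns:
            raise ConfigurationError(f"annotation file missing column {col!r}")
    pval = pd.to_numeric(df["pval"], errors="coerce")
    ok = pval.notna() & (pval > 0) & (pval <= 1)
    return pd.DataFrame({"rsid": df["rsid"].astype(str)[ok],
                         "trait": df["trait"].astype(str)[ok],
                         "pval": pval[ok]}).reset_index(drop=True)


def write_annotations(df: pd.DataFrame, path) -> None:
    df.loc[:, ["rsid", "trait", "pval"]].to_csv(
        path, sep="\t", index=False, float_format="%.17g")
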