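"""Genetic-instrument selection for two-sample MR.

Instruments must satisfy the relevance and independence assumptions of the
instrumental-variable design:

* genome-wide significance with the exposure (p < 5e-8) and instrument
  strength F = (beta/se)^2 > 10, guarding against weak-instrument bias;
* mutual linkage-disequilibrium independence, obtained by greedy LD clumping
  (r^2 < 0.001 within a +/-1 Mb window around each index SNP);
* no known association with a confounder of the exposure-outcome pair
  (screened against a local annotation table emulating PhenoScanner).

`select_instruments` composes the three screens and records the SNP count
surviving each stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyInstrumentsError
from .sumstats import SumstatsTable

logger = logging.getLogger(__name__)

#: Confounders of the autoimmune-disease / sarcopenia relationship screened
#: by default (matched case-insensitively against annotation trait names).
DEFAULT_CONFOUNDER_TRAITS = (
    "smoking",
    "body mass index",
    "physical inactivity",
    "malnutrition",
    "extreme sleep duration",
)


class LdReference:
    """Pairwise LD (r^2) lookup backing the clumping step.

    Built either from a dosage panel (per-sample allele dosages in [0, 2];
    r^2 is the squared Pearson correlation between dosage columns) or from a
    precomputed three-column pair table. In panel mode every pair of covered
    rsids has a known r^2; in pair-table mode uncovered pairs return None
    ("unknown").
    """

    def __init__(self, rsids: list[str],
                 matrix: np.ndarray | None = None,
                 pair_map: dict[tuple[str, str], float] | None = None):
        self._rsids = list(rsids)
        self._index = {r: i for i, r in enumerate(self._rsids)}
        self._matrix = matrix
        self._pair_map = pair_map

    @classmethod
    def from_panel(cls, dosages: pd.DataFrame) -> "LdReference":
        """Build from a dosage panel (rows = samples, columns = rsids)."""
        values = dosages.to_numpy(dtype=float)
        if values.size and (values.min() < 0 or values.max() > 2):
            raise ConfigurationError("dosages must lie in [0, 2]")
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(values, rowvar=False)
        corr = np.atleast_2d(corr)
        r2 = np.nan_to_num(corr, nan=0.0) ** 2
        np.fill_diagonal(r2, 1.0)
        return cls(rsids=list(dosages.columns), matrix=r2)

    @classmethod
    def from_pair_table(cls, pairs: pd.DataFrame) -> "LdReference":
        """Build from a precomputed table with columns rsid_i, rsid_j, r2."""
        for col in ("rsid_i", "rsid_j", "r2"):
            if col not in pairs.columns:
                raise ConfigurationError(f"pair table missing column {col!r}")
        r2 = pairs["r2"].astype(float)
        if ((r2 < 0) | (r2 > 1)).any():
            raise ConfigurationError("r2 values must lie in [0, 1]")
        pair_map: dict[tuple[str, str], float] = {}
        rsids: list[str] = []
        seen = set()
        for i, j, v in zip(pairs["rsid_i"].astype(str),
                           pairs["rsid_j"].astype(str), r2):
            pair_map[(i, j)] = v
            pair_map[(j, i)] = v
            for r in (i, j):
                if r not in seen:
                    seen.add(r)
                    rsids.append(r)
        return cls(rsids=rsids, pair_map=pair_map)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    @property
    def rsids(self) -> list[str]:
        return list(self._rsids)

    def r2(self, rsid_i: str, rsid_j: str) -> float | None:
        """Pairwise r^2, or None when the pair is not covered."""
        if rsid_i == rsid_j:
            return 1.0 if rsid_i in self._index else None
        if self._matrix is not None:
            try:
                return float(self._matrix[self._index[rsid_i], self._index[rsid_j]])
            except KeyError:
                return None
        return self._pair_map.get((rsid_i, rsid_j))


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure, with per-stage attrition log.

    ``data`` carries the canonical summary-statistic columns plus ``f_stat``;
    ``selection_log`` maps stage name -> SNP count surviving that stage.
    """

    exposure_id: str
    data: pd.DataFrame
    selection_log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def rsids(self) -> list[str]:
        return self.data["rsid"].tolist()


def compute_f_statistic(beta, se):
    """Instrument-strength F statistic, F = (beta/se)^2."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ConfigurationError("se must be strictly positive")
    return (beta / se) ** 2


def filter_significant(table: SumstatsTable, p_threshold: float = 5e-8,
                       f_threshold: float = 10.0) -> SumstatsTable:
    """Keep SNPs with p < p_threshold and F > f_threshold (strict), in order."""
    df = table.data
    f = compute_f_statistic(df["beta"].to_numpy(), df["se"].to_numpy())
    keep = (df["pval"].to_numpy() < p_threshold) & (f > f_threshold)
    return SumstatsTable(trait_id=table.trait_id, trait_type=table.trait_type,
                         data=df.loc[keep].reset_index(drop=True),
                         ancestry_label=table.ancestry_label)


def ld_clump(table: SumstatsTable, ld: LdReference, r2_threshold: float = 0.001,
             window_kb: float = 1000.0) -> SumstatsTable:
    """Greedy LD clumping: keep index SNPs, discard their LD partners.

    SNPs are visited by ascending p-value (ties broken by chromosome then
    position for determinism). Each visited, still-unassigned SNP becomes an
    index; every unassigned SNP on the same chromosome within ``window_kb``
    kilobases whose r^2 with the index is >= ``r2_threshold`` is discarded.
    A within-window pair missing from a pair-table reference is kept with a
    warning rather than silently discarded. SNPs absent from the reference
    entirely are dropped up front (count logged).
    """
    if not (0 < r2_threshold <= 1):
        raise ConfigurationError("r2_threshold must be in (0, 1]")
    if window_kb <= 0:
        raise ConfigurationError("window_kb must be positive")

    df = table.data
    covered = df["rsid"].map(lambda r: r in ld)
    n_uncovered = int((~covered).sum())
    if n_uncovered:
        logger.warning("ld_clump: %d SNPs absent from LD reference dropped",
                       n_uncovered)
    df = df.loc[covered].reset_index(drop=True)

    order = df.sort_values(["pval", "chrom", "pos"], kind="mergesort").index
    window_bp = window_kb * 1000.0
    unassigned = set(df.index)
    kept: list[int] = []
    for i in order:
        if i not in unassigned:
            continue
        kept.append(i)
        unassigned.discard(i)
        chrom_i, pos_i, rs_i = df.at[i, "chrom"], df.at[i, "pos"], df.at[i, "rsid"]
        for j in list(unassigned):
            if df.at[j, "chrom"] != chrom_i:
                continue
            if abs(int(df.at[j, "pos"]) - int(pos_i)) > window_bp:
                continue
            r2 = ld.r2(rs_i, df.at[j, "rsid"])
            if r2 is None:
                logger.warning("ld_clump: unknown r2 for within-window pair "
                               "(%s, %s); keeping", rs_i, df.at[j, "rsid"])
                continue
            if r2 >= r2_threshold:
                unassigned.discard(j)
    kept_sorted = sorted(kept)
    return SumstatsTable(trait_id=table.trait_id, trait_type=table.trait_type,
                         data=df.loc[kept_sorted].reset_index(drop=True),
                         ancestry_label=table.ancestry_label)


def screen_confounders(table: SumstatsTable, annotations: pd.DataFrame,
                       confounder_traits=DEFAULT_CONFOUNDER_TRAITS,
                       p_threshold: float = 5e-8) -> SumstatsTable:
    """Drop SNPs significantly associated with a listed confounder trait.

    Trait names are matched case-insensitively and exactly. A SNP is dropped
    when at least one annotation pairs it with a confounder trait at
    pval < p_threshold; dropped rsids and matched traits are logged.
    """
    targets = {t.lower() for t in confounder_traits}
    if annotations is None or len(annotations) == 0:
        return table
    ann = annotations
    hit = (ann["trait"].str.lower().isin(targets)
           & (ann["pval"].astype(float) < p_threshold))
    bad = set(ann.loc[hit, "rsid"].astype(str))
    df = table.data
    dropping = df["rsid"].isin(bad)
    if dropping.any():
        matched = ann.loc[hit & ann["rsid"].isin(df["rsid"])]
        for rs, tr in zip(matched["rsid"], matched["trait"]):
            logger.info("confounder screen: dropping %s (associated with %s)",
                        rs, tr)
    return SumstatsTable(trait_id=table.trait_id, trait_type=table.trait_type,
                         data=df.loc[~dropping].reset_index(drop=True),
                         ancestry_label=table.ancestry_label)


def select_instruments(table: SumstatsTable, ld: LdReference,
                       annotations: pd.DataFrame | None = None,
                       p_threshold: float = 5e-8, f_threshold: float = 10.0,
                       clump_r2: float = 0.001, clump_window_kb: float = 1000.0,
                       confounder_traits=DEFAULT_CONFOUNDER_TRAITS,
                       confounder_p: float = 5e-8,
                       allow_empty: bool = False) -> InstrumentSet:
    """Full instrument-selection cascade for one exposure.

    Stages: drop records lacking an effect-allele frequency (the downstream
    MAF filter cannot be evaluated without one), then significance/strength
    filter, LD clumping, confounder screen; finally attach per-SNP F
    statistics. ``selection_log`` records the count after each stage.

    Raises :class:`EmptyInstrumentsError` when nothing survives, unless
    ``allow_empty`` (the pipeline records the pair as not-estimable instead).
    """
    log = {"input": len(table)}
    with_eaf = table.data["eaf"].notna()
    stage0 = SumstatsTable(trait_id=table.trait_id, trait_type=table.trait_type,
                           data=table.data.loc[with_eaf].reset_index(drop=True),
                           ancestry_label=table.ancestry_label)
    log["with_eaf"] = len(stage0)
    stage1 = filter_significant(stage0, p_threshold, f_threshold)
    log["significant"] = len(stage1)
    stage2 = ld_clump(stage1, ld, clump_r2, clump_window_kb)
    log["clumped"] = len(stage2)
    stage3 = (screen_confounders(stage2, annotations, confounder_traits,
                                 confounder_p)
              if annotations is not None else stage2)
    log["confounder_screened"] = len(stage3)
    if len(stage3) == 0 and not allow_empty:
        raise EmptyInstrumentsError(
            f"no instruments for {table.trait_id}; attrition {log}")
    data = stage3.data.copy()
    data["f_stat"] = compute_f_statistic(data["beta"].to_numpy(),
                                         data["se"].to_numpy())
    return InstrumentSet(exposure_id=table.trait_id, data=data,
                         selection_log=log)
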