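"""Allele harmonization of exposure instruments against outcome statistics.

Two GWAS report the same SNP on possibly different effect alleles and
possibly opposite DNA strands. Harmonization re-expresses every outcome
association on the exposure's effect allele (the exposure frame is never
modified — instruments were selected on that side):

1. palindromic exposure alleles (A/T or C/G) are dropped outright — their
   strand cannot be resolved from allele labels, and no frequency-based
   rescue is attempted;
2. outcome alleles identical to the exposure's (same order) are kept as-is;
   in swapped order, the outcome beta is negated and its effect-allele
   frequency complemented;
3. otherwise the outcome alleles are strand-complemented (A<->T, C<->G) and
   step 2 retried, recording the strand action;
4. no match after complementing -> incompatible alleles, dropped;
5. an aligned pair whose minor-allele frequency is <= ``maf_min`` on either
   side (or missing) is dropped (the MAF > 0.01 filter).

Every input instrument lands exactly once in either the harmonized pairs or
the drop log, so stage counts always reconcile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyHarmonizationError, MrLinkError
from .instruments import InstrumentSet
from .sumstats import SumstatsTable

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PAIR_COLUMNS = ["rsid", "beta_exp", "se_exp", "beta_out", "se_out",
                "eaf_exp", "eaf_out", "action"]


@dataclass
class HarmonizedSet:
    """Aligned (exposure, outcome) effects for one trait pair.

    ``pairs`` has columns rsid, beta_exp, se_exp, beta_out, se_out, eaf_exp,
    eaf_out, action; ``drop_log`` maps rsid -> reason (not_in_outcome,
    palindromic, incompatible_alleles, low_maf, presso_outlier).
    """

    exposure_id: str
    outcome_id: str
    pairs: pd.DataFrame
    drop_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.pairs["rsid"]) & set(self.drop_log)
        if overlap:
            raise MrLinkError(f"rsids both kept and dropped: {sorted(overlap)[:5]}")

    def __len__(self) -> int:
        return len(self.pairs)

    def arrays(self):
        """(beta_exp, beta_out, se_exp, se_out) as float arrays."""
        p = self.pairs
        return (p["beta_exp"].to_numpy(float), p["beta_out"].to_numpy(float),
                p["se_exp"].to_numpy(float), p["se_out"].to_numpy(float))

    def without(self, rsids, reason: str) -> "HarmonizedSet":
        """Copy with the given rsids moved from pairs to the drop log."""
        rsids = set(rsids)
        keep = ~self.pairs["rsid"].isin(rsids)
        log = dict(self.drop_log)
        for rs in self.pairs.loc[~keep, "rsid"]:
            log[rs] = reason
        return HarmonizedSet(exposure_id=self.exposure_id,
                             outcome_id=self.outcome_id,
                             pairs=self.pairs.loc[keep].reset_index(drop=True),
                             drop_log=log)

    def to_frame(self) -> pd.DataFrame:
        return self.pairs.loc[:, PAIR_COLUMNS].copy()


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G pairs, whose strand is ambiguous."""
    pair = {a1.upper(), a2.upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


def harmonize_pair(exp_row, out_row, maf_min: float = 0.01):
    """Align one outcome record to the exposure's effect allele.

    ``exp_row``/``out_row`` are mappings with the canonical summary-statistic
    fields and equal rsid. Returns ``(pair_dict, None)`` on success or
    ``(None, reason)`` when dropped.
    """
    if exp_row["rsid"] != out_row["rsid"]:
        raise MrLinkError("harmonize_pair called with mismatched rsids")
    ea_e, oa_e = exp_row["effect_allele"], exp_row["other_allele"]
    if is_palindromic(ea_e, oa_e):
        return None, "palindromic"

    ea_o, oa_o = out_row["effect_allele"], out_row["other_allele"]
    beta_out = float(out_row["beta"])
    eaf_out = out_row["eaf"]
    eaf_out = float(eaf_out) if pd.notna(eaf_out) else np.nan

    action = None
    for attempt, (a, b) in enumerate([(ea_o, oa_o),
                                      (COMPLEMENT[ea_o], COMPLEMENT[oa_o])]):
        if (a, b) == (ea_e, oa_e):
            action = "kept_as_is" if attempt == 0 else "strand_complemented"
            break
        if (b, a) == (ea_e, oa_e):
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out if not np.isnan(eaf_out) else np.nan
            action = "flipped" if attempt == 0 else "strand_complemented_and_flipped"
            break
    if action is None:
        return None, "incompatible_alleles"

    eaf_exp = exp_row["eaf"]
    eaf_exp = float(eaf_exp) if pd.notna(eaf_exp) else np.nan
    for eaf in (eaf_exp, eaf_out):
        if np.isnan(eaf) or min(eaf, 1.0 - eaf) <= maf_min:
            return None, "low_maf"

    return {
        "rsid": exp_row["rsid"],
        "beta_exp": float(exp_row["beta"]),
        "se_exp": float(exp_row["se"]),
        "beta_out": beta_out,
        "se_out": float(out_row["se"]),
        "eaf_exp": eaf_exp,
        "eaf_out": eaf_out,
        "action": action,
    }, None


def harmonize(instruments: InstrumentSet, outcome: SumstatsTable,
              maf_min: float = 0.01, allow_empty: bool = False) -> HarmonizedSet:
    """Harmonize every instrument against the outcome table (keyed join).

    Instruments absent from the outcome are logged ``not_in_outcome``.
    Raises :class:`EmptyHarmonizationError` when no pair survives, unless
    ``allow_empty``.
    """
    out_by_rsid = outcome.data.set_index("rsid", drop=False)
    pairs: list[dict] = []
    drop_log: dict[str, str] = {}
    for _, exp_row in instruments.data.iterrows():
        rsid = exp_row["rsid"]
        if rsid not in out_by_rsid.index:
            drop_log[rsid] = "not_in_outcome"
            continue
        pair, reason = harmonize_pair(exp_row, out_by_rsid.loc[rsid],
                                      maf_min=maf_min)
        if pair is None:
            drop_log[rsid] = reason
        else:
            pairs.append(pair)
    frame = (pd.DataFrame(pairs, columns=PAIR_COLUMNS) if pairs
             else pd.DataFrame(columns=PAIR_COLUMNS))
    if len(frame) == 0 and not allow_empty:
        raise EmptyHarmonizationError(
            f"no harmonized pairs for {instruments.exposure_id} -> "
            f"{outcome.trait_id}; drops {drop_log}")
    return HarmonizedSet(exposure_id=instruments.exposure_id,
                         outcome_id=outcome.trait_id,
                         pairs=frame, drop_log=drop_log)


def write_harmonized(h: HarmonizedSet, path, drop_log_path=None) -> None:
    """Serialize pairs to TSV; optionally the drop log to a sidecar TSV."""
    h.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
    if drop_log_path is not None:
        pd.DataFrame(sorted(h.drop_log.items()), columns=["rsid", "reason"]) \
            .to_csv(drop_log_path, sep="\t", index=False)
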