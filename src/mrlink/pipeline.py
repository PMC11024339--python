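"""Bi-directional MR driver: every exposure against every outcome, twice.

The study design crosses a set of exposure traits with a set of outcome
traits (forward direction), then swaps the roles (reverse direction). For
each pair the pipeline runs instrument selection, harmonization, iterative
MR-PRESSO outlier removal, the five estimators, and the heterogeneity /
pleiotropy diagnostics; the fixed- vs random-effect IVW model is chosen
per-pair by the Cochran's Q p-value rule, binary outcomes are reported as
odds ratios, and the IVW p-value is gated against a per-direction Bonferroni
threshold of alpha divided by that direction's number of exposures.

A stage that leaves nothing to analyse (no instruments, nothing harmonized,
too few SNPs for IVW) marks the pair ``not_estimable`` with the stage named,
and the run continues. All randomness flows from one master seed, expanded
deterministically per pair in sorted pair order, so a run is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .estimators import (Diagnostics, EggerRegression, IVWEstimator,
                         MaximumLikelihoodEstimator, MrResult,
                         PenalizedWeightedMedianEstimator,
                         WeightedMedianEstimator, to_odds_ratio)
from .exceptions import (ConfigurationError, DegenerateWeightsError,
                         EmptyHarmonizationError, EmptyInstrumentsError,
                         EstimationError, InsufficientInstrumentsError)
from .harmonize import harmonize
from .instruments import (DEFAULT_CONFOUNDER_TRAITS, LdReference,
                          select_instruments)
from .presso import iterative_presso
from .sumstats import SumstatsTable

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "exposure", "outcome", "direction", "n_ivs", "cochran_q", "q_pval",
    "egger_intercept", "egger_intercept_pval", "method", "ivw_model",
    "effect_scale", "estimate", "ci_low", "ci_high", "pval",
    "significance_threshold", "significant", "status",
]


def bonferroni_threshold(n_exposures: int, alpha: float = 0.05) -> float:
    """Per-direction significance threshold alpha / number of exposures."""
    if n_exposures <= 0:
        raise ConfigurationError("n_exposures must be a positive integer")
    return alpha / n_exposures


@dataclass
class StudyConfig:
    """Everything one bi-directional run needs.

    ``exposures``/``outcomes`` are loaded SumstatsTables; ``ld`` covers the
    union of their SNPs; ``annotations`` is the confounder table (or None to
    skip the screen). Threshold defaults are the analysis constants:
    p < 5e-8 and F > 10 for instruments, clump at r^2 < 0.001 within 1 Mb,
    MAF > 0.01, alpha = 0.05 Bonferroni-split per direction.
    """

    exposures: list[SumstatsTable]
    outcomes: list[SumstatsTable]
    ld: LdReference
    annotations: pd.DataFrame | None = None
    p_threshold: float = 5e-8
    f_threshold: float = 10.0
    clump_r2: float = 0.001
    clump_window_kb: float = 1000.0
    confounder_traits: tuple = DEFAULT_CONFOUNDER_TRAITS
    confounder_p: float = 5e-8
    maf_min: float = 0.01
    presso_n_sim: int = 1000
    presso_significance: float = 0.05
    n_boot: int = 1000
    alpha: float = 0.05
    seed: int = 0


@dataclass
class PairAnalysis:
    """One exposure -> outcome record of the bi-directional grid."""

    exposure_id: str
    outcome_id: str
    direction: str                      # "forward" | "reverse"
    status: str = "ok"                  # or "not_estimable(<stage>)"
    stage_counts: dict = field(default_factory=dict)
    diagnostics: Diagnostics | None = None
    presso_global_pvals: list[float] = field(default_factory=list)
    presso_outliers: list[str] = field(default_factory=list)
    results: dict[str, MrResult] = field(default_factory=dict)
    method_failures: dict[str, str] = field(default_factory=dict)
    significance_threshold: float = 0.05
    significant: bool = False

    def to_records(self) -> list[dict]:
        """Long-format rows (one per method) for the results table."""
        d = self.diagnostics or Diagnostics()
        base = {
            "exposure": self.exposure_id, "outcome": self.outcome_id,
            "direction": self.direction,
            "n_ivs": self.stage_counts.get("final", 0),
            "cochran_q": d.cochran_q, "q_pval": d.q_pval,
            "egger_intercept": d.egger_intercept,
            "egger_intercept_pval": d.intercept_pval,
            "significance_threshold": self.significance_threshold,
            "status": self.status,
        }
        if not self.results:
            return [{**base, "method": None, "ivw_model": None,
                     "effect_scale": None, "estimate": None, "ci_low": None,
                     "ci_high": None, "pval": None,
                     "significant": self.significant}]
        rows = []
        for method, r in self.results.items():
            rows.append({**base, "method": method, "ivw_model": r.ivw_model,
                         "effect_scale": r.effect_scale, "estimate": r.beta,
                         "ci_low": r.ci_low, "ci_high": r.ci_high,
                         "pval": r.pval,
                         "significant": (self.significant
                                         if method == "ivw" else None)})
        return rows


def _pair_seed(master_seed: int, direction: str, index: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed,
                                spawn_key=(0 if direction == "forward" else 1,
                                           index))
    return int(ss.generate_state(1)[0] % (2**31))


def run_pair(exposure: SumstatsTable, outcome: SumstatsTable,
             ld: LdReference, annotations: pd.DataFrame | None,
             config: StudyConfig, direction: str, threshold: float,
             seed: int) -> PairAnalysis:
    """Analyse one exposure -> outcome pair end to end."""
    pa = PairAnalysis(exposure_id=exposure.trait_id,
                      outcome_id=outcome.trait_id, direction=direction,
                      significance_threshold=threshold)
    try:
        inst = select_instruments(
            exposure, ld, annotations,
            p_threshold=config.p_threshold, f_threshold=config.f_threshold,
            clump_r2=config.clump_r2, clump_window_kb=config.clump_window_kb,
            confounder_traits=config.confounder_traits,
            confounder_p=config.confounder_p)
    except EmptyInstrumentsError:
        pa.status = "not_estimable(selection)"
        return pa
    pa.stage_counts.update(inst.selection_log)

    try:
        h = harmonize(inst, outcome, maf_min=config.maf_min)
    except EmptyHarmonizationError:
        pa.status = "not_estimable(harmonization)"
        return pa
    pa.stage_counts["harmonized"] = len(h)

    h, presso_results = iterative_presso(
        h, n_sim=config.presso_n_sim,
        significance=config.presso_significance, seed=seed)
    pa.presso_global_pvals = [r.global_pval for r in presso_results]
    for r in presso_results:
        pa.presso_outliers.extend(r.outliers)
    pa.stage_counts["after_presso"] = len(h)
    pa.stage_counts["final"] = len(h)

    estimators = {
        "ivw": IVWEstimator(model="auto"),
        "egger": EggerRegression(),
        "weighted_median": WeightedMedianEstimator(n_boot=config.n_boot,
                                                   seed=seed),
        "penalized_weighted_median": PenalizedWeightedMedianEstimator(
            n_boot=config.n_boot, seed=seed),
        "max_likelihood": MaximumLikelihoodEstimator(),
    }
    diag = Diagnostics()
    for name, est in estimators.items():
        if name == "max_likelihood" and len(h) < 2:
            pa.method_failures[name] = "not_estimable"
            continue
        try:
            est.fit_harmonized(h)
        except (InsufficientInstrumentsError, DegenerateWeightsError,
                EstimationError) as exc:
            pa.method_failures[name] = f"not_estimable: {exc}"
            continue
        result = est.result_
        if outcome.trait_type == "binary":
            result = to_odds_ratio(result)
        pa.results[name] = result
        if hasattr(est, "diagnostics_"):
            diag = diag.merged_with(est.diagnostics_)
    pa.diagnostics = diag

    if "ivw" not in pa.results:
        pa.status = "not_estimable(estimation)"
        return pa
    pa.significant = bool(pa.results["ivw"].pval < threshold)
    return pa


def run_direction(exposures, outcomes, config: StudyConfig,
                  direction: str) -> list[PairAnalysis]:
    threshold = bonferroni_threshold(len(exposures), config.alpha)
    pairs = []
    ordering = sorted(
        ((e, o) for e in exposures for o in outcomes),
        key=lambda eo: (eo[0].trait_id, eo[1].trait_id))
    for index, (exp, out) in enumerate(ordering):
        seed = _pair_seed(config.seed, direction, index)
        logger.info("%s: %s -> %s", direction, exp.trait_id, out.trait_id)
        pairs.append(run_pair(exp, out, config.ld, config.annotations,
                              config, direction, threshold, seed))
    return pairs


def run_bidirectional(config: StudyConfig):
    """Run the full grid in both directions.

    Returns ``(pairs, results, manifest)``: all PairAnalysis records, the
    long-format results DataFrame, and a manifest recording the version,
    seed, thresholds (exact and at printed precision) and pair counts.
    """
    forward = run_direction(config.exposures, config.outcomes, config,
                            "forward")
    reverse = run_direction(config.outcomes, config.exposures, config,
                            "reverse")
    pairs = forward + reverse
    results = results_frame(pairs)
    fwd_thr = bonferroni_threshold(len(config.exposures), config.alpha)
    rev_thr = bonferroni_threshold(len(config.outcomes), config.alpha)
    manifest = {
        "package": "mrlink",
        "version": __version__,
        "seed": config.seed,
        "n_exposures": len(config.exposures),
        "n_outcomes": len(config.outcomes),
        "forward_pairs": len(forward),
        "reverse_pairs": len(reverse),
        "thresholds": {
            "instrument_p": config.p_threshold,
            "instrument_f": config.f_threshold,
            "clump_r2": config.clump_r2,
            "clump_window_kb": config.clump_window_kb,
            "maf_min": config.maf_min,
            "alpha": config.alpha,
            "bonferroni_forward": fwd_thr,
            "bonferroni_forward_printed": round(fwd_thr, 3),
            "bonferroni_reverse": rev_thr,
            "bonferroni_reverse_printed": round(rev_thr, 3),
        },
        "presso": {"n_sim": config.presso_n_sim,
                   "significance": config.presso_significance,
                   "distortion_test": "omitted"},
        "n_boot": config.n_boot,
    }
    return pairs, results, manifest


def results_frame(pairs: list[PairAnalysis]) -> pd.DataFrame:
    rows = [row for pa in pairs for row in pa.to_records()]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_outputs(results: pd.DataFrame, manifest: dict, out_dir) -> None:
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.to_csv(out / "results.tsv", sep="\t", index=False,
                   float_format="%.10g")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
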