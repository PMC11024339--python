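"""MR-PRESSO: Monte-Carlo pleiotropy residual sum and outlier test.

The global test asks whether the observed spread of outcome effects around
the per-SNP leave-one-out causal fit exceeds what sampling error alone would
produce; the per-SNP test flags individual outliers (horizontal pleiotropy).

For each SNP j the leave-one-out IVW slope theta_{-j} is the weighted
through-origin regression of beta_Y on beta_X over the other SNPs (weights
1/se_Y^2). The observed residual is r_j = w_j (beta_Yj - theta_{-j}
beta_Xj)^2 and RSS_obs = sum_j r_j. Expected data are simulated n_sim times
as beta_X* ~ N(beta_X, se_X) and beta_Y* ~ N(theta_{-j} beta_Xj, se_Y), and
the whole leave-one-out residual computation is repeated on each simulated
dataset. Monte-Carlo p-values carry the +1 correction, so the global p can
never fall below 1/(n_sim+1); per-SNP p-values are Bonferroni-multiplied by
k and capped at 1.

``iterative_presso`` re-runs the test after each removal round until no
outlier remains, too few SNPs are left, or a hard cap of rounds is hit —
the pipeline's final screening step before estimation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .exceptions import InsufficientInstrumentsError
from .harmonize import HarmonizedSet

logger = logging.getLogger(__name__)

#: Fewest SNPs on which the test runs (leaves >= 3 for leave-one-out slopes).
MIN_SNPS = 4


@dataclass(frozen=True)
class PressoResult:
    """Outcome of one MR-PRESSO run (no distortion test; see metadata)."""

    rss_obs: float
    global_pval: float
    outlier_pvals: dict[str, float]
    outliers: tuple[str, ...]
    n_sim: int
    seed: int
    metadata: dict = field(default_factory=lambda: {"distortion_test": "omitted"})

    def to_json(self) -> str:
        return json.dumps({
            "rss_obs": self.rss_obs,
            "global_pval": self.global_pval,
            "outlier_pvals": self.outlier_pvals,
            "outliers": list(self.outliers),
            "n_sim": self.n_sim,
            "seed": self.seed,
            "metadata": self.metadata,
        }, indent=2)


def _loo_slopes(bx, by, w):
    """Leave-one-out weighted through-origin slopes, vectorized.

    Supports batched input: bx/by of shape (..., k) with weights (k,).
    """
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


class MRPresso(BaseEstimator):
    """sklearn-style wrapper: ``fit`` runs the test, fitted attributes hold
    the result (``rss_obs_``, ``global_pval_``, ``outlier_pvals_``,
    ``outliers_``, ``result_``)."""

    def __init__(self, n_sim: int = 1000, significance: float = 0.05,
                 seed: int = 0):
        self.n_sim = n_sim
        self.significance = significance
        self.seed = seed

    def fit(self, X, y, se_exposure=None, se_outcome=None, rsids=None):
        bx = np.asarray(X, dtype=float).ravel()
        by = np.asarray(y, dtype=float).ravel()
        sx = np.asarray(se_exposure, dtype=float).ravel()
        sy = np.asarray(se_outcome, dtype=float).ravel()
        k = len(bx)
        if k < MIN_SNPS:
            raise InsufficientInstrumentsError(
                f"MR-PRESSO needs >= {MIN_SNPS} SNPs, got {k}")
        rsids = list(rsids) if rsids is not None else [str(i) for i in range(k)]

        w = 1.0 / sy**2
        theta_loo = _loo_slopes(bx, by, w)
        resid_obs = w * (by - theta_loo * bx) ** 2
        rss_obs = float(np.sum(resid_obs))

        rng = np.random.default_rng(self.seed)
        bx_star = bx + sx * rng.standard_normal((self.n_sim, k))
        by_star = (theta_loo * bx + sy * rng.standard_normal((self.n_sim, k)))
        theta_loo_star = _loo_slopes(bx_star, by_star, w)
        resid_star = w * (by_star - theta_loo_star * bx_star) ** 2
        rss_star = np.sum(resid_star, axis=1)

        global_pval = float((1 + np.sum(rss_star >= rss_obs)) / (self.n_sim + 1))
        exceed = np.sum(resid_star >= resid_obs, axis=0)
        raw_p = (1 + exceed) / (self.n_sim + 1)
        adj_p = np.minimum(1.0, raw_p * k)
        outliers = tuple(r for r, p in zip(rsids, adj_p)
                         if p < self.significance)

        self.rss_obs_ = rss_obs
        self.global_pval_ = global_pval
        self.outlier_pvals_ = {r: float(p) for r, p in zip(rsids, adj_p)}
        self.outliers_ = outliers
        self.result_ = PressoResult(rss_obs=rss_obs, global_pval=global_pval,
                                    outlier_pvals=self.outlier_pvals_,
                                    outliers=outliers, n_sim=self.n_sim,
                                    seed=self.seed)
        return self


def presso_test(h: HarmonizedSet, n_sim: int = 1000,
                significance: float = 0.05, seed: int = 0) -> PressoResult:
    """Run MR-PRESSO on a harmonized set (>= 4 SNPs required)."""
    bx, by, sx, sy = h.arrays()
    est = MRPresso(n_sim=n_sim, significance=significance, seed=seed)
    est.fit(bx, by, se_exposure=sx, se_outcome=sy,
            rsids=h.pairs["rsid"].tolist())
    return est.result_


def remove_outliers(h: HarmonizedSet, p: PressoResult) -> HarmonizedSet:
    """Drop flagged outliers, extending the drop log (reason presso_outlier)."""
    if not p.outliers:
        return h
    return h.without(p.outliers, reason="presso_outlier")


def iterative_presso(h: HarmonizedSet, n_sim: int = 1000,
                     significance: float = 0.05, seed: int = 0,
                     max_rounds: int = 10):
    """Repeatedly test and remove outliers until none remain.

    Stops when no outlier is flagged, fewer than 4 SNPs remain, or
    ``max_rounds`` rounds have run. Returns ``(reduced set, results)``
    where ``results`` lists one PressoResult per round (empty when the
    initial set was too small — the test is skipped and logged).
    """
    results: list[PressoResult] = []
    for round_no in range(max_rounds):
        if len(h) < MIN_SNPS:
            if round_no == 0:
                logger.info("MR-PRESSO skipped for %s -> %s: only %d SNPs",
                            h.exposure_id, h.outcome_id, len(h))
            break
        res = presso_test(h, n_sim=n_sim, significance=significance,
                          seed=seed + round_no)
        results.append(res)
        if not res.outliers:
            break
        h = remove_outliers(h, res)
    return h, results
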