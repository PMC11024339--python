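"""Causal-effect estimators and diagnostics for summary-data MR.

Given k harmonized SNPs with exposure effects beta_X (SE se_X) and outcome
effects beta_Y (SE se_Y), each SNP gives a Wald ratio estimate
theta_j = beta_Yj / beta_Xj with first-order SE se_Yj / |beta_Xj|, and the
estimators combine them:

* **IVW** — inverse-variance-weighted mean of the ratios, identical to
  weighted regression of beta_Y on beta_X through the origin with weights
  1/se_Y^2. Cochran's Q = sum w_j (theta_j - theta)^2 measures heterogeneity;
  the fixed-effect SE is used when the Q p-value is >= 0.05 and a
  multiplicative random-effect SE (fixed SE scaled by max(1, sqrt(Q/(k-1))))
  otherwise.
* **MR-Egger** — the same regression with a free intercept, after orienting
  every SNP to beta_X >= 0; a nonzero intercept indicates directional
  horizontal pleiotropy. Inference uses t(k-2) with the residual scale
  floored at 1.
* **Weighted median** — consistent when valid instruments carry >= 50% of
  the weight; the point estimate interpolates the weighted quantile at 0.5
  and the SE comes from a seeded parametric bootstrap.
* **Penalized weighted median** — down-weights SNPs with outlying
  heterogeneity contributions (weight multiplied by min(1, 20 p_j) where
  p_j is the chi-square(1) tail of the SNP's Q contribution) before taking
  the weighted median.
* **Maximum likelihood** — profile estimate minimizing
  sum (beta_Yj - theta beta_Xj)^2 / (se_Yj^2 + theta^2 se_Xj^2), which
  unlike IVW accounts for exposure-side sampling error.

Each method is an sklearn-style estimator (``fit``, fitted attributes with a
trailing underscore, ``get_params``/``set_params``); module-level functions
are thin wrappers that consume a :class:`~mrlink.harmonize.HarmonizedSet`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (DegenerateWeightsError, EstimationError,
                         InsufficientInstrumentsError, MrLinkError)
from .harmonize import HarmonizedSet

logger = logging.getLogger(__name__)

#: 95% two-sided normal quantile used for all confidence intervals.
Z95 = 1.959964


@dataclass(frozen=True)
class MrResult:
    """One method's causal estimate for one exposure->outcome pair."""

    method: str
    n_snp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    effect_scale: str = "beta"   # "beta" or "or"
    ivw_model: str | None = None  # "fixed" | "random", IVW only


@dataclass(frozen=True)
class Diagnostics:
    """Heterogeneity and directional-pleiotropy diagnostics.

    A Cochran's Q p-value >= 0.05 indicates no significant heterogeneity;
    an Egger-intercept p-value >= 0.05 indicates no significant pleiotropy.
    """

    cochran_q: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None

    def merged_with(self, other: "Diagnostics") -> "Diagnostics":
        kwargs = {}
        for f in ("cochran_q", "q_df", "q_pval", "egger_intercept",
                  "intercept_se", "intercept_pval"):
            a, b = getattr(self, f), getattr(other, f)
            kwargs[f] = a if a is not None else b
        return Diagnostics(**kwargs)


def _as_1d(x, name):
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr.ravel()
    if arr.ndim != 1:
        raise MrLinkError(f"{name} must be one-dimensional")
    return arr


def _validate(bx, by, se_x, se_y, need_se_x):
    bx = _as_1d(bx, "X")
    by = _as_1d(by, "y")
    if se_y is None:
        raise MrLinkError("se_outcome is required")
    se_y = _as_1d(se_y, "se_outcome")
    if need_se_x:
        if se_x is None:
            raise MrLinkError("se_exposure is required for this method")
        se_x = _as_1d(se_x, "se_exposure")
    else:
        se_x = (_as_1d(se_x, "se_exposure") if se_x is not None
                else np.zeros_like(bx))
    lengths = {len(bx), len(by), len(se_x), len(se_y)}
    if len(lengths) != 1:
        raise MrLinkError("all input arrays must share one length")
    if np.any(se_y <= 0) or np.any(se_x < 0):
        raise MrLinkError("standard errors must be positive")
    # SNPs with a null exposure effect have no defined ratio
    nonzero = bx != 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} SNP(s) with beta_exposure = 0",
                      stacklevel=3)
    return bx[nonzero], by[nonzero], se_x[nonzero], se_y[nonzero]


def wald_ratios(h: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP ratio estimates: ratio, first-order SE, and IV weight.

    ratio_j = beta_out_j / beta_exp_j, se_j = se_out_j / |beta_exp_j|,
    weight w_j = 1/se_j^2. SNPs with beta_exp = 0 are dropped with a warning.
    """
    p = h.pairs
    keep = p["beta_exp"] != 0
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} SNP(s) with "
                      "beta_exposure = 0")
    p = p.loc[keep]
    ratio = p["beta_out"].to_numpy(float) / p["beta_exp"].to_numpy(float)
    se = p["se_out"].to_numpy(float) / np.abs(p["beta_exp"].to_numpy(float))
    return pd.DataFrame({"rsid": p["rsid"].to_numpy(),
                         "ratio": ratio, "se": se, "weight": 1.0 / se**2})


def _normal_result(method, k, beta, se, effect_scale="beta", ivw_model=None):
    pval = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 1.0
    pval = max(pval, np.nextafter(0, 1))
    return MrResult(method=method, n_snp=int(k), beta=float(beta),
                    se=float(se), ci_low=float(beta - Z95 * se),
                    ci_high=float(beta + Z95 * se), pval=min(pval, 1.0),
                    effect_scale=effect_scale, ivw_model=ivw_model)


class _SummaryMrEstimator(RegressorMixin, BaseEstimator):
    """Shared fit plumbing: inputs are per-SNP effects, not samples."""

    _needs_se_x = False
    _min_snps = 2
    method_name = "base"

    def fit(self, X, y, se_exposure=None, se_outcome=None):
        """Fit from per-SNP exposure effects ``X`` and outcome effects ``y``."""
        bx, by, sx, sy = _validate(X, y, se_exposure, se_outcome,
                                   self._needs_se_x)
        if len(bx) < self._min_snps:
            raise InsufficientInstrumentsError(
                f"{self.method_name} needs >= {self._min_snps} SNPs with "
                f"nonzero exposure effects, got {len(bx)}")
        self.n_snp_ = len(bx)
        self._fit(bx, by, sx, sy)
        self.ci_low_ = self.beta_ - Z95 * self.se_
        self.ci_high_ = self.beta_ + Z95 * self.se_
        return self

    def fit_harmonized(self, h: HarmonizedSet):
        bx, by, sx, sy = h.arrays()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return self.fit(bx, by, se_exposure=sx, se_outcome=sy)

    def predict(self, X):
        return self.beta_ * _as_1d(X, "X")

    @property
    def result_(self) -> MrResult:
        return _normal_result(self.method_name, self.n_snp_, self.beta_,
                              self.se_,
                              ivw_model=getattr(self, "model_", None))


class IVWEstimator(_SummaryMrEstimator):
    """Inverse-variance-weighted estimator with the fixed/random switch.

    Parameters
    ----------
    model : {"auto", "fixed", "random"}
        "auto" applies the rule: fixed-effect SE when Cochran's Q p >= 0.05,
        multiplicative random-effect SE otherwise.
    """

    _min_snps = 2
    method_name = "ivw"

    def __init__(self, model: str = "auto"):
        self.model = model

    def _fit(self, bx, by, sx, sy):
        if self.model not in ("auto", "fixed", "random"):
            raise MrLinkError(f"unknown IVW model rule {self.model!r}")
        ratio = by / bx
        w = bx**2 / sy**2          # == 1/(se_out/|beta_exp|)^2
        beta = float(np.sum(w * ratio) / np.sum(w))
        se_fixed = float(np.sqrt(1.0 / np.sum(w)))
        k = len(bx)
        q = float(np.sum(w * (ratio - beta) ** 2))
        q_df = k - 1
        q_pval = float(stats.chi2.sf(q, q_df))
        scale = max(1.0, np.sqrt(q / q_df))
        if self.model == "fixed":
            model = "fixed"
        elif self.model == "random":
            model = "random"
        else:
            model = "random" if q_pval < 0.05 else "fixed"
        self.beta_ = beta
        self.se_ = se_fixed if model == "fixed" else se_fixed * scale
        self.se_fixed_ = se_fixed
        self.model_ = model
        self.q_, self.q_df_, self.q_pval_ = q, q_df, q_pval

    @property
    def diagnostics_(self) -> Diagnostics:
        return Diagnostics(cochran_q=self.q_, q_df=self.q_df_,
                           q_pval=self.q_pval_)


class EggerRegression(_SummaryMrEstimator):
    """MR-Egger weighted regression with a free pleiotropy intercept."""

    _min_snps = 3
    method_name = "egger"

    def _fit(self, bx, by, sx, sy):
        # orient so every exposure effect is non-negative
        sign = np.where(bx < 0, -1.0, 1.0)
        bx, by = bx * sign, by * sign
        w = 1.0 / sy**2
        X = np.column_stack([np.ones_like(bx), bx])
        xtwx = X.T @ (w[:, None] * X)
        xtwy = X.T @ (w * by)
        coef = np.linalg.solve(xtwx, xtwy)
        resid = by - X @ coef
        k = len(bx)
        rss_w = float(np.sum(w * resid**2))
        phi = max(1.0, np.sqrt(rss_w / (k - 2)))
        cov = phi**2 * np.linalg.inv(xtwx)
        self.intercept_, self.beta_ = float(coef[0]), float(coef[1])
        self.intercept_se_ = float(np.sqrt(cov[0, 0]))
        self.se_ = float(np.sqrt(cov[1, 1]))
        self.phi_ = float(phi)
        self.df_ = k - 2
        self.intercept_pval_ = float(
            2.0 * stats.t.sf(abs(self.intercept_) / self.intercept_se_, self.df_))

    def predict(self, X):
        return self.intercept_ + self.beta_ * _as_1d(X, "X")

    @property
    def result_(self) -> MrResult:
        pval = float(2.0 * stats.t.sf(abs(self.beta_) / self.se_, self.df_))
        return MrResult(method=self.method_name, n_snp=self.n_snp_,
                        beta=self.beta_, se=self.se_, ci_low=self.ci_low_,
                        ci_high=self.ci_high_, pval=min(max(pval, 1e-300), 1.0))

    @property
    def diagnostics_(self) -> Diagnostics:
        return Diagnostics(egger_intercept=self.intercept_,
                           intercept_se=self.intercept_se_,
                           intercept_pval=self.intercept_pval_)


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ratio estimates.

    Sort ratios ascending; with normalized weights w', the cumulative
    midpoint of SNP j is p_j = sum_{i<=j} w'_i - w'_j/2. The estimate
    linearly interpolates the ratio between the midpoints straddling 0.5
    (exactly the ratio when some p_j = 0.5).
    """
    total = weights.sum()
    if total <= 0:
        raise DegenerateWeightsError("all weights are zero")
    order = np.argsort(ratios, kind="mergesort")
    r, w = ratios[order], weights[order] / total
    cum = np.cumsum(w) - w / 2.0
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    idx = int(np.searchsorted(cum, 0.5))
    if cum[idx] == 0.5:
        return float(r[idx])
    j = idx - 1
    frac = (0.5 - cum[j]) / (cum[j + 1] - cum[j])
    return float(r[j] + (r[j + 1] - r[j]) * frac)


def _penalized_weights(ratios, weights, theta, penalty_k):
    """Down-weight SNPs by their heterogeneity tail probability."""
    q_j = weights * (ratios - theta) ** 2
    p_j = stats.chi2.sf(q_j, df=1)
    return weights * np.minimum(1.0, penalty_k * p_j)


class WeightedMedianEstimator(_SummaryMrEstimator):
    """Weighted-median estimator with parametric-bootstrap SE.

    Parameters
    ----------
    n_boot : int
        Bootstrap draws for the SE (exposure and outcome effects resampled
        from normal distributions centred on the observed values).
    seed : int
        Seed for the bootstrap RNG; fixed seeds make results reproducible.
    """

    _needs_se_x = True
    _min_snps = 3
    method_name = "weighted_median"

    def __init__(self, n_boot: int = 1000, seed: int = 0):
        self.n_boot = n_boot
        self.seed = seed

    def _point_estimate(self, bx, by, sy):
        ratio = by / bx
        weights = bx**2 / sy**2
        return _weighted_median(ratio, weights)

    def _fit(self, bx, by, sx, sy):
        self.beta_ = self._point_estimate(bx, by, sy)
        self.se_ = self._bootstrap_se(bx, by, sx, sy)

    def _bootstrap_se(self, bx, by, sx, sy):
        rng = np.random.default_rng(self.seed)
        zx = rng.standard_normal((self.n_boot, len(bx)))
        zy = rng.standard_normal((self.n_boot, len(bx)))
        bx_star = bx + sx * zx
        by_star = by + sy * zy
        draws = np.empty(self.n_boot)
        for b in range(self.n_boot):
            bxb, byb = bx_star[b], by_star[b]
            ok = bxb != 0
            try:
                draws[b] = self._point_estimate(bxb[ok], byb[ok], sy[ok])
            except DegenerateWeightsError:
                draws[b] = np.nan
        draws = draws[~np.isnan(draws)]
        if len(draws) < 2:
            raise EstimationError("bootstrap produced too few valid draws")
        return float(np.std(draws, ddof=1))


class PenalizedWeightedMedianEstimator(WeightedMedianEstimator):
    """Weighted median with heterogeneity-penalized weights.

    SNP j's weight is multiplied by min(1, penalty_k * p_j), p_j being the
    upper chi-square(1) tail of its Q contribution at the unpenalized
    weighted-median estimate; gross outliers get weight ~0.
    """

    method_name = "penalized_weighted_median"

    def __init__(self, penalty_k: float = 20.0, n_boot: int = 1000,
                 seed: int = 0):
        self.penalty_k = penalty_k
        super().__init__(n_boot=n_boot, seed=seed)

    def _point_estimate(self, bx, by, sy):
        ratio = by / bx
        weights = bx**2 / sy**2
        theta0 = _weighted_median(ratio, weights)
        w_pen = _penalized_weights(ratio, weights, theta0, self.penalty_k)
        if not np.any(w_pen > 0):
            raise DegenerateWeightsError(
                "all penalized weights are zero (penalty_k too small?)")
        return _weighted_median(ratio, w_pen)


class MaximumLikelihoodEstimator(_SummaryMrEstimator):
    """Profile-likelihood estimator accounting for exposure-side error.

    Minimizes L(theta) = sum (beta_Yj - theta beta_Xj)^2 /
    (se_Yj^2 + theta^2 se_Xj^2) over a bracket around the IVW estimate;
    the SE comes from the curvature of L/2 at the optimum (central
    differences). In the se_X -> 0 limit this reduces to fixed-effect IVW.
    """

    _needs_se_x = True
    _min_snps = 1
    method_name = "max_likelihood"

    def __init__(self, bracket_factor: float = 10.0, xatol: float = 1e-10):
        self.bracket_factor = bracket_factor
        self.xatol = xatol

    def _fit(self, bx, by, sx, sy):
        def loss(theta):
            return float(np.sum((by - theta * bx) ** 2
                                / (sy**2 + theta**2 * sx**2)))

        w = bx**2 / sy**2
        b0 = float(np.sum(by * bx / sy**2) / np.sum(w))
        se0 = float(np.sqrt(1.0 / np.sum(w)))
        half = self.bracket_factor * max(abs(b0), 5.0 * se0, 1e-3)
        for _ in range(3):
            res = optimize.minimize_scalar(
                loss, bounds=(b0 - half, b0 + half), method="bounded",
                options={"xatol": self.xatol})
            if not res.success:
                raise EstimationError("bounded minimization failed")
            margin = 1e-6 * half
            if (res.x - (b0 - half) > margin) and ((b0 + half) - res.x > margin):
                break
            half *= 10.0   # optimum pinned at the bracket edge: widen once more
        else:
            raise EstimationError("optimum stuck at bracket boundary")
        theta = float(res.x)
        h = 1e-4 * (1.0 + abs(theta))
        curv = (loss(theta + h) - 2.0 * loss(theta) + loss(theta - h)) / h**2
        if curv <= 0:
            raise EstimationError("non-positive curvature at optimum")
        self.beta_ = theta
        self.se_ = float(np.sqrt(1.0 / (curv / 2.0)))


# ---------------------------------------------------------------------------
# Functional wrappers over a HarmonizedSet


def ivw(h: HarmonizedSet, model_rule: str = "auto") -> tuple[MrResult, Diagnostics]:
    est = IVWEstimator(model=model_rule).fit_harmonized(h)
    return est.result_, est.diagnostics_


def mr_egger(h: HarmonizedSet) -> tuple[MrResult, Diagnostics]:
    est = EggerRegression().fit_harmonized(h)
    return est.result_, est.diagnostics_


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MrResult:
    return WeightedMedianEstimator(n_boot=n_boot, seed=seed) \
        .fit_harmonized(h).result_


def penalized_weighted_median(h: HarmonizedSet, penalty_k: float = 20.0,
                              n_boot: int = 1000, seed: int = 0) -> MrResult:
    return PenalizedWeightedMedianEstimator(
        penalty_k=penalty_k, n_boot=n_boot, seed=seed).fit_harmonized(h).result_


def max_likelihood(h: HarmonizedSet) -> MrResult:
    return MaximumLikelihoodEstimator().fit_harmonized(h).result_


def to_odds_ratio(r: MrResult) -> MrResult:
    """Exponentiate a log-odds causal estimate into an odds ratio.

    Valid only for binary outcomes, whose betas are log-odds; the p-value is
    unchanged and ``se`` keeps its log-scale value.
    """
    if r.effect_scale != "beta":
        raise MrLinkError("result is already on the odds-ratio scale")
    return replace(r, beta=float(np.exp(r.beta)),
                   ci_low=float(np.exp(r.ci_low)),
                   ci_high=float(np.exp(r.ci_high)), effect_scale="or")
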