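"""The five MR estimators and their diagnostics, checked against
independent oracles (statsmodels WLS, grid search, re-implemented
interpolation) and known closed-form cases."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st
from scipy import stats

from conftest import make_h, tables_to_harmonized
from mrlink.estimators import (EggerRegression, IVWEstimator,
                               MaximumLikelihoodEstimator,
                               PenalizedWeightedMedianEstimator,
                               WeightedMedianEstimator, _weighted_median,
                               ivw, max_likelihood, mr_egger,
                               penalized_weighted_median, to_odds_ratio,
                               wald_ratios, weighted_median)
from mrlink.exceptions import (DegenerateWeightsError,
                               InsufficientInstrumentsError, MrLinkError)
from mrlink.simulate import SimulationConfig, simulate_pair


def _random_instance(rng, k=20):
    bx = rng.normal(0.15, 0.05, k) * rng.choice([-1, 1], k)
    sx = rng.uniform(0.01, 0.03, k)
    sy = rng.uniform(0.01, 0.03, k)
    by = 0.3 * bx + rng.normal(0, 0.02, k)
    return bx, by, sx, sy


def test_wald_ratios_closed_form_and_sign():
    h = make_h([0.5, -0.5], [0.1, 0.1], sy=[0.05, 0.05])
    w = wald_ratios(h)
    assert w["ratio"].tolist() == pytest.approx([0.2, -0.2])
    assert w["se"].tolist() == pytest.approx([0.1, 0.1])
    assert w["weight"].tolist() == pytest.approx([100.0, 100.0])


def test_wald_ratios_drop_zero_exposure_effect_with_warning(rng):
    bx, by, sx, sy = _random_instance(rng, 100)
    bx[7] = 0.0
    with pytest.warns(UserWarning, match="beta_exposure = 0"):
        w = wald_ratios(make_h(bx, by, sx, sy))
    assert len(w) == 99
    keep = bx != 0
    assert np.allclose(w["weight"], bx[keep] ** 2 / sy[keep] ** 2, rtol=1e-12)


def test_ivw_two_snp_hand_case():
    # ratios 0.5 and 0.3 with equal ratio SE 0.1 -> mean 0.4, SE sqrt(1/200)
    h = make_h([1.0, 1.0], [0.5, 0.3], sy=[0.1, 0.1])
    r, d = ivw(h)
    assert r.beta == pytest.approx(0.4, abs=1e-12)
    est = IVWEstimator(model="fixed").fit_harmonized(h)
    assert est.se_ == pytest.approx(np.sqrt(1 / 200), abs=1e-12)


def test_ivw_degenerate_heterogeneity_chooses_fixed():
    h = make_h([1.0, 2.0, 4.0], [0.5, 1.0, 2.0], sy=[0.1, 0.1, 0.1])
    r, d = ivw(h)
    assert d.cochran_q == pytest.approx(0.0, abs=1e-20)
    assert d.q_pval == pytest.approx(1.0)
    assert r.ivw_model == "fixed"


def test_ivw_and_egger_match_wls_oracle(rng):
    """200 random instances: closed forms equal statsmodels WLS to 1e-10."""
    for _ in range(200):
        k = rng.integers(3, 40)
        bx, by, sx, sy = _random_instance(rng, k)
        h = make_h(bx, by, sx, sy)
        w = 1.0 / sy**2

        fit0 = sm.WLS(by, bx, weights=w).fit()
        est = IVWEstimator(model="fixed").fit_harmonized(h)
        assert est.beta_ == pytest.approx(fit0.params[0], abs=1e-10)

        sign = np.where(bx < 0, -1, 1)
        X = sm.add_constant(bx * sign)
        fit1 = sm.WLS(by * sign, X, weights=w).fit()
        egger = EggerRegression().fit_harmonized(h)
        assert egger.intercept_ == pytest.approx(fit1.params[0], abs=1e-10)
        assert egger.beta_ == pytest.approx(fit1.params[1], abs=1e-10)


def test_egger_se_matches_wls_when_scale_above_one(rng):
    bx = rng.normal(0.2, 0.05, 25)
    by = 0.3 * bx + rng.normal(0, 0.2, 25)   # gross overdispersion
    sy = np.full(25, 0.02)
    h = make_h(bx, by, sy=sy)
    egger = EggerRegression().fit_harmonized(h)
    assert egger.phi_ > 1
    fit = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
    assert egger.se_ == pytest.approx(fit.bse[1], rel=1e-10)
    assert egger.intercept_se_ == pytest.approx(fit.bse[0], rel=1e-10)


def test_egger_exact_fit_recovers_line():
    bx = np.array([0.1, 0.2, 0.3])
    by = 0.1 + 0.6 * bx
    egger = EggerRegression().fit_harmonized(make_h(bx, by))
    assert egger.beta_ == pytest.approx(0.6, abs=1e-10)
    assert egger.intercept_ == pytest.approx(0.1, abs=1e-10)
    assert egger.phi_ == 1.0   # RSS 0 floors the scale


def test_egger_intercept_calibrated_under_no_pleiotropy():
    """Without pleiotropy the intercept should sit within 3 SE of zero in
    ~99.7% of replicates; allow a small margin over 300 draws."""
    hits = 0
    for seed in range(300):
        cfg = SimulationConfig(n_snp=30, n_instrument=30, theta=0.3,
                               seed=seed)
        exposure, outcome, _ = simulate_pair(cfg)
        egger = EggerRegression().fit_harmonized(
            tables_to_harmonized(exposure, outcome))
        hits += abs(egger.intercept_) <= 3 * egger.intercept_se_
    assert hits / 300 >= 0.98


def test_weighted_median_symmetric_case_and_exact_midpoint():
    h = make_h([1.0, 1.0, 1.0], [0.2, 0.4, 0.6], sy=[0.1, 0.1, 0.1])
    est = WeightedMedianEstimator(n_boot=50, seed=0).fit_harmonized(h)
    assert est.beta_ == pytest.approx(0.4, abs=1e-12)


def _wm_oracle(ratios, weights):
    """Plain-loop re-implementation of the interpolated weighted median."""
    pairs = sorted(zip(ratios, weights))
    total = sum(w for _, w in pairs)
    cum = 0.0
    points = []
    for r, w in pairs:
        points.append((cum + w / 2.0 / total, r))
        cum += w / total
    if points[0][0] >= 0.5:
        return points[0][1]
    if points[-1][0] <= 0.5:
        return points[-1][1]
    for (p0, r0), (p1, r1) in zip(points, points[1:]):
        if p0 == 0.5:
            return r0
        if p0 < 0.5 <= p1:
            if p1 == 0.5:
                return r1
            return r0 + (r1 - r0) * (0.5 - p0) / (p1 - p0)


@given(st.lists(st.tuples(st.floats(-5, 5), st.floats(0.01, 10)),
                min_size=1, max_size=30))
def test_weighted_median_matches_interpolation_oracle(pairs):
    ratios = np.array([r for r, _ in pairs])
    weights = np.array([w for _, w in pairs])
    assert _weighted_median(ratios, weights) == pytest.approx(
        _wm_oracle(ratios, weights), abs=1e-12)


def test_weighted_median_approaches_simple_median_with_equal_weights(rng):
    ratios = rng.normal(0.3, 0.05, 501)
    assert _weighted_median(ratios, np.ones(501)) == pytest.approx(
        np.median(ratios), abs=1e-9)


def test_weighted_median_bootstrap_is_seeded():
    h = make_h(*_random_instance(np.random.default_rng(0)))
    a = WeightedMedianEstimator(n_boot=200, seed=42).fit_harmonized(h)
    b = WeightedMedianEstimator(n_boot=200, seed=42).fit_harmonized(h)
    c = WeightedMedianEstimator(n_boot=200, seed=43).fit_harmonized(h)
    assert a.se_ == b.se_
    assert a.se_ != c.se_


def test_penalized_median_equals_unpenalized_without_outliers():
    h = make_h([1.0, 1.0, 1.0, 1.0], [0.30, 0.31, 0.29, 0.305],
               sy=[0.1, 0.1, 0.1, 0.1])
    wm = WeightedMedianEstimator(n_boot=20, seed=0).fit_harmonized(h)
    pwm = PenalizedWeightedMedianEstimator(n_boot=20, seed=0) \
        .fit_harmonized(h)
    assert pwm.beta_ == pytest.approx(wm.beta_, abs=1e-12)


def test_penalty_zero_is_degenerate():
    h = make_h(*_random_instance(np.random.default_rng(1)))
    with pytest.raises(DegenerateWeightsError):
        PenalizedWeightedMedianEstimator(penalty_k=0.0, n_boot=10, seed=0) \
            .fit_harmonized(h)


def test_penalized_median_beats_ivw_with_gross_outlier(rng):
    """One wild ratio among 20 concordant SNPs: the penalized estimate is
    closer to truth than IVW in >= 95% of 200 replicates."""
    wins = 0
    for _ in range(200):
        bx, by, sx, sy = _random_instance(rng, 20)
        by = 0.3 * bx + rng.normal(0, 0.02, 20)
        by[0] += 2.0 * np.sign(bx[0])    # gross direct effect, ratio off by ~13
        h = make_h(bx, by, sx, sy)
        pen = PenalizedWeightedMedianEstimator(n_boot=2, seed=0) \
            .fit_harmonized(h).beta_
        naive = IVWEstimator().fit_harmonized(h).beta_
        wins += abs(pen - 0.3) < abs(naive - 0.3)
    assert wins / 200 >= 0.95


def test_max_likelihood_matches_grid_oracle(rng):
    """Two-stage grid search at 1e-6 resolution agrees to 1e-5."""
    for _ in range(10):
        bx, by, sx, sy = _random_instance(rng, 15)
        est = MaximumLikelihoodEstimator().fit(bx, by, se_exposure=sx,
                                               se_outcome=sy)

        def loss(theta):
            theta = np.atleast_1d(theta)[:, None]
            return np.sum((by - theta * bx) ** 2
                          / (sy**2 + theta**2 * sx**2), axis=1)

        coarse = np.arange(-1.0, 1.0, 1e-3)
        t0 = coarse[np.argmin(loss(coarse))]
        fine = np.arange(t0 - 2e-3, t0 + 2e-3, 1e-6)
        t1 = fine[np.argmin(loss(fine))]
        assert est.beta_ == pytest.approx(t1, abs=1e-5)


def test_max_likelihood_limits():
    rng = np.random.default_rng(5)
    bx, by, _, sy = _random_instance(rng, 30)
    sx0 = np.full(30, 1e-8)
    ml = MaximumLikelihoodEstimator().fit(bx, by, se_exposure=sx0,
                                          se_outcome=sy)
    ivw_est = IVWEstimator(model="fixed").fit(bx, by, se_outcome=sy)
    assert ml.beta_ == pytest.approx(ivw_est.beta_, abs=1e-6)
    # single SNP without exposure error reduces to the Wald ratio
    single = MaximumLikelihoodEstimator().fit([0.5], [0.1],
                                              se_exposure=[0.0],
                                              se_outcome=[0.05])
    assert single.beta_ == pytest.approx(0.2, abs=1e-8)


def test_odds_ratio_transform():
    h = make_h([1.0, 1.0], [np.log(2), np.log(2)], sy=[0.1, 0.1])
    r, _ = ivw(h)
    orr = to_odds_ratio(r)
    assert orr.beta == pytest.approx(2.0)
    assert orr.effect_scale == "or"
    assert orr.pval == r.pval
    assert orr.ci_low < orr.beta < orr.ci_high   # exp is monotone
    zero = to_odds_ratio(ivw(make_h([1., 1.], [0., 0.], sy=[.1, .1]))[0])
    assert zero.beta == pytest.approx(1.0)
    with pytest.raises(MrLinkError):
        to_odds_ratio(orr)


@given(st.floats(0.1, 10.0))
def test_scale_equivariance_of_all_methods(c):
    """Rescaling exposure betas and SEs by c divides every estimate by c."""
    rng = np.random.default_rng(17)
    bx, by, sx, sy = _random_instance(rng, 12)
    h1 = make_h(bx, by, sx, sy)
    h2 = make_h(c * bx, by, c * sx, sy)
    for fn in (lambda h: ivw(h)[0], lambda h: mr_egger(h)[0],
               lambda h: weighted_median(h, n_boot=20, seed=3),
               lambda h: penalized_weighted_median(h, n_boot=20, seed=3),
               max_likelihood):
        r1, r2 = fn(h1), fn(h2)
        assert r2.beta == pytest.approx(r1.beta / c, rel=1e-7)


@pytest.mark.parametrize("cls,k", [
    (IVWEstimator, 1), (EggerRegression, 2), (WeightedMedianEstimator, 2),
    (PenalizedWeightedMedianEstimator, 2),
])
def test_methods_reject_too_few_instruments(cls, k):
    h = make_h(np.ones(k), np.zeros(k))
    with pytest.raises(InsufficientInstrumentsError):
        cls().fit_harmonized(h)
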