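"""Regression stage: saturated-model identities, independent-optimizer
oracles, chi-square arithmetic, and null recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import chi2

from ltarisk import effects
from ltarisk import simulate as sim


def _toy_trial(seed=0, n=800, p1=None, p0=None):
    """Directly simulated classify-analyze dataset with known cell probs."""
    rng = np.random.default_rng(seed)
    classes = rng.integers(0, 4, size=n)
    arm = rng.integers(0, 2, size=n).astype(float)
    if p1 is None:
        p1 = np.array([0.95, 0.64, 0.68, 0.53])
    if p0 is None:
        p0 = np.array([0.87, 0.71, 0.61, 0.37])
    p = np.where(arm == 1, p1[classes], p0[classes])
    low = (rng.random(n) < p).astype(float)
    return low, arm, classes


def test_saturated_logit_reproduces_cell_proportions():
    low, arm, classes = _toy_trial(seed=1)
    m = effects.lowrisk_glm(low, arm, classes)
    phat = np.asarray(m.result.predict(m.design))
    df = pd.DataFrame({"low": low, "arm": arm, "k": classes, "p": phat})
    for (a, k), cell in df.groupby(["arm", "k"]):
        assert cell["p"].to_numpy() == pytest.approx(cell["low"].mean(), abs=1e-8)


def test_saturated_ame_equals_raw_proportion_difference():
    low, arm, classes = _toy_trial(seed=2)
    m = effects.lowrisk_glm(low, arm, classes)
    ames = {a.baseline_class: a for a in effects.average_marginal_effects(m)}
    df = pd.DataFrame({"low": low, "arm": arm, "k": classes})
    for k, sub in df.groupby("k"):
        raw = (sub.loc[sub["arm"] == 1, "low"].mean()
               - sub.loc[sub["arm"] == 0, "low"].mean())
        assert ames[k].dydx == pytest.approx(raw, abs=1e-8)
        assert -1.0 <= ames[k].dydx <= 1.0
        assert ames[k].se > 0


def test_logit_deviance_matches_independent_optimizer():
    low, arm, classes = _toy_trial(seed=3, n=30)
    m = effects.lowrisk_glm(low, arm, classes)
    X = m.design

    def negll(beta):
        eta = X @ beta
        return -(low * eta - np.log1p(np.exp(eta))).sum()

    res = minimize(negll, np.zeros(X.shape[1]), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 2000})
    assert -res.fun == pytest.approx(m.result.llf, abs=1e-6)


def test_arm_odds_ratio_closed_form():
    low, arm, classes = _toy_trial(seed=4, n=20_000)
    m = effects.lowrisk_glm(low, arm, classes)
    df = pd.DataFrame({"low": low, "arm": arm, "k": classes})
    sub = df[df["k"] == 3]
    pa = sub.loc[sub["arm"] == 1, "low"].mean()
    pb = sub.loc[sub["arm"] == 0, "low"].mean()
    expected = (pa / (1 - pa)) / (pb / (1 - pb))
    orr = effects.arm_odds_ratio(m, 3)
    assert orr.odds_ratio == pytest.approx(expected, rel=1e-6)
    assert orr.ci_low < orr.odds_ratio < orr.ci_high


def test_empty_cell_raises():
    low, arm, classes = _toy_trial(seed=5, n=200)
    arm[classes == 2] = 0.0  # no treated subjects in class 2
    with pytest.raises(ValueError, match="empty"):
        effects.lowrisk_glm(low, arm, classes)


def test_null_interaction_recovery():
    """Equal transitions across arms: interaction terms estimate ~0."""
    cfg = sim.default_paper_config(n=50_000, seed=6)
    cfg.tau = {"control": sim.TAU_CONTROL.copy(),
               "pei": sim.TAU_CONTROL.copy()}
    coh = sim.generate(cfg)
    t = coh.truth[~coh.truth["dropped"]]
    low = (t["class_w2"] == 0).to_numpy(dtype=float)
    arm = (t["arm"] == "pei").to_numpy(dtype=float)
    m = effects.lowrisk_glm(low, arm, t["class_w1"].to_numpy())
    beta = np.asarray(m.result.params)
    for ci in m.interaction_cols.values():
        assert abs(beta[ci]) < 0.12
    ames = effects.average_marginal_effects(m)
    assert max(abs(a.dydx) for a in ames) < 0.03


def test_ame_ci_coverage_under_null():
    """Zero-effect generator: 95% CIs cover 0 at roughly nominal rate."""
    rng = np.random.default_rng(7)
    covered = total = 0
    for _ in range(200):
        low, arm, classes = _toy_trial(
            seed=int(rng.integers(2**31)), n=1200,
            p1=np.array([0.8, 0.6, 0.5, 0.4]),
            p0=np.array([0.8, 0.6, 0.5, 0.4]))
        m = effects.lowrisk_glm(low, arm, classes)
        for a in effects.average_marginal_effects(m):
            covered += a.ci_low <= 0.0 <= a.ci_high
            total += 1
    rate = covered / total
    assert 0.92 < rate < 0.98


def test_multinomial_rrr_cross_product_closed_form():
    """Binary covariate, 2 classes: RRR equals the 2x2 cross-product ratio."""
    y = np.repeat([0, 0, 1, 1], [40, 60, 30, 20])
    x = np.r_[np.zeros(40), np.ones(60), np.zeros(30), np.ones(20)]
    tab = effects.multinomial_rrr(y, pd.DataFrame({"x": x}), reference_class=0)
    expected = (20 * 40) / (30 * 60)
    est = [e for e in tab.estimates if e.covariate == "x"][0]
    assert est.rrr == pytest.approx(expected, rel=1e-6)
    assert est.ci_low < est.rrr < est.ci_high
    assert tab.df == 1


def test_multinomial_loglik_matches_direct_optimizer():
    rng = np.random.default_rng(8)
    y = rng.integers(0, 3, size=60)
    x = rng.normal(size=60)
    tab = effects.multinomial_rrr(y, pd.DataFrame({"x": x}))

    def negll(theta):
        b = theta.reshape(2, 2)  # (const, slope) for classes 1 and 2
        eta = np.column_stack([np.zeros(60), b[:, 0] + np.outer(x, b[:, 1])])
        return -(eta[np.arange(60), y]
                 - np.log(np.exp(eta).sum(axis=1))).sum()

    res = minimize(negll, np.zeros(4), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 5000})
    assert -res.fun == pytest.approx(tab.loglik, abs=1e-6)


def test_multinomial_null_covariate():
    rng = np.random.default_rng(9)
    y = rng.integers(0, 3, size=10_000)
    x = rng.integers(0, 2, size=10_000).astype(float)
    tab = effects.multinomial_rrr(y, pd.DataFrame({"x": x}))
    for e in tab.estimates:
        assert e.rrr == pytest.approx(1.0, abs=0.2)
    assert tab.p_value > 0.001


def test_multinomial_separation_detected():
    y = np.repeat([0, 1], 30)
    x = y.astype(float)  # perfectly predicts class
    with pytest.raises(ValueError, match="separation"):
        effects.multinomial_rrr(y, pd.DataFrame({"x": x}))


def test_attrition_chi2_hand_example():
    # 2x2 table [[10, 90], [20, 80]]: expected cells 15/85, chi2 = 3.9216
    arm = np.repeat([0, 1], 100)
    returned = np.r_[np.repeat([False, True], [10, 90]),
                     np.repeat([False, True], [20, 80])]
    stat, p = effects.attrition_test(returned, arm)
    expected = 25 / 15 + 25 / 85 + 25 / 15 + 25 / 85
    assert stat == pytest.approx(expected)
    assert p == pytest.approx(float(chi2.sf(expected, 1)))


def test_attrition_equal_rates_gives_zero():
    arm = np.repeat([0, 1], 50)
    returned = np.tile(np.repeat([True, False], [45, 5]), 2)
    stat, p = effects.attrition_test(returned, arm)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_attrition_symmetry_under_joint_relabeling():
    rng = np.random.default_rng(10)
    arm = rng.integers(0, 2, 300)
    returned = rng.random(300) < 0.8 - 0.1 * arm
    s1, _ = effects.attrition_test(returned, arm)
    s2, _ = effects.attrition_test(~returned, 1 - arm)
    assert s1 == pytest.approx(s2)


def test_participation_bias_df_and_null():
    rng = np.random.default_rng(11)
    classes = rng.integers(0, 4, size=2000)
    randomized = rng.random(2000) < 0.54
    stat, df, p = effects.participation_bias_test(classes, randomized)
    assert df == 3
    assert p > 0.001
    # identical distributions -> exactly zero
    k = np.repeat([0, 1, 2, 3], 50)
    r = np.tile([True, False], 100)
    stat0, _, _ = effects.participation_bias_test(k, r)
    assert stat0 == pytest.approx(0.0, abs=1e-12)
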