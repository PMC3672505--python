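"""Transition-model engine: oracles, constraints, recovery and the scaled
likelihood-ratio machinery."""

import numpy as np
import pytest

from conftest import brute_force_lta_loglik
from ltarisk import lta
from ltarisk import simulate as sim
from ltarisk._utils import MISSING


def _tiny_two_wave(seed=0, n=20, J=2):
    rng = np.random.default_rng(seed)
    X1 = rng.integers(0, 3, size=(n, J))
    X2 = rng.integers(0, 3, size=(n, J))
    X2[rng.random(n) < 0.25] = MISSING  # some lost to follow-up
    arm = np.where(rng.random(n) < 0.5, "pei", "control")
    return X1, X2, arm


def test_loglik_matches_pair_enumeration_oracle():
    X1, X2, arm = _tiny_two_wave(seed=1)
    m = lta.fit_lta(X1, X2, arm, K=2, n_starts=3, warm_start_starts=3, seed=2)
    arm_idx = np.array([m.arm_labels.index(a) for a in arm])
    oracle = brute_force_lta_loglik(X1, X2, arm_idx, m.delta,
                                    [m.tau_for(a) for a in m.arm_labels],
                                    m.pi1[0], m.pi2[0])
    assert m.loglik == pytest.approx(oracle, abs=1e-8)


def test_loglik_oracle_without_time_invariance():
    X1, X2, arm = _tiny_two_wave(seed=3, n=30)
    m = lta.fit_lta(X1, X2, arm, K=2, time_invariant=False, n_starts=3, seed=4)
    arm_idx = np.array([m.arm_labels.index(a) for a in arm])
    oracle = brute_force_lta_loglik(X1, X2, arm_idx, m.delta,
                                    [m.tau_for(a) for a in m.arm_labels],
                                    m.pi1[0], m.pi2[0])
    assert m.loglik == pytest.approx(oracle, abs=1e-8)


def test_em_trace_monotone_and_converged():
    X1, X2, arm = _tiny_two_wave(seed=5, n=60)
    m = lta.fit_lta(X1, X2, arm, K=2, n_starts=2, seed=6)
    assert (np.diff(m.loglik_trace) >= -1e-8).all()
    assert m.converged


def test_parameter_counts():
    X1, X2, arm = _tiny_two_wave(seed=7, n=40, J=3)
    inv = lta.fit_lta(X1, X2, arm, K=2, n_starts=2, seed=8)
    # delta: 1; tau: 2 arms * 2 rows * 1; measurement: 2 classes * 3 items * 2
    assert inv.n_params == 1 + 4 + 12
    free = lta.fit_lta(X1, X2, arm, K=2, time_invariant=False, init=inv, seed=8)
    assert free.n_params == inv.n_params + 12
    partial = lta.fit_lta(X1, X2, arm, K=2, free_classes=(1,), init=inv, seed=8)
    assert partial.n_params == inv.n_params + 6
    armfree = lta.fit_lta(X1, X2, arm, K=2, arm_specific_measurement=True,
                          init=inv, seed=8)
    assert armfree.n_params == inv.n_params + 12


def test_nested_ordering_and_lrt():
    X1, X2, arm = _tiny_two_wave(seed=9, n=80)
    inv = lta.fit_lta(X1, X2, arm, K=2, n_starts=3, seed=10)
    free = lta.fit_lta(X1, X2, arm, K=2, time_invariant=False, init=inv, seed=10)
    assert free.loglik >= inv.loglik - 1e-6
    res = lta.lrt_compare(inv, free)
    assert res.df == free.n_params - inv.n_params
    assert 0.0 <= res.p_value <= 1.0
    same = lta.lrt_compare(inv, free)
    assert same.statistic >= 0.0
    with pytest.raises(ValueError):
        lta.lrt_compare(free, inv)  # wrong nesting direction


def test_lrt_identical_loglik_gives_zero_stat_p_one():
    import dataclasses
    X1, X2, arm = _tiny_two_wave(seed=11, n=50)
    inv = lta.fit_lta(X1, X2, arm, K=2, n_starts=2, seed=12)
    general = dataclasses.replace(inv, n_params=inv.n_params + 12)
    res = lta.lrt_compare(inv, general)
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_single_arm_with_arm_specific_tau_errors():
    X1, X2, _ = _tiny_two_wave(seed=13)
    arm = np.array(["control"] * len(X1))
    with pytest.raises(ValueError, match="one arm"):
        lta.fit_lta(X1, X2, arm, K=2, seed=1)
    m = lta.fit_lta(X1, X2, arm, K=2, arm_specific_tau=False, n_starts=2, seed=1)
    assert m.tau.shape == (1, 2, 2)


def test_unknown_free_class_errors():
    X1, X2, arm = _tiny_two_wave(seed=14)
    with pytest.raises(ValueError, match="unknown"):
        lta.fit_lta(X1, X2, arm, K=2, free_classes=(5,), seed=1)


def test_identity_transition_recovery():
    """Generator with identity transitions: fitted diagonals near 1."""
    cfg = sim.default_paper_config(n=20_000, seed=31)
    eye = np.eye(4)
    cfg.tau = {"control": eye.copy(), "pei": eye.copy()}
    coh = sim.generate(cfg)
    X1, X2, arm = sim.two_wave_matrices(coh.records)
    # boundary MLE: EM approaches the identity geometrically, so use a
    # tighter tolerance than the interior-fit default
    m = lta.fit_lta(X1, X2, arm, K=4, n_starts=2, seed=32, tol=1e-9,
                    max_iter=3000)
    for a in m.arm_labels:
        assert np.diag(m.tau_for(a)).min() >= 0.98
    w1, w2 = lta.marginal_class_probs(m)
    assert w2 == pytest.approx(w1, abs=0.02)


def test_marginal_probs_sum_to_one_and_mix_arms():
    X1, X2, arm = _tiny_two_wave(seed=15, n=100)
    m = lta.fit_lta(X1, X2, arm, K=2, n_starts=2, seed=16)
    w1, w2 = lta.marginal_class_probs(m)
    assert w1.sum() == pytest.approx(1.0)
    assert w2.sum() == pytest.approx(1.0)
    wa = lta.marginal_class_probs(m, arm_weights=[1.0, 0.0])[1]
    wb = lta.marginal_class_probs(m, arm_weights=[0.0, 1.0])[1]
    mid = lta.marginal_class_probs(m, arm_weights=[0.5, 0.5])[1]
    assert mid == pytest.approx(0.5 * (wa + wb))


def test_missing_wave2_rows_are_mar_consistent():
    """Deleting 30% of follow-ups completely at random moves tau little."""
    cfg = sim.default_paper_config(n=40_000, seed=33)
    coh = sim.generate(cfg)
    X1, X2, arm = sim.two_wave_matrices(coh.records)
    full = lta.fit_lta(X1, X2, arm, K=4, n_starts=2, seed=34)
    rng = np.random.default_rng(35)
    X2c = X2.copy()
    X2c[rng.random(len(X2)) < 0.3] = MISSING
    cc = lta.fit_lta(X1, X2c, arm, K=4, n_starts=2, seed=36)
    for a in full.arm_labels:
        assert np.abs(full.tau_for(a) - cc.tau_for(a)).max() < 0.02


def test_sb_scaled_difference_closed_form():
    res = lta.sb_scaled_difference(-5000.0, 1.2, 10, -4980.0, 1.3, 20)
    assert res.cd == pytest.approx(1.4)
    assert res.trd == pytest.approx(200.0 / 7.0)
    assert res.df == 10


def test_sb_unit_scaling_reduces_to_ordinary_lrt():
    X1, X2, arm = _tiny_two_wave(seed=17, n=80)
    inv = lta.fit_lta(X1, X2, arm, K=2, n_starts=3, seed=18)
    free = lta.fit_lta(X1, X2, arm, K=2, time_invariant=False, init=inv, seed=18)
    plain = lta.lrt_compare(inv, free)
    scaled = lta.sb_scaled_difference(inv.loglik, 1.0, inv.n_params,
                                      free.loglik, 1.0, free.n_params)
    assert scaled.trd == pytest.approx(plain.statistic)
    assert scaled.p_value == pytest.approx(plain.p_value)


def test_sb_guards():
    # d0*c0 = 50 > d1*c1 = 1.2 with d0 < d1 makes cd negative
    with pytest.raises(ValueError, match="cd"):
        lta.sb_scaled_difference(-100.0, 5.0, 10, -90.0, 0.1, 12)
    with pytest.raises(ValueError, match="general"):
        lta.sb_scaled_difference(-100.0, 1.0, 10, -90.0, 1.0, 10)
    with pytest.raises(ValueError, match="positive"):
        lta.sb_scaled_difference(-100.0, -1.0, 10, -90.0, 1.0, 12)


def test_scaling_correction_near_one_when_well_specified():
    """Information identity: with a correctly specified model, the sandwich
    scaling factor tends to 1."""
    cfg = sim.smoothed_config(n=50_000, seed=41)
    coh = sim.generate(cfg)
    X1, X2, arm = sim.two_wave_matrices(coh.records)
    m = lta.fit_lta(X1, X2, arm, K=4, n_starts=2, seed=42)
    c = lta.scaling_correction(m, (X1, X2, arm))
    assert c == pytest.approx(1.0, abs=0.1)


def test_scaling_correction_lca_and_guards():
    from ltarisk import lca as lca_mod
    from ltarisk import recoding
    cfg = sim.smoothed_config(n=20_000, seed=44)
    coh = sim.generate(cfg)
    X = recoding.build_indicators(coh.records, "baseline")
    m = lca_mod.em_fit(X, 4, n_starts=5, seed=45)
    c = lta.scaling_correction(m, X)
    assert c == pytest.approx(1.0, abs=0.1)
    m.n_params += 1  # dimension mismatch must be caught
    with pytest.raises(ValueError, match="does not match"):
        lta.scaling_correction(m, X)
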