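import numpy as np
import pytest

from ltarisk import simulate as sim


@pytest.fixture(scope="session")
def small_trial_cohort():
    """A modest trial cohort shared by tests that only need plausible data."""
    cfg = sim.default_paper_config(n=3000, seed=424242)
    return sim.generate(cfg)


def brute_force_lca_loglik(X, lam, pi):
    """Independent log-likelihood oracle: direct per-row sum over classes.

    Deliberately written with plain Python loops and no shared helpers.
    """
    total = 0.0
    for row in X:
        acc = 0.0
        for k in range(len(lam)):
            term = lam[k]
            for j, x in enumerate(row):
                if x >= 0:
                    term *= pi[k, j, x]
            acc += term
        total += np.log(acc)
    return total


def brute_force_lta_loglik(X1, X2, arm_idx, delta, tau, pi1, pi2):
    """Independent transition-model log-likelihood: enumerate (a, b) pairs."""
    K = len(delta)
    total = 0.0
    for row1, row2, g in zip(X1, X2, arm_idx):
        acc = 0.0
        for a in range(K):
            for b in range(K):
                term = delta[a] * tau[g][a, b]
                for j, x in enumerate(row1):
                    if x >= 0:
                        term *= pi1[a, j, x]
                for j, x in enumerate(row2):
                    if x >= 0:
                        term *= pi2[b, j, x]
                acc += term
        total += np.log(acc)
    return total
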