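"""Shared numerical helpers for the mixture engines."""

from __future__ import annotations

import numpy as np

#: sentinel for a missing indicator entry (never 0, which codes "never")
MISSING = -1

#: floor applied to estimated probabilities before taking logs
PROB_FLOOR = 1e-6


def child_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(int(master_seed))
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def as_indicator_array(data) -> np.ndarray:
    """Coerce an IndicatorMatrix or array-like to an (N, J) int array."""
    values = getattr(data, "values", data)
    X = np.asarray(values)
    if X.dtype.kind == "f":
        out = np.where(np.isnan(X), MISSING, X).astype(np.int64)
    else:
        out = X.astype(np.int64)
    return out


def categorical_loglik(X: np.ndarray, log_pi: np.ndarray) -> np.ndarray:
    """Per-row class-conditional log-likelihood of categorical items.

    Parameters
    ----------
    X : (N, J) int array with MISSING for unobserved entries.
    log_pi : (K, J, C) log item-response probabilities.

    Returns
    -------
    (N, K) array; missing entries contribute 0 (marginalized out), so an
    all-missing row yields a zero log-likelihood for every class.
    """
    N, J = X.shape
    K = log_pi.shape[0]
    out = np.zeros((N, K))
    for j in range(J):
        xj = X[:, j]
        obs = xj >= 0
        if obs.any():
            out[obs] += log_pi[:, j, xj[obs]].T
    return out


def floor_probs(p: np.ndarray, floor: float = PROB_FLOOR) -> np.ndarray:
    """Clip probabilities away from 0 and renormalize the last axis."""
    q = np.clip(p, floor, None)
    return q / q.sum(axis=-1, keepdims=True)


def safe_log(p: np.ndarray) -> np.ndarray:
    return np.log(np.clip(p, 1e-300, None))


def risk_order(pi: np.ndarray, primary_item: int = 0, secondary_item: int = 1,
               grid: float = 0.25) -> np.ndarray:
    """Canonical class permutation: ascending expected risk on the primary
    item (syringe sharing), ties broken by the secondary item (cookers).

    Scores are snapped to a coarse grid so that two classes whose true
    primary-item score coincides (e.g. the low-risk and equipment-sharing
    classes, which both never share syringes) tie reliably despite sampling
    noise, letting the secondary item decide.
    """
    C = pi.shape[2]
    cats = np.arange(C)
    primary = pi[:, primary_item, :] @ cats
    secondary = pi[:, secondary_item, :] @ cats if pi.shape[1] > 1 else primary
    snapped = np.round(primary / grid) * grid
    return np.lexsort((secondary, snapped))
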