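"""Two-wave latent transition analysis with a known trial-arm class.

The model: a baseline latent class a ~ delta, a follow-up class b drawn
from the arm-specific Markov row tau_g[a], and class-conditionally
independent 3-category indicators at each wave.  Trial arm is observed
("known class"), so the likelihood conditions on arm and every transition
matrix may differ by arm while the baseline class distribution delta is
shared (randomization).  Measurement invariance over time and over arm is
expressed as equality constraints on the item-response probability tables;
partial non-invariance frees the full wave-2 table of selected classes.

A participant with no follow-up record contributes the wave-1 factor only:
the follow-up class and items are marginalized out of that row's
likelihood, which is valid when attrition is ignorable given the baseline
class (MAR).  Estimation is by EM; per-iteration log-likelihood ascent and
nested-model ordering are contract properties checked by the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2

from ._utils import (MISSING, as_indicator_array, categorical_loglik,
                     floor_probs, risk_order, safe_log)
from .lca import ConvergenceError, em_fit

N_CATEGORIES = 3


@dataclass
class TransitionModel:
    K: int
    delta: np.ndarray                 # (K,) wave-1 class probabilities
    tau: np.ndarray                   # (G_tau, K, K) transition matrices
    pi1: np.ndarray                   # (G_meas, K, J, C) wave-1 measurement
    pi2: np.ndarray                   # (G_meas, K, J, C) wave-2 measurement
    arm_labels: tuple
    arm_freq: np.ndarray              # empirical arm frequencies
    time_invariant: bool
    free_classes: tuple
    arm_specific_tau: bool
    arm_specific_measurement: bool
    loglik: float
    n_params: int
    converged: bool
    n_starts: int
    n_obs: int
    loglik_trace: np.ndarray = field(repr=False, default=None)

    def tau_for(self, arm: str) -> np.ndarray:
        if not self.arm_specific_tau:
            return self.tau[0]
        return self.tau[self.arm_labels.index(arm)]


@dataclass
class LTAPosterior:
    joint: np.ndarray                 # (N, K, K) posterior over (a, b)
    r1: np.ndarray                    # (N, K) wave-1 marginal
    r2: np.ndarray                    # (N, K) wave-2 marginal
    modal1: np.ndarray
    modal2: np.ndarray
    has_wave2: np.ndarray             # rows with any observed wave-2 item


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class ScaledDiffResult:
    trd: float
    cd: float
    df: int
    p_value: float


def n_parameters(K: int, J: int, *, n_tau_tables: int, n_free_wave2_rows: int,
                 n_meas_groups: int, C: int = N_CATEGORIES) -> int:
    meas_rows = K + n_free_wave2_rows          # wave-1 rows plus freed wave-2 rows
    return ((K - 1)
            + n_tau_tables * K * (K - 1)
            + n_meas_groups * meas_rows * J * (C - 1))


def _unique_patterns(X: np.ndarray):
    pats, inv = np.unique(X, axis=0, return_inverse=True)
    return pats, inv.astype(np.int64)


def _pattern_counts(pats: np.ndarray, inv: np.ndarray, rows: np.ndarray,
                    r: np.ndarray):
    """Accumulate responsibility-weighted category counts over a row subset."""
    U, K = len(pats), r.shape[1]
    J = pats.shape[1]
    acc = np.empty((U, K))
    sub_inv = inv[rows]
    sub_r = r[rows]
    for k in range(K):
        acc[:, k] = np.bincount(sub_inv, weights=sub_r[:, k], minlength=U)
    counts = np.zeros((K, J, N_CATEGORIES))
    denom = np.zeros((K, J))
    for j in range(J):
        xj = pats[:, j]
        for c in range(N_CATEGORIES):
            counts[:, j, c] = acc[xj == c].sum(axis=0)
        denom[:, j] = acc[xj >= 0].sum(axis=0)
    return counts, denom


def _normalize_counts(counts: np.ndarray, denom: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        pi = counts / denom[:, :, None]
    pi[~np.isfinite(pi)] = 1.0 / N_CATEGORIES
    return floor_probs(pi)


class _Params:
    __slots__ = ("delta", "tau", "pi1", "pi2")

    def __init__(self, delta, tau, pi1, pi2):
        self.delta, self.tau, self.pi1, self.pi2 = delta, tau, pi1, pi2


def _e_step(P: _Params, pats1, inv1, pats2, inv2, tau_idx, gm_idx):
    N = len(inv1)
    K = len(P.delta)
    Gm = P.pi1.shape[0]
    logA = np.empty((N, K))
    logB = np.empty((N, K))
    for gm in range(Gm):
        pl1 = categorical_loglik(pats1, safe_log(P.pi1[gm]))
        pl2 = categorical_loglik(pats2, safe_log(P.pi2[gm]))
        rows = gm_idx == gm
        logA[rows] = pl1[inv1[rows]]
        logB[rows] = pl2[inv2[rows]]
    logW = (safe_log(P.delta)[None, :, None]
            + safe_log(P.tau)[tau_idx]
            + logA[:, :, None]
            + logB[:, None, :])
    m = logsumexp(logW, axis=(1, 2))
    w = np.exp(logW - m[:, None, None])
    return float(m.sum()), w


def _m_step(w, pats1, inv1, pats2, inv2, tau_idx, gm_idx, *, time_invariant,
            free_classes, G_tau, G_meas):
    K = w.shape[1]
    r1 = w.sum(axis=2)
    r2 = w.sum(axis=1)
    delta = r1.mean(axis=0)
    delta = delta / delta.sum()
    tau = np.empty((G_tau, K, K))
    for g in range(G_tau):
        rows = tau_idx == g
        num = w[rows].sum(axis=0)
        rs = num.sum(axis=1, keepdims=True)
        tau[g] = np.divide(num, rs, out=np.full((K, K), 1.0 / K), where=rs > 0)
    J = pats1.shape[1]
    pi1 = np.empty((G_meas, K, J, N_CATEGORIES))
    pi2 = np.empty_like(pi1)
    for gm in range(G_meas):
        rows = gm_idx == gm
        c1, d1 = _pattern_counts(pats1, inv1, rows, r1)
        c2, d2 = _pattern_counts(pats2, inv2, rows, r2)
        if time_invariant:
            shared = _normalize_counts(c1 + c2, d1 + d2)
            pi1[gm] = shared
            pi2[gm] = shared.copy()
            for k in free_classes:
                pi1[gm, k] = _normalize_counts(c1[[k]], d1[[k]])[0]
                pi2[gm, k] = _normalize_counts(c2[[k]], d2[[k]])[0]
        else:
            pi1[gm] = _normalize_counts(c1, d1)
            pi2[gm] = _normalize_counts(c2, d2)
    return _Params(delta, tau, pi1, pi2)


def _run_em(P, pats1, inv1, pats2, inv2, tau_idx, gm_idx, *, time_invariant,
            free_classes, G_tau, G_meas, tol, max_iter):
    trace = []
    converged = False
    for _ in range(max_iter):
        ll, w = _e_step(P, pats1, inv1, pats2, inv2, tau_idx, gm_idx)
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * abs(trace[-1]):
            converged = True
            break
        P = _m_step(w, pats1, inv1, pats2, inv2, tau_idx, gm_idx,
                    time_invariant=time_invariant, free_classes=free_classes,
                    G_tau=G_tau, G_meas=G_meas)
    return P, np.array(trace), converged


def _relabel(P: _Params):
    perm = risk_order(P.pi1[0])
    P.delta = P.delta[perm]
    P.tau = P.tau[:, perm][:, :, perm]
    P.pi1 = P.pi1[:, perm]
    P.pi2 = P.pi2[:, perm]
    return P


def fit_lta(X1, X2, arm, K: int = 4, *, time_invariant: bool = True,
            free_classes: tuple = (), arm_specific_tau: bool = True,
            arm_specific_measurement: bool = False, n_starts: int = 3,
            tol: float = 1e-7, max_iter: int = 1000, seed: int | None = None,
            init: TransitionModel | None = None,
            warm_start_starts: int = 5) -> TransitionModel:
    """Fit the two-wave latent transition model by EM.

    ``X1`` must be fully or partially observed for every row; a row of
    ``X2`` may be entirely missing (lost to follow-up), in which case the
    wave-2 factor is marginalized out.  The first EM start is warm-started
    from a wave-1 latent class fit (measurement and delta) with
    noise-perturbed uniform transition rows; remaining starts perturb it.
    Passing ``init`` (e.g. a restricted fit) replaces the warm start, which
    also guarantees the nested log-likelihood ordering via EM ascent.
    """
    X1 = as_indicator_array(X1)
    X2 = as_indicator_array(X2)
    arm = np.asarray(arm)
    if X1.shape != X2.shape or X1.shape[0] != len(arm):
        raise ValueError("X1, X2 and arm must be row-aligned")
    if (X1 == MISSING).all(axis=1).any():
        raise ValueError("every participant needs observed wave-1 items")
    bad = [k for k in free_classes if not 0 <= int(k) < K]
    if bad:
        raise ValueError(f"free_classes refers to unknown classes {bad}")
    free_classes = tuple(int(k) for k in free_classes)

    arm_labels = tuple(sorted(set(arm.tolist())))
    arm_idx = np.array([arm_labels.index(a) for a in arm.tolist()])
    G = len(arm_labels)
    if arm_specific_tau and G < 2:
        raise ValueError("arm-specific transitions requested but only one arm "
                         f"present: {arm_labels}")
    G_tau = G if arm_specific_tau else 1
    G_meas = G if arm_specific_measurement else 1
    tau_idx = arm_idx if arm_specific_tau else np.zeros(len(arm), dtype=np.int64)
    gm_idx = arm_idx if arm_specific_measurement else np.zeros(len(arm), dtype=np.int64)

    pats1, inv1 = _unique_patterns(X1)
    pats2, inv2 = _unique_patterns(X2)
    N, J = X1.shape
    d = n_parameters(
        K, J, n_tau_tables=G_tau,
        n_free_wave2_rows=(K if not time_invariant else len(free_classes)),
        n_meas_groups=G_meas)

    rng = np.random.default_rng(seed)
    run = dict(time_invariant=time_invariant, free_classes=free_classes,
               G_tau=G_tau, G_meas=G_meas)

    if init is not None:
        starts = [_Params(init.delta.copy(),
                          np.broadcast_to(init.tau, (G_tau,) + init.tau.shape[-2:]).copy(),
                          np.broadcast_to(init.pi1, (G_meas,) + init.pi1.shape[-3:]).copy(),
                          np.broadcast_to(init.pi2, (G_meas,) + init.pi2.shape[-3:]).copy())]
    else:
        warm = em_fit(X1, K, n_starts=warm_start_starts, tol=tol,
                      max_iter=max_iter, seed=int(rng.integers(2**31)))
        starts = []
        for s in range(max(1, n_starts)):
            if s == 0:
                pi0 = warm.pi.copy()
                delta0 = warm.lam.copy()
            else:
                noise = rng.dirichlet(np.full(N_CATEGORIES, 2.0), size=(K, J))
                pi0 = floor_probs(0.8 * warm.pi + 0.2 * noise)
                delta0 = floor_probs(0.7 * warm.lam + 0.3 * rng.dirichlet(np.full(K, 5.0)))
            tau0 = rng.dirichlet(np.full(K, 20.0), size=(G_tau, K))
            starts.append(_Params(delta0,
                                  tau0,
                                  np.broadcast_to(pi0, (G_meas, K, J, N_CATEGORIES)).copy(),
                                  np.broadcast_to(pi0, (G_meas, K, J, N_CATEGORIES)).copy()))

    best = None
    any_converged = False
    for P0 in starts:
        P, trace, conv = _run_em(P0, pats1, inv1, pats2, inv2, tau_idx, gm_idx,
                                 tol=tol, max_iter=max_iter, **run)
        any_converged |= conv
        if best is None or trace[-1] > best[1][-1]:
            best = (P, trace, conv)
    if not any_converged:
        raise ConvergenceError("no EM start converged within max_iter",
                               trace=best[1])
    P, trace, conv = best
    P = _relabel(P)
    arm_freq = np.bincount(arm_idx, minlength=G) / len(arm)
    return TransitionModel(
        K=K, delta=P.delta, tau=P.tau, pi1=P.pi1, pi2=P.pi2,
        arm_labels=arm_labels, arm_freq=arm_freq,
        time_invariant=time_invariant, free_classes=free_classes,
        arm_specific_tau=arm_specific_tau,
        arm_specific_measurement=arm_specific_measurement,
        loglik=float(trace[-1]), n_params=d, converged=conv,
        n_starts=len(starts), n_obs=N, loglik_trace=trace)


def posterior_lta(model: TransitionModel, X1, X2, arm) -> LTAPosterior:
    """Joint and marginal posterior class probabilities per participant."""
    X1 = as_indicator_array(X1)
    X2 = as_indicator_array(X2)
    arm = np.asarray(arm)
    arm_idx = np.array([model.arm_labels.index(a) for a in arm.tolist()])
    tau_idx = arm_idx if model.arm_specific_tau else np.zeros(len(arm), dtype=np.int64)
    gm_idx = arm_idx if model.arm_specific_measurement else np.zeros(len(arm), dtype=np.int64)
    pats1, inv1 = _unique_patterns(X1)
    pats2, inv2 = _unique_patterns(X2)
    P = _Params(model.delta, model.tau, model.pi1, model.pi2)
    _, w = _e_step(P, pats1, inv1, pats2, inv2, tau_idx, gm_idx)
    r1 = w.sum(axis=2)
    r2 = w.sum(axis=1)
    return LTAPosterior(joint=w, r1=r1, r2=r2,
                        modal1=np.argmax(r1, axis=1),
                        modal2=np.argmax(r2, axis=1),
                        has_wave2=(X2 != MISSING).any(axis=1))


def marginal_class_probs(model: TransitionModel,
                         arm_weights: np.ndarray | None = None):
    """Model-implied class probabilities at each wave.

    Wave 1 is delta; wave 2 is the arm-frequency-weighted mixture of
    delta' tau_g.  Both sum to 1 by construction.
    """
    if arm_weights is None:
        arm_weights = model.arm_freq
    arm_weights = np.asarray(arm_weights, dtype=float)
    arm_weights = arm_weights / arm_weights.sum()
    if model.arm_specific_tau:
        wave2 = sum(wg * (model.delta @ model.tau[g])
                    for g, wg in enumerate(arm_weights))
    else:
        wave2 = model.delta @ model.tau[0]
    return model.delta.copy(), wave2


def lrt_compare(restricted: TransitionModel, general: TransitionModel) -> LRTResult:
    """Ordinary likelihood-ratio test of a nested pair of fitted models."""
    df = general.n_params - restricted.n_params
    if df < 1:
        raise ValueError("general model must have more parameters than the "
                         "restricted model")
    stat = -2.0 * (restricted.loglik - general.loglik)
    if stat < -1e-6 * max(1.0, abs(general.loglik)):
        raise RuntimeError(
            "restricted fit exceeds general fit; optimization failure "
            f"(-2*dLL = {stat:.6g})")
    stat = max(0.0, stat)
    return LRTResult(statistic=stat, df=df, p_value=float(chi2.sf(stat, df)))


def sb_scaled_difference(L0: float, c0: float, d0: int,
                         L1: float, c1: float, d1: int) -> ScaledDiffResult:
    """Satorra-Bentler scaled chi-square difference test.

    Model 1 is the general model (d1 > d0).  The difference scaling factor
    is cd = (d0 c0 - d1 c1) / (d0 - d1) and the scaled statistic
    TRd = -2 (L0 - L1) / cd, referred to chi-square with d1 - d0 degrees of
    freedom.  With unit scaling factors this reduces exactly to the
    ordinary likelihood-ratio test.
    """
    if d1 <= d0:
        raise ValueError("model 1 must be the more general model (d1 > d0)")
    if c0 <= 0 or c1 <= 0:
        raise ValueError("scaling correction factors must be positive")
    cd = (d0 * c0 - d1 * c1) / (d0 - d1)
    if cd <= 0:
        raise ValueError(f"difference scaling factor cd = {cd:.6g} <= 0; the "
                         "scaled test is undefined for these inputs")
    trd = -2.0 * (L0 - L1) / cd
    df = d1 - d0
    return ScaledDiffResult(trd=float(trd), cd=float(cd), df=df,
                            p_value=float(chi2.sf(max(0.0, trd), df)))


# ---------------------------------------------------------------------------
# MLR-style scaling correction factor
# ---------------------------------------------------------------------------

def _softmax(eta_free: np.ndarray) -> np.ndarray:
    """Softmax with the last category's logit fixed at 0."""
    eta = np.concatenate([eta_free, [0.0]])
    eta = eta - eta.max()
    e = np.exp(eta)
    return e / e.sum()


def _logits(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, None)
    return np.log(p[:-1] / p[-1])


def _pack_lca(model) -> np.ndarray:
    parts = [_logits(model.lam)]
    K, J, C = model.pi.shape
    for k in range(K):
        for j in range(J):
            parts.append(_logits(model.pi[k, j]))
    return np.concatenate(parts)


def _unpack_lca(theta, K, J, C):
    lam = _softmax(theta[:K - 1])
    pi = np.empty((K, J, C))
    pos = K - 1
    for k in range(K):
        for j in range(J):
            pi[k, j] = _softmax(theta[pos:pos + C - 1])
            pos += C - 1
    return lam, pi


def _scores_lca(theta, X, K, J, C):
    lam, pi = _unpack_lca(theta, K, J, C)
    logp = safe_log(lam)[None, :] + categorical_loglik(X, safe_log(pi))
    r = np.exp(logp - logsumexp(logp, axis=1)[:, None])
    N = X.shape[0]
    s = np.empty((N, len(theta)))
    s[:, :K - 1] = r[:, :K - 1] - lam[None, :K - 1]
    pos = K - 1
    for k in range(K):
        for j in range(J):
            obs = X[:, j] >= 0
            for c in range(C - 1):
                col = np.zeros(N)
                col[obs] = r[obs, k] * ((X[obs, j] == c) - pi[k, j, c])
                s[:, pos] = col
                pos += 1
    return s


def _pack_lta(model: TransitionModel) -> np.ndarray:
    parts = [_logits(model.delta)]
    for g in range(model.tau.shape[0]):
        for a in range(model.K):
            parts.append(_logits(model.tau[g, a]))
    K, J, C = model.pi1.shape[1:]
    for k in range(K):
        for j in range(J):
            parts.append(_logits(model.pi1[0, k, j]))
    if not model.time_invariant:
        for k in range(K):
            for j in range(J):
                parts.append(_logits(model.pi2[0, k, j]))
    return np.concatenate(parts)


def _unpack_lta(theta, K, J, C, G_tau, time_invariant):
    pos = 0
    delta = _softmax(theta[pos:pos + K - 1]); pos += K - 1
    tau = np.empty((G_tau, K, K))
    for g in range(G_tau):
        for a in range(K):
            tau[g, a] = _softmax(theta[pos:pos + K - 1]); pos += K - 1
    pi1 = np.empty((K, J, C))
    for k in range(K):
        for j in range(J):
            pi1[k, j] = _softmax(theta[pos:pos + C - 1]); pos += C - 1
    if time_invariant:
        pi2 = pi1
    else:
        pi2 = np.empty((K, J, C))
        for k in range(K):
            for j in range(J):
                pi2[k, j] = _softmax(theta[pos:pos + C - 1]); pos += C - 1
    return delta, tau, pi1, pi2


def _scores_lta(theta, X1, X2, tau_idx, K, J, C, G_tau, time_invariant):
    delta, tau, pi1, pi2 = _unpack_lta(theta, K, J, C, G_tau, time_invariant)
    logA = categorical_loglik(X1, safe_log(pi1))
    logB = categorical_loglik(X2, safe_log(pi2))
    logW = (safe_log(delta)[None, :, None] + safe_log(tau)[tau_idx]
            + logA[:, :, None] + logB[:, None, :])
    m = logsumexp(logW, axis=(1, 2))
    w = np.exp(logW - m[:, None, None])
    r1 = w.sum(axis=2)
    r2 = w.sum(axis=1)
    N = X1.shape[0]
    s = np.empty((N, len(theta)))
    pos = 0
    s[:, :K - 1] = r1[:, :K - 1] - delta[None, :K - 1]
    pos += K - 1
    for g in range(G_tau):
        in_g = (tau_idx == g).astype(float)
        for a in range(K):
            for b in range(K - 1):
                s[:, pos] = in_g * (w[:, a, b] - r1[:, a] * tau[g, a, b])
                pos += 1
    for k in range(K):
        for j in range(J):
            obs1 = X1[:, j] >= 0
            obs2 = X2[:, j] >= 0
            for c in range(C - 1):
                col = np.zeros(N)
                col[obs1] += r1[obs1, k] * ((X1[obs1, j] == c) - pi1[k, j, c])
                if time_invariant:
                    col[obs2] += r2[obs2, k] * ((X2[obs2, j] == c) - pi1[k, j, c])
                s[:, pos] = col
                pos += 1
    if not time_invariant:
        for k in range(K):
            for j in range(J):
                obs2 = X2[:, j] >= 0
                for c in range(C - 1):
                    col = np.zeros(N)
                    col[obs2] = r2[obs2, k] * ((X2[obs2, j] == c) - pi2[k, j, c])
                    s[:, pos] = col
                    pos += 1
    return s


def scaling_correction(model, data, step: float = 1e-5) -> float:
    """Sandwich-style scaling correction factor c = tr(A^{-1} B) / d.

    A is the observed average information (numeric Jacobian of the analytic
    score, obtained through Fisher's identity from the E-step
    responsibilities) and B the average outer product of per-observation
    scores, both evaluated at the fitted parameters in an unconstrained
    multinomial-logit parameterization.  Under a correctly specified model
    A and B agree asymptotically and c tends to 1.

    ``data`` is an IndicatorMatrix/array for a latent class model, or a
    tuple ``(X1, X2, arm)`` for a transition model.
    """
    from .lca import LatentClassModel

    if isinstance(model, LatentClassModel):
        X = as_indicator_array(data)
        K, J, C = model.pi.shape
        theta = _pack_lca(model)
        score_fn = lambda t: _scores_lca(t, X, K, J, C)
    elif isinstance(model, TransitionModel):
        if model.arm_specific_measurement or model.free_classes:
            raise NotImplementedError(
                "scaling correction supports fully shared or fully "
                "wave-specific measurement only")
        X1, X2, arm = data
        X1 = as_indicator_array(X1)
        X2 = as_indicator_array(X2)
        arm_idx = np.array([model.arm_labels.index(a) for a in np.asarray(arm).tolist()])
        tau_idx = (arm_idx if model.arm_specific_tau
                   else np.zeros(len(arm_idx), dtype=np.int64))
        K, J, C = model.pi1.shape[1:]
        G_tau = model.tau.shape[0]
        theta = _pack_lta(model)
        score_fn = lambda t: _scores_lta(t, X1, X2, tau_idx, K, J, C, G_tau,
                                         model.time_invariant)
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")

    d = len(theta)
    if d != model.n_params:
        raise ValueError(f"parameter vector length {d} does not match the "
                         f"model's {model.n_params} free parameters")
    S = score_fn(theta)
    N = S.shape[0]
    B = (S.T @ S) / N

    # A = -average Hessian, via central differences of the total score
    A = np.empty((d, d))
    for i in range(d):
        h = step * (1.0 + abs(theta[i]))
        tp = theta.copy(); tp[i] += h
        tm = theta.copy(); tm[i] -= h
        A[:, i] = -(score_fn(tp).sum(axis=0) - score_fn(tm).sum(axis=0)) / (2 * h * N)
    A = 0.5 * (A + A.T)
    if np.linalg.cond(A) > 1e10:
        raise np.linalg.LinAlgError(
            "information matrix is singular or ill-conditioned; fall back to "
            "the ordinary likelihood-ratio test")
    c = float(np.trace(np.linalg.solve(A, B)) / d)
    if c <= 0:
        warnings.warn(f"non-positive scaling correction c = {c:.4g}")
    return c
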