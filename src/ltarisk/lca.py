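"""Latent class analysis for categorical indicators.

Maximum-likelihood estimation by EM with random multi-start, full-information
handling of missing items (missing entries are marginalized out of each
row's likelihood factor, valid under MAR), model-selection indices
(AIC/BIC/sample-size-adjusted BIC), relative entropy, the average-posterior
classification table, and a parametric bootstrap likelihood ratio test for
class enumeration.

Label switching is resolved by a canonical ordering of classes by expected
syringe-sharing risk (ascending), ties broken by cooker sharing, which maps
fitted classes onto the reproducible low / equipment / moderate / high
ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import chi2

from ._utils import (MISSING, as_indicator_array, categorical_loglik,
                     floor_probs, risk_order, safe_log)

N_CATEGORIES = 3


class ConvergenceError(RuntimeError):
    """No EM start reached the convergence tolerance."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class LatentClassModel:
    K: int
    lam: np.ndarray                  # (K,) class proportions
    pi: np.ndarray                   # (K, J, C) item-response probabilities
    loglik: float
    n_params: int
    converged: bool
    n_starts: int
    n_obs: int
    loglik_trace: np.ndarray = field(repr=False, default=None)


@dataclass
class PosteriorMatrix:
    p: np.ndarray                    # (N, K)
    modal: np.ndarray                # (N,) argmax class, ties -> lowest index


@dataclass
class FitIndices:
    K: int
    loglik: float
    n_params: int
    aic: float
    bic: float
    abic: float
    entropy: float
    avg_posterior: np.ndarray        # diagonal of the classification table
    converged: bool
    blrt_p: float | None = None


def n_parameters(K: int, J: int, C: int = N_CATEGORIES) -> int:
    """(K-1) mixing proportions plus K*J*(C-1) free response probabilities."""
    return (K - 1) + K * J * (C - 1)


def _collapse(X: np.ndarray):
    pats, inverse, counts = np.unique(X, axis=0, return_inverse=True,
                                      return_counts=True)
    return pats, counts.astype(float), inverse


def _m_step_pi(pats: np.ndarray, wk: np.ndarray, K: int) -> np.ndarray:
    """wk: (U, K) weighted responsibilities; returns (K, J, C)."""
    J = pats.shape[1]
    counts = np.zeros((K, J, N_CATEGORIES))
    denom = np.zeros((K, J))
    for j in range(J):
        xj = pats[:, j]
        for c in range(N_CATEGORIES):
            counts[:, j, c] = wk[xj == c].sum(axis=0)
        denom[:, j] = wk[xj >= 0].sum(axis=0)
    with np.errstate(invalid="ignore"):
        pi = counts / denom[:, :, None]
    # an item never observed for a class keeps a uniform row
    pi[~np.isfinite(pi)] = 1.0 / N_CATEGORIES
    return floor_probs(pi)


def _em_run(pats, w, K, lam0, pi0, tol, max_iter):
    lam, pi = lam0.copy(), pi0.copy()
    total = w.sum()
    trace = []
    converged = False
    for _ in range(max_iter):
        logp = safe_log(lam)[None, :] + categorical_loglik(pats, safe_log(pi))
        m = logsumexp(logp, axis=1)
        ll = float(w @ m)
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * abs(trace[-1]):
            converged = True
            break
        r = np.exp(logp - m[:, None])
        wk = r * w[:, None]
        lam = wk.sum(axis=0) / total
        pi = _m_step_pi(pats, wk, K)
    return lam, pi, np.array(trace), converged


def relabel(lam: np.ndarray, pi: np.ndarray):
    perm = risk_order(pi)
    return lam[perm], pi[perm], perm


def em_fit(data, K: int, n_starts: int = 50, tol: float = 1e-7,
           max_iter: int = 1000, seed: int | None = None) -> LatentClassModel:
    """Fit a K-class model, keeping the best of ``n_starts`` EM runs.

    The per-iteration observed-data log-likelihood is non-decreasing (EM
    ascent); the returned model's classes are canonically relabeled.
    """
    X = as_indicator_array(data)
    N, J = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    pats, w, _ = _collapse(X)
    if len(pats) < K:
        raise ValueError(f"only {len(pats)} distinct response patterns; cannot "
                         f"identify {K} classes")
    d = n_parameters(K, J)
    if d > N_CATEGORIES**J - 1:
        warnings.warn(f"K={K} exceeds the pattern-count identifiability bound")
    rng = np.random.default_rng(seed)
    best = None
    any_converged = False
    for _ in range(max(1, n_starts)):
        lam0 = rng.dirichlet(np.full(K, 5.0))
        pi0 = rng.dirichlet(np.full(N_CATEGORIES, 2.0), size=(K, J))
        lam, pi, trace, conv = _em_run(pats, w, K, lam0, pi0, tol, max_iter)
        any_converged |= conv
        if best is None or trace[-1] > best[2][-1]:
            best = (lam, pi, trace, conv)
    if not any_converged:
        raise ConvergenceError("no EM start converged within max_iter",
                               trace=best[2])
    lam, pi, trace, conv = best
    lam, pi, _ = relabel(lam, pi)
    return LatentClassModel(K=K, lam=lam, pi=pi, loglik=float(trace[-1]),
                            n_params=d, converged=conv, n_starts=n_starts,
                            n_obs=N, loglik_trace=trace)


def posterior(model: LatentClassModel, data) -> PosteriorMatrix:
    """Posterior class-membership probabilities p_ik.

    p_ik is proportional to lambda_k times the product of item-response
    probabilities over the row's non-missing items.  A row with every item
    missing carries no information and is assigned the uniform posterior
    (with a warning), per the module contract.
    """
    X = as_indicator_array(data)
    logp = safe_log(model.lam)[None, :] + categorical_loglik(X, safe_log(model.pi))
    p = np.exp(logp - logsumexp(logp, axis=1)[:, None])
    all_missing = (X == MISSING).all(axis=1)
    if all_missing.any():
        warnings.warn(f"{int(all_missing.sum())} all-missing rows assigned "
                      "uniform posteriors")
        p[all_missing] = 1.0 / model.K
    return PosteriorMatrix(p=p, modal=np.argmax(p, axis=1))


def entropy(post: PosteriorMatrix, K: int) -> float:
    """Relative entropy E = 1 - sum(-p log p) / (N log K), in [0, 1].

    1 means perfectly separated classes, 0 means uninformative posteriors.
    """
    if K < 2:
        warnings.warn("entropy is degenerate for K=1; returning 1.0")
        return 1.0
    p = post.p
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(p > 0, -p * np.log(p), 0.0).sum()
    return float(1.0 - h / (p.shape[0] * np.log(K)))


def classification_table(post: PosteriorMatrix) -> np.ndarray:
    """K x K matrix: entry (a, b) = mean posterior for class b among rows
    whose modal class is a; the diagonal is the usual classification
    diagnostic."""
    K = post.p.shape[1]
    out = np.full((K, K), np.nan)
    for a in range(K):
        rows = post.modal == a
        if rows.any():
            out[a] = post.p[rows].mean(axis=0)
        else:
            warnings.warn(f"modal class {a} is empty")
    return out


def simulate_responses(model: LatentClassModel, n: int, rng) -> np.ndarray:
    """Draw n complete response rows from a fitted model (for the BLRT)."""
    K, J, C = model.pi.shape
    z = rng.choice(K, size=n, p=model.lam / model.lam.sum())
    P = model.pi[z]
    u = rng.random((n, J))
    return (u[:, :, None] > np.cumsum(P, axis=2)[:, :, :-1]).sum(axis=2)


@dataclass
class BLRTResult:
    p_value: float
    statistic: float
    boot_stats: np.ndarray
    n_dropped: int


def blrt(data, K: int, n_boot: int = 100, seed: int | None = None,
         n_starts: int = 10, n_starts_boot: int = 2, tol: float = 1e-7,
         max_iter: int = 1000) -> BLRTResult:
    """Parametric bootstrap likelihood ratio test of K vs K-1 classes.

    Simulates ``n_boot`` datasets from the fitted (K-1)-class model, refits
    both models on each, and compares the observed -2 delta log-likelihood
    with the bootstrap distribution, using the add-one correction
    p = (1 + #{boot >= observed}) / (n_kept + 1).
    """
    if K < 2:
        raise ValueError("BLRT needs K >= 2")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    X = as_indicator_array(data)
    rng = np.random.default_rng(seed)
    m0 = em_fit(X, K - 1, n_starts=n_starts, tol=tol, max_iter=max_iter,
                seed=int(rng.integers(2**31)))
    m1 = em_fit(X, K, n_starts=n_starts, tol=tol, max_iter=max_iter,
                seed=int(rng.integers(2**31)))
    observed = max(0.0, -2.0 * (m0.loglik - m1.loglik))
    stats = []
    dropped = 0
    for _ in range(n_boot):
        Xb = simulate_responses(m0, X.shape[0], rng)
        try:
            b0 = em_fit(Xb, K - 1, n_starts=n_starts_boot, tol=tol,
                        max_iter=max_iter, seed=int(rng.integers(2**31)))
            b1 = em_fit(Xb, K, n_starts=n_starts_boot, tol=tol,
                        max_iter=max_iter, seed=int(rng.integers(2**31)))
        except (ConvergenceError, ValueError):
            dropped += 1
            continue
        stats.append(max(0.0, -2.0 * (b0.loglik - b1.loglik)))
    if dropped > 0.05 * n_boot:
        warnings.warn(f"{dropped}/{n_boot} bootstrap replicates dropped")
    stats = np.array(stats)
    p = (1.0 + float((stats >= observed).sum())) / (len(stats) + 1.0)
    return BLRTResult(p_value=p, statistic=observed, boot_stats=stats,
                      n_dropped=dropped)


def fit_indices(model: LatentClassModel, data,
                blrt_p: float | None = None) -> FitIndices:
    N = model.n_obs
    d = model.n_params
    post = posterior(model, data)
    table = classification_table(post)
    return FitIndices(
        K=model.K,
        loglik=model.loglik,
        n_params=d,
        aic=-2.0 * model.loglik + 2.0 * d,
        bic=-2.0 * model.loglik + d * np.log(N),
        abic=-2.0 * model.loglik + d * np.log((N + 2.0) / 24.0),
        entropy=entropy(post, model.K) if model.K >= 2 else 1.0,
        avg_posterior=np.diag(table),
        converged=model.converged,
        blrt_p=blrt_p,
    )


def select_model(data, K_range=range(2, 7), n_starts: int = 50,
                 tol: float = 1e-7, max_iter: int = 1000,
                 seed: int | None = None, run_blrt: bool = False,
                 n_boot: int = 100) -> pd.DataFrame:
    """Fit a range of class counts and tabulate fit indices per K.

    No automatic choice is made: like the trial analysis, selection
    combines indices with substantive judgment, so the table is the output.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for K in K_range:
        model = em_fit(data, K, n_starts=n_starts, tol=tol, max_iter=max_iter,
                       seed=int(rng.integers(2**31)))
        bp = None
        if run_blrt and K >= 2:
            bp = blrt(data, K, n_boot=n_boot,
                      seed=int(rng.integers(2**31))).p_value
        fi = fit_indices(model, data, blrt_p=bp)
        rows.append({
            "K": K, "loglik": fi.loglik, "n_params": fi.n_params,
            "aic": fi.aic, "bic": fi.bic, "abic": fi.abic,
            "entropy": fi.entropy,
            "min_avg_posterior": float(np.nanmin(fi.avg_posterior)),
            "max_avg_posterior": float(np.nanmax(fi.avg_posterior)),
            "converged": fi.converged, "blrt_p": bp,
        })
    return pd.DataFrame(rows)
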