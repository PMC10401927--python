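"""Latent Dirichlet Allocation fitted by variational EM.

A sample is a document over genus "terms".  The variational family is the
standard mean-field one: per-document Dirichlet parameters ``gamma_d`` and
per-term topic responsibilities ``phi``.  The fixed-point updates are

    phi[v][k]  ∝  beta[k][v] * exp(digamma(gamma_d[k]))
    gamma_d[k] =  alpha + sum_v n_v * phi[v][k]

The topic-term matrix ``beta`` is a point estimate with Dirichlet smoothing
``eta`` applied in the M step; the symmetric topic concentration ``alpha``
is optionally re-estimated by Newton ascent each iteration.  Fractional
counts are accepted throughout (the multinomial likelihood generalizes by
weighting), which is needed when refitting on assigned-read tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, polygamma, xlogy

from .data_model import CountTable

__all__ = ["LdaModel", "EStepResult", "fit_lda", "e_step", "estimate_alpha", "elbo"]

_EPS = 1e-300


@dataclass
class LdaModel:
    """A fitted LDA model.

    ``beta`` rows (topics) and ``gamma_norm`` rows (samples) are probability
    distributions.  ``gamma`` holds the unnormalized variational Dirichlet
    parameters; ``elbo_trace`` the objective after each EM iteration.
    """

    beta: np.ndarray          # K x V topic-term probabilities
    gamma_norm: np.ndarray    # D x K per-sample topic proportions
    gamma: np.ndarray         # D x K variational Dirichlet parameters
    alpha: float
    elbo_trace: np.ndarray
    K: int
    vocab: list[str]
    seed: int
    eta: float = 0.1
    converged: bool = True
    n_iter: int = 0
    estep_tol: float = 1e-8
    estep_max_iter: int = 100
    sample_ids: list[str] = field(default_factory=list)

    @property
    def topic_ids(self) -> list[str]:
        return [f"topic_{k + 1}" for k in range(self.K)]


@dataclass
class EStepResult:
    """Variational quantities for a single document."""

    gamma_d: np.ndarray   # length-K Dirichlet parameters
    phi_d: np.ndarray     # V x K responsibilities (rows sum to 1)
    bound_d: float
    n_iter: int


# ---------------------------------------------------------------------------
# batched E step (all documents at once)
# ---------------------------------------------------------------------------


def _batch_e_step(
    counts: np.ndarray,
    beta: np.ndarray,
    alpha: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (gamma D x K, suff stats K x V, per-document bounds)."""
    D, V = counts.shape
    K = beta.shape[0]
    gamma = np.full((D, K), alpha) + counts.sum(axis=1)[:, None] / K
    ratio = np.zeros_like(counts)
    nonzero = counts > 0
    for _ in range(max_iter):
        e_theta = np.exp(digamma(gamma) - digamma(gamma.sum(axis=1))[:, None])
        s = e_theta @ beta  # D x V mixture probabilities scaled by e_theta mass
        if np.any((s <= 0) & nonzero):
            d, v = np.argwhere((s <= 0) & nonzero)[0]
            raise ValueError(
                f"term index {v} has positive count in document {d} but zero "
                "probability under every topic; increase beta smoothing"
            )
        np.divide(counts, s, out=ratio, where=nonzero)
        gamma_new = alpha + e_theta * (ratio @ beta.T)
        change = np.abs(gamma_new - gamma).mean(axis=1)
        gamma = gamma_new
        if change.max() < tol:
            break
    e_theta = np.exp(digamma(gamma) - digamma(gamma.sum(axis=1))[:, None])
    s = e_theta @ beta
    np.divide(counts, s, out=ratio, where=nonzero)
    ss = beta * (e_theta.T @ ratio)  # K x V expected counts
    bounds = _doc_bounds(counts, gamma, s, alpha)
    return gamma, ss, bounds


def _doc_bounds(
    counts: np.ndarray, gamma: np.ndarray, s: np.ndarray, alpha: float
) -> np.ndarray:
    """Per-document ELBO with phi written implicitly through ``s``.

    Collapsing phi's optimal form, the likelihood + phi-entropy terms reduce
    to sum_v n_v log s_v.
    """
    K = gamma.shape[1]
    elog = digamma(gamma) - digamma(gamma.sum(axis=1))[:, None]
    like = xlogy(counts, s).sum(axis=1)
    prior = gammaln(K * alpha) - K * gammaln(alpha) + (alpha - 1.0) * elog.sum(axis=1)
    entropy = (
        gammaln(gamma.sum(axis=1))
        - gammaln(gamma).sum(axis=1)
        + ((gamma - 1.0) * elog).sum(axis=1)
    )
    return like + prior - entropy


def _beta_prior_term(beta: np.ndarray, eta: float) -> float:
    """Log Dirichlet(eta+1) prior on beta rows (the MAP smoothing term)."""
    if eta == 0:
        return 0.0
    K, V = beta.shape
    const = K * (gammaln(V * (eta + 1.0)) - V * gammaln(eta + 1.0))
    return const + eta * np.log(np.maximum(beta, _EPS)).sum()


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def e_step(
    doc_counts: np.ndarray,
    beta: np.ndarray,
    alpha: float,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> EStepResult:
    """Variational inference for one document at fixed ``beta`` and ``alpha``."""
    n = np.asarray(doc_counts, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if n.ndim != 1 or beta.ndim != 2 or beta.shape[1] != n.shape[0]:
        raise ValueError("doc_counts must be a length-V vector matching beta")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if np.any(n < 0):
        raise ValueError("doc_counts must be non-negative")
    K = beta.shape[0]
    gamma_d = np.full(K, alpha) + n.sum() / K
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        e_theta = np.exp(digamma(gamma_d) - digamma(gamma_d.sum()))
        s = e_theta @ beta  # length V
        if np.any((s <= 0) & (n > 0)):
            v = int(np.argwhere((s <= 0) & (n > 0))[0, 0])
            raise ValueError(
                f"term index {v} has positive count but zero probability under every topic"
            )
        ratio = np.divide(n, s, out=np.zeros_like(n), where=n > 0)
        gamma_new = alpha + e_theta * (beta @ ratio)
        change = np.abs(gamma_new - gamma_d).mean()
        gamma_d = gamma_new
        if change < tol:
            break
    e_theta = np.exp(digamma(gamma_d) - digamma(gamma_d.sum()))
    s = e_theta @ beta
    phi = beta.T * e_theta[None, :]  # V x K
    row = phi.sum(axis=1)
    safe = row > 0
    phi[safe] /= row[safe, None]
    phi[~safe] = 1.0 / K
    bound = float(
        _doc_bounds(n[None, :], gamma_d[None, :], s[None, :], alpha)[0]
    )
    return EStepResult(gamma_d=gamma_d, phi_d=phi, bound_d=bound, n_iter=n_iter)


def estimate_alpha(
    gammas: np.ndarray, alpha: float, tol: float = 1e-10, max_iter: int = 100
) -> float:
    """Newton update of the symmetric Dirichlet concentration.

    Maximizes the alpha-dependent ELBO terms
    ``D (lgamma(K a) - K lgamma(a)) + (a - 1) * sum E[log theta]`` and never
    decreases them: steps leaving the positive domain or lowering the
    objective are halved, and the input alpha is returned as a fallback.
    """
    gammas = np.asarray(gammas, dtype=float)
    if gammas.ndim != 2:
        raise ValueError("gammas must be a D x K matrix")
    if np.any(gammas <= 0):
        raise ValueError("gammas must be positive")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    D, K = gammas.shape
    s = float((digamma(gammas) - digamma(gammas.sum(axis=1))[:, None]).sum())

    def objective(a: float) -> float:
        return D * (gammaln(K * a) - K * gammaln(a)) + (a - 1.0) * s

    a = float(alpha)
    f = objective(a)
    for _ in range(max_iter):
        g = D * K * (digamma(K * a) - digamma(a)) + s
        h = D * K * (K * polygamma(1, K * a) - polygamma(1, a))
        if h == 0:
            break
        step = -g / h
        a_new = a + step
        halvings = 0
        while (a_new <= 0 or objective(a_new) < f) and halvings < 60:
            step /= 2.0
            a_new = a + step
            halvings += 1
        if a_new <= 0 or objective(a_new) < f:
            break
        if abs(a_new - a) <= tol * max(1.0, a):
            a = a_new
            break
        a, f = a_new, objective(a_new)
    return max(float(a), 1e-10)


def fit_lda(
    table: CountTable,
    K: int,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 200,
    estimate_alpha: bool = True,
    n_starts: int = 1,
    eta: float = 0.1,
    alpha0: float = 1.0,
    estep_tol: float = 1e-8,
    estep_max_iter: int = 100,
    beta_init: np.ndarray | None = None,
) -> LdaModel:
    """Fit LDA by variational EM; deterministic for fixed (seed, n_starts).

    The best of ``n_starts`` restarts by final objective is returned.
    ``beta_init`` overrides the seeded random initialization (single start).
    Non-convergence at ``max_iter`` is recorded as a warning on the model,
    not an error.
    """
    counts = table.counts
    D, V = counts.shape
    if K < 1 or K >= min(D, V):
        raise ValueError(f"K={K} out of range; need 1 <= K < min(D={D}, V={V})")
    if np.any(table.library_sizes <= 0):
        bad = table.sample_ids[int(np.argmax(table.library_sizes <= 0))]
        raise ValueError(f"sample {bad!r} has zero total count")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")

    children = np.random.SeedSequence(seed).spawn(max(n_starts, 1))
    best: dict | None = None
    for start in range(n_starts):
        if beta_init is not None:
            beta0 = np.asarray(beta_init, dtype=float)
            if beta0.shape != (K, V):
                raise ValueError("beta_init must be K x V")
            beta0 = beta0 / beta0.sum(axis=1, keepdims=True)
        else:
            rng = np.random.default_rng(children[start])
            beta0 = rng.gamma(100.0, 0.01, size=(K, V))
            beta0 /= beta0.sum(axis=1, keepdims=True)
        fit = _fit_single(
            counts, K, beta0, alpha0, eta, tol, max_iter,
            estimate_alpha, estep_tol, estep_max_iter,
        )
        if best is None or fit["elbo"][-1] > best["elbo"][-1]:
            best = fit
        if beta_init is not None:
            break

    assert best is not None
    if not best["converged"]:
        warnings.warn(
            f"LDA did not converge in {max_iter} iterations "
            f"(last relative change above {tol:g})",
            RuntimeWarning,
            stacklevel=2,
        )
    gamma = best["gamma"]
    return LdaModel(
        beta=best["beta"],
        gamma_norm=gamma / gamma.sum(axis=1, keepdims=True),
        gamma=gamma,
        alpha=best["alpha"],
        elbo_trace=np.asarray(best["elbo"]),
        K=K,
        vocab=list(table.feature_ids),
        seed=seed,
        eta=eta,
        converged=best["converged"],
        n_iter=len(best["elbo"]),
        estep_tol=estep_tol,
        estep_max_iter=estep_max_iter,
        sample_ids=list(table.sample_ids),
    )


def _fit_single(
    counts: np.ndarray,
    K: int,
    beta: np.ndarray,
    alpha: float,
    eta: float,
    tol: float,
    max_iter: int,
    est_alpha: bool,
    estep_tol: float,
    estep_max_iter: int,
) -> dict:
    trace: list[float] = []
    gamma = ss = None
    converged = False
    prev = -np.inf
    for it in range(max_iter):
        if it > 0:
            beta = ss + eta
            beta /= beta.sum(axis=1, keepdims=True)
            if est_alpha:
                alpha = estimate_alpha(gamma, alpha)
        gamma, ss, bounds = _batch_e_step(counts, beta, alpha, estep_tol, estep_max_iter)
        obj = float(bounds.sum() + _beta_prior_term(beta, eta))
        trace.append(obj)
        if it > 0 and abs(obj - prev) <= tol * abs(prev):
            converged = True
            break
        prev = obj
    return {
        "beta": beta,
        "gamma": gamma,
        "alpha": alpha,
        "elbo": trace,
        "converged": converged,
    }


def elbo(model: LdaModel, table: CountTable) -> float:
    """Recompute the variational objective of ``model`` on ``table``.

    Matches the internal value at the last EM iteration to 1e-6.
    """
    if list(table.feature_ids) != list(model.vocab):
        raise ValueError("table features do not match model vocabulary")
    _, _, bounds = _batch_e_step(
        table.counts, model.beta, model.alpha, model.estep_tol, model.estep_max_iter
    )
    return float(bounds.sum() + _beta_prior_term(model.beta, model.eta))
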