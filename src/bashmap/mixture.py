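"""Bernoulli-mixture deconvolution of a ReadSet into conformational states.

Each read x (a 0/1 vector over the full-length reference) is modelled as a
draw from a K-component product-Bernoulli mixture,

    P(x) = sum_k pi_k * prod_i mu_ki^x_i (1 - mu_ki)^(1 - x_i),

fit by EM with random restarts.  Reads from RNA molecules in different
conformations exhibit mutually exclusive modification patterns, which the
mixture separates into per-state modification profiles mu_k and abundances
pi_k.  State profiles can then be normalized exactly like population
reactivity profiles and differenced to localize the conformational change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp

from .io_formats import ReadSet
from .reactivity import ReactivityProfile, normalize_reactivity

__all__ = ["MixtureFit", "em_fit", "state_profiles", "bic", "match_states"]

_MU_CLIP = 1e-6


@dataclass
class MixtureFit:
    """Result of an EM fit: abundances, state profiles, responsibilities."""

    K: int
    proportions: np.ndarray  # (K,)
    mu: np.ndarray  # (K, L) per-state Bernoulli parameters
    responsibilities: np.ndarray  # (n, K)
    log_likelihood: float
    trace: np.ndarray  # per-iteration log-likelihood of the winning restart
    converged: bool
    n_reads: int
    flags: list[str] = field(default_factory=list)

    def informative_positions(self, min_delta: float = 0.01) -> int:
        """Positions whose mu differs by more than min_delta across states."""
        if self.K < 2:
            return 0
        spread = self.mu.max(axis=0) - self.mu.min(axis=0)
        return int((spread > min_delta).sum())

    def hard_labels(self) -> np.ndarray:
        return self.responsibilities.argmax(axis=1)


def _log_bernoulli(X: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """(n, K) per-read per-state log-likelihoods."""
    logmu = np.log(mu)
    log1m = np.log1p(-mu)
    return X @ logmu.T + (1.0 - X) @ log1m.T


def em_fit(
    rs: ReadSet,
    K: int,
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-4,
    max_iter: int = 300,
) -> MixtureFit:
    """Fit a K-state product-Bernoulli mixture to full-length reads.

    Restarts initialise per-read responsibilities from flat Dirichlet draws;
    the restart with the best final log-likelihood wins.  mu is clipped to
    [1e-6, 1 - 1e-6] to keep the likelihood finite; convergence is declared
    when the log-likelihood improves by less than ``tol``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    X = rs.to_matrix().astype(float)
    n, L = X.shape
    if K > n:
        raise ValueError(f"K={K} exceeds the number of reads ({n})")

    flags: list[str] = []
    if n > 0 and len(np.unique(X, axis=0)) == 1 and K >= 2:
        flags.append("non-identifiable")

    if K == 1:
        mu = np.clip(X.mean(axis=0, keepdims=True), _MU_CLIP, 1 - _MU_CLIP)
        ll = float(_log_bernoulli(X, mu).sum())
        return MixtureFit(
            K=1,
            proportions=np.array([1.0]),
            mu=mu,
            responsibilities=np.ones((n, 1)),
            log_likelihood=ll,
            trace=np.array([ll]),
            converged=True,
            n_reads=n,
            flags=flags,
        )

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(n_restarts, 1)):
        resp = rng.dirichlet(np.ones(K), size=n)
        trace = []
        converged = False
        prev_ll = -np.inf
        for _it in range(max_iter):
            # M step
            weights = resp.sum(axis=0)  # (K,)
            pi = weights / n
            mu = np.clip((resp.T @ X) / np.maximum(weights[:, None], 1e-12), _MU_CLIP, 1 - _MU_CLIP)
            # E step
            log_post = _log_bernoulli(X, mu) + np.log(np.maximum(pi, 1e-300))
            norm = logsumexp(log_post, axis=1, keepdims=True)
            resp = np.exp(log_post - norm)
            ll = float(norm.sum())
            trace.append(ll)
            if ll - prev_ll < tol and _it > 0:
                converged = True
                break
            prev_ll = ll
        fit = MixtureFit(
            K=K,
            proportions=pi,
            mu=mu,
            responsibilities=resp,
            log_likelihood=trace[-1],
            trace=np.array(trace),
            converged=converged,
            n_reads=n,
            flags=list(flags),
        )
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    if best.K >= 2 and best.informative_positions() < 10:
        best.flags.append("few-informative-positions")
    return best


def bic(fit: MixtureFit) -> float:
    """Bayesian information criterion: -2 logL + (#params) log n."""
    L = fit.mu.shape[1]
    n_params = (fit.K - 1) + fit.K * L
    return -2.0 * fit.log_likelihood + n_params * np.log(max(fit.n_reads, 1))


def match_states(fit_a: MixtureFit, fit_b: MixtureFit) -> np.ndarray:
    """Permutation aligning fit_b's states to fit_a's (Hungarian on mu L1)."""
    cost = np.abs(fit_a.mu[:, None, :] - fit_b.mu[None, :, :]).sum(axis=2)
    _, perm = linear_sum_assignment(cost)
    return perm


def state_profiles(
    fit: MixtureFit, reference, normalize: bool = True, per_base: bool = True
) -> list[ReactivityProfile]:
    """Per-state reactivity profiles from the fitted mu vectors.

    Each state's mu is treated as a misincorporation-rate vector and
    (optionally) normalized per nucleotide class, separately per state.
    """
    out = []
    for k in range(fit.K):
        prof = ReactivityProfile.from_rates(reference, fit.mu[k])
        if normalize:
            prof = normalize_reactivity(prof, per_base=per_base)
        out.append(prof)
    return out


def delta_reactivity(profiles: list[ReactivityProfile]) -> np.ndarray:
    """State 1 minus state 2 reactivity (requires exactly two profiles)."""
    if len(profiles) != 2:
        raise ValueError("delta_reactivity needs exactly two state profiles")
    return profiles[0].reactivities() - profiles[1].reactivities()
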