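"""Likelihood-ratio test of clonal relatedness for a tumor pair.

Whether two synchronous tumors are two primaries or share a clonal origin is
tested from their binary gene-level mutation profiles against a reference
series giving each gene's marginal mutation probability ``p_j``.

Model.  Under the null the two profiles are independent Bernoulli(p_j)
draws.  Under the alternative, with probability ``xi`` a gene behaves
clonally — the pair shares one outcome drawn with probability ``p_j`` — and
with probability ``1 - xi`` the tumors are independent at that gene.  The
per-gene joint probabilities (marginals are preserved) are::

    P(1,1) = xi*p + (1-xi)*p^2
    P(0,0) = xi*(1-p) + (1-xi)*(1-p)^2
    P(1,0) = P(0,1) = (1-xi)*p*(1-p)

The likelihood is evaluated over the genes mutated in at least one tumor of
the pair: concordant absence across a mostly-unmutated panel carries no
evidence of shared origin under this convention, so disjoint profiles always
give xi_hat = 0 and a zero statistic.  The statistic is
``2 * (max_xi loglik - loglik(0))``, maximized by golden-section search on
[0, 1] (the per-gene terms are log-linear in xi, hence the sum is concave).

Significance is assessed by Monte Carlo: null pairs are drawn as independent
Bernoulli(p_j) profiles conditioned on each tumor's observed mutation count
(exact conditional-Bernoulli sampling), which keeps mutation burden out of
the relatedness assessment; ``p = (1 + #{sim lr >= observed}) / (1 + n_sim)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

Profile = Union[Mapping[str, int], Iterable[str]]

_GOLDEN_ITERS = 40  # interval shrinks by 0.618 per step: well below 1e-6


@dataclass(frozen=True)
class ReferenceFrequencies:
    """Marginal per-gene mutation probabilities from a reference series."""

    genes: tuple[str, ...]
    p: np.ndarray
    n_reference_samples: int
    smoothing: float

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("empty gene universe")
        if np.any((self.p <= 0) | (self.p >= 1)):
            raise ValueError(
                "all reference frequencies must lie strictly in (0,1); "
                "use a positive pseudocount"
            )

    def index_of(self, gene: str) -> int:
        return self.genes.index(gene)


@dataclass(frozen=True)
class ClonalityVerdict:
    lr_statistic: float
    xi_hat: float
    p_value: float
    n_sim: int
    seed: int


def estimate_reference_frequencies(
    reference_profiles, pseudocount: float = 0.5
) -> ReferenceFrequencies:
    """p_j = (hits_j + pseudocount) / (n + 2*pseudocount).

    ``reference_profiles`` is a samples x genes 0/1 matrix: a pandas
    DataFrame (columns = genes) or a (matrix, genes) tuple.
    """
    import pandas as pd

    if isinstance(reference_profiles, tuple):
        matrix, genes = reference_profiles
        matrix = np.asarray(matrix)
        genes = tuple(genes)
    elif isinstance(reference_profiles, pd.DataFrame):
        matrix = reference_profiles.to_numpy()
        genes = tuple(reference_profiles.columns)
    else:
        raise TypeError("expected a DataFrame or (matrix, genes) tuple")
    if matrix.ndim != 2 or matrix.shape[1] != len(genes):
        raise ValueError("profile matrix shape does not match gene universe")
    if len(genes) == 0:
        raise ValueError("empty gene universe")
    n = matrix.shape[0]
    hits = matrix.sum(axis=0).astype(float)
    p = (hits + pseudocount) / (n + 2 * pseudocount)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError(
            "degenerate reference frequency (p=0 or p=1); "
            "a positive pseudocount is required"
        )
    return ReferenceFrequencies(
        genes=genes, p=p, n_reference_samples=n, smoothing=pseudocount
    )


def _as_vector(profile: Profile, ref: ReferenceFrequencies) -> np.ndarray:
    """Binary vector over the reference universe; site-level inputs (gene ->
    count) collapse to presence."""
    if isinstance(profile, np.ndarray):
        if profile.shape != (len(ref.genes),):
            raise ValueError("profile vector does not match the gene universe")
        return profile.astype(np.int8)
    vec = np.zeros(len(ref.genes), dtype=np.int8)
    index = {g: i for i, g in enumerate(ref.genes)}
    if isinstance(profile, Mapping):
        items = ((g, int(bool(c))) for g, c in profile.items())
    else:
        items = ((g, 1) for g in profile)
    for gene, present in items:
        if gene not in index:
            raise ValueError(f"gene {gene!r} not in the reference universe")
        if present:
            vec[index[gene]] = 1
    return vec


def _mixture_terms(
    a: np.ndarray, b: np.ndarray, p: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (C0, C1) with likelihood term C0 + xi*C1, restricted to genes
    mutated in at least one tumor (others contribute the neutral term 1)."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    pq = p * (1 - p)
    both = (a == 1) & (b == 1)
    disc = a != b
    C0 = np.ones(np.broadcast(a, b).shape)
    C1 = np.zeros_like(C0)
    C0 = np.where(both, p * p, C0)
    C1 = np.where(both, pq, C1)
    C0 = np.where(disc, pq, C0)
    C1 = np.where(disc, -pq, C1)
    return C0, C1


def _max_loglik_batch(
    C0: np.ndarray, C1: np.ndarray, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rowwise golden-section maximization of sum(log(C0 + xi*C1)) on [0,1].

    Returns (loglik_max, xi_hat, loglik_null).  The objective is concave, so
    golden-section converges; rows whose maximum sits at 0 report xi_hat 0.
    """
    def f(xi: np.ndarray) -> np.ndarray:
        return np.log(np.maximum(C0 + xi[:, None] * C1, 1e-300)).sum(axis=1)

    n_rows = C0.shape[0]
    invphi = (np.sqrt(5.0) - 1) / 2
    a = np.zeros(n_rows)
    b = np.ones(n_rows)
    x1 = b - invphi * (b - a)
    x2 = a + invphi * (b - a)
    f1, f2 = f(x1), f(x2)
    for _ in range(_GOLDEN_ITERS):
        left = f1 >= f2  # maximum lies in [a, x2] for these rows
        b = np.where(left, x2, b)
        a = np.where(left, a, x1)
        cand = np.where(left, b - invphi * (b - a), a + invphi * (b - a))
        f_cand = f(cand)
        x1_old, f1_old = x1, f1
        x1 = np.where(left, cand, x2)
        f1 = np.where(left, f_cand, f2)
        x2 = np.where(left, x1_old, cand)
        f2 = np.where(left, f1_old, f_cand)
    xi_hat = (a + b) / 2
    ll_max = f(xi_hat)
    ll0 = np.log(np.maximum(C0, 1e-300)).sum(axis=1)
    better = ll_max > ll0 + 1e-12
    xi_hat = np.where(better, xi_hat, 0.0)
    ll_max = np.where(better, ll_max, ll0)
    return ll_max, xi_hat, ll0


def clonality_lr(
    profile_a: Profile, profile_b: Profile, ref: ReferenceFrequencies
) -> tuple[float, float]:
    """(lr_statistic, xi_hat) for one tumor pair.

    Symmetric in the two profiles; disjoint profiles give (0, 0).
    """
    a = _as_vector(profile_a, ref)
    b = _as_vector(profile_b, ref)
    C0, C1 = _mixture_terms(a, b, ref.p)
    ll_max, xi_hat, ll0 = _max_loglik_batch(C0, C1)
    lr = max(2.0 * (ll_max[0] - ll0[0]), 0.0)
    if lr == 0.0:
        return 0.0, 0.0
    return lr, float(xi_hat[0])


def _log_esp_table(logw: np.ndarray, k: int) -> np.ndarray:
    """logE[i, r] = log elementary symmetric polynomial e_r(w_i..w_{n-1})."""
    n = len(logw)
    logE = np.full((n + 1, k + 1), -np.inf)
    logE[:, 0] = 0.0
    for i in range(n - 1, -1, -1):
        for r in range(1, k + 1):
            logE[i, r] = np.logaddexp(logE[i + 1, r], logw[i] + logE[i + 1, r - 1])
    return logE


def _sample_conditional_bernoulli(
    p: np.ndarray, k: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Draws from independent Bernoulli(p_j) conditioned on sum == k.

    Exact sequential sampling through the elementary-symmetric-polynomial
    recursion (Chen et al. sampling for conditional Bernoulli)."""
    n = len(p)
    if not 0 <= k <= n:
        raise ValueError(f"conditioned count {k} outside [0, {n}]")
    out = np.zeros((n_draws, n), dtype=np.int8)
    if k == 0:
        return out
    logw = np.log(p) - np.log1p(-p)
    logE = _log_esp_table(logw, k)
    remaining = np.full(n_draws, k)
    u = rng.random((n_draws, n))
    for i in range(n):
        active = remaining > 0
        if not active.any():
            break
        r = remaining[active]
        log_p1 = logw[i] + logE[i + 1, r - 1] - logE[i, r]
        take = u[active, i] < np.exp(log_p1)
        idx = np.flatnonzero(active)[take]
        out[idx, i] = 1
        remaining[idx] -= 1
    return out


def clonality_p(
    profile_a: Profile,
    profile_b: Profile,
    ref: ReferenceFrequencies,
    n_sim: int = 999,
    seed: int = 0,
) -> ClonalityVerdict:
    """Monte Carlo p-value for the clonal-relatedness statistic.

    Null pairs preserve each tumor's observed mutation count; the +1
    correction keeps the p-value strictly positive.
    """
    if n_sim < 999:
        raise ValueError("n_sim must be at least 999")
    a = _as_vector(profile_a, ref)
    b = _as_vector(profile_b, ref)
    lr_obs, xi_hat = clonality_lr(a, b, ref)

    rng = np.random.default_rng(seed)
    sim_a = _sample_conditional_bernoulli(ref.p, int(a.sum()), n_sim, rng)
    sim_b = _sample_conditional_bernoulli(ref.p, int(b.sum()), n_sim, rng)
    C0, C1 = _mixture_terms(sim_a, sim_b, ref.p)
    ll_max, _, ll0 = _max_loglik_batch(C0, C1)
    sim_lr = np.maximum(2.0 * (ll_max - ll0), 0.0)
    p_value = (1 + int(np.sum(sim_lr >= lr_obs - 1e-9))) / (1 + n_sim)
    return ClonalityVerdict(
        lr_statistic=lr_obs, xi_hat=xi_hat, p_value=p_value,
        n_sim=n_sim, seed=seed,
    )
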