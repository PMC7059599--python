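"""Reduced reparameterized unified model (RRUM) core.

The RRUM is a non-compensatory cognitive diagnosis model.  An examinee is
described by a binary attribute-mastery profile ``alpha`` of length ``K``;
item ``j`` is described by a Q-matrix row ``q_j`` (which attributes it
requires), a baseline correct-response probability ``pi*_j`` (examinee
masters every required attribute) and penalty ratios ``r*_jk in (0, 1)``,
one per required attribute.  The item response function is

    P(X_j = 1 | alpha) = pi*_j * prod_{k: q_jk = 1} (r*_jk) ** (1 - alpha_k)

so each required-but-unmastered attribute multiplies the success
probability by its penalty ratio.

This module provides the profile space, the response model, Bernoulli
response simulation, Bayesian posterior updating over the ``2**K``
candidate profiles, and MAP classification.  All randomness flows through
explicit :class:`numpy.random.Generator` instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MAX_ATTRIBUTES",
    "AttributeProfile",
    "RRUMItem",
    "ItemBank",
    "PosteriorDistribution",
    "enumerate_profiles",
    "profile_index",
    "rrum_response_prob",
    "response_prob_table",
    "simulate_response",
    "update_posterior",
    "map_estimate",
]

#: Hard cap on the attribute count; the candidate space is 2**K.
MAX_ATTRIBUTES = 20

#: An attribute-mastery profile is an int8 vector of 0/1 indicators.
AttributeProfile = np.ndarray

#: Relative tolerance used to detect ties in argmax operations.
_TIE_RTOL = 1e-12


def enumerate_profiles(K: int) -> np.ndarray:
    """Return all ``2**K`` mastery profiles as a ``(2**K, K)`` int8 array.

    Profiles are ordered lexicographically with attribute 1 as the most
    significant bit, i.e. row ``i`` is the ``K``-bit binary expansion of
    ``i``.  Every module in the package indexes the candidate space in
    this order.
    """
    if not isinstance(K, (int, np.integer)) or isinstance(K, bool):
        raise TypeError(f"K must be an integer, got {K!r}")
    if not 1 <= K <= MAX_ATTRIBUTES:
        raise ValueError(f"K must be in [1, {MAX_ATTRIBUTES}], got {K}")
    idx = np.arange(2**K, dtype=np.int64)
    shifts = np.arange(K - 1, -1, -1)
    return ((idx[:, None] >> shifts[None, :]) & 1).astype(np.int8)


def profile_index(alpha) -> int:
    """Inverse of :func:`enumerate_profiles`: profile bits -> integer rank."""
    bits = np.asarray(alpha, dtype=np.int64).ravel()
    K = bits.size
    if K < 1 or K > MAX_ATTRIBUTES:
        raise ValueError(f"profile length must be in [1, {MAX_ATTRIBUTES}]")
    if np.any((bits != 0) & (bits != 1)):
        raise ValueError("profile entries must be 0 or 1")
    weights = 1 << np.arange(K - 1, -1, -1, dtype=np.int64)
    return int(bits @ weights)


@dataclass(frozen=True)
class RRUMItem:
    """One RRUM item: Q-matrix row, ``pi*`` and the ``r*`` penalty ratios.

    ``r_star`` entries are only meaningful where ``q == 1``; positions with
    ``q == 0`` are stored as NaN.
    """

    q: np.ndarray
    pi_star: float
    r_star: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=np.int8).ravel()
        r = np.asarray(self.r_star, dtype=float).ravel()
        if q.size != r.size:
            raise ValueError("q and r_star must have the same length")
        if np.any((q != 0) & (q != 1)):
            raise ValueError("q entries must be 0 or 1")
        if q.sum() < 1:
            raise ValueError("an item must measure at least one attribute")
        if not 0.0 < float(self.pi_star) < 1.0:
            raise ValueError(f"pi_star must lie in (0, 1), got {self.pi_star}")
        measured = q == 1
        if np.any(~((r[measured] > 0.0) & (r[measured] < 1.0))):
            raise ValueError("r_star must lie in (0, 1) for every measured attribute")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "pi_star", float(self.pi_star))
        object.__setattr__(self, "r_star", np.where(measured, r, np.nan))

    @property
    def K(self) -> int:
        return self.q.size

    def response_probs(self, profiles: np.ndarray | None = None) -> np.ndarray:
        """P(X=1 | alpha) for every candidate profile, in profile order."""
        if profiles is None:
            profiles = enumerate_profiles(self.K)
        return response_prob_table(
            self.q[None, :], np.array([self.pi_star]), self.r_star[None, :], profiles
        )[0]


def rrum_response_prob(item: RRUMItem, alpha) -> float:
    """RRUM item response function P(X_j = 1 | alpha)."""
    bits = np.asarray(alpha, dtype=np.int8).ravel()
    if bits.size != item.K:
        raise ValueError(f"profile length {bits.size} does not match item K={item.K}")
    if np.any((bits != 0) & (bits != 1)):
        raise ValueError("profile entries must be 0 or 1")
    measured = item.q == 1
    penalties = np.where(measured & (bits == 0), item.r_star, 1.0)
    return float(item.pi_star * np.prod(penalties))


def response_prob_table(
    Q: np.ndarray, pi_star: np.ndarray, r_star: np.ndarray, profiles: np.ndarray
) -> np.ndarray:
    """Vectorized response probabilities, shape ``(J, 2**K)``.

    ``log P = log pi* + sum_k q_jk (1 - alpha_k) log r*_jk`` evaluated for
    every item row against every profile row.
    """
    Q = np.asarray(Q)
    non_mastery = (1 - profiles).astype(float)  # (C, K)
    log_r = np.where(Q == 1, np.log(np.where(Q == 1, r_star, 0.5)), 0.0)
    log_p = np.log(np.asarray(pi_star, float))[:, None] + log_r @ non_mastery.T
    return np.exp(log_p)


def simulate_response(prob: float, rng: np.random.Generator) -> int:
    """Draw a Bernoulli response with success probability ``prob``."""
    p = float(prob)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    return int(rng.random() < p)


@dataclass
class PosteriorDistribution:
    """Posterior over the ``2**K`` candidate profiles.

    The log-likelihood accumulates in log space; the normalized mass is
    recovered by a max-shifted softmax, so arbitrarily long response
    strings cannot underflow.
    """

    log_likelihood: np.ndarray
    log_prior: np.ndarray
    _mass: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.log_likelihood = np.asarray(self.log_likelihood, dtype=float)
        self.log_prior = np.asarray(self.log_prior, dtype=float)
        if self.log_likelihood.shape != self.log_prior.shape:
            raise ValueError("log_likelihood and log_prior shapes differ")

    @classmethod
    def uniform(cls, n_profiles: int) -> "PosteriorDistribution":
        """Uniform prior over ``n_profiles`` candidates, no responses yet."""
        return cls(
            log_likelihood=np.zeros(n_profiles),
            log_prior=np.full(n_profiles, -np.log(n_profiles)),
        )

    @property
    def n_profiles(self) -> int:
        return self.log_likelihood.size

    @property
    def mass(self) -> np.ndarray:
        """Normalized posterior mass (sums to 1)."""
        if self._mass is None:
            lp = self.log_prior + self.log_likelihood
            lp = lp - lp.max()
            w = np.exp(lp)
            total = w.sum()
            if not np.isfinite(total) or total <= 0.0:
                raise FloatingPointError("posterior mass is not normalizable")
            self._mass = w / total
        return self._mass

    def updated(self, success_probs: np.ndarray, x: int) -> "PosteriorDistribution":
        """Posterior after observing response ``x`` on an item whose
        per-profile success probabilities are ``success_probs``."""
        if x not in (0, 1):
            raise ValueError(f"response must be 0 or 1, got {x!r}")
        p = np.asarray(success_probs, dtype=float)
        if p.shape != self.log_likelihood.shape:
            raise ValueError("success_probs shape does not match the profile space")
        delta = np.log(p) if x == 1 else np.log1p(-p)
        return PosteriorDistribution(self.log_likelihood + delta, self.log_prior)


def update_posterior(
    post: PosteriorDistribution, item, x: int
) -> PosteriorDistribution:
    """Bayes update after response ``x`` on ``item``.

    ``item`` may be an :class:`RRUMItem` (per-profile probabilities are
    computed from the model) or a precomputed vector of per-profile
    success probabilities (the fast path used by the CAT engine).
    """
    if isinstance(item, RRUMItem):
        probs = item.response_probs()
    else:
        probs = np.asarray(item, dtype=float)
    return post.updated(probs, x)


def map_estimate(
    post: PosteriorDistribution, rng: np.random.Generator | None = None
) -> int:
    """Index of the maximum a posteriori profile.

    Ties (within relative tolerance 1e-12) are broken uniformly at random
    from the session's generator, so e.g. a uniform posterior yields each
    profile with equal probability rather than systematically favouring
    the all-zero profile.
    """
    mass = post.mass
    m = mass.max()
    ties = np.flatnonzero(mass >= m - _TIE_RTOL * max(m, 1e-300))
    if ties.size == 1:
        return int(ties[0])
    if rng is None:
        rng = np.random.default_rng()
    return int(rng.choice(ties))


class ItemBank:
    """An ordered collection of RRUM items sharing one attribute space.

    Stores the Q-matrix ``(J, K)``, ``pi_star (J,)`` and ``r_star (J, K)``
    (NaN where ``q_jk = 0``) and precomputes the ``(J, 2**K)`` table of
    response probabilities.  Per-item KL kernels and attribute
    discrimination indices are cached here by :mod:`cdcat.discrimination`.
    """

    def __init__(self, Q, pi_star, r_star, label: str | None = None):
        Q = np.asarray(Q, dtype=np.int8)
        pi = np.asarray(pi_star, dtype=float).ravel()
        r = np.asarray(r_star, dtype=float)
        if Q.ndim != 2 or Q.shape[0] < 1:
            raise ValueError("Q must be a non-empty J x K matrix")
        J, K = Q.shape
        if not 1 <= K <= MAX_ATTRIBUTES:
            raise ValueError(f"K must be in [1, {MAX_ATTRIBUTES}], got {K}")
        if np.any((Q != 0) & (Q != 1)):
            raise ValueError("Q entries must be 0 or 1")
        if np.any(Q.sum(axis=1) < 1):
            bad = int(np.flatnonzero(Q.sum(axis=1) < 1)[0])
            raise ValueError(f"item {bad} measures no attribute (all-zero Q row)")
        if pi.size != J or r.shape != (J, K):
            raise ValueError("parameter shapes do not match Q")
        if np.any(~((pi > 0.0) & (pi < 1.0))):
            raise ValueError("pi_star must lie in (0, 1) for every item")
        measured = Q == 1
        if np.any(~((r[measured] > 0.0) & (r[measured] < 1.0))):
            raise ValueError("r_star must lie in (0, 1) wherever q_jk = 1")

        self.Q = Q
        self.pi_star = pi
        self.r_star = np.where(measured, r, np.nan)
        self.label = label
        self.profiles = enumerate_profiles(K)
        #: (J, 2**K) success probabilities for every item x profile.
        self.prob = response_prob_table(self.Q, self.pi_star, self.r_star, self.profiles)
        # caches filled lazily by cdcat.discrimination
        self._d_tensor: np.ndarray | None = None
        self._adi_directional: np.ndarray | None = None

    @property
    def J(self) -> int:
        return self.Q.shape[0]

    @property
    def K(self) -> int:
        return self.Q.shape[1]

    def __len__(self) -> int:
        return self.J

    def item(self, j: int) -> RRUMItem:
        return RRUMItem(q=self.Q[j], pi_star=self.pi_star[j], r_star=self.r_star[j])

    def __iter__(self):
        return (self.item(j) for j in range(self.J))
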