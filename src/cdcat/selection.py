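"""Item selection: PWKL / MPWKL information and attribute-balance indices.

Two information indices drive adaptive item choice:

* PWKL — posterior-weighted KL: KL divergence between the response
  distribution at the current MAP profile estimate and at each candidate
  profile, weighted by the candidate's posterior mass.
* MPWKL — the point estimate is replaced by the full posterior, giving a
  double sum over (reference, candidate) profile pairs weighted by the
  product of their posterior masses.

Attribute-coverage balancing multiplies the information index by an
attribute-balance index (ABI) in [0, 1]:

* count-based (the MGDI method): per-attribute deficit ``(B_k - b_k)/B_k``
  where ``B_k`` is the minimum number of items that must measure attribute
  ``k`` and ``b_k`` the number already administered;
* ADI-based: the item-count deficit is replaced by an information deficit
  ``(ADI_k - adi_k)/ADI_k`` where ``ADI_k`` is a lower bound on the
  accumulated attribute discrimination index and ``adi_k`` the ADI already
  delivered for ``k``.

In both cases only the attributes the item measures enter the product,
met constraints contribute a factor 0, and once every candidate item's
ABI is 0 (all constraints met or unreachable) selection falls back to the
bare information index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cdm_core import (
    ItemBank,
    PosteriorDistribution,
    RRUMItem,
    enumerate_profiles,
    profile_index,
    rrum_response_prob,
)
from .discrimination import bank_adi, build_d_matrix, d_tensor

__all__ = [
    "INFORMATION_METHODS",
    "CONSTRAINT_MODES",
    "ConstraintState",
    "SelectionConfig",
    "PoolExhaustedError",
    "pwkl_index",
    "mpwkl_index",
    "count_abi",
    "adi_abi",
    "abi_bank",
    "combined_index",
    "select_next",
]

INFORMATION_METHODS = ("PWKL", "MPWKL")
CONSTRAINT_MODES = ("uncontrolled", "count_based", "adi_based")

_TIE_RTOL = 1e-12


class PoolExhaustedError(RuntimeError):
    """Raised when no unadministered item remains."""


@dataclass
class ConstraintState:
    """Per-attribute coverage accumulators for one CAT session.

    ``b`` counts administered items measuring each attribute against the
    lower bounds ``B``; ``adi_acc`` accumulates administered items'
    averaged ADIs against the bounds ``adi_bound`` (nats).  Both
    accumulators advance for every administered item regardless of mode,
    so uncontrolled sessions can be scored against the same yardsticks.
    """

    mode: str
    B: np.ndarray
    b: np.ndarray
    adi_bound: np.ndarray
    adi_acc: np.ndarray

    def __post_init__(self) -> None:
        if self.mode not in CONSTRAINT_MODES:
            raise ValueError(f"unknown constraint mode {self.mode!r}")
        self.B = np.asarray(self.B, dtype=np.int64)
        self.b = np.asarray(self.b, dtype=np.int64)
        self.adi_bound = np.asarray(self.adi_bound, dtype=float)
        self.adi_acc = np.asarray(self.adi_acc, dtype=float)
        if np.any(self.B < 1):
            raise ValueError("item-count lower bounds B_k must be >= 1")
        if np.any(self.adi_bound <= 0.0):
            raise ValueError("ADI lower bounds must be > 0")

    @classmethod
    def fresh(
        cls,
        mode: str,
        K: int,
        item_lower_bound: int | np.ndarray = 2,
        adi_lower_bound: float | np.ndarray = 1.0,
    ) -> "ConstraintState":
        return cls(
            mode=mode,
            B=np.broadcast_to(np.asarray(item_lower_bound, np.int64), (K,)).copy(),
            b=np.zeros(K, dtype=np.int64),
            adi_bound=np.broadcast_to(np.asarray(adi_lower_bound, float), (K,)).copy(),
            adi_acc=np.zeros(K, dtype=float),
        )

    def administer(self, q: np.ndarray, adi_row: np.ndarray) -> None:
        """Record one administered item (Q-row ``q``, averaged ADIs ``adi_row``)."""
        q = np.asarray(q)
        self.b = self.b + (q == 1)
        self.adi_acc = self.adi_acc + np.where(q == 1, np.asarray(adi_row, float), 0.0)

    def counts_satisfied(self) -> bool:
        return bool(np.all(self.b >= self.B))

    def adi_satisfied(self) -> bool:
        return bool(np.all(self.adi_acc >= self.adi_bound))


@dataclass(frozen=True)
class SelectionConfig:
    """How items are chosen in one condition.

    ``clamp`` controls how negative ADI deficits are handled: ``"factor"``
    floors each per-attribute factor at 0 before multiplying (default;
    avoids two negative factors producing a spuriously positive index),
    ``"product"`` floors only the final product, the literal reading of
    the clamping rule.
    """

    information: str = "PWKL"
    constraint: str = "uncontrolled"
    test_length: int = 10
    item_lower_bound: int = 2
    adi_lower_bound: float = 1.0
    clamp: str = "factor"

    def __post_init__(self) -> None:
        if self.information not in INFORMATION_METHODS:
            raise ValueError(f"unknown information method {self.information!r}")
        if self.constraint not in CONSTRAINT_MODES:
            raise ValueError(f"unknown constraint mode {self.constraint!r}")
        if self.test_length < 1:
            raise ValueError("test_length must be >= 1")
        if self.clamp not in ("factor", "product"):
            raise ValueError(f"clamp must be 'factor' or 'product', got {self.clamp!r}")


def _q_of(item) -> np.ndarray:
    return item.q if isinstance(item, RRUMItem) else np.asarray(item)


def pwkl_index(item: RRUMItem, post: PosteriorDistribution, alpha_hat) -> float:
    """Posterior-weighted KL information of one item at the MAP estimate."""
    probs = item.response_probs()
    p_hat = rrum_response_prob(item, alpha_hat)
    kl = p_hat * np.log(p_hat / probs) + (1.0 - p_hat) * np.log(
        (1.0 - p_hat) / (1.0 - probs)
    )
    return float(kl @ post.mass)


def mpwkl_index(item: RRUMItem, post: PosteriorDistribution) -> float:
    """Fully posterior-weighted KL information (double sum over profiles)."""
    D = build_d_matrix(item)
    mass = post.mass
    return float(mass @ D @ mass)


def count_abi(item, state: ConstraintState) -> float:
    """Count-based attribute-balance index of one item, in [0, 1]."""
    q = _q_of(item)
    deficit = np.clip((state.B - state.b) / state.B, 0.0, None)
    return float(np.prod(np.where(q == 1, deficit, 1.0)))


def adi_abi(item, state: ConstraintState, clamp: str = "factor") -> float:
    """ADI-based attribute-balance index of one item, in [0, 1]."""
    q = _q_of(item)
    deficit = (state.adi_bound - state.adi_acc) / state.adi_bound
    if clamp == "factor":
        deficit = np.maximum(deficit, 0.0)
    value = float(np.prod(np.where(q == 1, deficit, 1.0)))
    return max(value, 0.0) if clamp == "product" else value


def abi_bank(bank: ItemBank, state: ConstraintState, clamp: str = "factor") -> np.ndarray:
    """Vector of ABIs for every item in the bank under the state's mode."""
    if state.mode == "uncontrolled":
        return np.ones(bank.J)
    if state.mode == "count_based":
        deficit = np.clip((state.B - state.b) / state.B, 0.0, None)
    else:
        deficit = (state.adi_bound - state.adi_acc) / state.adi_bound
        if clamp == "factor":
            deficit = np.maximum(deficit, 0.0)
    values = np.prod(np.where(bank.Q == 1, deficit[None, :], 1.0), axis=1)
    return np.maximum(values, 0.0) if clamp == "product" else values


def _information_bank(
    bank: ItemBank, post: PosteriorDistribution, alpha_hat, method: str
) -> np.ndarray:
    """Information index for every item, vectorized over the cached D tensors."""
    D = d_tensor(bank)
    mass = post.mass
    if method == "PWKL":
        hat_idx = alpha_hat if isinstance(alpha_hat, (int, np.integer)) else profile_index(alpha_hat)
        return D[:, hat_idx, :] @ mass
    return np.einsum("jdc,d,c->j", D, mass, mass, optimize=True)


def combined_index(
    item: RRUMItem,
    post: PosteriorDistribution,
    alpha_hat,
    state: ConstraintState,
    config: SelectionConfig,
) -> float:
    """Information index multiplied by the active ABI (bare index when
    uncontrolled)."""
    if config.information == "PWKL":
        if isinstance(alpha_hat, (int, np.integer)):
            alpha_hat = enumerate_profiles(item.K)[alpha_hat]
        info = pwkl_index(item, post, alpha_hat)
    else:
        info = mpwkl_index(item, post)
    if state.mode == "uncontrolled":
        return info
    abi = (
        count_abi(item, state)
        if state.mode == "count_based"
        else adi_abi(item, state, config.clamp)
    )
    return info * abi


def select_next(
    bank: ItemBank,
    administered: np.ndarray,
    post: PosteriorDistribution,
    alpha_hat,
    state: ConstraintState,
    config: SelectionConfig,
    rng: np.random.Generator,
) -> int:
    """Choose, mark and account the next item; returns its index.

    While any unadministered item has a positive ABI, the argmax runs
    over ``information * ABI`` restricted to those items; once every
    candidate's ABI is 0 the bare information index decides.  Ties are
    broken uniformly at random from ``rng``.  ``administered`` is a
    J-length boolean mask and is updated in place, as is ``state``.
    """
    administered = np.asarray(administered, dtype=bool)
    candidates = ~administered
    if not candidates.any():
        raise PoolExhaustedError("no unadministered item remains in the pool")

    info = _information_bank(bank, post, alpha_hat, config.information)
    if state.mode != "uncontrolled":
        abi = abi_bank(bank, state, config.clamp)
        eligible = candidates & (abi > 0.0)
        if eligible.any():
            score = info * abi
        else:
            eligible = candidates
            score = info
    else:
        eligible = candidates
        score = info

    masked = np.where(eligible, score, -np.inf)
    best = masked.max()
    ties = np.flatnonzero(masked >= best - _TIE_RTOL * max(abs(best), 1e-300))
    j = int(ties[0]) if ties.size == 1 else int(rng.choice(ties))

    administered[j] = True
    state.administer(bank.Q[j], bank_adi(bank)[j])
    return j
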