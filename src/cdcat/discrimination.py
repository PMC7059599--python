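"""Kullback-Leibler item kernels and attribute discrimination indices (ADI).

For item ``j`` and any ordered pair of mastery profiles ``(alpha_u,
alpha_v)`` the two-outcome KL divergence

    D_juv = P_u(1) ln(P_u(1)/P_v(1)) + P_u(0) ln(P_u(0)/P_v(0))

measures how well the item separates an examinee with profile ``alpha_u``
from one with ``alpha_v``.  Collecting all ordered pairs gives the
``(2**K, 2**K)`` D-matrix of the item.

The ADI of item ``j`` for attribute ``k`` aggregates the D-matrix over the
``2**(K-1)`` profile pairs that differ *only* in attribute ``k``: the
"1" direction discriminates masters from non-masters, the "0" direction
the reverse, each pair weighted uniformly with ``1 / 2**(K-1)`` (the
uniform-weight variant, written ADI_(A); a joint-probability weighting
over knowledge states exists in the literature but is not built here).
An item with ``q_jk = 0`` has ADI exactly 0 for ``k``: its response
distribution does not depend on ``alpha_k``.

Natural logarithms are used throughout; a fixed change of base would
rescale every index and every ADI lower bound jointly, leaving the
selection behaviour unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cdm_core import ItemBank, RRUMItem, enumerate_profiles, rrum_response_prob

__all__ = [
    "AttributeDiscrimination",
    "pairwise_kl",
    "build_d_matrix",
    "d_tensor",
    "directional_adi",
    "bank_adi",
    "bank_adi_directional",
    "bank_adi_summary",
]


@dataclass(frozen=True)
class AttributeDiscrimination:
    """Directional ADIs of one item for one attribute (nats)."""

    adi_1: float  #: discriminates masters of the attribute from non-masters
    adi_0: float  #: discriminates non-masters from masters
    adi_avg: float  #: arithmetic mean of the two directions

    def __post_init__(self) -> None:
        if abs(self.adi_avg - (self.adi_1 + self.adi_0) / 2.0) > 1e-12:
            raise ValueError("adi_avg must equal (adi_1 + adi_0) / 2")


def _binary_kl(p_u: np.ndarray, p_v: np.ndarray) -> np.ndarray:
    """KL divergence between Bernoulli(p_u) and Bernoulli(p_v), natural log."""
    p_u = np.asarray(p_u, float)
    p_v = np.asarray(p_v, float)
    if np.any((p_u <= 0) | (p_u >= 1) | (p_v <= 0) | (p_v >= 1)):
        raise FloatingPointError("response probabilities must lie strictly in (0, 1)")
    return p_u * np.log(p_u / p_v) + (1.0 - p_u) * np.log((1.0 - p_u) / (1.0 - p_v))


def pairwise_kl(item: RRUMItem, alpha_u, alpha_v) -> float:
    """D_juv for a single ordered pair of profiles."""
    p_u = rrum_response_prob(item, alpha_u)
    p_v = rrum_response_prob(item, alpha_v)
    return float(_binary_kl(p_u, p_v))


def build_d_matrix(item: RRUMItem) -> np.ndarray:
    """Full ``(2**K, 2**K)`` D-matrix of one item (row = alpha_u, col = alpha_v)."""
    p = item.response_probs()
    return _d_from_probs(p[None, :])[0]


def _d_from_probs(prob: np.ndarray) -> np.ndarray:
    """D tensors from a (J, C) success-probability table -> (J, C, C)."""
    lp = np.log(prob)
    l1p = np.log1p(-prob)
    q = 1.0 - prob
    D = prob[:, :, None] * (lp[:, :, None] - lp[:, None, :]) + q[:, :, None] * (
        l1p[:, :, None] - l1p[:, None, :]
    )
    # exact zeros on the diagonal and clip negative rounding noise
    return np.maximum(D, 0.0)


def d_tensor(bank: ItemBank) -> np.ndarray:
    """Cached ``(J, 2**K, 2**K)`` stack of all D-matrices of a bank."""
    if bank._d_tensor is None:
        bank._d_tensor = _d_from_probs(bank.prob)
    return bank._d_tensor


def _pair_indices(K: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Profile-index pairs differing only in attribute ``k`` (0-based).

    Returns ``(masters, non_masters)``: ``masters[i]`` has attribute ``k``
    mastered, ``non_masters[i]`` is the same profile with it unmastered.
    """
    profiles = enumerate_profiles(K)
    bit = 1 << (K - 1 - k)
    masters = np.flatnonzero(profiles[:, k] == 1)
    return masters, masters - bit


def directional_adi(item: RRUMItem, k: int, weights: str = "uniform") -> AttributeDiscrimination:
    """Both directional ADIs of ``item`` for attribute ``k`` (0-based).

    Only the uniform ADI_(A) weighting (each of the ``2**(K-1)`` pairs
    weighted ``1 / 2**(K-1)``) is implemented.
    """
    if weights != "uniform":
        raise NotImplementedError(
            "only the uniform-weight ADI_(A) variant is implemented"
        )
    K = item.K
    if not 0 <= k < K:
        raise ValueError(f"attribute index must lie in [0, {K - 1}], got {k}")
    if item.q[k] == 0:
        return AttributeDiscrimination(0.0, 0.0, 0.0)
    D = build_d_matrix(item)
    ones, zeros = _pair_indices(K, k)
    adi_1 = float(D[ones, zeros].mean())
    adi_0 = float(D[zeros, ones].mean())
    return AttributeDiscrimination(adi_1, adi_0, (adi_1 + adi_0) / 2.0)


def bank_adi_directional(bank: ItemBank) -> np.ndarray:
    """Cached ``(J, K, 2)`` array of directional ADIs (``[..., 0]`` = adi_1)."""
    if bank._adi_directional is None:
        D = d_tensor(bank)
        out = np.zeros((bank.J, bank.K, 2))
        for k in range(bank.K):
            ones, zeros = _pair_indices(bank.K, k)
            measured = bank.Q[:, k] == 1
            out[measured, k, 0] = D[measured][:, ones, zeros].mean(axis=1)
            out[measured, k, 1] = D[measured][:, zeros, ones].mean(axis=1)
        bank._adi_directional = out
    return bank._adi_directional


def bank_adi(bank: ItemBank) -> np.ndarray:
    """``(J, K)`` averaged ADIs (mean of the two directions; 0 where q_jk=0)."""
    return bank_adi_directional(bank).mean(axis=2)


def bank_adi_summary(bank: ItemBank) -> pd.DataFrame:
    """Per-attribute count, sum and mean of item ADIs over measuring items.

    One row per attribute with columns ``pool, attribute, n_items,
    adi_sum, adi_mean``, mirroring the descriptive pool summaries the
    simulation study reports.
    """
    adi = bank_adi(bank)
    rows = []
    for k in range(bank.K):
        measured = bank.Q[:, k] == 1
        n = int(measured.sum())
        total = float(adi[measured, k].sum())
        rows.append(
            {
                "pool": bank.label or "",
                "attribute": k + 1,
                "n_items": n,
                "adi_sum": total,
                "adi_mean": total / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
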