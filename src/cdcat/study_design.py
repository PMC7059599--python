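"""Simulation study fixtures: item pools and examinee populations.

Three item pools, each with J=775 items measuring K=5 attributes, differ
only in the range of the penalty ratios r* (smaller r* = stronger
discrimination):

* LD  (low discrimination):    r* ~ U(0.15, 0.50)
* HD  (high discrimination):   r* ~ U(0.05, 0.40)
* HyD (hybrid discrimination): r* ~ U(0.05, 0.50)

with pi* ~ U(0.75, 0.95) in every pool.  The Q-matrix replicates each of
the 2**K - 1 = 31 nonzero attribute patterns 775/31 = 25 times, so every
attribute is measured by exactly 16 * 25 = 400 items.

Three examinee populations of N=3,200:

* Unif — every one of the 32 mastery profiles held by exactly 100
  examinees (stratified, then shuffled);
* Norm-0.5 / Norm-0.8 — profiles from a thresholded multivariate normal:
  z ~ MVN(0, Sigma) with unit variances and common correlation rho
  (0.5 or 0.8), attribute k mastered iff z_k exceeds the (1 - p_k)
  quantile, marginal mastery probabilities p = (0.45, 0.50, 0.55, 0.60,
  0.65).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cdm_core import ItemBank, enumerate_profiles
from .discrimination import bank_adi, d_tensor

__all__ = [
    "PoolSpec",
    "PopulationSpec",
    "POOL_SPECS",
    "POPULATION_SPECS",
    "build_q_matrix",
    "generate_item_pool",
    "generate_population_uniform",
    "generate_population_mvn",
    "generate_population",
    "pool_parameter_summary",
    "population_attribute_counts",
]


@dataclass(frozen=True)
class PoolSpec:
    """Recipe for one simulated item pool."""

    label: str
    J: int = 775
    K: int = 5
    pi_range: tuple[float, float] = (0.75, 0.95)
    r_range: tuple[float, float] = (0.15, 0.50)
    q_design: str = "balanced_replicates"

    def __post_init__(self) -> None:
        for lo, hi in (self.pi_range, self.r_range):
            if not (0.0 < lo < hi < 1.0):
                raise ValueError("parameter ranges must lie strictly inside (0, 1)")
        if self.J < 1 or self.K < 1:
            raise ValueError("J and K must be positive")


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for one simulated examinee population."""

    label: str
    N: int = 3200
    K: int = 5
    mastery_probs: tuple[float, ...] = (0.45, 0.50, 0.55, 0.60, 0.65)
    rho: float | None = None  #: None -> uniform over all profiles

    def __post_init__(self) -> None:
        if len(self.mastery_probs) != self.K:
            raise ValueError("mastery_probs length must equal K")
        if any(not 0.0 < p < 1.0 for p in self.mastery_probs):
            raise ValueError("mastery probabilities must lie in (0, 1)")


#: The three pool configurations of the study.
POOL_SPECS: dict[str, PoolSpec] = {
    "LD": PoolSpec(label="LD", r_range=(0.15, 0.50)),
    "HD": PoolSpec(label="HD", r_range=(0.05, 0.40)),
    "HyD": PoolSpec(label="HyD", r_range=(0.05, 0.50)),
}

#: The three population configurations of the study.
POPULATION_SPECS: dict[str, PopulationSpec] = {
    "Unif": PopulationSpec(label="Unif", rho=None),
    "Norm-0.5": PopulationSpec(label="Norm-0.5", rho=0.5),
    "Norm-0.8": PopulationSpec(label="Norm-0.8", rho=0.8),
}


def build_q_matrix(spec: PoolSpec) -> np.ndarray:
    """Deterministic balanced Q-matrix for a pool spec.

    Each of the ``2**K - 1`` nonzero attribute patterns (in profile
    order) is replicated ``J / (2**K - 1)`` times consecutively.
    """
    if spec.q_design != "balanced_replicates":
        raise ValueError(f"unknown q_design {spec.q_design!r}")
    n_patterns = 2**spec.K - 1
    if spec.J % n_patterns:
        raise ValueError(
            f"J={spec.J} is not divisible by the {n_patterns} nonzero patterns"
        )
    patterns = enumerate_profiles(spec.K)[1:]  # drop the all-zero profile
    return np.repeat(patterns, spec.J // n_patterns, axis=0)


def generate_item_pool(spec: PoolSpec, rng: np.random.Generator) -> ItemBank:
    """Draw a pool: Q from :func:`build_q_matrix`, parameters from the
    spec's uniform ranges.  KL kernels and ADIs are precomputed."""
    Q = build_q_matrix(spec)
    pi = rng.uniform(*spec.pi_range, size=spec.J)
    r = rng.uniform(*spec.r_range, size=(spec.J, spec.K))
    r = np.where(Q == 1, r, np.nan)
    bank = ItemBank(Q, pi, r, label=spec.label)
    d_tensor(bank)
    bank_adi(bank)
    return bank


def generate_population_uniform(
    N: int, K: int, rng: np.random.Generator
) -> np.ndarray:
    """Exactly ``N / 2**K`` examinees per mastery profile, shuffled."""
    n_profiles = 2**K
    if N % n_profiles:
        raise ValueError(f"N={N} is not divisible by the {n_profiles} profiles")
    profiles = enumerate_profiles(K)
    pop = np.repeat(profiles, N // n_profiles, axis=0)
    return pop[rng.permutation(N)]


def generate_population_mvn(
    spec: PopulationSpec, rng: np.random.Generator
) -> np.ndarray:
    """Thresholded multivariate-normal population, shape ``(N, K)``."""
    if spec.rho is None:
        raise ValueError("spec.rho is None; use generate_population_uniform")
    K = spec.K
    sigma = np.full((K, K), spec.rho)
    np.fill_diagonal(sigma, 1.0)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"correlation matrix with rho={spec.rho} is not positive definite"
        ) from exc
    z = rng.standard_normal((spec.N, K)) @ chol.T
    thresholds = stats.norm.ppf(1.0 - np.asarray(spec.mastery_probs))
    return (z > thresholds).astype(np.int8)


def generate_population(spec: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Dispatch on the spec: uniform-stratified or thresholded MVN."""
    if spec.rho is None:
        return generate_population_uniform(spec.N, spec.K, rng)
    return generate_population_mvn(spec, rng)


def pool_parameter_summary(bank: ItemBank) -> pd.DataFrame:
    """Min/max/mean/SD of pi* and of each r* column over measuring items."""
    rows = []
    cols = {"pi_star": bank.pi_star}
    for k in range(bank.K):
        cols[f"r{k + 1}"] = bank.r_star[bank.Q[:, k] == 1, k]
    for name, values in cols.items():
        rows.append(
            {
                "pool": bank.label or "",
                "parameter": name,
                "min": float(np.min(values)),
                "max": float(np.max(values)),
                "mean": float(np.mean(values)),
                "sd": float(np.std(values, ddof=1)),
            }
        )
    return pd.DataFrame(rows)


def population_attribute_counts(population: np.ndarray) -> pd.Series:
    """Examinee counts by number of mastered attributes (0..K)."""
    K = population.shape[1]
    totals = population.sum(axis=1)
    return pd.Series(
        np.bincount(totals, minlength=K + 1),
        index=pd.RangeIndex(K + 1, name="n_attributes"),
        name="n_examinees",
    )
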