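"""Evaluation criteria for simulated CAT conditions.

Five statistics summarize one condition (N examinees, fixed test length
L, pool of J items):

* PCCR — proportion of examinees whose whole estimated mastery profile
  matches the truth;
* ACCR_k — proportion correctly classified on attribute k;
* E-ACCR — coefficient of variation of the K ACCR values in percent,
  100 * SD(ACCR) / mean(ACCR) (sample SD, ddof=1); smaller = more even
  accuracy across attributes;
* item exposure chi^2 — discrepancy between observed exposure rates
  exp_j = N_j / N and the uniform target L / J, summed over the J items;
* examinee qualification rate — fraction of examinees whose administered
  test measured every attribute at least B_k times (B_k = 2 by default,
  applied to all constraint modes so uncontrolled runs are scored against
  the same yardstick).  The ADI analogue (accumulated ADI >= bound on
  every attribute) is reported as a secondary statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConditionResult",
    "pccr",
    "accr",
    "e_accr",
    "exposure_chi2",
    "qualification_rate",
    "qualification_rate_adi",
    "summarize",
]


def _stack_profiles(records) -> tuple[np.ndarray, np.ndarray]:
    if not len(records):
        raise ValueError("records must be nonempty")
    true = np.asarray([r.true_profile for r in records])
    est = np.asarray([r.estimated_profile for r in records])
    return true, est


def pccr(records) -> float:
    """Mastery-pattern correct classification rate."""
    true, est = _stack_profiles(records)
    return float(np.mean(np.all(true == est, axis=1)))


def accr(records) -> np.ndarray:
    """Per-attribute correct classification rates, shape ``(K,)``."""
    true, est = _stack_profiles(records)
    return np.mean(true == est, axis=0)


def e_accr(accr_values) -> float:
    """Equalization of ACCR: 100 * sample SD / mean of the K values."""
    values = np.asarray(accr_values, dtype=float)
    if values.size < 2:
        raise ValueError("e_accr needs at least two attribute values")
    mean = values.mean()
    if mean == 0.0:
        raise FloatingPointError("mean ACCR is zero")
    return float(100.0 * values.std(ddof=1) / mean)


def exposure_chi2(records, J: int, L: int | None = None, N: int | None = None) -> float:
    """Chi-square-style item exposure index against the uniform rate L/J."""
    N = len(records) if N is None else N
    if L is None:
        L = len(records[0].administered)
    counts = np.zeros(J, dtype=np.int64)
    for r in records:
        counts[np.asarray(r.administered)] += 1
    rates = counts / N
    target = L / J
    return float(np.sum((rates - target) ** 2 / target))


def qualification_rate(records, B=2) -> float:
    """Fraction of examinees with >= B_k items measuring every attribute."""
    b = np.asarray([r.state.b for r in records])
    bounds = np.broadcast_to(np.asarray(B, np.int64), b.shape[1:])
    return float(np.mean(np.all(b >= bounds, axis=1)))


def qualification_rate_adi(records, bound=1.0) -> float:
    """Fraction of examinees whose accumulated ADI met the bound everywhere."""
    acc = np.asarray([r.state.adi_acc for r in records])
    bounds = np.broadcast_to(np.asarray(bound, float), acc.shape[1:])
    return float(np.mean(np.all(acc >= bounds, axis=1)))


@dataclass
class ConditionResult:
    """Evaluation statistics for one simulated condition."""

    pool: str
    population: str
    constraint: str
    information: str
    n_examinees: int
    test_length: int
    pccr: float
    accr: np.ndarray
    accr_mean: float
    accr_sd: float
    e_accr: float
    exposure_chi2: float
    qualification_rate: float
    qualification_rate_adi: float

    def to_row(self) -> dict:
        row = {
            "pool": self.pool,
            "population": self.population,
            "constraint": self.constraint,
            "information": self.information,
            "n_examinees": self.n_examinees,
            "test_length": self.test_length,
            "pccr": self.pccr,
        }
        for k, v in enumerate(self.accr, start=1):
            row[f"accr_{k}"] = float(v)
        row.update(
            accr_mean=self.accr_mean,
            accr_sd=self.accr_sd,
            e_accr=self.e_accr,
            exposure_chi2=self.exposure_chi2,
            qualification_rate=self.qualification_rate,
            qualification_rate_adi=self.qualification_rate_adi,
        )
        return row


def summarize(
    records,
    J: int,
    *,
    pool: str = "",
    population: str = "",
    constraint: str = "",
    information: str = "",
    B=2,
    adi_bound=1.0,
) -> ConditionResult:
    """All five criteria for one condition's session records."""
    rates = accr(records)
    L = len(records[0].administered)
    return ConditionResult(
        pool=pool,
        population=population,
        constraint=constraint,
        information=information,
        n_examinees=len(records),
        test_length=L,
        pccr=pccr(records),
        accr=rates,
        accr_mean=float(rates.mean()),
        accr_sd=float(rates.std(ddof=1)),
        e_accr=e_accr(rates),
        exposure_chi2=exposure_chi2(records, J=J, L=L),
        qualification_rate=qualification_rate(records, B=B),
        qualification_rate_adi=qualification_rate_adi(records, bound=adi_bound),
    )
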