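"""CAT session engine and the factorial simulation study.

One session administers a fixed-length adaptive test to one examinee:
the first item is drawn uniformly at random from the pool, every
response is simulated from the examinee's true profile under the RRUM,
the posterior over the 2**K candidate profiles is updated after each
response (uniform prior), the profile estimate is re-computed by MAP,
and items 2..L are chosen by the configured selection rule.  The first
item's attribute coverage counts toward the balance constraints like any
other administered item.

The full study crosses 3 item pools x 3 populations x 3 constraint
levels x 2 information methods = 54 conditions.  Within each pool x
population block the same pool, population and per-examinee seeds are
shared across the 6 method cells, so method comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from . import evaluation
from .cdm_core import ItemBank, PosteriorDistribution, map_estimate, profile_index
from .discrimination import bank_adi
from .selection import (
    CONSTRAINT_MODES,
    INFORMATION_METHODS,
    ConstraintState,
    PoolExhaustedError,
    SelectionConfig,
    select_next,
)
from .study_design import (
    POOL_SPECS,
    POPULATION_SPECS,
    PoolSpec,
    PopulationSpec,
    generate_item_pool,
    generate_population,
)

__all__ = [
    "SessionRecord",
    "StudyConfig",
    "run_cat_session",
    "run_condition",
    "run_full_study",
]


@dataclass
class SessionRecord:
    """Everything recorded about one examinee's adaptive test."""

    examinee_id: int
    true_profile: np.ndarray
    estimated_profile: np.ndarray
    administered: np.ndarray  #: item indices in administration order, length L
    responses: np.ndarray  #: binary responses, length L
    state: ConstraintState  #: final coverage accumulators


def run_cat_session(
    examinee,
    bank: ItemBank,
    config: SelectionConfig,
    rng: np.random.Generator,
    examinee_id: int = 0,
) -> SessionRecord:
    """Administer one fixed-length CAT session to ``examinee`` (true profile)."""
    L = config.test_length
    if L > bank.J:
        raise PoolExhaustedError(f"test length {L} exceeds pool size {bank.J}")
    true_alpha = np.asarray(examinee, dtype=np.int8)
    true_idx = profile_index(true_alpha)

    post = PosteriorDistribution.uniform(2**bank.K)
    state = ConstraintState.fresh(
        config.constraint, bank.K, config.item_lower_bound, config.adi_lower_bound
    )
    administered = np.zeros(bank.J, dtype=bool)
    adi = bank_adi(bank)
    items = np.empty(L, dtype=np.int64)
    responses = np.empty(L, dtype=np.int8)
    hat_idx = 0  # overwritten after the first response

    for t in range(L):
        if t == 0:
            j = int(rng.integers(bank.J))
            administered[j] = True
            state.administer(bank.Q[j], adi[j])
        else:
            j = select_next(bank, administered, post, hat_idx, state, config, rng)
        x = int(rng.random() < bank.prob[j, true_idx])
        post = post.updated(bank.prob[j], x)
        hat_idx = map_estimate(post, rng)
        items[t] = j
        responses[t] = x

    return SessionRecord(
        examinee_id=examinee_id,
        true_profile=true_alpha,
        estimated_profile=bank.profiles[hat_idx].copy(),
        administered=items,
        responses=responses,
        state=state,
    )


def run_condition(
    bank: ItemBank,
    population: np.ndarray,
    config: SelectionConfig,
    seed,
    *,
    pool_label: str = "",
    population_label: str = "",
    return_records: bool = False,
):
    """Run one condition: a session per examinee with independent sub-seeds.

    ``seed`` may be an integer or a :class:`numpy.random.SeedSequence`.
    Returns the :class:`~cdcat.evaluation.ConditionResult`, or
    ``(result, records)`` when ``return_records`` is true.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(population))
    records = [
        run_cat_session(alpha, bank, config, np.random.default_rng(child), i)
        for i, (alpha, child) in enumerate(zip(population, children))
    ]
    result = evaluation.summarize(
        records,
        J=bank.J,
        pool=pool_label or (bank.label or ""),
        population=population_label,
        constraint=config.constraint,
        information=config.information,
        B=config.item_lower_bound,
        adi_bound=config.adi_lower_bound,
    )
    return (result, records) if return_records else result


@dataclass
class StudyConfig:
    """Factorial design of the simulation study (defaults = full study)."""

    pools: tuple[str, ...] = ("LD", "HD", "HyD")
    populations: tuple[str, ...] = ("Unif", "Norm-0.5", "Norm-0.8")
    constraints: tuple[str, ...] = CONSTRAINT_MODES
    methods: tuple[str, ...] = INFORMATION_METHODS
    J: int = 775
    K: int = 5
    N: int = 3200
    L: int = 10
    item_lower_bound: int = 2
    adi_lower_bound: float = 1.0
    seed: int = 0
    replications: int = 1

    def n_conditions(self) -> int:
        return (
            len(self.pools)
            * len(self.populations)
            * len(self.constraints)
            * len(self.methods)
        )

    def pool_spec(self, label: str) -> PoolSpec:
        base = POOL_SPECS[label]
        return PoolSpec(label=label, J=self.J, K=self.K, pi_range=base.pi_range, r_range=base.r_range)

    def population_spec(self, label: str) -> PopulationSpec:
        base = POPULATION_SPECS[label]
        return PopulationSpec(
            label=label,
            N=self.N,
            K=self.K,
            mastery_probs=base.mastery_probs[: self.K],
            rho=base.rho,
        )


def _block_seeds(master: int, pool_i: int, pop_i: int, rep: int):
    """Child SeedSequences for one pool x population block: pool draw,
    population draw, and the session stream shared by its method cells."""
    pool_ss = np.random.SeedSequence([master, rep, pool_i, 1])
    pop_ss = np.random.SeedSequence([master, rep, pop_i, 2])
    session_ss = np.random.SeedSequence([master, rep, pool_i, pop_i, 3])
    return pool_ss, pop_ss, session_ss


def run_full_study(
    study: StudyConfig, progress: bool = False
) -> tuple[list[evaluation.ConditionResult], pd.DataFrame]:
    """Sweep the factorial design; returns the results and a tidy frame.

    Replications > 1 repeat every cell with fresh pools, populations and
    session seeds; the frame gains a ``replication`` column.
    """
    results: list[evaluation.ConditionResult] = []
    rows: list[dict] = []
    cells = list(product(range(study.replications), enumerate(study.pools), enumerate(study.populations)))
    iterator = cells
    if progress:
        from tqdm import tqdm

        iterator = tqdm(cells, desc="pool x population blocks")
    for rep, (pool_i, pool_label), (pop_i, pop_label) in iterator:
        pool_ss, pop_ss, session_ss = _block_seeds(study.seed, pool_i, pop_i, rep)
        bank = generate_item_pool(study.pool_spec(pool_label), np.random.default_rng(pool_ss))
        population = generate_population(
            study.population_spec(pop_label), np.random.default_rng(pop_ss)
        )
        for constraint in study.constraints:
            for method in study.methods:
                config = SelectionConfig(
                    information=method,
                    constraint=constraint,
                    test_length=study.L,
                    item_lower_bound=study.item_lower_bound,
                    adi_lower_bound=study.adi_lower_bound,
                )
                result = run_condition(
                    bank,
                    population,
                    config,
                    # same session seeds across the 6 method cells (paired)
                    np.random.SeedSequence(session_ss.entropy),
                    pool_label=pool_label,
                    population_label=pop_label,
                )
                results.append(result)
                row = result.to_row()
                row["replication"] = rep
                rows.append(row)
    return results, pd.DataFrame(rows)
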