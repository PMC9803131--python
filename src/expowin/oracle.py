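"""Exact period-prevalence oracle via dynamic programming.

For the ``max`` assignment rule the joint state (current category,
highest-category-so-far) evolves as a Markov chain on K^2 states, so the
exact distribution of max(S_l) can be propagated in closed form — no Monte
Carlo noise. Because the annual death probability within a stratum depends
only on age and year (not on the exposure category), mortality scales all
state masses equally; survival is tracked as a scalar product of (1 - q)
and the conditional category distribution among survivors is exact.

Alternative assignment rules have no small sufficient statistic and are
checked by full path enumeration on tiny instances only.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .categories import AGE_GROUP_LOWER, AGE_GROUPS_5Y
from .errors import SizeError
from .microsim import (
    LifeTable,
    SimulationConfig,
    assign_window_category,
    matrix_bank,
    _bank_row_ix,
)

__all__ = [
    "exact_period_prevalence",
    "enumerate_paths",
    "exact_cohort_results",
]

DP_MAX_K = 8
DP_MAX_WINDOW = 15
ENUM_MAX_K = 3
ENUM_MAX_WINDOW = 6


def _matrix_for_age(matrices, age: int, n_categories: int) -> np.ndarray:
    if callable(matrices):
        return np.asarray(matrices(age), dtype=float)
    arr = np.asarray(matrices, dtype=float)
    if arr.ndim == 2:
        return arr
    # banked (n_age, K, K), indexed like the engine's bank
    return arr[int(_bank_row_ix(np.asarray(age)))]


def exact_period_prevalence(initial: np.ndarray, matrices,
                            window_length: int, start_age: int = 40,
                            q_fn=None, start_year: int = 0,
                            estimation_year: int | None = None,
                            rule: str = "max",
                            ) -> tuple[np.ndarray, float]:
    """Exact distribution of the assigned category among survivors.

    Parameters
    ----------
    initial : (K,) distribution over categories at the window's first year.
    matrices : K x K array, callable age -> K x K, or banked (A, K, K).
    window_length : number of window years L (L - 1 transition steps).
    q_fn : callable (age, year) -> annual death probability, or None.
    rule : "max" uses the DP; other rules fall back to path enumeration
        (small instances only).

    Returns
    -------
    (dist, alive_prob) : exact category distribution conditional on being
    alive at the estimation year, and the survival probability.
    """
    initial = np.asarray(initial, dtype=float)
    K = initial.size
    if estimation_year is None:
        estimation_year = start_year + window_length - 1
    if rule != "max":
        if K > ENUM_MAX_K or window_length > ENUM_MAX_WINDOW:
            raise SizeError(
                f"rule '{rule}' requires path enumeration; limits are "
                f"K <= {ENUM_MAX_K}, window <= {ENUM_MAX_WINDOW}")
        return enumerate_paths(initial, matrices, window_length, start_age,
                               q_fn, start_year, estimation_year, rule)
    if K > DP_MAX_K or window_length > DP_MAX_WINDOW:
        raise SizeError(f"DP limits are K <= {DP_MAX_K}, window length <= "
                        f"{DP_MAX_WINDOW}")

    # state P[current, max-so-far]
    P = np.zeros((K, K))
    P[np.arange(K), np.arange(K)] = initial
    survive = 1.0
    age = start_age
    for step in range(1, window_length):
        year = start_year + step
        age += 1
        if q_fn is not None:
            survive *= 1.0 - float(q_fn(age, year))
        M = _matrix_for_age(matrices, age, K)
        Pn = np.zeros_like(P)
        # new max = max(old max, destination)
        for m in range(K):
            flow = P[:, m] @ M            # (K,) mass arriving per destination
            d = np.arange(K)
            Pn[d, np.maximum(m, d)] += flow
        P = Pn
    last_year = start_year + window_length - 1
    for year in range(last_year + 1, estimation_year + 1):
        age += 1
        if q_fn is not None:
            survive *= 1.0 - float(q_fn(age, year))
    dist = P.sum(axis=0)
    total = dist.sum()
    if total > 0:
        dist = dist / total
    return dist, float(survive)


def enumerate_paths(initial: np.ndarray, matrices, window_length: int,
                    start_age: int = 40, q_fn=None, start_year: int = 0,
                    estimation_year: int | None = None, rule: str = "max",
                    ) -> tuple[np.ndarray, float]:
    """Brute-force oracle: sum over all K^L category paths."""
    initial = np.asarray(initial, dtype=float)
    K = initial.size
    if estimation_year is None:
        estimation_year = start_year + window_length - 1
    mats = []
    survive = 1.0
    age = start_age
    for step in range(1, window_length):
        age += 1
        if q_fn is not None:
            survive *= 1.0 - float(q_fn(age, start_year + step))
        mats.append(_matrix_for_age(matrices, age, K))
    for year in range(start_year + window_length, estimation_year + 1):
        age += 1
        if q_fn is not None:
            survive *= 1.0 - float(q_fn(age, year))

    dist = np.zeros(K)
    for path in itertools.product(range(K), repeat=window_length):
        p = initial[path[0]]
        for step in range(1, window_length):
            p *= mats[step - 1][path[step - 1], path[step]]
        if p == 0.0:
            continue
        seq = np.asarray(path, dtype=np.int8)[None, :]
        k = int(assign_window_category(seq, rule, K)[0])
        dist[k] += p
    total = dist.sum()
    if total > 0:
        dist = dist / total
    return dist, float(survive)


def exact_cohort_results(population: pd.DataFrame, prevalence,
                         transitions, life_table: LifeTable | None,
                         config: SimulationConfig, rule: str = "max",
                         sexes: tuple[str, ...] = ("female", "male"),
                         n_categories: int = 6) -> pd.DataFrame:
    """Deterministic backend: exact per-cohort period prevalence.

    Mirrors the Monte-Carlo engine cohort by cohort, representing each
    (sex, 5-year age group) stratum by the band's midpoint age. Returns the
    same long layout as :func:`expowin.microsim.period_prevalence`, with
    ``alive_n`` carrying the expected survivor count.
    """
    from .microsim import _prevalence_lookup

    lookup = _prevalence_lookup(prevalence, n_categories)
    bank = matrix_bank(transitions, sexes, n_categories)
    L = config.window_end - config.window_start + 1
    rows = []
    pop = population[population["count"] > 0]
    total = pop["count"].sum()
    for row in pop.itertuples(index=False):
        s = sexes.index(row.sex)
        g = AGE_GROUPS_5Y.index(row.age_group)
        start_age = AGE_GROUP_LOWER[g] + 2
        q_fn = (None if life_table is None
                else lambda age, year, s=s: float(
                    life_table.q(s, age, year)))
        dist, alive = exact_period_prevalence(
            lookup(row.sex, row.age_group), bank[s], L,
            start_age=start_age, q_fn=q_fn,
            start_year=config.window_start,
            estimation_year=config.estimation_year, rule=rule)
        share = row.count / total
        for k in range(n_categories):
            rows.append({"sex": row.sex, "age_group": row.age_group,
                         "category": k, "proportion": dist[k],
                         "alive_n": alive * share * config.n})
    return pd.DataFrame(rows)
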