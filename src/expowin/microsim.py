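"""Monte-Carlo microsimulation of exposure over a time window (Model 3).

Step A initialises a synthetic cohort representative of the population's
sex x age structure and of the exposure prevalence at the window's first
year. Step B evolves it year by year: each individual's age increases by
one, survival is drawn against the life-table death probability q(sex, age,
year), and survivors are reassigned an exposure category by inverse-CDF
sampling from their transition-matrix row (the unit interval is split at
the cumulative row sums and compared with a uniform draw). Step C applies
mortality-only steps from the window's end to the estimation year; only
individuals alive then enter the period-prevalence denominator.

Period prevalence assigns each surviving individual a single category from
its sequence S_l of annual categories: the highest category experienced
(``max``, the headline rule), the highest category held for at least two
consecutive years (``max-2-consecutive``, falling back to ``max`` when no
category was), or the category in which most time was spent (``most-time``,
ties resolved toward the higher category). The occupational-turnover ratio
OT_k = period prevalence / point prevalence links the two scales
(point x OT = period).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categories import (
    AGE_GROUP_LOWER,
    AGE_GROUPS_5Y,
    MAX_AGE,
    MIN_AGE,
    SEXES,
    repair_proportions,
)
from .errors import ConfigurationError, InputError
from .transitions import MultinomialTransitionModel, TransitionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "LifeTable",
    "initialize_cohort",
    "step_transition",
    "step_mortality",
    "simulate_window",
    "censor_to_estimation_year",
    "period_prevalence",
    "PeriodPrevalenceResult",
    "occupational_turnover",
    "largest_remainder",
    "matrix_bank",
]

RULES = ("max", "max-2-consecutive", "most-time")

_BANK_AGE_LO, _BANK_AGE_HI = MIN_AGE, 121


@dataclass(frozen=True)
class SimulationConfig:
    """Window, estimation year, cohort size, assignment rule and seed."""

    window_start: int
    window_end: int
    estimation_year: int | None = None
    n: int = 200_000
    rule: str = "max"
    seed: int = 0
    mortality_first: bool = True   # within-year order: age, mortality, transition

    def __post_init__(self) -> None:
        est = self.estimation_year
        if est is None:
            object.__setattr__(self, "estimation_year", self.window_end)
            est = self.window_end
        if not self.window_start < self.window_end <= est:
            raise ConfigurationError(
                f"need window_start < window_end <= estimation_year, got "
                f"{self.window_start}, {self.window_end}, {est}")
        if self.n < 1:
            raise ConfigurationError("cohort size n must be >= 1")
        if self.rule not in RULES:
            raise ConfigurationError(f"rule must be one of {RULES}")

    @property
    def window_years(self) -> np.ndarray:
        return np.arange(self.window_start, self.window_end + 1)


# ---------------------------------------------------------------------------
# life table
# ---------------------------------------------------------------------------

class LifeTable:
    """Annual death probabilities q indexed by sex, single-year age, year.

    Ages outside the tabulated range are clamped to the nearest tabulated
    age (open-ended top band behaviour); a year outside the table raises an
    error naming the missing cell.
    """

    def __init__(self, q: np.ndarray, sexes: tuple[str, ...],
                 age_min: int, years: tuple[int, ...]):
        q = np.asarray(q, dtype=float)
        if q.ndim != 3:
            raise InputError("life-table array must be (sex, age, year)")
        if np.any((q < 0) | (q > 1)):
            raise InputError("life-table qx values must lie in [0, 1]")
        self._q = q
        self.sexes = tuple(sexes)
        self.age_min = int(age_min)
        self.years = tuple(int(y) for y in years)
        self._year_index = {y: i for i, y in enumerate(self.years)}

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   sexes: tuple[str, ...] = SEXES) -> "LifeTable":
        for col in ("sex", "age", "year", "qx"):
            if col not in df.columns:
                raise InputError(f"life table missing column '{col}'")
        bad = df[(df["qx"] < 0) | (df["qx"] > 1)]
        if len(bad):
            raise InputError(
                f"life-table qx outside [0, 1] at row(s) "
                f"{bad.index[:5].tolist()}")
        ages = np.arange(df["age"].min(), df["age"].max() + 1)
        years = tuple(sorted(df["year"].unique()))
        q = np.full((len(sexes), len(ages), len(years)), np.nan)
        for (sex, age, year), group in df.groupby(["sex", "age", "year"]):
            q[sexes.index(sex), int(age) - ages[0],
              years.index(int(year))] = group["qx"].iloc[-1]
        if np.isnan(q).any():
            logger.warning("life table has %d missing interior cells; "
                           "filling by nearest-age carry-forward",
                           int(np.isnan(q).sum()))
            for s in range(q.shape[0]):
                for t in range(q.shape[2]):
                    col = q[s, :, t]
                    if np.isnan(col).all():
                        raise InputError(
                            f"life table empty for sex={sexes[s]}, "
                            f"year={years[t]}")
                    idx = np.arange(len(col))
                    good = ~np.isnan(col)
                    q[s, :, t] = np.interp(idx, idx[good], col[good])
        return cls(q, sexes, int(ages[0]), years)

    @classmethod
    def from_function(cls, fn, sexes: tuple[str, ...] = SEXES,
                      ages: range = range(MIN_AGE, MAX_AGE + 1),
                      years: tuple[int, ...] = (0,)) -> "LifeTable":
        """Tabulate q(sex, age, year) from a callable."""
        q = np.empty((len(sexes), len(ages), len(years)))
        for s, sex in enumerate(sexes):
            for t, year in enumerate(years):
                q[s, :, t] = np.clip(
                    [fn(sex, a, year) for a in ages], 0.0, 1.0)
        return cls(q, sexes, ages.start, years)

    @classmethod
    def constant(cls, value: float, sexes: tuple[str, ...] = SEXES,
                 years: tuple[int, ...] = (0,)) -> "LifeTable":
        return cls.from_function(lambda *_: value, sexes=sexes, years=years)

    # -- lookup ---------------------------------------------------------
    def _year_ix(self, year: int) -> int:
        if year in self._year_index:
            return self._year_index[year]
        if len(self.years) == 1:
            return 0            # year-invariant table
        raise InputError(f"life table has no year {year} "
                         f"(available {self.years[0]}..{self.years[-1]})")

    def q(self, sex_idx: np.ndarray | int, age: np.ndarray | int,
          year: int) -> np.ndarray:
        t = self._year_ix(int(year))
        a = np.clip(np.asarray(age, dtype=int) - self.age_min, 0,
                    self._q.shape[1] - 1)
        return self._q[np.asarray(sex_idx, dtype=int), a, t]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, sex in enumerate(self.sexes):
            for t, year in enumerate(self.years):
                for a in range(self._q.shape[1]):
                    rows.append({"sex": sex, "age": self.age_min + a,
                                 "year": year, "qx": self._q[s, a, t]})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Arrays-of-attributes view of the simulated individuals."""

    sexes: tuple[str, ...]
    sex: np.ndarray                 # (n,) index into sexes
    age0: np.ndarray                # (n,) exact age at window start
    age_group: np.ndarray           # (n,) 5-year band label at window start
    categories: np.ndarray          # (n, L) category per window year
    alive: np.ndarray               # (n,) alive after last processed step
    death_year: np.ndarray          # (n,) year of death, -1 if alive
    start_year: int
    n_categories: int
    alive_at_estimation: np.ndarray | None = None
    _steps_done: int = 0            # window years already simulated

    @property
    def n(self) -> int:
        return self.sex.shape[0]

    @property
    def window_length(self) -> int:
        return self.categories.shape[1]

    def window_years(self) -> np.ndarray:
        return self.start_year + np.arange(self.window_length)

    def trajectories(self) -> pd.DataFrame:
        """Long-format per-individual trajectories (id, year, category, alive)."""
        n, L = self.categories.shape
        years = self.window_years()
        dy = self.death_year[:, None]
        alive = (dy < 0) | (years[None, :] < dy)
        return pd.DataFrame({
            "id": np.repeat(np.arange(n), L),
            "year": np.tile(years, n),
            "category": self.categories.ravel(),
            "alive": alive.ravel(),
        })


def largest_remainder(shares: np.ndarray, n: int) -> np.ndarray:
    """Integer allocation of n by largest remainder (ties to lower index)."""
    shares = np.asarray(shares, dtype=float)
    if shares.sum() <= 0:
        raise InputError("shares must have positive total")
    quota = shares / shares.sum() * n
    base = np.floor(quota).astype(int)
    short = n - base.sum()
    # stable sort => ties resolved toward the lower index
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return base


def _prevalence_lookup(prevalence, n_categories: int):
    """Normalise the Step-A prevalence input to a callable (sex, group)->K."""
    if callable(prevalence):
        return lambda sex, grp: repair_proportions(
            np.asarray(prevalence(sex, grp), dtype=float))
    df = prevalence
    table = {}
    for (sex, grp), cell in df.groupby(["sex", "age_group"]):
        vec = np.zeros(n_categories)
        vec[cell["category"].to_numpy(int)] = cell["proportion"].to_numpy()
        table[(sex, grp)] = repair_proportions(vec)
    def lookup(sex, grp):
        try:
            return table[(sex, grp)]
        except KeyError:
            raise InputError(f"no prevalence for cohort ({sex}, {grp})")
    return lookup


def initialize_cohort(population: pd.DataFrame, prevalence,
                      config: SimulationConfig, n_categories: int = 6,
                      sexes: tuple[str, ...] = SEXES) -> SyntheticCohort:
    """Step A: build a representative cohort at the window's first year.

    ``population`` has columns (sex, age_group, count); stratum sizes are
    allocated by largest-remainder rounding of the population shares to the
    configured cohort size. ``prevalence`` is a long table (sex, age_group,
    category, proportion) or a callable; initial categories are multinomial
    draws from it, and exact ages are uniform within the 5-year band.
    """
    for col in ("sex", "age_group", "count"):
        if col not in population.columns:
            raise InputError(f"population table missing column '{col}'")
    pop = population[population["count"] > 0]
    if pop.empty or pop["count"].sum() <= 0:
        raise InputError("population counts are all zero")
    lookup = _prevalence_lookup(prevalence, n_categories)

    sizes = largest_remainder(pop["count"].to_numpy(float), config.n)
    rng = np.random.default_rng([config.seed, 0])
    L = config.window_end - config.window_start + 1

    sex_arr = np.empty(config.n, dtype=np.int8)
    age_arr = np.empty(config.n, dtype=float)
    grp_arr = np.empty(config.n, dtype=object)
    cat0 = np.empty(config.n, dtype=np.int8)

    pos = 0
    for (row, size) in zip(pop.itertuples(index=False), sizes):
        if size == 0:
            continue
        sl = slice(pos, pos + size)
        s = sexes.index(row.sex)
        g = AGE_GROUPS_5Y.index(row.age_group)
        lo = AGE_GROUP_LOWER[g]
        sex_arr[sl] = s
        grp_arr[sl] = row.age_group
        age_arr[sl] = rng.uniform(lo, lo + 5, size=size)
        cat0[sl] = rng.choice(n_categories, size=size,
                              p=lookup(row.sex, row.age_group))
        pos += size

    categories = np.zeros((config.n, L), dtype=np.int8)
    categories[:, 0] = cat0
    return SyntheticCohort(
        sexes=sexes, sex=sex_arr, age0=age_arr, age_group=grp_arr,
        categories=categories, alive=np.ones(config.n, dtype=bool),
        death_year=np.full(config.n, -1, dtype=np.int32),
        start_year=config.window_start, n_categories=n_categories)


# ---------------------------------------------------------------------------
# elementary steps (scalar contracts; the engine uses vectorised forms)
# ---------------------------------------------------------------------------

def step_transition(category: int, row: np.ndarray, u: float) -> int:
    """Inverse-CDF draw: smallest k with u < sum_{j<=k} row_j."""
    row = np.asarray(row, dtype=float)
    if np.any(row < 0) or abs(row.sum() - 1.0) > 1e-9:
        raise InputError("transition row is not a valid distribution")
    if not 0.0 <= u < 1.0:
        raise InputError("u must lie in [0, 1)")
    return int(min(np.searchsorted(np.cumsum(row), u, side="right"),
                   len(row) - 1))


def step_mortality(sex: str, age: int, year: int, life_table: LifeTable,
                   u: float) -> bool:
    """True (alive) unless u falls below q(sex, age, year)."""
    q = float(life_table.q(life_table.sexes.index(sex), age, year))
    return not (u < q)


def _draw_next(rows: np.ndarray, u: np.ndarray) -> np.ndarray:
    cum = np.cumsum(rows, axis=1)
    nxt = (u[:, None] >= cum).sum(axis=1)
    return np.minimum(nxt, rows.shape[1] - 1)


def matrix_bank(transitions, sexes: tuple[str, ...] = SEXES,
                n_categories: int = 6) -> np.ndarray:
    """Normalise any transition input to an array (n_sex, n_age, K, K).

    Accepts a single :class:`TransitionMatrix` (applied to every sex and
    age), a dict sex -> TransitionMatrix, a fitted
    :class:`MultinomialTransitionModel` (evaluated at every integer age),
    or an already-banked array.
    """
    ages = np.arange(_BANK_AGE_LO, _BANK_AGE_HI + 1)
    A = len(ages)
    if isinstance(transitions, np.ndarray):
        if transitions.shape[-1] != n_categories:
            raise InputError("banked transition array has wrong K")
        return transitions
    bank = np.empty((len(sexes), A, n_categories, n_categories))
    if isinstance(transitions, TransitionMatrix):
        bank[...] = transitions.probs
    elif isinstance(transitions, dict):
        for s, sex in enumerate(sexes):
            bank[s, ...] = transitions[sex].probs
    elif isinstance(transitions, MultinomialTransitionModel):
        for s, sex in enumerate(sexes):
            bank[s] = transitions.predict_matrices(sex, ages)
    else:
        raise InputError(f"unsupported transition input "
                         f"{type(transitions).__name__}")
    return bank


def _bank_row_ix(age: np.ndarray) -> np.ndarray:
    return np.clip(age - _BANK_AGE_LO, 0, _BANK_AGE_HI - _BANK_AGE_LO)


def simulate_window(cohort: SyntheticCohort, transitions,
                    life_table: LifeTable | None,
                    config: SimulationConfig) -> SyntheticCohort:
    """Step B: evolve the cohort over the window (in place; returns it).

    Per simulated year, in order: ages increase by one; mortality is drawn
    (unless ``mortality_first`` is False, in which case the exposure
    transition precedes it); survivors transition between categories. Dead
    individuals keep their last category (absorbing). Uniform draws are
    made for every individual each year from a generator derived from the
    master seed, so trajectories do not depend on iteration order.
    """
    bank = matrix_bank(transitions, cohort.sexes, cohort.n_categories)
    rng = np.random.default_rng([config.seed, 1])
    n = cohort.n
    age = cohort.age0.copy()
    for t, year in enumerate(range(config.window_start + 1,
                                   config.window_end + 1), start=1):
        age += 1.0
        iage = age.astype(int)
        u_mort = rng.random(n)
        u_trans = rng.random(n)

        def do_mortality():
            if life_table is None:
                return
            q = life_table.q(cohort.sex, iage, year)
            dying = cohort.alive & (u_mort < q)
            cohort.alive[dying] = False
            cohort.death_year[dying] = year

        def do_transition():
            cur = cohort.categories[:, t - 1]
            rows = bank[cohort.sex, _bank_row_ix(iage), cur]
            nxt = _draw_next(rows, u_trans)
            cohort.categories[:, t] = np.where(cohort.alive, nxt, cur)

        if config.mortality_first:
            do_mortality()
            do_transition()
        else:
            do_transition()
            do_mortality()
        cohort._steps_done = t
    return cohort


def censor_to_estimation_year(cohort: SyntheticCohort,
                              life_table: LifeTable | None,
                              estimation_year: int,
                              config: SimulationConfig) -> SyntheticCohort:
    """Step C: mortality-only years up to the estimation year.

    Exposure sequences are frozen; only the alive flag evolves. Sets
    ``alive_at_estimation``.
    """
    last_year = cohort.start_year + cohort.window_length - 1
    if estimation_year < last_year:
        raise ConfigurationError("estimation year precedes the window end")
    rng = np.random.default_rng([config.seed, 2])
    age = cohort.age0 + (cohort.window_length - 1)
    for year in range(last_year + 1, estimation_year + 1):
        age += 1.0
        u = rng.random(cohort.n)
        if life_table is not None:
            q = life_table.q(cohort.sex, age.astype(int), year)
            dying = cohort.alive & (u < q)
            cohort.alive[dying] = False
            cohort.death_year[dying] = year
    cohort.alive_at_estimation = cohort.alive.copy()
    return cohort


# ---------------------------------------------------------------------------
# period prevalence and turnover
# ---------------------------------------------------------------------------

@dataclass
class PeriodPrevalenceResult:
    """Per-cohort proportions over the window among survivors."""

    cohort_key: tuple
    proportions: np.ndarray
    alive_n: int
    ot: np.ndarray | None = None
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None


def assign_window_category(categories: np.ndarray, rule: str,
                           n_categories: int) -> np.ndarray:
    """Collapse each sequence S_l to a single category under a rule."""
    if rule == "max":
        return categories.max(axis=1)
    if rule == "most-time":
        counts = np.stack([(categories == k).sum(axis=1)
                           for k in range(n_categories)], axis=1)
        # argmax over reversed order so ties resolve to the higher category
        return n_categories - 1 - np.argmax(counts[:, ::-1], axis=1)
    if rule == "max-2-consecutive":
        held = np.zeros((categories.shape[0], n_categories), dtype=bool)
        same = categories[:, 1:] == categories[:, :-1]
        for k in range(n_categories):
            held[:, k] = (same & (categories[:, 1:] == k)).any(axis=1)
        best = np.where(held.any(axis=1),
                        n_categories - 1 - np.argmax(held[:, ::-1], axis=1),
                        categories.max(axis=1))   # fallback: max rule
        return best
    raise ConfigurationError(f"unknown rule '{rule}'")


def period_prevalence(cohort: SyntheticCohort, rule: str = "max",
                      by: tuple[str, ...] | None = ("sex", "age_group")
                      ) -> pd.DataFrame:
    """Period prevalence per cohort key among individuals alive at year_a.

    Returns long format (key columns, category, proportion, alive_n);
    cohorts with zero survivors are reported with NaN proportions and
    alive_n 0. ``by=None`` aggregates over the whole population.
    """
    alive = (cohort.alive_at_estimation if cohort.alive_at_estimation
             is not None else cohort.alive)
    assigned = assign_window_category(cohort.categories, rule,
                                      cohort.n_categories)
    sex_labels = np.asarray(cohort.sexes)[cohort.sex]
    df = pd.DataFrame({"sex": sex_labels, "age_group": cohort.age_group,
                       "assigned": assigned, "alive": alive})
    keys = list(by) if by else []
    rows = []
    groups = df.groupby(keys, sort=True) if keys else [((), df)]
    for key, group in groups:
        key = key if isinstance(key, tuple) else (key,)
        surv = group[group["alive"]]
        n_alive = len(surv)
        if n_alive == 0:
            props = np.full(cohort.n_categories, np.nan)
        else:
            props = (np.bincount(surv["assigned"],
                                 minlength=cohort.n_categories) / n_alive)
        for k in range(cohort.n_categories):
            rows.append(dict(zip(keys, key))
                        | {"category": k, "proportion": props[k],
                           "alive_n": n_alive})
    return pd.DataFrame(rows)


def point_prevalence(cohort: SyntheticCohort, year: int,
                     by: tuple[str, ...] | None = ("sex", "age_group")
                     ) -> pd.DataFrame:
    """Single-year category shares among survivors, from the sequences."""
    t = year - cohort.start_year
    if not 0 <= t < cohort.window_length:
        raise InputError(f"year {year} outside the recorded window")
    alive = (cohort.alive_at_estimation if cohort.alive_at_estimation
             is not None else cohort.alive)
    sex_labels = np.asarray(cohort.sexes)[cohort.sex]
    df = pd.DataFrame({"sex": sex_labels, "age_group": cohort.age_group,
                       "assigned": cohort.categories[:, t], "alive": alive})
    keys = list(by) if by else []
    rows = []
    groups = df.groupby(keys, sort=True) if keys else [((), df)]
    for key, group in groups:
        key = key if isinstance(key, tuple) else (key,)
        surv = group[group["alive"]]
        n_alive = len(surv)
        props = (np.bincount(surv["assigned"],
                             minlength=cohort.n_categories) / n_alive
                 if n_alive else np.full(cohort.n_categories, np.nan))
        for k in range(cohort.n_categories):
            rows.append(dict(zip(keys, key))
                        | {"category": k, "proportion": props[k],
                           "alive_n": n_alive})
    return pd.DataFrame(rows)


def occupational_turnover(period: pd.DataFrame | np.ndarray,
                          point: pd.DataFrame | np.ndarray):
    """OT_k = period prevalence / point prevalence, per category.

    Oriented so that point x OT = period. Categories with zero (or
    missing) point prevalence are undefined (NaN). Accepts aligned arrays
    or the long-format frames produced by :func:`period_prevalence` /
    :func:`point_prevalence` (joined on their shared key columns).
    """
    if isinstance(period, np.ndarray) or isinstance(period, (list, tuple)):
        period = np.asarray(period, dtype=float)
        point = np.asarray(point, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ot = np.where(point > 0, period / point, np.nan)
        return ot
    keys = [c for c in period.columns
            if c in point.columns and c not in ("proportion", "alive_n")]
    merged = period.merge(point, on=keys, suffixes=("_period", "_point"))
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["ot"] = np.where(
            merged["proportion_point"] > 0,
            merged["proportion_period"] / merged["proportion_point"], np.nan)
    return merged[keys + ["ot"]]
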