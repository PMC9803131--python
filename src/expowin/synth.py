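"""Synthetic truth worlds and survey-like samples.

Every statistical module in the package is exercised against fully known
"truth" worlds: a linear-in-year prevalence surface per (country, sex,
age-group, category), a smooth age-dependent transition structure (a
per-origin multinomial logit in age and age squared with an additive sex
shift), a Gompertz life table, and a population structure. The samplers
emulate a rotating-panel labour-force survey: repeated cross-sections and
two-wave household records carrying the quasi-identifiers used for
pseudo-longitudinal matching (household number, household sequence number,
sex, year of birth), with configurable attrition and key collisions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categories import (
    AGE_GROUP_LOWER,
    AGE_GROUPS_5Y,
    SEXES,
    WORKING_HOURS_BANDS,
    age_group_of,
)
from .errors import ConfigurationError, InputError

__all__ = [
    "TruthConfig",
    "TruthWorld",
    "make_truth",
    "sample_cross_sections",
    "sample_rotating_panel",
    "export_fixtures",
]


@dataclass(frozen=True)
class TruthConfig:
    """Generator settings for a truth world.

    Prevalence slopes are drawn uniformly in ``(-slope_scale, +slope_scale)``
    per category and centred to sum to zero within each cell, then shrunk so
    the truth stays inside [margin, 1-margin] over the whole year range.
    Mortality is Gompertz, q(age) = min(1, a * exp(b * age)), with
    sex-specific level ``gompertz_a`` and an optional multiplicative
    per-calendar-year factor.
    """

    n_categories: int = 6
    countries: tuple[str, ...] = ("Italia",)
    sexes: tuple[str, ...] = SEXES
    age_groups: tuple[str, ...] = AGE_GROUPS_5Y
    years: tuple[int, ...] = tuple(range(1992, 2012))
    seed: int = 0
    slope_scale: float = 0.004
    prevalence_margin: float = 0.005
    dirichlet_alpha: tuple[float, ...] | None = None
    transition_diag_bonus: float = 1.6
    transition_coef_scale: float = 0.8
    gompertz_a: tuple[float, ...] = (3.1e-5, 4.7e-5)  # female, male
    gompertz_b: float = 0.085
    mortality_year_factor: float = 1.0

    def validate(self) -> None:
        if self.n_categories < 2:
            raise ConfigurationError("n_categories must be >= 2")
        if not self.countries:
            raise ConfigurationError("countries must be non-empty")
        if not self.years:
            raise ConfigurationError("years must be non-empty")
        if not self.sexes:
            raise ConfigurationError("sexes must be non-empty")
        if not self.age_groups:
            raise ConfigurationError("age_groups must be non-empty")
        if self.seed is None:
            raise ConfigurationError("seed must be given")


def _category_labels(k: int) -> tuple[str, ...]:
    if k == len(WORKING_HOURS_BANDS):
        return WORKING_HOURS_BANDS
    return tuple(f"cat{i}" for i in range(k))


@dataclass
class TruthWorld:
    """A fully specified generative world.

    Attributes
    ----------
    intercepts, slopes : ndarray, shape (C, S, G, K)
        Linear-in-year prevalence coefficients per country, sex, age group
        and category; year is measured from ``years[0]``.
    transition_coef : ndarray, shape (K, K, 4)
        Per-origin logit coefficients for each destination, in the basis
        (1, male, a, a^2) with a = (age - 45) / 30; destination 0 is the
        pivot (all-zero row).
    population : ndarray, shape (S, G)
        Counts by sex and age group at the first year of the window.
    """

    config: TruthConfig
    category_labels: tuple[str, ...]
    intercepts: np.ndarray
    slopes: np.ndarray
    transition_coef: np.ndarray
    population: np.ndarray

    # -- coordinate helpers -------------------------------------------------
    @property
    def n_categories(self) -> int:
        return self.config.n_categories

    @property
    def years(self) -> tuple[int, ...]:
        return self.config.years

    def _cix(self, country: str) -> int:
        return self.config.countries.index(country)

    def _six(self, sex: str) -> int:
        return self.config.sexes.index(sex)

    def _gix(self, age_group: str) -> int:
        return self.config.age_groups.index(age_group)

    # -- truth surfaces -----------------------------------------------------
    def prevalence(self, country: str, sex: str, age_group: str,
                   year: int) -> np.ndarray:
        """Truth prevalence vector (sums to 1) for one cell and year."""
        if year not in self.config.years:
            raise InputError(f"year {year} outside truth range "
                             f"{self.config.years[0]}..{self.config.years[-1]}")
        dy = year - self.config.years[0]
        p = (self.intercepts[self._cix(country), self._six(sex),
                             self._gix(age_group)]
             + dy * self.slopes[self._cix(country), self._six(sex),
                                self._gix(age_group)])
        return p

    def transition_matrix(self, sex: str, age: float) -> np.ndarray:
        """Row-stochastic K x K truth matrix at an exact age."""
        return self.transition_matrices(sex, np.asarray([age]))[0]

    def transition_matrices(self, sex: str, ages: np.ndarray) -> np.ndarray:
        """Vectorised truth matrices, shape (len(ages), K, K)."""
        ages = np.asarray(ages, dtype=float)
        male = 1.0 if sex == "male" else 0.0
        a = (ages - 45.0) / 30.0
        x = np.stack([np.ones_like(a), np.full_like(a, male), a, a * a],
                     axis=-1)                      # (n, 4)
        logits = np.einsum("np,kjp->nkj", x, self.transition_coef)
        logits -= logits.max(axis=2, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=2, keepdims=True)

    def qx(self, sex: str, age: float | np.ndarray,
           year: int | np.ndarray) -> np.ndarray:
        a = self.config.gompertz_a[self._six(sex)]
        b = self.config.gompertz_b
        age = np.asarray(age, dtype=float)
        year = np.asarray(year)
        fac = self.config.mortality_year_factor ** (year - self.config.years[0])
        return np.minimum(1.0, a * np.exp(b * age) * fac)

    # -- tabular views ------------------------------------------------------
    def population_table(self) -> pd.DataFrame:
        rows = [
            {"sex": sex, "age_group": grp,
             "count": float(self.population[s, g])}
            for s, sex in enumerate(self.config.sexes)
            for g, grp in enumerate(self.config.age_groups)
        ]
        return pd.DataFrame(rows)

    def life_table(self, ages: range = range(15, 111),
                   years: tuple[int, ...] | None = None) -> pd.DataFrame:
        if years is None:
            # cover a post-window censoring horizon beyond the truth years
            years = tuple(range(self.config.years[0],
                                self.config.years[-1] + 11))
        rows = []
        for sex in self.config.sexes:
            for year in years:
                q = self.qx(sex, np.asarray(list(ages), float), year)
                for a, qa in zip(ages, q):
                    rows.append({"sex": sex, "age": a, "year": year,
                                 "qx": float(qa)})
        return pd.DataFrame(rows)

    def proportion_table(self, years: tuple[int, ...] | None = None
                         ) -> pd.DataFrame:
        """Exact (noise-free) cell-level proportions, Model-1 ready."""
        years = years if years is not None else self.config.years
        rows = []
        for country in self.config.countries:
            for sex in self.config.sexes:
                for grp in self.config.age_groups:
                    for year in years:
                        p = self.prevalence(country, sex, grp, year)
                        for k in range(self.n_categories):
                            rows.append({
                                "country": country, "sex": sex,
                                "age_group": grp, "year": year,
                                "category": k, "proportion": p[k],
                                "weight_total": 1.0,
                            })
        return pd.DataFrame(rows)


def make_truth(config: TruthConfig | None = None, **overrides) -> TruthWorld:
    """Build a deterministic truth world from a config (and/or overrides)."""
    config = dataclasses.replace(config or TruthConfig(), **overrides)
    config.validate()
    rng = np.random.default_rng(config.seed)
    C, S, G, K = (len(config.countries), len(config.sexes),
                  len(config.age_groups), config.n_categories)

    alpha = config.dirichlet_alpha
    if alpha is None:
        # inactive-heavy, tapering toward the long-hours bands
        base = np.array([10.0, 5.0, 6.0, 3.0, 1.5, 1.0])
        alpha = tuple(base[:K]) if K <= 6 else tuple(
            np.r_[base, np.full(K - 6, 1.0)])
    intercepts = rng.dirichlet(np.asarray(alpha), size=(C, S, G))

    slopes = rng.uniform(-config.slope_scale, config.slope_scale,
                         size=(C, S, G, K))
    slopes -= slopes.mean(axis=3, keepdims=True)   # rows keep summing to 1
    span = config.years[-1] - config.years[0]
    if span > 0:
        # shrink slopes so every truth prevalence stays in [margin, 1-margin]
        lo = intercepts + np.minimum(0.0, slopes * span)
        hi = intercepts + np.maximum(0.0, slopes * span)
        m = config.prevalence_margin
        with np.errstate(divide="ignore", invalid="ignore"):
            shrink_lo = np.where(lo < m, (intercepts - m)
                                 / np.maximum(1e-12, intercepts - lo), 1.0)
            shrink_hi = np.where(hi > 1 - m, (1 - m - intercepts)
                                 / np.maximum(1e-12, hi - intercepts), 1.0)
        shrink = np.clip(np.minimum(shrink_lo, shrink_hi), 0.0, 1.0)
        slopes *= shrink.min(axis=3, keepdims=True)

    coef = rng.uniform(-1.0, 1.0, size=(K, K, 4))
    coef[:, :, 1] *= 0.5 * config.transition_coef_scale   # sex shift
    coef[:, :, 2] *= config.transition_coef_scale         # age
    coef[:, :, 3] *= 0.6 * config.transition_coef_scale   # age^2
    for h in range(K):
        coef[h, h, 0] += config.transition_diag_bonus     # stayers dominate
        coef[h, 0, :] = 0.0                               # pivot destination

    # smooth, Italy-like population pyramid (deterministic given the seed
    # only through the mild jitter below)
    mid = np.asarray(AGE_GROUP_LOWER[:G], dtype=float) + 2.0
    shape = np.exp(-np.clip(mid - 55.0, 0.0, None) ** 2 / (2 * 18.0 ** 2))
    base = 1.8e6 * shape
    jitter = rng.uniform(0.95, 1.05, size=(S, G))
    population = np.maximum(1.0, base[None, :] * jitter).round()

    return TruthWorld(
        config=config,
        category_labels=_category_labels(K),
        intercepts=intercepts,
        slopes=slopes,
        transition_coef=coef,
        population=population,
    )


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def sample_cross_sections(truth: TruthWorld, n_per_cell: int,
                          years: list[int] | tuple[int, ...],
                          seed: int | None = None) -> pd.DataFrame:
    """Draw survey records (year, country, sex, age_group, category, weight).

    Categories are drawn multinomially from the truth prevalence of each
    (country, sex, age-group, year) cell; weights are the cell population
    divided by the per-cell sample size, so weighted totals reproduce the
    population scale.
    """
    if n_per_cell < 1:
        raise ConfigurationError("n_per_cell must be >= 1")
    for y in years:
        if y not in truth.config.years:
            raise InputError(f"year {y} outside truth range")
    rng = np.random.default_rng(truth.config.seed + 1 if seed is None
                                else seed)
    frames = []
    K = truth.n_categories
    for country in truth.config.countries:
        for s, sex in enumerate(truth.config.sexes):
            for g, grp in enumerate(truth.config.age_groups):
                w = truth.population[s, g] / n_per_cell
                for year in years:
                    p = truth.prevalence(country, sex, grp, year)
                    counts = rng.multinomial(n_per_cell, p)
                    cats = np.repeat(np.arange(K), counts)
                    frames.append(pd.DataFrame({
                        "year": year, "country": country, "sex": sex,
                        "age_group": grp, "category": cats,
                        "weight": w,
                    }))
    return pd.concat(frames, ignore_index=True)


def sample_rotating_panel(truth: TruthWorld, n_households: int,
                          year_pair: tuple[int, int], seed: int | None = None,
                          attrition: float = 0.1, collision_fraction: float = 0.0,
                          max_household_size: int = 3,
                          country: str | None = None,
                          origin_distribution: str = "prevalence",
                          age_range: tuple[float, float] = (16.0, 85.0)
                          ) -> pd.DataFrame:
    """Two-wave raw records for the pseudo-longitudinal matcher.

    Each individual carries the four quasi-identifiers (hh_id, seq, sex,
    birth_year). Wave-1 categories are drawn from the truth prevalence at
    the individual's age; wave-2 categories from the truth transition row of
    the wave-1 category at that age. A fraction ``attrition`` of individuals
    is absent from wave 2; a fraction ``collision_fraction`` of individuals
    is duplicated under the same key tuple (ambiguous records the matcher
    must discard).

    ``origin_distribution`` controls the wave-1 categories: "prevalence"
    (survey-like) draws them from the truth prevalence at the individual's
    age, "uniform" allocates them evenly — the design of choice for
    transition-recovery experiments, where rare origin categories would
    otherwise dominate the estimation error.
    """
    if n_households < 1:
        raise ConfigurationError("n_households must be >= 1")
    t0, t1 = year_pair
    if t1 != t0 + 1:
        raise InputError(f"year pair ({t0}, {t1}) is not consecutive")
    if t0 not in truth.config.years:
        raise InputError(f"year {t0} outside truth range")
    country = country or truth.config.countries[0]
    rng = np.random.default_rng(truth.config.seed + 2 if seed is None
                                else seed)

    sizes = rng.integers(1, max_household_size + 1, size=n_households)
    n = int(sizes.sum())
    hh_id = np.repeat(np.arange(n_households), sizes)
    seq = np.concatenate([np.arange(1, s + 1) for s in sizes])
    sex_idx = rng.integers(0, len(truth.config.sexes), size=n)
    ages = rng.uniform(age_range[0], age_range[1], size=n)
    birth_year = t0 - ages.astype(int)
    weight = np.ones(n)

    groups = age_group_of(ages)
    cat1 = np.empty(n, dtype=int)
    if origin_distribution == "uniform":
        cat1[:] = rng.integers(0, truth.n_categories, size=n)
    elif origin_distribution == "prevalence":
        for s, sex in enumerate(truth.config.sexes):
            for grp in truth.config.age_groups:
                m = (sex_idx == s) & (groups == grp)
                if not m.any():
                    continue
                p = truth.prevalence(country, sex, grp, t0)
                cat1[m] = rng.choice(truth.n_categories, size=m.sum(), p=p)
    else:
        raise ConfigurationError(
            "origin_distribution must be 'prevalence' or 'uniform'")

    cat2 = np.empty(n, dtype=int)
    for s, sex in enumerate(truth.config.sexes):
        m = sex_idx == s
        if not m.any():
            continue
        mats = truth.transition_matrices(sex, ages[m])
        rows = mats[np.arange(m.sum()), cat1[m]]
        u = rng.random(m.sum())
        cat2[m] = np.minimum((u[:, None] >= rows.cumsum(axis=1)).sum(axis=1),
                             truth.n_categories - 1)

    attrited = rng.random(n) < attrition
    collided = rng.random(n) < collision_fraction

    sex_lab = np.asarray(truth.config.sexes)[sex_idx]

    def wave(year, cats, keep):
        return pd.DataFrame({
            "hh_id": hh_id[keep], "seq": seq[keep], "sex": sex_lab[keep],
            "birth_year": birth_year[keep], "year": year,
            "category": cats[keep], "weight": weight[keep],
        })

    keep1 = np.ones(n, dtype=bool)
    keep2 = ~attrited
    w1, w2 = wave(t0, cat1, keep1), wave(t1, cat2, keep2)

    if collided.any():
        # duplicate keys with independently drawn categories in both waves
        dup = np.flatnonzero(collided)
        dup_cat1 = rng.integers(0, truth.n_categories, size=dup.size)
        dup_cat2 = rng.integers(0, truth.n_categories, size=dup.size)
        d1 = pd.DataFrame({
            "hh_id": hh_id[dup], "seq": seq[dup], "sex": sex_lab[dup],
            "birth_year": birth_year[dup], "year": t0, "category": dup_cat1,
            "weight": weight[dup]})
        d2 = d1.assign(year=t1, category=dup_cat2)
        w1 = pd.concat([w1, d1], ignore_index=True)
        w2 = pd.concat([w2, d2], ignore_index=True)

    out = pd.concat([w1, w2], ignore_index=True)
    out.attrs["n_individuals"] = n
    out.attrs["n_attrited"] = int(attrited.sum())
    out.attrs["n_collided"] = int(collided.sum())
    out.attrs["n_unambiguous_pairs"] = int((~attrited & ~collided).sum())
    return out


def export_fixtures(truth: TruthWorld, out_dir, n_per_cell: int = 200,
                    years: tuple[int, ...] | None = None,
                    panel_households: int = 2000,
                    panel_year_pair: tuple[int, int] | None = None,
                    **panel_kwargs) -> dict[str, str]:
    """Write population, life-table, cross-section and panel CSVs."""
    from . import io as eio  # local import: io depends on nothing here

    from pathlib import Path

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise InputError(f"cannot create output directory {out}: {exc}")

    years = years if years is not None else truth.config.years
    if panel_year_pair is None:
        panel_year_pair = (truth.config.years[-2], truth.config.years[-1])

    paths = {
        "population": out / "population.csv",
        "life_table": out / "life_table.csv",
        "cross_sections": out / "cross_sections.csv",
        "panel": out / "panel.csv",
    }
    eio.write_population(truth.population_table(), paths["population"])
    eio.write_life_table(truth.life_table(), paths["life_table"])
    eio.write_cross_sections(
        sample_cross_sections(truth, n_per_cell, list(years)),
        paths["cross_sections"])
    eio.write_panel(
        sample_rotating_panel(truth, panel_households, panel_year_pair,
                              **panel_kwargs),
        paths["panel"])
    return {k: str(v) for k, v in paths.items()}
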