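"""Exposure prevalence at the first year of the time window (Model 1).

Cell-level category proportions, observed over many survey years, are
modelled linearly in calendar year:

    proportion_i = A_i(sex, age, country) + B_i(sex, age, country) * year

one regression per exposure category, residuals assumed normal (the model
is deliberately linear on the proportion scale, not a logit model). With
several countries the intercept and year slope carry random effects nested
in country, fitted with ``statsmodels`` MixedLM; with a single country the
model collapses to per-(sex, age-group) weighted least squares of the
proportion on centred year.

Because the K categories are fitted independently, raw predictions need not
form a distribution: predictions are clamped to [0, 1] and renormalised,
and both the raw and repaired vectors are kept on the estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .categories import repair_proportions
from .errors import FittingError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "aggregate_proportions",
    "PrevalenceTrendModel",
    "PrevalenceEstimate",
    "fit_prevalence_model",
    "predict_prevalence",
]

_CELL = ["country", "sex", "age_group"]


def aggregate_proportions(records: pd.DataFrame,
                          n_categories: int | None = None) -> pd.DataFrame:
    """Weighted category proportions per (country, sex, age_group, year).

    Cells whose total weight is zero are excluded with a logged warning.
    The output is long format with every category 0..K-1 present (zero
    proportions included) and a ``weight_total`` column usable as a fitting
    weight.
    """
    required = {"year", "country", "sex", "age_group", "category", "weight"}
    missing = required - set(records.columns)
    if missing:
        raise InputError(f"survey records missing columns: {sorted(missing)}")
    if (records["weight"] < 0).any():
        raise InputError("survey weights must be non-negative")
    K = int(n_categories if n_categories is not None
            else records["category"].max() + 1)

    keys = _CELL + ["year"]
    totals = records.groupby(keys, sort=True)["weight"].sum()
    zero = totals[totals <= 0]
    if len(zero):
        logger.warning("excluding %d zero-weight cells from proportions",
                       len(zero))
        totals = totals[totals > 0]

    by_cat = (records.groupby(keys + ["category"], sort=True)["weight"]
              .sum().unstack("category", fill_value=0.0)
              .reindex(columns=range(K), fill_value=0.0))
    by_cat = by_cat.loc[totals.index]
    props = by_cat.div(totals, axis=0)

    out = props.stack().rename("proportion").reset_index()
    out = out.merge(totals.rename("weight_total").reset_index(), on=keys)
    return out


@dataclass
class PrevalenceEstimate:
    """Category proportions for one cohort, one country, one year."""

    country: str
    sex: str
    age_group: str
    year: int
    raw: np.ndarray
    proportions: np.ndarray
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    def __post_init__(self) -> None:
        s = float(np.sum(self.proportions))
        if abs(s - 1.0) > 1e-9:
            raise InputError(f"proportions sum to {s}, expected 1")


class PrevalenceTrendModel(BaseEstimator):
    """Per-category linear-in-year model of cell prevalences.

    Parameters
    ----------
    n_categories : int
        Number of exposure categories K.
    year_origin : int or None
        Year at which the intercept A is defined; defaults to the first
        training year (the window's first year in the intended use).
    weighted : bool
        Weight cells by their survey-weight totals in the single-country
        WLS path.
    random_structure : {"slope", "intercept"}
        Multi-country path: random intercept + year slope per country
        ("slope", default) or random intercept only ("intercept").
    extrapolation_horizon : float
        Years beyond the training range after which predictions trigger a
        warning (they are still returned).

    Attributes
    ----------
    coef_ : DataFrame indexed by (category, country, sex, age_group) with
        columns A, B, se_A, se_B.
    resid_var_ : dict category -> residual variance.
    year_origin_, years_ : centring origin and training years.
    """

    def __init__(self, n_categories: int = 6, year_origin: int | None = None,
                 weighted: bool = True, random_structure: str = "slope",
                 extrapolation_horizon: float = 10.0):
        self.n_categories = n_categories
        self.year_origin = year_origin
        self.weighted = weighted
        self.random_structure = random_structure
        self.extrapolation_horizon = extrapolation_horizon

    # ------------------------------------------------------------------
    def fit(self, proportions: pd.DataFrame, y=None) -> "PrevalenceTrendModel":
        required = set(_CELL + ["year", "category", "proportion"])
        missing = required - set(proportions.columns)
        if missing:
            raise InputError(f"proportion table missing columns: "
                             f"{sorted(missing)}")
        years = np.sort(proportions["year"].unique())
        if len(years) < 2:
            raise FittingError(
                "only one distinct survey year: the year slope B is "
                "unidentifiable; provide at least two years")
        self.years_ = years
        self.year_origin_ = int(self.year_origin if self.year_origin
                                is not None else years.min())
        self.countries_ = sorted(proportions["country"].unique())

        df = proportions.copy()
        df["year_c"] = df["year"] - self.year_origin_
        if "weight_total" not in df.columns or not self.weighted:
            df["weight_total"] = 1.0

        rows: list[dict] = []
        self.resid_var_ = {}
        for k in range(self.n_categories):
            sub = df[df["category"] == k]
            if sub.empty:
                continue
            if len(self.countries_) == 1:
                rows_k, rv = self._fit_single_country(sub, k)
            else:
                rows_k, rv = self._fit_multi_country(sub, k)
            rows.extend(rows_k)
            self.resid_var_[k] = rv

        self.coef_ = (pd.DataFrame(rows)
                      .set_index(["category"] + _CELL)
                      .sort_index())
        return self

    def _fit_single_country(self, sub: pd.DataFrame, k: int):
        """Per-(sex, age-group) WLS of proportion on centred year."""
        import statsmodels.api as sm

        rows, resids, nobs = [], [], 0
        country = self.countries_[0]
        for (sex, grp), cell in sub.groupby(["sex", "age_group"], sort=True):
            X = sm.add_constant(cell["year_c"].to_numpy(float))
            res = sm.WLS(cell["proportion"].to_numpy(float), X,
                         weights=cell["weight_total"].to_numpy(float)).fit()
            a, b = res.params
            se = res.bse if res.df_resid > 0 else np.array([np.nan, np.nan])
            rows.append({"category": k, "country": country, "sex": sex,
                         "age_group": grp, "A": a, "B": b,
                         "se_A": se[0], "se_B": se[1]})
            resids.append(res.resid)
            nobs += len(cell)
        resid = np.concatenate(resids) if resids else np.zeros(0)
        dof = max(1, nobs - 2 * len(rows))
        return rows, float(resid @ resid / dof)

    def _fit_multi_country(self, sub: pd.DataFrame, k: int):
        """MixedLM: full sex x age-group fixed trend, country random effects."""
        import statsmodels.formula.api as smf

        re_formula = "~year_c" if self.random_structure == "slope" else "~1"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "proportion ~ C(sex) * C(age_group) * year_c",
                data=sub, groups=sub["country"], re_formula=re_formula)
            res = model.fit(method=["lbfgs"], maxiter=200)
        rows = []
        cells = sub[["sex", "age_group"]].drop_duplicates()
        for _, cell in cells.iterrows():
            grid = pd.DataFrame({"sex": cell["sex"],
                                 "age_group": cell["age_group"],
                                 "year_c": [0.0, 1.0]})
            fe = res.predict(grid).to_numpy()
            for country in self.countries_:
                re = res.random_effects.get(country, None)
                a_re = float(re.iloc[0]) if re is not None else 0.0
                b_re = (float(re.iloc[1])
                        if re is not None and len(re) > 1 else 0.0)
                a = fe[0] + a_re
                b = (fe[1] - fe[0]) + b_re
                rows.append({"category": k, "country": country,
                             "sex": cell["sex"],
                             "age_group": cell["age_group"],
                             "A": a, "B": b, "se_A": np.nan, "se_B": np.nan})
        return rows, float(res.scale)

    # ------------------------------------------------------------------
    def _coeffs(self, country: str, sex: str, age_group: str) -> np.ndarray:
        """(K, 2) array of (A, B); falls back to country mean if unseen."""
        out = np.zeros((self.n_categories, 2))
        for k in range(self.n_categories):
            key = (k, country, sex, age_group)
            try:
                row = self.coef_.loc[key]
                out[k] = (row["A"], row["B"])
            except KeyError:
                # unseen country: average over trained countries (fixed
                # effects + zero-mean random effects)
                try:
                    block = self.coef_.loc[(k, slice(None), sex, age_group)]
                except KeyError:
                    raise InputError(
                        f"cohort (sex={sex}, age_group={age_group}) not in "
                        f"training data")
                out[k] = (block["A"].mean(), block["B"].mean())
        return out

    def predict(self, country: str, sex: str, age_group: str,
                year: int) -> PrevalenceEstimate:
        """Predicted prevalence vector, clamped and renormalised."""
        if not hasattr(self, "coef_"):
            raise FittingError("model is not fitted")
        dist = max(self.years_.min() - year, year - self.years_.max())
        if dist > self.extrapolation_horizon:
            logger.warning(
                "prediction year %d is %.0f years outside the training "
                "range %d-%d", year, dist, self.years_.min(),
                self.years_.max())
        ab = self._coeffs(country, sex, age_group)
        raw = ab[:, 0] + ab[:, 1] * (year - self.year_origin_)
        return PrevalenceEstimate(
            country=country, sex=sex, age_group=age_group, year=int(year),
            raw=raw, proportions=repair_proportions(raw))

    def predict_table(self, year: int, country: str | None = None
                      ) -> pd.DataFrame:
        """All-cohort predictions in long format (prevalence CSV layout)."""
        if country is None:
            country = self.countries_[0]
        cohorts = (self.coef_.reset_index()[["sex", "age_group"]]
                   .drop_duplicates())
        rows = []
        for _, c in cohorts.iterrows():
            est = self.predict(country, c["sex"], c["age_group"], year)
            for k in range(self.n_categories):
                rows.append({"country": country, "sex": c["sex"],
                             "age_group": c["age_group"], "year": year,
                             "category": k,
                             "proportion": est.proportions[k],
                             "lower": np.nan, "upper": np.nan})
        return pd.DataFrame(rows)

    def slope_confint(self, category: int, alpha: float = 0.05
                      ) -> pd.DataFrame:
        """Per-cell 95% confidence intervals for the year slope B."""
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        block = self.coef_.loc[category].copy()
        block["B_lower"] = block["B"] - z * block["se_B"]
        block["B_upper"] = block["B"] + z * block["se_B"]
        return block[["B", "B_lower", "B_upper"]]


def fit_prevalence_model(proportions: pd.DataFrame, **params
                         ) -> PrevalenceTrendModel:
    """Thin functional wrapper over :class:`PrevalenceTrendModel`."""
    return PrevalenceTrendModel(**params).fit(proportions)


def predict_prevalence(fit: PrevalenceTrendModel, country: str, sex: str,
                       age_group: str, year: int) -> PrevalenceEstimate:
    return fit.predict(country, sex, age_group, year)
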