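"""Annual transition probabilities between exposure categories (Model 2).

A pseudo-longitudinal sample of (category at t, category at t+1) pairs is
built by matching two overlapping rotating-panel waves on quasi-identifiers
and post-stratifying to cross-sectional margins. Per origin category a
weighted multinomial logit over the K destinations is fitted, with
destination 0 as the pivot outcome and covariates intercept, sex and a
fractional polynomial in age selected by lowest deviance. Predicted rows at
any (sex, age) assemble into a row-stochastic K x K annual transition
matrix.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .categories import decade_group_of
from .errors import FittingError, InputError
from .fracpoly import FPSpec, fp_candidates, fp_transform
from .mnlogit import MNLogitFit, fit_weighted_mnlogit, mnlogit_proba

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionMatrix",
    "match_pseudo_panel",
    "reweight_panel",
    "select_fp",
    "MultinomialTransitionModel",
    "fit_transition_model",
    "predict_transition_matrix",
    "load_fixed_matrix",
]

MATCH_KEYS = ("hh_id", "seq", "sex", "birth_year")

AGE_LO, AGE_HI = 15.0, 110.0


@dataclass
class TransitionMatrix:
    """Row-stochastic K x K annual transition matrix for one (sex, age)."""

    probs: np.ndarray
    sex: str | None = None
    age: float | None = None
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != self.probs.shape[1]:
            raise InputError("transition matrix must be square")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise InputError("transition probabilities must lie in [0, 1]")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-9):
            raise InputError("transition matrix rows must sum to 1")

    @property
    def n_categories(self) -> int:
        return self.probs.shape[0]


# ---------------------------------------------------------------------------
# pseudo-panel construction
# ---------------------------------------------------------------------------

def match_pseudo_panel(wave_t: pd.DataFrame, wave_t1: pd.DataFrame,
                       keys: tuple[str, ...] = MATCH_KEYS) -> pd.DataFrame:
    """Match two waves on quasi-identifiers into transition pairs.

    Key tuples occurring more than once in either wave are ambiguous and
    discarded. Returns columns sex, age (at first wave), category_from,
    category_to, weight (first-wave weight); the achieved match rate is
    logged and stored in ``attrs``.
    """
    for name, wave in (("wave_t", wave_t), ("wave_t1", wave_t1)):
        for col in keys + ("category", "weight", "year"):
            if col not in wave.columns:
                raise InputError(f"{name} is missing column '{col}'")

    def dedup(wave):
        return wave[~wave.duplicated(list(keys), keep=False)]

    a, b = dedup(wave_t), dedup(wave_t1)
    merged = a.merge(b, on=list(keys), suffixes=("_t", "_t1"))
    year_t = merged["year_t"] if "year_t" in merged else wave_t["year"].iloc[0]
    pairs = pd.DataFrame({
        "sex": merged["sex"],
        "age": (year_t - merged["birth_year"]).astype(float),
        "category_from": merged["category_t"].astype(int),
        "category_to": merged["category_t1"].astype(int),
        "weight": merged["weight_t"].astype(float),
    })
    pairs = pairs[pairs["age"] >= AGE_LO].reset_index(drop=True)
    rate = len(pairs) / max(1, len(wave_t))
    logger.info("pseudo-panel match: %d pairs from %d wave-t records "
                "(rate %.1f%%)", len(pairs), len(wave_t), 100 * rate)
    pairs.attrs["match_rate"] = rate
    return pairs


def reweight_panel(pairs: pd.DataFrame, targets: pd.DataFrame) -> pd.DataFrame:
    """Post-stratify pair weights to cross-sectional margins.

    Margins are totals by (labour status = origin category, sex, 10-year
    age group); each pair's weight is scaled by target / panel mass of its
    cell. Target cells without panel mass are skipped with a warning.
    """
    for col in ("status", "sex", "age10", "target"):
        if col not in targets.columns:
            raise InputError(f"targets missing column '{col}'")
    out = pairs.copy()
    out["age10"] = decade_group_of(out["age"].to_numpy())
    key = ["status", "sex", "age10"]
    panel = (out.assign(status=out["category_from"])
             .groupby(key)["weight"].sum().rename("panel_mass"))
    tgt = targets.set_index(key)["target"]
    factors = {}
    for cell, target in tgt.items():
        if cell in panel.index and panel.loc[cell] > 0:
            factors[cell] = target / panel.loc[cell]
        else:
            logger.warning("reweight target cell %s has no panel mass; "
                           "skipped", cell)
    cell_of = list(zip(out["category_from"], out["sex"], out["age10"]))
    scale = np.array([factors.get(c, 1.0) for c in cell_of])
    out["weight"] = out["weight"].to_numpy() * scale
    return out.drop(columns="age10")


def panel_margins(pairs: pd.DataFrame) -> pd.DataFrame:
    """Current weighted margins of a pair table, in the targets layout."""
    df = pairs.assign(status=pairs["category_from"],
                      age10=decade_group_of(pairs["age"].to_numpy()))
    return (df.groupby(["status", "sex", "age10"])["weight"].sum()
            .rename("target").reset_index())


# ---------------------------------------------------------------------------
# fractional-polynomial model selection and fitting
# ---------------------------------------------------------------------------

def _design(pairs: pd.DataFrame, powers: tuple[float, ...]) -> np.ndarray:
    male = (pairs["sex"].to_numpy() == "male").astype(float)
    fp = fp_transform(pairs["age"].to_numpy(), powers)
    return np.column_stack([np.ones(len(pairs)), male, fp])


def _compress_destinations(y: np.ndarray, n_categories: int):
    """Map observed destination codes to 0..m-1, keeping original labels."""
    observed = np.unique(y)
    codes = {int(c): i for i, c in enumerate(observed)}
    return np.array([codes[int(v)] for v in y]), observed


def select_fp(pairs: pd.DataFrame, n_categories: int = 6, pivot: int = 0,
              tol: float = 1e-8, ridge: float = 0.0) -> FPSpec:
    """Exhaustive lowest-deviance search over the 44 FP candidates.

    Ties are broken toward lower degree, then lexicographically smaller
    powers (the candidate list is emitted in exactly that order). Use
    :meth:`MultinomialTransitionModel.fit`, which records per-origin
    search logs in ``deviance_log_``, if the full 44-entry log is needed.
    """
    spec, _ = _select_fp_logged(pairs, n_categories, pivot, tol, ridge)
    return spec


def _select_fp_logged(pairs, n_categories, pivot, tol, ridge):
    y_raw = pairs["category_to"].to_numpy(int)
    if len(np.unique(y_raw)) < 2:
        raise FittingError("need >= 2 observed destination categories "
                           "to select a fractional polynomial")
    y, observed = _compress_destinations(y_raw, n_categories)
    pivot_code = int(np.searchsorted(observed, pivot)) \
        if pivot in observed else 0
    w = pairs["weight"].to_numpy(float)
    best: FPSpec | None = None
    log: list[FPSpec] = []
    for powers in fp_candidates():
        try:
            X = _design(pairs, powers)
            fit = fit_weighted_mnlogit(X, y, w, n_classes=len(observed),
                                       pivot=pivot_code, tol=tol,
                                       ridge=ridge)
        except (FittingError, FloatingPointError) as exc:
            logger.warning("FP candidate %s failed: %s", powers, exc)
            continue
        if not np.isfinite(fit.deviance):
            logger.warning("FP candidate %s: non-finite deviance", powers)
            continue
        cand = FPSpec(powers=powers, deviance=fit.deviance)
        log.append(cand)
        if best is None or cand.deviance < best.deviance - 1e-9:
            best = cand
    if best is None:
        raise FittingError("every fractional-polynomial candidate failed")
    return best, log


class MultinomialTransitionModel(BaseEstimator):
    """Per-origin weighted multinomial logits with FP(age) covariates.

    Parameters
    ----------
    n_categories : int
        Number of exposure categories K.
    pivot : int
        Pivot destination (coefficients fixed at zero); if unobserved from
        an origin, the smallest observed destination is used for that
        origin.
    fp_spec : "auto", power tuple, or dict origin -> power tuple
        "auto" runs the lowest-deviance search per origin.
    floor : float
        Laplace-style probability floor for destinations never observed
        from an origin (rows are renormalised); 0 reproduces the omit rule.
    tol, ridge : float
        Solver gradient tolerance and optional ridge penalty.

    Attributes
    ----------
    fits_ : dict origin -> MNLogitFit
    fp_specs_ : dict origin -> FPSpec
    destinations_ : dict origin -> observed destination labels
    deviance_log_ : dict origin -> list of FPSpec candidates (search log)
    """

    def __init__(self, n_categories: int = 6, pivot: int = 0,
                 fp_spec="auto", floor: float = 0.0, tol: float = 1e-8,
                 ridge: float = 0.0):
        self.n_categories = n_categories
        self.pivot = pivot
        self.fp_spec = fp_spec
        self.floor = floor
        self.tol = tol
        self.ridge = ridge

    # -- fitting --------------------------------------------------------
    def fit(self, pairs: pd.DataFrame, y=None) -> "MultinomialTransitionModel":
        for col in ("sex", "age", "category_from", "category_to", "weight"):
            if col not in pairs.columns:
                raise InputError(f"pair table missing column '{col}'")
        if (pairs["weight"] <= 0).any():
            raise InputError("pair weights must be positive")
        self.fits_ = {}
        self.fp_specs_ = {}
        self.destinations_ = {}
        self.deviance_log_ = {}
        for origin in range(self.n_categories):
            sub = pairs[pairs["category_from"] == origin]
            if sub.empty:
                logger.warning("origin %d has no pairs; its row will be "
                               "the identity", origin)
                continue
            spec = self._resolve_spec(origin, sub)
            y_raw = sub["category_to"].to_numpy(int)
            y_c, observed = _compress_destinations(y_raw, self.n_categories)
            pivot_code = (int(np.searchsorted(observed, self.pivot))
                          if self.pivot in observed else 0)
            X = _design(sub, spec.powers)
            fit = fit_weighted_mnlogit(
                X, y_c, sub["weight"].to_numpy(float),
                n_classes=len(observed), pivot=pivot_code, tol=self.tol,
                ridge=self.ridge)
            self.fits_[origin] = fit
            self.fp_specs_[origin] = FPSpec(spec.powers, fit.deviance)
            self.destinations_[origin] = observed
        if not self.fits_:
            raise FittingError("no origin category had any pairs")
        return self

    def _resolve_spec(self, origin: int, sub: pd.DataFrame) -> FPSpec:
        if self.fp_spec == "auto":
            if len(np.unique(sub["category_to"])) < 2:
                logger.warning("origin %d: single destination observed; "
                               "defaulting to linear age", origin)
                return FPSpec((1.0,))
            spec, log = _select_fp_logged(sub, self.n_categories, self.pivot,
                                          self.tol, self.ridge)
            self.deviance_log_[origin] = log
            return spec
        if isinstance(self.fp_spec, dict):
            return FPSpec(tuple(self.fp_spec[origin]))
        return FPSpec(tuple(self.fp_spec))

    @classmethod
    def from_coefficients(cls, coefs: dict[int, np.ndarray],
                          fp_powers: tuple[float, ...] = (1.0,),
                          n_categories: int = 6, pivot: int = 0
                          ) -> "MultinomialTransitionModel":
        """Build an unfitted-from-data model from explicit coefficients.

        ``coefs[origin]`` has shape (P, K) over all destinations, pivot
        column zero, covariates (1, male, FP(age)...).
        """
        model = cls(n_categories=n_categories, pivot=pivot,
                    fp_spec=fp_powers)
        model.fits_ = {}
        model.fp_specs_ = {}
        model.destinations_ = {}
        model.deviance_log_ = {}
        for origin, coef in coefs.items():
            coef = np.asarray(coef, dtype=float)
            model.fits_[origin] = MNLogitFit(
                coef=coef, pivot=pivot, classes=np.arange(coef.shape[1]),
                loglik=np.nan, deviance=np.nan, cov=None, converged=True,
                n_iter=0)
            model.fp_specs_[origin] = FPSpec(tuple(fp_powers))
            model.destinations_[origin] = np.arange(coef.shape[1])
        return model

    # -- prediction -----------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "fits_"):
            raise FittingError("transition model is not fitted")

    def _row(self, origin: int, x: np.ndarray) -> np.ndarray:
        row = np.zeros(self.n_categories)
        if origin not in self.fits_:
            row[origin] = 1.0          # unobserved origin: stay put
            return row
        fit = self.fits_[origin]
        p = mnlogit_proba(fit.coef, x[None, :])[0]
        row[self.destinations_[origin]] = p
        if self.floor > 0.0:
            row = np.maximum(row, self.floor)
            row /= row.sum()
        return row

    def predict_matrix(self, sex: str, age: float) -> TransitionMatrix:
        """Row-stochastic K x K matrix at one (sex, exact age)."""
        self._check_fitted()
        if not AGE_LO <= age <= AGE_HI:
            clamped = float(np.clip(age, AGE_LO, AGE_HI))
            logger.warning("age %.1f outside [%d, %d]; clamped to %.1f",
                           age, AGE_LO, AGE_HI, clamped)
            age = clamped
        probs = np.zeros((self.n_categories, self.n_categories))
        for origin in range(self.n_categories):
            spec = self.fp_specs_.get(origin, FPSpec((1.0,)))
            x = np.concatenate([[1.0, 1.0 if sex == "male" else 0.0],
                                fp_transform(age, spec.powers)[0]])
            probs[origin] = self._row(origin, x)
        return TransitionMatrix(probs=probs, sex=sex, age=float(age))

    def predict_matrices(self, sex: str, ages: np.ndarray) -> np.ndarray:
        """Stacked matrices for many ages, shape (len(ages), K, K)."""
        self._check_fitted()
        ages = np.clip(np.asarray(ages, dtype=float), AGE_LO, AGE_HI)
        out = np.zeros((len(ages), self.n_categories, self.n_categories))
        male = 1.0 if sex == "male" else 0.0
        for origin in range(self.n_categories):
            if origin not in self.fits_:
                out[:, origin, origin] = 1.0
                continue
            spec = self.fp_specs_[origin]
            X = np.column_stack([np.ones(len(ages)),
                                 np.full(len(ages), male),
                                 fp_transform(ages, spec.powers)])
            p = mnlogit_proba(self.fits_[origin].coef, X)
            out[:, origin, self.destinations_[origin]] = p
            if self.floor > 0.0:
                out[:, origin] = np.maximum(out[:, origin], self.floor)
                out[:, origin] /= out[:, origin].sum(axis=1, keepdims=True)
        return out

    def table_with_ur(self, sex: str, age: float) -> pd.DataFrame:
        """Matrix in percent with delta-method 95% URs.

        The URs derive from the inverse observed information of each
        per-origin fit (not a bootstrap); the method is recorded in the
        ``method`` column.
        """
        from scipy.stats import norm

        self._check_fitted()
        z = norm.ppf(0.975)
        rows = []
        mat = self.predict_matrix(sex, age)
        for origin in range(self.n_categories):
            fit = self.fits_.get(origin)
            ses = np.zeros(self.n_categories)
            if fit is not None and fit.cov is not None:
                spec = self.fp_specs_[origin]
                x = np.concatenate([[1.0, 1.0 if sex == "male" else 0.0],
                                    fp_transform(age, spec.powers)[0]])
                ses_obs = _delta_method_se(fit, x)
                ses[self.destinations_[origin]] = ses_obs
            for dest in range(self.n_categories):
                p = mat.probs[origin, dest]
                rows.append({
                    "sex": sex, "origin": origin, "destination": dest,
                    "probability_pct": 100 * p,
                    "lower_pct": 100 * max(0.0, p - z * ses[dest]),
                    "upper_pct": 100 * min(1.0, p + z * ses[dest]),
                    "method": "delta",
                })
        return pd.DataFrame(rows)


def _delta_method_se(fit: MNLogitFit, x: np.ndarray) -> np.ndarray:
    """SEs of softmax probabilities at covariates x via the delta method."""
    K = fit.coef.shape[1]
    P = fit.coef.shape[0]
    p = mnlogit_proba(fit.coef, x[None, :])[0]
    free = [k for k in range(K) if k != fit.pivot]
    # d p_j / d b_m = p_j (1[j=m] - p_m) x
    ses = np.zeros(K)
    for j in range(K):
        grad = np.zeros((P, len(free)))
        for mi, m in enumerate(free):
            grad[:, mi] = p[j] * ((1.0 if j == m else 0.0) - p[m]) * x
        g = grad.flatten(order="F")
        var = float(g @ fit.cov @ g)
        ses[j] = np.sqrt(max(var, 0.0))
    return ses


def fit_transition_model(pairs: pd.DataFrame, fp_specs=None, **params
                         ) -> MultinomialTransitionModel:
    """Functional wrapper over :class:`MultinomialTransitionModel`."""
    if fp_specs is not None:
        params["fp_spec"] = fp_specs
    return MultinomialTransitionModel(**params).fit(pairs)


def predict_transition_matrix(model: MultinomialTransitionModel, sex: str,
                              age: float) -> TransitionMatrix:
    return model.predict_matrix(sex, age)


# ---------------------------------------------------------------------------
# fixed matrices (printed-table layout)
# ---------------------------------------------------------------------------

def load_fixed_matrix(table, renormalize: bool = True,
                      sex: str | None = None) -> TransitionMatrix:
    """Build a TransitionMatrix from a K x K table of percentages.

    Printed rows may not sum exactly to 100%; with ``renormalize`` each row
    is divided by its sum. A row deviating from 100% by more than 20% is
    rejected as malformed.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise InputError("fixed transition table must be square")
    if np.any(arr < 0):
        raise InputError("fixed transition table has a negative entry")
    sums = arr.sum(axis=1)
    bad = np.abs(sums - 100.0) > 20.0
    if bad.any():
        raise InputError(
            f"row(s) {np.flatnonzero(bad).tolist()} sum to "
            f"{sums[bad].round(2).tolist()}%, more than 20% away from 100%")
    probs = arr / 100.0
    if renormalize:
        probs = probs / probs.sum(axis=1, keepdims=True)
    return TransitionMatrix(probs=probs, sex=sex, age=None)
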