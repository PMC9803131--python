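"""Fractional-polynomial transforms of age.

Powers are drawn from the conventional set {-2, -1, -0.5, 0, 0.5, 1, 2, 3},
with power 0 denoting ln(x) and a repeated power at degree 2 adding a
multiplication by ln(x): powers (p, p) expand to (x^p, x^p ln x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

FP_POWERS: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

__all__ = ["FP_POWERS", "FPSpec", "fp_transform", "fp_candidates"]


@dataclass(frozen=True)
class FPSpec:
    """A selected fractional-polynomial specification."""

    powers: tuple[float, ...]
    deviance: float | None = None

    @property
    def degree(self) -> int:
        return len(self.powers)

    def sort_key(self) -> tuple:
        """Tie-break order: lower degree first, then lexicographic powers."""
        return (self.degree, self.powers)


def _term(x: np.ndarray, p: float) -> np.ndarray:
    return np.log(x) if p == 0.0 else x ** p


def fp_transform(age, powers: tuple[float, ...] | FPSpec) -> np.ndarray:
    """Covariate columns for ages under a power tuple; shape (n, degree)."""
    if isinstance(powers, FPSpec):
        powers = powers.powers
    x = np.atleast_1d(np.asarray(age, dtype=float))
    if np.any(x <= 0):
        raise InputError("fractional polynomials require age > 0")
    if len(powers) == 1:
        cols = [_term(x, powers[0])]
    elif len(powers) == 2:
        p1, p2 = powers
        if p1 == p2:
            base = _term(x, p1)
            cols = [base, base * np.log(x)]
        else:
            cols = [_term(x, p1), _term(x, p2)]
    else:
        raise InputError("fractional-polynomial degree must be 1 or 2")
    return np.column_stack(cols)


def fp_candidates() -> list[tuple[float, ...]]:
    """All degree-1 and degree-2 power tuples (8 + 36 = 44 candidates).

    Degree-2 tuples are unordered pairs with repetition allowed; the list is
    sorted by (degree, powers) so the first minimal-deviance candidate in
    this order is the tie-break winner.
    """
    cands: list[tuple[float, ...]] = [(p,) for p in FP_POWERS]
    for i, p1 in enumerate(FP_POWERS):
        for p2 in FP_POWERS[i:]:
            cands.append((p1, p2))
    return cands
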