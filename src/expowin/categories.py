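"""Default exposure-category and age-group layouts.

The default exposure scale is the six weekly-working-hours bands used for
the long-working-hours risk factor: labour-force inactive, 0-34, 35-40,
41-48, 49-54 and >=55 hours per week, indexed 0..5 in that (ordered) sense.
Ages are grouped in 5-year bands from 15-19 up to the open-ended 95+ band
(17 groups); 10-year bands are used only as post-stratification margins.
"""

from __future__ import annotations

import numpy as np

WORKING_HOURS_BANDS: tuple[str, ...] = (
    "inactive",
    "0-34h",
    "35-40h",
    "41-48h",
    "49-54h",
    ">=55h",
)

SEXES: tuple[str, ...] = ("female", "male")

AGE_GROUPS_5Y: tuple[str, ...] = tuple(
    f"{lo}-{lo + 4}" for lo in range(15, 95, 5)
) + ("95+",)

#: lower bound of each 5-year band, aligned with AGE_GROUPS_5Y
AGE_GROUP_LOWER: tuple[int, ...] = tuple(range(15, 100, 5))

#: width used when sampling exact ages inside a band; the open band 95+ is
#: treated as [95, 100) so draws stay within the life-table range
AGE_BAND_WIDTH: int = 5

MIN_AGE: int = 15
MAX_AGE: int = 110


def age_group_of(age: float | np.ndarray) -> np.ndarray:
    """Map exact age(s) to the 5-year band labels of ``AGE_GROUPS_5Y``."""
    age = np.asarray(age)
    idx = np.clip((age.astype(int) - MIN_AGE) // 5, 0, len(AGE_GROUPS_5Y) - 1)
    return np.asarray(AGE_GROUPS_5Y)[idx]


def age_group_index(label: str) -> int:
    return AGE_GROUPS_5Y.index(label)


def decade_group_of(age: float | np.ndarray) -> np.ndarray:
    """10-year margin bands 15-24, 25-34, ..., 65-74, 75+."""
    age = np.asarray(age)
    lo = np.clip((age.astype(int) - 15) // 10 * 10 + 15, 15, 75)
    labels = np.where(lo >= 75, "75+", np.char.add(
        np.char.add(lo.astype(str), "-"), (lo + 9).astype(str)))
    return labels


def repair_proportions(raw: np.ndarray) -> np.ndarray:
    """Clamp a raw vector to [0, 1] and renormalise to sum to 1.

    K independently-fitted category proportions need not form a valid
    distribution; this is the canonical repair applied before any vector is
    used downstream. An all-zero vector after clamping repairs to uniform.
    """
    raw = np.asarray(raw, dtype=float)
    clipped = np.clip(raw, 0.0, 1.0)
    total = clipped.sum()
    if total <= 0.0:
        return np.full_like(clipped, 1.0 / clipped.size)
    return clipped / total
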