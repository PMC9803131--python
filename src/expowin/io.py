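"""Readers and writers for the tabular interchange formats.

All files are plain UTF-8 CSV with a header row. External transition
tables use percentages with 95% ranges in the printed-table cell style
"36.9 (33.2-40.6)"; everything internal is a proportion. Conversions
happen only at this boundary.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .microsim import LifeTable
from .transitions import TransitionMatrix, load_fixed_matrix

__all__ = [
    "read_population", "write_population",
    "read_life_table", "write_life_table",
    "read_cross_sections", "write_cross_sections",
    "read_panel", "write_panel",
    "read_prevalence", "write_prevalence",
    "write_period_prevalence",
    "read_transition_table", "write_transition_table",
    "packaged_transition_table",
]

_FLOAT_FORMAT = "%.10g"


def _read_csv(path, required: set[str], name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"{name} file not found: {path}")
    df = pd.read_csv(path)
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{name} {path} missing columns {sorted(missing)}")
    return df


def _write_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


# -- population -------------------------------------------------------------

def read_population(path) -> pd.DataFrame:
    df = _read_csv(path, {"sex", "age_group", "count"}, "population table")
    if (df["count"] < 0).any():
        raise InputError("population counts must be non-negative")
    return df


def write_population(df: pd.DataFrame, path) -> None:
    _write_csv(df[["sex", "age_group", "count"]], path)


# -- life table -------------------------------------------------------------

def read_life_table(path, sexes=("female", "male")) -> LifeTable:
    df = _read_csv(path, {"sex", "age", "year", "qx"}, "life table")
    bad = df[(df["qx"] < 0) | (df["qx"] > 1)]
    if len(bad):
        raise InputError(f"life-table qx outside [0, 1] at data row(s) "
                         f"{(bad.index + 2).tolist()[:5]}")  # 1-based + header
    return LifeTable.from_frame(df, sexes=tuple(sexes))


def write_life_table(df_or_table, path) -> None:
    df = (df_or_table.to_frame() if isinstance(df_or_table, LifeTable)
          else df_or_table)
    _write_csv(df[["sex", "age", "year", "qx"]], path)


# -- surveys ----------------------------------------------------------------

def read_cross_sections(path) -> pd.DataFrame:
    return _read_csv(path, {"year", "country", "sex", "age_group",
                            "category", "weight"}, "cross-section table")


def write_cross_sections(df: pd.DataFrame, path) -> None:
    _write_csv(df[["year", "country", "sex", "age_group", "category",
                   "weight"]], path)


def read_panel(path) -> pd.DataFrame:
    return _read_csv(path, {"hh_id", "seq", "sex", "birth_year", "year",
                            "category", "weight"}, "panel table")


def write_panel(df: pd.DataFrame, path) -> None:
    _write_csv(df[["hh_id", "seq", "sex", "birth_year", "year", "category",
                   "weight"]], path)


# -- prevalence / period prevalence -----------------------------------------

_PREV_COLS = ["country", "sex", "age_group", "year", "category",
              "proportion", "lower", "upper"]


def read_prevalence(path) -> pd.DataFrame:
    return _read_csv(path, {"sex", "age_group", "year", "category",
                            "proportion"}, "prevalence table")


def write_prevalence(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in _PREV_COLS:
        if col not in out.columns:
            out[col] = np.nan
    _write_csv(out[_PREV_COLS], path)


def write_period_prevalence(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("sex", "age_group", "category", "proportion",
                        "point_unperturbed", "lower", "point", "upper",
                        "alive_n") if c in df.columns]
    _write_csv(df[cols], path)


# -- printed-style transition tables ----------------------------------------

_CELL_RE = re.compile(
    r"^\s*([0-9.]+)\s*(?:\(\s*([0-9.]+)\s*[-–—]\s*([0-9.]+)\s*\))?\s*$")


def _parse_cell(text, where: str) -> tuple[float, float, float]:
    m = _CELL_RE.match(str(text))
    if not m:
        raise InputError(f"malformed transition cell at {where}: {text!r}")
    point = float(m.group(1))
    lower = float(m.group(2)) if m.group(2) else point
    upper = float(m.group(3)) if m.group(3) else point
    return point, lower, upper


def read_transition_table(path, n_categories: int = 6,
                          renormalize: bool = True
                          ) -> dict[str, dict[str, np.ndarray]]:
    """Parse a printed-layout transition CSV.

    Expected columns: ``sex``, ``origin`` (h0..h5 or 0..5) and one column
    per destination (h0..h5). Cells are percentages "p (l-u)". Returns a
    dict sex -> {"matrix": TransitionMatrix (renormalised proportions),
    "point_pct", "lower_pct", "upper_pct" (raw percent arrays)}.
    """
    df = _read_csv(path, {"sex", "origin"}, "transition table")
    dest_cols = [c for c in df.columns if c not in ("sex", "origin")]
    if len(dest_cols) != n_categories:
        raise InputError(f"expected {n_categories} destination columns, "
                         f"found {dest_cols}")
    out = {}
    for sex, block in df.groupby("sex", sort=False):
        if len(block) != n_categories:
            raise InputError(f"sex block '{sex}' has {len(block)} rows, "
                             f"expected {n_categories}")
        block = block.assign(_o=[_origin_code(o) for o in block["origin"]])
        block = block.sort_values("_o")
        point = np.empty((n_categories, n_categories))
        lower = np.empty_like(point)
        upper = np.empty_like(point)
        for i, row in enumerate(block.itertuples(index=False)):
            for j, col in enumerate(dest_cols):
                cell = block.iloc[i][col]
                point[i, j], lower[i, j], upper[i, j] = _parse_cell(
                    cell, f"sex={sex}, origin row {i}, column {col}")
        out[str(sex)] = {
            "matrix": load_fixed_matrix(point, renormalize=renormalize,
                                        sex=str(sex)),
            "point_pct": point, "lower_pct": lower, "upper_pct": upper,
        }
    return out


def _origin_code(label) -> int:
    s = str(label).strip().lower()
    m = re.match(r"^h?_?(\d+)$", s)
    if not m:
        raise InputError(f"unrecognised origin label {label!r}")
    return int(m.group(1))


def write_transition_table(tables: pd.DataFrame | dict, path) -> None:
    """Write printed-layout CSV from the frame made by ``table_with_ur``."""
    if isinstance(tables, dict):
        frames = []
        for sex, parts in tables.items():
            p, lo, up = (parts["point_pct"], parts["lower_pct"],
                         parts["upper_pct"])
            for i in range(p.shape[0]):
                row = {"sex": sex, "origin": f"h{i}"}
                for j in range(p.shape[1]):
                    row[f"h{j}"] = f"{p[i, j]:.1f} ({lo[i, j]:.1f}-{up[i, j]:.1f})"
                frames.append(row)
        df = pd.DataFrame(frames)
    else:
        t = tables
        df_rows = []
        for (sex, origin), block in t.groupby(["sex", "origin"], sort=True):
            row = {"sex": sex, "origin": f"h{origin}"}
            for rec in block.itertuples(index=False):
                row[f"h{rec.destination}"] = (
                    f"{rec.probability_pct:.1f} "
                    f"({rec.lower_pct:.1f}-{rec.upper_pct:.1f})")
            df_rows.append(row)
        df = pd.DataFrame(df_rows)
    _write_csv(df, path)


def packaged_transition_table() -> Path:
    """Path to the packaged printed transition table (both sexes + by sex)."""
    return Path(str(resources.files("expowin") / "data"
                    / "italy_working_hours_transitions.csv"))
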