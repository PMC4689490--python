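"""Core DALY arithmetic.

DALY = YLL + YLD, cell by cell. Two morbidity conventions are supported:

* prevalence-based (GBD 2010): YLD = prevalent cases x disability weight,
* incidence-based (earlier GBD rounds): YLD = incident cases x expected
  duration x disability weight,

and mortality burden is YLL = deaths x standard remaining life expectancy at
the age of death. All computation is in full precision; rounding belongs to
the presentation layer only. No age weighting and no discounting are applied.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import AgeBand
from .life_table import LifeTable, expectancy_at

DEATH_AGE_CONVENTIONS = ("midpoint", "lower", "upper")


def _check_nonneg(**named: float) -> None:
    for name, value in named.items():
        if not np.isfinite(value) or value < 0:
            raise ValueError(f"{name} must be finite and non-negative, got {value}")


def yld_prevalence(population: float, prevalence: float, dw: float) -> float:
    """Annual years lived with disability: prevalent cases x disability weight."""
    _check_nonneg(population=population, prevalence=prevalence, dw=dw)
    if prevalence > 1 or dw > 1:
        raise ValueError("prevalence and dw are fractions in [0, 1]")
    return population * prevalence * dw


def yld_incidence(population: float, incidence: float, duration: float, dw: float) -> float:
    """Annual years lived with disability: incident cases x duration x weight."""
    _check_nonneg(population=population, incidence=incidence, duration=duration, dw=dw)
    if dw > 1:
        raise ValueError("dw is a fraction in [0, 1]")
    return population * incidence * duration * dw


def yll(
    deaths_by_age: Iterable[tuple[float | AgeBand, float]],
    table: LifeTable,
    *,
    convention: str = "midpoint",
    age_cap: float | None = None,
) -> float:
    """Years of life lost: sum of deaths x standard remaining life expectancy.

    Deaths may be keyed by exact age or by :class:`AgeBand`; band deaths are
    assigned an age per ``convention`` (midpoint | lower | upper), with
    open-ended bands truncated at ``age_cap`` (default: the table's last age).
    """
    if convention not in DEATH_AGE_CONVENTIONS:
        raise ValueError(f"unknown death-age convention {convention!r}")
    cap = table.max_age if age_cap is None else age_cap
    total = 0.0
    for where, count in deaths_by_age:
        if count < 0:
            raise ValueError("death counts must be non-negative")
        if isinstance(where, AgeBand):
            if convention == "midpoint":
                age = where.midpoint(cap)
            elif convention == "lower":
                age = where.lower
            else:
                age = where.closed_upper(cap)
        else:
            age = float(where)
        total += count * expectancy_at(table, min(age, table.max_age))
    return total


def assemble_daly(cells: pd.DataFrame) -> pd.DataFrame:
    """Assemble a burden table from per-stratum YLL/YLD.

    ``cells`` needs columns ``sex, age_lo, age_hi, population, yll, yld``
    (one row per sex x band stratum). Returns those rows plus per-sex
    all-ages rows and both-sex rows (``sex='both'``), each with ``daly`` and
    per-1,000 rates. All-ages rows carry ``age_lo = NaN``.
    """
    required = {"sex", "age_lo", "age_hi", "population", "yll", "yld"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"burden cells lack columns {sorted(missing)}")
    df = cells.copy()
    if df.duplicated(subset=["sex", "age_lo"]).any():
        raise ValueError("duplicate strata in burden cells")
    for col in ("population", "yll", "yld"):
        vals = df[col].to_numpy(dtype=float)
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError(f"{col} must be finite and non-negative")

    num = ["population", "yll", "yld"]
    rows = [df]
    for sex, grp in df.groupby("sex", sort=True):
        tot = grp[num].sum()
        rows.append(pd.DataFrame([{"sex": sex, "age_lo": np.nan, "age_hi": np.nan, **tot}]))
    for (lo, hi), grp in df.groupby(["age_lo", "age_hi"], sort=True, dropna=False):
        tot = grp[num].sum()
        rows.append(pd.DataFrame([{"sex": "both", "age_lo": lo, "age_hi": hi, **tot}]))
    tot = df[num].sum()
    rows.append(pd.DataFrame([{"sex": "both", "age_lo": np.nan, "age_hi": np.nan, **tot}]))

    out = pd.concat(rows, ignore_index=True)
    out["daly"] = out["yll"] + out["yld"]
    with np.errstate(divide="ignore", invalid="ignore"):
        for col in ("yll", "yld", "daly"):
            out[f"{col}_per_1000"] = np.where(
                out["population"] > 0, out[col] / out["population"] * 1000.0, 0.0
            )
    return out


def burden_total(table: pd.DataFrame, sex: str = "both") -> pd.Series:
    """The all-ages row for ``sex`` from an assembled burden table."""
    mask = (table["sex"] == sex) & table["age_lo"].isna()
    if not mask.any():
        raise ValueError(f"no all-ages row for sex={sex!r}")
    return table.loc[mask].iloc[0]


def compare_methods(yld_prev: float, yld_inc: float, yll_years: float) -> dict[str, float]:
    """Percent by which the prevalence-based method undercounts the incidence-based one.

    Returns full-precision ``pct_diff_yld`` and ``pct_diff_daly``; presentation
    layers round to integers.
    """
    _check_nonneg(yld_prev=yld_prev, yll_years=yll_years)
    if yld_inc <= 0:
        raise ValueError("incidence-based YLD must be positive for a comparison")
    daly_inc = yll_years + yld_inc
    return {
        "pct_diff_yld": (yld_inc - yld_prev) / yld_inc * 100.0,
        "pct_diff_daly": (daly_inc - (yll_years + yld_prev)) / daly_inc * 100.0,
    }
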