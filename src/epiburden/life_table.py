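"""Standard life tables for years-of-life-lost (YLL) calculation.

A standard (aspirational) life table maps age to the remaining life
expectancy a death at that age forfeits. The packaged ``gbd2010_standard``
table is the GBD 2010 reference life table (Murray et al., Lancet 2012,
supplementary material), with a life expectancy at birth of 86.02 years,
applied identically to both sexes. It is swappable for any CSV with
``age,ex`` columns.

No age weighting and no time discounting are applied anywhere in this
package; YLL at age *a* is exactly ``deaths(a) * ex(a)``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

BUILTIN_TABLES = {"gbd2010_standard": "gbd2010_standard.csv"}

#: life expectancy at birth of the GBD 2010 standard table
GBD2010_E0 = 86.02


@dataclass(frozen=True)
class LifeTable:
    """Ordered (age, remaining life expectancy) pairs with linear interpolation."""

    ages: np.ndarray
    ex: np.ndarray
    name: str = "custom"
    e0_declared: float | None = field(default=None)

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        ex = np.asarray(self.ex, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "ex", ex)
        if ages.ndim != 1 or ages.shape != ex.shape or ages.size < 2:
            raise ValueError("life table needs matching 1-d age/ex columns with >= 2 rows")
        if ages[0] != 0:
            raise ValueError("life table must start at age 0")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("life-table ages must be strictly increasing (no duplicates)")
        if np.any(ex <= 0):
            raise ValueError("remaining life expectancy must be positive")
        if self.e0_declared is not None and not np.isclose(ex[0], self.e0_declared, atol=1e-9):
            raise ValueError(
                f"ex(0)={ex[0]} does not match declared life expectancy at birth {self.e0_declared}"
            )

    @property
    def e0(self) -> float:
        """Life expectancy at birth."""
        return float(self.ex[0])

    @property
    def max_age(self) -> float:
        return float(self.ages[-1])


def load_life_table(source: str | Path) -> LifeTable:
    """Load a life table from a built-in name or a CSV path with ``age,ex`` columns."""
    if isinstance(source, str) and source in BUILTIN_TABLES:
        ref = resources.files("epiburden.data") / BUILTIN_TABLES[source]
        with resources.as_file(ref) as path:
            df = pd.read_csv(path)
        declared = GBD2010_E0 if source == "gbd2010_standard" else None
        return LifeTable(df["age"].to_numpy(), df["ex"].to_numpy(), name=source, e0_declared=declared)
    path = Path(source)
    if not path.exists():
        raise ValueError(f"life table source {source!r} is neither a built-in name nor an existing file")
    df = pd.read_csv(path)
    missing = {"age", "ex"} - set(df.columns)
    if missing:
        raise ValueError(f"life-table CSV lacks columns {sorted(missing)}")
    return LifeTable(df["age"].to_numpy(), df["ex"].to_numpy(), name=path.stem)


def expectancy_at(table: LifeTable, age: float | np.ndarray) -> float | np.ndarray:
    """Remaining standard life expectancy at ``age``, linearly interpolated.

    Ages beyond the last tabulated age clamp to the terminal expectancy with
    a warning (a death past the table end still accrues the terminal value).
    Negative ages are rejected.
    """
    a = np.asarray(age, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be non-negative")
    if np.any(a > table.max_age):
        warnings.warn(
            f"age beyond life-table end ({table.max_age:g}); clamping to terminal expectancy",
            stacklevel=2,
        )
    out = np.interp(a, table.ages, table.ex)
    return float(out) if np.isscalar(age) or a.ndim == 0 else out
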