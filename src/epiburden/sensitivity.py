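"""One-way disability-weight sensitivity analysis.

Disability weights enter the YLD formulas multiplicatively, so scanning the
GBD 2010 epilepsy health states amounts to exact rescaling of the reference
YLD by dw / reference_dw; uncertainty bounds rescale the same way (an exact
consequence of linearity for the point estimate, and a documented
approximation for bootstrap interval bounds).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: GBD 2010 epilepsy health-state weights; "reference" is the sub-Saharan
#: Africa mean weight used for the headline estimates.
GBD2010_DWS: dict[str, float] = {
    "reference": 0.346,
    "treated_seizure_free": 0.072,
    "treated_recent_seizures": 0.319,
    "untreated": 0.42,
    "severe": 0.657,
}


@dataclass(frozen=True)
class DWSet:
    """Named disability weights, each strictly inside (0, 1)."""

    weights: Mapping[str, float] = field(default_factory=lambda: dict(GBD2010_DWS))

    def __post_init__(self) -> None:
        for name, w in self.weights.items():
            if not 0.0 < w < 1.0:
                raise ValueError(f"disability weight {name}={w} must lie in (0, 1)")

    def items(self):
        return self.weights.items()

    def __getitem__(self, name: str) -> float:
        return self.weights[name]


def dw_scan(
    base_yld: float,
    reference_dw: float,
    dw_set: DWSet | Mapping[str, float] | None = None,
    *,
    base_interval: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Rescale a reference YLD across a set of disability weights.

    Returns one row per weight with ``yld`` (= base_yld x dw/reference_dw),
    the percent change of YLD versus the reference, and rescaled interval
    bounds when ``base_interval`` is given.
    """
    if reference_dw <= 0:
        raise ValueError("reference disability weight must be positive")
    if base_yld < 0:
        raise ValueError("base YLD must be non-negative")
    weights = dw_set.weights if isinstance(dw_set, DWSet) else (dw_set or GBD2010_DWS)
    rows = []
    for name, dw in weights.items():
        ratio = dw / reference_dw
        row = {
            "state": name,
            "dw": dw,
            "yld": base_yld * ratio,
            "pct_change_yld": (ratio - 1.0) * 100.0,
        }
        if base_interval is not None:
            row["yld_lo"] = base_interval[0] * ratio
            row["yld_hi"] = base_interval[1] * ratio
        rows.append(row)
    return pd.DataFrame(rows)


def dw_effect_on_daly(yll_years: float, scan: pd.DataFrame, base_yld: float) -> pd.DataFrame:
    """Percent change of total DALYs for each scanned weight vs the reference.

    Reference DALY = yll + base_yld; scanned DALY = yll + scanned YLD.
    Values are full precision; presentation rounds to integers.
    """
    reference_daly = yll_years + base_yld
    if reference_daly <= 0:
        raise ValueError("reference DALY must be positive")
    out = scan.copy()
    out["daly"] = yll_years + out["yld"]
    out["pct_change_daly"] = (out["daly"] - reference_daly) / reference_daly * 100.0
    return out
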