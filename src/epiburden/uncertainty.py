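"""Bootstrap 95% uncertainty intervals for burden statistics.

The resampling unit is configurable: ``counts`` draws each stratum count
afresh from a Poisson centred on the observed count (the natural bootstrap
for rare-event surveillance tallies with person-time denominators), while
``parametric`` redraws rate-like cells from normals truncated at zero using
supplied standard errors. Intervals are percentile (2.5/97.5) over the
replicate statistics; the point estimate always comes from the unresampled
input. Deterministic under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

RESAMPLING_UNITS = ("counts", "parametric")


@dataclass(frozen=True)
class BootstrapSpec:
    """Bootstrap settings; percentile intervals at the fixed 2.5/97.5 levels."""

    iterations: int = 1000
    seed: int = 20151223
    method: str = "percentile"
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("bootstrap iterations must be >= 1")
        if self.method != "percentile":
            raise ValueError("only the percentile interval method is implemented")
        if self.unit not in RESAMPLING_UNITS:
            raise ValueError(f"unknown resampling unit {self.unit!r}")


@dataclass(frozen=True)
class BootstrapResult:
    point: float
    lo: float
    hi: float
    n_failed: int = 0

    def interval(self) -> tuple[float, float]:
        return (self.lo, self.hi)


def _resample(data, spec: BootstrapSpec, rng: np.random.Generator):
    if spec.unit == "counts":
        if isinstance(data, pd.DataFrame):
            out = data.copy()
            num = out.select_dtypes(include=[np.number]).columns
            out[num] = rng.poisson(out[num].to_numpy(dtype=float))
            return out
        arr = np.asarray(data, dtype=float)
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        return rng.poisson(arr).astype(float)
    # parametric: DataFrame with value/se column pairs
    if not isinstance(data, pd.DataFrame):
        raise ValueError("parametric resampling needs a DataFrame with '<name>_se' columns")
    out = data.copy()
    cols = [c for c in data.columns if f"{c}_se" in data.columns]
    if not cols:
        raise ValueError("parametric resampling found no '<name>_se' columns")
    for c in cols:
        mu = data[c].to_numpy(dtype=float)
        se = data[f"{c}_se"].to_numpy(dtype=float)
        draw = mu.copy()
        pos = se > 0
        if pos.any():
            a = (0.0 - mu[pos]) / se[pos]
            draw[pos] = stats.truncnorm.rvs(
                a, np.inf, loc=mu[pos], scale=se[pos], random_state=rng
            )
        out[c] = draw
    return out


def bootstrap_interval(
    data,
    statistic: Callable[[object], float],
    spec: BootstrapSpec | None = None,
) -> BootstrapResult:
    """Percentile bootstrap interval for ``statistic(data)``.

    ``data`` is an array/Series of counts (``unit='counts'``) or a DataFrame
    with ``<name>_se`` columns (``unit='parametric'``). Replicates on which
    the statistic raises or returns a non-finite value are dropped and
    counted; more than 5% failures aborts.
    """
    spec = spec or BootstrapSpec()
    rng = np.random.default_rng(spec.seed)
    point = float(statistic(data))
    values = np.empty(spec.iterations)
    failed = 0
    kept = 0
    for _ in range(spec.iterations):
        rep = _resample(data, spec, rng)
        try:
            v = float(statistic(rep))
        except Exception:
            failed += 1
            continue
        if not np.isfinite(v):
            failed += 1
            continue
        values[kept] = v
        kept += 1
    if failed > 0.05 * spec.iterations:
        raise RuntimeError(
            f"statistic failed on {failed}/{spec.iterations} bootstrap replicates (>5%)"
        )
    lo, hi = np.percentile(values[:kept], [2.5, 97.5])
    return BootstrapResult(point, float(lo), float(hi), failed)
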