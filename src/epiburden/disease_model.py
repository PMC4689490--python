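"""Three-state illness-death consistency engine.

The generic disease model tracks, along age *a*, the fraction of a birth
cohort that is alive and disease-free, W(a), and alive with disease, C(a),
under four age-specific hazards (all per person-year):

* ``i`` — incidence (W -> C),
* ``r`` — remission (C -> W),
* ``f`` — excess (cause-specific) mortality of cases,
* ``m`` — background mortality (everyone).

The cohort obeys the linear system

    dW/da = -(i + m) W + r C
    dC/da =  i W - (r + m + f) C

from which prevalence p(a) = C/(W+C), case duration D(a) (expected remaining
sojourn in C under exit hazard r+m+f), and the standardized mortality ratio
SMR(a) = (m+f)/m follow. ``fit_consistent`` inverts the forward model: given
band-level observations of at least three of {prevalence, incidence,
remission, cause-specific mortality} it finds the hazard schedule whose
forward solution matches them in weighted least squares — the internal
consistency adjustment that burden-of-disease pipelines traditionally
delegate to DisMod II.

Numerics: hazards are piecewise-constant on the age bands, so the classical
fixed-step RK4 update (step 0.1 year by default) has a constant 2x2 step
matrix per band — the 4th-order Taylor polynomial of expm(h A). States on the
grid are obtained by closed-form matrix powers of that step matrix, which
reproduces the fixed-step RK4 trajectory exactly and reproducibly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares

from .bands import DEFAULT_BANDS, AgeBand, band_index, validate_partition

#: quantities fit_consistent can consume as observations
OBSERVABLE_QUANTITIES = ("prevalence", "incidence", "remission", "cause_mortality")

DEFAULT_AGE_CAP = 100.0
DEFAULT_STEP = 0.1


@dataclass(frozen=True)
class HazardSchedule:
    """Band-constant hazards (per person-year) for one sex."""

    bands: tuple[AgeBand, ...]
    incidence: np.ndarray
    remission: np.ndarray
    excess_mortality: np.ndarray
    background_mortality: np.ndarray
    sex: str | None = None

    def __post_init__(self) -> None:
        bands = validate_partition(self.bands)
        object.__setattr__(self, "bands", bands)
        for name in ("incidence", "remission", "excess_mortality", "background_mortality"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(bands),):
                raise ValueError(f"{name} must have one value per band ({len(bands)})")
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite and non-negative")
            object.__setattr__(self, name, arr)

    # short aliases matching the field's i/r/f/m notation
    @property
    def i(self) -> np.ndarray:
        return self.incidence

    @property
    def r(self) -> np.ndarray:
        return self.remission

    @property
    def f(self) -> np.ndarray:
        return self.excess_mortality

    @property
    def m(self) -> np.ndarray:
        return self.background_mortality

    def at(self, age: float) -> tuple[float, float, float, float]:
        k = band_index(self.bands, age)
        return (self.i[k], self.r[k], self.f[k], self.m[k])

    def smr(self) -> np.ndarray:
        """Band-level (m+f)/m; equals 1 where f=0 (and where m=f=0 by convention)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(self.m > 0, (self.m + self.f) / np.where(self.m > 0, self.m, 1.0),
                           np.where(self.f > 0, np.inf, 1.0))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_lo": [b.lower for b in self.bands],
                "age_hi": [b.upper for b in self.bands],
                "incidence": self.i,
                "remission": self.r,
                "excess_mortality": self.f,
                "background_mortality": self.m,
            }
        )


@dataclass(frozen=True)
class UncertaintySpec:
    """Monte-Carlo propagation settings: independent normals truncated at zero."""

    distribution: str = "normal"
    iterations: int = 1000
    seed: int = 20151223

    def __post_init__(self) -> None:
        if self.distribution != "normal":
            raise ValueError("only the normal input distribution is supported")
        if self.iterations < 1:
            raise ValueError("iteration count must be >= 1")


@dataclass
class DiseaseStateSolution:
    """Forward solution of the illness-death system on an age grid."""

    ages: np.ndarray
    well: np.ndarray       # W(a), fraction alive and disease-free
    cases: np.ndarray      # C(a), fraction alive with disease
    prevalence: np.ndarray  # p(a) = C/(W+C)
    duration: np.ndarray    # D(a), expected remaining years in the disease state
    smr: np.ndarray         # (m+f)/m at each grid age
    hazards: HazardSchedule

    def summary(self) -> pd.DataFrame:
        """Band-level summary: mean prevalence, population rates, midpoint duration, SMR.

        ``incidence_rate`` and ``cause_mortality_rate`` are population-level
        event rates per person-year (i scaled by the susceptible fraction and
        f by the prevalent fraction), the quantities a surveillance system
        observes.
        """
        bands = self.hazards.bands
        rows = []
        cap = float(self.ages[-1])
        for k, band in enumerate(bands):
            hi = band.closed_upper(cap)
            mask = (self.ages >= band.lower) & (self.ages < hi)
            if band is bands[-1]:
                mask |= np.isclose(self.ages, cap)
            p_bar = float(self.prevalence[mask].mean()) if mask.any() else float("nan")
            rows.append(
                {
                    "age_lo": band.lower,
                    "age_hi": band.upper,
                    "prevalence": p_bar,
                    "incidence_rate": self.hazards.i[k] * (1.0 - p_bar),
                    "remission": self.hazards.r[k],
                    "cause_mortality_rate": self.hazards.f[k] * p_bar,
                    "duration": float(np.interp(band.midpoint(cap), self.ages, self.duration)),
                    "smr": float(self.hazards.smr()[k]),
                }
            )
        return pd.DataFrame(rows)


def _step_matrix(i: float, r: float, f: float, m: float, h: float) -> np.ndarray:
    """RK4 step matrix for the linear system: 4th-order Taylor polynomial of expm(hA)."""
    A = np.array([[-(i + m), r], [i, -(r + m + f)]], dtype=float)
    hA = h * A
    M = np.eye(2) + hA
    term = hA
    for k in (2, 3, 4):
        term = term @ hA / k
        M = M + term
    return M


def _propagate(M: np.ndarray, x0: np.ndarray, n: int) -> np.ndarray:
    """States after 1..n applications of the 2x2 step matrix, via closed-form powers."""
    tr = M[0, 0] + M[1, 1]
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    half = tr / 2.0
    disc = complex(half * half - det)
    sq = np.sqrt(disc)
    l1, l2 = half + sq, half - sq
    ks = np.arange(1, n + 1)
    x0c = x0.astype(complex)
    if abs(l1 - l2) > 1e-12 * max(abs(l1), abs(l2), 1e-300):
        a = M @ x0c - l2 * x0c
        b = M @ x0c - l1 * x0c
        xs = (np.power(l1, ks)[:, None] * a[None, :] - np.power(l2, ks)[:, None] * b[None, :]) / (l1 - l2)
    else:  # repeated eigenvalue: M = l I + N with N nilpotent, M^k = l^k I + k l^(k-1) N
        lam = half
        Nx = M @ x0c - lam * x0c
        xs = np.power(lam, ks)[:, None] * x0c[None, :] + (
            ks * np.power(lam, ks - 1.0)
        )[:, None] * Nx[None, :]
    return xs.real


def _band_ids(bands: Sequence[AgeBand], ages: np.ndarray) -> np.ndarray:
    """Vectorised band membership (ages past a bounded terminal band clamp to it)."""
    lowers = np.array([b.lower for b in bands])
    return np.clip(np.searchsorted(lowers, ages, side="right") - 1, 0, len(bands) - 1)


def _segments(
    bands: Sequence[AgeBand], ages: np.ndarray
) -> list[tuple[int, int, int]]:
    """Runs of consecutive grid intervals sharing a band: (band_idx, start, n_steps)."""
    idx = _band_ids(bands, 0.5 * (ages[:-1] + ages[1:]))
    breaks = np.flatnonzero(np.diff(idx)) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [len(idx)]))
    return [(int(idx[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def solve_forward(
    hazards: HazardSchedule,
    age_grid: np.ndarray | Sequence[float] | None = None,
    initial_prevalence: float = 0.0,
    *,
    age_cap: float = DEFAULT_AGE_CAP,
    step: float = DEFAULT_STEP,
) -> DiseaseStateSolution:
    """Integrate the illness-death system forward in age.

    Starts the cohort at the youngest grid age with ``initial_prevalence``
    cases and no prior mortality. Returns the full state trajectory plus
    derived prevalence, duration and SMR. ``age_grid`` defaults to a uniform
    grid from the first band's lower bound to ``age_cap`` at ``step`` years;
    a custom grid must be strictly increasing.
    """
    if not 0.0 <= initial_prevalence <= 1.0:
        raise ValueError("initial_prevalence must lie in [0, 1]")
    if age_grid is None:
        a0 = hazards.bands[0].lower
        n = int(round((age_cap - a0) / step))
        if n < 1:
            raise ValueError("age cap must exceed the first band's lower bound")
        ages = a0 + step * np.arange(n + 1)
    else:
        ages = np.asarray(age_grid, dtype=float)
        if ages.ndim != 1 or ages.size < 2 or np.any(np.diff(ages) <= 0):
            raise ValueError("age grid must be strictly increasing with >= 2 points")

    uniform = age_grid is None or np.allclose(np.diff(ages), ages[1] - ages[0])
    W = np.empty_like(ages)
    C = np.empty_like(ages)
    x = np.array([1.0 - initial_prevalence, initial_prevalence])
    W[0], C[0] = x
    if uniform:
        h = float(ages[1] - ages[0])
        for k, start, n in _segments(hazards.bands, ages):
            M = _step_matrix(hazards.i[k], hazards.r[k], hazards.f[k], hazards.m[k], h)
            xs = _propagate(M, x, n)
            W[start + 1 : start + n + 1] = xs[:, 0]
            C[start + 1 : start + n + 1] = xs[:, 1]
            x = xs[-1]
    else:
        for j in range(len(ages) - 1):
            h = ages[j + 1] - ages[j]
            i, r, f, m = hazards.at(0.5 * (ages[j] + ages[j + 1]))
            x = _step_matrix(i, r, f, m, h) @ x
            W[j + 1], C[j + 1] = x

    np.clip(W, 0.0, None, out=W)
    np.clip(C, 0.0, None, out=C)
    alive = W + C
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(alive > 0, C / np.where(alive > 0, alive, 1.0), 0.0)
    np.clip(p, 0.0, 1.0, out=p)

    duration = _sojourn_time(hazards, ages)
    smr = hazards.smr()[_band_ids(hazards.bands, np.minimum(ages, ages[-1] - 1e-9))]
    return DiseaseStateSolution(ages, W, C, p, duration, smr, hazards)


def _sojourn_time(hazards: HazardSchedule, ages: np.ndarray) -> np.ndarray:
    """Expected remaining years in the disease state at each grid age.

    Exact for piecewise-constant exit hazard q = r+m+f; beyond the grid end
    an analytic exponential tail with the terminal band's hazard is attached,
    so constant-hazard durations equal 1/q irrespective of the age cap.
    """
    q_band = hazards.r + hazards.m + hazards.f
    q_last = q_band[_band_ids(hazards.bands, np.array([ages[-1] - 1e-9]))[0]]
    D = np.empty_like(ages)
    D[-1] = 1.0 / q_last if q_last > 0 else 0.0
    for k, start, n in reversed(_segments(hazards.bands, ages)):
        q = q_band[k]
        h = np.diff(ages[start : start + n + 1])
        # backward closed form within the segment, distance j steps from its end
        d_end = D[start + n]
        if q > 0:
            e = np.exp(-q * h)
            ecum = np.concatenate(([1.0], np.cumprod(e[::-1])))  # survival back from segment end
            # D_j = (1 - prod e)/q + prod e * d_end for j steps before the end
            D[start : start + n + 1] = ((1.0 - ecum) / q + ecum * d_end)[::-1]
        else:
            back = np.concatenate(([0.0], np.cumsum(h[::-1])))
            D[start : start + n + 1] = (back + d_end)[::-1]
    return D


# ---------------------------------------------------------------------------
# Consistency fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of a consistency fit for one sex."""

    schedule: HazardSchedule
    solution: DiseaseStateSolution
    discrepancy: float
    converged: bool
    flags: set[str] = field(default_factory=set)

    def summary(self) -> pd.DataFrame:
        return self.solution.summary()


def _observed_columns(observed: pd.DataFrame) -> list[str]:
    return [q for q in OBSERVABLE_QUANTITIES if q in observed.columns]


def _residual_scales(observed: pd.DataFrame, cols: list[str]) -> dict[str, np.ndarray]:
    """Per-cell residual scales: the supplied SE where present, else a relative scale."""
    scales = {}
    for q in cols:
        vals = observed[q].to_numpy(dtype=float)
        se_col = f"{q}_se"
        if se_col in observed.columns:
            se = observed[se_col].to_numpy(dtype=float)
            if np.any(se < 0):
                raise ValueError(f"{se_col} must be non-negative")
            floor = np.nanmax(np.abs(vals))
            floor = 1e-12 if not np.isfinite(floor) or floor == 0 else 1e-6 * floor
            scales[q] = np.maximum(se, floor)
        else:
            ref = np.mean(np.abs(vals)) if np.any(vals != 0) else 1.0
            scales[q] = np.maximum(np.abs(vals), 0.1 * ref)
    return scales


def fit_consistent(
    observed: pd.DataFrame,
    mortality: np.ndarray | Sequence[float],
    bands: Sequence[AgeBand] = DEFAULT_BANDS,
    *,
    age_cap: float = DEFAULT_AGE_CAP,
    step: float = DEFAULT_STEP,
    max_nfev: int = 4000,
) -> FitResult:
    """Fit a hazard schedule consistent with band-level observations (one sex).

    ``observed`` carries one row per band, with columns among ``prevalence``
    (fraction), ``incidence`` (events per person-year, population level),
    ``remission`` (per person-year) and ``cause_mortality`` (cause-specific
    deaths per person-year, population level), plus optional ``<name>_se``
    columns giving standard errors for inverse-variance weighting; without
    SEs relative (proportional) weighting is used. ``mortality`` is the
    band-level all-cause mortality rate (per person-year), taken as the
    model's background hazard. At least three observed quantities are
    required; fewer leaves the system underdetermined and is rejected.
    """
    bands = validate_partition(bands)
    nb = len(bands)
    if len(observed) != nb:
        raise ValueError(f"observed table must have one row per band ({nb})")
    m = np.asarray(mortality, dtype=float)
    if m.shape != (nb,) or np.any(m < 0):
        raise ValueError("mortality must be a non-negative per-band vector")
    cols = _observed_columns(observed)
    if len(cols) < 3:
        raise ValueError(
            f"underdetermined: need >= 3 observed quantities, got {cols or 'none'}"
        )
    obs = {q: observed[q].to_numpy(dtype=float) for q in cols}
    for q, vals in obs.items():
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError(f"observed {q} must be finite and non-negative")

    # empty-disease shortcut: nothing identifies r or f
    no_disease = all(np.all(obs[q] == 0) for q in ("prevalence", "incidence") if q in obs)
    if no_disease:
        zeros = np.zeros(nb)
        schedule = HazardSchedule(bands, zeros, zeros, zeros, m)
        sol = solve_forward(schedule, age_cap=age_cap, step=step)
        return FitResult(schedule, sol, 0.0, True, {"unidentified"})

    scales = _residual_scales(observed, cols)

    # analytic warm start from the local steady state
    p0 = obs.get("prevalence", np.full(nb, 1e-3))
    p0 = np.clip(p0, 1e-6, 1 - 1e-6)
    i0 = obs["incidence"] / (1.0 - p0) if "incidence" in obs else np.full(nb, 1e-4)
    f0 = obs["cause_mortality"] / p0 if "cause_mortality" in obs else np.zeros(nb)
    if "remission" in obs:
        r0 = obs["remission"].copy()
    else:
        r0 = np.clip(i0 * (1.0 - p0) / p0 - f0 - m, 1e-4, 2.0)
    x0 = np.concatenate([i0, r0, f0])
    x0 = np.clip(x0, 1e-9, None)
    upper = np.concatenate([np.full(nb, 1.0), np.full(nb, 5.0), np.full(nb, 5.0)])

    # precompute grid -> band membership for fast band-mean prevalence
    a0 = bands[0].lower
    n = int(round((age_cap - a0) / step))
    grid = a0 + step * np.arange(n + 1)
    ids = _band_ids(bands, np.minimum(grid, age_cap - 1e-9))
    pts_per_band = np.bincount(ids, minlength=nb)

    def residuals(x: np.ndarray) -> np.ndarray:
        i, r, f = x[:nb], x[nb : 2 * nb], x[2 * nb :]
        schedule = HazardSchedule(bands, i, r, f, m)
        sol = solve_forward(schedule, age_cap=age_cap, step=step)
        p_bar = np.bincount(ids, weights=sol.prevalence, minlength=nb) / pts_per_band
        pred = {
            "prevalence": p_bar,
            "incidence": i * (1.0 - p_bar),
            "remission": r,
            "cause_mortality": f * p_bar,
        }
        return np.concatenate([(pred[q] - obs[q]) / scales[q] for q in cols])

    res = least_squares(
        residuals, x0, bounds=(0.0, upper), method="trf", max_nfev=max_nfev, x_scale="jac"
    )
    i, r, f = res.x[:nb], res.x[nb : 2 * nb], res.x[2 * nb :]
    schedule = HazardSchedule(bands, i, r, f, m)
    sol = solve_forward(schedule, age_cap=age_cap, step=step)
    flags: set[str] = set()
    converged = res.status > 0
    if not converged:
        flags.add("non_converged")
    return FitResult(schedule, sol, float(2.0 * res.cost), converged, flags)


def fit_by_sex(
    observed: pd.DataFrame,
    mortality: pd.DataFrame,
    bands: Sequence[AgeBand] = DEFAULT_BANDS,
    **kwargs,
) -> dict[str, FitResult]:
    """Run :func:`fit_consistent` per sex; both inputs need a ``sex`` column."""
    out = {}
    for sex, grp in observed.groupby("sex", sort=True):
        mvals = mortality.loc[mortality["sex"] == sex, "mortality"].to_numpy(dtype=float)
        out[str(sex)] = fit_consistent(grp.reset_index(drop=True), mvals, bands, **kwargs)
    return out


# ---------------------------------------------------------------------------
# Smoothing and Monte-Carlo propagation
# ---------------------------------------------------------------------------

SMOOTHING_METHODS = ("piecewise-linear", "moving-average", "cubic-spline")


def smooth_schedule(
    values: Sequence[float],
    method: str,
    bands: Sequence[AgeBand] = DEFAULT_BANDS,
    *,
    age_cap: float = DEFAULT_AGE_CAP,
) -> Callable[[np.ndarray | float], np.ndarray | float]:
    """Turn band-level values into a function of continuous age.

    ``piecewise-linear`` interpolates band midpoints (constant beyond the
    outermost midpoints); ``moving-average`` first smooths the band values
    with a centred window of 3 (shrunk at the edges) and then interpolates;
    ``cubic-spline`` is a natural cubic spline through the midpoints, clamped
    to the end values outside them. All methods reproduce the band values at
    midpoints exactly except the moving average.
    """
    bands = validate_partition(bands)
    vals = np.asarray(values, dtype=float)
    if vals.shape != (len(bands),):
        raise ValueError("one value per band is required")
    if len(bands) < 2:
        raise ValueError("smoothing needs at least two bands")
    mids = np.array([b.midpoint(age_cap) for b in bands])

    if method == "piecewise-linear":
        anchor = vals
    elif method == "moving-average":
        anchor = np.array(
            [vals[max(0, j - 1) : j + 2].mean() for j in range(len(vals))]
        )
    elif method == "cubic-spline":
        spline = CubicSpline(mids, vals, bc_type="natural")

        def fn(age):
            a = np.clip(np.asarray(age, dtype=float), mids[0], mids[-1])
            out = spline(a)
            return float(out) if np.isscalar(age) else out

        return fn
    else:
        raise ValueError(f"unknown smoothing method {method!r}; choose from {SMOOTHING_METHODS}")

    def fn(age):
        out = np.interp(np.asarray(age, dtype=float), mids, anchor)
        return float(out) if np.isscalar(age) else out

    return fn


def _truncated_normal(rng: np.random.Generator, mean: float, se: float, size: int | None = None):
    """Normal(mean, se) truncated at zero (rates cannot go negative)."""
    if se == 0:
        return np.full(size, mean) if size else mean
    a = (0.0 - mean) / se
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=se, size=size, random_state=rng)


def propagate_uncertainty(
    observed: pd.DataFrame,
    mortality: np.ndarray | Sequence[float] | None,
    spec: UncertaintySpec,
    *,
    bands: Sequence[AgeBand] = DEFAULT_BANDS,
    model: Callable[[pd.DataFrame], Mapping[str, float]] | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Monte-Carlo 95% uncertainty intervals for consistency-fit outputs.

    Each iteration redraws every observed cell from an independent normal
    (truncated at zero) centred on its value with its ``<name>_se`` standard
    error, re-runs the fit (or a caller-supplied ``model``) and records the
    outputs; the 2.5th/97.5th percentiles across iterations form the interval.
    Deterministic for a fixed ``spec.seed``. Output rows: one per scalar
    output, columns ``value`` (point estimate from the unperturbed inputs),
    ``lo``, ``hi``.
    """
    rng = np.random.default_rng(spec.seed)

    if model is None:
        if mortality is None:
            raise ValueError("mortality is required when using the default consistency-fit model")

        def model(df: pd.DataFrame) -> Mapping[str, float]:
            fit = fit_consistent(df, mortality, bands, **fit_kwargs)
            summ = fit.summary()
            out: dict[str, float] = {}
            for j, band in enumerate(fit.schedule.bands):
                for q in ("prevalence", "incidence_rate", "remission", "cause_mortality_rate", "duration", "smr"):
                    out[f"{band.label}:{q}"] = float(summ.loc[j, q])
            return out

    value_cols = [c for c in observed.columns if f"{c}_se" in observed.columns]
    if not value_cols:
        raise ValueError("no '<name>_se' columns found; standard errors are required")

    point = pd.Series(model(observed), dtype=float)
    draws = np.empty((spec.iterations, len(point)))
    for it in range(spec.iterations):
        perturbed = observed.copy()
        for c in value_cols:
            mu = observed[c].to_numpy(dtype=float)
            se = observed[f"{c}_se"].to_numpy(dtype=float)
            perturbed[c] = [
                _truncated_normal(rng, float(mu[j]), float(se[j])) for j in range(len(mu))
            ]
        draws[it] = pd.Series(model(perturbed), dtype=float).reindex(point.index).to_numpy()

    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    return pd.DataFrame({"value": point.to_numpy(), "lo": lo, "hi": hi}, index=point.index)
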