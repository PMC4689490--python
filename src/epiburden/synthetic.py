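"""Synthetic HDSS cohorts and packaged surveillance fixtures.

``generate_cohort`` simulates the stratified count tables an HDSS-based
disease study would yield (person-years, all-cause deaths, prevalent cases
at baseline, incident cases over follow-up, cause-specific deaths) for 2
sexes x 6 age bands with *known* illness-death hazards, so every pipeline
stage can be scored against ground truth. Expected counts come from the
forward illness-death solution; realised counts are Poisson (rare events on
person-time denominators). Loss to follow-up is an optional uniform thinning
of person-time, off by default.

``agincourt_fixture`` returns the packaged rural-South-Africa surveillance
tables (demography/mortality and consistency-model outputs with 95%
uncertainty intervals) used as downstream fixtures; the female 0-5 duration
interval is stored as missing (unparseable in the source).
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .bands import DEFAULT_BANDS, AgeBand, parse_band, validate_partition
from .disease_model import DEFAULT_AGE_CAP, DEFAULT_STEP, HazardSchedule, solve_forward

SEXES = ("male", "female")

STRATA_COLUMNS = [
    "sex",
    "age_lo",
    "age_hi",
    "person_years",
    "deaths_all_cause",
    "population",
    "cases_prevalent",
    "cases_incident",
    "deaths_cause",
]


@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth description of a simulated surveillance cohort."""

    bands: tuple[AgeBand, ...]
    populations: Mapping[str, np.ndarray]   # persons per band, by sex
    hazards: Mapping[str, HazardSchedule]   # true i/r/f/m per band, by sex
    years: float = 4.0                      # follow-up duration (2008-2012 style)
    loss_to_followup: float = 0.0           # uniform person-time thinning fraction
    seed: int = 20151223

    def __post_init__(self) -> None:
        validate_partition(self.bands)
        for sex in self.populations:
            pop = np.asarray(self.populations[sex], dtype=float)
            if pop.shape != (len(self.bands),) or np.any(pop < 0):
                raise ValueError(f"populations[{sex!r}] must be non-negative, one per band")
            object.__getattribute__(self, "populations")[sex] = pop  # type: ignore[index]
        if set(self.populations) != set(self.hazards):
            raise ValueError("populations and hazards must cover the same sexes")
        if self.years <= 0:
            raise ValueError("observation years must be positive")
        if not 0.0 <= self.loss_to_followup < 1.0:
            raise ValueError("loss_to_followup must lie in [0, 1)")


def default_spec(seed: int = 20151223) -> CohortSpec:
    """Agincourt-scale study conditions: 2 sexes x 6 bands, 4 years follow-up.

    Populations are the surveillance person-years divided by the follow-up
    length; hazards take the fixture incidence/remission/mortality levels
    (excess mortality backed out of the band SMRs as f = (SMR-1) m).
    """
    t1 = load_table1()
    t2 = load_table2()
    populations: dict[str, np.ndarray] = {}
    hazards: dict[str, HazardSchedule] = {}
    for sex in SEXES:
        d1 = t1[t1["sex"] == sex]
        d2 = t2[(t2["sex"] == sex) & t2["age_lo"].notna()]
        m = d1["mortality_per_1000_pyo"].to_numpy() / 1000.0
        i = d2["incidence_per_100k"].to_numpy() / 1e5
        r = d2["remission_per_100"].to_numpy() / 100.0
        f = np.maximum(d2["smr"].to_numpy() - 1.0, 0.0) * m
        populations[sex] = d1["person_years"].to_numpy() / 4.0
        hazards[sex] = HazardSchedule(DEFAULT_BANDS, i, r, f, m, sex=sex)
    return CohortSpec(DEFAULT_BANDS, populations, hazards, years=4.0, seed=seed)


def expected_counts(spec: CohortSpec, *, age_cap: float = DEFAULT_AGE_CAP, step: float = DEFAULT_STEP) -> pd.DataFrame:
    """Noise-free expected stratum counts implied by the illness-death model."""
    rows = []
    for sex in sorted(spec.populations):
        sched = spec.hazards[sex]
        summ = solve_forward(sched, age_cap=age_cap, step=step).summary()
        pop = spec.populations[sex]
        pyo = pop * spec.years * (1.0 - spec.loss_to_followup)
        for k, band in enumerate(spec.bands):
            p_bar = summ.loc[k, "prevalence"]
            rows.append(
                {
                    "sex": sex,
                    "age_lo": band.lower,
                    "age_hi": band.upper,
                    "person_years": pyo[k],
                    "deaths_all_cause": pyo[k] * (sched.m[k] + sched.f[k] * p_bar),
                    "population": pop[k],
                    "cases_prevalent": pop[k] * p_bar,
                    "cases_incident": pyo[k] * summ.loc[k, "incidence_rate"],
                    "deaths_cause": pyo[k] * summ.loc[k, "cause_mortality_rate"],
                }
            )
    return pd.DataFrame(rows, columns=STRATA_COLUMNS)


def generate_cohort(
    spec: CohortSpec, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Simulate one stratified cohort: Poisson counts around the model expectations.

    Returns the stratum table (``STRATA_COLUMNS``) and a truth record holding
    the generating spec, the expected counts and the band-level true
    epidemiological quantities for scoring.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    expected = expected_counts(spec)
    observed = expected.copy()
    for col in ("deaths_all_cause", "cases_prevalent", "cases_incident", "deaths_cause"):
        observed[col] = rng.poisson(expected[col].to_numpy(dtype=float)).astype(float)
    truth = {
        "spec": spec,
        "expected": expected,
        "summaries": {
            sex: solve_forward(spec.hazards[sex]).summary() for sex in sorted(spec.hazards)
        },
    }
    return observed, truth


def observed_rates(strata: pd.DataFrame) -> pd.DataFrame:
    """Band-level observed rates (with Poisson standard errors) from a stratum table.

    Produces the input format of :func:`epiburden.disease_model.fit_consistent`:
    prevalence (fraction), incidence and cause_mortality (per person-year),
    each with an SE column, plus the all-cause mortality rate. Zero counts get
    the conventional one-event SE floor.
    """
    df = strata.copy()
    out = pd.DataFrame({"sex": df["sex"], "age_lo": df["age_lo"], "age_hi": df["age_hi"]})
    pop = df["population"].to_numpy(dtype=float)
    pyo = df["person_years"].to_numpy(dtype=float)
    for num, denom, name in (
        ("cases_prevalent", pop, "prevalence"),
        ("cases_incident", pyo, "incidence"),
        ("deaths_cause", pyo, "cause_mortality"),
    ):
        counts = df[num].to_numpy(dtype=float)
        out[name] = counts / denom
        out[f"{name}_se"] = np.sqrt(np.maximum(counts, 1.0)) / denom
    out["mortality"] = df["deaths_all_cause"].to_numpy(dtype=float) / pyo
    return out


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------


def _read_packaged(name: str) -> pd.DataFrame:
    ref = resources.files("epiburden.data") / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_table1() -> pd.DataFrame:
    """Demography and all-cause mortality fixture (per-band person-years, deaths, rates)."""
    return _read_packaged("table1_agincourt.csv")


def load_table2() -> pd.DataFrame:
    """Consistency-model output fixture: incidence, prevalence, remission, duration, SMR.

    Rows with ``age_lo`` NaN are the all-ages aggregates. The female 0-5
    duration interval is missing in the source and stored as NaN.
    """
    return _read_packaged("table2_agincourt.csv")


def load_table3() -> pd.DataFrame:
    """Prevalence-method burden fixture (YLL/YLD/DALY with 95% UIs); ``sex='both'`` rows included."""
    return _read_packaged("table3_agincourt.csv")


def load_table5() -> pd.DataFrame:
    """All-ages method-comparison fixture: populations, aggregate rates, YLDs."""
    return _read_packaged("table5_agincourt.csv")


def agincourt_fixture() -> dict[str, pd.DataFrame]:
    """All packaged Agincourt surveillance fixtures, with computed all-ages rows for demography."""
    t1 = load_table1()
    aggregates = []
    for sex, grp in t1.groupby("sex", sort=True):
        pyo = grp["person_years"].sum()
        deaths = grp["deaths_all_cause"].sum()
        aggregates.append(
            {
                "sex": sex,
                "age_lo": np.nan,
                "age_hi": np.nan,
                "person_years": pyo,
                "deaths_all_cause": deaths,
                "mortality_per_1000_pyo": deaths / pyo * 1000.0,
                "mortality_lo": np.nan,
                "mortality_hi": np.nan,
            }
        )
    t1_full = pd.concat([t1, pd.DataFrame(aggregates)], ignore_index=True)
    return {
        "table1": t1_full,
        "table2": load_table2(),
        "table3": load_table3(),
        "table5": load_table5(),
    }


def agincourt_strata(years: float = 4.0) -> pd.DataFrame:
    """Synthetic stratum-count reconstruction of the Agincourt cohort.

    Person-years and all-cause deaths are the fixture values; epilepsy counts
    are back-calculated from the fixture band rates (prevalent cases =
    population x prevalence, incident cases = person-years x incidence,
    cause deaths from the SMR-implied excess hazard). This is a synthetic
    stand-in for the unpublished individual-level data, intended as a
    realistic pipeline input, not a data product.
    """
    t1, t2 = load_table1(), load_table2()
    rows = []
    for sex in SEXES:
        d1 = t1[t1["sex"] == sex].reset_index(drop=True)
        d2 = t2[(t2["sex"] == sex) & t2["age_lo"].notna()].reset_index(drop=True)
        pop = d1["person_years"].to_numpy() / years
        pyo = d1["person_years"].to_numpy(dtype=float)
        m = d1["mortality_per_1000_pyo"].to_numpy() / 1000.0
        prev = d2["prevalence_per_1000"].to_numpy() / 1000.0
        inc = d2["incidence_per_100k"].to_numpy() / 1e5
        f = np.maximum(d2["smr"].to_numpy() - 1.0, 0.0) * m
        for k in range(len(d1)):
            rows.append(
                {
                    "sex": sex,
                    "age_lo": d1.loc[k, "age_lo"],
                    "age_hi": d1.loc[k, "age_hi"],
                    "person_years": pyo[k],
                    "deaths_all_cause": d1.loc[k, "deaths_all_cause"],
                    "population": pop[k],
                    "cases_prevalent": pop[k] * prev[k],
                    "cases_incident": pyo[k] * inc[k] * (1.0 - prev[k]),
                    "deaths_cause": pyo[k] * f[k] * prev[k],
                }
            )
    return pd.DataFrame(rows, columns=STRATA_COLUMNS)


def load_strata(path) -> pd.DataFrame:
    """Read and validate a ``strata.csv`` stratum table."""
    df = pd.read_csv(path)
    missing = set(STRATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"strata table lacks columns {sorted(missing)}")
    for col in STRATA_COLUMNS[3:]:
        vals = df[col].to_numpy(dtype=float)
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError(f"strata column {col} must be finite and non-negative")
    [parse_band(lo, hi) for lo, hi in zip(df["age_lo"], df["age_hi"])]
    return df
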