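"""Run configuration for the end-to-end pipeline."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .sensitivity import GBD2010_DWS
from .uncertainty import BootstrapSpec

METHODS = ("prevalence", "incidence", "both")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; serialisable and hashable for provenance.

    ``strata`` is a CSV path or the built-in name ``"agincourt"`` (the packaged
    synthetic reconstruction of the rural-South-Africa cohort).
    ``uncertainty_iterations=0`` skips the Monte-Carlo consistency-fit stage
    (the burden-stage bootstrap still supplies uncertainty intervals; the two
    stages are deliberately not nested by default).
    """

    strata: str = "agincourt"
    life_table: str = "gbd2010_standard"
    death_age_convention: str = "midpoint"
    method: str = "both"
    dw_reference: str = "reference"
    dws: dict[str, float] = field(default_factory=lambda: dict(GBD2010_DWS))
    bootstrap_iterations: int = 1000
    bootstrap_unit: str = "counts"
    uncertainty_iterations: int = 0
    seed: int = 20151223
    outdir: str = "epiburden_out"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.death_age_convention not in ("midpoint", "lower", "upper"):
            raise ValueError("death_age_convention must be midpoint|lower|upper")
        if self.dw_reference not in self.dws:
            raise ValueError(f"dw_reference {self.dw_reference!r} not in dws")
        if self.strata != "agincourt" and not Path(self.strata).exists():
            raise ValueError(f"strata file {self.strata!r} does not exist")
        if self.life_table != "gbd2010_standard" and not Path(self.life_table).exists():
            raise ValueError(f"life table {self.life_table!r} does not exist")

    def bootstrap_spec(self) -> BootstrapSpec:
        return BootstrapSpec(
            iterations=self.bootstrap_iterations, seed=self.seed, unit=self.bootstrap_unit
        )

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in every output."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a YAML run configuration; keyword overrides win over file values."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config YAML must be a mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**raw)
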