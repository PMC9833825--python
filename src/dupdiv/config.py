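"""Run configuration: parameter blocks, presets, TOML loading, hashing.

A `RunConfig` bundles everything one simulated experiment needs.  The three
named demand presets correspond to the study's three selective environments:

* low demand (D=4): a modest expression increase suffices, reachable by
  amplification to ~4 copies OR a single promoter point mutation — the
  regime where the two mutation routes are mutually exclusive and the
  frequent route (amplification, in the IS+ strain) wins;
* intermediate demand (D=25): one strong point mutation or a large array;
* high demand (D=60): unreachable by either route alone (beta_mut = 20,
  kmax = 20 with per-copy cost), so only combination mutants (amplified
  arrays containing mutant copies) reach the plateau.

Strain presets differ only in the duplication-formation rate: IS+ carries
flanking insertion-sequence repeats (mu_dup = 1e-3 per cell per generation);
IS- lacks them and forms duplications only through rare repeat-independent
events (mu_dup = 1e-6).  Once a duplication exists, the per-junction
amplification/deletion rate mu_step is identical in both strains.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

from .classify import Thresholds
from .model_core import AlleleParams, Environment, MutationRates
from .evolve import SerialProtocol
from .reporter import ReporterParams

__all__ = ["RunConfig", "DEMAND_LEVELS", "STRAIN_RATES", "preset", "load_config", "config_hash"]

DEMAND_LEVELS = {"low": 4.0, "intermediate": 25.0, "high": 60.0}

STRAIN_RATES = {
    "IS+": MutationRates(mu_dup=1e-3, mu_step=1e-2, mu_pm=1e-7),
    "IS-": MutationRates(mu_dup=1e-6, mu_step=1e-2, mu_pm=1e-7),
}


@dataclass(frozen=True)
class RunConfig:
    """All parameter blocks of one simulated evolution experiment."""

    environment: Environment = field(default_factory=lambda: Environment(demand=DEMAND_LEVELS["low"]))
    alleles: AlleleParams = field(default_factory=AlleleParams)
    rates: MutationRates = field(default_factory=lambda: STRAIN_RATES["IS+"])
    protocol: SerialProtocol = field(default_factory=SerialProtocol)
    reporter: ReporterParams = field(default_factory=ReporterParams)
    thresholds: Thresholds = field(default_factory=Thresholds)
    kmax: int = 20
    base_seed: int = 1

    def __post_init__(self) -> None:
        if self.kmax < 2:
            raise ValueError("kmax must be >= 2")


def preset(demand: str = "low", strain: str = "IS+", **overrides) -> RunConfig:
    """A ready-made RunConfig for a named demand level and strain.

    ``overrides`` may replace any top-level RunConfig field, e.g.
    ``preset("low", "IS-", protocol=SerialProtocol(carrying_capacity=1e6))``.
    """
    if demand not in DEMAND_LEVELS:
        raise ValueError(f"unknown demand level {demand!r}; choose from {sorted(DEMAND_LEVELS)}")
    if strain not in STRAIN_RATES:
        raise ValueError(f"unknown strain {strain!r}; choose from {sorted(STRAIN_RATES)}")
    cfg = RunConfig(
        environment=Environment(demand=DEMAND_LEVELS[demand]),
        rates=STRAIN_RATES[strain],
    )
    return replace(cfg, **overrides) if overrides else cfg


_BLOCK_TYPES = {
    "environment": Environment,
    "alleles": AlleleParams,
    "rates": MutationRates,
    "protocol": SerialProtocol,
    "reporter": ReporterParams,
    "thresholds": Thresholds,
}


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a TOML file; unknown keys are rejected.

    Each parameter block is a TOML table named after the RunConfig field;
    scalar fields (kmax, base_seed) sit at the top level.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    kwargs = {}
    top_scalars = {"kmax", "base_seed"}
    for key, value in raw.items():
        if key in _BLOCK_TYPES:
            cls = _BLOCK_TYPES[key]
            known = {f.name for f in fields(cls)}
            unknown = set(value) - known
            if unknown:
                raise ValueError(f"unknown keys in [{key}]: {sorted(unknown)}")
            kwargs[key] = cls(**value)
        elif key in top_scalars:
            kwargs[key] = value
        else:
            raise ValueError(f"unknown configuration key: {key!r}")
    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    """Stable sha256 of the canonical JSON form of a config."""
    payload = json.dumps(asdict(config), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()
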