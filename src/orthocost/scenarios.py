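"""Cohort parameters, intervention profiles and scenario-grid configuration.

A *scenario* is one column of the reporting grid: an orthodontic intervention
(labial or lingual multi-bracket appliance, with its white-spot-lesion and
cavitation incidence model and WSL treatment policy), a GOZ fee increment
factor, and a median composite-restoration repair time.  The default grid
crosses {lingual, labial} × {2.3, 3.5} × {180, 372, 60, 120} months, sixteen
scenarios in all.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError
from .fees import FeeSchedule, FACTORS, default_fee_schedule, load_fee_schedule

WslPolicy = Literal["fluoridation", "restoration"]

#: Repair medians (months) grouped as the two published scenario tables:
#: "3" = the evidence-based composite survival scenarios (15 y / 31 y),
#: "4" = the shortened esthetic-renewal scenarios (5 y / 10 y).
TABLE_MEDIANS: dict[str, tuple[float, ...]] = {"3": (180.0, 372.0), "4": (60.0, 120.0)}

DEFAULT_MASTER_SEED = 20190809


@dataclass(frozen=True)
class CohortParams:
    """Population-level simulation parameters.

    Ages are in years, durations and the residual-lifetime median in months.
    ``max_teeth`` caps each defect count (incisors to first molars, 24 teeth);
    ``max_age`` caps age at start + treatment duration + residual lifetime.
    """

    n_sim: int = 1_000_000
    age_min: float = 12.0
    age_max: float = 18.0
    tx_min: float = 9.0
    tx_max: float = 45.0
    median_residual: float = 696.0
    max_age: float = 100.0
    max_teeth: int = 24

    def __post_init__(self):
        if self.n_sim < 1:
            raise ConfigurationError("n_sim must be >= 1")
        if not self.age_min < self.age_max:
            raise ConfigurationError("age_min must be < age_max")
        if not self.tx_min < self.tx_max:
            raise ConfigurationError("tx_min must be < tx_max")
        if self.median_residual <= 0:
            raise ConfigurationError("median_residual must be positive")
        if self.max_teeth < 1:
            raise ConfigurationError("max_teeth must be >= 1")
        if self.max_age * 12 < self.age_max * 12 + self.tx_max:
            raise ConfigurationError("max_age leaves no room for treatment")


@dataclass(frozen=True)
class InterventionProfile:
    """Incidence model and WSL treatment policy for one appliance type.

    Rates are per tooth-bearing patient per month of active treatment;
    dispersions are negative-binomial size parameters (smaller = more
    overdispersed = more defect-free patients at a fixed mean).
    """

    name: str
    wsl_rate: float
    cav_rate: float
    wsl_dispersion: float
    cav_dispersion: float
    wsl_policy: WslPolicy

    def __post_init__(self):
        for attr in ("wsl_rate", "cav_rate", "wsl_dispersion", "cav_dispersion"):
            if getattr(self, attr) <= 0:
                raise ConfigurationError(f"{self.name}: {attr} must be positive")
        if self.wsl_policy not in ("fluoridation", "restoration"):
            raise ConfigurationError(
                f"{self.name}: unknown wsl_policy {self.wsl_policy!r}"
            )


#: Lingual appliances: low labial-surface exposure, WSL invisible from the
#: front and managed by a single topical fluoridation.
LINGUAL = InterventionProfile(
    name="lingual",
    wsl_rate=0.0248,
    cav_rate=0.0012,
    wsl_dispersion=0.3,
    cav_dispersion=1.0,
    wsl_policy="fluoridation",
)

#: Conventional labial appliances: esthetically relevant WSL restored with a
#: single-surface composite, entering the repair process like cavitations.
LABIAL = InterventionProfile(
    name="labial",
    wsl_rate=0.1537,
    cav_rate=0.0015,
    wsl_dispersion=0.72,
    cav_dispersion=1.0,
    wsl_policy="restoration",
)

INTERVENTIONS: dict[str, InterventionProfile] = {"lingual": LINGUAL, "labial": LABIAL}


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one simulated scenario, including its RNG seed."""

    intervention: InterventionProfile
    fee_factor: float
    repair_median: float
    cohort: CohortParams = field(default_factory=CohortParams)
    max_repairs: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.fee_factor not in FACTORS:
            raise ConfigurationError(
                f"fee_factor must be one of {FACTORS}, got {self.fee_factor!r}"
            )
        if self.repair_median <= 0:
            raise ConfigurationError("repair_median must be positive")
        if self.max_repairs < 0:
            raise ConfigurationError("max_repairs must be >= 0")

    @property
    def label(self) -> str:
        return (
            f"{self.intervention.name}/GOZ{self.fee_factor}/"
            f"{self.repair_median:g}mo"
        )


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Per-scenario seeds from one master seed.

    Uses numpy's SeedSequence: the i-th scenario seed is the i-th word of
    ``SeedSequence(master_seed).generate_state(n)`` masked to 31 bits, so
    scenario streams are mutually independent and the whole grid is
    reproducible from a single integer.
    """
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def default_scenario_grid(
    table: str = "all",
    n_sim: int = 1_000_000,
    master_seed: int = DEFAULT_MASTER_SEED,
    max_repairs: int = 5,
    cohort: CohortParams | None = None,
) -> list[ScenarioConfig]:
    """The published scenario grid in column order.

    Within each repair-median block the order is (lingual, 2.3), (labial,
    2.3), (lingual, 3.5), (labial, 3.5); medians run 180, 372 for table "3"
    and 60, 120 for table "4"; ``table="all"`` concatenates both.
    """
    if table not in ("3", "4", "all"):
        raise ConfigurationError(f"table must be '3', '4' or 'all', got {table!r}")
    medians = (
        TABLE_MEDIANS["3"] + TABLE_MEDIANS["4"] if table == "all" else TABLE_MEDIANS[table]
    )
    return _build_grid(
        medians=medians,
        fee_factors=(2.3, 3.5),
        interventions=("lingual", "labial"),
        n_sim=n_sim,
        master_seed=master_seed,
        max_repairs=max_repairs,
        cohort=cohort,
    )


def _build_grid(
    medians: Sequence[float],
    fee_factors: Sequence[float],
    interventions: Sequence[str],
    n_sim: int,
    master_seed: int,
    max_repairs: int,
    cohort: CohortParams | None,
) -> list[ScenarioConfig]:
    base = cohort if cohort is not None else CohortParams()
    if base.n_sim != n_sim:
        base = replace(base, n_sim=n_sim)
    combos = [
        (median, factor, name)
        for median in medians
        for factor in fee_factors
        for name in interventions
    ]
    seeds = derive_seeds(master_seed, len(combos))
    grid = []
    for (median, factor, name), seed in zip(combos, seeds):
        if name not in INTERVENTIONS:
            raise ConfigurationError(f"unknown intervention: {name!r}")
        grid.append(
            ScenarioConfig(
                intervention=INTERVENTIONS[name],
                fee_factor=float(factor),
                repair_median=float(median),
                cohort=base,
                max_repairs=max_repairs,
                seed=seed,
            )
        )
    return grid


_TOP_KEYS = {
    "n_sim",
    "master_seed",
    "max_repairs",
    "table",
    "repair_medians",
    "fee_factors",
    "interventions",
    "cohort",
    "fees",
}
_COHORT_KEYS = {
    "n_sim",
    "age_min",
    "age_max",
    "tx_min",
    "tx_max",
    "median_residual",
    "max_age",
    "max_teeth",
}


def load_config(source) -> tuple[list[ScenarioConfig], FeeSchedule]:
    """Parse a YAML/JSON scenario-grid configuration.

    ``source`` may be a mapping, a path to a file, or a YAML/JSON string.
    Unknown keys are rejected (named in the error) rather than ignored.
    Returns the scenario list and the (possibly overridden) fee schedule.
    """
    if isinstance(source, dict):
        raw = source
    else:
        text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration root must be a mapping")

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown configuration key: {sorted(unknown)[0]!r}")

    cohort_raw = raw.get("cohort", {})
    if not isinstance(cohort_raw, dict):
        raise ConfigurationError("cohort: expected a mapping")
    bad = set(cohort_raw) - _COHORT_KEYS
    if bad:
        raise ConfigurationError(f"cohort: unknown key {sorted(bad)[0]!r}")
    n_sim = int(raw.get("n_sim", cohort_raw.get("n_sim", 1_000_000)))
    cohort = CohortParams(**{**cohort_raw, "n_sim": n_sim})

    if "table" in raw and ("repair_medians" in raw):
        raise ConfigurationError("give either 'table' or 'repair_medians', not both")
    if "table" in raw:
        medians = TABLE_MEDIANS["3"] + TABLE_MEDIANS["4"] if raw["table"] in ("all",) else None
        table = str(raw["table"])
        if table not in ("3", "4", "all"):
            raise ConfigurationError(f"table must be '3', '4' or 'all', got {table!r}")
        medians = (
            TABLE_MEDIANS["3"] + TABLE_MEDIANS["4"]
            if table == "all"
            else TABLE_MEDIANS[table]
        )
    else:
        medians = tuple(float(m) for m in raw.get("repair_medians", (180, 372, 60, 120)))
    for m in medians:
        if m <= 0:
            raise ConfigurationError(f"repair_medians: must be positive, got {m:g}")

    configs = _build_grid(
        medians=medians,
        fee_factors=tuple(float(f) for f in raw.get("fee_factors", (2.3, 3.5))),
        interventions=tuple(raw.get("interventions", ("lingual", "labial"))),
        n_sim=n_sim,
        master_seed=int(raw.get("master_seed", DEFAULT_MASTER_SEED)),
        max_repairs=int(raw.get("max_repairs", 5)),
        cohort=cohort,
    )
    schedule = (
        load_fee_schedule(raw["fees"]) if "fees" in raw else default_fee_schedule()
    )
    return configs, schedule


def load_scenario_grid(source) -> list[ScenarioConfig]:
    """Scenario list from a config source (see :func:`load_config`)."""
    return load_config(source)[0]
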