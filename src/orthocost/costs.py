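"""Per-patient cost accounting.

Turns defect counts and repair counts into itemized Eur amounts under a
scenario's fee factor: initial treatment at debonding (fluoridation or
single-surface restoration per WSL, restoration per cavitation) plus one
restoration fee per repair cycle.  Costs accrue undiscounted at face value
regardless of when a repair falls in the patient's remaining lifetime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import PatientCohort
from .fees import FeeSchedule, default_fee_schedule, treatment_cost
from .scenarios import ScenarioConfig


@dataclass(frozen=True)
class PatientLedger:
    """Itemized per-patient costs (Eur) and the counts that generated them."""

    n_wsl: np.ndarray
    n_cav: np.ndarray
    n_wsl_repairs: np.ndarray
    n_cav_repairs: np.ndarray
    wsl_initial_cost: np.ndarray
    cav_initial_cost: np.ndarray
    wsl_retx_cost: np.ndarray
    cav_retx_cost: np.ndarray
    total_cost: np.ndarray

    def __post_init__(self):
        n = len(self.n_wsl)
        for name in (
            "n_cav",
            "n_wsl_repairs",
            "n_cav_repairs",
            "wsl_initial_cost",
            "cav_initial_cost",
            "wsl_retx_cost",
            "cav_retx_cost",
            "total_cost",
        ):
            if len(getattr(self, name)) != n:
                raise ValueError(f"ledger field {name} has mismatched length")

    @property
    def n(self) -> int:
        return len(self.n_wsl)

    @property
    def has_any_defect(self) -> np.ndarray:
        """pop1 membership: at least one WSL and/or cavitation."""
        return (self.n_wsl + self.n_cav) >= 1

    @property
    def has_cavitation(self) -> np.ndarray:
        """pop2 membership: at least one cavitation (WSL allowed on top)."""
        return self.n_cav >= 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_wsl": self.n_wsl,
                "n_cav": self.n_cav,
                "n_wsl_repairs": self.n_wsl_repairs,
                "n_cav_repairs": self.n_cav_repairs,
                "wsl_initial_cost": self.wsl_initial_cost,
                "cav_initial_cost": self.cav_initial_cost,
                "wsl_retx_cost": self.wsl_retx_cost,
                "cav_retx_cost": self.cav_retx_cost,
                "total_cost": self.total_cost,
            }
        )


def cost_patients(
    cohort: PatientCohort,
    wsl_repairs: np.ndarray,
    cav_repairs: np.ndarray,
    config: ScenarioConfig,
    schedule: FeeSchedule | None = None,
) -> PatientLedger:
    """Itemize costs for every patient under one scenario.

    Initial WSL treatment is priced per lesion at the policy's event fee
    (fluoridation for lingual, restoration for labial); cavitations are
    always restored.  Every repair cycle of a restored surface costs one
    further restoration fee.  Under the fluoridation policy WSL never enter
    the repair process, so passing nonzero ``wsl_repairs`` there is an
    internal inconsistency and raises.
    """
    schedule = schedule if schedule is not None else default_fee_schedule()
    wsl_repairs = np.asarray(wsl_repairs)
    cav_repairs = np.asarray(cav_repairs)
    if not (cohort.n == len(wsl_repairs) == len(cav_repairs)):
        raise ValueError("cohort and repair-count arrays have mismatched lengths")

    policy = config.intervention.wsl_policy
    factor = config.fee_factor
    wsl_fee = float(treatment_cost(schedule, policy, factor))
    resto_fee = float(treatment_cost(schedule, "restoration", factor))

    if policy == "fluoridation" and np.any(wsl_repairs != 0):
        raise ValueError("fluoridated WSL cannot have repair cycles")

    wsl_initial = cohort.n_wsl * wsl_fee
    cav_initial = cohort.n_cav * resto_fee
    wsl_retx = (
        wsl_repairs * resto_fee
        if policy == "restoration"
        else np.zeros(cohort.n)
    )
    cav_retx = cav_repairs * resto_fee
    total = wsl_initial + cav_initial + wsl_retx + cav_retx

    return PatientLedger(
        n_wsl=cohort.n_wsl,
        n_cav=cohort.n_cav,
        n_wsl_repairs=np.asarray(wsl_repairs, dtype=np.int64),
        n_cav_repairs=np.asarray(cav_repairs, dtype=np.int64),
        wsl_initial_cost=wsl_initial,
        cav_initial_cost=cav_initial,
        wsl_retx_cost=wsl_retx,
        cav_retx_cost=cav_retx,
        total_cost=total,
    )
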