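"""Synthetic patient cohort generation.

One simulated patient is: an age at appliance placement drawn uniformly on
[12, 18] years, a treatment duration uniform on [9, 45] months, white-spot
lesion (WSL) and cavitation counts drawn from negative-binomial distributions
whose mean is the per-month incidence rate times the treatment duration
(each capped at 24 affected teeth), and a residual lifetime after debonding
drawn from a shape-1 Weibull (exponential) with median 696 months, truncated
so that total age never exceeds 100 years.

The negative binomial uses the ecological "size/mu" parameterization:
``X ~ NB(size=dispersion, mean=mu)`` with zero probability
``(size / (size + mu)) ** size``; smaller dispersion means heavier
overdispersion and more defect-free patients at the same mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .scenarios import CohortParams, InterventionProfile

LN2 = math.log(2.0)


@dataclass(frozen=True)
class PatientCohort:
    """Per-patient simulation state, one array entry per patient."""

    age_start: np.ndarray  # years at appliance placement
    tx_duration: np.ndarray  # months of active treatment
    n_wsl: np.ndarray  # WSL count at debonding
    n_cav: np.ndarray  # cavitation count at debonding
    residual_months: np.ndarray  # lifetime remaining after debonding

    def __post_init__(self):
        n = len(self.age_start)
        for name in ("tx_duration", "n_wsl", "n_cav", "residual_months"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"cohort field {name} has mismatched length")

    @property
    def n(self) -> int:
        return len(self.age_start)

    @property
    def age_debond(self) -> np.ndarray:
        """Age in years at appliance removal."""
        return self.age_start + self.tx_duration / 12.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_start": self.age_start,
                "tx_duration": self.tx_duration,
                "n_wsl": self.n_wsl,
                "n_cav": self.n_cav,
                "residual_months": self.residual_months,
            }
        )


def sample_ages(params: CohortParams, rng: np.random.Generator) -> np.ndarray:
    """Ages at treatment start: continuous uniform on [age_min, age_max] years."""
    return rng.uniform(params.age_min, params.age_max, params.n_sim)


def sample_durations(params: CohortParams, rng: np.random.Generator) -> np.ndarray:
    """Treatment durations: continuous uniform on [tx_min, tx_max] months."""
    return rng.uniform(params.tx_min, params.tx_max, params.n_sim)


def sample_defect_counts(
    rate: float,
    dispersion: float,
    durations: np.ndarray,
    cap: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-patient defect counts, NB(size=dispersion, mean=rate*duration), capped.

    The cap models the fixed number of bracket-bearing teeth: a patient
    cannot accrue more defects than teeth, so draws above ``cap`` are clamped.
    """
    if rate <= 0:
        raise ValueError(f"incidence rate must be positive, got {rate}")
    if dispersion <= 0:
        raise ValueError(f"dispersion must be positive, got {dispersion}")
    if cap < 1:
        raise ValueError(f"cap must be >= 1, got {cap}")
    mu = rate * np.asarray(durations, dtype=float)
    p = dispersion / (dispersion + mu)
    return np.minimum(rng.negative_binomial(dispersion, p), cap).astype(np.int64)


def nb_zero_probability(mean, dispersion) -> float | np.ndarray:
    """P(X = 0) for X ~ NB(size=dispersion, mean): (d / (d + mean)) ** d.

    Closed form used as the analytic oracle for :func:`sample_defect_counts`;
    at dispersion 1 it reduces to the geometric 1 / (1 + mean).
    """
    mean = np.asarray(mean, dtype=float)
    if np.any(mean < 0):
        raise ValueError("mean must be non-negative")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    out = (dispersion / (dispersion + mean)) ** dispersion
    return out if out.ndim else float(out)


def nb_zero_probability_uniform_duration(
    rate: float, dispersion: float, t_min: float = 9.0, t_max: float = 45.0
) -> float:
    """Zero-count probability averaged over a uniform treatment duration.

    Integrates the closed-form zero probability over duration ~ U(t_min,
    t_max) by adaptive quadrature; its complement is the expected fraction of
    patients with at least one defect.
    """
    if t_max <= t_min:
        raise ValueError("t_max must exceed t_min")
    val, _ = quad(
        lambda t: nb_zero_probability(rate * t, dispersion), t_min, t_max
    )
    return val / (t_max - t_min)


def sample_residual_lifetimes(
    params: CohortParams, age_debond: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Residual lifetimes after debonding, in months.

    Shape-1 Weibull (exponential) with median ``params.median_residual``
    (scale = median / ln 2), clamped to the months remaining until
    ``params.max_age``; the distribution is truncated, not renormalized.
    """
    age_debond = np.asarray(age_debond, dtype=float)
    if np.any(age_debond > params.max_age):
        raise ValueError("age at debonding exceeds the maximum age")
    t = rng.exponential(params.median_residual / LN2, size=age_debond.shape)
    return np.minimum(t, (params.max_age - age_debond) * 12.0)


def simulate_cohort(
    params: CohortParams, profile: InterventionProfile, rng: np.random.Generator
) -> PatientCohort:
    """Draw a full cohort for one intervention.

    Stream order is fixed (ages, durations, WSL counts, cavitation counts,
    residual lifetimes) so that a seed pins down the whole cohort.
    """
    ages = sample_ages(params, rng)
    durations = sample_durations(params, rng)
    n_wsl = sample_defect_counts(
        profile.wsl_rate, profile.wsl_dispersion, durations, params.max_teeth, rng
    )
    n_cav = sample_defect_counts(
        profile.cav_rate, profile.cav_dispersion, durations, params.max_teeth, rng
    )
    residual = sample_residual_lifetimes(params, ages + durations / 12.0, rng)
    return PatientCohort(ages, durations, n_wsl, n_cav, residual)
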