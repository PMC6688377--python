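"""Composite-restoration repair chains over the patient's residual lifetime.

Each restored surface starts its clock at debonding.  Successive times until
the next repair are shape-1 Weibull (exponential) with a configurable median;
a repair happens whenever the cumulative repair time still undercuts the
patient's residual lifetime, up to a hard cap (5 re-restorations per surface
by default).  Because exponential inter-event times form a Poisson process,
the chain length is ``min(N, max_repairs)`` with
``N ~ Poisson(ln 2 * residual / repair_median)`` — both routes are
implemented; the truncated-Poisson expectation serves as the analytic oracle.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

LN2 = math.log(2.0)


def _validate(residual: np.ndarray, repair_median: float, max_repairs: int) -> None:
    if np.any(residual < 0):
        raise ValueError("residual lifetime must be non-negative")
    if repair_median <= 0:
        raise ValueError(f"repair_median must be positive, got {repair_median}")
    if max_repairs < 0:
        raise ValueError(f"max_repairs must be >= 0, got {max_repairs}")


def count_repairs(
    residual,
    repair_median: float,
    max_repairs: int,
    rng: np.random.Generator,
    method: str = "poisson",
) -> np.ndarray:
    """Number of repairs of one restored surface within the residual lifetime.

    Vectorized over ``residual`` (months).  ``method="poisson"`` draws the
    Poisson-process event count directly and clips it at ``max_repairs``;
    ``method="sequential"`` draws the first ``max_repairs`` exponential
    inter-repair times and counts how many cumulative sums fall strictly
    below the residual lifetime.  The two routes sample the same
    distribution exactly (ties have probability zero).
    """
    residual = np.atleast_1d(np.asarray(residual, dtype=float))
    _validate(residual, repair_median, max_repairs)
    if max_repairs == 0:
        return np.zeros(residual.shape, dtype=np.int64)
    if method == "poisson":
        lam = LN2 * residual / repair_median
        return np.minimum(rng.poisson(lam), max_repairs).astype(np.int64)
    if method == "sequential":
        gaps = rng.exponential(
            repair_median / LN2, size=(residual.size, max_repairs)
        )
        arrival = np.cumsum(gaps, axis=1)
        return np.count_nonzero(
            arrival < residual[:, None], axis=1
        ).astype(np.int64)
    raise ValueError(f"unknown method: {method!r}")


def total_repairs(
    n_defects: np.ndarray,
    residual: np.ndarray,
    repair_median: float,
    max_repairs: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-patient total repair count over all of that patient's surfaces.

    Each of the ``n_defects[i]`` restored surfaces of patient ``i`` runs an
    independent chain against the same residual lifetime; totals are the sum
    of the per-surface chain lengths.
    """
    n_defects = np.asarray(n_defects)
    residual = np.asarray(residual, dtype=float)
    if n_defects.shape != residual.shape:
        raise ValueError("n_defects and residual must have the same length")
    _validate(residual, repair_median, max_repairs)
    idx = np.repeat(np.arange(n_defects.size), n_defects)
    per_surface = count_repairs(residual[idx], repair_median, max_repairs, rng)
    return np.bincount(idx, weights=per_surface, minlength=n_defects.size).astype(
        np.int64
    )


def expected_repairs(residual, repair_median: float, max_repairs: int):
    """Expected chain length: E[min(N, max_repairs)], N ~ Poisson(ln2·t/median).

    Evaluated by direct summation of the Poisson pmf,
    ``sum_{k<max} k·P(N=k) + max·P(N>=max)``; as ``max_repairs`` grows it
    approaches the uncapped mean ``ln 2 · residual / repair_median``.
    Vectorized over ``residual``.
    """
    residual = np.asarray(residual, dtype=float)
    _validate(np.atleast_1d(residual), repair_median, max_repairs)
    if max_repairs == 0:
        out = np.zeros(residual.shape)
        return out if out.ndim else float(out)
    lam = LN2 * residual / repair_median
    k = np.arange(max_repairs)
    body = np.sum(k * stats.poisson.pmf(k, lam[..., None]), axis=-1)
    tail = max_repairs * stats.poisson.sf(max_repairs - 1, lam)
    out = body + tail
    return out if out.ndim else float(out)
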