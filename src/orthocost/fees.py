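"""German private dental fee catalogue (GOZ) items and per-event treatment costs.

Only two preventive-dentistry events are priced in this model: a single
topical fluoridation (GOZ 1020) and a single-surface adhesive composite
restoration (GOZ 2030 + 2040 + 2060).  Fees are the catalogue amounts at the
two customary increment factors, 2.3 (standard) and 3.5 (maximum), and are
held as exact decimal cents so that event totals are cent-exact; anaesthesia
and radiograph positions are intentionally absent.

Also provides the survival-point → exponential-median conversion used to turn
a published restoration survival rate (e.g. "80 % survive 10 years") into the
median repair time of the shape-1 Weibull (exponential) repair model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal
from typing import Iterable, Literal

from .errors import ConfigurationError

Event = Literal["fluoridation", "restoration"]

#: Fee increment factors the schedule carries amounts for.
FACTORS = (2.3, 3.5)


def _as_money(value) -> Decimal:
    """Coerce a fee to an exact Decimal amount (floats go through str)."""
    if isinstance(value, Decimal):
        return value
    return Decimal(str(value))


@dataclass(frozen=True)
class FeeItem:
    """One GOZ fee position with its Eur amount at each increment factor."""

    goz_position: str
    label: str
    fee_2_3: Decimal
    fee_3_5: Decimal

    def __post_init__(self):
        object.__setattr__(self, "fee_2_3", _as_money(self.fee_2_3))
        object.__setattr__(self, "fee_3_5", _as_money(self.fee_3_5))
        if self.fee_2_3 < 0 or self.fee_3_5 < 0:
            raise ConfigurationError(
                f"GOZ {self.goz_position}: fees must be non-negative"
            )
        if self.fee_3_5 < self.fee_2_3:
            raise ConfigurationError(
                f"GOZ {self.goz_position}: factor-3.5 fee below factor-2.3 fee"
            )

    def fee(self, factor: float) -> Decimal:
        if factor == 2.3:
            return self.fee_2_3
        if factor == 3.5:
            return self.fee_3_5
        raise ConfigurationError(f"unknown fee increment factor: {factor!r}")


@dataclass(frozen=True)
class FeeSchedule:
    """Fee items per treatment event (fluoridation vs composite restoration)."""

    fluoridation_items: tuple[FeeItem, ...]
    restoration_items: tuple[FeeItem, ...]

    def __post_init__(self):
        object.__setattr__(self, "fluoridation_items", tuple(self.fluoridation_items))
        object.__setattr__(self, "restoration_items", tuple(self.restoration_items))
        if not self.fluoridation_items or not self.restoration_items:
            raise ConfigurationError("fee schedule must price both event types")

    def items_for(self, event: Event) -> tuple[FeeItem, ...]:
        if event == "fluoridation":
            return self.fluoridation_items
        if event == "restoration":
            return self.restoration_items
        raise ConfigurationError(f"unknown treatment event: {event!r}")


def default_fee_schedule() -> FeeSchedule:
    """The GOZ amounts used throughout: 6.47/9.84 Eur per fluoridation and
    84.99/129.34 Eur per single-surface restoration at factors 2.3/3.5."""
    return FeeSchedule(
        fluoridation_items=(
            FeeItem("1020", "Topical fluoridation", Decimal("6.47"), Decimal("9.84")),
        ),
        restoration_items=(
            FeeItem(
                "2030",
                "Specific measures during preparation or filling",
                Decimal("8.41"),
                Decimal("12.80"),
            ),
            FeeItem("2040", "Use of rubberdam", Decimal("8.41"), Decimal("12.80")),
            FeeItem(
                "2060",
                "Adhesive restoration, one surface",
                Decimal("68.17"),
                Decimal("103.74"),
            ),
        ),
    )


def treatment_cost(schedule: FeeSchedule, event: Event, factor: float) -> Decimal:
    """Total cost of one treatment event at a fee factor, exact to the cent.

    Sums the schedule's per-item amounts for the event: one fluoridation
    session, or one single-surface composite restoration (the same total is
    charged for each re-restoration cycle).

    Raises
    ------
    ConfigurationError
        If ``event`` or ``factor`` is not covered by the schedule.
    """
    if factor not in FACTORS:
        raise ConfigurationError(f"unknown fee increment factor: {factor!r}")
    return sum((item.fee(factor) for item in schedule.items_for(event)), Decimal(0))


def load_fee_schedule(mapping: dict) -> FeeSchedule:
    """Build a FeeSchedule from a config mapping (e.g. a parsed YAML block).

    Expected shape::

        fluoridation: [{goz_position, label, fee_2_3, fee_3_5}, ...]
        restoration:  [...]
    """
    if not isinstance(mapping, dict):
        raise ConfigurationError("fees: expected a mapping")
    unknown = set(mapping) - {"fluoridation", "restoration"}
    if unknown:
        raise ConfigurationError(f"fees: unknown key {sorted(unknown)[0]!r}")

    def build(items: Iterable[dict], section: str) -> tuple[FeeItem, ...]:
        out = []
        for raw in items:
            extra = set(raw) - {"goz_position", "label", "fee_2_3", "fee_3_5"}
            if extra:
                raise ConfigurationError(
                    f"fees.{section}: unknown key {sorted(extra)[0]!r}"
                )
            try:
                out.append(
                    FeeItem(
                        str(raw["goz_position"]),
                        str(raw.get("label", "")),
                        raw["fee_2_3"],
                        raw["fee_3_5"],
                    )
                )
            except KeyError as exc:
                raise ConfigurationError(
                    f"fees.{section}: missing key {exc.args[0]!r}"
                ) from None
        return tuple(out)

    default = default_fee_schedule()
    return FeeSchedule(
        fluoridation_items=build(mapping["fluoridation"], "fluoridation")
        if "fluoridation" in mapping
        else default.fluoridation_items,
        restoration_items=build(mapping["restoration"], "restoration")
        if "restoration" in mapping
        else default.restoration_items,
    )


def median_from_survival(surv_frac: float, at_time: float) -> float:
    """Median lifetime of an exponential model pinned to one survival point.

    If a fraction ``surv_frac`` of restorations survive to ``at_time``, the
    exponential (shape-1 Weibull) hazard is λ = −log(surv_frac)/at_time and
    the implied median is −log(0.5)/λ.  Units follow ``at_time``.

    Examples
    --------
    >>> round(median_from_survival(0.8, 10), 2)   # 80 % survival at 10 y
    31.06
    >>> median_from_survival(0.5, 15.0)           # a median maps to itself
    15.0
    """
    if not 0.0 < surv_frac < 1.0:
        raise ValueError(f"survival fraction must lie in (0, 1), got {surv_frac}")
    if at_time <= 0:
        raise ValueError(f"survival time point must be positive, got {at_time}")
    lam = -math.log(surv_frac) / at_time
    return -math.log(0.5) / lam
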