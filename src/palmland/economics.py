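"""25-year discounted cash-flow economics of oil-palm cultivation.

The model prices one hectare of plantation over a 25-year crop life.
Revenue is the sale of fresh fruit bunches (FFB) at a constant price
(default US$178/t, a 2011 east-Sabah average).  The full-stand yield curve
is zero in the two immature years, ramps to a 30 t FFB/ha plateau in peak
years 8-11, declines to 17 t in year 25, and averages exactly 21.92 t over
the crop life.  Palm capacity c (the standing fraction of the 136
stands-per-hectare full planting density) scales yield proportionally.

Costs have three components: fixed general charges and field upkeep
(USD/ha/yr), harvesting-and-transport proportional to yield (USD/t), and a
"supplying" (replanting) charge in years 1-2 proportional to the missing
capacity (1 - c).  Net flows are discounted at a per-annum rate (default
11%, sensitivity set 5/8/14%) and the NPV is annualized as total/25.

The absolute cost levels are not published, so :func:`calibrate_costs`
solves them in closed form from two anchor points — the full-stand class
endpoints (capacity 0.76 -> $413/ha/yr, 1.00 -> $637/ha/yr at 11%).
Because every cost term is affine in capacity, the calibrated model's NPV
at any other capacity lies exactly on the two-anchor line, independent of
the supplying base.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "HORIZON_YEARS",
    "DEFAULT_PRICE",
    "DEFAULT_DISCOUNT_RATE",
    "SENSITIVITY_RATES",
    "FULL_STAND_SPH",
    "PRODUCTIVITY_CLASSES",
    "YieldCurve",
    "CostSchedule",
    "EconomicScenario",
    "CashFlowSeries",
    "NPVResult",
    "ProductivityClass",
    "build_default_yield_curve",
    "scale_yield",
    "cash_flows",
    "npv",
    "annualized_npv",
    "calibrate_costs",
    "sensitivity_table",
    "breakeven_capacity",
    "CalibrationError",
]

HORIZON_YEARS = 25
DEFAULT_PRICE = 178.0           # USD per t FFB (2011 average)
DEFAULT_DISCOUNT_RATE = 0.11    # industry rate, 2011
SENSITIVITY_RATES = (0.05, 0.08, 0.11, 0.14)
FULL_STAND_SPH = 136            # stands per hectare at 100% palm capacity

#: Default anchors for cost calibration: full-stand class endpoints at 11%
#: discount, (capacity, annualized NPV USD/ha/yr).
DEFAULT_ANCHORS = ((0.76, 413.0), (1.00, 637.0))


class CalibrationError(ValueError):
    """Anchors cannot be met with non-negative cost components."""


@dataclass(frozen=True)
class ProductivityClass:
    """An oil-palm productivity class defined as a palm-capacity range."""

    name: str
    capacity_low: float
    capacity_high: float

    @property
    def capacity_bounds(self) -> tuple[float, float]:
        return (self.capacity_low, self.capacity_high)


#: The four modelled productivity classes with their nominal capacity
#: endpoints (fractions of 136 SPH).
PRODUCTIVITY_CLASSES = (
    ProductivityClass("full_stand", 0.76, 1.00),
    ProductivityClass("up75", 0.51, 0.75),
    ProductivityClass("up50", 0.26, 0.50),
    ProductivityClass("up25", 0.00, 0.25),
)


@dataclass(frozen=True)
class YieldCurve:
    """Annual FFB yields (t/ha) for crop years 1..25."""

    yields: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.yields) != HORIZON_YEARS:
            raise ValueError(
                f"yield curve must cover exactly {HORIZON_YEARS} years, "
                f"got {len(self.yields)}"
            )
        if any(y < 0 for y in self.yields):
            raise ValueError("yields must be non-negative")

    def __getitem__(self, year: int) -> float:
        """Yield in crop year ``year`` (1-based)."""
        if not 1 <= year <= HORIZON_YEARS:
            raise IndexError(f"crop year must be in 1..{HORIZON_YEARS}")
        return self.yields[year - 1]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.yields, dtype=float)

    @property
    def mean(self) -> float:
        return float(np.mean(self.yields))


@dataclass(frozen=True)
class CostSchedule:
    """Annual per-hectare cost structure.

    ``general_charges`` and ``field_upkeep`` are fixed USD/ha/yr;
    ``harvest_transport_rate`` is USD per t FFB (the only yield-proportional
    component); ``supplying_base`` is the USD/ha replanting charge applied in
    years 1-2, scaled by the missing capacity (1 - c).
    """

    general_charges: float
    field_upkeep: float
    harvest_transport_rate: float
    supplying_base: float = 0.0

    def __post_init__(self) -> None:
        for name in ("general_charges", "field_upkeep",
                     "harvest_transport_rate", "supplying_base"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def fixed_annual(self) -> float:
        return self.general_charges + self.field_upkeep


@dataclass(frozen=True)
class EconomicScenario:
    price: float = DEFAULT_PRICE
    discount_rate: float = DEFAULT_DISCOUNT_RATE
    capacity: float = 1.0
    horizon: int = HORIZON_YEARS

    def __post_init__(self) -> None:
        if self.price <= 0:
            raise ValueError("price must be > 0")
        if not 0.0 <= self.capacity <= 1.0:
            raise ValueError(f"capacity must be in [0, 1], got {self.capacity}")
        if self.discount_rate <= -1.0:
            raise ValueError("discount rate must exceed -100%")


@dataclass(frozen=True)
class CashFlowSeries:
    """Net USD/ha flows for years 1..25."""

    net_flows: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.net_flows) != HORIZON_YEARS:
            raise ValueError(f"cash-flow series must have {HORIZON_YEARS} entries")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.net_flows, dtype=float)


@dataclass(frozen=True)
class NPVResult:
    npv_total: float        # USD/ha over the 25-year crop life
    npv_annualized: float   # USD/ha/yr = total / 25


def build_default_yield_curve() -> YieldCurve:
    """The default full-stand (136 SPH) yield curve.

    Years 1-2 immature (zero yield); a monotone ramp over years 3-7
    (11.5, 17, 22, 26, 29 t); the 30 t peak plateau in years 8-11; linear
    decline from the plateau to 17 t in year 25.  The curve sums to 548.0 t,
    so the 25-year mean is exactly 21.92 t FFB/ha/yr.
    """
    ramp = [11.5, 17.0, 22.0, 26.0, 29.0]
    peak = [30.0] * 4
    # linear decline years 12..25: 30 - k * 13/14, k = 1..14, ending at 17
    decline = [30.0 - k * 13.0 / 14.0 for k in range(1, 15)]
    return YieldCurve(tuple([0.0, 0.0] + ramp + peak + decline))


def scale_yield(curve: YieldCurve, capacity: float) -> YieldCurve:
    """Scale every year's yield by palm capacity (direct proportionality
    between standing palms and yield).

    Raises
    ------
    ValueError
        If capacity lies outside [0, 1].
    """
    if not 0.0 <= capacity <= 1.0:
        raise ValueError(f"capacity must be in [0, 1], got {capacity}")
    return YieldCurve(tuple(y * capacity for y in curve.yields))


def cash_flows(curve: YieldCurve, costs: CostSchedule,
               scenario: EconomicScenario) -> CashFlowSeries:
    """Annual net flows: revenue minus fixed, yield-proportional and
    supplying costs.

    ``curve`` is the full-stand curve; it is scaled by the scenario's
    capacity here.  Supplying applies in years 1-2 only, at
    ``supplying_base * (1 - capacity)``.
    """
    c = scenario.capacity
    y = scale_yield(curve, c).as_array()
    net = (scenario.price * y
           - costs.fixed_annual
           - costs.harvest_transport_rate * y)
    net[:2] -= costs.supplying_base * (1.0 - c)
    return CashFlowSeries(tuple(float(v) for v in net))


def npv(series: CashFlowSeries, rate: float) -> NPVResult:
    """Discounted sum of the 25 net flows; annualized as total / 25.

    Raises
    ------
    ValueError
        If the rate does not exceed -100%.
    """
    if rate <= -1.0:
        raise ValueError("discount rate must exceed -100%")
    t = np.arange(1, HORIZON_YEARS + 1, dtype=float)
    total = float(np.sum(series.as_array() / (1.0 + rate) ** t))
    return NPVResult(npv_total=total, npv_annualized=total / HORIZON_YEARS)


def annualized_npv(curve: YieldCurve, costs: CostSchedule, capacity: float,
                   rate: float, price: float = DEFAULT_PRICE) -> float:
    """Convenience: annualized NPV (USD/ha/yr) of one capacity scenario."""
    scenario = EconomicScenario(price=price, discount_rate=rate, capacity=capacity)
    return npv(cash_flows(curve, costs, scenario), rate).npv_annualized


def calibrate_costs(anchor_low: tuple[float, float] = DEFAULT_ANCHORS[0],
                    anchor_high: tuple[float, float] = DEFAULT_ANCHORS[1],
                    curve: YieldCurve | None = None,
                    price: float = DEFAULT_PRICE,
                    rate: float = DEFAULT_DISCOUNT_RATE,
                    supplying_base: float = 15.0,
                    general_share: float = 0.35) -> CostSchedule:
    """Solve the cost schedule so the model reproduces two anchor NPVs.

    With discount factors d_t, discounted yield sum Y = sum(y_t d_t),
    annuity D = sum(d_t) and E = d_1 + d_2, the annualized NPV is affine in
    capacity c:

        A(c) = [c (p - h) Y  -  F D  -  S0 (1 - c) E] / 25

    Two anchors (c1, A1), (c2, A2) determine the yield-proportional harvest
    rate h and the total fixed cost F in closed form; F is split between
    general charges and field upkeep by ``general_share``.  The supplying
    base S0 is not identifiable from the anchors (it is absorbed into the
    line) and is passed through as a small default.

    Raises
    ------
    CalibrationError
        If the anchors share a capacity or would force a negative cost
        component.
    """
    if curve is None:
        curve = build_default_yield_curve()
    (c1, a1), (c2, a2) = anchor_low, anchor_high
    if c1 == c2:
        raise CalibrationError("anchor capacities must differ")
    t = np.arange(1, HORIZON_YEARS + 1, dtype=float)
    d = (1.0 + rate) ** -t
    Y = float(np.sum(curve.as_array() * d))
    D = float(np.sum(d))
    E = float(d[0] + d[1])
    # A(c)*25 = c*(p-h)*Y - F*D - S0*(1-c)*E ; subtract the two anchor rows
    slope = (a2 * HORIZON_YEARS - a1 * HORIZON_YEARS) / (c2 - c1)
    pmh = (slope - supplying_base * E) / Y          # p - h
    F_D = c2 * pmh * Y - supplying_base * (1 - c2) * E - a2 * HORIZON_YEARS
    fixed = F_D / D
    harvest = price - pmh
    if harvest < 0 or fixed < 0:
        raise CalibrationError(
            f"anchors infeasible: harvest rate {harvest:.2f}, fixed {fixed:.2f}"
        )
    return CostSchedule(
        general_charges=general_share * fixed,
        field_upkeep=(1.0 - general_share) * fixed,
        harvest_transport_rate=harvest,
        supplying_base=supplying_base,
    )


def sensitivity_table(curve: YieldCurve, costs: CostSchedule,
                      capacities: list[float] | None = None,
                      rates: tuple[float, ...] = SENSITIVITY_RATES,
                      price: float = DEFAULT_PRICE) -> pd.DataFrame:
    """Annualized NPV (USD/ha/yr) per (capacity, discount rate).

    Rows are capacities, columns the discount rates as percentages, mirroring
    the class-endpoint x rate layout of the published sensitivity table.

    Raises
    ------
    ValueError
        On empty capacities or rates.
    """
    if capacities is None:
        capacities = sorted(
            {b for cls in PRODUCTIVITY_CLASSES for b in cls.capacity_bounds}
        )
    if not capacities or not rates:
        raise ValueError("capacities and rates must be non-empty")
    data = {
        f"{int(round(r * 100))}%": [
            annualized_npv(curve, costs, c, r, price=price) for c in capacities
        ]
        for r in rates
    }
    return pd.DataFrame(data, index=pd.Index(capacities, name="capacity"))


def breakeven_capacity(curve: YieldCurve, costs: CostSchedule,
                       rate: float = DEFAULT_DISCOUNT_RATE,
                       price: float = DEFAULT_PRICE,
                       tol: float = 0.01) -> float:
    """Capacity c* at which the annualized NPV crosses zero, by bisection.

    Raises
    ------
    ValueError
        If NPV(0) and NPV(1) do not straddle zero.
    """
    lo, hi = 0.0, 1.0
    f_lo = annualized_npv(curve, costs, lo, rate, price=price)
    f_hi = annualized_npv(curve, costs, hi, rate, price=price)
    if not (f_lo < 0.0 < f_hi):
        raise ValueError(
            f"no sign change over capacity [0, 1]: NPV(0)={f_lo:.1f}, NPV(1)={f_hi:.1f}"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = annualized_npv(curve, costs, mid, rate, price=price)
        if abs(f_mid) < tol:
            return mid
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
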