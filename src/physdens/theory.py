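"""Two-region economic model of physician practice location.

A representative household with Cobb-Douglas preferences demands GP and
specialist services; each visit carries a money price (after co-insurance)
and a time cost that falls with regional physician density.  Physicians
locate so that rural income equals a preference-weighted multiple of urban
income.  The module provides the closed-form demand system, an independent
numeric utility-maximization oracle, the regional equilibrium solver and
comparative statics over any single parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import DegenerateInputError, DomainError, SolverError

__all__ = [
    "HouseholdParams",
    "DemandBundle",
    "RegionGeometry",
    "TimeCostParams",
    "SupplySideParams",
    "EquilibriumSolution",
    "time_cost",
    "optimal_demand",
    "oracle_max_utility",
    "physician_income",
    "closed_form_urban_rural_ratio",
    "sp_gp_ratio_multiplier",
    "solve_equilibrium",
    "comparative_statics",
    "DEFAULT_HOUSEHOLD",
    "DEFAULT_GEOMETRY",
    "DEFAULT_TIME_COST",
    "DEFAULT_SUPPLY",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HouseholdParams:
    """Consumer-side parameters.

    Attributes
    ----------
    income : gross income per period.
    payroll_tax : health-insurance payroll tax rate, in [0, 1).
    coinsurance : out-of-pocket share of the service price, in [0, 1].
    price_gp, price_sp : prices per service unit.
    time_value : opportunity cost of one unit of time.
    time_budget : total time endowment per period.
    pref_gp, pref_sp, pref_other : Cobb-Douglas exponents; the specialist
        exponent must exceed the GP exponent.
    """

    income: float = 1.0
    payroll_tax: float = 0.0
    coinsurance: float = 0.0
    price_gp: float = 1.0
    price_sp: float = 1.0
    time_value: float = 1.0
    time_budget: float = 1.0
    pref_gp: float = 1.0
    pref_sp: float = 2.0
    pref_other: float = 1.0

    def __post_init__(self):
        if not (self.income > 0 and self.time_budget > 0 and self.time_value > 0):
            raise DomainError("income, time_budget and time_value must be positive")
        if not (self.price_gp > 0 and self.price_sp > 0):
            raise DomainError("service prices must be positive")
        if not 0 <= self.payroll_tax < 1:
            raise DomainError("payroll_tax must lie in [0, 1)")
        if not 0 <= self.coinsurance <= 1:
            raise DomainError("coinsurance must lie in [0, 1]")
        if not (self.pref_gp > 0 and self.pref_other > 0):
            raise DomainError("preference exponents must be positive")
        if not self.pref_sp > self.pref_gp:
            raise DomainError("specialist preference must exceed GP preference")

    @property
    def full_income(self) -> float:
        """Net money income plus the monetary value of the time endowment."""
        return self.income * (1.0 - self.payroll_tax) + self.time_value * self.time_budget


@dataclass(frozen=True)
class DemandBundle:
    """Utility-maximizing consumption plan of the representative household.

    ``other_consumption`` equals ``goods_spend + time_value * leisure`` by
    construction; only the merged money-and-time budget is binding, so
    ``leisure`` may come out negative for extreme parameters.
    """

    demand_gp: float
    demand_sp: float
    other_consumption: float
    leisure: float
    goods_spend: float

    def budget_residual(self, h: HouseholdParams, t_gp: float, t_sp: float) -> float:
        """Residual of the merged money/time constraint (0 at an optimum)."""
        k_gp = h.coinsurance * h.price_gp + h.time_value * t_gp
        k_sp = h.coinsurance * h.price_sp + h.time_value * t_sp
        return (
            self.other_consumption
            - h.full_income
            + k_gp * self.demand_gp
            + k_sp * self.demand_sp
        )


@dataclass(frozen=True)
class RegionGeometry:
    """Equal-population two-region layout; the rural region is larger."""

    population_per_region: float = 100_000.0
    area_urban: float = 100.0
    area_rural: float = 400.0

    def __post_init__(self):
        if self.population_per_region <= 0:
            raise DomainError("population must be positive")
        if not 0 < self.area_urban <= self.area_rural:
            raise DomainError("need 0 < area_urban <= area_rural")

    @property
    def area_ratio(self) -> float:
        return self.area_rural / self.area_urban


@dataclass(frozen=True)
class TimeCostParams:
    """Elasticities linking physician density to per-visit time cost."""

    q_gp: float = 0.3
    q_sp: float = 0.5

    def __post_init__(self):
        if not (0 < self.q_gp < 1 and 0 < self.q_sp < 1):
            raise DomainError("time-cost elasticities must lie in (0, 1)")
        if self.q_sp < self.q_gp:
            raise DomainError("specialist elasticity must be >= GP elasticity")


@dataclass(frozen=True)
class SupplySideParams:
    """Per-service margins and the rural income premium physicians demand."""

    margin_gp: float = 0.5
    margin_sp: float = 0.5
    preference_weight: float = 1.2
    preference_weight_sp: float | None = None  # optional per-type weight

    def __post_init__(self):
        if not (self.margin_gp > 0 and self.margin_sp > 0):
            raise DomainError("service margins must be positive")
        if self.preference_weight < 1:
            raise DomainError("preference weight must be >= 1")
        if self.preference_weight_sp is not None and self.preference_weight_sp < 1:
            raise DomainError("specialist preference weight must be >= 1")

    @property
    def w_gp(self) -> float:
        return self.preference_weight

    @property
    def w_sp(self) -> float:
        return (
            self.preference_weight
            if self.preference_weight_sp is None
            else self.preference_weight_sp
        )


@dataclass(frozen=True)
class EquilibriumSolution:
    """Urban/rural allocation with incomes, demands and residuals."""

    gp_urban: float
    gp_rural: float
    sp_urban: float
    sp_rural: float
    income_gp_urban: float
    income_gp_rural: float
    income_sp_urban: float
    income_sp_rural: float
    demand_urban: DemandBundle
    demand_rural: DemandBundle
    residual_gp: float
    residual_sp: float

    @property
    def gp_ratio(self) -> float:
        return self.gp_urban / self.gp_rural

    @property
    def sp_ratio(self) -> float:
        return self.sp_urban / self.sp_rural


DEFAULT_HOUSEHOLD = HouseholdParams()
DEFAULT_GEOMETRY = RegionGeometry()
DEFAULT_TIME_COST = TimeCostParams()
DEFAULT_SUPPLY = SupplySideParams()


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def time_cost(count: float, area: float, q: float) -> float:
    """Per-visit time cost ``(count/area) ** -q``.

    Strictly decreasing in physician density ``count/area``.
    """
    if count <= 0 or area <= 0:
        raise DomainError("count and area must be positive")
    if not 0 < q < 1:
        raise DomainError("elasticity q must lie in (0, 1)")
    return (count / area) ** (-q)


def _visit_costs(h: HouseholdParams, t_gp: float, t_sp: float) -> tuple[float, float]:
    """Full per-visit cost (money share + time value) for each service type."""
    k_gp = h.coinsurance * h.price_gp + h.time_value * t_gp
    k_sp = h.coinsurance * h.price_sp + h.time_value * t_sp
    return k_gp, k_sp


def optimal_demand(h: HouseholdParams, t_gp: float, t_sp: float) -> DemandBundle:
    """Closed-form utility-maximizing demand bundle.

    The Cobb-Douglas structure splits full income across the three goods in
    proportion to the preference exponents, each physician service deflated
    by its full per-visit cost.
    """
    if t_gp <= 0 or t_sp <= 0:
        raise DomainError("time costs must be positive")
    full = h.full_income
    if full <= 0:
        raise DegenerateInputError("full income must be positive")
    k_gp, k_sp = _visit_costs(h, t_gp, t_sp)
    total_pref = h.pref_gp + h.pref_sp + h.pref_other
    a_demand = h.pref_gp * full / (k_gp * total_pref)
    s_demand = h.pref_sp * full / (k_sp * total_pref)
    z = h.pref_other * full / total_pref
    goods = (
        h.income * (1.0 - h.payroll_tax)
        - h.coinsurance * h.price_gp * a_demand
        - h.coinsurance * h.price_sp * s_demand
    )
    leisure = h.time_budget - t_gp * a_demand - t_sp * s_demand
    return DemandBundle(
        demand_gp=a_demand,
        demand_sp=s_demand,
        other_consumption=z,
        leisure=leisure,
        goods_spend=goods,
    )


def oracle_max_utility(
    h: HouseholdParams,
    t_gp: float,
    t_sp: float,
    *,
    xtol: float = 1e-10,
    maxiter: int = 500,
) -> DemandBundle:
    """Numerically maximize utility subject to the merged budget.

    Independent check on :func:`optimal_demand`: maximizes the log utility
    ``a*ln A + s*ln S + z*ln Z`` over ``(ln A, ln S)`` with ``Z`` eliminated
    through the budget.  Raises :class:`SolverError` on non-convergence.
    """
    if t_gp <= 0 or t_sp <= 0:
        raise DomainError("time costs must be positive")
    full = h.full_income
    if full <= 0:
        raise DegenerateInputError("full income must be positive")
    k_gp, k_sp = _visit_costs(h, t_gp, t_sp)

    def neg_log_utility(x: np.ndarray) -> float:
        a_d, s_d = np.exp(x)
        z = full - k_gp * a_d - k_sp * s_d
        if z <= 0:
            return np.inf
        return -(h.pref_gp * x[0] + h.pref_sp * x[1] + h.pref_other * np.log(z))

    # start from an interior equal split of the budget
    x0 = np.log([full / (3 * k_gp), full / (3 * k_sp)])
    res = optimize.minimize(
        neg_log_utility,
        x0,
        method="Nelder-Mead",
        options={"xatol": xtol, "fatol": xtol, "maxiter": maxiter * 10},
    )
    if not res.success:
        raise SolverError(
            "utility maximization did not converge",
            diagnostics={"message": res.message, "x": res.x.tolist(), "fun": res.fun},
        )
    a_d, s_d = np.exp(res.x)
    z = full - k_gp * a_d - k_sp * s_d
    goods = (
        h.income * (1.0 - h.payroll_tax)
        - h.coinsurance * h.price_gp * a_d
        - h.coinsurance * h.price_sp * s_d
    )
    leisure = h.time_budget - t_gp * a_d - t_sp * s_d
    return DemandBundle(a_d, s_d, z, leisure, goods)


def physician_income(
    margin: float, percap_demand: float, n: float, count: float
) -> float:
    """Income per physician: margin x per-capita demand x population / count."""
    if count <= 0:
        raise DomainError("physician count must be positive")
    if margin <= 0 or percap_demand <= 0 or n <= 0:
        raise DomainError("margin, demand and population must be positive")
    return margin * percap_demand * n / count


def closed_form_urban_rural_ratio(q: float, geometry: RegionGeometry, w: float) -> float:
    """Urban/rural physician count ratio in the zero-coinsurance equilibrium.

    ``(m_r/m_u)**(q/(1-q)) * w**(1/(1-q))``; at least 1 whenever ``w >= 1``
    and the rural region is at least as large as the urban one.
    """
    if not 0 < q < 1:
        raise DomainError("q must lie in (0, 1)")
    if w < 1:
        raise DomainError("preference weight must be >= 1")
    ratio = geometry.area_ratio
    return ratio ** (q / (1.0 - q)) * w ** (1.0 / (1.0 - q))


def sp_gp_ratio_multiplier(tc: TimeCostParams, geometry: RegionGeometry) -> float:
    """Factor by which the urban SP/GP mix exceeds the rural one.

    Equals the ratio of the two closed-form urban/rural ratios at w = 1:
    ``(m_r/m_u)**((q_S - q_A)/((1-q_A)(1-q_S)))``.
    """
    expo = (tc.q_sp - tc.q_gp) / ((1.0 - tc.q_gp) * (1.0 - tc.q_sp))
    return geometry.area_ratio**expo


# ---------------------------------------------------------------------------
# regional equilibrium
# ---------------------------------------------------------------------------

_BRACKET_EPS = 1e-9


def _solve_one_type(
    total: float,
    q: float,
    margin: float,
    pref: float,
    price: float,
    w: float,
    h: HouseholdParams,
    geometry: RegionGeometry,
) -> tuple[float, float, float, float, float]:
    """Split one physician type across regions so rural income = w x urban.

    Demand for each type depends only on its own time cost, so the two
    markets decouple and each reduces to a scalar root-finding problem in
    the urban count.  Returns (urban, rural, income_u, income_r, residual).
    """
    total_pref = h.pref_gp + h.pref_sp + h.pref_other
    full = h.full_income
    n = geometry.population_per_region

    def income(count: float, area: float) -> float:
        t = time_cost(count, area, q)
        k = h.coinsurance * price + h.time_value * t
        demand = pref * full / (k * total_pref)
        return physician_income(margin, demand, n, count)

    def gap(urban: float) -> float:
        rural = total - urban
        return income(rural, geometry.area_rural) - w * income(urban, geometry.area_urban)

    lo = _BRACKET_EPS * total
    hi = (1.0 - _BRACKET_EPS) * total
    g_lo, g_hi = gap(lo), gap(hi)
    if not (g_lo < 0 < g_hi):
        raise SolverError(
            "equilibrium root not bracketed",
            diagnostics={"gap_low": g_lo, "gap_high": g_hi, "total": total},
        )
    urban = optimize.brentq(gap, lo, hi, xtol=1e-14 * total, rtol=8.9e-16)
    rural = total - urban
    inc_u = income(urban, geometry.area_urban)
    inc_r = income(rural, geometry.area_rural)
    residual = (inc_r - w * inc_u) / inc_u
    return urban, rural, inc_u, inc_r, residual


def solve_equilibrium(
    gp_total: float,
    sp_total: float,
    h: HouseholdParams = DEFAULT_HOUSEHOLD,
    geometry: RegionGeometry = DEFAULT_GEOMETRY,
    tc: TimeCostParams = DEFAULT_TIME_COST,
    supply: SupplySideParams = DEFAULT_SUPPLY,
) -> EquilibriumSolution:
    """Allocate fixed totals of GPs and specialists across the two regions.

    Works for any coinsurance rate; at zero coinsurance the resulting ratios
    match :func:`closed_form_urban_rural_ratio`.
    """
    if gp_total <= 0 or sp_total <= 0:
        raise DomainError("physician totals must be positive")
    gp_u, gp_r, yau, yar, res_gp = _solve_one_type(
        gp_total, tc.q_gp, supply.margin_gp, h.pref_gp, h.price_gp,
        supply.w_gp, h, geometry,
    )
    sp_u, sp_r, ysu, ysr, res_sp = _solve_one_type(
        sp_total, tc.q_sp, supply.margin_sp, h.pref_sp, h.price_sp,
        supply.w_sp, h, geometry,
    )
    t_gp_u = time_cost(gp_u, geometry.area_urban, tc.q_gp)
    t_sp_u = time_cost(sp_u, geometry.area_urban, tc.q_sp)
    t_gp_r = time_cost(gp_r, geometry.area_rural, tc.q_gp)
    t_sp_r = time_cost(sp_r, geometry.area_rural, tc.q_sp)
    return EquilibriumSolution(
        gp_urban=gp_u,
        gp_rural=gp_r,
        sp_urban=sp_u,
        sp_rural=sp_r,
        income_gp_urban=yau,
        income_gp_rural=yar,
        income_sp_urban=ysu,
        income_sp_rural=ysr,
        demand_urban=optimal_demand(h, t_gp_u, t_sp_u),
        demand_rural=optimal_demand(h, t_gp_r, t_sp_r),
        residual_gp=res_gp,
        residual_sp=res_sp,
    )


# ---------------------------------------------------------------------------
# comparative statics
# ---------------------------------------------------------------------------

_VARYABLE = {
    "preference_weight": ("supply", "preference_weight"),
    "coinsurance": ("household", "coinsurance"),
    "area_ratio": ("geometry", "area_rural"),
    "q_gp": ("tc", "q_gp"),
    "q_sp": ("tc", "q_sp"),
    "payroll_tax": ("household", "payroll_tax"),
    "time_value": ("household", "time_value"),
}


def comparative_statics(
    vary: str,
    grid,
    *,
    gp_total: float = 100.0,
    sp_total: float = 50.0,
    h: HouseholdParams = DEFAULT_HOUSEHOLD,
    geometry: RegionGeometry = DEFAULT_GEOMETRY,
    tc: TimeCostParams = DEFAULT_TIME_COST,
    supply: SupplySideParams = DEFAULT_SUPPLY,
) -> pd.DataFrame:
    """Solve the equilibrium along a one-parameter grid.

    ``vary='area_ratio'`` rescales the rural area with the urban area held
    fixed.  Grid points where the solver fails yield NaN rows rather than
    aborting the sweep.
    """
    if vary not in _VARYABLE:
        raise DomainError(f"unknown parameter {vary!r}; one of {sorted(_VARYABLE)}")
    holder_name, attr = _VARYABLE[vary]
    rows = []
    for value in grid:
        holders = {"household": h, "geometry": geometry, "tc": tc, "supply": supply}
        try:
            if vary == "area_ratio":
                holders["geometry"] = replace(geometry, area_rural=geometry.area_urban * value)
            else:
                holders[holder_name] = replace(holders[holder_name], **{attr: value})
            sol = solve_equilibrium(
                gp_total, sp_total,
                holders["household"], holders["geometry"], holders["tc"], holders["supply"],
            )
            rows.append(
                {
                    vary: value,
                    "gp_urban": sol.gp_urban,
                    "gp_rural": sol.gp_rural,
                    "sp_urban": sol.sp_urban,
                    "sp_rural": sol.sp_rural,
                    "gp_ratio": sol.gp_ratio,
                    "sp_ratio": sol.sp_ratio,
                    "sp_gp_multiplier": (sol.sp_urban / sol.gp_urban)
                    / (sol.sp_rural / sol.gp_rural),
                    "residual_gp": sol.residual_gp,
                    "residual_sp": sol.residual_sp,
                }
            )
        except (SolverError, DomainError):
            rows.append({vary: value})
    return pd.DataFrame(rows)
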