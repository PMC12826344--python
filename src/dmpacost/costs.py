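"""Ingredient-based costing of DMPA service-delivery visits.

A service contact is costed bottom-up from four components: the commodity
(DMPA-IM or DMPA-SC units dispensed, with DMPA-SC carrying a fixed price
premium over DMPA-IM), consumable supplies, provider labour (contact
minutes times a wage rate) and a per-visit infrastructure allocation.
Four visit types are distinguished: a provider-administered DMPA-IM
injection, a provider-administered DMPA-SC injection, a supervised first
self-injection (the transition visit), and a self-injection resupply
visit at which take-home units are dispensed in advance.

The shipped default inventory is a CALIBRATED stand-in: the underlying
wage, minute and supply figures behind the published per-option costs
are not publicly available, so defaults are back-solved to
reproduce the published steady-state cost per person-year of each
delivery option ($11.56 IM / $13.81 PA DMPA-SC / $10.35 SI at facilities;
$11.36 / $14.05 / $6.30 in communities).  Every figure can be overridden
through a structured YAML configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import yaml

from .states import COMMUNITY, FACILITY, IM, LOCATIONS, NONE, OTHER_METHOD, PA_SC, SI

IM_INJECT = "IM_inject"
PASC_INJECT = "PASC_inject"
SI_SUPERVISED = "SI_supervised"
SI_RESUPPLY = "SI_resupply"
VISIT_TYPES = (IM_INJECT, PASC_INJECT, SI_SUPERVISED, SI_RESUPPLY)

#: DMPA-SC units handed over at each visit type (take-home units for
#: resupply visits are set by the inventory's ``units_per_si_resupply``).
_SC_VISITS = (PASC_INJECT, SI_SUPERVISED, SI_RESUPPLY)

COMPONENTS = ("commodity", "supplies", "labour", "infrastructure")


class CostConfigError(ValueError):
    """Missing or invalid cost-inventory configuration entry."""


@dataclass(frozen=True)
class SupplyItem:
    item: str
    unit_cost: float
    quantity: float

    def __post_init__(self):
        if self.unit_cost < 0 or self.quantity < 0:
            raise CostConfigError(f"negative supply cost/quantity for {self.item!r}")

    @property
    def cost(self) -> float:
        return self.unit_cost * self.quantity


@dataclass(frozen=True)
class ResourceInventory:
    """Itemised resource inputs by visit type and location (all USD).

    ``wage_rate`` is USD per provider minute by location (the provider
    cadre is implied: facility visits are delivered by nurses/midwives,
    community visits by health surveillance assistants).  MWK-denominated
    inputs must be pre-converted with ``mwk_per_usd``.
    """

    commodity_price_im: float
    sc_premium: float = 0.20
    supplies: Mapping[str, tuple[SupplyItem, ...]] = field(default_factory=dict)
    labour_minutes: Mapping[tuple[str, str], float] = field(default_factory=dict)
    wage_rate: Mapping[str, float] = field(default_factory=dict)
    infrastructure_cost_per_visit: Mapping[tuple[str, str], float] = field(
        default_factory=dict
    )
    units_per_si_resupply: int = 2
    mwk_per_usd: float = 1200.0

    def __post_init__(self):
        if self.commodity_price_im < 0 or self.sc_premium < 0:
            raise CostConfigError("commodity prices must be non-negative")
        if self.units_per_si_resupply < 1:
            raise CostConfigError("units_per_si_resupply must be >= 1")
        for key, minutes in self.labour_minutes.items():
            if minutes < 0:
                raise CostConfigError(f"negative labour minutes for {key}")
        for loc, wage in self.wage_rate.items():
            if wage < 0:
                raise CostConfigError(f"negative wage rate for {loc!r}")
        for key, cost in self.infrastructure_cost_per_visit.items():
            if cost < 0:
                raise CostConfigError(f"negative infrastructure cost for {key}")

    def sc_unit_price(self) -> float:
        """DMPA-SC unit price: the IM price plus the SC premium, once."""
        return self.commodity_price_im + self.sc_premium


@dataclass(frozen=True)
class VisitCostBundle:
    """Itemised USD cost of one service contact."""

    visit_type: str
    location: str
    commodity: float
    supplies: float
    labour: float
    infrastructure: float

    def __post_init__(self):
        for name in COMPONENTS:
            if getattr(self, name) < 0:
                raise CostConfigError(f"negative {name} component")

    @property
    def total(self) -> float:
        return self.commodity + self.supplies + self.labour + self.infrastructure

    def as_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in COMPONENTS}
        d["total"] = self.total
        return d


def units_dispensed(visit_type: str, inventory: ResourceInventory) -> int:
    """DMPA units handed over at a visit (1 per injection, more at resupply)."""
    return inventory.units_per_si_resupply if visit_type == SI_RESUPPLY else 1


def visit_cost(
    inventory: ResourceInventory, visit_type: str, location: str
) -> VisitCostBundle:
    """Itemised cost of one visit of ``visit_type`` at ``location``."""
    if visit_type not in VISIT_TYPES:
        raise CostConfigError(f"unknown visit type {visit_type!r}")
    if location not in LOCATIONS:
        raise CostConfigError(f"unknown location {location!r}")
    unit_price = (
        inventory.sc_unit_price() if visit_type in _SC_VISITS else inventory.commodity_price_im
    )
    commodity = unit_price * units_dispensed(visit_type, inventory)
    if visit_type not in inventory.supplies:
        raise CostConfigError(f"missing inventory entry supplies[{visit_type!r}]")
    supplies = sum(item.cost for item in inventory.supplies[visit_type])
    key = (visit_type, location)
    if key not in inventory.labour_minutes:
        raise CostConfigError(f"missing inventory entry labour_minutes[{key!r}]")
    if location not in inventory.wage_rate:
        raise CostConfigError(f"missing inventory entry wage_rate[{location!r}]")
    labour = inventory.labour_minutes[key] * inventory.wage_rate[location]
    if key not in inventory.infrastructure_cost_per_visit:
        raise CostConfigError(
            f"missing inventory entry infrastructure_cost_per_visit[{key!r}]"
        )
    infrastructure = inventory.infrastructure_cost_per_visit[key]
    return VisitCostBundle(
        visit_type=visit_type,
        location=location,
        commodity=commodity,
        supplies=supplies,
        labour=labour,
        infrastructure=infrastructure,
    )


@dataclass(frozen=True)
class CostSchedule:
    """Per-cycle DMPA service cost for each Markov state and location.

    Provider-administered states incur one injection bundle per quarterly
    cycle.  The SI state incurs a resupply bundle every
    ``units_per_si_resupply`` cycles (one dispensed unit covers one
    cycle), spread evenly per cycle, plus a one-off supervised-injection
    bundle at the cycle of transition into SI.  Non-DMPA states carry no
    DMPA service cost.
    """

    per_cycle: Mapping[tuple[str, str], float]
    si_entry_cost: Mapping[str, float]
    bundles: Mapping[tuple[str, str], VisitCostBundle] = field(default_factory=dict)

    def state_cost(self, state: str, location: str) -> float:
        return float(self.per_cycle.get((state, location), 0.0))

    def entry_cost(self, state: str, location: str) -> float:
        return float(self.si_entry_cost.get(location, 0.0)) if state == SI else 0.0

    def cost_per_person_year(self, state: str, location: str) -> float:
        """Steady-state annual cost of one person held in ``state``."""
        return 4.0 * self.state_cost(state, location)


def build_cost_schedule(inventory: ResourceInventory) -> CostSchedule:
    """Assemble the per-cycle cost schedule from visit bundles."""
    per_cycle: dict[tuple[str, str], float] = {}
    entry: dict[str, float] = {}
    bundles: dict[tuple[str, str], VisitCostBundle] = {}
    cadence = inventory.units_per_si_resupply  # cycles between resupply visits
    for loc in LOCATIONS:
        for vt in VISIT_TYPES:
            bundles[(vt, loc)] = visit_cost(inventory, vt, loc)
        per_cycle[(IM, loc)] = bundles[(IM_INJECT, loc)].total
        per_cycle[(PA_SC, loc)] = bundles[(PASC_INJECT, loc)].total
        per_cycle[(SI, loc)] = bundles[(SI_RESUPPLY, loc)].total / cadence
        per_cycle[(OTHER_METHOD, loc)] = 0.0
        per_cycle[(NONE, loc)] = 0.0
        entry[loc] = bundles[(SI_SUPERVISED, loc)].total
    return CostSchedule(per_cycle=per_cycle, si_entry_cost=entry, bundles=bundles)


def labour_share(annual_costs_by_component: Mapping[str, float]) -> float:
    """Labour's proportion of total annual service cost."""
    if any(v < 0 for v in annual_costs_by_component.values()):
        raise CostConfigError("component totals must be non-negative")
    total = sum(annual_costs_by_component.values())
    if total == 0:
        raise CostConfigError("all component totals are zero")
    return annual_costs_by_component.get("labour", 0.0) / total


# ---------------------------------------------------------------------------
# calibrated default inventory
# ---------------------------------------------------------------------------

def default_inventory() -> ResourceInventory:
    """Calibrated default inventory (see module docstring).

    Labour minutes are back-solved from the published per-option costs per
    person-year given the wage rates below; they are stand-ins, not
    measured values.
    """
    supplies = {
        IM_INJECT: (
            SupplyItem("syringe_and_needle", 0.06, 1),
            SupplyItem("gloves_pair", 0.02, 2),
            SupplyItem("alcohol_swab", 0.02, 1),
        ),
        PASC_INJECT: (
            SupplyItem("gloves_pair", 0.02, 2),
            SupplyItem("alcohol_swab", 0.02, 1),
        ),
        SI_SUPERVISED: (
            SupplyItem("gloves_pair", 0.02, 2),
            SupplyItem("alcohol_swab", 0.02, 1),
            SupplyItem("self_injection_job_aid", 0.04, 1),
        ),
        SI_RESUPPLY: (SupplyItem("client_instructions_and_bag", 0.02, 1),),
    }
    labour_minutes = {
        (IM_INJECT, FACILITY): 22.125,
        (IM_INJECT, COMMUNITY): 26.0,
        (PASC_INJECT, FACILITY): 27.40625,
        (PASC_INJECT, COMMUNITY): 33.60714285714286,
        (SI_SUPERVISED, FACILITY): 35.0,
        (SI_SUPERVISED, COMMUNITY): 30.0,
        (SI_RESUPPLY, FACILITY): 36.3125,
        (SI_RESUPPLY, COMMUNITY): 14.0,
    }
    infrastructure = {
        (vt, FACILITY): 0.15 for vt in VISIT_TYPES
    } | {(vt, COMMUNITY): 0.05 for vt in VISIT_TYPES}
    return ResourceInventory(
        commodity_price_im=0.85,
        sc_premium=0.20,
        supplies=supplies,
        labour_minutes=labour_minutes,
        wage_rate={FACILITY: 0.08, COMMUNITY: 0.07},
        infrastructure_cost_per_visit=infrastructure,
        units_per_si_resupply=2,
    )


def with_sc_premium(inventory: ResourceInventory, sc_premium: float) -> ResourceInventory:
    return replace(inventory, sc_premium=sc_premium)


# ---------------------------------------------------------------------------
# structured YAML configuration
# ---------------------------------------------------------------------------

_TOP_KEYS = {"commodities", "supplies", "labour", "infrastructure"}


def inventory_to_dict(inv: ResourceInventory) -> dict:
    """Serialisable form of an inventory (inverse of :func:`inventory_from_dict`)."""
    return {
        "commodities": {
            "price_im": inv.commodity_price_im,
            "sc_premium": inv.sc_premium,
            "units_per_si_resupply": inv.units_per_si_resupply,
            "mwk_per_usd": inv.mwk_per_usd,
        },
        "supplies": {
            vt: [
                {"item": s.item, "unit_cost": s.unit_cost, "quantity": s.quantity}
                for s in items
            ]
            for vt, items in inv.supplies.items()
        },
        "labour": {
            "wage_rate": dict(inv.wage_rate),
            "minutes": {
                vt: {
                    loc: inv.labour_minutes[(vt, loc)]
                    for loc in LOCATIONS
                    if (vt, loc) in inv.labour_minutes
                }
                for vt in VISIT_TYPES
            },
        },
        "infrastructure": {
            vt: {
                loc: inv.infrastructure_cost_per_visit[(vt, loc)]
                for loc in LOCATIONS
                if (vt, loc) in inv.infrastructure_cost_per_visit
            }
            for vt in VISIT_TYPES
        },
    }


def _require(mapping: Mapping, key, where: str):
    if key not in mapping:
        raise CostConfigError(f"missing configuration key {where}.{key}")
    return mapping[key]


def inventory_from_dict(cfg: Mapping) -> ResourceInventory:
    """Build an inventory from a nested mapping with strict validation."""
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise CostConfigError(f"unknown inventory section(s): {sorted(unknown)}")
    commodities = _require(cfg, "commodities", "inventory")
    supplies_cfg = _require(cfg, "supplies", "inventory")
    labour_cfg = _require(cfg, "labour", "inventory")
    infra_cfg = _require(cfg, "infrastructure", "inventory")

    supplies = {}
    for vt in VISIT_TYPES:
        items = _require(supplies_cfg, vt, "inventory.supplies")
        supplies[vt] = tuple(
            SupplyItem(
                _require(it, "item", f"inventory.supplies.{vt}[]"),
                float(_require(it, "unit_cost", f"inventory.supplies.{vt}[]")),
                float(_require(it, "quantity", f"inventory.supplies.{vt}[]")),
            )
            for it in items
        )
    wage = {
        loc: float(v)
        for loc, v in _require(labour_cfg, "wage_rate", "inventory.labour").items()
    }
    minutes_cfg = _require(labour_cfg, "minutes", "inventory.labour")
    minutes = {}
    infra = {}
    for vt in VISIT_TYPES:
        vt_minutes = _require(minutes_cfg, vt, "inventory.labour.minutes")
        vt_infra = _require(infra_cfg, vt, "inventory.infrastructure")
        for loc in LOCATIONS:
            minutes[(vt, loc)] = float(
                _require(vt_minutes, loc, f"inventory.labour.minutes.{vt}")
            )
            infra[(vt, loc)] = float(
                _require(vt_infra, loc, f"inventory.infrastructure.{vt}")
            )
    return ResourceInventory(
        commodity_price_im=float(_require(commodities, "price_im", "inventory.commodities")),
        sc_premium=float(_require(commodities, "sc_premium", "inventory.commodities")),
        supplies=supplies,
        labour_minutes=minutes,
        wage_rate=wage,
        infrastructure_cost_per_visit=infra,
        units_per_si_resupply=int(commodities.get("units_per_si_resupply", 2)),
        mwk_per_usd=float(commodities.get("mwk_per_usd", 1200.0)),
    )


def load_inventory(path) -> ResourceInventory:
    """Load an inventory from a YAML file with an ``inventory`` section."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if "inventory" not in cfg:
        raise CostConfigError("missing configuration key inventory")
    return inventory_from_dict(cfg["inventory"])


def save_inventory(inv: ResourceInventory, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"inventory": inventory_to_dict(inv)}, fh, sort_keys=False)
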