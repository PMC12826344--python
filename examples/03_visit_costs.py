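"""Itemised visit costs and per-option cost per person-year of use.

Each service contact is costed from commodity, supplies, labour and
infrastructure. A self-injection resupply visit dispenses two take-home
units (six months of coverage), so held over a year self-injection needs
two contacts where provider administration needs four.
"""

from dmpacost import build_cost_schedule, default_inventory, labour_share, visit_cost
from dmpacost.costs import VISIT_TYPES
from dmpacost.states import COMMUNITY, FACILITY, IM, PA_SC, SI

inventory = default_inventory()
schedule = build_cost_schedule(inventory)

print("itemised facility visit costs (USD):")
print(f"{'visit type':<16}{'commodity':>10}{'supplies':>10}{'labour':>8}{'infra':>7}{'total':>8}")
for vt in VISIT_TYPES:
    b = visit_cost(inventory, vt, FACILITY)
    print(
        f"{vt:<16}{b.commodity:>10.2f}{b.supplies:>10.2f}"
        f"{b.labour:>8.2f}{b.infrastructure:>7.2f}{b.total:>8.2f}"
    )

b = visit_cost(inventory, "PASC_inject", FACILITY)
share = labour_share({k: v for k, v in b.as_dict().items() if k != "total"})
print(f"\nlabour share of a facility PA DMPA-SC visit: {share:.0%}")

print("\nsteady-state DMPA service cost per person-year of use (USD):")
print(f"{'option':<18}{'facility':>9}{'community':>10}")
for state, label in ((IM, "DMPA-IM"), (PA_SC, "PA DMPA-SC"), (SI, "self-injection")):
    fac = schedule.cost_per_person_year(state, FACILITY)
    com = schedule.cost_per_person_year(state, COMMUNITY)
    print(f"{label:<18}{fac:>9.2f}{com:>10.2f}")
print("(calibrated default inventory; override any input via YAML config)")
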