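"""Markov state space for injectable-contraceptive service use.

Five method states are tracked quarterly: the two provider-administered
DMPA products (intramuscular ``IM`` and subcutaneous ``PA_SC``),
self-injected DMPA-SC (``SI``), use of a non-DMPA contraceptive method
(``OTHER_METHOD``) and no family-planning use (``NONE``).  ``MISSING`` is
an observation label only (loss to follow-up), never a model state.
"""

from __future__ import annotations

IM = "IM"
PA_SC = "PA_SC"
SI = "SI"
OTHER_METHOD = "OTHER_METHOD"
NONE = "NONE"
MISSING = "MISSING"

#: Ordered Markov state space (MISSING excluded: it is an observation gap).
STATES: tuple[str, ...] = (IM, PA_SC, SI, OTHER_METHOD, NONE)

#: States that accrue DMPA person-years of protection.
DMPA_STATES: frozenset[str] = frozenset({IM, PA_SC, SI})

#: Enrolment arms (one per injectable option).
ARMS: tuple[str, ...] = (IM, PA_SC, SI)

#: Valid per-wave observation labels in cohort records.
OBS_STATES: tuple[str, ...] = STATES + (MISSING,)

FACILITY = "facility"
COMMUNITY = "community"
LOCATIONS: tuple[str, str] = (FACILITY, COMMUNITY)

STATE_INDEX = {s: i for i, s in enumerate(STATES)}
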