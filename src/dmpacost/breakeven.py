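"""Break-even self-injection share for DMPA-SC cost-competitiveness.

DMPA-SC carries a commodity premium and (when provider-administered)
longer contact time than DMPA-IM, but a self-injection (SI) resupply
visit is cheaper and covers two quarters per contact.  As the share of
DMPA-SC visits delivered as SI grows, the DMPA-SC cost per person-year of
use falls; the break-even share is the smallest SI visit share at which
DMPA-SC is no more costly per person-year than DMPA-IM delivered at the
same location.

Two blending modes are provided.  The default ``"visit"`` mode works at
the visit level, as the share is defined: with SI share ``s``, the mean
coverage per visit is ``1 - s + s * cadence`` cycles (cadence = units per
resupply visit), so the per-cycle cost is
``(s * R + (1 - s) * C_PA) / (1 - s + s * cadence)`` with ``R`` the
resupply bundle and ``C_PA`` the provider-administered injection bundle.
``"linear"`` interpolates the two boundary per-cycle costs directly,
which makes the cost per person-year exactly linear in the share (a
person-level mixing of steady-state users).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .costs import SI_RESUPPLY, CostSchedule
from .estimation import TransitionMatrix
from .markov import run_deterministic
from .states import DMPA_STATES, FACILITY, IM, NONE, PA_SC, SI, STATES

BLEND_MODES = ("visit", "linear")


class BreakevenError(ValueError):
    """Invalid break-even parameters."""


@dataclass(frozen=True)
class BreakevenCurve:
    """DMPA-SC cost per person-year as a function of the SI visit share."""

    si_shares: np.ndarray
    sc_cost_per_py: np.ndarray
    im_cost_per_py: float
    threshold: float | None          # smallest grid share with SC <= IM
    threshold_continuous: float | None  # bisection root of the continuous blend
    location: str = FACILITY
    mode: str = "visit"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "si_share": self.si_shares,
                "sc_cost_per_py": self.sc_cost_per_py,
                "im_cost_per_py": self.im_cost_per_py,
            }
        )


@dataclass(frozen=True)
class BreakevenVerdict:
    cost_saving: bool
    margin: float | None


def _dmpa_stay_prob(matrix: TransitionMatrix, state: str) -> float:
    """Probability of remaining a DMPA user next cycle, from ``state``'s row."""
    i = matrix.states.index(state)
    return float(
        sum(matrix.p[i, j] for j, s in enumerate(matrix.states) if s in DMPA_STATES)
    )


def _single_state_matrix(stay: float) -> TransitionMatrix:
    p = np.eye(len(STATES))
    i, j = STATES.index(PA_SC), STATES.index(NONE)
    p[i, i] = stay
    p[i, j] = 1.0 - stay
    return TransitionMatrix(states=STATES, p=p)


def _cost_per_py(per_cycle_cost: float, stay: float, location: str) -> float:
    schedule = CostSchedule(
        per_cycle={(PA_SC, location): per_cycle_cost}, si_entry_cost={}
    )
    res = run_deterministic(
        _single_state_matrix(stay),
        schedule,
        n0=100_000.0,
        n_cycles=4,
        start=PA_SC,
        location=location,
    )
    return res.cost_per_py.mean


def blended_per_cycle_cost(
    share: float, schedule: CostSchedule, location: str, mode: str = "visit"
) -> float:
    """Per-cycle cost of the DMPA-SC service with SI visit share ``share``."""
    if not 0.0 <= share <= 1.0:
        raise BreakevenError("share must lie in [0, 1]")
    if mode not in BLEND_MODES:
        raise BreakevenError(f"unknown blend mode {mode!r}")
    c_pa = schedule.state_cost(PA_SC, location)
    c_si_cycle = schedule.state_cost(SI, location)
    if mode == "linear":
        return (1.0 - share) * c_pa + share * c_si_cycle
    # visit-level blend: an SI resupply visit covers `cadence` cycles
    resupply_bundle = schedule.bundles.get((SI_RESUPPLY, location))
    if resupply_bundle is not None:
        r_total = resupply_bundle.total
        cadence = r_total / c_si_cycle if c_si_cycle > 0 else 1.0
    else:
        # schedule built by hand: per-cycle SI cost implies the bundle at cadence 2
        cadence = 2.0
        r_total = c_si_cycle * cadence
    coverage = (1.0 - share) + share * cadence
    return (share * r_total + (1.0 - share) * c_pa) / coverage


def sc_cost_at_share(
    share: float,
    schedule: CostSchedule,
    matrix: TransitionMatrix,
    location: str = FACILITY,
    mode: str = "visit",
) -> float:
    """DMPA-SC cost per person-year when ``share`` of its visits are SI."""
    stay = _dmpa_stay_prob(matrix, PA_SC)
    return _cost_per_py(blended_per_cycle_cost(share, schedule, location, mode), stay, location)


def im_reference_cost(
    schedule: CostSchedule, matrix: TransitionMatrix, location: str = FACILITY
) -> float:
    """DMPA-IM cost per person-year at the same location and retention."""
    stay = _dmpa_stay_prob(matrix, PA_SC)
    return _cost_per_py(schedule.state_cost(IM, location), stay, location)


def find_breakeven(
    schedule: CostSchedule,
    matrix: TransitionMatrix,
    location: str = FACILITY,
    grid_step: float = 0.01,
    mode: str = "visit",
) -> BreakevenCurve:
    """Break-even SI visit share on a grid, cross-validated by bisection.

    SC cheaper everywhere gives threshold 0; SC never cheaper gives
    threshold ``None``.  Both are valid outputs, not errors.
    """
    if not 0.0 < grid_step <= 0.5:
        raise BreakevenError("grid_step must lie in (0, 0.5]")
    shares = np.round(np.arange(0.0, 1.0 + grid_step / 2.0, grid_step), 12)
    if shares[-1] < 1.0:
        shares = np.append(shares, 1.0)
    im_cost = im_reference_cost(schedule, matrix, location)
    sc_costs = np.array(
        [sc_cost_at_share(s, schedule, matrix, location, mode) for s in shares]
    )
    below = sc_costs <= im_cost + 1e-12
    threshold = float(shares[np.argmax(below)]) if below.any() else None

    def gap(s: float) -> float:
        return sc_cost_at_share(s, schedule, matrix, location, mode) - im_cost

    if gap(0.0) <= 0.0:
        continuous = 0.0
    elif gap(1.0) > 0.0:
        continuous = None
    else:
        continuous = float(optimize.brentq(gap, 0.0, 1.0, xtol=1e-6))

    if (threshold is None) != (continuous is None):
        raise BreakevenError("grid and bisection disagree on break-even existence")
    if threshold is not None and abs(threshold - continuous) > grid_step + 1e-9:
        raise BreakevenError("grid and bisection thresholds disagree beyond one grid step")
    return BreakevenCurve(
        si_shares=shares,
        sc_cost_per_py=sc_costs,
        im_cost_per_py=im_cost,
        threshold=threshold,
        threshold_continuous=continuous,
        location=location,
        mode=mode,
    )


def threshold_vs_observed(
    threshold: float | None, observed_si_share: float
) -> BreakevenVerdict:
    """Is the observed SI visit share at or above the break-even threshold?"""
    if not 0.0 <= observed_si_share <= 1.0:
        raise BreakevenError("observed share must lie in [0, 1]")
    if threshold is None:
        return BreakevenVerdict(cost_saving=False, margin=None)
    if not 0.0 <= threshold <= 1.0:
        raise BreakevenError("threshold must lie in [0, 1]")
    return BreakevenVerdict(
        cost_saving=observed_si_share >= threshold,
        margin=observed_si_share - threshold,
    )
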