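"""Continuation, hazard-ratio and transition-probability estimation.

All estimators operate on the discrete quarterly wave grid (times 1..4):
surveys happened approximately every three months, so event times are only
known to the wave.  A subject whose follow-up goes missing at wave ``w``
was last seen event-free at wave ``w - 1`` and is coded as censored at
``w``; censoring times are *exclusive* — a subject censored at time ``t``
is not in the risk set for events at ``t``.  Day-scale summaries impute
events at the interval midpoint (``cycle_days * (wave - 0.5)``).

Tied event times are the norm on a quarterly grid, so the two-group
proportional-hazards estimator maximises the Efron tie-corrected partial
likelihood (Newton iteration with analytic score and information).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ParticipantRecord
from .states import ARMS, MISSING, SI, STATES

logger = logging.getLogger(__name__)

EVENT_METHOD_CHANGE = "method_status_change"
EVENT_TRANSITION_SI = "transition_to_si"
EVENT_DEFINITIONS = (EVENT_METHOD_CHANGE, EVENT_TRANSITION_SI)


class EstimationError(ValueError):
    """Estimation impossible on the given records (no risk time, no events...)."""


# ---------------------------------------------------------------------------
# record -> (time, event) coding
# ---------------------------------------------------------------------------

def times_and_events(
    records: Iterable[ParticipantRecord], event_definition: str
) -> tuple[np.ndarray, np.ndarray]:
    """Code records as (time, event-flag) pairs on the wave grid.

    Event time is the first follow-up wave at which the event condition
    holds.  Event-free subjects are censored at ``last observed wave + 1``
    (exclusive convention), so they remain at risk through every wave at
    which they were actually observed.
    """
    if event_definition not in EVENT_DEFINITIONS:
        raise ValueError(f"unknown event definition {event_definition!r}")
    times, events = [], []
    for rec in records:
        t, e = None, 0
        for w in range(1, rec.n_waves + 1):
            s = rec.wave_status[w]
            if s == MISSING:
                t, e = w, 0
                break
            hit = (
                s != rec.arm
                if event_definition == EVENT_METHOD_CHANGE
                else s == SI
            )
            if hit:
                t, e = w, 1
                break
        if t is None:
            t, e = rec.n_waves + 1, 0
        times.append(t)
        events.append(e)
    return np.asarray(times, dtype=float), np.asarray(events, dtype=int)


def _at_risk(times: np.ndarray, events: np.ndarray, t: float) -> int:
    """Risk-set size at event time ``t`` under the exclusive convention."""
    return int(np.sum((events == 1) & (times >= t)) + np.sum((events == 0) & (times > t)))


def _has_risk_time(times: np.ndarray, events: np.ndarray) -> bool:
    """Whether any subject contributes risk time on the wave grid.

    An event at wave ``t >= 1`` contributes, as does a censoring at
    ``t > 1`` (the subject was observed event-free at wave ``t - 1``).
    """
    risk = times - (events == 0)
    return bool(np.any(risk >= 1.0 - 1e-12))


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit curve on a discrete time grid with Greenwood variances."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    variance: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S = 1 before the first grid time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def variance_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.variance[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
                "greenwood_variance": self.variance,
            }
        )


def product_limit(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimate from explicit (time, event) pairs.

    Censorings at time ``t`` are excluded from the risk set at ``t``
    (they represent losses during the interval ending at ``t``).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise EstimationError("no records")
    if not _has_risk_time(times, events):
        raise EstimationError("no risk time")
    grid = np.unique(times)
    s, gw = 1.0, 0.0
    out_t, out_s, out_n, out_d, out_v = [], [], [], [], []
    for t in grid:
        n = _at_risk(times, events, t)
        d = int(np.sum((events == 1) & (times == t)))
        if n > 0:
            s *= 1.0 - d / n
            if n > d:
                gw += d / (n * (n - d))
        out_t.append(t)
        out_s.append(s)
        out_n.append(n)
        out_d.append(d)
        out_v.append(s * s * gw)
    return SurvivalCurve(
        times=np.array(out_t),
        survival=np.array(out_s),
        at_risk=np.array(out_n),
        events=np.array(out_d),
        variance=np.array(out_v),
    )


def km_continuation(
    records: Sequence[ParticipantRecord], event_definition: str
) -> SurvivalCurve:
    """Product-limit continuation curve over the quarterly wave grid."""
    times, events = times_and_events(records, event_definition)
    return product_limit(times, events)


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------

def logrank_from_times(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank statistic and p-value from (time, event) pairs."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    for t, e, name in ((ta, ea, "A"), (tb, eb, "B")):
        if t.size == 0 or not _has_risk_time(t, e):
            raise EstimationError(f"group {name} has no observed risk time")
    grid = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e, var = 0.0, 0.0
    for t in grid:
        na, nb = _at_risk(ta, ea, t), _at_risk(tb, eb, t)
        da = int(np.sum((ea == 1) & (ta == t)))
        db = int(np.sum((eb == 1) & (tb == t)))
        n, d = na + nb, da + db
        if n == 0 or d == 0:
            continue
        o_minus_e += da - d * na / n
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    stat = 0.0 if var == 0.0 else o_minus_e**2 / var
    return float(stat), float(stats.chi2.sf(stat, df=1))


def logrank_test(
    records_a: Sequence[ParticipantRecord],
    records_b: Sequence[ParticipantRecord],
    event_definition: str = EVENT_METHOD_CHANGE,
) -> tuple[float, float]:
    """Two-group log-rank comparison of continuation between record sets."""
    ta, ea = times_and_events(records_a, event_definition)
    tb, eb = times_and_events(records_b, event_definition)
    return logrank_from_times(ta, ea, tb, eb)


# ---------------------------------------------------------------------------
# two-group proportional hazards (Efron ties)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HazardRatioResult:
    """Two-group hazard ratio with Wald 95% CI on the log scale."""

    hr: float
    ci_low: float
    ci_high: float
    log_hr_se: float

    def __post_init__(self):
        if not (self.ci_low <= self.hr <= self.ci_high) or self.ci_low <= 0:
            raise ValueError("invalid hazard-ratio interval")


def _efron_blocks(times, events, group):
    """Per-event-time risk/death counts split by group membership."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group, int)
    blocks = []
    for t in np.unique(times[events == 1]):
        at_risk = ((events == 1) & (times >= t)) | ((events == 0) & (times > t))
        dead = (events == 1) & (times == t)
        r1 = int(np.sum(at_risk & (group == 1)))
        r0 = int(np.sum(at_risk)) - r1
        d1 = int(np.sum(dead & (group == 1)))
        d0 = int(np.sum(dead)) - d1
        blocks.append((r0, r1, d0, d1))
    return blocks


def efron_partial_loglik(beta: float, blocks) -> float:
    """Efron tie-corrected two-group partial log-likelihood at log-HR beta."""
    eb = np.exp(beta)
    ll = 0.0
    for r0, r1, d0, d1 in blocks:
        d = d0 + d1
        r_sum, d_sum = r0 + r1 * eb, d0 + d1 * eb
        j = np.arange(d)
        ll += d1 * beta - np.sum(np.log(r_sum - (j / d) * d_sum))
    return float(ll)


def _efron_score_info(beta: float, blocks) -> tuple[float, float]:
    eb = np.exp(beta)
    score, info = 0.0, 0.0
    for r0, r1, d0, d1 in blocks:
        d = d0 + d1
        j = np.arange(d)
        a = (r0 + r1 * eb) - (j / d) * (d0 + d1 * eb)
        b = eb * (r1 - (j / d) * d1)
        score += d1 - np.sum(b / a)
        info += np.sum(b * (a - b) / (a * a))
    return score, info


def hazard_ratio_from_times(times, events, group) -> HazardRatioResult:
    """Efron-tie proportional-hazards fit of a binary group indicator."""
    events = np.asarray(events, int)
    group = np.asarray(group, int)
    if np.sum(events[group == 1]) == 0 or np.sum(events[group == 0]) == 0:
        raise EstimationError("hazard ratio undefined: zero events in a group")
    blocks = _efron_blocks(times, events, group)
    beta = 0.0
    for _ in range(100):
        score, info = _efron_score_info(beta, blocks)
        if info <= 0:
            raise EstimationError("hazard ratio undefined: singular information")
        step = score / info
        beta = float(np.clip(beta + step, -30.0, 30.0))
        if abs(step) < 1e-13:
            break
    _, info = _efron_score_info(beta, blocks)
    se = float(np.sqrt(1.0 / info))
    return HazardRatioResult(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        log_hr_se=se,
    )


def hazard_ratio(
    records: Sequence[ParticipantRecord],
    group_label: str,
    reference_label: str,
    event_definition: str = EVENT_METHOD_CHANGE,
) -> HazardRatioResult:
    """Hazard ratio of ``group_label`` relative to ``reference_label`` arms."""
    subset = [r for r in records if r.arm in (group_label, reference_label)]
    if not subset:
        raise EstimationError("no records in either group")
    times, events = times_and_events(subset, event_definition)
    group = np.array([1 if r.arm == group_label else 0 for r in subset])
    return hazard_ratio_from_times(times, events, group)


# ---------------------------------------------------------------------------
# cumulative incidence and switch timing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CumulativeIncidence:
    estimate: float
    ci_low: float
    ci_high: float


def cumulative_incidence_si(
    records: Sequence[ParticipantRecord], arm: str
) -> CumulativeIncidence:
    """12-month cumulative SI-transition probability (1 - S) with 95% CI.

    The complement of the product-limit curve for the transition-to-SI
    event at the final wave, with a Greenwood-variance Wald interval.
    """
    if arm not in (ARMS[0], ARMS[1]):
        raise ValueError("cumulative SI incidence is defined for the IM and PA_SC arms")
    subset = [r for r in records if r.arm == arm]
    if not subset:
        raise EstimationError(f"no records in arm {arm}")
    curve = km_continuation(subset, EVENT_TRANSITION_SI)
    t_end = subset[0].n_waves
    p = 1.0 - curve.survival_at(t_end)
    half = 1.959963984540054 * np.sqrt(curve.variance_at(t_end))
    return CumulativeIncidence(
        estimate=float(p),
        ci_low=float(max(0.0, p - half)),
        ci_high=float(min(1.0, p + half)),
    )


def mean_days_to_switch(
    records: Sequence[ParticipantRecord],
    arm: str,
    cycle_days: float = 91.0,
    event_definition: str = EVENT_TRANSITION_SI,
) -> float:
    """Mean days to switch among switchers, midpoint-imputed within waves."""
    subset = [r for r in records if r.arm == arm]
    times, events = times_and_events(subset, event_definition)
    switch_waves = times[events == 1]
    if switch_waves.size == 0:
        raise EstimationError(f"no switchers in arm {arm}")
    return float(np.mean(cycle_days * (switch_waves - 0.5)))


# ---------------------------------------------------------------------------
# transition matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionMatrix:
    """Per-cycle Markov transition probabilities over the method states."""

    states: tuple[str, ...] = STATES
    p: np.ndarray = field(default=None)  # type: ignore[assignment]
    cycle_index: int | str = "stationary"

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.shape != (len(self.states), len(self.states)):
            raise ValueError("transition matrix shape does not match state labels")
        if np.any(p < 0.0) or np.any(p > 1.0):
            raise ValueError("transition probabilities must lie in [0, 1]")
        rows = p.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-12):
            raise ValueError("transition-matrix rows must sum to 1 within 1e-12")
        object.__setattr__(self, "p", p)

    def prob(self, src: str, dst: str) -> float:
        return float(self.p[self.states.index(src), self.states.index(dst)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=list(self.states), columns=list(self.states))


def estimate_transition_matrix(
    records: Sequence[ParticipantRecord],
    arm: str | None = None,
    cycle_index: int | None = None,
) -> TransitionMatrix:
    """Row-normalised counts of observed wave-to-wave state pairs.

    Pairs with a MISSING member are excluded entirely.  By default counts
    are pooled over cycles (stationary matrix); ``cycle_index`` restricts
    to transitions out of one wave.  Rows with no observed pairs default
    to a self-loop of probability 1 (logged as a warning).
    """
    subset = [r for r in records if arm is None or r.arm == arm]
    k = len(STATES)
    idx = {s: i for i, s in enumerate(STATES)}
    counts = np.zeros((k, k))
    for rec in subset:
        waves = (
            range(rec.n_waves)
            if cycle_index is None
            else [cycle_index]
        )
        for w in waves:
            if w + 1 > rec.n_waves:
                continue
            a, b = rec.wave_status[w], rec.wave_status[w + 1]
            if a == MISSING or b == MISSING:
                continue
            counts[idx[a], idx[b]] += 1
    if counts.sum() == 0:
        raise EstimationError("no observed consecutive wave pairs")
    p = np.zeros_like(counts)
    for i, s in enumerate(STATES):
        row_sum = counts[i].sum()
        if row_sum == 0:
            logger.warning(
                "no observed transitions out of state %s; defaulting to self-loop", s
            )
            p[i, i] = 1.0
        else:
            p[i] = counts[i] / row_sum
            p[i, i] += 1.0 - p[i].sum()  # absorb rounding so rows sum exactly
    return TransitionMatrix(
        states=STATES,
        p=p,
        cycle_index="stationary" if cycle_index is None else cycle_index,
    )
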