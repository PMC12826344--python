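"""Recursive quarterly Markov cohort model with Monte-Carlo input uncertainty.

A closed cohort of ``n0`` clients starts in its enrolment state and is
pushed through quarterly cycles by a per-cycle transition matrix over the
five method states.  Accounting is intent-to-treat: clients who switch
DMPA product, take up self-injection, move to a non-DMPA method or stop
using contraception all stay inside the run with their accumulated costs.

Per cycle, in order: DMPA person-years (0.25 per occupant of a DMPA
state) and service costs accrue on the start-of-cycle occupancy (no
half-cycle correction — visits happen at the start of the quarter they
cover); an optional contraceptive-failure exit moves
``1 - (1 - annual rate)^(1/4)`` of each DMPA state to non-use; then the
behavioural transition matrix is applied.  Clients entering the
self-injection state are charged one supervised-injection bundle at the
transition cycle.

Input uncertainty follows the probabilistic-sensitivity-analysis
convention for probabilities: each behavioural transition probability is
treated as a beta-distributed estimate (mean = point estimate,
concentration = effective sample size), sampled per replicate with rows
renormalised, and the replicate distribution of each metric is summarised
by its mean and 5th/95th percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .costs import CostSchedule
from .estimation import TransitionMatrix
from .states import DMPA_STATES, FACILITY, SI, STATES


class MarkovModelError(ValueError):
    """Invalid model inputs or a degenerate run."""


@dataclass(frozen=True)
class BetaInput:
    """A probability input with beta-distributed uncertainty.

    ``concentration`` is the effective sample size kappa: the draw is
    Beta(mean * kappa, (1 - mean) * kappa), so the zero-variance limit
    kappa -> inf recovers the mean.  Degenerate means (0 or 1) and
    ``fixed_flag`` inputs are never sampled.
    """

    mean: float
    concentration: float = 300.0
    fixed_flag: bool = False

    def __post_init__(self):
        if not 0.0 <= self.mean <= 1.0:
            raise MarkovModelError("BetaInput mean must lie in [0, 1]")
        if self.concentration <= 0:
            raise MarkovModelError("BetaInput concentration must be positive")

    def sample(self, rng: np.random.Generator) -> float:
        if self.fixed_flag or self.mean in (0.0, 1.0) or np.isinf(self.concentration):
            return self.mean
        return float(
            rng.beta(self.mean * self.concentration, (1.0 - self.mean) * self.concentration)
        )


@dataclass(frozen=True)
class Metric:
    """A model metric with Monte-Carlo mean and percentile interval."""

    mean: float
    p5: float
    p95: float

    @classmethod
    def point(cls, value: float) -> "Metric":
        return cls(value, value, value)


@dataclass(frozen=True)
class MarkovResult:
    """Person-years, cost and cost per person-year of one cohort model."""

    person_years: Metric
    total_cost: Metric
    cost_per_py: Metric
    occupancy: np.ndarray  # states x (n_cycles + 1), start-of-cycle counts
    states: tuple[str, ...] = STATES
    n0: float = 100_000.0
    n_cycles: int = 4
    location: str = FACILITY
    state_person_years: Mapping[str, float] = field(default_factory=dict)
    state_costs: Mapping[str, float] = field(default_factory=dict)
    #: per-replicate metric draws (Monte-Carlo runs only; empty otherwise)
    replicates: Mapping[str, np.ndarray] = field(default_factory=dict)

    def metrics(self) -> dict[str, Metric]:
        return {
            "person_years": self.person_years,
            "total_cost": self.total_cost,
            "cost_per_py": self.cost_per_py,
        }

    def occupancy_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.occupancy,
            index=list(self.states),
            columns=[f"cycle_{c}" for c in range(self.occupancy.shape[1])],
        )


def _start_vector(start, n0: float) -> np.ndarray:
    if isinstance(start, str):
        if start not in STATES:
            raise MarkovModelError(f"unknown start state {start!r}")
        vec = np.zeros(len(STATES))
        vec[STATES.index(start)] = n0
        return vec
    if isinstance(start, Mapping):
        vec = np.zeros(len(STATES))
        for s, w in start.items():
            vec[STATES.index(s)] = w
        total = vec.sum()
        if total <= 0:
            raise MarkovModelError("start distribution has no mass")
        return vec * (n0 / total)
    vec = np.asarray(start, dtype=float)
    if vec.shape != (len(STATES),) or vec.sum() <= 0:
        raise MarkovModelError("start vector must be a positive length-5 vector")
    return vec * (n0 / vec.sum())


def run_deterministic(
    matrix: TransitionMatrix,
    schedule: CostSchedule,
    n0: float = 100_000.0,
    n_cycles: int = 4,
    failure_rate_annual: float = 0.0,
    start: str | Mapping[str, float] | Sequence[float] = SI,
    location: str = FACILITY,
) -> MarkovResult:
    """Run the quarterly cohort recursion once, with fixed inputs."""
    if not isinstance(matrix, TransitionMatrix):
        raise MarkovModelError("matrix must be a TransitionMatrix")
    if matrix.states != STATES:
        raise MarkovModelError("matrix states must match the model state space")
    if n_cycles < 1:
        raise MarkovModelError("n_cycles must be >= 1")
    if n0 <= 0:
        raise MarkovModelError("n0 must be positive")
    if not 0.0 <= failure_rate_annual < 1.0:
        raise MarkovModelError("failure_rate_annual must lie in [0, 1)")

    dmpa_mask = np.array([s in DMPA_STATES for s in STATES])
    si_idx = STATES.index(SI)
    costs_vec = np.array([schedule.state_cost(s, location) for s in STATES])
    entry_cost = schedule.entry_cost(SI, location)
    failure_q = 1.0 - (1.0 - failure_rate_annual) ** 0.25

    occ = _start_vector(start, n0)
    occupancy = np.empty((len(STATES), n_cycles + 1))
    occupancy[:, 0] = occ
    person_years = 0.0
    total_cost = 0.0
    state_py = dict.fromkeys(STATES, 0.0)
    state_cost = dict.fromkeys(STATES, 0.0)

    for c in range(n_cycles):
        person_years += 0.25 * occ[dmpa_mask].sum()
        total_cost += float(occ @ costs_vec)
        for i, s in enumerate(STATES):
            if dmpa_mask[i]:
                state_py[s] += 0.25 * occ[i]
            state_cost[s] += occ[i] * costs_vec[i]
        # contraceptive failure: exit from DMPA states to non-use
        if failure_q > 0.0:
            leak = occ * dmpa_mask * failure_q
            occ = occ - leak
            occ[STATES.index("NONE")] += leak.sum()
        # behavioural transition
        inflow_si = float(occ @ matrix.p[:, si_idx]) - occ[si_idx] * matrix.p[si_idx, si_idx]
        occ = occ @ matrix.p
        if c + 1 <= n_cycles - 1:
            # entrants whose first SI cycle falls inside the costed window
            total_cost += inflow_si * entry_cost
            state_cost[SI] += inflow_si * entry_cost
        occupancy[:, c + 1] = occ

    if person_years <= 0:
        raise MarkovModelError("no DMPA person-years accrued")
    return MarkovResult(
        person_years=Metric.point(person_years),
        total_cost=Metric.point(total_cost),
        cost_per_py=Metric.point(total_cost / person_years),
        occupancy=occupancy,
        n0=float(n0),
        n_cycles=n_cycles,
        location=location,
        state_person_years=state_py,
        state_costs=state_cost,
    )


# ---------------------------------------------------------------------------
# Monte Carlo over beta-distributed transition probabilities
# ---------------------------------------------------------------------------

def matrix_inputs(
    matrix: TransitionMatrix, concentration: float = 300.0, fixed: bool = False
) -> np.ndarray:
    """Wrap every transition probability as a :class:`BetaInput`."""
    k = len(matrix.states)
    out = np.empty((k, k), dtype=object)
    for i in range(k):
        for j in range(k):
            out[i, j] = BetaInput(
                mean=float(matrix.p[i, j]), concentration=concentration, fixed_flag=fixed
            )
    return out


def _sample_matrix(inputs: np.ndarray, rng: np.random.Generator) -> TransitionMatrix:
    k = inputs.shape[0]
    p = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            p[i, j] = inputs[i, j].sample(rng)
        row_sum = p[i].sum()
        if row_sum <= 0:
            raise MarkovModelError(f"sampled row {i} has zero mass")
        p[i] /= row_sum
        p[i, i] += 1.0 - p[i].sum()  # absorb float residue on the diagonal
    return TransitionMatrix(states=STATES, p=p)


def run_monte_carlo(
    inputs: np.ndarray | TransitionMatrix,
    schedule: CostSchedule,
    n0: float = 100_000.0,
    n_cycles: int = 4,
    failure_rate_annual: float = 0.0,
    start: str | Mapping[str, float] | Sequence[float] = SI,
    location: str = FACILITY,
    n_replicates: int = 1000,
    seed: int = 0,
    concentration: float = 300.0,
    percentiles: tuple[float, float] = (5.0, 95.0),
) -> MarkovResult:
    """Monte-Carlo simulation of replicate cohorts with beta-sampled inputs.

    ``inputs`` is either an object array of :class:`BetaInput` (one per
    transition probability) or a plain :class:`TransitionMatrix`, in which
    case every behavioural probability is sampled at ``concentration``.
    Reports the replicate mean and the empirical 5th/95th percentiles of
    each metric (pass ``percentiles=(2.5, 97.5)`` for a conventional
    equal-tailed 95% interval); identical seeds give identical results.
    """
    if isinstance(inputs, TransitionMatrix):
        mean_matrix = inputs
        inputs = matrix_inputs(inputs, concentration=concentration)
    else:
        means = np.array([[b.mean for b in row] for row in inputs])
        means = means / means.sum(axis=1, keepdims=True)
        for i in range(means.shape[0]):
            means[i, i] += 1.0 - means[i].sum()
        mean_matrix = TransitionMatrix(states=STATES, p=means)
    if n_replicates < 1:
        raise MarkovModelError("n_replicates must be >= 1")

    rng = np.random.default_rng(seed)
    kwargs = dict(
        schedule=schedule,
        n0=n0,
        n_cycles=n_cycles,
        failure_rate_annual=failure_rate_annual,
        start=start,
        location=location,
    )
    py = np.empty(n_replicates)
    cost = np.empty(n_replicates)
    cpy = np.empty(n_replicates)
    for rep in range(n_replicates):
        try:
            res = run_deterministic(_sample_matrix(inputs, rng), **kwargs)
        except MarkovModelError as err:
            raise MarkovModelError(f"replicate {rep} failed: {err}") from err
        py[rep] = res.person_years.mean
        cost[rep] = res.total_cost.mean
        cpy[rep] = res.cost_per_py.mean

    mean_run = run_deterministic(mean_matrix, **kwargs)

    def metric(v: np.ndarray) -> Metric:
        return Metric(
            mean=float(v.mean()),
            p5=float(np.percentile(v, percentiles[0])),
            p95=float(np.percentile(v, percentiles[1])),
        )

    return MarkovResult(
        person_years=metric(py),
        total_cost=metric(cost),
        cost_per_py=metric(cpy),
        occupancy=mean_run.occupancy,
        n0=float(n0),
        n_cycles=n_cycles,
        location=location,
        state_person_years=mean_run.state_person_years,
        state_costs=mean_run.state_costs,
        replicates={"person_years": py, "total_cost": cost, "cost_per_py": cpy},
    )


# ---------------------------------------------------------------------------
# comparisons and shares
# ---------------------------------------------------------------------------

def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def compare_cohorts(
    result_a: MarkovResult | Mapping[str, float],
    result_b: MarkovResult | Mapping[str, float],
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Absolute and relative (B vs A) differences per metric.

    Accepts model results or plain metric mappings (e.g. published table
    values).  Relative differences are signed percentages of the A value,
    rounded to one decimal, half away from zero.
    """

    def as_means(r) -> dict[str, float]:
        if isinstance(r, MarkovResult):
            return {k: m.mean for k, m in r.metrics().items()}
        return dict(r)

    a, b = as_means(result_a), as_means(result_b)
    if set(a) != set(b):
        raise MarkovModelError("results do not share the same metrics")
    rows = []
    for name in a:
        if a[name] == 0:
            raise MarkovModelError(
                f"relative difference undefined: metric {name!r} is zero in {label_a}"
            )
        rows.append(
            {
                "metric": name,
                label_a: a[name],
                label_b: b[name],
                "abs_diff": b[name] - a[name],
                "rel_diff_pct": round_half_away(100.0 * (b[name] - a[name]) / a[name], 1),
            }
        )
    return pd.DataFrame(rows).set_index("metric")


def component_shares(result: MarkovResult, schedule: CostSchedule | None = None) -> pd.DataFrame:
    """Per-state shares of DMPA person-years and of total cost.

    The cost breakdown is carried on the result, so ``schedule`` is
    accepted only for interface symmetry.
    """
    total_py = sum(result.state_person_years.values())
    total_cost = sum(result.state_costs.values())
    if total_py <= 0:
        raise MarkovModelError("zero person-years: shares undefined")
    rows = []
    for s in result.states:
        rows.append(
            {
                "state": s,
                "person_years": result.state_person_years.get(s, 0.0),
                "py_share": result.state_person_years.get(s, 0.0) / total_py,
                "cost": result.state_costs.get(s, 0.0),
                "cost_share": (
                    result.state_costs.get(s, 0.0) / total_cost if total_cost > 0 else 0.0
                ),
            }
        )
    return pd.DataFrame(rows).set_index("state")
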