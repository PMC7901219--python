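"""Half-cycle-corrected, discounted 4-state Markov cohort model.

A cohort enters the model (by default entirely in the stable state), moves
between states once per annual cycle according to a row-stochastic
transition matrix with death absorbing, and accumulates per-state costs
and utilities.  State membership for accumulation is half-cycle corrected:
the membership credited to cycle t is the trapezoidal average of the
occupancies at the start and end of the cycle.  Discounting uses the
first-cycle-undiscounted convention, factor ``1/(1+r)^(t-1)``; the one-off
intervention cost is charged at cycle 1 and is neither discounted nor
half-cycle corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ModelDefinitionError

STATES: tuple[str, ...] = ("stable", "remission", "relapse", "death")

_ROW_TOL_BUILD = 1e-12   # row-sum tolerance when a matrix is constructed
_ROW_TOL_ITER = 1e-10    # occupancy-sum tolerance during iteration


@dataclass(frozen=True)
class TransitionMatrix:
    """Annual transition probabilities over (stable, remission, relapse, death).

    Rows sum to 1 within 1e-12; death is absorbing; in the base model the
    only route to death is through relapse (stable->death and
    remission->death are zero), but the container accepts any valid
    stochastic matrix so perturbed scenarios remain representable.
    """

    p: np.ndarray
    states: tuple[str, ...] = STATES

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        n = len(self.states)
        if p.shape != (n, n):
            raise ModelDefinitionError(f"matrix shape {p.shape}, expected {(n, n)}")
        if np.any(p < -_ROW_TOL_BUILD) or np.any(p > 1 + _ROW_TOL_BUILD):
            raise ModelDefinitionError("transition probabilities outside [0, 1]")
        row_sums = p.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > _ROW_TOL_BUILD):
            raise ModelDefinitionError(
                f"rows must sum to 1 within {_ROW_TOL_BUILD}; got {row_sums}"
            )
        death = self.states.index("death")
        expected = np.zeros(n)
        expected[death] = 1.0
        if not np.array_equal(p[death], expected):
            raise ModelDefinitionError("death row must be the identity (absorbing)")

    @classmethod
    def from_derived(cls, derived) -> "TransitionMatrix":
        """Build the 4x4 matrix from per-arm derived probabilities."""
        d = derived
        p = np.array([
            [d.p_ss, d.p_sr, d.p_sp, 0.0],
            [0.0, d.p_rr, d.p_rp, 0.0],
            [0.0, 0.0, d.p_pp, d.p_pd],
            [0.0, 0.0, 0.0, 1.0],
        ])
        return cls(p=p)


def _default_init() -> np.ndarray:
    init = np.zeros(len(STATES))
    init[STATES.index("stable")] = 1.0
    return init


@dataclass
class ModelSpec:
    """Full definition of one strategy arm's cohort model."""

    arm_label: str
    matrix: TransitionMatrix
    init: np.ndarray = field(default_factory=_default_init)
    n_cycles: int = 5
    cycle_length: float = 1.0          # years per cycle
    discount_rate: float = 0.05        # per year
    half_cycle: bool = True
    utilities: Mapping[str, float] = field(
        default_factory=lambda: {"stable": 0.74, "remission": 0.85,
                                 "relapse": 0.5, "death": 0.0})
    state_costs: Mapping[str, float] = field(
        default_factory=lambda: {s: 0.0 for s in STATES})
    intervention_cost: float = 0.0

    def __post_init__(self) -> None:
        self.init = np.asarray(self.init, dtype=float)
        if self.init.shape != (len(STATES),) or abs(self.init.sum() - 1.0) > _ROW_TOL_ITER:
            raise ModelDefinitionError("init must be a distribution over the 4 states")
        if self.n_cycles < 1:
            raise ModelDefinitionError("n_cycles must be >= 1")
        if self.discount_rate < 0:
            raise ModelDefinitionError("discount_rate must be >= 0")


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy of the cohort.

    ``occupancy`` has n_cycles+1 rows (cycle boundaries 0..n);
    ``corrected_occupancy`` has n_cycles rows, the trapezoidal average of
    adjacent boundaries, used when the half-cycle correction is on.
    """

    occupancy: np.ndarray
    corrected_occupancy: np.ndarray
    states: tuple[str, ...] = STATES


def run_cohort(spec: ModelSpec) -> CohortTrace:
    """Iterate the cohort: occupancy[t] = occupancy[t-1] @ P."""
    P = spec.matrix.p
    occ = np.empty((spec.n_cycles + 1, len(spec.matrix.states)))
    occ[0] = spec.init
    for t in range(1, spec.n_cycles + 1):
        occ[t] = occ[t - 1] @ P
        if abs(occ[t].sum() - 1.0) > _ROW_TOL_ITER:
            raise ModelDefinitionError(
                f"occupancy mass not conserved at cycle {t}: sum={occ[t].sum()}"
            )
    return CohortTrace(occupancy=occ,
                       corrected_occupancy=half_cycle_correct(occ),
                       states=spec.matrix.states)


def half_cycle_correct(occupancy: np.ndarray | CohortTrace) -> np.ndarray:
    """Trapezoidal per-cycle membership: mean of adjacent boundary occupancies."""
    occ = occupancy.occupancy if isinstance(occupancy, CohortTrace) else np.asarray(occupancy)
    return 0.5 * (occ[:-1] + occ[1:])


def discount_factor(rate: float, t: int | np.ndarray) -> float | np.ndarray:
    """Discount factor for cycle t (1-based); cycle 1 is undiscounted."""
    return (1.0 + rate) ** -(np.asarray(t) - 1.0)


def accumulate(
    trace: CohortTrace,
    per_state_values: Mapping[str, float],
    rate: float = 0.0,
    one_off: float = 0.0,
    half_cycle: bool = True,
    cycle_length: float = 1.0,
) -> float:
    """Total discounted value over the horizon.

    Per cycle t = 1..n: discount_factor(rate, t) * cycle_length *
    sum_state membership[t, state] * value[state], using half-cycle
    corrected memberships when ``half_cycle`` is on (end-of-cycle
    occupancies otherwise), plus ``one_off`` at t=1 undiscounted.
    Serves both QALYs (utilities, one_off=0) and costs (state costs,
    one_off=intervention cost).
    """
    missing = [s for s in trace.states if s not in per_state_values]
    if missing:
        raise ModelDefinitionError(f"missing per-state values for: {missing}")
    values = np.array([per_state_values[s] for s in trace.states])
    membership = trace.corrected_occupancy if half_cycle else trace.occupancy[1:]
    n = membership.shape[0]
    factors = discount_factor(rate, np.arange(1, n + 1))
    return float((factors * (membership @ values)).sum() * cycle_length + one_off)


@dataclass(frozen=True)
class StrategyOutcome:
    """Discounted totals for one strategy arm."""

    label: str
    cost: float
    effect: float


def evaluate(spec: ModelSpec) -> StrategyOutcome:
    """Run the cohort and accumulate discounted cost and QALY totals."""
    trace = run_cohort(spec)
    cost = accumulate(trace, spec.state_costs, rate=spec.discount_rate,
                      one_off=spec.intervention_cost,
                      half_cycle=spec.half_cycle, cycle_length=spec.cycle_length)
    effect = accumulate(trace, spec.utilities, rate=spec.discount_rate,
                        one_off=0.0, half_cycle=spec.half_cycle,
                        cycle_length=spec.cycle_length)
    return StrategyOutcome(label=spec.arm_label, cost=cost, effect=effect)


def trace_frame(spec: ModelSpec, trace: CohortTrace | None = None) -> pd.DataFrame:
    """Cycle-by-cycle export: occupancies, discount factor, cycle cost/QALY."""
    if trace is None:
        trace = run_cohort(spec)
    states = trace.states
    costs = np.array([spec.state_costs[s] for s in states])
    utils = np.array([spec.utilities[s] for s in states])
    rows = [{
        "cycle": 0,
        **{f"occ_{s}": trace.occupancy[0, i] for i, s in enumerate(states)},
        **{f"corrected_{s}": np.nan for s in states},
        "discount_factor": np.nan, "cycle_cost": np.nan, "cycle_qaly": np.nan,
    }]
    for t in range(1, trace.occupancy.shape[0]):
        member = (trace.corrected_occupancy[t - 1] if spec.half_cycle
                  else trace.occupancy[t])
        f = float(discount_factor(spec.discount_rate, t))
        row = {
            "cycle": t,
            **{f"occ_{s}": trace.occupancy[t, i] for i, s in enumerate(states)},
            **{f"corrected_{s}": trace.corrected_occupancy[t - 1, i]
               for i, s in enumerate(states)},
            "discount_factor": f,
            "cycle_cost": f * spec.cycle_length * float(member @ costs)
            + (spec.intervention_cost if t == 1 else 0.0),
            "cycle_qaly": f * spec.cycle_length * float(member @ utils),
        }
        rows.append(row)
    return pd.DataFrame(rows)
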