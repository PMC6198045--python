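"""Cohort and individual-level simulation engines.

Both engines walk the same per-cycle transition matrices and share one
accrual convention (cycle-start accrual, discounted at ``(1+r)^-t``,
no half-cycle correction by default):

* drug acquisition and BPH-management costs accrue to time spent in the
  BPH state (patients beyond BPH receive follow-up "medical
  intervention" pharmacotherapy instead of study drug);
* the AUR episode cost and the TURP procedure cost are charged per
  event, i.e. per cycle spent in those one-cycle tunnel states (a
  patient dying of surgical complications still incurs the procedure
  cost);
* the annual medical-intervention cost accrues to occupancy of that
  state; an optional one-off follow-up cost is charged on first entry
  into recovery;
* QALYs apply each state's utility to the time spent in it; death
  contributes nothing from the death cycle onward.

Episode counts are undiscounted: BPH is person-years in state, AUR and
TURP are event counts, deaths are cumulative mortality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .markov import build_expanded_matrix
from .parameters import ModelParameters, validate_parameters
from .states import Arm, ExpandedState as X, N_STATES, StateId

__all__ = ["SimulationResult", "CohortTrace", "discount_factor", "run_cohort",
           "run_microsimulation", "accumulate_outcomes", "event_log_from_history"]

_OCC_TOL = 1e-9

#: expanded -> public index vector
_TO_PUBLIC = np.array([
    StateId.BPH, StateId.AUR, StateId.TURP, StateId.REPEAT_TURP,
    StateId.MEDICAL_INTERVENTION, StateId.MEDICAL_INTERVENTION,
    StateId.RECOVERY, StateId.RECOVERY, StateId.DEATH,
], dtype=np.int64)


@dataclass(frozen=True)
class SimulationResult:
    """Discounted per-patient totals and undiscounted episode counts."""

    arm: Arm
    horizon_years: int
    engine: str                       # "cohort" | "microsim"
    total_cost: float                 # discounted US$ per patient
    cost_breakdown: dict              # {drug, bph, aur, turp, medical, recovery_followup}
    total_qaly: float                 # discounted QALYs per patient
    episodes: dict                    # {bph_years, aur_episodes, turp_procedures, deaths}
    n_patients: Optional[int] = None  # microsimulation sample size

    def __post_init__(self):
        if abs(sum(self.cost_breakdown.values()) - self.total_cost) > 1e-6:
            raise ValueError("cost categories do not sum to the total")


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle public-state occupancy and discounted increments."""

    occupancy: np.ndarray       # (T+1, 7), rows sum to 1
    cost_increments: np.ndarray  # (T,)
    qaly_increments: np.ndarray  # (T,)


def discount_factor(cycle_index: float, annual_rate: float,
                    cycles_per_year: int = 1) -> float:
    """Discount factor ``(1+rate)^(-t)`` with t in years; cycle 0 is
    undiscounted."""
    if annual_rate < 0:
        raise ValueError("discount rate must be >= 0")
    if cycle_index < 0:
        raise ValueError("cycle index must be >= 0")
    return float((1.0 + annual_rate) ** (-(cycle_index / cycles_per_year)))


def _arm_drug_cost(params: ModelParameters, arm: Arm) -> float:
    if arm == Arm.COMBINATION:
        return params.costs.annual_drug_combination
    return params.costs.annual_drug_tamsulosin


def _cycle_weights(n_cycles: int, half_cycle_correction: bool) -> np.ndarray:
    """Accrual weight per cycle index 0..T (index T only used under HCC)."""
    w = np.ones(n_cycles + 1)
    w[-1] = 0.0
    if half_cycle_correction:
        w[0] = 0.5
        w[-1] = 0.5
    return w


def _require_valid(params: ModelParameters) -> None:
    rep = validate_parameters(params)
    if not rep.ok:
        raise ValueError(f"invalid parameters:\n{rep}")


def _accrue(params: ModelParameters, arm: Arm, occupancy: np.ndarray,
            rec_inflow: np.ndarray, engine: str,
            n_patients: Optional[int] = None):
    """Shared accrual: occupancy is (T+1, 9) expected expanded-state
    occupancy per patient; rec_inflow[t] is first-entry mass into
    recovery at cycle t."""
    s, c, u = params.settings, params.costs, params.utilities
    cpy = s.cycles_per_year
    T = occupancy.shape[0] - 1
    disc = np.array([discount_factor(t, s.discount_rate, cpy) for t in range(T + 1)])
    w = _cycle_weights(T, s.half_cycle_correction)

    occ_bph = occupancy[:, X.BPH]
    occ_aur = occupancy[:, X.AUR]
    occ_turp = occupancy[:, X.TURP] + occupancy[:, X.REPEAT_TURP]
    occ_med = occupancy[:, X.MEDICAL_1] + occupancy[:, X.MEDICAL_2]
    occ_rec = occupancy[:, X.RECOVERY_1] + occupancy[:, X.RECOVERY_2]

    dw = disc * w
    breakdown = {
        "drug": float(_arm_drug_cost(params, arm) / cpy * occ_bph @ dw),
        "bph": float(c.annual_bph_management / cpy * occ_bph @ dw),
        "aur": float(c.aur_episode * occ_aur @ dw),
        "turp": float(c.turp_procedure * occ_turp @ dw),
        "medical": float(c.annual_medical_intervention / cpy * occ_med @ dw),
        "recovery_followup": float(c.recovery_followup * rec_inflow @ disc),
    }

    per_state_utility = (
        occ_bph * u.u_bph + occ_aur * u.u_aur + occ_turp * u.u_turp
        + occ_med * u.u_medical + occ_rec * u.u_recovery
    )
    qaly_inc = per_state_utility / cpy * dw
    cost_inc = (
        (_arm_drug_cost(params, arm) + c.annual_bph_management) / cpy * occ_bph
        + c.aur_episode * occ_aur + c.turp_procedure * occ_turp
        + c.annual_medical_intervention / cpy * occ_med
    ) * dw + c.recovery_followup * rec_inflow * disc

    episodes = {
        "bph_years": float((occ_bph * w).sum() / cpy),
        "aur_episodes": float((occ_aur * w).sum()),
        "turp_procedures": float((occ_turp * w).sum()),
        "deaths": float(occupancy[-1, X.DEATH]),
    }

    result = SimulationResult(
        arm=arm, horizon_years=s.horizon_years, engine=engine,
        total_cost=sum(breakdown.values()), cost_breakdown=breakdown,
        total_qaly=float(qaly_inc.sum()), episodes=episodes,
        n_patients=n_patients,
    )
    trace = CohortTrace(
        occupancy=_aggregate_public(occupancy),
        cost_increments=cost_inc[:-1],
        qaly_increments=qaly_inc[:-1],
    )
    return result, trace


def _aggregate_public(occupancy: np.ndarray) -> np.ndarray:
    pub = np.zeros((occupancy.shape[0], N_STATES))
    np.add.at(pub.T, _TO_PUBLIC, occupancy.T)
    return pub


def run_cohort(params: ModelParameters, arm: Arm):
    """Deterministic cohort trace: expected occupancy propagated by
    matrix multiplication.  Returns ``(SimulationResult, CohortTrace)``."""
    _require_valid(params)
    s = params.settings
    T = s.horizon_years * s.cycles_per_year
    occ = np.zeros((T + 1, len(X)))
    occ[0, X.BPH] = 1.0
    rec_inflow = np.zeros(T + 1)
    for t in range(T):
        age = s.cohort_start_age + t / s.cycles_per_year
        m = build_expanded_matrix(params, arm, age)
        nxt = occ[t] @ m
        rec_inflow[t + 1] = (
            occ[t, X.TURP] * m[X.TURP, X.RECOVERY_1]
            + occ[t, X.REPEAT_TURP] * m[X.REPEAT_TURP, X.RECOVERY_2]
        )
        if (nxt < -_OCC_TOL).any() or abs(nxt.sum() - 1.0) > 1e-9:
            raise RuntimeError("occupancy propagation left the simplex")
        occ[t + 1] = np.clip(nxt, 0.0, None)
    return _accrue(params, arm, occ, rec_inflow, engine="cohort")


def run_microsimulation(params: ModelParameters, arm: Arm,
                        n_patients: Optional[int] = None,
                        seed: Optional[int] = None):
    """First-order Monte Carlo: each patient walks the chain by sampled
    transitions.  Identical seeds give identical output.

    Returns ``(SimulationResult, history)`` where ``history`` is an
    ``(n_patients, T+1)`` integer array of public states per cycle — the
    per-patient event log consumed by :func:`accumulate_outcomes`.
    """
    _require_valid(params)
    if seed is None:
        raise ValueError("microsimulation requires an explicit seed for reproducibility")
    s = params.settings
    n = n_patients if n_patients is not None else s.n_microsim_patients
    if n < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    T = s.horizon_years * s.cycles_per_year

    states = np.full(n, int(X.BPH), dtype=np.int64)
    history = np.empty((n, T + 1), dtype=np.int64)
    history[:, 0] = states
    for t in range(T):
        age = s.cohort_start_age + t / s.cycles_per_year
        m = build_expanded_matrix(params, arm, age)
        cum = np.cumsum(m, axis=1)
        cum[:, -1] = 1.0  # guard against round-off
        u = rng.random(n)
        states = (u[:, None] < cum[states]).argmax(axis=1)
        history[:, t + 1] = states

    public_history = _TO_PUBLIC[history]
    result = accumulate_outcomes(public_history, params, arm)
    return result, public_history


def accumulate_outcomes(history: np.ndarray, params: ModelParameters,
                        arm: Arm) -> SimulationResult:
    """Recompute a :class:`SimulationResult` from a stored event log.

    ``history`` holds public state ids, one row per patient, one column
    per cycle boundary 0..T.  Accumulation is idempotent: re-running it
    on the same log reproduces the same result.
    """
    history = np.asarray(history)
    if history.ndim != 2:
        raise ValueError("history must be (n_patients, n_cycles+1)")
    s = params.settings
    T = s.horizon_years * s.cycles_per_year
    if history.shape[1] != T + 1:
        raise ValueError(
            f"event log spans {history.shape[1] - 1} cycles but settings give {T}")
    if history.min() < 0 or history.max() >= N_STATES:
        raise ValueError("event log contains out-of-range state ids")
    n = history.shape[0]

    # empirical expanded occupancy; the TURP-count split is irrelevant to
    # accrual (both medical and both recovery sub-states share costs and
    # utilities), so public states map onto the first-TURP sub-states.
    pub_to_exp = {
        StateId.BPH: X.BPH, StateId.AUR: X.AUR, StateId.TURP: X.TURP,
        StateId.REPEAT_TURP: X.REPEAT_TURP,
        StateId.MEDICAL_INTERVENTION: X.MEDICAL_1,
        StateId.RECOVERY: X.RECOVERY_1, StateId.DEATH: X.DEATH,
    }
    occupancy = np.zeros((T + 1, len(X)))
    for pub, exp in pub_to_exp.items():
        occupancy[:, exp] = (history == int(pub)).mean(axis=0)

    # first entries into recovery per cycle
    is_rec = history == int(StateId.RECOVERY)
    first_entry = np.zeros(T + 1)
    seen = np.zeros(n, dtype=bool)
    for t in range(T + 1):
        new = is_rec[:, t] & ~seen
        first_entry[t] = new.mean()
        seen |= new

    result, _ = _accrue(params, arm, occupancy, first_entry,
                        engine="microsim", n_patients=n)
    return result


def event_log_from_history(history: np.ndarray):
    """Per-patient list of ``(cycle, StateId)`` state entries."""
    logs = []
    for row in np.asarray(history):
        entries = [(0, StateId(int(row[0])))]
        for t in range(1, len(row)):
            if row[t] != row[t - 1]:
                entries.append((t, StateId(int(row[t]))))
        logs.append(entries)
    return logs
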