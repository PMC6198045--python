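"""Transition-matrix construction.

Each cycle's matrix is assembled from the per-cycle disease transitions,
the arm's treatment effect (relative risk reductions on the BPH->AUR and
BPH->TURP transitions under combination therapy), and age-specific
background mortality combined as a competing risk: state-specific
transitions are scaled by the cycle's survival probability and the death
entry receives the complement of the product of survival from background
and state-specific (surgical) mortality.

Structural rules encoded here:

* AUR is a one-cycle tunnel: surviving patients either proceed to TURP
  (probability ``p_aur_to_turp``) or return to BPH.
* TURP and repeat TURP are one-cycle tunnels; 30-day surgical mortality
  applies in the procedure cycle, survivors split between repeat
  surgery, medical management and recovery.
* Repeat-TURP survivors cannot undergo a third procedure: they move to
  medical management or recovery only.
* Death is absorbing.

Rows whose printed exits do not sum to one (BPH, recovery, medical)
keep their leftover mass in the self-loop by default (``residual``
mode); ``printed`` mode instead pins the self-loop at the printed stay
probability and renormalises the explicit exits over the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ModelParameters
from .states import (
    EXPANDED_TO_PUBLIC,
    N_EXPANDED,
    N_STATES,
    Arm,
    ExpandedState as X,
    StateId,
)

__all__ = ["TransitionMatrix", "apply_efficacy", "combine_with_background_mortality",
           "build_transition_matrix", "build_expanded_matrix", "per_cycle_probability"]

ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 7x7 matrix over the public state space.

    This aggregate view is memoryless: it cannot express the
    at-most-two-TURPs history rule, which the engines enforce on an
    internal 9-state expansion (see :func:`build_expanded_matrix`).
    """

    probs: np.ndarray          # (7, 7)
    cycle: int
    arm: Arm

    def __post_init__(self):
        p = self.probs
        if p.shape != (N_STATES, N_STATES):
            raise ValueError("transition matrix must be 7x7")
        if (p < -ROW_SUM_TOL).any():
            raise ValueError("negative transition probability")
        if not np.allclose(p.sum(axis=1), 1.0, atol=ROW_SUM_TOL):
            raise ValueError("transition matrix rows must sum to 1")


def apply_efficacy(base_prob: float, rrr: float) -> float:
    """Apply a relative risk reduction to a monotherapy transition:
    returns ``base_prob * (1 - rrr)``."""
    if not 0.0 <= base_prob <= 1.0:
        raise ValueError(f"base_prob {base_prob} outside [0, 1]")
    if not 0.0 <= rrr <= 1.0:
        raise ValueError(f"rrr {rrr} outside [0, 1]")
    return base_prob * (1.0 - rrr)


def combine_with_background_mortality(
    exit_probs, p_bg_death: float, state_mortality: float = 0.0
):
    """Competing-risk combination of a row's exits with mortality.

    ``exit_probs`` are the state-specific destination probabilities
    (conditional on surviving the cycle); they are scaled by the joint
    survival ``(1 - state_mortality) * (1 - p_bg_death)`` and the death
    entry receives its complement.

    Returns ``(scaled_exits, p_death_total)``.
    """
    exits = np.asarray(exit_probs, dtype=float)
    if not 0.0 <= p_bg_death <= 1.0:
        raise ValueError(f"background mortality {p_bg_death} outside [0, 1]")
    if not 0.0 <= state_mortality <= 1.0:
        raise ValueError(f"state mortality {state_mortality} outside [0, 1]")
    total = float(exits.sum())
    if total > 1.0 + ROW_SUM_TOL:
        raise ValueError(f"exit probabilities sum to {total:.6g} > 1")
    survival = (1.0 - state_mortality) * (1.0 - p_bg_death)
    return exits * survival, 1.0 - survival


def per_cycle_probability(p: float, timescale: str, cycles_per_year: int) -> float:
    """Convert a printed per-period probability to the model's per-cycle
    scale.  Under the default annual reading with annual cycles this is
    the identity; under the monthly reading p_cycle = 1-(1-p_m)^(12/cpy)."""
    if timescale == "annual":
        months_per_cycle = 12.0 / cycles_per_year
        if months_per_cycle == 12.0:
            return p
        return 1.0 - (1.0 - p) ** (months_per_cycle / 12.0)
    if timescale == "monthly":
        return 1.0 - (1.0 - p) ** (12.0 / cycles_per_year)
    raise ValueError(f"unknown probability timescale {timescale!r}")


def _cycle_rates(params: ModelParameters):
    """Per-cycle BPH/recovery/medical hazards on the model timescale.

    Event-conditional probabilities (AUR->TURP, surgical mortality, the
    post-TURP split) are per episode, not per unit time, and are never
    rescaled.
    """
    tr = params.transitions
    ts = params.settings.probability_timescale
    cpy = params.settings.cycles_per_year
    conv = lambda p: per_cycle_probability(p, ts, cpy)
    return {
        "bph_to_turp": conv(tr.p_bph_to_turp),
        "bph_to_aur": conv(tr.p_bph_to_aur),
        "recovery_to_medical": conv(tr.p_recovery_to_medical),
        "medical_to_second_turp": conv(tr.p_medical_to_second_turp),
        "medical_to_aur": conv(tr.p_medical_to_aur),
    }


def _background_cycle_prob(params: ModelParameters, cohort_age: float) -> float:
    lt = params.life_table
    if lt is None:
        return 0.0
    q_annual = lt.prob_at(cohort_age)
    cpy = params.settings.cycles_per_year
    if cpy == 1:
        return q_annual
    return 1.0 - (1.0 - q_annual) ** (1.0 / cpy)


def _residual_row(row: np.ndarray, self_idx: int, printed_stay, mode: str,
                  exit_idx, p_death_total: float, row_name: str) -> None:
    """Assign the row's leftover mass.

    residual mode: leftover -> self-loop.  printed mode: self-loop pinned
    at printed_stay * survival, explicit exits rescaled to fill the rest.
    """
    leftover = 1.0 - row.sum()
    if leftover < -ROW_SUM_TOL:
        raise ValueError(f"{row_name} row exits exceed 1 (by {-leftover:.3g})")
    if mode == "residual" or printed_stay is None:
        row[self_idx] += max(leftover, 0.0)
        return
    survival = 1.0 - p_death_total
    stay = printed_stay * survival
    target_exit_mass = 1.0 - p_death_total - stay
    if target_exit_mass < -ROW_SUM_TOL:
        raise ValueError(f"{row_name} printed stay probability exceeds survival mass")
    current = sum(row[i] for i in exit_idx)
    if current > 0:
        scale = max(target_exit_mass, 0.0) / current
        for i in exit_idx:
            row[i] *= scale
        row[self_idx] = stay
    else:
        row[self_idx] = stay + max(target_exit_mass, 0.0)


def build_expanded_matrix(params: ModelParameters, arm: Arm, cohort_age: float) -> np.ndarray:
    """9x9 row-stochastic matrix on the engine state space for one cycle."""
    tr = params.transitions
    mode = params.settings.residual_mode
    rates = _cycle_rates(params)
    bg = _background_cycle_prob(params, cohort_age)

    p_turp = rates["bph_to_turp"]
    p_aur = rates["bph_to_aur"]
    if arm == Arm.COMBINATION:
        p_turp = apply_efficacy(p_turp, params.efficacy.rrr_turp)
        p_aur = apply_efficacy(p_aur, params.efficacy.rrr_aur)

    m = np.zeros((N_EXPANDED, N_EXPANDED))

    # BPH
    exits, death = combine_with_background_mortality([p_turp, p_aur], bg)
    row = m[X.BPH]
    row[X.TURP], row[X.AUR] = exits
    row[X.DEATH] = death
    _residual_row(row, X.BPH, tr.p_bph_stay, mode, (X.TURP, X.AUR), death, "BPH")

    # AUR tunnel: survivors to TURP or back to BPH
    exits, death = combine_with_background_mortality(
        [tr.p_aur_to_turp, 1.0 - tr.p_aur_to_turp], bg)
    m[X.AUR, X.TURP], m[X.AUR, X.BPH] = exits
    m[X.AUR, X.DEATH] = death

    # TURP tunnel: surgical mortality, survivors split repeat/medical/recovery
    rec = 1.0 - tr.p_turp_to_repeat - tr.p_turp_to_medical
    exits, death = combine_with_background_mortality(
        [tr.p_turp_to_repeat, tr.p_turp_to_medical, rec], bg,
        state_mortality=tr.p_turp_30day_mortality)
    m[X.TURP, X.REPEAT_TURP], m[X.TURP, X.MEDICAL_1], m[X.TURP, X.RECOVERY_1] = exits
    m[X.TURP, X.DEATH] = death

    # repeat TURP tunnel: no third procedure possible afterwards
    rec2 = 1.0 - tr.p_repeat_to_medical
    exits, death = combine_with_background_mortality(
        [tr.p_repeat_to_medical, rec2], bg, state_mortality=tr.p_repeat_turp_mortality)
    m[X.REPEAT_TURP, X.MEDICAL_2], m[X.REPEAT_TURP, X.RECOVERY_2] = exits
    m[X.REPEAT_TURP, X.DEATH] = death

    # medical management after one TURP: may need the second procedure
    exits, death = combine_with_background_mortality(
        [rates["medical_to_second_turp"], rates["medical_to_aur"]], bg)
    row = m[X.MEDICAL_1]
    row[X.REPEAT_TURP], row[X.AUR] = exits
    row[X.DEATH] = death
    _residual_row(row, X.MEDICAL_1, tr.p_medical_stay, mode,
                  (X.REPEAT_TURP, X.AUR), death, "MEDICAL_INTERVENTION")

    # medical management after two TURPs: surgery foreclosed
    exits, death = combine_with_background_mortality([rates["medical_to_aur"]], bg)
    row = m[X.MEDICAL_2]
    row[X.AUR] = exits[0]
    row[X.DEATH] = death
    row[X.MEDICAL_2] = 1.0 - row.sum()

    # recovery, by prior procedure count
    for rec_state, med_state in ((X.RECOVERY_1, X.MEDICAL_1), (X.RECOVERY_2, X.MEDICAL_2)):
        exits, death = combine_with_background_mortality([rates["recovery_to_medical"]], bg)
        row = m[rec_state]
        row[med_state] = exits[0]
        row[X.DEATH] = death
        _residual_row(row, rec_state, tr.p_recovery_stay, mode,
                      (med_state,), death, "RECOVERY")

    m[X.DEATH, X.DEATH] = 1.0

    sums = m.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=ROW_SUM_TOL):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(f"row {X(bad).name} sums to {sums[bad]!r}")
    return m


def build_transition_matrix(params: ModelParameters, arm: Arm, cohort_age: float,
                            cycle: int = 0) -> TransitionMatrix:
    """Public 7x7 per-cycle matrix (aggregated over the TURP-count split).

    Aggregation weights medical/recovery sub-states equally; exact for
    every row except that MEDICAL -> REPEAT_TURP reflects the
    first-procedure pathway (the memoryless approximation).
    """
    me = build_expanded_matrix(params, arm, cohort_age)
    m = np.zeros((N_STATES, N_STATES))
    # representative sub-state per public state (first-TURP pathway)
    rep = {
        StateId.BPH: X.BPH, StateId.AUR: X.AUR, StateId.TURP: X.TURP,
        StateId.REPEAT_TURP: X.REPEAT_TURP,
        StateId.MEDICAL_INTERVENTION: X.MEDICAL_1,
        StateId.RECOVERY: X.RECOVERY_1, StateId.DEATH: X.DEATH,
    }
    for pub, sub in rep.items():
        for j in range(N_EXPANDED):
            m[pub, EXPANDED_TO_PUBLIC[X(j)]] += me[sub, j]
    return TransitionMatrix(probs=m, cycle=cycle, arm=arm)
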