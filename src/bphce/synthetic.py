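"""Synthetic fixtures: toy chains with closed-form solutions and random
valid parameter sets.

The toy models are degenerate configurations of the real model whose
discounted outcomes have geometric-series closed forms, computed here
independently of the simulation engines (oracle-first: the engine is
tested against these values, never against itself).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .lifetable import constant_life_table
from .parameters import (
    CostParameters,
    EfficacyParameters,
    ModelParameters,
    TransitionParameters,
    UtilityParameters,
    base_case_parameters,
    get_field,
    set_field,
    validate_parameters,
)

__all__ = ["ToyModelSpec", "closed_form_occupancy", "closed_form_tunnel_qaly",
           "make_toy_model", "generate_random_parameters"]


@dataclass(frozen=True)
class ToyModelSpec:
    """A 2- or 3-state chain with an analytic solution.

    2 states: start state with stay probability ``p_stay``, remainder to
    death.  3 states: the leaving mass instead passes through a
    one-cycle surgical tunnel into an absorbing recovery state.
    """

    n_states: int = 2            # 2 or 3
    p_stay: float = 0.9
    utility: float = 1.0         # start-state utility
    tunnel_utility: float = 0.25  # 3-state only
    recovery_utility: float = 1.0  # 3-state only
    annual_cost: float = 0.0     # start-state per-cycle cost
    horizon_years: int = 4
    discount_rate: float = 0.0

    def __post_init__(self):
        if self.n_states not in (2, 3):
            raise ValueError("toy models have 2 or 3 states")
        if not 0.0 <= self.p_stay <= 1.0:
            raise ValueError("p_stay must be in [0, 1]")


def closed_form_occupancy(p_stay: float, rate: float, horizon_cycles: int) -> float:
    """Expected discounted cycles spent in the start state of a
    stay-or-leave chain: the geometric sum
    ``sum_{t=0}^{H-1} (p_stay / (1+rate))^t`` in closed form."""
    if not 0.0 <= p_stay <= 1.0:
        raise ValueError("p_stay must be in [0, 1]")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if horizon_cycles < 1:
        raise ValueError("horizon must be >= 1 cycle")
    q = p_stay / (1.0 + rate)
    if q == 1.0:
        return float(horizon_cycles)
    return float((1.0 - q**horizon_cycles) / (1.0 - q))


def closed_form_tunnel_qaly(spec: ToyModelSpec) -> float:
    """Discounted QALYs of the 3-state toy, by direct summation of the
    occupancy recursions (independent of the matrix engine)."""
    p, v = spec.p_stay, 1.0 / (1.0 + spec.discount_rate)
    leave = 1.0 - p
    occ_start, occ_tunnel, occ_rec = 1.0, 0.0, 0.0
    total = 0.0
    for t in range(spec.horizon_years):
        total += (v**t) * (occ_start * spec.utility
                           + occ_tunnel * spec.tunnel_utility
                           + occ_rec * spec.recovery_utility)
        occ_rec += occ_tunnel
        occ_tunnel = occ_start * leave
        occ_start *= p
    return total


def make_toy_model(spec: ToyModelSpec) -> ModelParameters:
    """Realise a toy spec as a degenerate :class:`ModelParameters`.

    The start state is BPH.  For the 2-state toy all leaving mass is
    background mortality (a flat life table at ``1 - p_stay``); for the
    3-state toy it is routed BPH -> TURP -> recovery with all surgical
    branches switched off.
    """
    base = base_case_parameters()
    settings = replace(
        base.settings,
        discount_rate=spec.discount_rate,
        horizon_years=spec.horizon_years,
        cycles_per_year=1,
        probability_timescale="annual",
    )
    costs = CostParameters(0.0, 0.0, spec.annual_cost, 0.0, 0.0, 0.0, 0.0)
    if spec.n_states == 2:
        transitions = TransitionParameters(
            p_bph_to_turp=0.0, p_bph_to_aur=0.0,
            p_turp_30day_mortality=0.0, p_turp_to_medical=0.0,
            p_turp_to_repeat=0.0, p_recovery_to_medical=0.0,
            p_medical_to_second_turp=0.0, p_medical_to_aur=0.0,
            p_repeat_to_medical=0.0)
        life_table = constant_life_table(settings.cohort_start_age, 1.0 - spec.p_stay)
        utilities = UtilityParameters(u_bph=spec.utility, u_aur=0.0, u_turp=0.0,
                                      u_medical=0.0, u_recovery=0.0)
    else:
        transitions = TransitionParameters(
            p_bph_to_turp=1.0 - spec.p_stay, p_bph_to_aur=0.0,
            p_turp_30day_mortality=0.0, p_turp_to_medical=0.0,
            p_turp_to_repeat=0.0, p_recovery_to_medical=0.0,
            p_medical_to_second_turp=0.0, p_medical_to_aur=0.0,
            p_repeat_to_medical=0.0)
        life_table = constant_life_table(settings.cohort_start_age, 0.0)
        utilities = UtilityParameters(u_bph=spec.utility, u_aur=0.0,
                                      u_turp=spec.tunnel_utility,
                                      u_medical=0.0,
                                      u_recovery=spec.recovery_utility)
    params = ModelParameters(
        transitions=transitions,
        efficacy=EfficacyParameters(rrr_aur=0.0, rrr_turp=0.0),
        costs=costs, utilities=utilities, settings=settings,
        life_table=life_table,
        psa_distributions=(), owsa_ranges=(),
    )
    rep = validate_parameters(params)
    if not rep.ok:
        raise ValueError(f"toy spec has no valid realisation:\n{rep}")
    return params


def generate_random_parameters(seed: int, n: int,
                               base: Optional[ModelParameters] = None):
    """``n`` random parameter sets drawn uniformly within the published
    uncertainty ranges (property-test input generator).

    Every draw passes validation; fields without a published range stay
    at base.  Reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if base is None:
        base = base_case_parameters()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        draw = base
        for r in base.owsa_ranges:
            draw = set_field(draw, r.target, float(rng.uniform(r.low, r.high)))
        rep = validate_parameters(draw)
        if not rep.ok:  # ranges are jointly sub-stochastic, so this cannot trip
            raise RuntimeError(f"random draw failed validation:\n{rep}")
        out.append(draw)
    return out
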